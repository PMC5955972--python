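# Methods

`denatens` characterizes heat-denatured ensembles of small protein monomers
from MD-style coordinate trajectories. It was built around the analysis of
CutA1 stability mutants (~112-residue monomers, microsecond trajectories
sampled every 0.4 ns), but every operation is generic over the internal
`Topology`/`Trajectory` model. This note records the models, conventions,
parameters and deliberate design choices.

## Salt bridges

A salt bridge is operationalized purely geometrically: the distance between
the charge-bearing side-chain carbon of a basic residue and that of an
acidic residue is below a cutoff.

* Criterion atoms: Lys → Cε, Arg → Cδ, Glu → Cδ, Asp → Cγ. The Arg atom is
  read distributively from the "Cε or Cδ of (Lys or Arg)" convention; Cζ is
  available by configuring `CriterionAtomMap.positive["ARG"] = "CZ"`.
* Cutoff: 0.6 nm, strict inequality (exactly 0.6 nm does not count). Ties
  are measure-zero but deterministic.
* The C-terminal carboxyl carbon (backbone C of the last residue) is an
  extra negative site; the N-terminal backbone nitrogen can be enabled as a
  positive site. Histidine is not treated as charged. Intra-residue pairs
  are excluded; sequence-adjacent (i, i±1) pairs are not.
* Occupancy of a pair = 100 × (frames in window below cutoff)/(frames in
  window). A residue's occupancy summed over partners may exceed 100% when
  it bridges several partners simultaneously. An optional prefilter (the
  `t = 0.4 nm` reporting convention) omits pairs whose minimum distance over
  the whole trajectory never drops below the prefilter; it is purely a
  reporting filter and never alters retained values.
* Count series: per time bin (default 0.4 ns, the trajectory reporting
  granularity), the mean number of distinct partners below the cutoff. On
  identical frames the series mean equals Σ pair occupancies / 100 exactly
  (linearity of the indicator sum); the test suite asserts this identity.
* Subunit aggregation is the elementwise arithmetic mean with missing pairs
  treated as 0; for equal-length runs it coincides exactly with pooling all
  frames, which is also asserted.

## Accessible surface area and hydrophobic energy

Per-atom ASA uses the Shrake–Rupley method with a **deterministic
golden-spiral lattice** (no RNG): each heavy atom's van der Waals sphere is
expanded by the probe radius and covered with `n_points` quasi-uniform
points; a point is occluded if it lies inside any other considered atom's
expanded sphere. Neighbor search uses a k-d tree.

* Probe radius 0.14 nm (water); default `n_points = 960`.
* vdW radii (Bondi, nm): C 0.170, N 0.155, O 0.152, S 0.180 (H 0.120 when
  hydrogens are included). The radii table is configurable; different MD
  tool tables shift absolute class totals by a few percent, which cancels
  in ensemble differences.
* Hydrogens are excluded from surface and occlusion by default (united-atom
  view, matching force fields that treat aliphatic H implicitly).
* Class partition is strictly by element of heavy atoms: hydrophobic =
  {C, S}, hydrophilic = {N, O}; anything else is reported separately, so
  the three classes always sum to the total.
* Numerical behaviour: the lattice is exactly reproducible but only
  approximately rotation invariant — per-atom areas move by up to ~1% under
  rigid motion at 960 points; doubling points twice (3840) changes areas by
  ≤ 1% (convergence asserted in tests). An isolated atom reproduces
  4π(r+probe)² to the lattice resolution.

Ensemble statistics are the mean ± population SD of the class totals over
the frames of a named time window. The hydrophobic stabilization energy of
folding follows from the class-ASA change between a native-like window and
a denatured window:

    ΔG_HP (kJ/mol) = 15.4 · ΔASA_non-polar − 2.6 · ΔASA_polar

with ΔASA in nm² (denatured minus native means) and the coefficients in
kJ·mol⁻¹·nm⁻². Differences of ΔG_HP between variants (`energy_differences`)
quantify relative hydrophobic stabilization.

## Secondary structure

Backbone hydrogen bonds use the Kabsch–Sander electrostatic model,
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol with distances
in Å between the acceptor's C=O and the donor's N–H; a bond exists when
E < −0.5 kcal/mol, only for |i−j| ≥ 2. Proline never donates. A missing
amide hydrogen is placed geometrically (N–H 1.0 Å along the bisector of
N→C(prev) and N→CA), so GRO/PDB inputs without hydrogens are handled.

Assignment per residue, priority H > E > B > T:

* **H** (α-helix): runs of ≥ 2 consecutive i→i+4 bonds (minimal 4-turn
  rule). 3₁₀- and π-helices are folded into T/C because only the α category
  is accounted.
* **E** (β-sheet): residues in ladders of ≥ 2 consecutive parallel or
  antiparallel bridges; **B** for isolated bridges (|i−j| ≥ 3).
* **T** (turn): interior residues of any 3/4/5-turn not already H/E/B.
* **C** otherwise; bends are counted as C.

The "structure" aggregate is H + E + B + T. Windowed accounting reports
mean ± population SD of per-frame category counts; the helicity profile is
each residue's H-fraction over window frames. Helicity is derived from the
same assignment as the category counts for internal consistency, rather
than from a separate helix-axis fit.

## Geometry

RMSD uses Kabsch superposition (weighted SVD with the sign correction that
forces a proper rotation, preserving chirality); the default selection is
Cα only, unweighted, against the first frame (configurable — trajectories
rarely state their natural reference). Radius of gyration is
√(Σ wᵢ|rᵢ−r̄|²/Σ wᵢ), mass-weighted by default with standard atomic masses.
No periodic-boundary unwrapping is attempted; inputs are assumed to contain
whole molecules.

## Synthetic ensembles

Real microsecond trajectories are not distributable, so validation rests on
generated ensembles with known ground truth. The generator controls exactly
the observables the analyses consume, nothing more — no force field,
solvent, thermostat or realistic kinetics.

* **Chain builder**: NeRF construction with ideal bond geometry
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°); α-helix φ=−57°,
  ψ=−47°; extended φ=−139°, ψ=135°; seeded coil. Backbone N/H/CA/C/O plus
  CB and the salt-bridge criterion carbons are placed; other side-chain
  atoms are not.
* **Sheet fixture**: two flat strands (φ=−140°, ψ=137.52°, the exact
  two-fold-screw solution, so the inter-strand bond pattern repeats along
  the ladder) paired antiparallel ~0.42 nm apart by a rigid transform
  fitted once against the hydrogen-bond energy and frozen as constants.
* **Contact trajectories**: residues sit on a sparse lattice (2.4 nm
  spacing) so untargeted charged atoms never approach within 0.7 nm. For
  each targeted pair, the acceptor residue is rigidly re-placed each frame
  at a criterion-atom distance drawn uniformly from 0.35–0.55 nm (bonded)
  or 0.8–2.5 nm (unbonded); the bands keep the 0.6 nm classification
  unambiguous away from the boundary. The bonded/unbonded sequence pins the
  bonded frame count to round(p·n) arranged in seeded runs of mean length
  ~5 frames: occupancy, not kinetics, is the controlled quantity, and
  pinning keeps every seed's realized fraction within 1/(2n) of the target
  (a free-running two-state chain with the same dwell would wander several
  binomial standard errors). Moved acceptors are rejection-sampled away
  from all other charged sites. An acceptor shared by two pairs is
  geometrically infeasible and rejected with the conflict listed.
* **Rg trajectories**: isotropic Gaussian clouds (one carbon per residue)
  rescaled so the exact Rg follows a linear drift plus seeded noise.
* **Helicity trajectories**: designated segments switch between helical and
  extended dihedrals with a controlled active fraction; ground truth covers
  the segment interior (two residues in from each end), where the 4-turn
  rule is insensitive to end effects.

Default ensemble parameters mirror the study conditions: a 112-residue
chain with charged residues at the salt-bridge participant positions,
0.4 ns sampling, 2000 frames (800 ns) per subunit, pair targets patterned
on the heat-denatured occupancies (one ~50% partner, several 5–20%), and
an Rg drift 1.5 → 1.2 nm (ellipsoid-like monomer compacting to a globular
disordered state). What passing recovery tests show is that the analysis
stages measure what the generator prescribed — not that the generator
resembles real solvated dynamics (it has no physics, no correlated
backbone motion, and its unfolded states are abstract lattices or ideal
dihedral chains).

## Pipeline

`run_pipeline` executes geometry → salt bridges → ASA → secondary structure
per input, then aggregates inputs sharing a mutant label (subunits) and
emits CSV/JSON tables. Temperatures are labels on separate inputs. Named
windows default to native 50–400 ns, denatured 400–1400 ns, late
1000–1400 ns, helicity 1200–1400 ns and are clipped to the available span
with a warning (desk-scale runs are shorter). ASA is evaluated on at most
`max_asa_frames` (default 50) evenly strided frames. Any stage failure
aborts with the stage name and input label; partial tables are flushed
alongside a `FAILED.json` marker. Reports are byte-identical across reruns
of the same config: provenance records a config hash and package version,
never wall-clock time.

## Known limitations

* The salt-bridge definition is the carbon–carbon distance criterion only;
  no hydrogen-bond (N–O) definitions, no charge-group centers, no
  electrostatic energies, no bridge-network analysis.
* DSSP emulation is partial: no chirality angles, no PP-II, bends folded
  into C; category totals can differ slightly from full DSSP
  implementations at helix/sheet termini.
* Absolute ASA values depend on the radii table and point density;
  comparisons should difference ensembles computed with identical
  parameters.
* The synthetic generator validates analysis correctness, not biological
  realism; occupancy recovery tolerances assume its pinned-count sampling.
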