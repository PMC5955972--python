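"""Seeded synthetic trajectories with known ground-truth observables.

Every analysis stage in this package (salt bridges, secondary structure,
radius of gyration, surface area) needs inputs whose true answer is known.
Microsecond MD of a ~112-residue monomer is far outside desk scale, so this
module generates stand-in ensembles with controllable observables:

* ``build_chain`` — single conformers with ideal backbone geometry
  (α-helical, extended or coil dihedrals) for geometry/secondary-structure
  fixtures.
* ``generate_contact_trajectory`` — selected charged-residue pairs toggle
  between a bonded band (criterion-atom distance 0.35–0.55 nm) and an
  unbonded band (0.8–2.5 nm) in seeded runs, with the bonded frame count
  pinned to the requested occupancy.
* ``generate_rg_trajectory`` — isotropic Gaussian clouds rescaled so the
  exact radius of gyration drifts linearly between two values.
* ``generate_helicity_trajectory`` — helix segments switch on and off so
  each residue's helical fraction over frames is controlled.

No force field, solvent or thermostat is emulated; only the observables the
downstream operators consume are controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import AtomRecord, Frame, Topology, Trajectory

# Ideal backbone internal coordinates (nm / degrees)
_B_N_CA = 0.1458
_B_CA_C = 0.1525
_B_C_N = 0.1329
_B_C_O = 0.1231
_B_N_H = 0.100
_B_CA_CB = 0.153
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8

#: Backbone dihedrals by named conformation (phi, psi) in degrees.
CONFORMATIONS = {"ideal_helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}

#: Distance (nm) from CA to the salt-bridge criterion carbon, along the
#: CA→CB direction; roughly the extended side-chain through-space values.
_CRITERION_EXTENSION = {
    ("LYS", "CE"): 0.50,
    ("ARG", "CD"): 0.39,
    ("GLU", "CD"): 0.39,
    ("ASP", "CG"): 0.25,
}

_STANDARD = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, ∠(b,c,d)=angle, dihedral(a,b,c,d)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(dih), math.sin(ang) * math.sin(dih)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_from_dihedrals(phi: np.ndarray, psi: np.ndarray):
    """Backbone N/CA/C positions for given per-residue dihedrals (ω fixed at 180°)."""
    n_res = len(phi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])
    return N, CA, C


def _chain_coords(sequence: list[str], phi: np.ndarray, psi: np.ndarray):
    """Full atom build: backbone N/CA/C/O/H plus CB and criterion carbons."""
    n_res = len(sequence)
    N, CA, C = _backbone_from_dihedrals(phi, psi)
    atoms: list[tuple[int, str, str]] = []  # (residue, atom_name, element)
    coords: list[np.ndarray] = []
    # virtual C(-1), consistent with residue 0's phi, for the first amide H
    c_prev_virtual = _place(C[0], CA[0], N[0], _B_C_N, _A_C_N_CA, phi[0])
    for i, resname in enumerate(sequence):
        atoms.append((i, "N", "N"))
        coords.append(N[i])
        if resname != "PRO":
            cp = C[i - 1] if i > 0 else c_prev_virtual
            h = N[i] + _B_N_H * _unit(_unit(N[i] - cp) + _unit(N[i] - CA[i]))
            atoms.append((i, "H", "H"))
            coords.append(h)
        atoms.append((i, "CA", "C"))
        coords.append(CA[i])
        if resname != "GLY":
            un = _unit(N[i] - CA[i])
            uc = _unit(C[i] - CA[i])
            cos_t = math.cos(math.radians(110.5))
            a = cos_t / (1.0 + float(un @ uc))
            in_plane = a * (un + uc)
            perp = _unit(np.cross(uc, un))
            b = math.sqrt(max(0.0, 1.0 - float(in_plane @ in_plane)))
            cb = CA[i] + _B_CA_CB * (in_plane + b * perp)
            atoms.append((i, "CB", "C"))
            coords.append(cb)
            for (rn, crit_name), dist in _CRITERION_EXTENSION.items():
                if rn == resname:
                    atoms.append((i, crit_name, "C"))
                    coords.append(CA[i] + dist * _unit(cb - CA[i]))
        atoms.append((i, "C", "C"))
        coords.append(C[i])
        o_dih = psi[i] + 180.0 if i + 1 < n_res else psi[i] + 180.0
        atoms.append((i, "O", "O"))
        coords.append(_place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, o_dih))
    return atoms, np.array(coords)


def _build_topology(sequence: list[str], atom_list) -> Topology:
    records = []
    residues = []
    start = 0
    prev = None
    for idx, (res_i, name, element) in enumerate(atom_list):
        if res_i != prev:
            if prev is not None:
                residues.append((sequence[prev], start, idx))
                start = idx
            prev = res_i
        records.append(
            AtomRecord(
                atom_name=name,
                element=element,
                residue_index=res_i,
                residue_name=sequence[res_i],
                serial=idx + 1,
            )
        )
    residues.append((sequence[prev], start, len(records)))
    return Topology(atoms=records, residues=residues, chain_id="A")


def build_chain(
    sequence: list[str], conformation: str = "ideal_helix", seed: int = 0
) -> tuple[Topology, Frame]:
    """Build a single conformer with ideal bond geometry.

    ``ideal_helix`` uses φ=−57°, ψ=−47°; ``extended`` uses φ=−139°, ψ=135°;
    ``coil`` draws seeded dihedrals from the broad left half of the
    Ramachandran plane.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = [s.upper() for s in sequence]
    unknown = sorted(set(sequence) - _STANDARD)
    if unknown:
        raise ValueError(f"unknown residue code(s): {', '.join(unknown)}")
    n = len(sequence)
    if conformation in CONFORMATIONS:
        phi0, psi0 = CONFORMATIONS[conformation]
        phi = np.full(n, phi0)
        psi = np.full(n, psi0)
    elif conformation == "coil":
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-180.0, -40.0, size=n)
        psi = rng.uniform(-180.0, 180.0, size=n)
    else:
        raise ValueError(f"unknown conformation {conformation!r}")
    atom_list, coords = _chain_coords(sequence, phi, psi)
    top = _build_topology(sequence, atom_list)
    return top, Frame(time_ns=0.0, coords=coords)


# The sheet fixture uses strand dihedrals with an exact two-fold screw
# (flat, untwisted strand) so the inter-strand hydrogen-bond pattern repeats
# along the whole ladder; ψ solves twist(φ=−140°, ψ) = 180°.
_SHEET_PHI = -140.0
_SHEET_PSI = 137.52

# Rigid placement (XYZ Euler angles, rad / translation, nm) of the partner
# strand relative to the canonicalized first strand, fitted once to maximise
# the Kabsch–Sander bond energy of the antiparallel register without steric
# clashes. Validated for 8-residue strands.
_SHEET_PARTNER_TRANSFORM = (5.170018, -0.00383, 3.140319, -0.009586, -0.218899, 0.352837)


def _euler_xyz(ax: float, ay: float, az: float) -> np.ndarray:
    def rot(axis, ang):
        c, s = math.cos(ang), math.sin(ang)
        if axis == 0:
            return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        if axis == 1:
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    return rot(2, az) @ rot(1, ay) @ rot(0, ax)


def build_antiparallel_sheet(n_per_strand: int = 8) -> tuple[Topology, Frame]:
    """Two flat poly-Ala strands paired antiparallel in one topology.

    The first strand is canonicalized with its screw axis along +x and
    centred; the second is the first under a fitted 180°-flip transform.
    Residues ``0..n-1`` and ``n..2n-1`` form the two strands, running in
    opposite directions ~0.42 nm apart. Interior residues of each strand
    carry the full antiparallel ladder of backbone hydrogen bonds; the
    strand ends adjacent to the index junction see spurious short-range
    turn patterns, as any single-chain two-strand construction does.
    """
    if n_per_strand < 8:
        raise ValueError("sheet fixture needs at least 8 residues per strand")
    seq = ["ALA"] * n_per_strand
    atom_list, raw = _chain_coords(
        seq, np.full(n_per_strand, _SHEET_PHI), np.full(n_per_strand, _SHEET_PSI)
    )
    ca = np.array([c for (r, nm, el), c in zip(atom_list, raw) if nm == "CA"])
    axis = _unit(ca[6] - ca[2])
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot0 = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot0 = np.eye(3) + vx + vx @ vx * ((1 - float(axis @ x)) / s**2)
    n_first8 = sum(1 for r, _, _ in atom_list if r < 8)
    coords = (raw - raw[:n_first8].mean(axis=0)) @ rot0.T
    ax, ay, az, tx, ty, tz = _SHEET_PARTNER_TRANSFORM
    coords2 = coords @ _euler_xyz(ax, ay, az).T + np.array([tx, ty, tz])
    atom_list2 = [(r + n_per_strand, nm, el) for r, nm, el in atom_list]
    top = _build_topology(seq + seq, atom_list + atom_list2)
    return top, Frame(time_ns=0.0, coords=np.vstack([coords, coords2]))


# ---------------------------------------------------------------------------
# Ensemble specification


def cuta1_like_sequence() -> list[str]:
    """A 112-residue synthetic sequence with charged residues at the positions
    of the ionic-mutant monomer's salt-bridge participants; alanine elsewhere."""
    charged = {
        3: "ASP", 4: "GLU", 5: "LYS", 20: "ASP", 21: "GLU", 26: "ASP",
        30: "LYS", 34: "GLU", 35: "LYS", 39: "ASP", 48: "LYS", 53: "GLU",
        55: "LYS", 57: "GLU", 59: "GLU", 67: "LYS", 72: "LYS", 78: "GLU",
        81: "LYS", 82: "LYS", 87: "LYS", 88: "ARG", 90: "GLU",
        100: "ASP", 102: "ASP", 112: "ARG",
    }
    return [charged.get(i, "ALA") for i in range(1, 113)]


def default_pair_targets() -> dict[tuple[int, int], float]:
    """Default per-pair bonded-fraction targets (0-based residue indices).

    Modelled on the heat-denatured (450 K) occupancy pattern of the ionic
    mutant's substituted residues: one strong partner near 50%, several in
    the 5–20% band. Each acceptor appears in at most one pair.
    """
    pairs_1based = {
        (88, 90): 0.495,
        (88, 20): 0.205,
        (87, 21): 0.206,
        (87, 59): 0.197,
        (82, 78): 0.130,
        (72, 34): 0.095,
        (48, 39): 0.064,
    }
    return {(d - 1, a - 1): p for (d, a), p in pairs_1based.items()}


@dataclass
class EnsembleSpec:
    """Parameters of a synthetic ensemble.

    Defaults emulate one heat-denatured monomer subunit at desk scale:
    a 112-residue chain sampled every 0.4 ns for 2000 frames (800 ns),
    with salt-bridge pair targets patterned on the denatured-state
    occupancies and a compaction of the radius of gyration from the
    ellipsoid-like native monomer (~1.5 nm) toward a globular disordered
    state (~1.2 nm).
    """

    sequence: list[str] = field(default_factory=cuta1_like_sequence)
    pair_occupancy_targets: dict[tuple[int, int], float] = field(
        default_factory=default_pair_targets
    )
    helix_segments: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(10, 29, 0.4)]
    )
    rg_start_nm: float = 1.5
    rg_end_nm: float = 1.2
    rg_noise_sd_nm: float = 0.02
    n_frames: int = 2000
    dt_ns: float = 0.4
    seed: int = 0

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        if self.rg_start_nm <= 0 or self.rg_end_nm <= 0:
            raise ValueError("rg profile endpoints must be positive")
        for (d, a), p in self.pair_occupancy_targets.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy target for pair {(d, a)} outside [0, 1]")
            if not (0 <= d < self.n_residues and 0 <= a < self.n_residues):
                raise ValueError(f"pair {(d, a)} outside chain")
        for s, e, f in self.helix_segments:
            if not (0 <= s < e < self.n_residues):
                raise ValueError(f"helix segment ({s}, {e}) outside chain")
            if not 0.0 <= f <= 1.0:
                raise ValueError("helicity fraction outside [0, 1]")


@dataclass
class GroundTruth:
    """Realized observables of a generated ensemble."""

    pair_fractions: dict[tuple[int, int], float] = field(default_factory=dict)
    pair_bonded: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    helicity: dict[int, float] = field(default_factory=dict)
    segment_active: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    rg_nm: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Contact (salt-bridge) trajectories

_POSITIVE_CRIT = {"LYS": "CE", "ARG": "CD"}
_NEGATIVE_CRIT = {"GLU": "CD", "ASP": "CG"}

_BONDED_BAND = (0.35, 0.55)
_UNBONDED_BAND = (0.8, 2.5)
_AVOID_NM = 0.7
_MEAN_DWELL_STEPS = 5.0


def _bonded_states(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    """Two-state occupancy sequence with the bonded frame count pinned.

    Exactly ``round(p·n)`` frames are bonded, arranged in runs of mean
    length ~5 frames at seeded random positions. Pinning the count keeps
    the realized fraction within 1/(2n) of the target for every seed —
    a free-running two-state Markov chain with the same dwell would wander
    several binomial standard errors away. Kinetics are not emulated; the
    run structure only avoids frame-to-frame toggling.
    """
    m = int(round(p * n))
    if m <= 0:
        return np.zeros(n, dtype=bool)
    if m >= n:
        return np.ones(n, dtype=bool)
    # split the m bonded frames into runs (geometric, mean _MEAN_DWELL_STEPS)
    run_lengths = []
    remaining = m
    while remaining > 0:
        r = 1 + int(rng.geometric(1.0 / _MEAN_DWELL_STEPS) - 1)
        r = min(r, remaining)
        run_lengths.append(r)
        remaining -= r
    k = len(run_lengths)
    # distribute the n−m unbonded frames into k+1 gaps (uniform composition)
    u = n - m
    cuts = np.sort(rng.integers(0, u + 1, size=k))
    gaps = np.diff(np.concatenate([[0], cuts, [u]]))
    states = np.zeros(n, dtype=bool)
    pos = 0
    for g, r in zip(gaps[:-1], run_lengths):
        pos += int(g)
        states[pos : pos + r] = True
        pos += r
    return states


def _lattice_anchor(i: int, spacing: float = 2.4) -> np.ndarray:
    m = 5
    return spacing * np.array([i % m, (i // m) % m, i // (m * m)], dtype=float)


#: Compact per-residue template (local nm coordinates); criterion carbons
#: appended per residue type at a fixed offset.
_TEMPLATE = [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (0.1458, 0.0, 0.0)),
    ("C", "C", (0.196, 0.144, 0.0)),
    ("O", "O", (0.132, 0.252, 0.0)),
]
_CRIT_LOCAL = (0.1458, -0.30, 0.0)


def _contact_topology(sequence: list[str]):
    atom_list = []
    base = []
    crit_atom_index: dict[int, int] = {}
    residue_atom_slices = []
    for i, resname in enumerate(sequence):
        anchor = _lattice_anchor(i)
        start = len(atom_list)
        for name, element, local in _TEMPLATE:
            atom_list.append((i, name, element))
            base.append(anchor + np.array(local))
        crit = _POSITIVE_CRIT.get(resname) or _NEGATIVE_CRIT.get(resname)
        if crit:
            crit_atom_index[i] = len(atom_list)
            atom_list.append((i, crit, "C"))
            base.append(anchor + np.array(_CRIT_LOCAL))
        residue_atom_slices.append(slice(start, len(atom_list)))
    top = _build_topology(sequence, atom_list)
    return top, np.array(base), crit_atom_index, residue_atom_slices


def generate_contact_trajectory(spec: EnsembleSpec) -> tuple[Trajectory, GroundTruth]:
    """Trajectory whose targeted pairs toggle between bonded and unbonded bands.

    Untargeted charged residues sit on a sparse lattice so no accidental
    contact (< 0.7 nm between criterion atoms) occurs; moved acceptors are
    rejection-sampled away from every other charged site.
    """
    spec.validate()
    seq = [s.upper() for s in spec.sequence]
    pairs = list(spec.pair_occupancy_targets.items())
    # feasibility: an acceptor residue may be moved by only one pair
    seen_acceptors: dict[int, tuple[int, int]] = {}
    conflicts = []
    for (d, a), _ in pairs:
        if seq[d] not in _POSITIVE_CRIT:
            raise ValueError(f"pair donor residue {d} ({seq[d]}) is not Lys/Arg")
        if seq[a] not in _NEGATIVE_CRIT:
            raise ValueError(f"pair acceptor residue {a} ({seq[a]}) is not Glu/Asp")
        if a in seen_acceptors:
            conflicts.append(f"acceptor {a} shared by pairs {seen_acceptors[a]} and {(d, a)}")
        seen_acceptors[a] = (d, a)
    if conflicts:
        raise ValueError("infeasible pair targets: " + "; ".join(conflicts))

    top, base, crit_idx, res_slices = _contact_topology(seq)
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    state_arrays = {}
    for (d, a), p in pairs:
        states = _bonded_states(rng, p, spec.n_frames)
        state_arrays[(d, a)] = states
        truth.pair_bonded[(d, a)] = states
        truth.pair_fractions[(d, a)] = float(states.mean())

    charged_positions_base = {r: base[crit_idx[r]] for r in crit_idx}
    frames = []
    for k in range(spec.n_frames):
        coords = base.copy()
        placed = dict(charged_positions_base)
        for (d, a), _ in pairs:
            bonded = state_arrays[(d, a)][k]
            lo, hi = _BONDED_BAND if bonded else _UNBONDED_BAND
            donor_pos = placed[d]
            for _attempt in range(200):
                dist = rng.uniform(lo, hi)
                v = rng.standard_normal(3)
                direction = v / np.linalg.norm(v)
                candidate = donor_pos + dist * direction
                ok = all(
                    np.linalg.norm(candidate - pos) > _AVOID_NM
                    for r, pos in placed.items()
                    if r not in (d, a)
                )
                if ok:
                    break
            else:
                raise RuntimeError(f"could not place acceptor {a} away from other charges")
            shift = candidate - base[crit_idx[a]]
            coords[res_slices[a]] = base[res_slices[a]] + shift
            placed[a] = candidate
        frames.append(Frame(time_ns=k * spec.dt_ns, coords=coords))
    return Trajectory(topology=top, frames=frames), truth


# ---------------------------------------------------------------------------
# Radius-of-gyration trajectories


def generate_rg_trajectory(spec: EnsembleSpec) -> tuple[Trajectory, GroundTruth]:
    """Gaussian clouds rescaled so the exact Rg follows a linear drift.

    One carbon pseudo-atom per residue; the frame-k target is the linear
    interpolation from ``rg_start_nm`` to ``rg_end_nm`` plus seeded normal
    noise of SD ``rg_noise_sd_nm`` (floored at 0.01 nm).
    """
    spec.validate()
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed)
    if spec.n_frames > 1:
        targets = np.linspace(spec.rg_start_nm, spec.rg_end_nm, spec.n_frames)
    else:
        targets = np.array([spec.rg_start_nm])
    if spec.rg_noise_sd_nm > 0:
        targets = targets + rng.normal(0.0, spec.rg_noise_sd_nm, size=spec.n_frames)
    targets = np.maximum(targets, 0.01)
    atom_list = [(i, "CA", "C") for i in range(n)]
    top = _build_topology(spec.sequence, atom_list)
    frames = []
    for k in range(spec.n_frames):
        cloud = rng.standard_normal((n, 3))
        cloud -= cloud.mean(axis=0)
        rg = math.sqrt(float(np.einsum("ij,ij->i", cloud, cloud).mean()))
        frames.append(Frame(time_ns=k * spec.dt_ns, coords=cloud * (targets[k] / rg)))
    truth = GroundTruth(rg_nm=targets.copy())
    return Trajectory(topology=top, frames=frames), truth


# ---------------------------------------------------------------------------
# Helicity trajectories


def generate_helicity_trajectory(spec: EnsembleSpec) -> tuple[Trajectory, GroundTruth]:
    """Frames in which each helix segment is ideal-helical in a controlled
    fraction of frames and extended otherwise.

    Ground truth records, per segment, the active-frame mask and per-residue
    realized helicity for the segment's interior residues (two residues in
    from each end, where the minimal 4-turn rule is insensitive to ends).
    """
    spec.validate()
    seq = [s.upper() for s in spec.sequence]
    rng = np.random.default_rng(spec.seed)
    phi_ext, psi_ext = CONFORMATIONS["extended"]
    phi_hel, psi_hel = CONFORMATIONS["ideal_helix"]
    active = {
        (s, e): rng.random(spec.n_frames) < f for s, e, f in spec.helix_segments
    }
    frames = []
    top = None
    for k in range(spec.n_frames):
        phi = np.full(spec.n_residues, phi_ext)
        psi = np.full(spec.n_residues, psi_ext)
        for (s, e), mask in active.items():
            if mask[k]:
                phi[s : e + 1] = phi_hel
                psi[s : e + 1] = psi_hel
        atom_list, coords = _chain_coords(seq, phi, psi)
        if top is None:
            top = _build_topology(seq, atom_list)
        frames.append(Frame(time_ns=k * spec.dt_ns, coords=coords))
    truth = GroundTruth()
    for (s, e), mask in active.items():
        truth.segment_active[(s, e)] = mask
        frac = float(mask.mean())
        for r in range(s + 2, e - 1):
            truth.helicity[r] = frac
    return Trajectory(topology=top, frames=frames), truth
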