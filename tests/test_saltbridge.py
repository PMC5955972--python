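import numpy as np
import pytest

from denatens import saltbridge as sb
from denatens.model import Frame, Trajectory
from denatens.synthetic_data import EnsembleSpec, generate_contact_trajectory

from conftest import make_trajectory


@pytest.fixture(scope="module")
def contact_run():
    spec = EnsembleSpec(
        sequence=["LYS", "ALA", "ALA", "GLU", "ALA", "ASP", "ALA", "ARG", "ALA", "GLU"],
        pair_occupancy_targets={(0, 3): 0.6, (0, 5): 0.25, (7, 9): 0.4},
        helix_segments=[],
        n_frames=1000,
        seed=13,
    )
    traj, truth = generate_contact_trajectory(spec)
    return spec, traj, truth


class TestCriterionAtoms:
    def test_mapped_atoms(self, contact_run):
        _, traj, _ = contact_run
        top = traj.topology
        assert sb.criterion_atom(top, 0, "positive") == top.atom_index(0, "CE")
        assert sb.criterion_atom(top, 5, "negative") == top.atom_index(5, "CG")
        assert sb.criterion_atom(top, 7, "positive") == top.atom_index(7, "CD")

    def test_uncharged_residue_rejected(self, contact_run):
        _, traj, _ = contact_run
        with pytest.raises(ValueError, match="Ala2"):
            sb.criterion_atom(traj.topology, 1, "positive")

    def test_arg_alternative_atom(self):
        cmap = sb.CriterionAtomMap(positive={"LYS": "CE", "ARG": "CZ"})
        assert cmap.positive["ARG"] == "CZ"

    def test_terminal_sites(self, contact_run):
        _, traj, _ = contact_run
        sites = sb.charged_sites(traj.topology, sb.CriterionAtomMap(include_n_terminal=True))
        labels = [s.label for s in sites]
        assert "C-terminal" in labels and "N-terminal" in labels
        cterm = next(s for s in sites if s.label == "C-terminal")
        assert cterm.role == "negative"
        assert traj.topology.atoms[cterm.atom_index].atom_name == "C"


class TestPairDistances:
    def test_trivial_distance(self):
        # two-residue system: Lys CE at origin, Glu CD 0.3 nm away
        from denatens.model import AtomRecord, Topology

        atoms = [
            AtomRecord("CE", "C", 0, "LYS", 1),
            AtomRecord("CD", "C", 1, "GLU", 2),
        ]
        top = Topology(atoms=atoms, residues=[("LYS", 0, 1), ("GLU", 1, 2)])
        traj = make_trajectory(top, [[[0, 0, 0], [0, 0, 0.3]]])
        series = sb.pair_distances(traj, 0, 1)
        assert series.distance_nm[0] == pytest.approx(0.3, abs=1e-12)

    def test_matches_brute_force_double_loop(self, contact_run):
        _, traj, _ = contact_run
        series = sb.pair_distances(traj, 0, 3)
        a = traj.topology.atom_index(0, "CE")
        b = traj.topology.atom_index(3, "CD")
        for k, fr in enumerate(traj.frames):
            expected = np.sqrt(((fr.coords[a] - fr.coords[b]) ** 2).sum())
            assert series.distance_nm[k] == pytest.approx(expected, abs=1e-12)

    def test_bonded_frames_in_band(self, contact_run):
        _, traj, truth = contact_run
        series = sb.pair_distances(traj, 0, 3)
        bonded = truth.pair_bonded[(0, 3)]
        assert np.all((series.distance_nm[bonded] >= 0.35) & (series.distance_nm[bonded] <= 0.55))


class TestOccupancy:
    def test_recovers_generator_truth(self, contact_run):
        spec, traj, truth = contact_run
        rep = sb.occupancy(traj, [0, 7])
        for pair, frac in truth.pair_fractions.items():
            assert rep.per_pair_occupancy_pct[pair] == pytest.approx(100 * frac, abs=1e-9)

    def test_per_residue_sum_dominates_pairs(self, contact_run):
        _, traj, _ = contact_run
        rep = sb.occupancy(traj, [0, 7])
        for (target, _), v in rep.per_pair_occupancy_pct.items():
            assert rep.per_residue_sum_pct[target] >= v - 1e-9

    def test_strict_cutoff_boundary(self):
        from denatens.model import AtomRecord, Topology

        atoms = [AtomRecord("CE", "C", 0, "LYS", 1), AtomRecord("CD", "C", 1, "GLU", 2)]
        top = Topology(atoms=atoms, residues=[("LYS", 0, 1), ("GLU", 1, 2)])
        cmap = sb.CriterionAtomMap(include_c_terminal=False)
        traj = make_trajectory(
            top, [[[0, 0, 0], [0, 0, 0.6]], [[0, 0, 0], [0, 0, 0.5999]]]
        )
        rep = sb.occupancy(traj, [0], cmap=cmap)
        assert rep.per_pair_occupancy_pct[(0, 1)] == pytest.approx(50.0)

    def test_prefilter_omits_only_never_close_pairs(self, contact_run):
        _, traj, _ = contact_run
        loose = sb.occupancy(traj, [0])
        filtered = sb.occupancy(traj, [0], prefilter_nm=0.4)
        assert (0, 9) in loose.per_pair_occupancy_pct  # untargeted pair, 0%
        assert (0, 9) not in filtered.per_pair_occupancy_pct
        for key, v in filtered.per_pair_occupancy_pct.items():
            assert v == loose.per_pair_occupancy_pct[key]

    def test_frame_order_invariance(self, contact_run):
        _, traj, _ = contact_run
        rep = sb.occupancy(traj, [0])
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = Trajectory(
            topology=traj.topology,
            frames=[
                Frame(time_ns=k * 0.4, coords=traj.frames[p].coords)
                for k, p in enumerate(perm)
            ],
        )
        rep2 = sb.occupancy(shuffled, [0])
        assert rep.per_pair_occupancy_pct == rep2.per_pair_occupancy_pct

    def test_empty_window_rejected(self, contact_run):
        _, traj, _ = contact_run
        with pytest.raises(ValueError):
            sb.occupancy(traj, [0], window=(1e6, 2e6))


class TestCountSeries:
    def test_permanent_double_bridge(self):
        # last residue is uncharged so the C-terminal site stays on the
        # lattice instead of riding along with a moved acceptor
        spec = EnsembleSpec(
            sequence=["LYS", "ALA", "GLU", "ALA", "ASP", "ALA"],
            pair_occupancy_targets={(0, 2): 1.0, (0, 4): 1.0},
            helix_segments=[],
            n_frames=40,
            seed=2,
        )
        traj, _ = generate_contact_trajectory(spec)
        cs = sb.count_series(traj, 0, bin_ns=0.4)
        assert np.all(cs.counts == 2.0)

    def test_no_partners_all_zero(self):
        spec = EnsembleSpec(
            sequence=["LYS", "ALA", "GLU"],
            pair_occupancy_targets={(0, 2): 0.0},
            helix_segments=[],
            n_frames=20,
            seed=3,
        )
        traj, _ = generate_contact_trajectory(spec)
        cmap = sb.CriterionAtomMap(include_c_terminal=False)
        cs = sb.count_series(traj, 0, cmap=cmap)
        assert np.all(cs.counts == 0.0)

    def test_mean_equals_sum_of_occupancies(self, contact_run):
        """Per-residue partner-count mean equals Σ occupancies / 100 on the
        same frames (count/occupancy consistency)."""
        _, traj, _ = contact_run
        for res in (0, 7):
            rep = sb.occupancy(traj, [res])
            cs = sb.count_series(traj, res, bin_ns=0.4)
            assert cs.overall_mean == pytest.approx(
                rep.per_residue_sum_pct[res] / 100.0, abs=1e-9
            )

    def test_linearity_of_expectation(self, contact_run):
        spec, traj, truth = contact_run
        cs = sb.count_series(traj, 0)
        expected = sum(truth.pair_fractions[p] for p in [(0, 3), (0, 5)])
        p1, p2 = 0.6, 0.25
        se = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / traj.n_frames)
        assert abs(cs.overall_mean - expected) <= 3 * se + 1e-9

    def test_bin_smaller_than_spacing_rejected(self, contact_run):
        _, traj, _ = contact_run
        with pytest.raises(ValueError, match="spacing"):
            sb.count_series(traj, 0, bin_ns=0.1)


class TestAggregation:
    def _make_report(self, value: float) -> sb.OccupancyReport:
        return sb.OccupancyReport(
            per_pair_occupancy_pct={(0, 3): value},
            per_residue_sum_pct={0: value},
            window=(0.0, 10.0),
            sampling_interval_ns=0.4,
            pair_labels={(0, 3): ("Lys1", "Glu4")},
        )

    def test_identical_reports_unchanged(self):
        reports = [self._make_report(42.0) for _ in range(3)]
        agg = sb.aggregate_subunits(reports)
        assert agg.per_pair_occupancy_pct[(0, 3)] == 42.0

    def test_arithmetic_mean(self):
        agg = sb.aggregate_subunits([self._make_report(v) for v in (30.0, 60.0, 90.0)])
        assert agg.per_pair_occupancy_pct[(0, 3)] == pytest.approx(60.0)

    def test_missing_pairs_count_as_zero(self):
        a = self._make_report(90.0)
        b = sb.OccupancyReport(
            per_pair_occupancy_pct={},
            per_residue_sum_pct={0: 0.0},
            window=(0.0, 10.0),
            sampling_interval_ns=0.4,
        )
        agg = sb.aggregate_subunits([a, b])
        assert agg.per_pair_occupancy_pct[(0, 3)] == pytest.approx(45.0)

    def test_target_mismatch_rejected(self):
        a = self._make_report(10.0)
        b = sb.OccupancyReport(
            per_pair_occupancy_pct={(5, 3): 1.0},
            per_residue_sum_pct={5: 1.0},
            window=(0.0, 10.0),
            sampling_interval_ns=0.4,
        )
        with pytest.raises(ValueError):
            sb.aggregate_subunits([a, b])

    def test_equal_frames_aggregate_matches_pooled(self):
        """Averaging three equal-length subunit reports equals computing
        occupancy on the pooled frames."""
        seqs = [1, 2, 3]
        reports = []
        pooled_frames = []
        top = None
        for seed in seqs:
            spec = EnsembleSpec(
                sequence=["LYS", "ALA", "ALA", "GLU"],
                pair_occupancy_targets={(0, 3): 0.5},
                helix_segments=[],
                n_frames=200,
                seed=seed,
            )
            traj, _ = generate_contact_trajectory(spec)
            top = traj.topology
            reports.append(sb.occupancy(traj, [0]))
            pooled_frames.extend(fr.coords for fr in traj.frames)
        agg = sb.aggregate_subunits(reports)
        pooled = sb.occupancy(make_trajectory(top, pooled_frames), [0])
        for key, v in agg.per_pair_occupancy_pct.items():
            assert v == pytest.approx(pooled.per_pair_occupancy_pct[key], abs=1e-9)
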