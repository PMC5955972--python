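import math

import numpy as np
import pytest

from denatens import sasa
from denatens.model import Frame

from conftest import point_topology, single_atom_topology, make_trajectory


def two_sphere_exact_asa(r1: float, r2: float, d: float) -> float:
    """Closed-form accessible area of expanded sphere 1 partially occluded
    by expanded sphere 2 (spherical-cap subtraction)."""
    if d >= r1 + r2:
        return 4 * math.pi * r1**2
    if d + r1 <= r2:
        return 0.0
    h = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    return 4 * math.pi * r1**2 - 2 * math.pi * r1 * h


class TestShrakeRupley:
    def test_isolated_carbon_closed_form(self):
        top = single_atom_topology("C")
        res = sasa.shrake_rupley(Frame(0.0, [[0.0, 0.0, 0.0]]), top)
        expected = 4 * math.pi * 0.31**2  # (0.170 + 0.140) nm expanded radius
        assert res.per_atom_asa_nm2[0] == pytest.approx(expected, rel=5e-3)
        assert res.class_totals["hydrophobic"] == pytest.approx(expected, rel=5e-3)

    def test_caged_atom_fully_buried(self):
        elements = ["C"] + ["S"] * 26
        top = point_topology(elements)
        offsets = [
            np.array([i, j, k], dtype=float) * 0.25
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        coords = np.vstack([[0.0, 0.0, 0.0], offsets])
        res = sasa.shrake_rupley(Frame(0.0, coords), top)
        assert res.per_atom_asa_nm2[0] == 0.0

    @pytest.mark.parametrize("d", [0.25, 0.40, 0.55])
    def test_dimer_against_monte_carlo_oracle(self, d):
        top = point_topology(["C", "C"])
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        res = sasa.shrake_rupley(Frame(0.0, coords), top)
        rng = np.random.default_rng(42)
        r = 0.170 + 0.14
        pts = rng.standard_normal((100_000, 3))
        pts = r * pts / np.linalg.norm(pts, axis=1)[:, None]
        frac = np.mean(np.linalg.norm(pts - coords[1], axis=1) >= r)
        mc = 4 * math.pi * r**2 * frac
        assert res.per_atom_asa_nm2[0] == pytest.approx(mc, rel=1e-2)
        # and against the spherical-cap closed form
        assert res.per_atom_asa_nm2[0] == pytest.approx(
            two_sphere_exact_asa(r, r, d), rel=1e-2
        )

    def test_point_count_convergence(self):
        top = point_topology(["C", "N", "O"])
        coords = np.array([[0.0, 0, 0], [0.3, 0, 0], [0.15, 0.25, 0]])
        a = sasa.shrake_rupley(Frame(0.0, coords), top, n_points=960)
        b = sasa.shrake_rupley(Frame(0.0, coords), top, n_points=3840)
        rel = np.abs(a.per_atom_asa_nm2 - b.per_atom_asa_nm2) / b.per_atom_asa_nm2
        assert rel.max() <= 0.01

    def test_monotone_under_atom_removal(self):
        rng = np.random.default_rng(1)
        n = 6
        coords = rng.uniform(0, 0.5, size=(n, 3))
        top_all = point_topology(["C"] * n)
        full = sasa.shrake_rupley(Frame(0.0, coords), top_all)
        top_less = point_topology(["C"] * (n - 1))
        less = sasa.shrake_rupley(Frame(0.0, coords[1:]), top_less)
        assert np.all(less.per_atom_asa_nm2 >= full.per_atom_asa_nm2[1:] - 1e-12)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 0.6, size=(5, 3))
        top = point_topology(["C", "N", "O", "S", "C"])
        base = sasa.shrake_rupley(Frame(0.0, coords), top)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = sasa.shrake_rupley(Frame(0.0, coords @ rot.T + 3.0), top)
        # the fixed point lattice is only approximately rotation invariant;
        # at 960 points per-atom areas move by <1% under rigid motion
        rel = np.abs(moved.per_atom_asa_nm2 - base.per_atom_asa_nm2) / base.per_atom_asa_nm2
        assert rel.max() <= 1e-2
        for cls in ("hydrophobic", "hydrophilic"):
            assert moved.class_totals[cls] == pytest.approx(
                base.class_totals[cls], rel=1e-2
            )

    def test_hydrogens_excluded_by_default(self):
        top = point_topology(["C", "H"])
        coords = np.array([[0.0, 0, 0], [0.15, 0, 0]])
        res = sasa.shrake_rupley(Frame(0.0, coords), top)
        iso = 4 * math.pi * 0.31**2
        assert res.per_atom_asa_nm2[1] == 0.0
        assert res.per_atom_asa_nm2[0] == pytest.approx(iso, rel=5e-3)

    def test_class_totals_partition(self):
        rng = np.random.default_rng(3)
        elements = ["C", "N", "O", "S", "C", "O"]
        top = point_topology(elements)
        res = sasa.shrake_rupley(Frame(0.0, rng.uniform(0, 0.8, size=(6, 3))), top)
        hp = sum(res.per_atom_asa_nm2[i] for i, e in enumerate(elements) if e in "CS")
        hl = sum(res.per_atom_asa_nm2[i] for i, e in enumerate(elements) if e in "NO")
        assert res.class_totals["hydrophobic"] == pytest.approx(hp, abs=1e-9)
        assert res.class_totals["hydrophilic"] == pytest.approx(hl, abs=1e-9)
        total = res.class_totals["hydrophobic"] + res.class_totals["hydrophilic"] + res.class_totals["other"]
        assert total == pytest.approx(res.total_nm2, abs=1e-9)

    def test_missing_radius_names_element(self):
        top = point_topology(["C", "X"])
        with pytest.raises(ValueError, match="X"):
            sasa.shrake_rupley(Frame(0.0, np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]]), top)


class TestWindowSummary:
    def _series(self, hp_values, hl_values=None):
        hl_values = hl_values if hl_values is not None else hp_values
        results = [
            sasa.AsaFrameResult(
                per_atom_asa_nm2=np.array([h]),
                class_totals={"hydrophobic": h, "hydrophilic": l, "other": 0.0},
            )
            for h, l in zip(hp_values, hl_values)
        ]
        return sasa.AsaSeries(time_ns=np.arange(len(results), dtype=float), results=results)

    def test_constant_series(self):
        s = sasa.window_summary(self._series([7.5] * 5))
        assert (s.mean_hydrophobic_nm2, s.sd_hydrophobic_nm2) == (7.5, 0.0)

    def test_two_frame_arithmetic(self):
        s = sasa.window_summary(self._series([10.0, 20.0]))
        assert s.mean_hydrophobic_nm2 == pytest.approx(15.0)
        assert s.sd_hydrophobic_nm2 == pytest.approx(5.0)

    def test_matches_numpy_recompute(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(20, 40, size=100)
        s = sasa.window_summary(self._series(vals))
        assert s.mean_hydrophobic_nm2 == pytest.approx(vals.mean(), rel=1e-12)
        assert s.sd_hydrophobic_nm2 == pytest.approx(vals.std(), rel=1e-12)

    def test_windowing_and_empty_window(self):
        series = self._series(list(range(10)))
        s = sasa.window_summary(series, window=(2.0, 5.0))
        assert s.n_frames == 4
        with pytest.raises(ValueError):
            sasa.window_summary(series, window=(100.0, 200.0))


def summary(hp: float, hl: float) -> sasa.AsaWindowSummary:
    return sasa.AsaWindowSummary(
        window=(0.0, 1.0),
        mean_hydrophobic_nm2=hp,
        sd_hydrophobic_nm2=0.0,
        mean_hydrophilic_nm2=hl,
        sd_hydrophilic_nm2=0.0,
    )


class TestHydrophobicEnergy:
    def test_delta_asa_bookkeeping(self):
        d_np, d_p = sasa.delta_asa(summary(21.88, 22.45), summary(33.41, 30.64))
        assert d_np == pytest.approx(11.53, abs=1e-9)
        assert d_p == pytest.approx(8.19, abs=1e-9)
        assert sasa.delta_asa(summary(5.0, 6.0), summary(5.0, 6.0)) == (0.0, 0.0)

    def test_equation_worked_examples(self):
        assert sasa.hydrophobic_energy(11.53, 8.18).delta_g_hp_kj_mol == pytest.approx(
            156.3, abs=0.2
        )
        assert sasa.hydrophobic_energy(12.54, 7.76).delta_g_hp_kj_mol == pytest.approx(
            172.9, abs=0.2
        )
        assert sasa.hydrophobic_energy(11.68, 7.90).delta_g_hp_kj_mol == pytest.approx(
            159.4, abs=0.2
        )
        assert sasa.hydrophobic_energy(0.0, 0.0).delta_g_hp_kj_mol == 0.0

    def test_linearity_and_sign_flip(self):
        a = sasa.hydrophobic_energy(2.0, 1.0).delta_g_hp_kj_mol
        b = sasa.hydrophobic_energy(4.0, 2.0).delta_g_hp_kj_mol
        assert b == pytest.approx(2 * a, rel=1e-12)
        assert sasa.hydrophobic_energy(-2.0, -1.0).delta_g_hp_kj_mol == pytest.approx(
            -a, rel=1e-12
        )

    def test_energy_differences(self):
        results = {
            "Ec0VV": sasa.hydrophobic_energy(11.37, 7.76),
            "Ec0SH": sasa.hydrophobic_energy(9.95, 7.33),
        }
        table = sasa.energy_differences(results, ["Ec0SH"])
        row = table.set_index("mutant").loc["Ec0VV"]
        assert row["vs_Ec0SH"] == pytest.approx(20.8, abs=0.2)
        assert table.set_index("mutant").loc["Ec0SH", "vs_Ec0SH"] == 0.0

    def test_missing_baseline_rejected(self):
        with pytest.raises(KeyError):
            sasa.energy_differences({"a": sasa.hydrophobic_energy(1, 1)}, ["b"])
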