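"""DSSP-style secondary-structure assignment and category accounting.

Backbone hydrogen bonds follow the Kabsch–Sander electrostatic model:

    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332  kcal/mol

with distances in Å between the acceptor's C=O and the donor's N–H; a bond
exists when E < −0.5 kcal/mol. Proline cannot donate; a missing amide
hydrogen is placed geometrically (N–H 1.0 Å along the bisector of the
N−C(prev) and N−CA directions).

Assignment categories: H (α-helix; runs of ≥2 consecutive i→i+4 bonds),
E (β-sheet; ladders of ≥2 consecutive bridges), B (isolated β-bridge),
T (3/4/5-turn not already H/E/B), C (everything else), with priority
H > E > B > T. The "structure" aggregate is H + E + B + T. 3₁₀- and
π-helices are folded into T/C since only the α category is counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Frame, Topology, Trajectory

KCAL_COUPLING = 0.084 * 332.0  # Kabsch–Sander q1·q2·f
HBOND_CUTOFF_KCAL = -0.5
CATEGORIES = ("H", "E", "B", "T", "C")


@dataclass(frozen=True)
class HbondEnergy:
    donor: int
    acceptor: int
    energy_kcal_mol: float

    @property
    def is_bond(self) -> bool:
        return self.energy_kcal_mol < HBOND_CUTOFF_KCAL


@dataclass
class SecStructFrame:
    """One-letter label per residue for a single frame."""

    labels: np.ndarray  # dtype U1

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        out = {c: int(np.sum(self.labels == c)) for c in CATEGORIES}
        out["structure"] = out["H"] + out["E"] + out["B"] + out["T"]
        return out

    def __str__(self) -> str:
        return "".join(self.labels)


@dataclass
class SecStructSeries:
    time_ns: np.ndarray
    frames: list[SecStructFrame]


@dataclass
class SecStructWindowCounts:
    window: tuple[float, float]
    mean: dict[str, float]
    sd: dict[str, float]
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        cats = ["structure", "E", "H", "B", "T"]
        names = {"structure": "structure", "E": "beta_sheet", "H": "alpha_helix",
                 "B": "beta_bridge", "T": "turn"}
        return pd.DataFrame(
            [{"category": names[c], "mean_residues": self.mean[c], "sd_residues": self.sd[c]}
             for c in cats]
        )


@dataclass
class HelicityProfile:
    fraction: np.ndarray  # per residue, in [0, 1]
    window: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": np.arange(1, len(self.fraction) + 1), "helicity": self.fraction}
        )


def _backbone_arrays(frame: Frame, topology: Topology):
    """Per-residue N, CA, C, O, H coordinates (nm); NaN where absent."""
    n = topology.n_residues
    out = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O", "H")}
    for i in range(n):
        for name in ("N", "CA", "C", "O", "H"):
            if topology.has_atom(i, name):
                out[name][i] = frame.coords[topology.atom_index(i, name)]
    # geometric amide H where missing (not for Pro, not for the first residue)
    for i in range(1, n):
        if np.isnan(out["H"][i]).any() and topology.residue_name(i) != "PRO":
            npos, ca, cprev = out["N"][i], out["CA"][i], out["C"][i - 1]
            if np.isnan(npos).any() or np.isnan(ca).any() or np.isnan(cprev).any():
                continue
            u1 = npos - cprev
            u2 = npos - ca
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            out["H"][i] = npos + 0.100 * (u1 + u2) / np.linalg.norm(u1 + u2)
    return out


def backbone_hbond_energy(
    frame: Frame, topology: Topology, donor_i: int, acceptor_j: int
) -> HbondEnergy:
    """Kabsch–Sander energy of the N–H(donor) ··· O=C(acceptor) interaction."""
    if abs(donor_i - acceptor_j) < 2:
        raise ValueError("hydrogen bonds are defined only for |i−j| ≥ 2")
    if topology.residue_name(donor_i) == "PRO":
        raise ValueError("proline cannot donate a backbone hydrogen bond")
    bb = _backbone_arrays(frame, topology)
    npos, h = bb["N"][donor_i], bb["H"][donor_i]
    c, o = bb["C"][acceptor_j], bb["O"][acceptor_j]
    if any(np.isnan(v).any() for v in (npos, h, c, o)):
        raise KeyError(
            f"incomplete backbone for donor {donor_i} / acceptor {acceptor_j}"
        )
    # nm → Å
    r_on = 10.0 * np.linalg.norm(o - npos)
    r_ch = 10.0 * np.linalg.norm(c - h)
    r_oh = 10.0 * np.linalg.norm(o - h)
    r_cn = 10.0 * np.linalg.norm(c - npos)
    e = KCAL_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return HbondEnergy(donor=donor_i, acceptor=acceptor_j, energy_kcal_mol=float(e))


def _hbond_set(frame: Frame, topology: Topology) -> set[tuple[int, int]]:
    """Set of (acceptor, donor) residue pairs with a Kabsch–Sander bond."""
    n = topology.n_residues
    bb = _backbone_arrays(frame, topology)
    donors = [
        i
        for i in range(n)
        if topology.residue_name(i) != "PRO"
        and not np.isnan(bb["N"][i]).any()
        and not np.isnan(bb["H"][i]).any()
    ]
    acceptors = [
        j for j in range(n) if not np.isnan(bb["C"][j]).any() and not np.isnan(bb["O"][j]).any()
    ]
    bonds: set[tuple[int, int]] = set()
    if not donors or not acceptors:
        return bonds
    dN = bb["N"][donors]
    dH = bb["H"][donors]
    aC = bb["C"][acceptors]
    aO = bb["O"][acceptors]

    def pd2(a, b):
        diff = a[:, None, :] - b[None, :, :]
        return 10.0 * np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))  # Å

    e = KCAL_COUPLING * (
        1.0 / pd2(aO, dN) + 1.0 / pd2(aC, dH) - 1.0 / pd2(aO, dH) - 1.0 / pd2(aC, dN)
    )
    for jj, j in enumerate(acceptors):
        for ii, i in enumerate(donors):
            if abs(i - j) >= 2 and e[jj, ii] < HBOND_CUTOFF_KCAL:
                bonds.add((j, i))
    return bonds


def assign_frame(frame: Frame, topology: Topology) -> SecStructFrame:
    """Assign H/E/B/T/C per residue from the frame's backbone hydrogen bonds."""
    n = topology.n_residues
    if n < 5:
        return SecStructFrame(labels=np.full(n, "C", dtype="U1"))
    hb = _hbond_set(frame, topology)

    def turn(i: int, k: int) -> bool:
        return (i, i + k) in hb  # CO of i accepts NH of i+k

    labels = np.full(n, "C", dtype="U1")

    # bridges (|i−j| ≥ 3)
    parallel: set[tuple[int, int]] = set()
    antiparallel: set[tuple[int, int]] = set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if ((i - 1, j) in hb and (j, i + 1) in hb) or ((j - 1, i) in hb and (i, j + 1) in hb):
                parallel.add((i, j))
            if ((i, j) in hb and (j, i) in hb) or ((i - 1, j + 1) in hb and (j - 1, i + 1) in hb):
                antiparallel.add((i, j))

    def in_ladder(i: int, j: int, bridges: set, anti: bool) -> bool:
        step = -1 if anti else 1
        return (i + 1, j + step) in bridges or (i - 1, j - step) in bridges

    sheet: set[int] = set()
    bridge: set[int] = set()
    for (i, j) in parallel:
        (sheet if in_ladder(i, j, parallel, False) else bridge).update((i, j))
    for (i, j) in antiparallel:
        (sheet if in_ladder(i, j, antiparallel, True) else bridge).update((i, j))

    # α-helix: two consecutive 4-turns at i−1 and i → residues i..i+3
    helix: set[int] = set()
    for i in range(1, n - 4):
        if turn(i - 1, 4) and turn(i, 4):
            helix.update(range(i, i + 4))

    # turns: interior residues of any 3/4/5-turn
    turn_res: set[int] = set()
    for k in (3, 4, 5):
        for i in range(0, n - k):
            if turn(i, k):
                turn_res.update(range(i + 1, i + k))

    for i in range(n):
        if i in helix:
            labels[i] = "H"
        elif i in sheet:
            labels[i] = "E"
        elif i in bridge:
            labels[i] = "B"
        elif i in turn_res:
            labels[i] = "T"
    return SecStructFrame(labels=labels)


def assign_series(traj: Trajectory) -> SecStructSeries:
    frames = [assign_frame(fr, traj.topology) for fr in traj.frames]
    return SecStructSeries(time_ns=traj.times, frames=frames)


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(len(times), dtype=bool)
    t0, t1 = window
    return (times >= t0) & (times <= t1)


def window_counts(
    series: SecStructSeries, window: tuple[float, float] | None = None
) -> SecStructWindowCounts:
    """Mean ± population SD of per-frame category counts over a window."""
    mask = _window_mask(series.time_ns, window)
    chosen = [f for f, m in zip(series.frames, mask) if m]
    if len(chosen) < 2:
        raise ValueError("window must contain at least 2 frames")
    keys = list(CATEGORIES) + ["structure"]
    table = {k: np.array([f.counts()[k] for f in chosen], dtype=float) for k in keys}
    t = series.time_ns[mask]
    return SecStructWindowCounts(
        window=(float(t[0]), float(t[-1])),
        mean={k: float(v.mean()) for k, v in table.items()},
        sd={k: float(v.std()) for k, v in table.items()},
        n_frames=len(chosen),
    )


def helicity_profile(
    series: SecStructSeries, window: tuple[float, float] | None = None
) -> HelicityProfile:
    """Per-residue fraction of window frames labelled H."""
    mask = _window_mask(series.time_ns, window)
    chosen = [f for f, m in zip(series.frames, mask) if m]
    if not chosen:
        raise ValueError("window contains no frames")
    stack = np.stack([f.labels == "H" for f in chosen])
    t = series.time_ns[mask]
    return HelicityProfile(
        fraction=stack.mean(axis=0), window=(float(t[0]), float(t[-1]))
    )
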