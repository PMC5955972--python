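"""Ion-pair (salt-bridge) detection and occupancy statistics.

A salt bridge is operationalized as a side-chain carbon–carbon contact:
the distance between Cε/Cδ of a positively charged residue (Lys → Cε,
Arg → Cδ) and Cδ/Cγ of a negatively charged residue (Glu → Cδ, Asp → Cγ)
below a cutoff, 0.6 nm by default, with strict inequality (exactly 0.6 nm
does not count). The C-terminal carboxyl carbon participates as an extra
negative site; the N-terminal backbone nitrogen can optionally participate
as a positive site. Histidine is not treated as charged.

Occupancy of a pair is the percentage of sampled frames in which the
criterion holds; a residue's summed occupancy over partners may exceed
100% when it bridges more than one partner at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import Topology, Trajectory

PartnerKey = int | str  # residue index, "C-terminal" or "N-terminal"


@dataclass
class CriterionAtomMap:
    """Which side-chain carbon carries each residue's charge, plus the cutoff.

    ``positive["ARG"]`` may be set to ``"CZ"`` (guanidinium carbon) as an
    alternative convention; the default follows the Cδ criterion.
    """

    positive: dict[str, str] = field(default_factory=lambda: {"LYS": "CE", "ARG": "CD"})
    negative: dict[str, str] = field(default_factory=lambda: {"GLU": "CD", "ASP": "CG"})
    cutoff_nm: float = 0.6
    include_c_terminal: bool = True
    include_n_terminal: bool = False

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff_nm must be positive")

    def role_of(self, residue_name: str) -> str | None:
        if residue_name in self.positive:
            return "positive"
        if residue_name in self.negative:
            return "negative"
        return None


class ChargedSite(NamedTuple):
    residue_index: int
    role: str  # "positive" | "negative"
    atom_index: int
    label: str  # e.g. "Lys87", "C-terminal"


def residue_label(topology: Topology, residue_index: int) -> str:
    """1-based human-readable residue label, e.g. ``Lys87``."""
    return f"{topology.residue_name(residue_index).capitalize()}{residue_index + 1}"


def criterion_atom(
    topology: Topology, residue_index: int, role: str, cmap: CriterionAtomMap | None = None
) -> int:
    """Atom index of the criterion carbon for a residue in the given role."""
    cmap = cmap or CriterionAtomMap()
    table = {"positive": cmap.positive, "negative": cmap.negative}[role]
    resname = topology.residue_name(residue_index)
    if resname not in table:
        raise ValueError(
            f"residue {residue_label(topology, residue_index)} is not chargeable as {role}"
        )
    return topology.atom_index(residue_index, table[resname])


def charged_sites(topology: Topology, cmap: CriterionAtomMap | None = None) -> list[ChargedSite]:
    """All charged criterion sites of a chain, terminal sites included."""
    cmap = cmap or CriterionAtomMap()
    sites: list[ChargedSite] = []
    for i in range(topology.n_residues):
        role = cmap.role_of(topology.residue_name(i))
        if role is not None:
            sites.append(
                ChargedSite(i, role, criterion_atom(topology, i, role, cmap), residue_label(topology, i))
            )
    if cmap.include_c_terminal:
        last = topology.n_residues - 1
        sites.append(ChargedSite(last, "negative", topology.atom_index(last, "C"), "C-terminal"))
    if cmap.include_n_terminal:
        sites.append(ChargedSite(0, "positive", topology.atom_index(0, "N"), "N-terminal"))
    return sites


@dataclass
class PairDistanceSeries:
    donor: int
    acceptor: int
    time_ns: np.ndarray
    distance_nm: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.time_ns, "distance_nm": self.distance_nm})


@dataclass
class OccupancyReport:
    """Per-pair and per-residue salt-bridge occupancy percentages."""

    per_pair_occupancy_pct: dict[tuple[int, PartnerKey], float]
    per_residue_sum_pct: dict[int, float]
    window: tuple[float, float]
    sampling_interval_ns: float
    pair_labels: dict[tuple[int, PartnerKey], tuple[str, str]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.per_pair_occupancy_pct, key=_pair_sort_key):
            res_lab, part_lab = self.pair_labels.get(key, (str(key[0] + 1), str(key[1])))
            rows.append(
                {
                    "residue": res_lab,
                    "partner": part_lab,
                    "occupancy_pct": self.per_pair_occupancy_pct[key],
                }
            )
        return pd.DataFrame(rows, columns=["residue", "partner", "occupancy_pct"])


def _pair_sort_key(key: tuple[int, PartnerKey]):
    target, partner = key
    if isinstance(partner, int):
        return (target, 0, partner)
    return (target, 1, partner)


@dataclass
class CountSeries:
    """Mean number of salt-bridge partners of one residue per time bin."""

    residue_index: int
    time_ns: np.ndarray  # left bin edges
    counts: np.ndarray
    bin_ns: float

    @property
    def overall_mean(self) -> float:
        return float(self.counts.mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.time_ns, "mean_count": self.counts})


def _site_distances(traj: Trajectory, atom_a: int, atom_b: int) -> np.ndarray:
    xyz = traj.coords
    diff = xyz[:, atom_a, :] - xyz[:, atom_b, :]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def pair_distances(
    traj: Trajectory, donor: int, acceptor: int, cmap: CriterionAtomMap | None = None
) -> PairDistanceSeries:
    """Per-frame criterion-atom distance between a positive and a negative residue."""
    cmap = cmap or CriterionAtomMap()
    atom_d = criterion_atom(traj.topology, donor, "positive", cmap)
    atom_a = criterion_atom(traj.topology, acceptor, "negative", cmap)
    return PairDistanceSeries(
        donor=donor,
        acceptor=acceptor,
        time_ns=traj.times,
        distance_nm=_site_distances(traj, atom_d, atom_a),
    )


def _window_frames(
    traj: Trajectory, window: tuple[float, float] | None, sampling_interval_ns: float | None
) -> np.ndarray:
    times = traj.times
    if window is None:
        idx = np.arange(traj.n_frames)
        window = (float(times[0]), float(times[-1]) + 1e-12)
    else:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window must satisfy t0 < t1")
        idx = np.nonzero((times >= t0) & (times <= t1))[0]
    if idx.size == 0:
        raise ValueError("window contains no frames")
    if sampling_interval_ns is not None:
        spacing = np.min(np.diff(times)) if traj.n_frames > 1 else sampling_interval_ns
        stride = max(1, int(round(sampling_interval_ns / spacing)))
        idx = idx[::stride]
    return idx


def occupancy(
    traj: Trajectory,
    targets: list[int],
    window: tuple[float, float] | None = None,
    cmap: CriterionAtomMap | None = None,
    prefilter_nm: float | None = None,
    sampling_interval_ns: float | None = None,
) -> OccupancyReport:
    """Occupancy of every oppositely charged partner for each target residue.

    A pair counts in a frame when the criterion-atom distance is strictly
    below the cutoff. ``prefilter_nm`` drops pairs whose minimum distance
    over the *whole* trajectory never falls below it — a reporting filter
    that mimics discarding never-close pairs, without altering the values
    of the pairs retained.
    """
    cmap = cmap or CriterionAtomMap()
    top = traj.topology
    sites = charged_sites(top, cmap)
    idx = _window_frames(traj, window, sampling_interval_ns)
    times = traj.times
    win = (float(times[idx[0]]), float(times[idx[-1]]))
    interval = sampling_interval_ns or (
        float(np.min(np.diff(times))) if traj.n_frames > 1 else 0.0
    )

    per_pair: dict[tuple[int, PartnerKey], float] = {}
    labels: dict[tuple[int, PartnerKey], tuple[str, str]] = {}
    per_res: dict[int, float] = {}
    for target in targets:
        role = cmap.role_of(top.residue_name(target))
        if role is None:
            raise ValueError(f"target {residue_label(top, target)} is not a charged residue")
        target_atom = criterion_atom(top, target, role, cmap)
        opposite = "negative" if role == "positive" else "positive"
        total = 0.0
        for site in sites:
            if site.role != opposite or site.residue_index == target:
                continue
            dists = _site_distances(traj, target_atom, site.atom_index)
            occ = 100.0 * float(np.mean(dists[idx] < cmap.cutoff_nm))
            total += occ
            if prefilter_nm is not None and float(dists.min()) > prefilter_nm:
                continue
            is_terminal = site.label.endswith("terminal")
            key = (target, site.label if is_terminal else site.residue_index)
            per_pair[key] = occ
            labels[key] = (residue_label(top, target), site.label)
        per_res[target] = total
    return OccupancyReport(
        per_pair_occupancy_pct=per_pair,
        per_residue_sum_pct=per_res,
        window=win,
        sampling_interval_ns=interval,
        pair_labels=labels,
    )


def count_series(
    traj: Trajectory,
    residue_index: int,
    bin_ns: float = 0.4,
    cmap: CriterionAtomMap | None = None,
) -> CountSeries:
    """Mean number of distinct partners within the cutoff, per time bin."""
    cmap = cmap or CriterionAtomMap()
    top = traj.topology
    times = traj.times
    if traj.n_frames > 1:
        spacing = float(np.min(np.diff(times)))
        if bin_ns < spacing - 1e-12:
            raise ValueError(f"bin_ns={bin_ns} smaller than frame spacing {spacing}")
    role = cmap.role_of(top.residue_name(residue_index))
    if role is None:
        raise ValueError(f"residue {residue_label(top, residue_index)} is not charged")
    target_atom = criterion_atom(top, residue_index, role, cmap)
    opposite = "negative" if role == "positive" else "positive"
    counts_per_frame = np.zeros(traj.n_frames)
    for site in charged_sites(top, cmap):
        if site.role != opposite or site.residue_index == residue_index:
            continue
        dists = _site_distances(traj, target_atom, site.atom_index)
        counts_per_frame += (dists < cmap.cutoff_nm).astype(float)
    t0 = times[0]
    bin_of = np.floor((times - t0) / bin_ns + 1e-9).astype(int)
    n_bins = int(bin_of.max()) + 1
    sums = np.bincount(bin_of, weights=counts_per_frame, minlength=n_bins)
    ns = np.bincount(bin_of, minlength=n_bins)
    mask = ns > 0
    return CountSeries(
        residue_index=residue_index,
        time_ns=t0 + bin_ns * np.nonzero(mask)[0],
        counts=sums[mask] / ns[mask],
        bin_ns=bin_ns,
    )


def aggregate_subunits(reports: list):
    """Elementwise mean across subunit reports; pairs missing from a report
    are treated as 0 before averaging."""
    if not reports:
        raise ValueError("no reports to aggregate")
    first = reports[0]
    if isinstance(first, OccupancyReport):
        targets = set(first.per_residue_sum_pct)
        for r in reports[1:]:
            if set(r.per_residue_sum_pct) != targets:
                raise ValueError("occupancy reports cover different target residues")
        n = len(reports)
        all_keys = set().union(*(r.per_pair_occupancy_pct.keys() for r in reports))
        per_pair = {
            k: sum(r.per_pair_occupancy_pct.get(k, 0.0) for r in reports) / n
            for k in all_keys
        }
        per_res = {
            t: sum(r.per_residue_sum_pct[t] for r in reports) / n for t in targets
        }
        labels: dict = {}
        for r in reports:
            labels.update(r.pair_labels)
        return OccupancyReport(
            per_pair_occupancy_pct=per_pair,
            per_residue_sum_pct=per_res,
            window=first.window,
            sampling_interval_ns=first.sampling_interval_ns,
            pair_labels=labels,
        )
    if isinstance(first, CountSeries):
        for r in reports[1:]:
            if r.residue_index != first.residue_index:
                raise ValueError("count series refer to different residues")
            if r.counts.shape != first.counts.shape or r.bin_ns != first.bin_ns:
                raise ValueError("count series have mismatched binning")
        counts = np.mean([r.counts for r in reports], axis=0)
        return CountSeries(
            residue_index=first.residue_index,
            time_ns=first.time_ns.copy(),
            counts=counts,
            bin_ns=first.bin_ns,
        )
    raise TypeError(f"cannot aggregate objects of type {type(first).__name__}")
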