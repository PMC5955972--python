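"""End-to-end orchestration: per-subunit analyses, window selection,
subunit aggregation and report tables, driven by a single JSON config.

Temperatures (300/400/450 K) are labels on separate input trajectories;
nothing is simulated here. Named analysis windows default to the study
layout: a native window early in the run, a denatured window covering the
bulk, a late window, and a helicity window at the end. Windows that extend
beyond a trajectory are clipped to the available span with a warning, since
desk-scale runs are far shorter than the microsecond originals.

Reports are deterministic given config and seed: provenance records a
config hash and package version, never wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import geometry, saltbridge, sasa, secstruct, trajectory_io
from .model import Trajectory
from .saltbridge import CriterionAtomMap

DEFAULT_WINDOWS = {
    "native": (50.0, 400.0),
    "denatured": (400.0, 1400.0),
    "late": (1000.0, 1400.0),
    "helix_window": (1200.0, 1400.0),
}


@dataclass
class AnalysisConfig:
    """Inputs, windows and parameters of a full analysis run."""

    inputs: list[dict]  # {label, topology, trajectory, formats...}
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    target_residues: list[int] = field(default_factory=list)  # 1-based
    cutoff_nm: float = 0.6
    probe_nm: float = 0.14
    n_points: int = 960
    prefilter_nm: float | None = None
    bin_ns: float = 0.4
    max_asa_frames: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (t0, t1) in self.windows.items():
            if t0 < 0 or t1 <= t0:
                raise ValueError(f"window {name!r}: need 0 <= t0 < t1")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        if "windows" in raw:
            raw["windows"] = {k: tuple(v) for k, v in raw["windows"].items()}
        return cls(**raw)

    def canonical_json(self) -> str:
        def default(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError

        payload = {
            "inputs": self.inputs,
            "windows": {k: list(v) for k, v in self.windows.items()},
            "target_residues": self.target_residues,
            "cutoff_nm": self.cutoff_nm,
            "probe_nm": self.probe_nm,
            "n_points": self.n_points,
            "prefilter_nm": self.prefilter_nm,
            "bin_ns": self.bin_ns,
            "max_asa_frames": self.max_asa_frames,
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True, default=default)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame]
    provenance: dict
    output_dir: Path | None = None


class StageError(RuntimeError):
    """An analysis stage failed; carries stage name and input label."""


def _clip_window(window, traj: Trajectory, name: str):
    t0, t1 = window
    times = traj.times
    lo, hi = float(times[0]), float(times[-1])
    c0, c1 = max(t0, lo), min(t1, hi)
    if (c0, c1) != (t0, t1):
        warnings.warn(f"window {name!r} [{t0}, {t1}] clipped to [{c0}, {c1}] ns")
    if c1 <= c0:
        return None
    return (c0, c1)


def _load_trajectory(inp: dict) -> Trajectory:
    top = trajectory_io.read_topology(inp["topology"], inp.get("topology_format", "pdb"))
    return trajectory_io.read_trajectory(
        top,
        inp["trajectory"],
        inp.get("trajectory_format", "multi_model_pdb"),
        stride_ns=inp.get("stride_ns", 0.4),
    )


def run_pipeline(config: AnalysisConfig, out_dir=None) -> RunReport:
    """Run geometry → salt bridges → ASA → secondary structure for every
    input, aggregate subunits sharing a label, and emit all tables."""
    cmap = CriterionAtomMap(cutoff_nm=config.cutoff_nm)
    targets0 = [t - 1 for t in config.target_residues]
    tables: dict[str, pd.DataFrame] = {}
    by_label: dict[str, list] = {}

    try:
        _run_stages(config, cmap, targets0, tables, by_label)
    except StageError as exc:
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name, df in sorted(tables.items()):
                trajectory_io.write_table(df, out / f"{name}.csv", "csv")
            (out / "FAILED.json").write_text(
                json.dumps({"error": str(exc)}, indent=1) + "\n"
            )
        raise

    provenance = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "n_inputs": len(config.inputs),
    }
    report = RunReport(tables=tables, provenance=provenance)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(tables.items()):
            trajectory_io.write_table(df, out / f"{name}.csv", "csv")
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")
        report.output_dir = out
    return report


def _run_stages(config, cmap, targets0, tables, by_label) -> None:
    for inp in config.inputs:
        label = inp["label"]
        subunit = inp.get("subunit", "A")
        key = f"{label}_{subunit}"
        try:
            traj = _load_trajectory(inp)
        except Exception as exc:
            raise StageError(f"stage=load input={key}: {exc}") from exc

        try:
            tables[f"rmsd_{key}"] = geometry.rmsd_series(traj).to_dataframe()
            tables[f"rg_{key}"] = geometry.rg_series(traj).to_dataframe()
        except Exception as exc:
            raise StageError(f"stage=geometry input={key}: {exc}") from exc

        occ = None
        if targets0:
            try:
                win = _clip_window(
                    config.windows.get("denatured", DEFAULT_WINDOWS["denatured"]),
                    traj,
                    "denatured",
                )
                occ = saltbridge.occupancy(
                    traj, targets0, window=win, cmap=cmap, prefilter_nm=config.prefilter_nm
                )
                counts = [
                    saltbridge.count_series(traj, t, bin_ns=config.bin_ns, cmap=cmap)
                    for t in targets0
                ]
            except Exception as exc:
                raise StageError(f"stage=saltbridge input={key}: {exc}") from exc
            tables[f"occupancy_{key}"] = occ.to_dataframe()
            for t, cs in zip(config.target_residues, counts):
                tables[f"counts_{key}_res{t}"] = cs.to_dataframe()

        try:
            stride = max(1, traj.n_frames // config.max_asa_frames)
            sub = Trajectory(topology=traj.topology, frames=traj.frames[::stride])
            series = sasa.asa_series(sub, probe_nm=config.probe_nm, n_points=config.n_points)
            asa_summaries = {}
            for name in ("native", "denatured"):
                win = _clip_window(config.windows[name], sub, name) if name in config.windows else None
                if win is not None:
                    try:
                        asa_summaries[name] = sasa.window_summary(series, win)
                    except ValueError:
                        pass
        except Exception as exc:
            raise StageError(f"stage=sasa input={key}: {exc}") from exc
        for name, summ in asa_summaries.items():
            tables[f"asa_{name}_{key}"] = summ.to_dataframe()

        try:
            ss = secstruct.assign_series(traj)
            win = _clip_window(
                config.windows.get("denatured", DEFAULT_WINDOWS["denatured"]), traj, "denatured"
            )
            counts_tab = secstruct.window_counts(ss, win).to_dataframe()
            hwin = _clip_window(
                config.windows.get("helix_window", DEFAULT_WINDOWS["helix_window"]),
                traj,
                "helix_window",
            )
            heli = secstruct.helicity_profile(ss, hwin).to_dataframe()
        except Exception as exc:
            raise StageError(f"stage=secstruct input={key}: {exc}") from exc
        tables[f"secstruct_{key}"] = counts_tab
        tables[f"helicity_{key}"] = heli

        by_label.setdefault(label, []).append(
            {"occ": occ, "asa": asa_summaries, "key": key}
        )

    # aggregate subunits sharing a mutant label
    for label, runs in by_label.items():
        occs = [r["occ"] for r in runs if r["occ"] is not None]
        if len(occs) > 1:
            tables[f"occupancy_{label}_mean"] = saltbridge.aggregate_subunits(occs).to_dataframe()
        natives = [r["asa"].get("native") for r in runs if r["asa"].get("native")]
        denatureds = [r["asa"].get("denatured") for r in runs if r["asa"].get("denatured")]
        if natives and denatureds:
            d_np = float(np.mean([d.mean_hydrophobic_nm2 for d in denatureds])) - float(
                np.mean([n.mean_hydrophobic_nm2 for n in natives])
            )
            d_p = float(np.mean([d.mean_hydrophilic_nm2 for d in denatureds])) - float(
                np.mean([n.mean_hydrophilic_nm2 for n in natives])
            )
            res = sasa.hydrophobic_energy(d_np, d_p, native_label=label, denatured_label=label)
            tables[f"hpenergy_{label}"] = pd.DataFrame(
                [
                    {
                        "mutant": label,
                        "delta_asa_nonpolar_nm2": res.delta_asa_nonpolar_nm2,
                        "delta_asa_polar_nm2": res.delta_asa_polar_nm2,
                        "delta_g_hp_kj_mol": res.delta_g_hp_kj_mol,
                    }
                ]
            )


def hpenergy_from_tables(
    native_table: pd.DataFrame, denatured_table: pd.DataFrame
) -> pd.DataFrame:
    """Hydrophobic energies from class-ASA summary tables.

    Both tables need columns ``mutant``, ``class`` (hydrophobic/hydrophilic)
    and ``mean_nm2``; rows are matched by mutant and class, differenced
    (denatured − native) and fed through the energy equation.
    """
    out_rows = []
    for df, req in ((native_table, "native"), (denatured_table, "denatured")):
        for col in ("mutant", "class", "mean_nm2"):
            if col not in df.columns:
                raise ValueError(f"{req} table lacks column {col!r}")
    nat = native_table.set_index(["mutant", "class"])["mean_nm2"]
    den = denatured_table.set_index(["mutant", "class"])["mean_nm2"]
    for mutant in denatured_table["mutant"].unique():
        try:
            d_np = float(den[(mutant, "hydrophobic")]) - float(nat[(mutant, "hydrophobic")])
            d_p = float(den[(mutant, "hydrophilic")]) - float(nat[(mutant, "hydrophilic")])
        except KeyError as exc:
            raise ValueError(f"missing class row for mutant {mutant!r}: {exc}") from exc
        res = sasa.hydrophobic_energy(d_np, d_p)
        out_rows.append(
            {
                "mutant": mutant,
                "delta_asa_nonpolar_nm2": d_np,
                "delta_asa_polar_nm2": d_p,
                "delta_g_hp_kj_mol": res.delta_g_hp_kj_mol,
            }
        )
    return pd.DataFrame(out_rows)
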