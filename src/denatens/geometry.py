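"""Frame-level geometric observables: superposition RMSD and radius of gyration.

RMSD uses the Kabsch least-squares rigid superposition with the standard
reflection correction (the smallest singular value is sign-flipped when the
optimal orthogonal transform would be improper), so chirality is preserved.
No periodic-boundary unwrapping is performed; frames are assumed to contain
whole molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Frame, Trajectory


@dataclass
class RmsdSeries:
    time_ns: np.ndarray
    rmsd_nm: np.ndarray
    reference_frame: int | str = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_ns": self.time_ns, "rmsd_nm": self.rmsd_nm})


@dataclass
class RgSeries:
    time_ns: np.ndarray
    rg_nm: np.ndarray
    mass_weighted: bool = True

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_ns": self.time_ns, "rg_nm": self.rg_nm})


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_nm)`` such that
    ``mobile @ rotation.T + translation`` minimises the weighted RMS
    distance to ``reference`` over all proper rotations and translations.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    pm = mobile - mu_m
    pr = reference - mu_r

    # degenerate (collinear) configurations have rank-deficient covariance
    if np.linalg.matrix_rank(pm.T @ (pm * w[:, None]), tol=1e-12) < 2:
        raise ValueError("degenerate (collinear) configuration")

    h = (pm * w[:, None]).T @ pr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = pm @ rot.T - pr
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    trans = mu_r - rot @ mu_m
    return rot, trans, rmsd


def rmsd_series(
    traj: Trajectory,
    selection: str | np.ndarray = "calpha",
    reference: Frame | None = None,
) -> RmsdSeries:
    """Per-frame superposed RMSD against a fixed reference (default: frame 0)."""
    idx = traj.topology.select(selection) if isinstance(selection, str) else np.asarray(selection)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    ref = reference if reference is not None else traj.frames[0]
    ref_xyz = ref.coords[idx]
    values = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        _, _, values[k] = superpose(fr.coords[idx], ref_xyz)
    return RmsdSeries(
        time_ns=traj.times,
        rmsd_nm=values,
        reference_frame=0 if reference is None else "external",
    )


def radius_of_gyration(
    frame: Frame,
    selection: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted radius of gyration sqrt(Σ w_i |r_i − r̄|² / Σ w_i) in nm."""
    xyz = frame.coords if selection is None else frame.coords[np.asarray(selection)]
    if xyz.shape[0] == 0:
        raise ValueError("empty atom selection")
    if weights is None:
        w = np.ones(xyz.shape[0])
    else:
        w = np.asarray(weights, dtype=np.float64)
        if selection is not None and w.shape[0] != xyz.shape[0]:
            w = w[np.asarray(selection)]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    centroid = (w[:, None] * xyz).sum(axis=0) / wsum
    d2 = np.einsum("ij,ij->i", xyz - centroid, xyz - centroid)
    return float(np.sqrt((w @ d2) / wsum))


def rg_series(
    traj: Trajectory,
    selection: str | np.ndarray = "all",
    mass_weighted: bool = True,
) -> RgSeries:
    """Per-frame radius of gyration; mass-weighted by default (gyrate convention)."""
    idx = traj.topology.select(selection) if isinstance(selection, str) else np.asarray(selection)
    weights = traj.topology.masses[idx] if mass_weighted else None
    values = np.array(
        [radius_of_gyration(fr, selection=idx, weights=weights) for fr in traj.frames]
    )
    return RgSeries(time_ns=traj.times, rg_nm=values, mass_weighted=mass_weighted)
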