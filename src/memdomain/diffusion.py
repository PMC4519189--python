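"""Lateral diffusion from mean-squared displacement.

MSD is time- and molecule-averaged over the lateral (xy) coordinates after
periodic unwrapping (nearest-image displacement accumulation, assuming the
per-stride displacement stays below half the box) and after removing the
per-frame lateral centre-of-mass motion of the system.  The diffusion
coefficient is the least-squares slope over a lag window divided by 4
(two dimensions), reported in cm^2/s with 1 nm^2/ns = 1e-5 cm^2/s; no
coarse-graining speed-up factor is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Trajectory

__all__ = ["MSDResult", "DiffusionFit", "msd", "fit_diffusion", "NM2_PER_NS_TO_CM2_PER_S"]

NM2_PER_NS_TO_CM2_PER_S = 1.0e-5


@dataclass
class MSDResult:
    lags_ns: np.ndarray
    msd_nm2: np.ndarray
    n_molecules: int
    group: str = ""


@dataclass
class DiffusionFit:
    D_nm2_ns: float
    D_cm2_s: float
    slope: float
    intercept: float
    r_squared: float
    fit_window: tuple[float, float]


def _unwrap_xy(pos: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Accumulate nearest-image displacements: (F, M, 2) wrapped -> unwrapped."""
    d = np.diff(pos, axis=0)
    d -= box_xy * np.round(d / box_xy)
    return np.concatenate([pos[:1], pos[:1] + np.cumsum(d, axis=0)])


def select_group(
    traj: Trajectory,
    species: list[str] | None = None,
    leaflet: str | None = None,
    protein: bool = False,
    saturation: str | None = None,
) -> np.ndarray:
    """Molecule indices of a diffusion group."""
    top = traj.topology
    if protein:
        sel = top.is_protein
    else:
        sel = top.is_lipid
        if species is not None:
            sel &= np.isin(top.mol_species, species)
        if saturation is not None:
            sel &= top.mol_saturation == saturation
        if leaflet is not None:
            sel &= top.mol_leaflet == leaflet
    mols = np.flatnonzero(sel)
    if len(mols) == 0:
        raise ValueError("diffusion group is empty")
    return mols


def msd(
    traj: Trajectory,
    mols: np.ndarray | None = None,
    max_lag_fraction: float = 0.5,
    n_lags: int = 200,
    remove_com: bool = True,
    group: str = "",
    **group_kwargs,
) -> MSDResult:
    """Time- and molecule-averaged lateral MSD of a molecule group."""
    if len(traj) < 3:
        raise ValueError("need at least three frames for an MSD")
    if mols is None:
        mols = select_group(traj, **group_kwargs)
    top = traj.topology
    box_xy = traj.boxes[0, :2]
    ref = top.reference_bead()
    pos = _unwrap_xy(traj.coords[:, ref[mols], :2], box_xy)
    if remove_com:
        all_pos = _unwrap_xy(traj.coords[:, ref, :2], box_xy)
        drift = (all_pos - all_pos[:1]).mean(axis=1)
        pos = pos - drift[:, None, :]
    F = len(traj)
    max_lag = max(int(F * max_lag_fraction), 2)
    lags = np.unique(np.linspace(1, max_lag, min(n_lags, max_lag)).astype(int))
    out = np.empty(len(lags) + 1)
    out[0] = 0.0
    for k, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]
        out[k + 1] = float(np.mean((disp**2).sum(axis=-1)))
    lag_times = np.concatenate([[0.0], lags * traj.frame_stride])
    return MSDResult(lag_times, out, len(mols), group)


def fit_diffusion(
    result: MSDResult, fit_window: tuple[float, float] = (0.1, 0.5)
) -> DiffusionFit:
    """Least-squares line over the relative lag window; D = slope / 4."""
    lo, hi = fit_window
    if not 0 <= lo < hi <= 1:
        raise ValueError("fit window must satisfy 0 <= lo < hi <= 1")
    t_max = result.lags_ns[-1]
    sel = (result.lags_ns >= lo * t_max) & (result.lags_ns <= hi * t_max)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than two lag points")
    x = result.lags_ns[sel]
    y = result.msd_nm2[sel]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d = float(slope) / 4.0
    return DiffusionFit(
        D_nm2_ns=d,
        D_cm2_s=d * NM2_PER_NS_TO_CM2_PER_S,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        fit_window=fit_window,
    )
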