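"""Lateral density maps, the 2/3-of-maximum enrichment rule and the merged
Lo-like / Ld-like domain classification.

Density maps accumulate the lateral positions of one molecule class
(cholesterol, saturated+mono-unsaturated lipids, polyunsaturated lipids or
protein) over a time window, by default through one reference bead per lipid
(the linker bead; the hydroxyl for cholesterol).  A grid cell is "enriched"
in a class when its density reaches 2/3 of that class's maximum over the
box; the three lipid masks and the protein mask merge into a categorical
map: cells enriched in cholesterol and/or saturated+mono lipids form the
Lo-like domain, cells enriched only in polyunsaturated lipids the Ld-like
domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Topology, Trajectory

__all__ = [
    "DensityMap2D",
    "density_map",
    "class_molecules",
    "DomainClassMap",
    "classify_domains",
    "protein_domain_location",
    "protein_centered_overlay",
    "CODES",
    "LO_CODES",
    "LD_CODES",
]

#: categorical codes of the merged map
CODES = {
    "none": 0,
    "protein": 1,
    "chol_only": 2,
    "satmono_only": 3,
    "lo": 4,  # cholesterol AND saturated/mono
    "ld": 5,  # polyunsaturated only
    "all_mix": 6,
    "chol_poly": 7,
    "poly_satmono": 8,
}
CODE_NAMES = {v: k for k, v in CODES.items()}

#: codes forming the Lo-like domain (enriched in CHOL, sat+mono, or both)
LO_CODES = (CODES["chol_only"], CODES["satmono_only"], CODES["lo"])
#: codes forming the Ld-like domain
LD_CODES = (CODES["ld"],)

CLASSES = ("CHOL", "satmono", "poly", "protein")

DEFAULT_CELL = 0.5  # nm
DEFAULT_WINDOW = 2000.0  # ns


def class_molecules(top: Topology, cls: str) -> np.ndarray:
    """Molecule indices of one density class."""
    sat = top.mol_saturation
    if cls == "CHOL":
        return np.flatnonzero(top.is_chol)
    if cls == "satmono":
        return np.flatnonzero(np.isin(sat, ["saturated", "mono"]) & top.is_phospholipid)
    if cls == "poly":
        return np.flatnonzero((sat == "poly") & top.is_phospholipid)
    if cls == "protein":
        return np.flatnonzero(top.is_protein)
    raise ValueError(f"unknown density class {cls!r}")


@dataclass
class DensityMap2D:
    """Window-averaged lateral density of one molecule class."""

    cls: str
    density: np.ndarray  # (nx, ny), count / nm^2 averaged over window frames
    cell_size: tuple[float, float]
    window: tuple[float, float]  # (t_start, t_end) ns
    n_frames: int
    total_count: float  # beads binned, summed over frames

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape

    def enriched(self, threshold_fraction: float = 2.0 / 3.0) -> np.ndarray:
        """Cells whose density reaches *threshold_fraction* of the map max."""
        m = self.density.max()
        if m <= 0:
            return np.zeros(self.shape, dtype=bool)
        return self.density >= threshold_fraction * m


def _class_beads(top: Topology, cls: str, all_beads: bool) -> np.ndarray:
    mols = class_molecules(top, cls)
    if cls == "protein" or all_beads:
        return (
            np.concatenate([np.arange(top.mol_start[m], top.mol_stop[m]) for m in mols])
            if len(mols)
            else np.empty(0, dtype=np.int64)
        )
    return top.reference_bead()[mols]


def density_map(
    traj: Trajectory,
    cls: str,
    window: tuple[float, float] | None = None,
    cell_size: float = DEFAULT_CELL,
    all_beads: bool = False,
    shift: np.ndarray | None = None,
) -> DensityMap2D:
    """Bin the lateral positions of one class over a time window.

    *shift* optionally translates coordinates per frame (used by the
    protein-centred overlay); positions are wrapped periodically.
    """
    if window is None:
        window = (float(traj.times[0]), traj.span_end)
    sub = traj.window(*window)
    top = traj.topology
    beads = _class_beads(top, cls, all_beads)
    box_xy = sub.boxes[0, :2]
    nx = max(int(round(box_xy[0] / cell_size)), 1)
    ny = max(int(round(box_xy[1] / cell_size)), 1)
    H = np.zeros((nx, ny))
    total = 0.0
    for f in range(len(sub)):
        if len(beads) == 0:
            break
        xy = sub.coords[f, beads, :2]
        if shift is not None:
            xy = xy + shift[f]
        xy = np.mod(xy, box_xy)
        h, _, _ = np.histogram2d(
            xy[:, 0], xy[:, 1], bins=[nx, ny], range=[[0, box_xy[0]], [0, box_xy[1]]]
        )
        H += h
        total += len(beads)
    cell_area = (box_xy[0] / nx) * (box_xy[1] / ny)
    density = H / (len(sub) * cell_area)
    return DensityMap2D(
        cls, density, (box_xy[0] / nx, box_xy[1] / ny), window, len(sub), total
    )


@dataclass
class DomainClassMap:
    """Categorical merge of the class density maps."""

    codes: np.ndarray  # (nx, ny) int8, values of CODES
    window: tuple[float, float]
    cell_size: tuple[float, float]

    def area_fraction(self, which: tuple[int, ...]) -> float:
        return float(np.isin(self.codes, which).mean())


def classify_domains(
    chol: DensityMap2D,
    satmono: DensityMap2D,
    poly: DensityMap2D,
    protein: DensityMap2D | None = None,
    threshold_fraction: float = 2.0 / 3.0,
) -> DomainClassMap:
    """Merge per-class enrichment masks into the categorical domain map.

    The protein mask (cells holding protein density) takes precedence."""
    shapes = {m.shape for m in (chol, satmono, poly) if m is not None}
    if protein is not None:
        shapes.add(protein.shape)
    if len(shapes) != 1:
        raise ValueError(f"density maps disagree on grid shape: {shapes}")
    c = chol.enriched(threshold_fraction)
    s = satmono.enriched(threshold_fraction)
    p = poly.enriched(threshold_fraction)
    codes = np.full(c.shape, CODES["none"], dtype=np.int8)
    codes[c & ~s & ~p] = CODES["chol_only"]
    codes[~c & s & ~p] = CODES["satmono_only"]
    codes[c & s & ~p] = CODES["lo"]
    codes[~c & ~s & p] = CODES["ld"]
    codes[c & s & p] = CODES["all_mix"]
    codes[c & ~s & p] = CODES["chol_poly"]
    codes[~c & s & p] = CODES["poly_satmono"]
    if protein is not None:
        codes[protein.density > 0] = CODES["protein"]
    return DomainClassMap(codes, chol.window, chol.cell_size)


def _windows(traj: Trajectory, window_ns: float) -> list[tuple[float, float]]:
    t0 = float(traj.times[0])
    t_end = traj.span_end
    out = []
    while t0 < t_end - 1e-9:
        out.append((t0, min(t0 + window_ns, t_end)))
        t0 += window_ns
    return out


def protein_domain_location(
    traj: Trajectory,
    window_ns: float = DEFAULT_WINDOW,
    cell_size: float = DEFAULT_CELL,
    all_beads: bool = False,
    threshold_fraction: float = 2.0 / 3.0,
) -> dict:
    """Fraction of time windows in which the protein sits in Ld-like vs
    Lo-like cells.

    Per window the lipid-only domain map is built and the protein footprint
    (cells containing any protein bead) is read out; the window's call is
    the modal code over the footprint.
    """
    windows = _windows(traj, window_ns)
    if not windows:
        raise ValueError("trajectory too short for one window")
    top = traj.topology
    prot_beads = top.protein_beads()
    if len(prot_beads) == 0:
        raise ValueError("no protein in trajectory")
    calls = []
    for w in windows:
        maps = {
            cls: density_map(traj, cls, w, cell_size, all_beads)
            for cls in ("CHOL", "satmono", "poly")
        }
        cm = classify_domains(
            maps["CHOL"], maps["satmono"], maps["poly"], None, threshold_fraction
        )
        sub = traj.window(*w)
        box_xy = sub.boxes[0, :2]
        nx, ny = cm.codes.shape
        xy = np.mod(sub.coords[:, prot_beads, :2].reshape(-1, 2), box_xy)
        ix = np.minimum((xy[:, 0] / box_xy[0] * nx).astype(int), nx - 1)
        iy = np.minimum((xy[:, 1] / box_xy[1] * ny).astype(int), ny - 1)
        # modal code over the footprint, weighted by protein occupancy so
        # cells merely grazed by the wandering dimer do not dominate
        codes_under = cm.codes[ix, iy]
        vals, counts = np.unique(codes_under, return_counts=True)
        calls.append(int(vals[np.argmax(counts)]))
    calls = np.asarray(calls)
    return {
        "windows": windows,
        "calls": [CODE_NAMES[c] for c in calls],
        "ld_fraction": float(np.isin(calls, LD_CODES).mean()),
        "lo_fraction": float(np.isin(calls, LO_CODES).mean()),
    }


def dimer_center_xy(traj: Trajectory) -> np.ndarray:
    """Per-frame lateral centre of geometry of the protein beads, computed
    as a circular mean so a dimer straddling the periodic boundary does not
    average to the middle of the box."""
    prot = traj.topology.protein_beads()
    if len(prot) == 0:
        raise ValueError("no protein in trajectory")
    box_xy = traj.boxes[0, :2]
    ang = traj.coords[:, prot, :2] / box_xy * 2 * np.pi
    cog = np.arctan2(np.sin(ang).mean(axis=1), np.cos(ang).mean(axis=1))
    return np.mod(cog, 2 * np.pi) / (2 * np.pi) * box_xy


def protein_centered_overlay(
    trajs: list[Trajectory],
    window_ns: float = DEFAULT_WINDOW,
    cell_size: float = DEFAULT_CELL,
    classes: tuple[str, ...] = ("CHOL", "satmono", "poly", "protein"),
    all_beads: bool = False,
) -> dict[str, DensityMap2D]:
    """Pooled class density maps of the final *window_ns* of each run, with
    every frame translated so the dimer centre sits at the box centre."""
    pooled: dict[str, np.ndarray] = {}
    meta = {}
    n_frames_total = 0
    for traj in trajs:
        top = traj.topology
        prot = top.protein_beads()
        if len(prot) == 0:
            raise ValueError("every run must contain the dimer")
        t_end = traj.span_end
        window = (max(t_end - window_ns, float(traj.times[0])), t_end)
        sub = traj.window(*window)
        box_xy = sub.boxes[0, :2]
        shift = box_xy / 2.0 - dimer_center_xy(sub)
        for cls in classes:
            m = density_map(sub, cls, None, cell_size, all_beads, shift=shift)
            if cls not in pooled:
                pooled[cls] = np.zeros_like(m.density)
                meta[cls] = m
            pooled[cls] += m.density * len(sub)
        n_frames_total += len(sub)
    out = {}
    for cls, acc in pooled.items():
        m = meta[cls]
        out[cls] = DensityMap2D(
            cls,
            acc / n_frames_total,
            m.cell_size,
            m.window,
            n_frames_total,
            m.total_count,
        )
    return out
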