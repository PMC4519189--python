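"""Cholesterol leaflet assignment, flip-flop detection and density profiles.

Leaflet membership of cholesterol is decided per frame from the position of
its hydroxyl (ROH) bead relative to the band of the lipid linker beads
(GL1/AM1): the band is the linker mean +- 2 standard deviations per leaflet,
recomputed every frame from the linker-bead sample.  A hydroxyl between the
two bands is labelled "core" (hydrophobic interior); a transition between
inner and outer that persists is a flip-flop event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import Topology, Trajectory

__all__ = [
    "LeafletBands",
    "assign_leaflets",
    "detect_flipflops",
    "DensityProfile",
    "density_profile",
    "extract_distances",
    "INNER",
    "OUTER",
    "CORE",
]

INNER, OUTER, CORE = 0, 1, 2
STATE_NAMES = {INNER: "inner", OUTER: "outer", CORE: "core"}


@dataclass
class LeafletBands:
    """Per-frame linker-bead band (mean +- 2 SD) of each leaflet, nm."""

    outer_mean: np.ndarray  # (F,)
    outer_sd: np.ndarray
    inner_mean: np.ndarray
    inner_sd: np.ndarray

    @property
    def outer_low(self) -> np.ndarray:
        return self.outer_mean - 2 * self.outer_sd

    @property
    def inner_high(self) -> np.ndarray:
        return self.inner_mean + 2 * self.inner_sd


def _linker_beads(top: Topology, leaflet: str) -> np.ndarray:
    linkers = top.beads_of_role("GL1", "AM1")
    sel = top.mol_leaflet[top.bead_mol[linkers]] == leaflet
    return linkers[sel]


def assign_leaflets(traj: Trajectory) -> tuple[np.ndarray, LeafletBands]:
    """Per-frame leaflet state of every cholesterol molecule.

    Returns ``(states, bands)`` with states ``(F, n_chol)`` using the
    INNER/OUTER/CORE codes; cholesterol molecule order follows
    ``topology.molecules_of("CHOL")``.
    """
    top = traj.topology
    out_link = _linker_beads(top, "outer")
    in_link = _linker_beads(top, "inner")
    if len(out_link) == 0 or len(in_link) == 0:
        raise ValueError("both leaflets need linker beads (GL1/AM1) for band assignment")
    chol = top.molecules_of("CHOL")
    roh = np.asarray(
        [b for m in chol for b in range(top.mol_start[m], top.mol_stop[m])
         if top.bead_role[b] == "ROH"],
        dtype=np.int64,
    )
    z_out = traj.coords[:, out_link, 2]
    z_in = traj.coords[:, in_link, 2]
    bands = LeafletBands(
        outer_mean=z_out.mean(axis=1),
        outer_sd=z_out.std(axis=1),
        inner_mean=z_in.mean(axis=1),
        inner_sd=z_in.std(axis=1),
    )
    z = traj.coords[:, roh, 2]
    lo = bands.outer_low[:, None]
    hi = bands.inner_high[:, None]
    states = np.full(z.shape, CORE, dtype=np.int8)
    states[z >= lo] = OUTER
    states[z <= hi] = INNER
    return states, bands


def detect_flipflops(
    states: np.ndarray,
    persistence: int = 2,
    stride_ns: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flip-flop events and per-frame leaflet occupancy.

    An event is an inner->outer or outer->inner transition (core frames are
    transparent) where the new leaflet persists for at least *persistence*
    consecutive resident frames.

    Returns ``(events, occupancy)``: events has columns molecule/frame/
    time_ns/direction; occupancy counts molecules per state per frame.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    states = np.asarray(states)
    F, n = states.shape if states.ndim == 2 else (len(states), 0)
    records = []
    for c in range(n):
        s = states[:, c]
        resident = np.flatnonzero(s != CORE)
        if len(resident) == 0:
            continue
        comp = s[resident]
        # run-length encode the resident (compressed) sequence
        change = np.flatnonzero(np.diff(comp) != 0) + 1
        run_starts = np.concatenate([[0], change])
        run_lengths = np.diff(np.concatenate([run_starts, [len(comp)]]))
        # debounce: an excursion shorter than the persistence never counts,
        # and does not reset the accepted leaflet
        accepted = comp[0]
        for k in range(1, len(run_starts)):
            state = comp[run_starts[k]]
            if state != accepted and run_lengths[k] >= persistence:
                frame = resident[run_starts[k]]
                direction = "inner->outer" if state == OUTER else "outer->inner"
                records.append((c, int(frame), float(frame) * stride_ns, direction))
                accepted = state
    events = pd.DataFrame(records, columns=["molecule", "frame", "time_ns", "direction"])
    occupancy = pd.DataFrame(
        {
            "frame": np.arange(F),
            "n_inner": (states == INNER).sum(axis=1),
            "n_outer": (states == OUTER).sum(axis=1),
            "n_core": (states == CORE).sum(axis=1),
        }
    )
    return events, occupancy


@dataclass
class DensityProfile:
    """1D transmembrane number-density profile per bead selection."""

    z_centers: np.ndarray  # nm, relative to the linker-bead centre of mass
    densities: dict  # name -> (n_bins,) count / nm^3, frame-averaged
    counts: dict  # name -> raw counts summed over frames
    bin_width: float
    n_frames: int
    box_area: float


def density_profile(
    traj: Trajectory,
    selections: dict[str, np.ndarray] | None = None,
    roles: list[str] | None = None,
    bin_width: float = 0.1,
    half_span: float = 5.0,
) -> DensityProfile:
    """Histogram bead z positions (membrane-centred) per named selection.

    *selections* maps a profile name to bead indices; alternatively *roles*
    names bead roles to profile.  The membrane centre is the per-frame mean z
    of all linker beads.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = traj.topology
    if selections is None:
        if roles is None:
            roles = ["ROH", "PO4", "GL1", "AM1", "NC3", "CNO", "NH3"]
        selections = {}
        for role in roles:
            beads = top.beads_of_role(role)
            if len(beads) == 0:
                raise ValueError(f"role {role!r} absent from topology")
            selections[role] = beads
    linkers = top.beads_of_role("GL1", "AM1")
    center = (
        traj.coords[:, linkers, 2].mean(axis=1)
        if len(linkers)
        else traj.coords[:, :, 2].mean(axis=1)
    )
    edges = np.arange(-half_span, half_span + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = float(np.mean(traj.boxes[:, 0] * traj.boxes[:, 1]))
    F = len(traj)
    densities, counts = {}, {}
    for name, beads in selections.items():
        z = traj.coords[:, beads, 2] - center[:, None]
        h, _ = np.histogram(z.ravel(), bins=edges)
        counts[name] = h
        densities[name] = h / (F * bin_width * area)
    return DensityProfile(centers, densities, counts, bin_width, F, area)


def extract_distances(profile: DensityProfile, name: str) -> float:
    """Separation (nm) between the two density maxima of one selection,
    one on each side of the membrane centre."""
    if name not in profile.densities:
        raise ValueError(f"no profile named {name!r}")
    d = profile.densities[name]
    z = profile.z_centers
    upper = z > 0
    lower = z < 0
    if not d[upper].any() or not d[lower].any():
        raise ValueError(f"profile {name!r} lacks a peak on one side of the membrane")
    z_hi = z[upper][np.argmax(d[upper])]
    z_lo = z[lower][np.argmax(d[lower])]
    return float(z_hi - z_lo)
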