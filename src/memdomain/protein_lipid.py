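"""Protein-lipid interaction statistics: RDF shells, composition enrichment,
binding times, residue contact occupancy.

Lipid-protein distances are per-molecule minimum bead distances, lateral
(xy, minimum-image) by default: hydration shells and leaflet-resolved
composition are lateral concepts in a bilayer.  Residue-contact occupancy
uses full 3D distances instead, because a z-delocalized partner such as
cholesterol would otherwise register contacts from the opposite leaflet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter1d
from scipy.signal import argrelmin

from .leaflet import CORE, INNER, OUTER, assign_leaflets
from .model_io import Topology, Trajectory

__all__ = [
    "ShellDefinition",
    "lipid_protein_distances",
    "RDFResult",
    "protein_lipid_rdf",
    "shell_composition",
    "BindingRecord",
    "max_binding_time",
    "residue_occupancy",
]

BINDING_CUTOFF = 0.658  # nm, first RDF minimum


@dataclass(frozen=True)
class ShellDefinition:
    """Outer radii (nm) of the first three hydration shells."""

    r1: float = 0.658
    r2: float = 0.918
    r3: float = 1.178

    def __post_init__(self) -> None:
        if not 0 < self.r1 < self.r2 < self.r3:
            raise ValueError("shell radii must satisfy 0 < r1 < r2 < r3")


def _molecule_segments(top: Topology, mols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beads = np.concatenate(
        [np.arange(top.mol_start[m], top.mol_stop[m]) for m in mols]
    )
    seg = np.cumsum(
        np.concatenate([[0], (top.mol_stop[mols] - top.mol_start[mols])[:-1]])
    )
    return beads, seg


def lipid_protein_distances(
    traj: Trajectory, mols: np.ndarray | None = None, mode: str = "xy"
) -> np.ndarray:
    """Minimum distance of each molecule to any protein bead, per frame.

    Returns an ``(F, len(mols))`` array; *mode* is ``"xy"`` (lateral,
    minimum-image) or ``"3d"`` (lateral minimum-image plus direct z).
    """
    top = traj.topology
    prot = top.protein_beads()
    if len(prot) == 0:
        raise ValueError("trajectory contains no protein")
    if mols is None:
        mols = np.flatnonzero(top.is_lipid)
    beads, seg = _molecule_segments(top, mols)
    F = len(traj)
    out = np.empty((F, len(mols)))
    for f in range(F):
        box_xy = traj.boxes[f, :2]
        pl = traj.coords[f, beads]
        pp = traj.coords[f, prot]
        dxy = pl[:, None, :2] - pp[None, :, :2]
        dxy -= box_xy * np.round(dxy / box_xy)
        d2 = (dxy**2).sum(axis=-1)
        if mode == "3d":
            dz = pl[:, None, 2] - pp[None, :, 2]
            d2 = d2 + dz**2
        bead_min = np.sqrt(d2.min(axis=1))
        out[f] = np.minimum.reduceat(bead_min, seg)
    return out


@dataclass
class RDFResult:
    r: np.ndarray  # bin centres, nm
    g: np.ndarray  # radial distribution of molecule-protein min distances
    minima: list  # detected local minima radii, nm
    shells: ShellDefinition  # detected (or fallback) shell radii
    n_molecules: int


def _distance_bin_areas(
    traj: Trajectory, edges: np.ndarray, n_sample_frames: int = 10, grid: float = 0.05
) -> np.ndarray:
    """Box area (nm^2) at each protein-distance bin, from a periodic distance
    transform of the rasterized protein footprint, averaged over frames.

    This is the correct normalization for the distance-to-an-extended-object
    histogram: iso-distance contours around the dimer are not circles."""
    top = traj.topology
    prot = top.protein_beads()
    box_xy = traj.boxes[0, :2]
    nx = max(int(round(box_xy[0] / grid)), 8)
    ny = max(int(round(box_xy[1] / grid)), 8)
    cell_area = (box_xy[0] / nx) * (box_xy[1] / ny)
    px = box_xy[0] / nx
    frames = np.unique(np.linspace(0, len(traj) - 1, min(n_sample_frames, len(traj))).astype(int))
    acc = np.zeros(len(edges) - 1)
    for f in frames:
        xy = np.mod(traj.coords[f, prot, :2], box_xy)
        mask = np.ones((nx, ny), dtype=bool)
        ix = np.minimum((xy[:, 0] / box_xy[0] * nx).astype(int), nx - 1)
        iy = np.minimum((xy[:, 1] / box_xy[1] * ny).astype(int), ny - 1)
        mask[ix, iy] = False
        # periodic distances via 3x3 tiling of the occupancy mask
        tiled = np.tile(mask, (3, 3))
        d = distance_transform_edt(tiled, sampling=px)[nx : 2 * nx, ny : 2 * ny]
        h, _ = np.histogram(d.ravel(), bins=edges)
        acc += h * cell_area
    return acc / len(frames)


def protein_lipid_rdf(
    traj: Trajectory,
    species: list[str] | None = None,
    bin_width: float = 0.05,
    r_max: float | None = None,
    mode: str = "xy",
    smooth_sigma: float = 2.0,
) -> RDFResult:
    """Lateral radial distribution of lipid minimum distances to the protein,
    normalized by the accessible area at each distance and the bulk number
    density; local minima of the smoothed curve define the hydration-shell
    radii."""
    top = traj.topology
    if species is not None:
        if len(species) == 0:
            raise ValueError("empty species filter")
        mols = top.molecules_of(*species)
        if len(mols) == 0:
            raise ValueError(f"no molecules of species {species}")
    else:
        mols = np.flatnonzero(top.is_lipid)
    dist = lipid_protein_distances(traj, mols, mode=mode)
    if r_max is None:
        r_max = float(np.min(traj.boxes[:, :2])) / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h, _ = np.histogram(dist.ravel(), bins=edges)
    area_box = float(np.mean(traj.boxes[:, 0] * traj.boxes[:, 1]))
    rho_bulk = len(mols) / area_box
    bin_area = _distance_bin_areas(traj, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = h / (len(traj) * bin_area * rho_bulk)
    g[bin_area <= 0] = 0.0
    gs = gaussian_filter1d(g, smooth_sigma)
    (idx,) = argrelmin(gs)
    # ignore minima in the excluded region right at the protein surface
    idx = [i for i in idx if gs[i] > 0 or centers[i] > 0.3]
    minima = [float(centers[i]) for i in idx]
    if len(minima) >= 3:
        shells = ShellDefinition(minima[0], minima[1], minima[2])
    else:
        warnings.warn(
            "fewer than 3 RDF minima detected; falling back to default shell radii",
            stacklevel=2,
        )
        shells = ShellDefinition()
    return RDFResult(centers, g, minima, shells, len(mols))


def shell_composition(
    traj: Trajectory,
    shells: ShellDefinition | None = None,
    chol_states: np.ndarray | None = None,
    mode: str = "xy",
    eps: float = 0.05,
) -> pd.DataFrame:
    """Hydration-shell composition vs leaflet composition.

    Each lipid is assigned per frame to the innermost shell bounding its
    minimum distance to the protein; cholesterol is attributed to its
    current leaflet (core frames excluded).  Returns one row per
    (leaflet, shell, species) with shell fraction, leaflet fraction,
    enrichment ratio and a direction call (increased/decreased/neutral
    within a +-*eps* neutrality band).
    """
    shells = shells or ShellDefinition()
    top = traj.topology
    mols = np.flatnonzero(top.is_lipid)
    dist = lipid_protein_distances(traj, mols, mode=mode)
    F = len(traj)
    species = top.mol_species[mols]
    static_leaflet = top.mol_leaflet[mols]
    is_chol = species == "CHOL"
    if is_chol.any():
        if chol_states is None:
            chol_states, _ = assign_leaflets(traj)
        chol_cols = np.flatnonzero(is_chol)

    # per frame per molecule leaflet code: 0 inner, 1 outer, -1 excluded
    leaflet = np.where(static_leaflet == "outer", OUTER, INNER)[None, :].repeat(F, axis=0)
    if is_chol.any():
        st = chol_states
        leaflet[:, chol_cols] = np.where(st == CORE, -1, st)

    shell_idx = np.full(dist.shape, -1, dtype=np.int8)
    shell_idx[dist < shells.r3] = 2
    shell_idx[dist < shells.r2] = 1
    shell_idx[dist < shells.r1] = 0

    rows = []
    species_names = sorted(set(species))
    for lf, lf_name in ((INNER, "inner"), (OUTER, "outer")):
        in_leaflet = leaflet == lf
        leaflet_total = in_leaflet.sum()
        lf_frac = {
            s: (in_leaflet & (species == s)[None, :]).sum() / leaflet_total
            if leaflet_total
            else np.nan
            for s in species_names
        }
        for sh in (0, 1, 2):
            sel = in_leaflet & (shell_idx == sh)
            total = sel.sum()
            for s in species_names:
                n = (sel & (species == s)[None, :]).sum()
                sf = n / total if total else np.nan
                ratio = sf / lf_frac[s] if lf_frac[s] else np.nan
                if not np.isfinite(ratio):
                    direction = "neutral"
                elif ratio > 1 + eps:
                    direction = "increased"
                elif ratio < 1 - eps:
                    direction = "decreased"
                else:
                    direction = "neutral"
                rows.append(
                    (lf_name, sh + 1, s, sf, lf_frac[s], ratio, direction)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "leaflet", "shell", "species",
            "shell_fraction", "leaflet_fraction", "ratio", "direction",
        ],
    )


@dataclass
class BindingRecord:
    """Maximal contiguous protein-bound durations."""

    per_molecule: pd.DataFrame  # molecule, species, leaflet, max_bound_ns
    per_species: pd.DataFrame  # species, max_bound_ns


def _max_run(mask: np.ndarray) -> int:
    """Longest run of True in a 1D boolean array."""
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def max_binding_time(
    traj: Trajectory, cutoff: float = BINDING_CUTOFF, mode: str = "xy"
) -> BindingRecord:
    """Per molecule, the maximal run of consecutive frames within *cutoff*
    of the protein (no gap tolerance), converted to ns with the trajectory
    stride; per species, the maximum over molecules."""
    top = traj.topology
    mols = np.flatnonzero(top.is_lipid)
    dist = lipid_protein_distances(traj, mols, mode=mode)
    bound = dist < cutoff
    stride = traj.frame_stride if len(traj) > 1 else 0.0
    per_mol = pd.DataFrame(
        {
            "molecule": mols,
            "species": top.mol_species[mols],
            "leaflet": top.mol_leaflet[mols],
            "max_bound_ns": [_max_run(bound[:, k]) * stride for k in range(len(mols))],
        }
    )
    per_species = (
        per_mol.groupby("species")["max_bound_ns"].max().reset_index()
    )
    return BindingRecord(per_mol, per_species)


def residue_occupancy(
    traj: Trajectory,
    residues: list[int],
    partner_species: list[str],
    cutoff: float = BINDING_CUTOFF,
    chain: str = "A",
    mode: str = "3d",
) -> pd.Series:
    """Fraction of frames each residue's side-chain bead is within *cutoff*
    of any bead of any partner molecule."""
    top = traj.topology
    partners = top.molecules_of(*partner_species)
    out = {}
    F = len(traj)
    if len(partners) == 0:
        return pd.Series({r: 0.0 for r in residues}, name="occupancy")
    pbeads = np.concatenate(
        [np.arange(top.mol_start[m], top.mol_stop[m]) for m in partners]
    )
    for res in residues:
        sc = top.residue_beads(chain, res, role="sidechain")
        if len(sc) == 0:
            raise ValueError(f"residue {res} of chain {chain} has no side-chain bead")
        hits = 0
        for f in range(F):
            box_xy = traj.boxes[f, :2]
            d = traj.coords[f, pbeads] - traj.coords[f, sc[0]]
            d[:, :2] -= box_xy * np.round(d[:, :2] / box_xy)
            if mode == "xy":
                dmin = np.sqrt((d[:, :2] ** 2).sum(axis=1)).min()
            else:
                dmin = np.sqrt((d**2).sum(axis=1)).min()
            hits += dmin < cutoff
        out[res] = hits / F
    return pd.Series(out, name="occupancy")
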