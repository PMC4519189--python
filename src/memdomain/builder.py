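"""Construction of the starting membrane system.

The native-like membrane is created the way the original recipe prescribes:
a precursor bilayer of placeholder DOPC plus cholesterol is relabelled by
leaflet-constrained uniform random replacement into the target composition,
and the system is neutralized by exchanging water beads for counterions.
Unlike a self-assembly simulation, molecules are placed on a jittered lattice
at their leaflet depths — geometry only needs to be topologically valid for
the downstream analyses, not physically relaxed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import MEMBRANE_HALF_THICKNESS, bead_depths, leaflet_sign
from .model_io import (
    CompositionError,
    CompositionSpec,
    Frame,
    Topology,
    parse_species,
)

__all__ = ["BuiltSystem", "build_precursor", "apply_composition", "neutralize", "build_system"]

#: placeholder species of the precursor bilayer (di-C18:1 PC)
PLACEHOLDER_SPECIES = "PC_18:1/18:1"

#: target area per lipid site used when no box is given, nm^2
AREA_PER_SITE = 0.64

DEFAULT_LZ = 10.0


@dataclass
class BuiltSystem:
    """A constructed system: topology, one frame, and bookkeeping."""

    topology: Topology
    frame: Frame
    ion_count: int = 0

    @property
    def net_charge(self) -> int:
        return self.topology.net_charge

    def leaflet_counts(self) -> dict[tuple[str, str], int]:
        """Molecule count per (species, leaflet)."""
        out: dict[tuple[str, str], int] = {}
        for s, l in zip(self.topology.mol_species, self.topology.mol_leaflet):
            out[(s, l)] = out.get((s, l), 0) + 1
        return out

    def summary(self) -> dict:
        counts = self.leaflet_counts()
        per_leaflet = {
            leaflet: {s: n for (s, l), n in sorted(counts.items()) if l == leaflet}
            for leaflet in ("inner", "outer")
        }
        return {
            "n_molecules": int(self.topology.n_molecules),
            "n_beads": int(self.topology.n_beads),
            "per_leaflet": per_leaflet,
            "water_count": int((self.topology.mol_species == "W").sum()),
            "ion_count": int(self.ion_count),
            "net_charge": int(self.net_charge),
            "box_nm": [float(v) for v in self.frame.box],
        }


def _lattice_xy(n: int, box_xy: np.ndarray, rng: np.random.Generator,
                min_spacing: float) -> np.ndarray:
    """n jittered square-lattice sites in the periodic box cross-section."""
    if n == 0:
        return np.empty((0, 2))
    side = math.ceil(math.sqrt(n))
    spacing = min(box_xy) / side
    if 0.8 * spacing < min_spacing:  # jitter is +-0.1 spacing per axis
        raise ValueError(
            f"box too small: lattice spacing {spacing:.3f} nm cannot guarantee "
            f"the minimum site separation {min_spacing:.3f} nm for {n} sites"
        )
    ix, iy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    sites = (np.stack([ix, iy], axis=-1).reshape(-1, 2) + 0.5) * spacing
    sites = sites[rng.permutation(len(sites))[:n]]
    sites += rng.uniform(-0.1, 0.1, size=sites.shape) * spacing
    return np.mod(sites, box_xy)


def _place_molecules(
    topology: Topology, box: np.ndarray, rng: np.random.Generator, min_spacing: float
) -> Frame:
    """Deterministic leaflet-depth placement of every molecule."""
    coords = np.zeros((topology.n_beads, 3))
    mid = box[2] / 2.0
    depths = bead_depths(topology)
    sign = leaflet_sign(topology)

    for leaflet in ("outer", "inner"):
        mols = np.flatnonzero(topology.mol_leaflet == leaflet)
        sites = _lattice_xy(len(mols), box[:2], rng, min_spacing)
        for m, site in zip(mols, sites):
            s, e = topology.mol_start[m], topology.mol_stop[m]
            coords[s:e, 0] = site[0]
            coords[s:e, 1] = site[1]
    coords[:, 2] = mid + sign * depths

    # solvent (and any leaflet-less species) fills the two z slabs outside
    # the membrane region
    solvent = np.flatnonzero(topology.mol_leaflet == "none")
    if len(solvent):
        lo_top = mid - MEMBRANE_HALF_THICKNESS
        hi_bot = mid + MEMBRANE_HALF_THICKNESS
        if lo_top <= 0.2 or hi_bot >= box[2] - 0.2:
            raise ValueError("box too small in z to solvate the membrane")
        vol_lo = lo_top
        vol_hi = box[2] - hi_bot
        p_lo = vol_lo / (vol_lo + vol_hi)
        for m in solvent:
            s, e = topology.mol_start[m], topology.mol_stop[m]
            xy = rng.uniform(0, box[:2])
            z = (
                rng.uniform(0.1, lo_top - 0.1)
                if rng.uniform() < p_lo
                else rng.uniform(hi_bot + 0.1, box[2] - 0.1)
            )
            coords[s:e, 0] = xy[0]
            coords[s:e, 1] = xy[1]
            coords[s:e, 2] = z
    return Frame(0.0, box, coords)


def _precursor_entries(
    n_lip_inner: int, n_lip_outer: int, n_chol_inner: int, n_chol_outer: int, n_water: int
) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    entries += [(PLACEHOLDER_SPECIES, "outer")] * n_lip_outer
    entries += [(PLACEHOLDER_SPECIES, "inner")] * n_lip_inner
    entries += [("CHOL", "outer")] * n_chol_outer
    entries += [("CHOL", "inner")] * n_chol_inner
    entries += [("W", "none")] * n_water
    return entries


def default_box(n_sites_per_leaflet: int) -> np.ndarray:
    """Box giving ~0.64 nm^2 per lipid+cholesterol site."""
    side = math.sqrt(max(n_sites_per_leaflet, 1) * AREA_PER_SITE)
    return np.asarray([side, side, DEFAULT_LZ])


def build_precursor(
    n_lipid: int,
    n_chol: int,
    n_water: int,
    box=None,
    seed: int = 0,
    min_spacing: float = 0.4,
) -> BuiltSystem:
    """Placeholder bilayer: *n_lipid* DOPC and *n_chol* cholesterol split
    between the leaflets (odd remainders go to the outer leaflet), solvated
    by *n_water* CG water beads."""
    if n_lipid <= 0:
        raise ValueError("need at least one lipid")
    n_lip_out = n_lipid // 2 + n_lipid % 2
    n_lip_in = n_lipid // 2
    n_chol_out = n_chol // 2 + n_chol % 2
    n_chol_in = n_chol // 2
    if box is None:
        box = default_box(n_lip_out + n_chol_out)
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    top = Topology.from_molecules(
        _precursor_entries(n_lip_in, n_lip_out, n_chol_in, n_chol_out, n_water)
    )
    frame = _place_molecules(top, box, rng, min_spacing)
    return BuiltSystem(top, frame)


def apply_composition(
    precursor: BuiltSystem, spec: CompositionSpec, seed: int = 0
) -> BuiltSystem:
    """Relabel the placeholder lipids into the target composition by a
    uniform random permutation per leaflet; cholesterol and water are kept."""
    spec.validate()
    top = precursor.topology
    new_species = top.mol_species.copy()
    rng = np.random.default_rng(seed)
    for leaflet_i, leaflet in enumerate(("inner", "outer")):
        placeholders = np.flatnonzero(
            (top.mol_leaflet == leaflet) & top.is_phospholipid
        )
        labels: list[str] = []
        for s, ci, co in spec.phospholipid_rows:
            labels += [s] * (ci if leaflet == "inner" else co)
        if len(labels) != len(placeholders):
            raise CompositionError(
                f"{leaflet} leaflet: spec lists {len(labels)} phospholipids but the "
                f"precursor holds {len(placeholders)} placeholder sites "
                f"(deficit {len(placeholders) - len(labels)})"
            )
        chol_spec = next(((ci, co) for s, ci, co in spec.rows if s == "CHOL"), (0, 0))
        n_chol_leaflet = int(((top.mol_leaflet == leaflet) & top.is_chol).sum())
        want = chol_spec[0] if leaflet == "inner" else chol_spec[1]
        if want != n_chol_leaflet:
            raise CompositionError(
                f"{leaflet} leaflet: spec wants {want} CHOL, precursor has {n_chol_leaflet}"
            )
        perm = rng.permutation(len(placeholders))
        for k, m in enumerate(placeholders):
            new_species[m] = labels[perm[k]]

    entries = list(zip(new_species, top.mol_leaflet))
    new_top = Topology.from_molecules(entries, n_res_protein=top.n_res_protein)
    # all phospholipid templates share the bead count, so coordinates carry over
    frame = Frame(precursor.frame.time, precursor.frame.box, precursor.frame.coords.copy())
    return BuiltSystem(new_top, frame, ion_count=precursor.ion_count)


def neutralize(system: BuiltSystem, seed: int = 0) -> BuiltSystem:
    """Exchange water beads for Na+ counterions until the net charge is zero."""
    q = system.net_charge
    if q == 0:
        return BuiltSystem(system.topology, system.frame, ion_count=system.ion_count)
    if q > 0:
        raise CompositionError(
            "system carries positive net charge; only Na+ counterions are modelled"
        )
    n_ions = -q
    waters = np.flatnonzero(system.topology.mol_species == "W")
    if len(waters) < n_ions:
        raise CompositionError(
            f"insufficient water: need {n_ions} beads for neutralization, have {len(waters)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(waters, size=n_ions, replace=False)
    new_species = system.topology.mol_species.copy()
    new_species[chosen] = "NA"
    top = Topology.from_molecules(
        list(zip(new_species, system.topology.mol_leaflet)),
        n_res_protein=system.topology.n_res_protein,
    )
    frame = Frame(system.frame.time, system.frame.box, system.frame.coords.copy())
    return BuiltSystem(top, frame, ion_count=system.ion_count + n_ions)


def build_system(spec: CompositionSpec, seed: int = 0, box=None) -> BuiltSystem:
    """Full recipe: precursor -> leaflet-constrained replacement -> neutralize."""
    spec.validate()
    in_pl, out_pl = spec.leaflet_totals(include_chol=False)
    chol_in = sum(ci for s, ci, _ in spec.rows if s == "CHOL")
    chol_out = sum(co for s, _, co in spec.rows if s == "CHOL")
    if box is None:
        box = default_box(max(in_pl + chol_in, out_pl + chol_out))
    rng = np.random.default_rng(seed)
    top = Topology.from_molecules(
        _precursor_entries(in_pl, out_pl, chol_in, chol_out, spec.water_count)
    )
    frame = _place_molecules(top, np.asarray(box, dtype=float), rng, 0.4)
    precursor = BuiltSystem(top, frame)
    system = apply_composition(precursor, spec, seed=seed + 1)
    return neutralize(system, seed=seed + 2)
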