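"""Default transverse (z) geometry of the coarse-grained bilayer.

Depths are distances from the bilayer mid-plane in nm, signed by leaflet
(outer positive).  The hydroxyl depth of 1.45 nm puts the two cholesterol-OH
density peaks 2.9 nm apart and the head-group depth of 2.3 nm puts the
head-group peaks 4.6 nm apart, consistent with a red-blood-cell-like bilayer
(experimental head-to-head spacing 4.8 nm, hydrophobic core 2.5 nm).
"""

from __future__ import annotations

import numpy as np

from .model_io import Topology

#: mean |z| per bead, keyed by (role or name); names win over roles
Z_DEPTH = {
    "NC3": 2.30,
    "CNO": 2.30,
    "NH3": 2.30,
    "PO4": 2.00,
    "GL1": 1.60,
    "AM1": 1.60,
    "ROH": 1.45,
    "R1": 0.90,  # cholesterol ring/tail beads
    "R2": 0.45,
    "C1A": 0.90,
    "C2A": 0.40,
    "C1B": 0.90,
    "C2B": 0.40,
}

#: per-frame Gaussian z spread per bead role
Z_SD = {
    "NC3": 0.25,
    "CNO": 0.25,
    "NH3": 0.25,
    "PO4": 0.20,
    "GL1": 0.25,
    "AM1": 0.25,
    "ROH": 0.10,
    "tail": 0.30,
    "backbone": 0.0,
    "sidechain": 0.0,
    "water": 0.0,
    "ion": 0.0,
}

#: half-thickness of the region occupied by the membrane (for water placement)
MEMBRANE_HALF_THICKNESS = 2.8


def bead_depths(topology: Topology) -> np.ndarray:
    """Unsigned mean depth |z| of every bead (0 for water/ion/protein)."""
    depths = np.zeros(topology.n_beads)
    for i in range(topology.n_beads):
        name = topology.bead_name[i]
        depths[i] = Z_DEPTH.get(name, 0.0)
    return depths


def bead_z_sd(topology: Topology) -> np.ndarray:
    """Gaussian z spread per bead."""
    sd = np.zeros(topology.n_beads)
    for i in range(topology.n_beads):
        role = topology.bead_role[i]
        sd[i] = Z_SD.get(topology.bead_name[i], Z_SD.get(role, 0.0))
    return sd


def leaflet_sign(topology: Topology) -> np.ndarray:
    """+1 for outer-leaflet molecules, -1 for inner, 0 otherwise (per bead)."""
    sign_mol = np.where(
        topology.mol_leaflet == "outer", 1.0, np.where(topology.mol_leaflet == "inner", -1.0, 0.0)
    )
    return sign_mol[topology.bead_mol]


def min_image(delta: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention laterally (first two axes of the
    last dimension)."""
    out = delta.copy()
    out[..., 0] -= box_xy[0] * np.round(out[..., 0] / box_xy[0])
    out[..., 1] -= box_xy[1] * np.round(out[..., 1] / box_xy[1])
    return out
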