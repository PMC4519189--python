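"""Domain types and coordinate I/O for coarse-grained membrane systems.

The in-memory model mirrors a MARTINI-style coarse-grained system: molecules
(lipids, cholesterol, a two-chain transmembrane protein, water, ions) composed
of named beads with a closed vocabulary of roles.  Coordinates are stored in
nm and times in ns throughout (GRO native units); unit conversions happen only
at the reporting layer.

Trajectories are held as a dense ``(n_frames, n_beads, 3)`` array plus a
topology.  On disk the portable container is a concatenation of fixed-column
GRO frames; a molecule-level TSV carries the species metadata that GRO cannot.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "GroParseError",
    "CompositionError",
    "SpeciesInfo",
    "parse_species",
    "bead_template",
    "Topology",
    "Frame",
    "Trajectory",
    "CompositionSpec",
    "read_coordinates",
    "write_coordinates",
    "read_trajectory",
    "write_trajectory",
    "load_composition",
    "save_composition",
    "table1_composition",
    "save_topology",
    "load_topology",
]

#: closed vocabulary of bead roles
ROLES = frozenset(
    {
        "ROH", "GL1", "AM1", "PO4", "NC3", "CNO", "NH3",
        "tail", "backbone", "sidechain", "water", "ion",
    }
)

#: head-group bead role per lipid head class
HEAD_ROLE = {"PC": "NC3", "SM": "NC3", "PS": "CNO", "PE": "NH3", "PEpl": "NH3"}

#: species for which the outer leaflet is forbidden (cytoplasmic lipids)
INNER_ONLY_HEADS = {"PS", "PE", "PEpl"}
#: species for which the inner leaflet is forbidden
OUTER_ONLY_HEADS = {"SM"}

#: default residue count per protein chain (a single TM helix)
PROTEIN_N_RES = 24

_SPECIAL_SPECIES = {"CHOL", "W", "NA", "PROTEIN"}


class GroParseError(ValueError):
    """Raised on malformed GRO input; carries the offending line number."""


class CompositionError(ValueError):
    """Raised when a composition violates leaflet or count rules."""


@dataclass(frozen=True)
class SpeciesInfo:
    """Static properties of one molecular species."""

    token: str
    head: str  # PC/SM/PS/PE/PEpl or the token itself for special species
    tails: tuple[str, ...]  # e.g. ("16:0", "18:2"); empty for special species
    charge: int  # units of e
    saturation_class: str  # saturated | mono | poly | none
    linker: str  # ester | ether-ester | none


def _tail_double_bonds(tail: str) -> int:
    return int(tail.split(":")[1])


def parse_species(token: str) -> SpeciesInfo:
    """Classify a species token (``CHOL``, ``W``, ``NA``, ``PROTEIN`` or
    ``HEAD_sn1/sn2`` such as ``PC_16:0/18:2``)."""
    if token in _SPECIAL_SPECIES:
        charge = 1 if token == "NA" else 0
        return SpeciesInfo(token, token, (), charge, "none", "none")
    m = re.fullmatch(r"(PC|SM|PS|PE|PEpl)_(\d+:\d+)/(\d+:\d+)", token)
    if m is None:
        raise ValueError(f"unrecognized species token {token!r}")
    head, sn1, sn2 = m.groups()
    max_db = max(_tail_double_bonds(sn1), _tail_double_bonds(sn2))
    satclass = "saturated" if max_db == 0 else ("mono" if max_db == 1 else "poly")
    charge = -1 if head == "PS" else 0
    linker = "ether-ester" if head == "PEpl" else "ester"
    return SpeciesInfo(token, head, (sn1, sn2), charge, satclass, linker)


def bead_template(species: str) -> list[tuple[str, str]]:
    """Return the ``(role, name)`` bead list of one molecule of *species*.

    Protein molecules are handled separately (per-residue beads)."""
    if species == "CHOL":
        return [("ROH", "ROH"), ("tail", "R1"), ("tail", "R2")]
    if species == "W":
        return [("water", "W")]
    if species == "NA":
        return [("ion", "NA")]
    if species == "PROTEIN":
        raise ValueError("protein beads are generated per residue")
    info = parse_species(species)
    linker_role = "AM1" if info.head == "SM" else "GL1"
    return [
        (HEAD_ROLE[info.head], HEAD_ROLE[info.head]),
        ("PO4", "PO4"),
        (linker_role, linker_role),
        ("tail", "C1A"),
        ("tail", "C2A"),
        ("tail", "C1B"),
        ("tail", "C2B"),
    ]


# GRO residue names are at most 5 characters; keep a bidirectional registry
# for every species the package can build.
_SPECIES_TO_RESNAME = {
    "CHOL": "CHOL",
    "PC_16:0/18:2": "PC1",
    "PC_16:0/18:1": "PC2",
    "PC_16:0/16:0": "PC3",
    "PC_18:0/20:4": "PC4",
    "PC_16:0/20:4": "PC5",
    "PC_18:0/18:1": "PC6",
    "PC_18:1/18:1": "DOPC",
    "SM_16:0/16:0": "SM",
    "PS_18:0/20:4": "PS",
    "PE_16:0/18:1": "PE1",
    "PE_18:0/20:4": "PE2",
    "PE_16:0/20:4": "PE3",
    "PEpl_16:0/20:4": "PEP1",
    "PEpl_18:0/20:4": "PEP2",
    "W": "W",
    "NA": "ION",
}
_RESNAME_TO_SPECIES = {v: k for k, v in _SPECIES_TO_RESNAME.items()}


def species_resname(species: str) -> str:
    try:
        return _SPECIES_TO_RESNAME[species]
    except KeyError:
        # deterministic fallback, still round-trips as a plain string
        return "X" + str(abs(hash(species)) % 10000)


@dataclass
class Topology:
    """Per-bead and per-molecule annotation of a system.

    Beads of one molecule are contiguous; ``mol_start``/``mol_stop`` index
    into the bead arrays.
    """

    bead_role: np.ndarray  # (n_beads,) str
    bead_name: np.ndarray  # (n_beads,) str
    bead_mol: np.ndarray  # (n_beads,) int
    bead_chain: np.ndarray  # (n_beads,) str, "" for non-protein
    bead_residue: np.ndarray  # (n_beads,) int, -1 for non-protein
    mol_species: np.ndarray  # (n_mols,) str
    mol_leaflet: np.ndarray  # (n_mols,) str: inner|outer|none
    mol_start: np.ndarray  # (n_mols,) int
    mol_stop: np.ndarray  # (n_mols,) int
    n_res_protein: int = PROTEIN_N_RES

    # ---- construction ---------------------------------------------------
    @classmethod
    def from_molecules(
        cls,
        entries: Sequence[tuple[str, str]],
        n_res_protein: int = PROTEIN_N_RES,
    ) -> "Topology":
        """Build a topology from ``(species, leaflet)`` molecule entries.

        Successive PROTEIN entries are assigned chains A, B, A, B, ...
        """
        roles: list[str] = []
        names: list[str] = []
        mols: list[int] = []
        chains: list[str] = []
        residues: list[int] = []
        species_l: list[str] = []
        leaflet_l: list[str] = []
        starts: list[int] = []
        stops: list[int] = []
        chain_cycle = 0
        for mid, (species, leaflet) in enumerate(entries):
            starts.append(len(roles))
            if species == "PROTEIN":
                chain = "AB"[chain_cycle % 2]
                chain_cycle += 1
                for res in range(n_res_protein):
                    for role, name in (("backbone", "BB"), ("sidechain", "SC1")):
                        roles.append(role)
                        names.append(name)
                        mols.append(mid)
                        chains.append(chain)
                        residues.append(res)
            else:
                for role, name in bead_template(species):
                    roles.append(role)
                    names.append(name)
                    mols.append(mid)
                    chains.append("")
                    residues.append(-1)
            stops.append(len(roles))
            species_l.append(species)
            leaflet_l.append(leaflet)
        return cls(
            bead_role=np.asarray(roles, dtype=object),
            bead_name=np.asarray(names, dtype=object),
            bead_mol=np.asarray(mols, dtype=np.int64),
            bead_chain=np.asarray(chains, dtype=object),
            bead_residue=np.asarray(residues, dtype=np.int64),
            mol_species=np.asarray(species_l, dtype=object),
            mol_leaflet=np.asarray(leaflet_l, dtype=object),
            mol_start=np.asarray(starts, dtype=np.int64),
            mol_stop=np.asarray(stops, dtype=np.int64),
            n_res_protein=n_res_protein,
        )

    # ---- basic properties ------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.bead_role)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    @property
    def mol_charge(self) -> np.ndarray:
        return np.asarray([parse_species(s).charge for s in self.mol_species])

    @property
    def mol_saturation(self) -> np.ndarray:
        return np.asarray(
            [parse_species(s).saturation_class for s in self.mol_species], dtype=object
        )

    @property
    def net_charge(self) -> int:
        return int(self.mol_charge.sum())

    # ---- selectors -------------------------------------------------------
    def molecules_of(self, *species: str) -> np.ndarray:
        return np.flatnonzero(np.isin(self.mol_species, list(species)))

    @property
    def is_phospholipid(self) -> np.ndarray:
        return np.asarray(
            [s not in _SPECIAL_SPECIES for s in self.mol_species], dtype=bool
        )

    @property
    def is_chol(self) -> np.ndarray:
        return self.mol_species == "CHOL"

    @property
    def is_protein(self) -> np.ndarray:
        return self.mol_species == "PROTEIN"

    @property
    def is_lipid(self) -> np.ndarray:
        """Phospholipids plus cholesterol."""
        return self.is_phospholipid | self.is_chol

    def beads_of_role(self, *roles: str) -> np.ndarray:
        return np.flatnonzero(np.isin(self.bead_role, list(roles)))

    def protein_beads(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.bead_mol, np.flatnonzero(self.is_protein)))

    def reference_bead(self) -> np.ndarray:
        """One reference bead per molecule: linker bead for phospholipids,
        ROH for cholesterol, the first bead otherwise."""
        ref = self.mol_start.copy()
        is_pl = self.is_phospholipid
        # linker is always the third bead of the phospholipid template
        ref[is_pl] = self.mol_start[is_pl] + 2
        return ref

    def mol_bead_lists(self, mol_indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Flattened bead indices of *mol_indices* and the parallel molecule
        index (position within *mol_indices*) of each bead."""
        counts = self.mol_stop[mol_indices] - self.mol_start[mol_indices]
        beads = np.concatenate(
            [np.arange(self.mol_start[m], self.mol_stop[m]) for m in mol_indices]
        ) if len(mol_indices) else np.empty(0, dtype=np.int64)
        owner = np.repeat(np.arange(len(mol_indices)), counts)
        return beads, owner

    def residue_beads(self, chain: str, residue: int, role: str | None = None) -> np.ndarray:
        sel = (self.bead_chain == chain) & (self.bead_residue == residue)
        if role is not None:
            sel &= self.bead_role == role
        return np.flatnonzero(sel)

    def validate(self) -> None:
        bad = set(np.unique(self.bead_role)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown bead roles: {sorted(bad)}")
        if not np.all(np.diff(self.mol_start) >= 0):
            raise ValueError("molecule beads must be contiguous")


@dataclass
class Frame:
    """One snapshot: time (ns), periodic box (nm) and bead coordinates (nm)."""

    time: float
    box: np.ndarray  # (3,)
    coords: np.ndarray  # (n_beads, 3)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology with a uniform stride (ns)."""

    topology: Topology
    times: np.ndarray  # (F,)
    boxes: np.ndarray  # (F, 3)
    coords: np.ndarray  # (F, n_beads, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.times) == 0:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_beads:
            raise ValueError(
                f"coordinate count {self.coords.shape[1]} != topology bead "
                f"count {self.topology.n_beads}"
            )
        d = np.diff(self.times)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9)):
            raise ValueError("frame times must increase with a uniform stride")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_stride(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def span_end(self) -> float:
        """Exclusive end time: one stride past the last frame."""
        dt = self.frame_stride if len(self.times) > 1 else 1.0
        return float(self.times[-1]) + dt

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times[i]), self.boxes[i], self.coords[i])

    def __iter__(self) -> Iterable[Frame]:
        return (self.frame(i) for i in range(len(self)))

    def with_stride(self, step: int) -> "Trajectory":
        """Sub-sampled view (every *step*-th frame) for per-analysis strides."""
        return Trajectory(
            self.topology, self.times[::step], self.boxes[::step], self.coords[::step]
        )

    def window(self, t_start: float, t_end: float) -> "Trajectory":
        """Frames with ``t_start <= t < t_end``."""
        sel = (self.times >= t_start) & (self.times < t_end)
        if not sel.any():
            raise ValueError(f"window [{t_start}, {t_end}) outside trajectory span")
        return Trajectory(self.topology, self.times[sel], self.boxes[sel], self.coords[sel])


# ---------------------------------------------------------------------------
# composition spec
# ---------------------------------------------------------------------------


@dataclass
class CompositionSpec:
    """Per-leaflet species counts plus solvent, as in the membrane recipe."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)  # species, inner, outer
    water_count: int = 0
    target_net_charge: int = 0

    def validate(self) -> None:
        for species, inner, outer in self.rows:
            if inner < 0 or outer < 0:
                raise CompositionError(f"negative count for {species}")
            info = parse_species(species)
            if info.head in INNER_ONLY_HEADS and outer > 0:
                raise CompositionError(
                    f"{species} is restricted to the inner leaflet (count_outer={outer})"
                )
            if info.head in OUTER_ONLY_HEADS and inner > 0:
                raise CompositionError(
                    f"{species} is restricted to the outer leaflet (count_inner={inner})"
                )
        if self.water_count < 0:
            raise CompositionError("negative water count")

    # ---- derived counts --------------------------------------------------
    def count(self, species: str) -> int:
        return sum(i + o for s, i, o in self.rows if s == species)

    @property
    def species(self) -> list[str]:
        return [s for s, _, _ in self.rows]

    @property
    def phospholipid_rows(self) -> list[tuple[str, int, int]]:
        return [r for r in self.rows if r[0] != "CHOL"]

    def leaflet_totals(self, include_chol: bool = True) -> tuple[int, int]:
        rows = self.rows if include_chol else self.phospholipid_rows
        return (sum(r[1] for r in rows), sum(r[2] for r in rows))

    def lipid_charge(self) -> int:
        return sum(parse_species(s).charge * (i + o) for s, i, o in self.rows)

    def scaled(self, factor: float) -> "CompositionSpec":
        """Proportionally scaled-down copy (counts rounded, >=1 where nonzero)."""
        rows = []
        for s, i, o in self.rows:
            si = int(round(i * factor)) if i else 0
            so = int(round(o * factor)) if o else 0
            if i and not si:
                si = 1
            if o and not so:
                so = 1
            rows.append((s, si, so))
        return CompositionSpec(rows, int(round(self.water_count * factor)), self.target_net_charge)


def load_composition(path: str | Path) -> CompositionSpec:
    """Read a composition TSV with columns ``species  count_inner  count_outer``.

    A row with species ``W`` contributes to ``water_count`` instead of the
    leaflet table (water has no leaflet).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"species", "count_inner", "count_outer"}
    if not required.issubset(df.columns):
        raise CompositionError(f"composition file needs columns {sorted(required)}")
    spec = CompositionSpec()
    for _, row in df.iterrows():
        s = str(row["species"])
        i, o = int(row["count_inner"]), int(row["count_outer"])
        if s == "W":
            spec.water_count += i + o
        else:
            parse_species(s)  # validates the token
            spec.rows.append((s, i, o))
    spec.validate()
    return spec


def save_composition(path: str | Path, spec: CompositionSpec) -> None:
    rows = list(spec.rows)
    if spec.water_count:
        rows.append(("W", spec.water_count, 0))
    pd.DataFrame(rows, columns=["species", "count_inner", "count_outer"]).to_csv(
        path, sep="\t", index=False
    )


def table1_composition() -> CompositionSpec:
    """The bundled native-like red-blood-cell membrane recipe."""
    with resources.files("memdomain.data").joinpath("table1.tsv").open("r") as fh:
        df = fh.read()
    spec = load_composition(io.StringIO(df))
    return spec


# ---------------------------------------------------------------------------
# GRO fixed-column I/O
# ---------------------------------------------------------------------------


def _format_gro_frame(
    frame: Frame,
    resids: np.ndarray,
    resnames: np.ndarray,
    names: np.ndarray,
    title: str,
) -> str:
    out = [title, f"{len(frame.coords):5d}"]
    x, y, z = frame.coords[:, 0], frame.coords[:, 1], frame.coords[:, 2]
    for i in range(len(frame.coords)):
        out.append(
            f"{int(resids[i]) % 100000:5d}{str(resnames[i]):<5s}"
            f"{str(names[i]):>5s}{(i + 1) % 100000:5d}"
            f"{x[i]:8.3f}{y[i]:8.3f}{z[i]:8.3f}"
        )
    out.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    return "\n".join(out) + "\n"


def _gro_annotation(topology: Topology) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bead (resid, resname, atomname) arrays for writing."""
    resids = np.empty(topology.n_beads, dtype=np.int64)
    resnames = np.empty(topology.n_beads, dtype=object)
    resid = 0
    for m in range(topology.n_molecules):
        s, e = topology.mol_start[m], topology.mol_stop[m]
        species = topology.mol_species[m]
        if species == "PROTEIN":
            chain = topology.bead_chain[s]
            for b in range(s, e):
                if b == s or topology.bead_residue[b] != topology.bead_residue[b - 1]:
                    resid += 1
                resids[b] = resid
                resnames[b] = f"PRO{chain}"
        else:
            resid += 1
            resids[s:e] = resid
            resnames[s:e] = species_resname(species)
    return resids, resnames, topology.bead_name


def write_coordinates(
    path: str | Path,
    frame: Frame,
    topology: Topology | None = None,
    skeleton: pd.DataFrame | None = None,
    mode: str = "w",
) -> None:
    """Write one GRO frame.  Annotation comes from *topology* or from a
    *skeleton* DataFrame (columns resid/resname/name) as returned by
    :func:`read_coordinates`."""
    if skeleton is not None:
        resids = skeleton["resid"].to_numpy()
        resnames = skeleton["resname"].to_numpy()
        names = skeleton["name"].to_numpy()
    elif topology is not None:
        resids, resnames, names = _gro_annotation(topology)
    else:
        raise ValueError("need a topology or a skeleton to annotate GRO atoms")
    title = f"memdomain t={frame.time:.3f} ns"
    with open(path, mode) as fh:
        fh.write(_format_gro_frame(frame, resids, resnames, names, title))


def _parse_gro_block(lines: list[str], offset: int) -> tuple[Frame, pd.DataFrame, int]:
    """Parse one GRO frame starting at ``lines[offset]``; returns the frame,
    the annotation skeleton and the index just past the block."""
    if offset >= len(lines):
        raise GroParseError("unexpected end of file")
    title = lines[offset]
    m = re.search(r"t=\s*([0-9.eE+-]+)", title)
    time = float(m.group(1)) if m else np.nan
    try:
        natoms = int(lines[offset + 1].strip())
    except (IndexError, ValueError) as exc:
        raise GroParseError(
            f"line {offset + 2}: expected atom count, got "
            f"{lines[offset + 1]!r}" if offset + 1 < len(lines) else "missing atom count"
        ) from exc
    end = offset + 2 + natoms
    if end >= len(lines):
        raise GroParseError("box line missing (file truncated)")
    resids = np.empty(natoms, dtype=np.int64)
    resnames = np.empty(natoms, dtype=object)
    names = np.empty(natoms, dtype=object)
    coords = np.empty((natoms, 3), dtype=float)
    for k in range(natoms):
        ln = lines[offset + 2 + k]
        lineno = offset + 3 + k
        try:
            resids[k] = int(ln[0:5])
            resnames[k] = ln[5:10].strip()
            names[k] = ln[10:15].strip()
            coords[k, 0] = float(ln[20:28])
            coords[k, 1] = float(ln[28:36])
            coords[k, 2] = float(ln[36:44])
        except (ValueError, IndexError) as exc:
            raise GroParseError(f"line {lineno}: malformed GRO atom line {ln!r}") from exc
    box_parts = lines[end].split()
    if len(box_parts) < 3:
        raise GroParseError(f"line {end + 1}: malformed box line {lines[end]!r}")
    box = np.asarray([float(v) for v in box_parts[:3]])
    skeleton = pd.DataFrame({"resid": resids, "resname": resnames, "name": names})
    return Frame(time, box, coords), skeleton, end + 1


def read_coordinates(path: str | Path) -> tuple[Frame, pd.DataFrame]:
    """Read the first frame of a GRO file; returns (frame, skeleton)."""
    lines = Path(path).read_text().splitlines()
    frame, skeleton, _ = _parse_gro_block(lines, 0)
    return frame, skeleton


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a multi-frame concatenated GRO file against a known topology."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    offset = 0
    while offset < len(lines) and lines[offset].strip():
        frame, _, offset = _parse_gro_block(lines, offset)
        frames.append(frame)
    if not frames:
        raise GroParseError("no frames found")
    times = np.asarray([f.time for f in frames])
    if np.any(np.isnan(times)):
        times = np.arange(len(frames), dtype=float)
    return Trajectory(
        topology,
        times,
        np.stack([f.box for f in frames]),
        np.stack([f.coords for f in frames]),
    )


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    resids, resnames, names = _gro_annotation(traj.topology)
    with open(path, "w") as fh:
        for i in range(len(traj)):
            f = traj.frame(i)
            fh.write(_format_gro_frame(f, resids, resnames, names, f"memdomain t={f.time:.3f} ns"))


# ---------------------------------------------------------------------------
# molecule-level topology TSV (lossless species metadata alongside GRO)
# ---------------------------------------------------------------------------


def save_topology(path: str | Path, topology: Topology) -> None:
    pd.DataFrame(
        {
            "molecule_id": np.arange(topology.n_molecules),
            "species": topology.mol_species,
            "leaflet": topology.mol_leaflet,
        }
    ).to_csv(path, sep="\t", index=False)


def load_topology(path: str | Path, n_res_protein: int = PROTEIN_N_RES) -> Topology:
    df = pd.read_csv(path, sep="\t")
    entries = list(zip(df["species"].astype(str), df["leaflet"].astype(str)))
    return Topology.from_molecules(entries, n_res_protein=n_res_protein)
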