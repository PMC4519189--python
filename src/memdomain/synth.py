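"""Synthetic coarse-grained trajectories with planted ground truth.

The generator emulates the statistical structure of a 10 us CG membrane
simulation without any force field:

* lateral motion is 2D Brownian per molecule with species-specific diffusion
  coefficients under periodic wrapping;
* z coordinates are drawn per bead role around leaflet depths;
* cholesterol z follows a two-state telegraph process between the leaflet
  depths (asymmetric rates give the outer-leaflet excess), with a finite
  transit time through the hydrophobic core;
* "ordered" lipid patches concentrate cholesterol plus saturated and
  mono-unsaturated lipids inside drifting rigid discs, with polyunsaturated
  lipids depleted by the same ratio;
* the dimer's inter-monomer contact pairs follow a scripted template
  schedule, with independent per-pair flip noise.

Every planted parameter is recorded in :class:`SynthTruth` so the analysis
modules can be validated against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .builder import default_box
from .geometry import bead_depths, bead_z_sd, leaflet_sign
from .model_io import CompositionSpec, Topology, Trajectory, parse_species

__all__ = [
    "Patch",
    "DomainModel",
    "InterfaceModel",
    "SynthParams",
    "SynthTruth",
    "DEFAULT_TEMPLATES",
    "make_schedule",
    "generate_membrane",
    "generate_dimer",
    "generate_system",
]

#: |z| below which a cholesterol hydroxyl is (truth-)labelled "in the core",
#: matching the nominal linker band edge 1.6 - 2*0.25 nm
CORE_EDGE = 1.1

ROH_DEPTH = 1.45

STATE_INNER, STATE_OUTER, STATE_CORE = 0, 1, 2

#: bundled dimer interface templates (contact pairs on the helix diagonal);
#: "nmr" covers the GxxxG(xxxT)-motif face, the others are alternative faces
DEFAULT_TEMPLATES: dict[str, frozenset] = {
    "nmr": frozenset({(8, 8), (9, 9), (12, 12), (13, 13), (16, 16)}),
    "alt1": frozenset({(3, 3), (6, 6), (20, 20), (23, 23)}),
    "alt2": frozenset({(2, 2), (5, 5), (19, 19), (22, 22)}),
}


@dataclass
class Patch:
    center: tuple[float, float]
    radius: float


@dataclass
class DomainModel:
    """Drifting rigid discs enriched in cholesterol + saturated/mono lipids."""

    patches: list[Patch]
    concentration_ratio: float = 4.0  # inside/outside for the ordered classes
    drift_D: float = 0.0005  # nm^2/ns patch-centre diffusion (slow vs lipids)


@dataclass
class InterfaceModel:
    """Scripted dimer interface: which contact template holds when."""

    schedule: list[tuple[float, float, str]]  # (t_start ns, t_end ns, template id)
    templates: dict[str, frozenset] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    noise: float = 0.0  # per-pair flip probability per frame
    universe: frozenset | None = None  # pair universe for noise; default = union

    def pair_universe(self) -> frozenset:
        if self.universe is not None:
            return self.universe
        u: set = set()
        for pairs in self.templates.values():
            u |= set(pairs)
        return frozenset(u)

    def validate(self, total_ns: float, n_res: int) -> None:
        if len(self.templates) < 1:
            raise ValueError("need at least one interface template")
        for tid, pairs in self.templates.items():
            for i, j in pairs:
                if not (0 <= i < n_res and 0 <= j < n_res):
                    raise ValueError(
                        f"template {tid!r} pair ({i},{j}) outside chain length {n_res}"
                    )
        sched = sorted(self.schedule)
        if not sched or not math.isclose(sched[0][0], 0.0, abs_tol=1e-9):
            raise ValueError("schedule must start at t=0")
        for (a0, a1, _), (b0, _, _) in zip(sched, sched[1:]):
            if a1 > b0 + 1e-9:
                raise ValueError("schedule intervals overlap")
            if not math.isclose(a1, b0, abs_tol=1e-6):
                raise ValueError("schedule intervals must be contiguous")
        if sched[-1][1] < total_ns - 1e-6:
            raise ValueError("schedule does not cover the trajectory span")
        for _, _, tid in sched:
            if tid not in self.templates:
                raise ValueError(f"scheduled template {tid!r} not in template library")

    def template_at(self, t: float) -> str:
        sched = sorted(self.schedule)
        for t0, t1, tid in sched:
            if t0 - 1e-9 <= t < t1 - 1e-9:
                return tid
        return sched[-1][2]


def make_schedule(
    total_ns: float,
    rng: np.random.Generator,
    dwell_means: dict[str, float],
    probs: dict[str, float] | None = None,
    start: str = "nmr",
) -> list[tuple[float, float, str]]:
    """Alternating-template schedule with exponential dwell times.

    The next template is drawn from *probs* (renormalized after excluding the
    current one); dwell means are per template in ns."""
    ids = list(dwell_means)
    if probs is None:
        probs = {i: 1.0 / len(ids) for i in ids}
    t = 0.0
    cur = start
    out: list[tuple[float, float, str]] = []
    while t < total_ns:
        dwell = rng.exponential(dwell_means[cur])
        t1 = min(t + max(dwell, 1.0), total_ns)
        out.append((t, t1, cur))
        t = t1
        others = [i for i in ids if i != cur]
        w = np.asarray([probs[i] for i in others], dtype=float)
        cur = others[int(rng.choice(len(others), p=w / w.sum()))]
    out[-1] = (out[-1][0], total_ns, out[-1][2])
    return out


@dataclass
class SynthParams:
    """Planted generator parameters (nm, ns units)."""

    n_frames: int = 200
    frame_stride: float = 50.0
    seed: int = 0
    box: tuple | None = None  # derived from composition when None

    # lateral diffusion, nm^2/ns
    diffusion_by_class: dict = field(
        default_factory=lambda: {
            "saturated": 0.014,
            "mono": 0.019,
            "poly": 0.025,
            "CHOL": 0.020,
            "PROTEIN": 0.00614,
            "W": 0.05,
            "NA": 0.05,
        }
    )
    diffusion_by_species: dict = field(default_factory=dict)
    leaflet_diffusion_scale: dict = field(
        default_factory=lambda: {"outer": 0.85, "inner": 1.15, "none": 1.0}
    )

    # cholesterol flip-flop telegraph
    flip_rate: float = 0.3  # events / us / molecule at stationarity
    outer_resident_fraction: float = 0.5905  # 274 / (274 + 190)
    flip_transit_ns: float = 25.0

    # lateral organisation
    domains: DomainModel | None = None
    interface: InterfaceModel | None = None
    dimer_placement: str | None = None  # in-patch | out-patch | free | None
    protein_n_res: int = 24

    # planted protein-lipid interactions
    sticky: tuple | None = None  # (species, start_ns, duration_ns)
    tether: tuple | None = None  # (residue_index, bound_fraction) for one CHOL
    chol_halo: tuple | None = None  # (count, radius) CHOL kept near the dimer

    @property
    def total_ns(self) -> float:
        return self.n_frames * self.frame_stride


@dataclass
class SynthTruth:
    """Planted ground truth emitted alongside a synthetic trajectory."""

    mol_D: np.ndarray | None = None  # (n_mols,) planted diffusion coefficient
    patch_member: np.ndarray | None = None  # (n_mols,) patch id or -1
    patch_centers: np.ndarray | None = None  # (F, n_patches, 2) drifting centres
    dimer_xy: np.ndarray | None = None  # (F, 2) dimer centre trace
    chol_mols: np.ndarray | None = None  # molecule indices of cholesterol
    chol_states: np.ndarray | None = None  # (F, n_chol) int8 leaflet truth
    chol_flip_counts: np.ndarray | None = None  # (n_chol,) realized flips
    interface_template: np.ndarray | None = None  # (F,) template id per frame
    contact_pairs: list | None = None  # (F,) realized pair frozensets
    tether_mask: np.ndarray | None = None  # (F,) bool: tethered CHOL bound
    tether_mol: int | None = None
    sticky_mol: int | None = None


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _species_D(params: SynthParams, species: str, leaflet: str) -> float:
    if species in params.diffusion_by_species:
        base = params.diffusion_by_species[species]
    elif species in params.diffusion_by_class:
        base = params.diffusion_by_class[species]
    else:
        base = params.diffusion_by_class.get(parse_species(species).saturation_class, 0.02)
    return base * params.leaflet_diffusion_scale.get(leaflet, 1.0)


def _wrap(x: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    return np.mod(x, box_xy)


def _min_image_vec(delta: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    return delta - box_xy * np.round(delta / box_xy)


def _patch_assignments(
    params: SynthParams, top: Topology, rng: np.random.Generator, box_xy: np.ndarray
) -> np.ndarray:
    """Patch membership per molecule: -1 free, >=0 patch index."""
    member = np.full(top.n_molecules, -1, dtype=np.int64)
    dm = params.domains
    if dm is None or not dm.patches:
        return member
    area = float(box_xy[0] * box_xy[1])
    f = sum(math.pi * p.radius**2 for p in dm.patches) / area
    if not 0 < f < 1:
        raise ValueError("patch area must be a proper fraction of the box")
    rho = dm.concentration_ratio
    p_in_ordered = rho * f / (rho * f + (1 - f))
    p_in_poly = f / (f + rho * (1 - f))
    sat = top.mol_saturation
    areas = np.asarray([p.radius**2 for p in dm.patches], dtype=float)
    w = areas / areas.sum()
    for m in range(top.n_molecules):
        s = top.mol_species[m]
        if s == "CHOL" or sat[m] in ("saturated", "mono"):
            p_in = p_in_ordered
        elif sat[m] == "poly":
            p_in = p_in_poly
        else:
            continue  # water/ions/protein handled elsewhere
        if rng.uniform() < p_in:
            member[m] = int(rng.choice(len(dm.patches), p=w))
    return member


def _reflect_disc(rel: np.ndarray, radius: float) -> np.ndarray:
    """Radial reflection of 2D points into a disc of given radius."""
    r = np.linalg.norm(rel, axis=-1)
    out = rel.copy()
    over = r > radius
    if np.any(over):
        scale = (2 * radius - r[over]) / r[over]
        scale = np.clip(scale, 0.0, None)
        out[over] = rel[over] * scale[:, None]
    return out


def _push_out(pos: np.ndarray, centers: np.ndarray, radii: np.ndarray,
              box_xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
    """Push 2D points out of every patch disc (minimum-image)."""
    out = pos.copy()
    for c, r in zip(centers, radii):
        d = _min_image_vec(out - c, box_xy)
        dist = np.linalg.norm(d, axis=-1)
        inside = dist < r + margin
        if np.any(inside):
            dd = d[inside]
            n = np.linalg.norm(dd, axis=-1, keepdims=True)
            n[n < 1e-9] = 1e-9
            out[inside] = c + dd / n * (r + margin)
    return _wrap(out, box_xy)


def _telegraph_chol(
    params: SynthParams, n_chol: int, times: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the two-state flip-flop process for every cholesterol.

    Returns (z_mean (F, n_chol), truth state (F, n_chol), flips (n_chol,)).
    """
    F = len(times)
    total = float(times[-1]) if F else 0.0
    r = params.flip_rate / 1000.0  # events per ns
    b = params.outer_resident_fraction
    z_mean = np.empty((F, n_chol))
    states = np.empty((F, n_chol), dtype=np.int8)
    flips = np.zeros(n_chol, dtype=np.int64)
    if r <= 0:
        init = rng.uniform(size=n_chol) < b
        z_mean[:] = np.where(init, ROH_DEPTH, -ROH_DEPTH)[None, :]
        states[:] = np.where(init, STATE_OUTER, STATE_INNER)[None, :]
        return z_mean, states, flips
    # rate out of each state so that the stationary split is b and the mean
    # event rate per molecule is r
    k_leave_outer = r / (2 * b)
    k_leave_inner = r / (2 * (1 - b))
    tau = params.flip_transit_ns
    for c in range(n_chol):
        s0 = 1 if rng.uniform() < b else 0  # 1 = outer
        state = s0
        t = 0.0
        events: list[tuple[float, int]] = []  # (time, new_state)
        while t < total:
            k = k_leave_outer if state == 1 else k_leave_inner
            t += rng.exponential(1.0 / k)
            if t >= total:
                break
            state = 1 - state
            events.append((t, state))
        flips[c] = len(events)
        # piecewise z(t): resident depth, linear transit after each event
        if events:
            ev_t = np.asarray([e[0] for e in events])
            ev_s = np.asarray([e[1] for e in events], dtype=np.int64)
            idx = np.searchsorted(ev_t, times, side="right")
            st = np.where(idx == 0, s0, ev_s[np.clip(idx - 1, 0, None)])
            last_ev = np.where(idx == 0, -np.inf, ev_t[np.clip(idx - 1, 0, None)])
        else:
            st = np.full(F, s0)
            last_ev = np.full(F, -np.inf)
        target = np.where(st == 1, ROH_DEPTH, -ROH_DEPTH)
        frac = np.clip((times - last_ev) / tau, 0.0, 1.0)
        z = target * (2 * frac - 1.0)  # from -target to +target over the transit
        z_mean[:, c] = z
        states[:, c] = np.where(
            np.abs(z) < CORE_EDGE, STATE_CORE, np.where(z > 0, STATE_OUTER, STATE_INNER)
        )
    return z_mean, states, flips


# dimer gadget geometry (relative to the dimer centre), nm
_BB_X = 1.2  # backbone offset from the seam
_SC_RETRACT_X = 1.8
_SC_CONTACT_X = 0.2
_RES_DZ = 0.15
_SLOT_DZ = 0.7
_SLOT_YS = (-1.0, 0.0, 1.0)
_SLOT_ZS = (-1.4, -0.7, 0.0, 0.7, 1.4)


def _realize_contacts(
    pairs: frozenset, n_res: int
) -> tuple[np.ndarray, np.ndarray, frozenset]:
    """Relative coordinates of both chains realizing *pairs*.

    Returns (chain A beads (2*n_res, 3), chain B beads, realized pair set).
    Beads alternate backbone/sidechain per residue.  Exact for star-shaped
    contact components; otherwise the realized set is the bipartite closure
    of each component (also returned)."""
    a = np.zeros((2 * n_res, 3))
    b = np.zeros((2 * n_res, 3))
    z_res = (np.arange(n_res) - (n_res - 1) / 2.0) * _RES_DZ
    a[0::2] = np.stack([-_BB_X * np.ones(n_res), np.zeros(n_res), z_res], axis=1)
    b[0::2] = np.stack([_BB_X * np.ones(n_res), np.zeros(n_res), z_res], axis=1)
    a[1::2] = np.stack([-_SC_RETRACT_X * np.ones(n_res), np.zeros(n_res), z_res], axis=1)
    b[1::2] = np.stack([_SC_RETRACT_X * np.ones(n_res), np.zeros(n_res), z_res], axis=1)

    # connected components of the bipartite contact graph
    pairs = frozenset(pairs)
    parent: dict = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i, j in pairs:
        union(("A", i), ("B", j))
    comps: dict = {}
    for i, j in pairs:
        comps.setdefault(find(("A", i)), {"A": set(), "B": set()})
        comps[find(("A", i))]["A"].add(i)
        comps[find(("A", i))]["B"].add(j)

    slots = [(y, z) for y in _SLOT_YS for z in _SLOT_ZS]
    items = sorted(comps.values(), key=lambda c: (min(c["A"]), min(c["B"])))
    if len(items) > len(slots):
        raise ValueError(
            f"cannot realize {len(items)} simultaneous contact components "
            f"(max {len(slots)})"
        )
    realized: set = set()
    for slot, comp in zip(slots, items):
        y, z = slot
        for k, i in enumerate(sorted(comp["A"])):
            a[2 * i + 1] = (-_SC_CONTACT_X, y, z + 0.08 * k)
        for k, j in enumerate(sorted(comp["B"])):
            b[2 * j + 1] = (_SC_CONTACT_X, y, z + 0.08 * k)
        realized |= {(i, j) for i in comp["A"] for j in comp["B"]}
    return a, b, frozenset(realized)


def _apply_noise(
    template: frozenset, universe: frozenset, noise: float, rng: np.random.Generator
) -> frozenset:
    if noise <= 0:
        return frozenset(template)
    out = set()
    for pair in sorted(universe):
        present = pair in template
        if rng.uniform() < noise:
            present = not present
        if present:
            out.add(pair)
    return frozenset(out)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _build_entries(spec: CompositionSpec, with_dimer: bool) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    for s, ci, co in spec.rows:
        entries += [(s, "outer")] * co
        entries += [(s, "inner")] * ci
    entries += [("W", "none")] * spec.water_count
    if with_dimer:
        entries += [("PROTEIN", "none"), ("PROTEIN", "none")]
    return entries


def _simulate(params: SynthParams, spec: CompositionSpec, with_dimer: bool):
    rng = np.random.default_rng(params.seed)
    top = Topology.from_molecules(
        _build_entries(spec, with_dimer), n_res_protein=params.protein_n_res
    )
    F = params.n_frames
    times = np.arange(F, dtype=float) * params.frame_stride
    in_tot, out_tot = spec.leaflet_totals()
    box = (
        np.asarray(params.box, dtype=float)
        if params.box is not None
        else default_box(max(in_tot, out_tot, 1))
    )
    box_xy = box[:2]
    mid = box[2] / 2.0
    dt = params.frame_stride

    if params.interface is not None:
        if not with_dimer:
            raise ValueError("interface schedule requires a dimer")
        params.interface.validate(params.total_ns, params.protein_n_res)

    is_protein = top.is_protein
    protein_mols = np.flatnonzero(is_protein)
    nonprot = np.flatnonzero(~is_protein)
    n_mols = top.n_molecules

    # planted per-molecule diffusion coefficients
    mol_D = np.zeros(n_mols)
    for m in nonprot:
        mol_D[m] = _species_D(params, top.mol_species[m], top.mol_leaflet[m])
    mol_D[protein_mols] = _species_D(params, "PROTEIN", "none")

    member = _patch_assignments(params, top, rng, box_xy)
    dm = params.domains
    centers0 = (
        np.asarray([p.center for p in dm.patches], dtype=float)
        if dm is not None and dm.patches
        else np.empty((0, 2))
    )
    radii = (
        np.asarray([p.radius for p in dm.patches], dtype=float)
        if dm is not None and dm.patches
        else np.empty(0)
    )
    n_patches = len(radii)

    # cholesterol halo: dedicated patch tied to the dimer centre
    halo_mols = np.empty(0, dtype=np.int64)
    if params.chol_halo is not None:
        if not with_dimer:
            raise ValueError("chol_halo requires a dimer")
        n_halo, halo_radius = params.chol_halo
        chol_all = np.flatnonzero(top.is_chol)
        free_chol = chol_all[member[chol_all] < 0]
        if len(free_chol) < n_halo:
            raise ValueError("not enough free cholesterol for the requested halo")
        halo_mols = free_chol[:n_halo]

    # --- lateral dynamics -------------------------------------------------
    # patch centres drift as rigid discs
    if n_patches:
        steps = rng.normal(0.0, math.sqrt(2 * dm.drift_D * dt), size=(F - 1, n_patches, 2))
        centers = np.concatenate([centers0[None], centers0[None] + np.cumsum(steps, 0)])
    else:
        centers = np.zeros((F, 0, 2))

    # dimer centre
    dimer_xy = np.zeros((F, 2))
    if with_dimer:
        d_prot = mol_D[protein_mols[0]]
        start = box_xy / 2.0
        placement = params.dimer_placement or "free"
        if placement == "in-patch":
            if not n_patches:
                raise ValueError("in-patch dimer placement needs a domain model")
            rel = np.zeros(2)
            for f in range(F):
                if f:
                    rel = rel + rng.normal(0.0, math.sqrt(2 * d_prot * dt), 2)
                    rel = _reflect_disc(rel[None], max(radii[0] - 1.5, 0.5))[0]
                dimer_xy[f] = centers[f, 0] + rel
        else:
            pos = start.copy()
            if placement == "out-patch" and n_patches:
                pos = _push_out(pos[None], centers[0], radii, box_xy, margin=2.0)[0]
            for f in range(F):
                if f:
                    pos = pos + rng.normal(0.0, math.sqrt(2 * d_prot * dt), 2)
                if placement == "out-patch" and n_patches:
                    pos = _push_out(pos[None], centers[f], radii, box_xy, margin=2.0)[0]
                dimer_xy[f] = pos
        dimer_xy = _wrap(dimer_xy, box_xy)

    # molecule xy traces
    mol_xy = np.empty((F, n_mols, 2))
    free = np.flatnonzero((member < 0) & ~is_protein)
    halo_set = set(halo_mols.tolist())
    sat = top.mol_saturation
    # lipid-class molecules stay excluded from the ordered patches so the
    # planted concentration contrast persists
    constrained_free = np.asarray(
        [
            m
            for m in free
            if m not in halo_set
            and (top.mol_species[m] == "CHOL" or sat[m] in ("saturated", "mono", "poly"))
        ],
        dtype=np.int64,
    )

    # initial positions
    pos_free = rng.uniform(0, box_xy, size=(len(free), 2))
    free_index = {m: k for k, m in enumerate(free)}
    if n_patches and len(constrained_free):
        rows = np.asarray([free_index[m] for m in constrained_free])
        pos_free[rows] = _push_out(pos_free[rows], centers[0], radii, box_xy)
    rel_member = np.zeros((n_mols, 2))
    for m in np.flatnonzero(member >= 0):
        r = radii[member[m]]
        rr = r * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        rel_member[m] = (rr * math.cos(th), rr * math.sin(th))
    rel_halo = {}
    halo_radius = params.chol_halo[1] if params.chol_halo is not None else 0.0
    for m in halo_mols:
        rr = halo_radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        rel_halo[m] = np.asarray([rr * math.cos(th), rr * math.sin(th)])

    sigma = np.sqrt(2 * mol_D * dt)
    members_list = np.flatnonzero(member >= 0)
    for f in range(F):
        if f:
            pos_free += rng.normal(0.0, 1.0, size=pos_free.shape) * sigma[free][:, None]
            if n_patches and len(constrained_free):
                rows = np.asarray([free_index[m] for m in constrained_free])
                pos_free[rows] = _push_out(pos_free[rows], centers[f], radii, box_xy)
            for m in members_list:
                rel_member[m] += rng.normal(0.0, sigma[m], 2)
                rel_member[m] = _reflect_disc(
                    rel_member[m][None], radii[member[m]]
                )[0]
            for m in halo_mols:
                rel_halo[m] += rng.normal(0.0, sigma[m], 2)
                rel_halo[m] = _reflect_disc(rel_halo[m][None], halo_radius)[0]
        mol_xy[f, free] = pos_free
        for m in members_list:
            mol_xy[f, m] = centers[f, member[m]] + rel_member[m]
        for m in halo_mols:
            mol_xy[f, m] = dimer_xy[f] + rel_halo[m]
        if with_dimer:
            mol_xy[f, protein_mols] = dimer_xy[f]
    mol_xy = _wrap(mol_xy, box_xy)

    # --- transverse coordinates ------------------------------------------
    depths = bead_depths(top)
    zsd = bead_z_sd(top)
    sign = leaflet_sign(top)

    coords = np.empty((F, top.n_beads, 3))
    bead_mol = top.bead_mol
    coords[:, :, 0] = mol_xy[:, bead_mol, 0]
    coords[:, :, 1] = mol_xy[:, bead_mol, 1]
    znoise = rng.normal(0.0, 1.0, size=(F, top.n_beads)) * zsd[None, :]
    coords[:, :, 2] = mid + sign[None, :] * depths[None, :] + znoise

    # water keeps its initial random z in the solvent slabs
    wmask = np.isin(bead_mol, np.flatnonzero(np.isin(top.mol_species, ["W", "NA"])))
    if wmask.any():
        lo_top = mid - 2.8
        n_w = int(wmask.sum())
        side = rng.uniform(size=n_w) < 0.5
        zw = np.where(
            side,
            rng.uniform(0.1, max(lo_top - 0.1, 0.2), size=n_w),
            rng.uniform(min(mid + 2.8 + 0.1, box[2] - 0.2), box[2] - 0.1, size=n_w),
        )
        coords[:, wmask, 2] = zw[None, :]

    # cholesterol telegraph overrides the z placement of CHOL beads
    truth = SynthTruth(mol_D=mol_D, patch_member=member)
    if n_patches:
        truth.patch_centers = _wrap(centers, box_xy)
    if with_dimer:
        truth.dimer_xy = dimer_xy
    chol_mols = np.flatnonzero(top.is_chol)
    if len(chol_mols):
        z_mean, states, flips = _telegraph_chol(params, len(chol_mols), times, rng)
        truth.chol_mols = chol_mols
        truth.chol_states = states
        truth.chol_flip_counts = flips
        for k, m in enumerate(chol_mols):
            s, e = top.mol_start[m], top.mol_stop[m]
            scale = depths[s:e] / ROH_DEPTH  # ROH=1, ring/tail beads proportionally
            noise = rng.normal(0.0, 1.0, size=(F, e - s)) * zsd[s:e][None, :]
            coords[:, s:e, 2] = mid + z_mean[:, k][:, None] * scale[None, :] + noise

    # --- dimer contacts ---------------------------------------------------
    if with_dimer:
        n_res = params.protein_n_res
        a_mol, b_mol = protein_mols[0], protein_mols[1]
        sa, ea = top.mol_start[a_mol], top.mol_stop[a_mol]
        sb, eb = top.mol_start[b_mol], top.mol_stop[b_mol]
        iface = params.interface
        universe = iface.pair_universe() if iface is not None else frozenset()
        tmpl_ids = np.empty(F, dtype=object)
        realized_list: list[frozenset] = []
        for f in range(F):
            if iface is not None:
                tid = iface.template_at(times[f])
                wanted = _apply_noise(iface.templates[tid], universe, iface.noise, rng)
            else:
                tid, wanted = "", frozenset()
            a_rel, b_rel, realized = _realize_contacts(wanted, n_res)
            tmpl_ids[f] = tid
            realized_list.append(realized)
            for rel, s0 in ((a_rel, sa), (b_rel, sb)):
                coords[f, s0 : s0 + 2 * n_res, 0] = dimer_xy[f, 0] + rel[:, 0]
                coords[f, s0 : s0 + 2 * n_res, 1] = dimer_xy[f, 1] + rel[:, 1]
                coords[f, s0 : s0 + 2 * n_res, 2] = mid + rel[:, 2]
        truth.interface_template = tmpl_ids
        truth.contact_pairs = realized_list

        # planted sticky lipid: pinned adjacent to a backbone bead
        if params.sticky is not None:
            sp, t0, dur = params.sticky
            cand = np.flatnonzero(top.mol_species == sp)
            if not len(cand):
                raise ValueError(f"sticky species {sp!r} absent from composition")
            m = int(cand[0])
            truth.sticky_mol = m
            mask = (times >= t0) & (times < t0 + dur)
            s, e = top.mol_start[m], top.mol_stop[m]
            anchor = np.stack(
                [dimer_xy[mask, 0] - _BB_X + 0.3, dimer_xy[mask, 1]], axis=1
            )
            for b in range(s, e):
                coords[mask, b, 0] = anchor[:, 0]
                coords[mask, b, 1] = anchor[:, 1]

        # planted residue-cholesterol tether (3D contact with a side chain)
        if params.tether is not None:
            res, fraction = params.tether
            chol_free = [m for m in chol_mols if member[m] < 0 and m not in set(halo_mols)]
            if not chol_free:
                raise ValueError("tether needs an unconstrained cholesterol")
            m = int(chol_free[-1])
            truth.tether_mol = m
            n_bound = int(round(fraction * F))
            bound = np.zeros(F, dtype=bool)
            bound[rng.choice(F, size=n_bound, replace=False)] = True
            truth.tether_mask = bound
            sc_bead = sa + 2 * res + 1  # side chain of residue `res`, chain A
            s, e = top.mol_start[m], top.mol_stop[m]
            offs = np.linspace(0.0, 0.3, e - s)
            for k, b in enumerate(range(s, e)):
                coords[bound, b, 0] = coords[bound, sc_bead, 0] - 0.2
                coords[bound, b, 1] = coords[bound, sc_bead, 1]
                coords[bound, b, 2] = coords[bound, sc_bead, 2] - offs[k]

    boxes = np.tile(box, (F, 1))
    traj = Trajectory(top, times, boxes, coords)
    return traj, truth


def generate_membrane(params: SynthParams, spec: CompositionSpec) -> tuple[Trajectory, SynthTruth]:
    """Protein-free membrane trajectory with planted dynamics."""
    if params.interface is not None or params.dimer_placement is not None:
        raise ValueError("membrane-only generation cannot carry a dimer")
    return _simulate(params, spec, with_dimer=False)


def generate_dimer(
    params: SynthParams, templates: dict[str, frozenset] | None = None
) -> tuple[Trajectory, SynthTruth]:
    """Dimer-only trajectory following the scripted interface schedule."""
    if params.interface is None:
        if templates is None:
            templates = dict(DEFAULT_TEMPLATES)
        first = next(iter(templates))
        params = replace(
            params,
            interface=InterfaceModel(
                schedule=[(0.0, params.total_ns, first)], templates=templates
            ),
        )
    elif templates is not None:
        params = replace(params, interface=replace(params.interface, templates=templates))
    spec = CompositionSpec(rows=[], water_count=0)
    if params.box is None:
        params = replace(params, box=(8.0, 8.0, 10.0))
    return _simulate(params, spec, with_dimer=True)


def generate_system(params: SynthParams, spec: CompositionSpec) -> tuple[Trajectory, SynthTruth]:
    """Membrane plus embedded dimer, the full synthetic stand-in."""
    return _simulate(params, spec, with_dimer=True)
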