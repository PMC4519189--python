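"""Dimer interface identification and dynamics.

Per frame, the inter-monomer contact map is the set of residue pairs whose
minimum bead-bead distance (lateral minimum image) falls below a cutoff.
Maps are compared with the Dice dissimilarity, grouped by average-linkage
hierarchical clustering, summarized as per-run cluster frequency vectors,
and compared across conditions with Pearson's correlation.  The presence,
survival and reformation of the reference ("NMR") interface is tracked by
the Dice distance of each frame's map to the reference map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import min_image
from .model_io import Frame, Topology

__all__ = [
    "ContactMap",
    "contact_map",
    "contact_maps",
    "dice_dissimilarity",
    "InterfaceClustering",
    "cluster_interfaces",
    "compare_conditions",
    "NMRInterfaceTrace",
    "nmr_trace",
    "APART",
]

#: reserved cluster label for frames with an empty contact map
APART = "apart"

DEFAULT_CUTOFF = 0.6  # nm, CG first-shell contact scale


@dataclass(frozen=True)
class ContactMap:
    """Inter-monomer residue contact pairs of one frame."""

    time: float
    pairs: frozenset  # of (res_i chain A, res_j chain B)

    def __len__(self) -> int:
        return len(self.pairs)


def _chain_residue_beads(top: Topology, chain: str) -> tuple[np.ndarray, np.ndarray]:
    beads = np.flatnonzero(top.bead_chain == chain)
    if len(beads) == 0:
        raise ValueError(f"chain {chain!r} has no beads")
    return beads, top.bead_residue[beads]


def contact_map(
    frame: Frame,
    topology: Topology,
    chain_a: str = "A",
    chain_b: str = "B",
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactMap:
    """Residue pairs of the two chains closer than *cutoff* (any bead,
    minimum-image laterally)."""
    beads_a, res_a = _chain_residue_beads(topology, chain_a)
    beads_b, res_b = _chain_residue_beads(topology, chain_b)
    pa = frame.coords[beads_a]
    pb = frame.coords[beads_b]
    delta = pa[:, None, :] - pb[None, :, :]
    delta = min_image(delta, frame.box[:2])
    d = np.sqrt((delta**2).sum(axis=-1))
    hit = d < cutoff
    pairs = {(int(res_a[i]), int(res_b[j])) for i, j in zip(*np.nonzero(hit))}
    return ContactMap(frame.time, frozenset(pairs))


def contact_maps(traj, cutoff: float = DEFAULT_CUTOFF) -> list[ContactMap]:
    """Contact map of every frame of a trajectory containing the dimer."""
    return [contact_map(traj.frame(i), traj.topology, cutoff=cutoff) for i in range(len(traj))]


def dice_dissimilarity(a: ContactMap | frozenset, b: ContactMap | frozenset) -> float:
    """``1 - 2|a&b| / (|a|+|b|)``; two empty maps are identical (0)."""
    sa = a.pairs if isinstance(a, ContactMap) else frozenset(a)
    sb = b.pairs if isinstance(b, ContactMap) else frozenset(b)
    if not sa and not sb:
        return 0.0
    return 1.0 - 2.0 * len(sa & sb) / (len(sa) + len(sb))


def _dice_matrix(sets: list[frozenset]) -> np.ndarray:
    """Pairwise Dice dissimilarity, vectorized over the pair universe."""
    universe = sorted(set().union(*sets)) if sets else []
    if not universe:
        return np.zeros((len(sets), len(sets)))
    index = {p: k for k, p in enumerate(universe)}
    M = np.zeros((len(sets), len(universe)), dtype=np.float64)
    for r, s in enumerate(sets):
        for p in s:
            M[r, index[p]] = 1.0
    inter = M @ M.T
    sizes = M.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - 2.0 * inter / denom
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class InterfaceClustering:
    """Result of grouping contact maps into interface clusters."""

    labels: np.ndarray  # (n_maps,) str; APART for empty maps
    representatives: dict  # label -> ContactMap (cluster medoid)
    frequencies: pd.DataFrame  # index run, columns cluster labels, rows sum to 1
    frequent: dict  # label -> bool (frequency > 0.10 in every run)
    linkage_threshold: float

    def frequency_vector(self, run) -> pd.Series:
        return self.frequencies.loc[run]


def cluster_interfaces(
    maps: list[ContactMap],
    linkage_threshold: float = 0.25,
    run_ids: list | None = None,
    frequent_min: float = 0.10,
) -> InterfaceClustering:
    """Average-linkage hierarchical clustering of contact maps on the Dice
    distance, cut at *linkage_threshold*.

    Frames with an empty map get the reserved label ``apart`` and are
    excluded from the frequency vectors.  A cluster is flagged "frequent"
    when its frequency exceeds *frequent_min* in every run.
    """
    if not maps:
        raise ValueError("need at least one contact map")
    if run_ids is None:
        run_ids = [0] * len(maps)
    run_ids = list(run_ids)
    labels = np.empty(len(maps), dtype=object)
    nonempty = [k for k, m in enumerate(maps) if len(m.pairs)]
    labels[[k for k in range(len(maps)) if k not in set(nonempty)]] = APART

    reps: dict = {}
    if nonempty:
        sets = [maps[k].pairs for k in nonempty]
        d = _dice_matrix(sets)
        if len(sets) == 1:
            assignment = np.asarray([1])
        else:
            Z = linkage(squareform(d, checks=False), method="average")
            assignment = fcluster(Z, t=linkage_threshold, criterion="distance")
        # stable cluster names ordered by first appearance
        order: dict[int, str] = {}
        for cl in assignment:
            if cl not in order:
                order[cl] = f"C{len(order) + 1}"
        for k, cl in zip(nonempty, assignment):
            labels[k] = order[cl]
        for cl, name in order.items():
            members = np.flatnonzero(assignment == cl)
            sub = d[np.ix_(members, members)]
            medoid = members[int(np.argmin(sub.sum(axis=1)))]
            reps[name] = maps[nonempty[medoid]]

    runs = sorted(set(run_ids))
    cluster_names = sorted({l for l in labels if l != APART}, key=lambda s: int(s[1:]))
    freq = pd.DataFrame(0.0, index=runs, columns=cluster_names)
    for run in runs:
        sel = [k for k in range(len(maps)) if run_ids[k] == run and labels[k] != APART]
        if sel:
            counts = pd.Series([labels[k] for k in sel]).value_counts()
            freq.loc[run, counts.index] = counts.values / len(sel)
    frequent = {
        name: bool((freq[name] > frequent_min).all()) if len(freq) else False
        for name in cluster_names
    }
    return InterfaceClustering(labels, reps, freq, frequent, linkage_threshold)


def compare_conditions(fv1, fv2) -> float:
    """Pearson correlation of two cluster-frequency vectors, aligned on the
    union of cluster identities (absent cluster -> 0).  Returns NaN when a
    vector has zero variance."""
    s1 = pd.Series(fv1, dtype=float)
    s2 = pd.Series(fv2, dtype=float)
    idx = s1.index.union(s2.index)
    v1 = s1.reindex(idx, fill_value=0.0).to_numpy()
    v2 = s2.reindex(idx, fill_value=0.0).to_numpy()
    if np.std(v1) == 0 or np.std(v2) == 0:
        return float("nan")
    return float(np.corrcoef(v1, v2)[0, 1])


@dataclass
class NMRInterfaceTrace:
    """Presence, episodes, reformations and survival of the reference interface."""

    present: np.ndarray  # (F,) bool
    times: np.ndarray  # (F,) ns
    episodes: list  # [(t_start, t_end)] ns, end exclusive (start of first absent frame)
    reformations: list  # episode start times following a gap >= gap_ns
    durations: np.ndarray  # episode durations, ns
    gap_ns: float

    def survival(self, d_ns: float) -> float:
        """Empirical fraction of episodes lasting at least *d_ns*."""
        if len(self.durations) == 0:
            return float("nan")
        return float(np.mean(self.durations >= d_ns))

    def survival_curve(self) -> pd.DataFrame:
        ds = np.sort(np.unique(self.durations))
        return pd.DataFrame(
            {"duration_ns": ds, "probability": [self.survival(d) for d in ds]}
        )


def nmr_trace(
    maps: list[ContactMap],
    reference: ContactMap | frozenset,
    delta: float = 0.33,
    gap_ns: float = 500.0,
) -> NMRInterfaceTrace:
    """Track the reference interface: a frame is "present" when its map's
    Dice dissimilarity to *reference* is at most *delta*; a reformation is an
    episode starting at least *gap_ns* after the previous episode ended."""
    times = np.asarray([m.time for m in maps], dtype=float)
    present = np.asarray([dice_dissimilarity(m, reference) <= delta for m in maps])
    stride = float(times[1] - times[0]) if len(times) > 1 else 0.0
    episodes: list[tuple[float, float]] = []
    start = None
    for k, p in enumerate(present):
        if p and start is None:
            start = times[k]
        elif not p and start is not None:
            episodes.append((start, times[k]))
            start = None
    if start is not None:
        episodes.append((start, times[-1] + stride))
    # the gap is measured from the last frame the interface was present
    reformations = [
        e[0]
        for prev, e in zip(episodes, episodes[1:])
        if e[0] - (prev[1] - stride) >= gap_ns
    ]
    durations = np.asarray([e1 - e0 for e0, e1 in episodes])
    return NMRInterfaceTrace(present, times, episodes, reformations, durations, gap_ns)
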