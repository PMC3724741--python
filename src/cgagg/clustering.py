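"""Protein cluster detection and aggregation kinetics.

Two proteins are in contact when any two of their backbone beads lie within
a distance cutoff (default 0.75 nm, minimum image); clusters are the
connected components of the per-frame contact graph.  The module produces
per-frame partitions, cluster-count time series and an aggregation-time
estimate (first time the cluster count stays at or below a target for a
dwell number of frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import (
    BeadRole,
    Topology,
    Trajectory,
    TrajectoryFrame,
    periodic_pairs,
)

__all__ = [
    "ContactCriterion",
    "ClusterSeries",
    "protein_contact_pairs",
    "assign_clusters",
    "cluster_timeseries",
    "aggregation_time",
]

DEFAULT_CONTACT_CUTOFF_NM = 0.75


@dataclass(frozen=True)
class ContactCriterion:
    """Inter-protein contact rule: bead-role-filtered distance cutoff."""

    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM
    bead_role: str = BeadRole.BACKBONE.value

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


def protein_contact_pairs(
    frame: TrajectoryFrame,
    topo: Topology,
    crit: ContactCriterion = ContactCriterion(),
) -> set[tuple[int, int]]:
    """Unordered protein-id pairs with any two criterion beads within cutoff.

    The contact interval is closed (a pair exactly at the cutoff counts).
    Raises when the cutoff exceeds half the smallest box edge, where the
    minimum-image convention becomes ambiguous.
    """
    mask = topo.is_protein & (topo.bead_role == crit.bead_role)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValueError("topology has no protein beads matching the criterion")
    bead_pairs = periodic_pairs(frame.positions, frame.box, crit.cutoff,
                                subset=idx)
    if len(bead_pairs) == 0:
        return set()
    mol = topo.molecule_id
    a = mol[bead_pairs[:, 0]]
    b = mol[bead_pairs[:, 1]]
    keep = a != b
    lo = np.minimum(a[keep], b[keep])
    hi = np.maximum(a[keep], b[keep])
    return {(int(i), int(j)) for i, j in zip(lo, hi)}


def assign_clusters(pairs: set[tuple[int, int]] | np.ndarray,
                    n_proteins: int) -> np.ndarray:
    """Partition proteins into contact-graph connected components.

    Returns an integer label per protein id (0..n_proteins-1); the label of
    each cluster is canonicalized to its smallest member id.
    """
    pairs = np.asarray(sorted(pairs) if isinstance(pairs, set) else pairs,
                       dtype=int)
    if pairs.size and pairs.max() >= n_proteins:
        raise ValueError("pair ids must be < n_proteins")
    if pairs.size == 0:
        return np.arange(n_proteins)
    data = np.ones(len(pairs))
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])),
                       shape=(n_proteins, n_proteins))
    _, comp = connected_components(graph, directed=False)
    # canonicalize: label = smallest protein id in the component
    canon = np.full(comp.max() + 1, n_proteins, dtype=int)
    np.minimum.at(canon, comp, np.arange(n_proteins))
    return canon[comp]


@dataclass
class ClusterSeries:
    """Per-frame cluster assignment summary for one trajectory."""

    times: np.ndarray                     # ns
    labels: np.ndarray                    # (n_frames, n_proteins)
    n_clusters: np.ndarray                # per frame
    size_histogram: list[dict[int, int]]  # per frame: {size: multiplicity}

    @property
    def largest_size(self) -> np.ndarray:
        return np.array([max(h) if h else 0 for h in self.size_histogram])

    def __post_init__(self) -> None:
        n_prot = self.labels.shape[1]
        for k, h in enumerate(self.size_histogram):
            if sum(s * m for s, m in h.items()) != n_prot:
                raise ValueError(f"frame {k}: cluster sizes do not partition "
                                 f"the {n_prot} proteins")


def cluster_timeseries(
    traj: Trajectory,
    topo: Topology | None = None,
    crit: ContactCriterion = ContactCriterion(),
) -> ClusterSeries:
    """Apply contact detection and component assignment to every frame."""
    topo = topo if topo is not None else traj.topology
    if topo is None:
        raise ValueError("a topology is required")
    prot_ids = topo.protein_ids
    n = len(prot_ids)
    remap = {int(p): k for k, p in enumerate(prot_ids)}

    times, labels, counts, hists = [], [], [], []
    for fr in traj:
        pairs = protein_contact_pairs(fr, topo, crit)
        pairs0 = {(remap[a], remap[b]) for a, b in pairs}
        lab = assign_clusters(pairs0, n)
        uniq, sizes = np.unique(lab, return_counts=True)
        times.append(fr.time)
        labels.append(lab)
        counts.append(len(uniq))
        s, m = np.unique(sizes, return_counts=True)
        hists.append({int(a): int(b) for a, b in zip(s, m)})
    return ClusterSeries(times=np.array(times), labels=np.array(labels),
                         n_clusters=np.array(counts), size_histogram=hists)


NOT_REACHED = "not reached"


def aggregation_time(
    series: ClusterSeries,
    target_count: int = 1,
    dwell: int = 5,
):
    """First time the cluster count holds at or below `target_count`.

    The count must stay <= target_count for `dwell` consecutive frames
    starting at the returned time; returns the string ``"not reached"``
    when no such run exists (runs truncated by the end of the series do not
    qualify unless they are at least `dwell` frames long).
    """
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    below = series.n_clusters <= target_count
    run = 0
    for k, ok in enumerate(below):
        run = run + 1 if ok else 0
        if run >= dwell:
            return float(series.times[k - dwell + 1])
    return NOT_REACHED
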