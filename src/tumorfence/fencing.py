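"""Contact-graph construction and fencing-cluster identification.

Two cells are in contact when their centroids lie within a contact radius
``r_c`` (inclusive; 30 μm by default, roughly three cell diameters).  A
phenotype cluster is a connected component, of size at least ``N_F``, of the
contact graph restricted to cells of one non-tumor phenotype.  A cluster is
a *fencing* cluster when at least one member is in contact with a tumor
cell; the tumor cell itself is never part of the cluster.  The headline
count ``f_d`` is the number of phenotype cells that sit in any fencing
cluster of their phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .data import CellRecord, Slide

__all__ = [
    "FencingConfig",
    "NeighborGraph",
    "FencingResult",
    "build_neighbor_graph",
    "find_phenotype_clusters",
    "identify_fencing",
    "find_fencing",
]


@dataclass(frozen=True)
class FencingConfig:
    """Parameters of the fencing definition.

    r_c : contact radius in μm (edge iff centroid distance <= r_c).
    N_F : minimum number of same-phenotype cells in a cluster.
    """

    r_c: float = 30.0
    N_F: int = 3

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.N_F < 1:
            raise ValueError("N_F must be >= 1")


@dataclass
class NeighborGraph:
    """Undirected contact graph over cell indices.

    ``edges`` is an (m, 2) integer array of index pairs (i < j) with
    centroid distance <= r_c.  ``adjacency`` is the symmetric boolean CSR
    matrix over all n cells.
    """

    n: int
    r_c: float
    edges: np.ndarray
    adjacency: sparse.csr_matrix = field(repr=False)


def build_neighbor_graph(
    cells: list[CellRecord] | np.ndarray,
    r_c: float = 30.0,
) -> NeighborGraph:
    """Build the contact graph over all cells (any phenotype).

    Accepts either a list of :class:`CellRecord` or an (n, 2) coordinate
    array.  Uses a k-d tree, so ~10⁴-cell slides are handled comfortably;
    the result is exact (distance boundary inclusive, coincident centroids
    at distance 0 are connected).
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    if isinstance(cells, np.ndarray):
        pos = np.asarray(cells, dtype=float).reshape(-1, 2)
    else:
        pos = np.array([[c.x, c.y] for c in cells], dtype=float).reshape(-1, 2)
    n = len(pos)
    if n < 1:
        raise ValueError("need at least one cell")
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r_c, output_type="ndarray")  # boundary inclusive
    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=np.intp)
    data = np.ones(2 * len(pairs), dtype=bool)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adj = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return NeighborGraph(n=n, r_c=r_c, edges=pairs, adjacency=adj)


def find_phenotype_clusters(
    graph: NeighborGraph,
    cells: list[CellRecord],
    phenotype: str,
    N_F: int = 3,
) -> list[frozenset[int]]:
    """Connected components of the phenotype-induced subgraph, size >= N_F.

    Returned sets hold indices into ``cells``; ordering is by smallest
    member index so results are independent of graph construction order.
    """
    mask = np.array([c.phenotype == phenotype for c in cells], dtype=bool)
    return _clusters_from_mask(graph, mask, N_F)


def _clusters_from_mask(
    graph: NeighborGraph, mask: np.ndarray, N_F: int
) -> list[frozenset[int]]:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    sub = graph.adjacency[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    clusters: list[frozenset[int]] = []
    for k in range(n_comp):
        members = idx[labels == k]
        if len(members) >= N_F:
            clusters.append(frozenset(int(i) for i in members))
    clusters.sort(key=min)
    return clusters


@dataclass
class FencingResult:
    """Fencing clusters of one phenotype on one slide.

    f_d is the number of phenotype cells belonging to any fencing cluster
    (the sum of fencing-cluster sizes; clusters are disjoint).
    """

    phenotype: str
    clusters: list[frozenset[int]]
    fencing_clusters: list[frozenset[int]]
    f_d: int


def identify_fencing(
    clusters: list[frozenset[int]],
    graph: NeighborGraph,
    cells: list[CellRecord],
    phenotype: str = "",
) -> FencingResult:
    """Mark clusters touching the tumor and count fencing participants.

    A cluster is fencing iff any member has a contact-graph edge to a tumor
    cell.  Tumor cells are never cluster members.
    """
    tumor = np.array([c.is_tumor for c in cells], dtype=bool)
    return _identify_fencing_mask(clusters, graph, tumor, phenotype)


def _identify_fencing_mask(
    clusters: list[frozenset[int]],
    graph: NeighborGraph,
    tumor_mask: np.ndarray,
    phenotype: str,
) -> FencingResult:
    # a cell "touches tumor" iff it has >=1 tumor neighbor in the full graph
    touches = np.asarray(
        graph.adjacency.dot(tumor_mask.astype(np.int64))
    ).ravel() > 0
    fencing = [cl for cl in clusters if any(touches[i] for i in cl)]
    f_d = sum(len(cl) for cl in fencing)
    return FencingResult(
        phenotype=phenotype,
        clusters=clusters,
        fencing_clusters=fencing,
        f_d=f_d,
    )


def find_fencing(
    slide: Slide,
    phenotype: str,
    config: FencingConfig = FencingConfig(),
) -> FencingResult:
    """Convenience pipeline: graph -> clusters -> fencing for one slide."""
    graph = build_neighbor_graph(slide.cells, config.r_c)
    clusters = find_phenotype_clusters(graph, slide.cells, phenotype, config.N_F)
    return identify_fencing(clusters, graph, slide.cells, phenotype)


def fencing_count_for_mask(
    graph: NeighborGraph,
    g_mask: np.ndarray,
    tumor_touch: np.ndarray,
    N_F: int,
) -> int:
    """f_d for an arbitrary membership mask on a fixed graph.

    ``tumor_touch`` is the precomputed per-cell flag "has a tumor neighbor".
    Used by the permutation null, where the graph is fixed and only the
    membership mask changes.
    """
    idx = np.flatnonzero(g_mask)
    if len(idx) == 0:
        return 0
    sub = graph.adjacency[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    touch_any = np.zeros(n_comp, dtype=bool)
    np.logical_or.at(touch_any, labels, tumor_touch[idx])
    keep = (sizes >= N_F) & touch_any
    return int(sizes[keep].sum())
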