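"""Attractor landscape of community functional composition.

The chain implemented here treats a collection of sampled communities
as points in functional-composition space and asks whether they occupy
a small number of discrete, locally dense regions (metastable
attractors):

1. ``jsd_matrix`` — Jensen–Shannon divergence (base 2, so bounded by 1)
   between the relative functional profiles of every pair of samples.
2. ``pcoa`` — classical scaling of the dissimilarity matrix; the first
   two principal coordinates serve as the Mapper filter.
3. ``mapper`` — a 2-D rectangular cover of the filter image
   (overlapping windows per axis), single-linkage clustering of each
   window's preimage with the histogram-gap heuristic, and a graph
   connecting clusters that share samples.
4. ``prune_singletons`` / ``find_attractors`` — singleton nodes are
   removed; each sample gets a k-nearest-neighbour distance (inversely
   related to local density), node potential is the mean over member
   samples, and attractors are the local minima of the potential on the
   graph; basins follow steepest descent.

``MapperLandscape`` wraps the whole chain as a scikit-learn style
clusterer (``fit`` → ``labels_``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import jensenshannon, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .table_io import CommunityTable, SampleMetadata, to_relative_abundance

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "CoverSpec",
    "MapperGraph",
    "AttractorPartition",
    "jsd_matrix",
    "pcoa",
    "mapper",
    "preimage_clusters",
    "prune_singletons",
    "find_attractors",
    "occupancy_summary",
    "MapperLandscape",
]

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric pairwise dissimilarity matrix over samples."""

    sample_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        n = len(self.sample_ids)
        if D.shape != (n, n):
            raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
        if np.any(D < 0):
            raise ValueError("negative dissimilarity")
        if np.max(np.abs(D - D.T), initial=0.0) > 1e-12:
            raise ValueError("distance matrix not symmetric within 1e-12")
        if np.max(np.abs(np.diag(D)), initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.D[np.ix_(idx, idx)])


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``relative_eigenvalues`` are each retained eigenvalue divided by the
    sum of all positive eigenvalues — the "variance explained" per axis.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    relative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class CoverSpec:
    """Mapper cover hyperparameters.

    Defaults are the study settings: 15 intervals per principal
    coordinate, 70% overlap between consecutive intervals, and 10
    histogram bins for the preimage-clustering gap heuristic.
    """

    intervals_per_axis: int = 15
    overlap_fraction: float = 0.70
    histogram_bins: int = 10

    def __post_init__(self) -> None:
        if self.intervals_per_axis < 1:
            raise ValueError("intervals_per_axis must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.histogram_bins < 1:
            raise ValueError("histogram_bins must be positive")


@dataclass
class MapperGraph:
    """Cluster graph: nodes are sample sets, edges mark shared samples."""

    nodes: dict[int, frozenset]
    edges: set[frozenset]
    node_potential: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            a, b = tuple(e)
            if a == b:
                raise ValueError("self-edge in mapper graph")
            if not (self.nodes[a] & self.nodes[b]):
                raise ValueError(f"edge {a}-{b} endpoints share no sample")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, node: int) -> list[int]:
        out = []
        for e in self.edges:
            if node in e:
                (other,) = e - {node}
                out.append(other)
        return sorted(out)

    def samples(self) -> frozenset:
        out = frozenset()
        for members in self.nodes.values():
            out |= members
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, members in self.nodes.items():
            g.add_node(node, size=len(members), members=sorted(members))
            if node in self.node_potential:
                g.nodes[node]["potential"] = self.node_potential[node]
        for e in self.edges:
            a, b = sorted(e)
            g.add_edge(a, b, shared=len(self.nodes[a] & self.nodes[b]))
        return g


@dataclass
class AttractorPartition:
    """Attractors (potential minima) and their basins.

    ``basin_of_node`` / ``basin_of_sample`` map to an attractor index or
    to ``UNASSIGNED`` (-1) for pruned/unreachable samples.
    """

    attractors: list[frozenset]
    basin_of_node: dict[int, int]
    basin_of_sample: dict[str, int]
    knn_k: int

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def to_json(self) -> str:
        payload = {
            "knn_k": self.knn_k,
            "n_attractors": self.n_attractors,
            "attractors": [sorted(a) for a in self.attractors],
            "basin_of_node": {str(k): v for k, v in sorted(self.basin_of_node.items())},
            "basin_of_sample": dict(sorted(self.basin_of_sample.items())),
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def jsd_matrix(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Jensen–Shannon divergence between sample profiles.

    The table is converted to relative abundance if needed.  The
    divergence uses base-2 entropy, so values lie in [0, 1]; the
    divergence itself (not its square root) is returned.
    """
    if not table.is_relative:
        table = to_relative_abundance(table)
    P = table.values
    n = table.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # scipy returns the JS *distance* = sqrt(divergence)
            D[i, j] = D[j, i] = jensenshannon(P[i], P[j], base=2.0) ** 2
    np.fill_diagonal(D, 0.0)
    D = np.clip(0.5 * (D + D.T), 0.0, 1.0)
    return DistanceMatrix(list(table.sample_ids), D)


def pcoa(dist: DistanceMatrix, axis_tol: float = 1e-10) -> OrdinationResult:
    """Classical scaling (principal coordinate analysis).

    Double-centres −½ D∘D, eigendecomposes, and keeps axes whose
    eigenvalue exceeds ``axis_tol`` × the largest eigenvalue.
    Coordinates are eigenvectors scaled by sqrt(eigenvalue); relative
    eigenvalues are fractions of the positive-eigenvalue sum.
    """
    n = dist.n_samples
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    if np.all(dist.D == 0):
        raise ValueError("degenerate configuration: all distances zero")
    D2 = dist.D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)  # symmetrize against round-off
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive_sum = eigval[eigval > 0].sum()
    keep = eigval > axis_tol * eigval[0]
    eigval_kept = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval_kept)
    return OrdinationResult(
        sample_ids=list(dist.sample_ids),
        coordinates=coords,
        eigenvalues=eigval_kept,
        relative_eigenvalues=eigval_kept / positive_sum,
    )


def _cover_windows(lo: float, hi: float, k: int, overlap: float) -> list[tuple[float, float]]:
    """k closed intervals over [lo, hi]; consecutive windows share
    ``overlap`` of their length; first/last edges coincide with lo/hi."""
    span = hi - lo
    if k == 1 or span <= 0:
        return [(lo - 1e-12, hi + 1e-12)] * k
    L = span / (k - (k - 1) * overlap)
    step = L * (1 - overlap)
    windows = [(lo + i * step, lo + i * step + L) for i in range(k)]
    # guard against float round-off dropping the extreme points
    windows[0] = (lo - 1e-12 * max(1.0, abs(lo)), windows[0][1])
    windows[-1] = (windows[-1][0], hi + 1e-12 * max(1.0, abs(hi)))
    return windows


def preimage_clusters(
    members, dist: DistanceMatrix, histogram_bins: int = 10
) -> list[frozenset]:
    """Split a cover cell's preimage with the single-linkage histogram gap.

    Single-linkage merge heights among the members, together with the
    maximum pairwise distance d_max, are histogrammed into
    ``histogram_bins`` equal-width bins over [0, d_max].  The cut
    threshold is the left edge of the first empty bin that follows a
    populated one (empty bins below the smallest merge height carry no
    gap information); clusters are the single-linkage components at
    that threshold.  Without such a gap, the preimage is one cluster.
    """
    members = sorted(members)
    if len(members) == 0:
        raise ValueError("empty preimage")
    if len(members) == 1:
        return [frozenset(members)]
    sub = dist.submatrix(members)
    condensed = squareform(sub.D, checks=False)
    d_max = float(condensed.max())
    if d_max <= 0:
        return [frozenset(members)]
    Z = linkage(condensed, method="single")
    heights = np.concatenate([Z[:, 2], [d_max]])
    counts, edges = np.histogram(heights, bins=histogram_bins, range=(0.0, d_max))
    nonzero = np.flatnonzero(counts > 0)
    first_filled = nonzero[0]
    empty_after = np.flatnonzero((counts == 0) & (np.arange(histogram_bins) > first_filled))
    if empty_after.size == 0:
        return [frozenset(members)]
    threshold = float(edges[empty_after[0]])
    labels = fcluster(Z, t=threshold, criterion="distance")
    clusters: dict[int, set] = {}
    for sample, lab in zip(members, labels):
        clusters.setdefault(int(lab), set()).add(sample)
    # deterministic order: by smallest member id
    return [frozenset(c) for c in sorted(clusters.values(), key=lambda c: min(c))]


def mapper(
    ordination: OrdinationResult,
    dist: DistanceMatrix,
    cover: CoverSpec = CoverSpec(),
) -> MapperGraph:
    """Build the Mapper graph from the first two principal coordinates.

    The filter image is covered by a rectangular grid of overlapping
    windows (closed intervals anchored at the per-axis data min/max;
    boundary points belong to every window covering them).  Each
    nonempty cell's preimage is clustered in the original dissimilarity
    (not in filter space) via :func:`preimage_clusters`; clusters become
    nodes and nodes sharing at least one sample are connected.
    """
    if ordination.coordinates.shape[0] == 0:
        raise ValueError("empty ordination")
    if ordination.n_axes < 2:
        raise ValueError("mapper filter needs at least 2 ordination axes")
    xy = ordination.coordinates[:, :2]
    ids = ordination.sample_ids
    k, ov = cover.intervals_per_axis, cover.overlap_fraction
    wx = _cover_windows(xy[:, 0].min(), xy[:, 0].max(), k, ov)
    wy = _cover_windows(xy[:, 1].min(), xy[:, 1].max(), k, ov)

    nodes: dict[int, frozenset] = {}
    node_id = 0
    for ix, (x0, x1) in enumerate(wx):
        in_x = (xy[:, 0] >= x0) & (xy[:, 0] <= x1)
        if not in_x.any():
            continue
        for iy, (y0, y1) in enumerate(wy):
            sel = in_x & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
            if not sel.any():
                continue
            members = {ids[i] for i in np.flatnonzero(sel)}
            for cluster in preimage_clusters(members, dist, cover.histogram_bins):
                nodes[node_id] = cluster
                node_id += 1

    edges: set[frozenset] = set()
    node_items = sorted(nodes.items())
    for a in range(len(node_items)):
        ia, ma = node_items[a]
        for b in range(a + 1, len(node_items)):
            ib, mb = node_items[b]
            if ma & mb:
                edges.add(frozenset((ia, ib)))
    return MapperGraph(nodes=nodes, edges=edges)


def prune_singletons(graph: MapperGraph) -> MapperGraph:
    """Remove nodes with a single member sample, with incident edges.

    Samples that then occur in no node become unassigned downstream.
    Idempotent.
    """
    keep = {n: m for n, m in graph.nodes.items() if len(m) > 1}
    edges = {e for e in graph.edges if e <= keep.keys()}
    potential = {n: p for n, p in graph.node_potential.items() if n in keep}
    return MapperGraph(nodes=keep, edges=edges, node_potential=potential)


def knn_distances(dist: DistanceMatrix, k: int) -> np.ndarray:
    """Distance of each sample to its k-th nearest other sample."""
    n = dist.n_samples
    if not (1 <= k < n):
        raise ValueError(f"knn_k must be in [1, {n - 1}], got {k}")
    D = dist.D.copy()
    np.fill_diagonal(D, np.inf)
    return np.sort(D, axis=1)[:, k - 1]


def default_knn_k(n_samples: int) -> int:
    """Default neighbourhood size: ceil(sqrt(n)), clipped to [1, n-1]."""
    return int(min(max(1, np.ceil(np.sqrt(n_samples))), max(1, n_samples - 1)))


def find_attractors(
    graph: MapperGraph,
    dist: DistanceMatrix,
    knn_k: int | None = None,
    smooth_potential: bool = False,
    potential_tol: float = 1e-12,
    node_potential: dict[int, float] | None = None,
) -> AttractorPartition:
    """Locate potential minima on the Mapper graph and assign basins.

    Each sample's kNN value (distance to its ``knn_k``-th nearest
    neighbour over *all* samples) is a density surrogate; a node's
    potential is the mean kNN value of its members, optionally smoothed
    by one round of neighbour averaging.  An attractor is a maximal
    connected set of equal-potential nodes none of whose members has a
    strictly lower-potential neighbour.  Basins follow steepest descent
    (minimal-potential neighbour, ties to the smallest node id); a
    sample's basin is that of the lowest-potential node containing it.

    ``node_potential`` overrides the kNN-derived potential with a
    precomputed one (a custom "modification" of the density values).
    """
    if knn_k is None:
        knn_k = default_knn_k(dist.n_samples)
    if graph.n_nodes == 0:
        return AttractorPartition([], {}, {}, knn_k)

    if node_potential is not None:
        potential = {n: float(node_potential[n]) for n in graph.nodes}
    else:
        kvals = knn_distances(dist, knn_k)
        kval_of = dict(zip(dist.sample_ids, kvals))
        potential = {
            n: float(np.mean([kval_of[s] for s in members]))
            for n, members in graph.nodes.items()
        }
    adjacency = {n: graph.neighbors(n) for n in graph.nodes}
    if smooth_potential:
        potential = {
            n: float(np.mean([potential[n]] + [potential[m] for m in adjacency[n]]))
            for n in graph.nodes
        }
    graph.node_potential = dict(potential)

    scale = max(abs(p) for p in potential.values()) or 1.0
    tol = potential_tol * scale

    def equal(a: float, b: float) -> bool:
        return abs(a - b) <= tol

    # plateaus: connected components of equal-potential nodes
    unvisited = set(graph.nodes)
    plateaus: list[set[int]] = []
    while unvisited:
        seed = min(unvisited)
        stack, comp = [seed], {seed}
        unvisited.discard(seed)
        while stack:
            cur = stack.pop()
            for nb in adjacency[cur]:
                if nb in unvisited and equal(potential[nb], potential[cur]):
                    unvisited.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        plateaus.append(comp)

    attractors: list[frozenset] = []
    for comp in plateaus:
        is_min = all(
            all(potential[nb] >= potential[n] - tol for nb in adjacency[n]) for n in comp
        )
        if is_min:
            attractors.append(frozenset(comp))
    attractors.sort(key=min)
    attractor_of_node: dict[int, int] = {}
    for idx, comp in enumerate(attractors):
        for n in comp:
            attractor_of_node[n] = idx

    basin_of_node: dict[int, int] = {}
    for start in sorted(graph.nodes):
        cur = start
        visited = {cur}
        while cur not in attractor_of_node:
            candidates = [nb for nb in adjacency[cur] if nb not in visited]
            down = [nb for nb in candidates if potential[nb] <= potential[cur] + tol]
            if not down:
                break
            nxt = min(down, key=lambda nb: (potential[nb], nb))
            visited.add(nxt)
            cur = nxt
        basin_of_node[start] = attractor_of_node.get(cur, UNASSIGNED)

    basin_of_sample: dict[str, int] = {}
    for sample in sorted(graph.samples()):
        holding = sorted(n for n, m in graph.nodes.items() if sample in m)
        best = min(holding, key=lambda n: (potential[n], n))
        basin_of_sample[sample] = basin_of_node[best]
    return AttractorPartition(attractors, basin_of_node, basin_of_sample, knn_k)


def occupancy_summary(
    partition: AttractorPartition,
    metadata: SampleMetadata,
    keys,
) -> pd.DataFrame:
    """Count samples per attractor × metadata-key combination.

    Long format with columns ``attractor`` (index or "unassigned"),
    the requested keys, and ``count``.  Samples missing from the
    partition (e.g. pruned singletons) are counted as unassigned.
    """
    keys = list(keys)
    for key in keys:
        if key not in metadata.columns:
            raise KeyError(f"unknown metadata key {key!r}")
    rows = []
    for sample in metadata.sample_ids:
        basin = partition.basin_of_sample.get(sample, UNASSIGNED)
        label = "unassigned" if basin == UNASSIGNED else f"A{basin}"
        rows.append({"attractor": label, **{k: metadata.get(sample, k) for k in keys}})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["attractor"] + keys, dropna=False)
        .size()
        .reset_index(name="count")
        .sort_values(["attractor"] + keys, kind="stable")
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class MapperLandscape(ClusterMixin, BaseEstimator):
    """Metastable-attractor clustering of community profiles.

    Runs Jensen–Shannon divergence → PCoA → Mapper → singleton pruning
    → kNN-potential attractor detection on a sample × feature abundance
    matrix, and labels each sample with its basin of attraction.

    Parameters
    ----------
    n_intervals : int, default=15
        Mapper cover intervals per principal-coordinate axis.
    overlap : float, default=0.70
        Fractional overlap between consecutive cover intervals.
    n_bins : int, default=10
        Histogram bins for the preimage-clustering gap heuristic.
    knn_k : int or "auto", default="auto"
        Neighbourhood size for the density potential; "auto" uses
        ceil(sqrt(n_samples)).
    prune : bool, default=True
        Remove singleton Mapper nodes before attractor detection.
    smooth_potential : bool, default=False
        One round of neighbour-averaging of node potentials.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Basin index per sample; -1 for unassigned samples.
    n_attractors_ : int
    distance_matrix_ : DistanceMatrix
    ordination_ : OrdinationResult
    graph_ : MapperGraph
    partition_ : AttractorPartition

    Examples
    --------
    >>> from microscape.synthetic_data import SyntheticSpec, sample_cross_sectional
    >>> table, labels = sample_cross_sectional(SyntheticSpec(K=2, F=40, seed=0))
    >>> model = MapperLandscape().fit(table)
    >>> model.n_attractors_
    2
    """

    def __init__(
        self,
        n_intervals: int = 15,
        overlap: float = 0.70,
        n_bins: int = 10,
        knn_k="auto",
        prune: bool = True,
        smooth_potential: bool = False,
    ):
        self.n_intervals = n_intervals
        self.overlap = overlap
        self.n_bins = n_bins
        self.knn_k = knn_k
        self.prune = prune
        self.smooth_potential = smooth_potential

    def _as_table(self, X) -> CommunityTable:
        if isinstance(X, CommunityTable):
            return X
        if isinstance(X, pd.DataFrame):
            return CommunityTable.from_dataframe(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D sample x feature matrix")
        return CommunityTable(
            sample_ids=[f"s{i}" for i in range(X.shape[0])],
            feature_ids=[f"f{j}" for j in range(X.shape[1])],
            values=X,
        )

    def fit(self, X, y=None):
        """Run the full landscape chain on abundance data ``X``."""
        table = self._as_table(X)
        cover = CoverSpec(self.n_intervals, self.overlap, self.n_bins)
        self.distance_matrix_ = jsd_matrix(table)
        self.ordination_ = pcoa(self.distance_matrix_)
        graph = mapper(self.ordination_, self.distance_matrix_, cover)
        if self.prune:
            graph = prune_singletons(graph)
        k = default_knn_k(table.n_samples) if self.knn_k == "auto" else int(self.knn_k)
        self.partition_ = find_attractors(
            graph, self.distance_matrix_, knn_k=k, smooth_potential=self.smooth_potential
        )
        self.graph_ = graph
        self.n_attractors_ = self.partition_.n_attractors
        self.labels_ = np.array(
            [self.partition_.basin_of_sample.get(s, UNASSIGNED) for s in table.sample_ids]
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
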