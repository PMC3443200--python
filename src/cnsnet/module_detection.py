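"""Module detection: Markov clustering (MCL) and link communities (LCM).

MCL partitions nodes into mutually exclusive modules by alternating
expansion (matrix squaring of a column-stochastic adjacency with self
loops) and inflation (entry-wise power followed by column renormalization)
until the flow matrix stabilizes.  Link communities cluster *edges* by the
Jaccard similarity of the inclusive neighbourhoods of their non-shared
endpoints, cutting the single-linkage dendrogram at the height that
maximizes partition density; node overlap between the induced modules is
allowed.

Both algorithms operate on binary topology by default (edge weights
ignored), matching the usual defaults of the field's clustering tools; a
weighted mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .network_builder import Network


@dataclass
class ModuleSet:
    """Modules detected in one network by one method.

    MCL modules are pairwise disjoint and cover all nodes; LCM modules may
    overlap in nodes, and ``edge_membership`` records the edge community
    behind each module.
    """

    network: str
    method: str  # "MCL" or "LCM"
    modules: dict[str, set[str]] = field(default_factory=dict)
    edge_membership: dict[str, set[frozenset[str]]] = field(default_factory=dict)
    captured_nodes: float | None = None
    captured_edges: float | None = None

    def genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.modules.values():
            out |= members
        return out

    def modules_of(self, gene: str) -> set[str]:
        return {mid for mid, members in self.modules.items() if gene in members}


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


class MarkovClustering:
    """MCL over a symmetric adjacency matrix (sklearn-style estimator).

    Parameters follow the classic algorithm: ``inflation`` (default 2.0),
    ``prune_eps`` for numerical pruning, ``tol`` for convergence, and
    ``max_iter``.  Self loops are added with weight equal to the node's
    maximum incident weight before normalization.  After ``fit(X)``,
    ``labels_`` holds one integer cluster label per node; ``n_iter_`` and
    ``converged_`` describe the iteration.
    """

    def __init__(
        self,
        inflation: float = 2.0,
        prune_eps: float = 1e-5,
        tol: float = 1e-6,
        max_iter: int = 200,
    ):
        self.inflation = inflation
        self.prune_eps = prune_eps
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "inflation": self.inflation,
            "prune_eps": self.prune_eps,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "MarkovClustering":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray) -> "MarkovClustering":
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] == 0:
            raise ValueError("empty adjacency")
        A = A.copy()
        np.fill_diagonal(A, 0.0)
        loops = A.max(axis=0)
        loops[loops <= 0] = 1.0  # isolated nodes keep themselves
        A[np.diag_indices_from(A)] = loops

        M = A / A.sum(axis=0, keepdims=True)
        converged = False
        for it in range(1, self.max_iter + 1):
            prev = M
            M = M @ M  # expansion
            M = np.power(M, self.inflation)  # inflation
            M[M < self.prune_eps] = 0.0
            col = M.sum(axis=0, keepdims=True)
            col[col == 0] = 1.0
            M = M / col
            if np.max(np.abs(M - prev)) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"MCL did not converge in {self.max_iter} iterations; "
                "interpreting current matrix",
                stacklevel=2,
            )
        self.converged_ = converged
        self.n_iter_ = it
        self.labels_ = self._interpret(M)
        return self

    def fit_predict(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).labels_

    def _interpret(self, M: np.ndarray) -> np.ndarray:
        """Read clusters from attractor rows of the limit flow matrix.

        Attractors (nodes with positive return flow) sharing support are
        merged into one attractor system; each system's cluster is the
        union of its rows.  A node attracted by several systems goes to
        the larger cluster (tie: the system with the smallest leading
        node).  Nodes with no attractor flow (numerically starved) attach
        to the system holding most of their column mass.
        """
        n = M.shape[0]
        eps = self.prune_eps
        attractors = [i for i in range(n) if M[i, i] > eps]
        if not attractors:  # fully degenerate flow; everything in one cluster
            return np.zeros(n, dtype=int)
        rows = {i: set(np.flatnonzero(M[i] > eps)) for i in attractors}

        # union-find over attractors whose supports overlap on an attractor
        parent = {i: i for i in attractors}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: int, y: int) -> None:
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[max(rx, ry)] = min(rx, ry)

        attractor_set = set(attractors)
        for i in attractors:
            for j in rows[i] & attractor_set:
                union(i, j)

        systems: dict[int, set[int]] = {}
        for i in attractors:
            systems.setdefault(find(i), set()).update(rows[i])

        # stable ordering: by leading (smallest) attractor index
        ordered = sorted(systems.items())
        clusters = [set(members) for _, members in ordered]

        # resolve node overlap: larger cluster wins; tie → earlier cluster
        owner: dict[int, int] = {}
        for idx, members in enumerate(clusters):
            for node in members:
                if node not in owner:
                    owner[node] = idx
                else:
                    cur = owner[node]
                    if len(members) > len(clusters[cur]):
                        owner[node] = idx
        # numerically uncovered nodes: strongest attractor-system column mass
        for node in range(n):
            if node not in owner:
                mass = [sum(M[i, node] for i in systems[root]) for root, _ in ordered]
                owner[node] = int(np.argmax(mass))

        labels = np.empty(n, dtype=int)
        for node, idx in owner.items():
            labels[node] = idx
        return labels


def mcl_cluster(
    network: Network,
    inflation: float = 2.0,
    prune_eps: float = 1e-5,
    max_iter: int = 200,
    weighted: bool = False,
) -> ModuleSet:
    """Run MCL on a network and return a disjoint node-covering ModuleSet."""
    nodes = sorted(network.graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    A = nx.to_numpy_array(network.graph, nodelist=nodes, weight="weight" if weighted else None)
    if weighted:
        A = np.abs(A)
    est = MarkovClustering(inflation=inflation, prune_eps=prune_eps, max_iter=max_iter)
    labels = est.fit_predict(A)
    clusters: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), set()).add(node)
    ordered = sorted(clusters.values(), key=lambda s: (-len(s), min(s)))
    modules = {f"MCL{i + 1}": members for i, members in enumerate(ordered)}
    ms = ModuleSet(network=network.name, method="MCL", modules=modules)
    ms.captured_nodes, ms.captured_edges = capture_stats(network, ms)
    return ms


# ---------------------------------------------------------------------------
# Link communities
# ---------------------------------------------------------------------------


def edge_similarity(
    network: Network, edge_i: tuple[str, str], edge_j: tuple[str, str]
) -> float:
    """Jaccard similarity of two adjacent edges.

    For edges sharing exactly one node, similarity is
    |n+(a) ∩ n+(b)| / |n+(a) ∪ n+(b)| over the inclusive neighbourhoods
    n+(x) = {x} ∪ neighbours(x) of the two non-shared endpoints a, b.
    """
    si, sj = set(edge_i), set(edge_j)
    shared = si & sj
    if len(shared) != 1:
        raise ValueError(
            f"edges {edge_i} and {edge_j} share {len(shared)} nodes; "
            "similarity defined only for edges sharing exactly one"
        )
    (a,) = si - shared
    (b,) = sj - shared
    g = network.graph
    na = set(g.neighbors(a)) | {a}
    nb = set(g.neighbors(b)) | {b}
    return len(na & nb) / len(na | nb)


def partition_density(
    network: Network, edge_partition: dict[str, set[frozenset[str]]]
) -> tuple[float, dict[str, float]]:
    """Overall partition density D and per-community densities D_c.

    For a community with m_c edges over n_c nodes,
    D_c = (m_c - (n_c - 1)) / (n_c (n_c - 1)/2 - (n_c - 1)), defined as 0
    when n_c = 2; D is the m_c-weighted mean of D_c over all partitioned
    edges.
    """
    per: dict[str, float] = {}
    total_edges = 0
    acc = 0.0
    for cid, edges in edge_partition.items():
        if not edges:
            raise ValueError(f"community {cid} has no edges")
        nodes: set[str] = set()
        for e in edges:
            nodes |= set(e)
        m_c, n_c = len(edges), len(nodes)
        if n_c < 2:
            raise ValueError(f"community {cid} has edges but fewer than 2 nodes")
        if n_c == 2:
            d_c = 0.0
        else:
            d_c = (m_c - (n_c - 1)) / (n_c * (n_c - 1) / 2.0 - (n_c - 1))
        per[cid] = d_c
        acc += m_c * d_c
        total_edges += m_c
    overall = acc / total_edges if total_edges else 0.0
    return overall, per


class LinkCommunities:
    """Link-community detection over a network (sklearn-style estimator).

    ``fit(network)`` performs single-linkage hierarchical clustering of
    edges under the adjacent-edge Jaccard similarity (non-adjacent pairs
    have similarity 0), cuts at the height maximizing partition density
    (ties broken toward the lowest height), and stores
    ``edge_labels_`` (one label per edge, in sorted-edge order),
    ``cut_height_``, ``partition_density_`` and ``edges_``.
    """

    def __init__(self, discard_singletons: bool = True):
        self.discard_singletons = discard_singletons

    def get_params(self, deep: bool = True) -> dict:
        return {"discard_singletons": self.discard_singletons}

    def set_params(self, **params) -> "LinkCommunities":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, network: Network) -> "LinkCommunities":
        g = network.graph
        edges = sorted(tuple(sorted(e)) for e in g.edges)
        m = len(edges)
        if m < 2:
            raise ValueError("link communities require at least 2 edges")
        self.edges_ = edges
        index = {e: i for i, e in enumerate(edges)}

        # inclusive neighbourhoods once
        incl = {v: set(g.neighbors(v)) | {v} for v in g.nodes}

        # condensed distance matrix: 1 - similarity, non-adjacent pairs 1
        dist = np.ones(m * (m - 1) // 2)

        def cidx(i: int, j: int) -> int:
            # condensed index for i < j
            return m * i + j - ((i + 2) * (i + 1)) // 2

        for k in g.nodes:
            incident = sorted(tuple(sorted((k, nb))) for nb in g.neighbors(k))
            for x in range(len(incident)):
                for y in range(x + 1, len(incident)):
                    ei, ej = incident[x], incident[y]
                    a = next(v for v in ei if v != k)
                    b = next(v for v in ej if v != k)
                    if a == b:
                        continue
                    na, nb_ = incl[a], incl[b]
                    sim = len(na & nb_) / len(na | nb_)
                    i, j = sorted((index[ei], index[ej]))
                    d = 1.0 - sim
                    if d < dist[cidx(i, j)]:
                        dist[cidx(i, j)] = d

        Z = linkage(dist, method="single")
        heights = np.unique(np.concatenate([[0.0], Z[:, 2]]))
        best = (-np.inf, None, None)  # (density, height, labels)
        for h in heights:
            labels = fcluster(Z, t=h, criterion="distance")
            partition: dict[str, set[frozenset[str]]] = {}
            for e, lab in zip(edges, labels):
                partition.setdefault(str(lab), set()).add(frozenset(e))
            d, _ = partition_density(network, partition)
            if d > best[0] + 1e-12:  # strict improvement; ties keep lowest h
                best = (d, h, labels)
        self.partition_density_, self.cut_height_, self.edge_labels_ = best
        return self


def link_communities(network: Network, discard_singletons: bool = True) -> ModuleSet:
    """Detect link communities; modules are the node sets induced by each
    edge community (singleton edge communities discarded by default)."""
    est = LinkCommunities(discard_singletons=discard_singletons).fit(network)
    groups: dict[int, set[frozenset[str]]] = {}
    for e, lab in zip(est.edges_, est.edge_labels_):
        groups.setdefault(int(lab), set()).add(frozenset(e))
    kept = [
        edges
        for edges in groups.values()
        if len(edges) > 1 or not discard_singletons
    ]
    kept.sort(key=lambda edges: (-len(edges), min(min(e) for e in edges)))
    ms = ModuleSet(network=network.name, method="LCM")
    for i, edges in enumerate(kept):
        mid = f"LCM{i + 1}"
        nodes: set[str] = set()
        for e in edges:
            nodes |= set(e)
        ms.modules[mid] = nodes
        ms.edge_membership[mid] = edges
    if not ms.modules:
        warnings.warn(
            f"network {network.name!r}: all edge communities singletons; empty LCM set",
            stacklevel=2,
        )
    ms.captured_nodes, ms.captured_edges = capture_stats(network, ms)
    return ms


# ---------------------------------------------------------------------------
# Capture statistics
# ---------------------------------------------------------------------------


def capture_stats(network: Network, moduleset: ModuleSet) -> tuple[float, float]:
    """Fractions of network nodes and edges captured by a module set.

    A node is captured when it belongs to at least one module; an edge is
    intramodule when both endpoints share at least one module.
    """
    n, e = network.n_nodes, network.n_edges
    if n == 0:
        return 0.0, 0.0
    covered = moduleset.genes() & network.nodes
    node_frac = len(covered) / n
    membership: dict[str, set[str]] = {}
    for mid, members in moduleset.modules.items():
        for gene in members:
            membership.setdefault(gene, set()).add(mid)
    intra = 0
    for a, b in network.graph.edges:
        if membership.get(a, set()) & membership.get(b, set()):
            intra += 1
    edge_frac = intra / e if e else 0.0
    return node_frac, edge_frac
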