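"""Co-expression network construction with RMT hard thresholding.

The similarity measure is the pairwise Pearson correlation over
pairwise-complete samples.  The significance cutoff is chosen by a random
matrix theory criterion: scan candidate thresholds upward and keep the
lowest one at which the nearest-neighbour spacing distribution (NNSD) of
the thresholded matrix's unfolded eigenvalues is consistent with the
Poisson form e^(-s) (uncorrelated spectrum) rather than the Wigner–Dyson
form typical of a dense correlated random matrix.

Unfolding is a cubic least-squares spline fit to the empirical cumulative
eigenvalue distribution (20 quantile knots by default); degenerate
eigenvalues are collapsed before spacings are formed.  Goodness of fit is
a chi-square over 60 bins on s in [0, 3] plus an overflow bin, with bins
pooled from the right until each expected count is at least 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io_formats import ExpressionMatrix

DEFAULT_MIN_OVERLAP = 30


class InsufficientEigenvaluesError(ValueError):
    """Too few distinct eigenvalues to form a spacing distribution."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """Thresholded co-expression network.

    Nodes are exactly the union of edge endpoints (genes with no
    significant partner are absent).  Edge weights are the signed Pearson
    correlations; every |weight| >= threshold.
    """

    name: str
    graph: nx.Graph
    threshold: float
    n_samples: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}


@dataclass
class NetworkSummary:
    name: str
    n_arrays: int
    n_nodes: int
    n_edges: int
    avg_connectivity: float | None  # 2E/N to one decimal; None when N = 0
    threshold: float
    module_counts: dict[str, int] = field(default_factory=dict)


def average_connectivity(n_nodes: int, n_edges: int) -> float | None:
    """<k> = 2E/N, rounded half-up to one decimal; None for an empty network."""
    if n_nodes == 0:
        return None
    return round_half_up(2.0 * n_edges / n_nodes, 1)


def round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    return np.floor(x * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# Pairwise correlation
# ---------------------------------------------------------------------------


def pairwise_pcc(
    matrix: ExpressionMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> pd.DataFrame:
    """Gene × gene Pearson correlation over pairwise-complete samples.

    Pairs with fewer than ``min_overlap`` complete sample pairs, or with
    zero variance, are NaN (invalid), never 0.  The diagonal is 1.
    """
    if matrix.n_genes < 2:
        raise ValueError("need at least two genes to correlate")
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples to correlate")
    frame = matrix.to_frame().T  # samples × genes
    corr = frame.corr(method="pearson", min_periods=max(min_overlap, 2))
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# NNSD / RMT machinery
# ---------------------------------------------------------------------------


def _collapse_degenerate(eigs: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    eigs = np.sort(eigs)
    if len(eigs) == 0:
        return eigs
    keep = [eigs[0]]
    for e in eigs[1:]:
        if e - keep[-1] > tol:
            keep.append(e)
    return np.asarray(keep)


def _unfold(eigs: np.ndarray, n_knots: int = 20) -> np.ndarray:
    """Map eigenvalues to unfolded positions with unit mean spacing."""
    n = len(eigs)
    y = np.arange(1, n + 1, dtype=float)
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    knots = np.unique(np.quantile(eigs, qs))
    knots = knots[(knots > eigs[0]) & (knots < eigs[-1])]
    spline = interpolate.LSQUnivariateSpline(eigs, y, knots, k=3)
    return spline(eigs)


def nnsd_spacings(
    eigenvalues: np.ndarray,
    min_eigenvalues: int = 100,
    degeneracy_tol: float = 1e-8,
    n_knots: int = 20,
) -> np.ndarray:
    """Unfolded nearest-neighbour spacings, normalized to unit mean."""
    eigs = _collapse_degenerate(np.asarray(eigenvalues, dtype=float), degeneracy_tol)
    if len(eigs) < min_eigenvalues:
        raise InsufficientEigenvaluesError(
            f"{len(eigs)} distinct eigenvalues < required {min_eigenvalues}"
        )
    xi = _unfold(eigs, n_knots=n_knots)
    s = np.clip(np.diff(xi), 0.0, None)
    mean = s.mean()
    if mean <= 0:
        raise InsufficientEigenvaluesError("degenerate unfolded spectrum")
    return s / mean


def poisson_gof(
    spacings: np.ndarray,
    n_bins: int = 60,
    s_max: float = 3.0,
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Chi-square goodness of fit of spacings to the Poisson NNSD e^(-s).

    Returns (statistic, p-value).  Bins beyond ``s_max`` collapse into one
    overflow bin; bins are pooled from the right so every pooled bin has
    expected count >= ``min_expected``.
    """
    s = np.asarray(spacings, dtype=float)
    n = len(s)
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs = np.histogram(s, bins=edges)[0].astype(float)
    obs = np.append(obs, float(np.sum(s >= s_max)))
    prob = np.append(np.diff(-np.exp(-edges)), np.exp(-s_max))
    exp = n * prob

    obs_pooled: list[float] = []
    exp_pooled: list[float] = []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, exp):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_pooled.append(o_acc)
            exp_pooled.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and obs_pooled:
        obs_pooled[-1] += o_acc
        exp_pooled[-1] += e_acc
    obs_arr, exp_arr = np.asarray(obs_pooled), np.asarray(exp_pooled)
    chi2 = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    dof = max(len(obs_arr) - 1, 1)
    return chi2, float(stats.chi2.sf(chi2, dof))


def threshold_adjacency(
    corr: pd.DataFrame, threshold: float, signed: bool = True
) -> np.ndarray:
    """Correlation matrix with sub-threshold entries zeroed, diagonal 1.

    ``signed=True`` thresholds |PCC| (both tails kept); ``signed=False``
    keeps only positive correlations >= threshold.
    """
    values = corr.to_numpy(dtype=float, copy=True)
    values = np.nan_to_num(values, nan=0.0)
    if signed:
        mask = np.abs(values) >= threshold
    else:
        mask = values >= threshold
    values = np.where(mask, values, 0.0)
    np.fill_diagonal(values, 1.0)
    return values


def nnsd_poisson_chi2(
    corr: pd.DataFrame,
    candidate_threshold: float,
    signed: bool = True,
    min_eigenvalues: int = 100,
    n_knots: int = 20,
    n_bins: int = 60,
    s_max: float = 3.0,
) -> tuple[float, float]:
    """Chi-square statistic and p-value of the NNSD-vs-Poisson fit at one
    candidate hard threshold."""
    adj = threshold_adjacency(corr, candidate_threshold, signed=signed)
    eigs = np.linalg.eigvalsh(adj)
    s = nnsd_spacings(eigs, min_eigenvalues=min_eigenvalues, n_knots=n_knots)
    return poisson_gof(s, n_bins=n_bins, s_max=s_max)


class RMTThresholdSelector:
    """Scan thresholds upward; keep the lowest at which the NNSD fits Poisson.

    sklearn-style estimator: ``fit(corr)`` sets ``threshold_`` (or None if
    no scanned threshold passes) and ``scan_`` (per-candidate records).
    A candidate passes when the Poisson fit is not rejected (p >= p_cut)
    and the next grid step also passes; candidates with too few distinct
    eigenvalues never pass.
    """

    def __init__(
        self,
        start: float = 0.70,
        step: float = 0.01,
        p_cut: float = 0.001,
        signed: bool = True,
        min_eigenvalues: int = 100,
    ):
        self.start = start
        self.step = step
        self.p_cut = p_cut
        self.signed = signed
        self.min_eigenvalues = min_eigenvalues

    def get_params(self, deep: bool = True) -> dict:
        return {
            "start": self.start,
            "step": self.step,
            "p_cut": self.p_cut,
            "signed": self.signed,
            "min_eigenvalues": self.min_eigenvalues,
        }

    def set_params(self, **params) -> "RMTThresholdSelector":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, corr: pd.DataFrame) -> "RMTThresholdSelector":
        if not (0.0 < self.start < 1.0):
            raise ValueError("start must be in (0, 1)")
        if self.step <= 0:
            raise ValueError("step must be positive")
        grid = np.arange(self.start, 1.0, self.step)
        status: list[dict] = []
        for t in grid:
            t = float(round(t, 10))
            try:
                chi2, p = nnsd_poisson_chi2(
                    corr, t, signed=self.signed, min_eigenvalues=self.min_eigenvalues
                )
                status.append({"threshold": t, "chi2": chi2, "p": p, "pass": p >= self.p_cut})
            except InsufficientEigenvaluesError as exc:
                status.append(
                    {"threshold": t, "chi2": None, "p": None, "pass": False, "note": str(exc)}
                )
        self.scan_ = status
        self.threshold_ = None
        for i in range(len(status) - 1):
            if status[i]["pass"] and status[i + 1]["pass"]:
                self.threshold_ = status[i]["threshold"]
                break
        else:
            if len(status) == 1 and status[0]["pass"]:
                self.threshold_ = status[0]["threshold"]
        return self


def select_rmt_threshold(
    corr: pd.DataFrame,
    start: float = 0.70,
    step: float = 0.01,
    p_cut: float = 0.001,
    signed: bool = True,
    min_eigenvalues: int = 100,
) -> float | None:
    """Lowest scanned threshold where the NNSD Poisson fit is not rejected
    (and stays non-rejected one step further); None when nothing passes."""
    sel = RMTThresholdSelector(
        start=start, step=step, p_cut=p_cut, signed=signed, min_eigenvalues=min_eigenvalues
    ).fit(corr)
    return sel.threshold_


# ---------------------------------------------------------------------------
# Network assembly and summary
# ---------------------------------------------------------------------------


def build_network(
    corr: pd.DataFrame,
    threshold: float,
    name: str,
    signed: bool = True,
    n_samples: int = 0,
) -> Network:
    """Network whose edges are all valid gene pairs with |PCC| >= threshold
    (or PCC >= threshold when signed=False); isolated genes are excluded."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    values = corr.to_numpy(dtype=float)
    genes = list(corr.index)
    graph = nx.Graph()
    iu, ju = np.triu_indices(len(genes), k=1)
    w = values[iu, ju]
    valid = ~np.isnan(w)
    keep = (np.abs(w) >= threshold) if signed else (w >= threshold)
    keep &= valid
    for i, j, weight in zip(iu[keep], ju[keep], w[keep]):
        graph.add_edge(genes[i], genes[j], weight=float(weight))
    if graph.number_of_edges() == 0:
        warnings.warn(f"network {name!r}: no edges at threshold {threshold}", stacklevel=2)
    return Network(name=name, graph=graph, threshold=threshold, n_samples=n_samples)


def summarize_network(
    network: Network, modulesets: list | None = None, n_arrays: int | None = None
) -> NetworkSummary:
    """Table-style summary row: nodes, edges, <k> = 2E/N (one decimal),
    threshold, and module counts per detection method."""
    counts = {}
    for ms in modulesets or []:
        counts[ms.method] = len(ms.modules)
    return NetworkSummary(
        name=network.name,
        n_arrays=n_arrays if n_arrays is not None else network.n_samples,
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        avg_connectivity=average_connectivity(network.n_nodes, network.n_edges),
        threshold=network.threshold,
        module_counts=counts,
    )


def write_edge_list(network: Network, path) -> None:
    rows = [
        (a, b, network.graph.edges[a, b].get("weight", 1.0))
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc"]).to_csv(path, sep="\t", index=False)
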