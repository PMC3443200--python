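import networkx as nx
import numpy as np
import pytest

from cnsnet.network_builder import Network


def graph_network(edges, name="test", threshold=0.5):
    g = nx.Graph()
    for e in edges:
        if len(e) == 3:
            a, b, w = e
        else:
            (a, b), w = e, 1.0
        g.add_edge(a, b, weight=w)
    return Network(name=name, graph=g, threshold=threshold)


@pytest.fixture
def two_triangles():
    """Two disconnected triangles a-b-c and x-y-z."""
    return graph_network(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture
def bridged_cliques():
    """Two K5 cliques joined by a single bridge edge."""
    left = [f"L{i}" for i in range(5)]
    right = [f"R{i}" for i in range(5)]
    edges = [(a, b) for i, a in enumerate(left) for b in left[i + 1 :]]
    edges += [(a, b) for i, a in enumerate(right) for b in right[i + 1 :]]
    edges.append(("L0", "R0"))
    return graph_network(edges)


def planted_correlation(n_genes, n_samples, module_sizes, rho, seed):
    """Correlation matrix of a one-factor planted-module expression draw."""
    from cnsnet.synthetic import generate_expression
    from cnsnet.network_builder import pairwise_pcc

    mat, truth = generate_expression(
        n_genes, n_samples, [(s, rho) for s in module_sizes], seed=seed
    )
    return pairwise_pcc(mat, min_overlap=2), truth


def jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


def best_jaccard(truth_modules, found_modules):
    """Mean over planted modules of the best Jaccard against any found module."""
    scores = []
    for genes in truth_modules:
        genes = set(genes)
        scores.append(max((jaccard(genes, set(m)) for m in found_modules), default=0.0))
    return float(np.mean(scores))
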