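"""Collection-level summary arithmetic: average connectivity, capture
fractions against the measurable gene universe, module totals,
cross-network uniqueness and the duplicate-vs-non-duplicate proportion
test.

``ARABIDOPSIS_NETWORK_TABLE`` ships the reference properties of the ten
tissue-grouped Arabidopsis ATH1 co-expression networks (arrays, nodes,
edges, correlation threshold, module counts per method) as input data for
the summary arithmetic; derived columns (average connectivity, totals,
percentages) are always recomputed from the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy import stats

from .network_builder import Network, NetworkSummary, average_connectivity, round_half_up

# Number of measurable ATH1 probe sets after control/non-genic/ambiguous/
# redundant filtering — the denominator of every capture fraction.
MEASURABLE_GENES = 20_677

# Reference network properties: (arrays, nodes, edges, PCC threshold,
# MCL module count, LCM module count) per tissue group.
ARABIDOPSIS_NETWORK_TABLE = pd.DataFrame(
    [
        ("Aerial", 231, 1_780, 5_217, 0.862, 342, 278),
        ("Flower", 146, 972, 8_043, 0.941, 113, 187),
        ("Leaf", 877, 920, 4_553, 0.902, 148, 181),
        ("Root", 640, 1_690, 9_537, 0.837, 297, 323),
        ("Rosette", 268, 1_627, 5_867, 0.864, 285, 289),
        ("Seedling", 675, 1_722, 13_562, 0.836, 261, 435),
        ("Seed", 108, 1_081, 3_574, 0.942, 201, 177),
        ("Shoot", 305, 800, 4_699, 0.926, 119, 172),
        ("Whole", 771, 1_735, 17_111, 0.851, 211, 426),
        ("Global", 4_566, 2_606, 95_004, 0.487, 236, 810),
    ],
    columns=["network", "arrays", "nodes", "edges", "pcc", "mcl", "lcm"],
)

TISSUE_NETWORKS = [n for n in ARABIDOPSIS_NETWORK_TABLE["network"] if n != "Global"]


@dataclass
class CollectionSummary:
    rows: list[NetworkSummary] = field(default_factory=list)
    mcl_total: int = 0
    lcm_total: int = 0
    grand_total: int = 0
    unique_gene_count: int = 0
    capture_pct: float | None = None


def capture_fraction(count: int, total: int = MEASURABLE_GENES) -> float:
    """Percentage of the measurable gene universe, half-up to one decimal."""
    if not (0 <= count <= total):
        raise ValueError(f"count {count} outside [0, {total}]")
    return round_half_up(100.0 * count / total, 1)


def module_totals(summaries: Iterable[NetworkSummary]) -> tuple[int, int, int]:
    """(MCL sum, LCM sum, grand total) over one summary row per network."""
    mcl = sum(s.module_counts.get("MCL", 0) for s in summaries)
    lcm = sum(s.module_counts.get("LCM", 0) for s in summaries)
    return mcl, lcm, mcl + lcm


def reference_summaries(table: pd.DataFrame = ARABIDOPSIS_NETWORK_TABLE) -> list[NetworkSummary]:
    """NetworkSummary rows recomputed from the raw reference counts."""
    out = []
    for row in table.itertuples(index=False):
        out.append(
            NetworkSummary(
                name=row.network,
                n_arrays=int(row.arrays),
                n_nodes=int(row.nodes),
                n_edges=int(row.edges),
                avg_connectivity=average_connectivity(int(row.nodes), int(row.edges)),
                threshold=float(row.pcc),
                module_counts={"MCL": int(row.mcl), "LCM": int(row.lcm)},
            )
        )
    return out


def cross_network_uniqueness(networks: Iterable[Network]) -> pd.DataFrame:
    """Per-network percentage of nodes and edges absent from every other
    network (edge identity = unordered gene pair, weights ignored)."""
    nets = list(networks)
    if len(nets) < 2:
        raise ValueError("need at least two networks")
    node_sets = {n.name: n.nodes for n in nets}
    edge_sets = {n.name: n.edge_set() for n in nets}
    rows = []
    for n in nets:
        other_nodes: set[str] = set()
        other_edges: set[frozenset[str]] = set()
        for m in nets:
            if m.name != n.name:
                other_nodes |= node_sets[m.name]
                other_edges |= edge_sets[m.name]
        nn, ne = len(node_sets[n.name]), len(edge_sets[n.name])
        unique_nodes = len(node_sets[n.name] - other_nodes)
        unique_edges = len(edge_sets[n.name] - other_edges)
        rows.append(
            (
                n.name,
                round_half_up(100.0 * unique_nodes / nn, 1) if nn else 0.0,
                round_half_up(100.0 * unique_edges / ne, 1) if ne else 0.0,
            )
        )
    return pd.DataFrame(rows, columns=["network", "unique_node_pct", "unique_edge_pct"])


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided test of equal proportions (k1/n1 vs k2/n2).

    Chi-square with continuity correction on the 2×2 table; falls back to
    Fisher's exact test when any expected cell count is below 5.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2 and n1 >= 1 and n2 >= 1):
        raise ValueError("inconsistent counts")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    return float(stats.chi2_contingency(table, correction=True)[1])


def summary_table(summaries: Iterable[NetworkSummary]) -> pd.DataFrame:
    """Collection summary in the standard column layout (one row per
    network: arrays, nodes, edges, <k>, threshold, module counts)."""
    rows = [
        (
            s.name, s.n_arrays, s.n_nodes, s.n_edges, s.avg_connectivity,
            s.threshold, s.module_counts.get("MCL", 0), s.module_counts.get("LCM", 0),
        )
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["network", "arrays", "nodes", "edges", "avg_k", "pcc", "mcl", "lcm"]
    )
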