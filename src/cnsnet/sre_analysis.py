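"""Shared regulatory edges (SREs) and the edge-resampling permutation test.

A co-expression edge is an SRE when its two endpoint genes are assigned at
least one common conserved element.  For each module with more than one
intramodule edge and at least one SRE, the observed SRE count is compared
with a null built by drawing the same number of edges (without
replacement) from all network edges 10,000 times; the p-value is the
fraction of draws whose SRE count is strictly higher than observed.
Bonferroni correction runs over the eligible modules of one network ×
method pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_ALPHA
from .module_detection import ModuleSet
from .network_builder import Network

DEFAULT_N_PERM = 10_000


@dataclass
class ModuleEdges:
    module_id: str
    intramodule_edges: set[frozenset[str]]
    sre_edges: set[frozenset[str]]
    shared_elements: dict[frozenset[str], set[str]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.intramodule_edges)

    @property
    def n_sre(self) -> int:
        return len(self.sre_edges)


@dataclass
class SreResult:
    network: str
    method: str
    module_id: str
    n_edges_intramodule: int
    n_sre: int
    n_perm: int
    p_perm: float
    p_bonferroni: float = 1.0
    significant: bool = False
    elements_on_sres: set[str] = field(default_factory=set)
    exclusive_flags: dict[str, bool] = field(default_factory=dict)


def find_sre_edges(
    network: Network,
    moduleset: ModuleSet,
    assignments: Mapping[str, set[str]],
) -> dict[str, ModuleEdges]:
    """Per-module intramodule edge sets and the SREs among them.

    ``assignments`` maps gene_id → element-id set.  An edge is intramodule
    when both endpoints belong to the module; it is an SRE when the
    endpoint element sets intersect.
    """
    out: dict[str, ModuleEdges] = {}
    edges = [frozenset(e) for e in network.graph.edges]
    for module_id in sorted(moduleset.modules):
        members = moduleset.modules[module_id]
        me = ModuleEdges(module_id, set(), set())
        for e in edges:
            a, b = tuple(e)
            if a in members and b in members:
                me.intramodule_edges.add(e)
                shared = assignments.get(a, set()) & assignments.get(b, set())
                if shared:
                    me.sre_edges.add(e)
                    me.shared_elements[e] = shared
        out[module_id] = me
    return out


def _edge_sre_flags(
    edges: list[frozenset[str]], assignments: Mapping[str, set[str]]
) -> np.ndarray:
    flags = np.zeros(len(edges), dtype=bool)
    for i, e in enumerate(edges):
        a, b = tuple(e)
        if assignments.get(a, set()) & assignments.get(b, set()):
            flags[i] = True
    return flags


def sre_permutation_test(
    observed_sre: int,
    module_edge_count: int,
    all_network_edges: list[frozenset[str]],
    assignments: Mapping[str, set[str]],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    conservative: bool = False,
) -> float:
    """Permutation p-value for one module's SRE count.

    Each draw samples ``module_edge_count`` edges without replacement from
    all network edges and counts SREs among them.  Default p-value is
    #(draws with count strictly above observed) / n_perm; the
    ``conservative`` mode uses (#(count >= observed) + 1) / (n_perm + 1).
    """
    if module_edge_count <= 1:
        raise ValueError("module must have more than one intramodule edge")
    if observed_sre < 1:
        raise ValueError("module must have at least one SRE to be eligible")
    total = len(all_network_edges)
    if module_edge_count > total:
        raise ValueError(
            f"module edge count {module_edge_count} exceeds network total {total}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags = _edge_sre_flags(all_network_edges, assignments)
    counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        pick = rng.choice(total, size=module_edge_count, replace=False)
        counts[i] = int(flags[pick].sum())
    if conservative:
        return float((np.sum(counts >= observed_sre) + 1) / (n_perm + 1))
    return float(np.sum(counts > observed_sre) / n_perm)


def run_sre_analysis(
    networks: Iterable[Network],
    modulesets: Iterable[ModuleSet],
    assignments: Mapping[str, set[str]],
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    conservative: bool = False,
) -> list[SreResult]:
    """SRE permutation test for every eligible module of every module set.

    Eligibility: more than one intramodule edge and at least one SRE.
    Bonferroni runs over the eligible modules within one network × method.
    ``elements_on_sres`` is the union of shared-element ids over a
    module's SRE edges; an element is flagged exclusive when it appears in
    no other network's results (same method).  One seeded generator per
    (network, method), modules visited in sorted order, so per-module
    results do not depend on execution order.
    """
    nets = {n.name: n for n in networks}
    results: list[SreResult] = []
    groups: dict[tuple[str, str], list[SreResult]] = {}
    for ms in sorted(modulesets, key=lambda m: (m.network, m.method)):
        net = nets[ms.network]
        edges = sorted(
            (frozenset(e) for e in net.graph.edges), key=lambda e: tuple(sorted(e))
        )
        per_module = find_sre_edges(net, ms, assignments)
        stream = np.random.default_rng(
            np.random.SeedSequence(
                entropy=seed,
                spawn_key=(
                    int.from_bytes(ms.network.encode(), "little") % (2**31),
                    int.from_bytes(ms.method.encode(), "little") % (2**31),
                ),
            )
        )
        for module_id in sorted(per_module):
            me = per_module[module_id]
            if me.n_edges <= 1 or me.n_sre < 1:
                continue  # ineligible, skipped
            p = sre_permutation_test(
                me.n_sre, me.n_edges, edges, assignments,
                n_perm=n_perm, seed=stream, conservative=conservative,
            )
            elements: set[str] = set()
            for shared in me.shared_elements.values():
                elements |= shared
            res = SreResult(
                ms.network, ms.method, module_id,
                me.n_edges, me.n_sre, n_perm, p,
                elements_on_sres=elements,
            )
            results.append(res)
            groups.setdefault((ms.network, ms.method), []).append(res)

    for fam in groups.values():
        m = len(fam)
        for r in fam:
            # permutation p can be exactly 0 under the strict ">" rule
            r.p_bonferroni = min(1.0, r.p_perm * m)
            r.significant = r.p_bonferroni <= alpha

    # exclusivity across networks (same method): element present in no
    # other network's significant-module SRE elements
    by_method: dict[str, dict[str, set[str]]] = {}
    for r in results:
        if r.significant:
            by_method.setdefault(r.method, {}).setdefault(r.network, set()).update(
                r.elements_on_sres
            )
    for r in results:
        others: set[str] = set()
        for net_name, els in by_method.get(r.method, {}).items():
            if net_name != r.network:
                others |= els
        r.exclusive_flags = {el: el not in others for el in r.elements_on_sres}
    return results


def sre_results_to_frame(results: Iterable[SreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.network, r.method, r.module_id, r.n_edges_intramodule, r.n_sre,
                r.p_perm, r.p_bonferroni, r.significant,
                ",".join(sorted(r.elements_on_sres)),
                ",".join(sorted(e for e, x in r.exclusive_flags.items() if x)),
            )
            for r in results
        ],
        columns=[
            "network", "method", "module", "edges", "sres",
            "p", "bonferroni", "significant", "elements", "exclusive",
        ],
    )
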