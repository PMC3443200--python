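"""Node-based over-representation of element (or functional) terms in
modules: one-sided Fisher's exact test with Bonferroni and
Benjamini–Hochberg reporting.

For a module of n genes drawn from a background of N genes of which K
carry a term, the raw p-value is the upper hypergeometric tail
P(X >= k).  The correction family is, by default, all (module, term)
tests within one network × method pair; a module-term pair is flagged
significant when its Bonferroni p-value is at or below alpha
(default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .module_detection import ModuleSet

DEFAULT_ALPHA = 0.001


@dataclass
class EnrichmentResult:
    network: str
    method: str
    module_id: str
    term_id: str
    k: int  # module genes carrying the term
    n: int  # module size
    K: int  # background genes carrying the term
    N: int  # background size
    p_raw: float
    p_bonferroni: float = 1.0
    q_fdr: float = 1.0
    significant: bool = False


def fisher_overrep(k: int, n: int, K: int, N: int) -> float:
    """One-sided upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_family(p_raws: Iterable[float], m: int | None = None) -> tuple[list[float], list[float]]:
    """Bonferroni and Benjamini–Hochberg adjustments for one test family.

    ``m`` is the family size (defaults to the list length; may be larger
    when some family members are implicit).  Returns (bonferroni, bh_fdr)
    in input order.
    """
    p = np.asarray(list(p_raws), dtype=float)
    if len(p) == 0:
        return [], []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m_eff = len(p) if m is None else m
    if m_eff < len(p):
        raise ValueError("family size smaller than number of p-values")
    bonf = np.minimum(1.0, p * m_eff)
    if m_eff == len(p):
        q = multipletests(p, method="fdr_bh")[1]
    else:
        # BH step-up with implicit extra tests at p = 1
        padded = np.concatenate([p, np.ones(m_eff - len(p))])
        q = multipletests(padded, method="fdr_bh")[1][: len(p)]
    return bonf.tolist(), q.tolist()


def enrich_modules(
    modulesets: Iterable[ModuleSet],
    term_map: Mapping[str, set[str]],
    background: set[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    family: str = "per-network",
) -> list[EnrichmentResult]:
    """Test every (module, term) pair where the term occurs at least once
    in the module.

    ``term_map`` maps gene_id → set of term ids (element ids or functional
    terms).  ``background`` defaults, per module set, to the genes of the
    network under test (the union of that module set's genes); pass an
    explicit universe for genome-wide profiling.  ``family`` is
    "per-network" (all tests within one network × method corrected
    together) or "global" (one family over everything).
    """
    if family not in ("per-network", "global"):
        raise ValueError(f"unknown family {family!r}")
    results: list[EnrichmentResult] = []
    groups: dict[tuple[str, str], list[EnrichmentResult]] = {}
    for ms in modulesets:
        bg = background if background is not None else ms.genes()
        missing = ms.genes() - bg
        if missing:
            raise ValueError(
                f"module gene(s) absent from background: {sorted(missing)[:5]}"
            )
        N = len(bg)
        term_count: dict[str, int] = {}
        for gene in bg:
            for t in term_map.get(gene, ()):
                term_count[t] = term_count.get(t, 0) + 1
        for module_id in sorted(ms.modules):
            members = ms.modules[module_id]
            n = len(members)
            k_by_term: dict[str, int] = {}
            for gene in members:
                for t in term_map.get(gene, ()):
                    k_by_term[t] = k_by_term.get(t, 0) + 1
            for term_id in sorted(k_by_term):
                k = k_by_term[term_id]
                K = term_count[term_id]
                res = EnrichmentResult(
                    ms.network, ms.method, module_id, term_id,
                    k, n, K, N, fisher_overrep(k, n, K, N),
                )
                results.append(res)
                groups.setdefault((ms.network, ms.method), []).append(res)

    fams = [results] if family == "global" else list(groups.values())
    for fam in fams:
        if not fam:
            continue
        bonf, q = adjust_family([r.p_raw for r in fam])
        for r, b, qv in zip(fam, bonf, q):
            r.p_bonferroni = b
            r.q_fdr = qv
            r.significant = b <= alpha
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.network, r.method, r.module_id, r.term_id,
                r.k, r.n, r.K, r.N, r.p_raw, r.p_bonferroni, r.q_fdr, r.significant,
            )
            for r in results
        ],
        columns=[
            "network", "method", "module", "term", "k", "n", "K", "N",
            "p", "bonferroni", "fdr", "significant",
        ],
    )
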