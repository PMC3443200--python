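"""Mapping modules and conserved elements onto known gene-regulatory-network
(GRN) components: target loci, cis-regulatory element (CRE) motifs
embedded in elements, and transcription-factor-containing modules.

CRE-to-element matching is exact containment of the shorter sequence in
the longer one on both strands (the faithful equivalent of a
100%-identity / 100%-coverage short-sequence alignment filter); matches
are deterministic and deduplicated by offset with strand "+" preferred
for palindromes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .cns_screen import revcomp
from .module_detection import ModuleSet


@dataclass(frozen=True)
class CreMatch:
    cre_id: str
    element_id: str
    offset: int  # 1-based offset of the match within the element
    strand: str  # strand of the matched CRE ("+" or "-")


def match_cre_to_element(
    cre_seq: str,
    element_seq: str,
    cre_id: str = "",
    element_id: str = "",
) -> list[CreMatch]:
    """All exact containments of the CRE in the element, both strands.

    When the CRE is longer than the element the roles swap (containment of
    the shorter sequence in the longer).  A position matching on both
    strands (palindrome) is reported once with strand "+".
    """
    if not cre_seq or not element_seq:
        raise ValueError("empty sequence")
    short, long_ = cre_seq.upper(), element_seq.upper()
    if len(short) > len(long_):
        short, long_ = long_, short
    found: dict[int, str] = {}
    for strand in ("+", "-"):
        probe = short if strand == "+" else revcomp(short)
        start = 0
        while True:
            i = long_.find(probe, start)
            if i < 0:
                break
            found.setdefault(i + 1, strand)  # "+" scanned first wins ties
            start = i + 1
    return [
        CreMatch(cre_id, element_id, offset, strand)
        for offset, strand in sorted(found.items())
    ]


def match_all_cres(
    cre_motifs: Mapping[str, str], elements: Mapping[str, str]
) -> list[CreMatch]:
    matches: list[CreMatch] = []
    for cre_id in sorted(cre_motifs):
        for element_id in sorted(elements):
            matches.extend(
                match_cre_to_element(
                    cre_motifs[cre_id], elements[element_id], cre_id, element_id
                )
            )
    return matches


def map_grn_targets(
    modulesets: Iterable[ModuleSet], target_table: Mapping[str, Iterable[str]]
) -> tuple[pd.DataFrame, dict]:
    """Per-module known GRN target genes plus collection-level summary.

    The summary reports the fraction of modules containing at least one
    target and the mean target count both over all modules and
    conditionally over modules with >= 1 target (labelled explicitly).
    """
    targets: set[str] = set()
    for locus_list in target_table.values():
        targets |= set(locus_list)
    rows = []
    counts = []
    for ms in modulesets:
        for module_id in sorted(ms.modules):
            hit = sorted(ms.modules[module_id] & targets)
            rows.append((ms.network, ms.method, module_id, len(hit), ",".join(hit)))
            counts.append(len(hit))
    frame = pd.DataFrame(
        rows, columns=["network", "method", "module", "n_targets", "target_genes"]
    )
    nonzero = [c for c in counts if c > 0]
    summary = {
        "n_modules": len(counts),
        "fraction_with_target": (len(nonzero) / len(counts)) if counts else 0.0,
        "mean_targets_all_modules": (sum(counts) / len(counts)) if counts else None,
        "mean_targets_conditional": (sum(nonzero) / len(nonzero)) if nonzero else None,
    }
    return frame, summary


def flag_tf_modules(
    modulesets: Iterable[ModuleSet], tf_genes: Iterable[str]
) -> pd.DataFrame:
    """Flag modules containing at least one transcription-factor gene."""
    tfs = set(tf_genes)
    if not tfs:
        raise ValueError("empty transcription-factor list")
    rows = []
    for ms in modulesets:
        for module_id in sorted(ms.modules):
            inside = sorted(ms.modules[module_id] & tfs)
            rows.append(
                (ms.network, ms.method, module_id, bool(inside), ",".join(inside))
            )
    return pd.DataFrame(
        rows, columns=["network", "method", "module", "has_tf", "tf_genes"]
    )


def classify_novel_cres(
    associated_elements: Iterable[str], cre_matches: Iterable[CreMatch]
) -> dict[str, str]:
    """Partition module-associated elements into known vs novel.

    An element is "known" when at least one CRE motif matches it, "novel"
    otherwise; the two classes partition the associated set.
    """
    known = {m.element_id for m in cre_matches}
    return {
        el: ("known" if el in known else "novel") for el in sorted(set(associated_elements))
    }
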