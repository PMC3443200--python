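"""Genome screening for conserved non-coding element occurrences (CNS′)
and assignment of elements to genes within a proximity window.

The real-data route consumes external BLASTN tabular hits; the built-in
scanner finds maximal exact matches (both strands, >= 15 bp) and is the
no-download path for synthetic fixtures where elements were planted
verbatim.  Occurrence filtering keeps hits covering at least 90% of the
element's original length at e-value <= 0.2; retained occurrences are
assigned to every gene whose interval lies within 2,000 bp (boundary gap,
inclusive; an overlapping hit counts with distance 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import AlignmentHit, FormatError, GeneModel

DEFAULT_WINDOW = 2000
DEFAULT_MIN_FRAC = 0.90
DEFAULT_EVALUE_CUT = 0.2
MIN_EXACT = 15

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CnsElement:
    """A conserved non-coding element: id, sequence and class.

    ``CNS`` marks the original duplicate-proximal element; ``CNS_prime``
    an occurrence found elsewhere in the genome by the screen.
    """

    element_id: str
    sequence: str
    element_class: str = "CNS"  # "CNS" or "CNS_prime"

    @property
    def original_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ElementAssignment:
    element_id: str
    gene_id: str
    distance: int  # bp gap; 0 when overlapping
    side: str  # "upstream", "downstream", "overlapping"
    element_class: str = "CNS_prime"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("negative distance")
        if self.side not in ("upstream", "downstream", "overlapping"):
            raise ValueError(f"bad side {self.side!r}")


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def mask_genome(
    genome: dict[str, str],
    coding_intervals: dict[str, list[tuple[int, int]]] | None = None,
    repeat_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, str]:
    """Replace coding and repeat positions with N (union of both interval
    sets, 1-based inclusive); everything else unchanged."""
    masked = {}
    for chrom, seq in genome.items():
        arr = list(seq)
        for source in (coding_intervals, repeat_intervals):
            for start, end in (source or {}).get(chrom, []):
                if start < 1 or end > len(seq) or start > end:
                    raise ValueError(
                        f"interval ({start}, {end}) out of bounds on {chrom} "
                        f"(length {len(seq)})"
                    )
                arr[start - 1 : end] = "N" * (end - start + 1)
        masked[chrom] = "".join(arr)
    return masked


# ---------------------------------------------------------------------------
# Exact-match scanner
# ---------------------------------------------------------------------------


def scan_elements(
    genome: dict[str, str],
    elements: Sequence[CnsElement],
    min_exact: int = MIN_EXACT,
) -> list[AlignmentHit]:
    """Maximal exact matches (>= ``min_exact`` bp, both strands) of each
    element against the genome, reported as 100%-identity hits.

    Seed-and-extend over ``min_exact``-mers; each maximal match is
    reported once.  N positions never match.
    """
    for el in elements:
        if el.original_length < min_exact:
            raise ValueError(
                f"element {el.element_id} shorter than minimal exact unit {min_exact}"
            )
    # genome k-mer index
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(len(seq) - min_exact + 1):
            kmer = seq[i : i + min_exact]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((chrom, i))

    hits: list[AlignmentHit] = []
    for el in elements:
        seen: set[tuple[str, int, int, str]] = set()
        for strand in ("+", "-"):
            query = el.sequence if strand == "+" else revcomp(el.sequence)
            qlen = len(query)
            for qpos in range(qlen - min_exact + 1):
                kmer = query[qpos : qpos + min_exact]
                if "N" in kmer:
                    continue
                for chrom, gpos in index.get(kmer, []):
                    seq = genome[chrom]
                    # extend left
                    qs, gs = qpos, gpos
                    while qs > 0 and gs > 0 and query[qs - 1] == seq[gs - 1] != "N":
                        qs -= 1
                        gs -= 1
                    # extend right
                    qe, ge = qpos + min_exact, gpos + min_exact
                    while qe < qlen and ge < len(seq) and query[qe] == seq[ge] != "N":
                        qe += 1
                        ge += 1
                    key = (chrom, gs, ge, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(
                        AlignmentHit(
                            query_id=el.element_id,
                            subject_chrom=chrom,
                            subject_start=gs + 1,  # to 1-based inclusive
                            subject_end=ge,
                            aligned_length=ge - gs,
                            identity_pct=100.0,
                            e_value=0.0,
                            orientation=strand,
                        )
                    )
    hits.sort(
        key=lambda h: (h.query_id, h.subject_chrom, h.subject_start, h.orientation)
    )
    return hits


# ---------------------------------------------------------------------------
# Occurrence filtering and assignment
# ---------------------------------------------------------------------------


def filter_cns_hits(
    hits: Iterable[AlignmentHit],
    elements: Sequence[CnsElement],
    min_frac: float = DEFAULT_MIN_FRAC,
    evalue_cut: float = DEFAULT_EVALUE_CUT,
) -> list[AlignmentHit]:
    """Keep hits with e-value <= ``evalue_cut`` whose aligned length covers
    at least ``min_frac`` of the element's original length (inclusive);
    retained hits define CNS′ occurrences."""
    lengths = {el.element_id: el.original_length for el in elements}
    kept = []
    for h in hits:
        if h.query_id not in lengths:
            raise FormatError(f"hit references unknown element {h.query_id}")
        if h.e_value <= evalue_cut and h.aligned_length >= min_frac * lengths[h.query_id]:
            kept.append(h)
    return kept


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """bp gap between two 1-based inclusive intervals; 0 when they touch
    or overlap."""
    return max(0, max(start_a, start_b) - min(end_a, end_b) - 1)


def assign_elements(
    hits: Iterable[AlignmentHit],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    element_class: str = "CNS_prime",
) -> list[ElementAssignment]:
    """Assign each retained occurrence to all genes within ``window`` bp.

    The gap is measured between the closest interval boundaries
    (inclusive: gap <= window assigns).  ``side`` is relative to the gene's
    strand: a hit before the gene start is upstream of a + gene and
    downstream of a − gene.  Duplicate (element, gene) pairs collapse to
    the closest occurrence.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    best: dict[tuple[str, str], ElementAssignment] = {}
    for h in hits:
        for g in by_chrom.get(h.subject_chrom, []):
            gap = interval_gap(h.subject_start, h.subject_end, g.start, g.end)
            if gap > window:
                continue
            if gap == 0 and not (
                h.subject_end < g.start or h.subject_start > g.end
            ):
                side = "overlapping"
            elif h.subject_end < g.start:
                side = "upstream" if g.strand == "+" else "downstream"
            else:
                side = "downstream" if g.strand == "+" else "upstream"
            key = (h.query_id, g.gene_id)
            cand = ElementAssignment(h.query_id, g.gene_id, gap, side, element_class)
            if key not in best or cand.distance < best[key].distance:
                best[key] = cand
    return sorted(best.values(), key=lambda a: (a.element_id, a.gene_id))


def assignments_to_frame(assignments: Iterable[ElementAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.element_id, a.gene_id, a.distance, a.side, a.element_class)
            for a in assignments
        ],
        columns=["element_id", "gene_id", "distance", "side", "class"],
    )


def assignment_index(assignments: Iterable[ElementAssignment]) -> dict[str, set[str]]:
    """gene_id → set of element ids assigned to it."""
    idx: dict[str, set[str]] = {}
    for a in assignments:
        idx.setdefault(a.gene_id, set()).add(a.element_id)
    return idx
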