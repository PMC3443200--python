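"""Readers and writers for the external formats the pipeline touches.

Every downstream stage consumes only the domain types defined here:
expression matrices (TSV), gene models (GFF3), alignment hits (BLAST
tabular, 12-column dialect) and ATH1-style probe→locus maps.  Coordinates
are 1-based inclusive throughout, following the GFF3 convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of normalized log-scale intensities.

    Missing cells are stored as NaN, never zero.  ``group_label`` names the
    tissue group the samples belong to ("global" for the pooled set).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float, NaN = missing
    group_label: str = "global"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise FormatError(f"duplicated gene id: {g}")
            seen.add(g)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def degenerate_rows(self) -> list[str]:
        """Gene ids with fewer than two non-missing values."""
        ok = np.sum(~np.isnan(self.values), axis=1) >= 2
        return [g for g, flag in zip(self.gene_ids, ok) if not flag]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: 1-based inclusive coordinates on a chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if not self.chrom:
            raise FormatError(f"gene {self.gene_id}: empty chromosome name")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of an element (query) to a genome location.

    Subject coordinates are normalized so ``subject_start <= subject_end``;
    ``orientation`` records the original strand ("-" when the raw subject
    interval was reversed).
    """

    query_id: str
    subject_chrom: str
    subject_start: int
    subject_end: int
    aligned_length: int
    identity_pct: float
    e_value: float
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.aligned_length < 1:
            raise FormatError(f"hit {self.query_id}: aligned_length < 1")
        if self.e_value < 0:
            raise FormatError(f"hit {self.query_id}: negative e-value")
        if self.subject_start > self.subject_end:
            raise FormatError(f"hit {self.query_id}: interval not normalized")


PROBE_CLASSES = ("control", "non_genic", "ambiguous", "redundant", "valid")


@dataclass(frozen=True)
class ProbeMap:
    probe_id: str
    gene_id: str | None
    probe_class: str

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {self.probe_class!r}")
        if self.probe_class == "valid" and self.gene_id is None:
            raise ValueError(f"valid probe {self.probe_id} lacks a gene id")


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path, group_label: str = "global") -> ExpressionMatrix:
    """Read a genes × samples TSV (header = sample ids, first column = gene id).

    Empty cells and the literal strings ``NA``/``NaN`` load as missing
    values; a duplicated gene id or a ragged row is a format error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, "
                    f"expected {len(header)})"
                )
            gene_ids.append(row[0])
            rows.append([_parse_cell(c, path, lineno) for c in row[1:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(gene_ids, sample_ids, values, group_label)


def _parse_cell(cell: str, path: Path, lineno: int) -> float:
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN"):
        return float("nan")
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric cell {cell!r}") from None


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", *matrix.sample_ids])
        for gid, row in zip(matrix.gene_ids, matrix.values):
            writer.writerow([gid] + ["" if np.isnan(v) else repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene-type features from a GFF3 file, sorted by (chrom, start).

    Only ``gene`` features are loaded; mRNA/exon/CDS children are skipped.
    Coordinates stay 1-based inclusive as in the file.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype.lower() != "gene":
                continue
            gene_id = _gff3_id(attrs) or f"{chrom}:{start}-{end}"
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if s > e:
                raise FormatError(f"{path}:{lineno}: start {s} > end {e}")
            genes.append(GeneModel(gene_id, chrom, s, e, strand))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def _gff3_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        key, _, val = part.strip().partition("=")
        if key == "ID":
            return val
    return None


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcnsnet\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular output.

    Columns: query, subject, %identity, length, mismatches, gaps, qstart,
    qend, sstart, send, evalue, bitscore.  A subject interval with
    sstart > send is normalized and flagged orientation "-".
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            ident = float(fields[2])
            length = int(fields[3])
            sstart, send = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
            orientation = "+"
            if sstart > send:
                sstart, send = send, sstart
                orientation = "-"
            hits.append(
                AlignmentHit(q, s, sstart, send, length, ident, evalue, orientation)
            )
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (qstart/qend span the full query)."""
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            sstart, send = h.subject_start, h.subject_end
            if h.orientation == "-":
                sstart, send = send, sstart
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_chrom,
                        f"{h.identity_pct:.2f}",
                        str(h.aligned_length),
                        "0",
                        "0",
                        "1",
                        str(h.aligned_length),
                        str(sstart),
                        str(send),
                        repr(h.e_value),
                        "0.0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------


@dataclass
class ProbeFilterSummary:
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return self.counts.get("valid", 0)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def filter_probes(
    raw_map: Sequence[tuple[str, str | None]],
    *,
    control_prefix: str = "AFFX",
    keep_first_redundant: bool = False,
) -> tuple[list[ProbeMap], ProbeFilterSummary]:
    """Classify probe→locus mappings and drop unusable probes.

    ``raw_map`` holds (probe_id, gene_id-or-None) rows, possibly several per
    probe.  Rules apply in order: control (id prefixed ``AFFX``) →
    non_genic (no gene) → ambiguous (maps to ≥2 loci) → redundant (≥2
    probes map uniquely to the same gene).  By default every redundant
    probe is dropped; ``keep_first_redundant`` instead keeps the
    lexicographically first probe per gene as valid.
    """
    by_probe: dict[str, set[str | None]] = {}
    order: list[str] = []
    for probe_id, gene_id in raw_map:
        if probe_id not in by_probe:
            order.append(probe_id)
            by_probe[probe_id] = set()
        by_probe[probe_id].add(gene_id)

    # first pass: control / non_genic / ambiguous
    stage: dict[str, tuple[str, str | None]] = {}
    gene_to_probes: dict[str, list[str]] = {}
    for probe_id in order:
        genes = {g for g in by_probe[probe_id] if g is not None}
        if probe_id.startswith(control_prefix):
            stage[probe_id] = ("control", None)
        elif not genes:
            stage[probe_id] = ("non_genic", None)
        elif len(genes) > 1:
            stage[probe_id] = ("ambiguous", None)
        else:
            gene = next(iter(genes))
            stage[probe_id] = ("candidate", gene)
            gene_to_probes.setdefault(gene, []).append(probe_id)

    result: list[ProbeMap] = []
    counts = {c: 0 for c in PROBE_CLASSES}
    for probe_id in order:
        cls, gene = stage[probe_id]
        if cls == "candidate":
            siblings = gene_to_probes[gene]
            if len(siblings) > 1:
                if keep_first_redundant and probe_id == min(siblings):
                    cls = "valid"
                else:
                    cls = "redundant"
            else:
                cls = "valid"
        result.append(ProbeMap(probe_id, gene if cls == "valid" else None, cls))
        counts[cls] += 1
    return result, ProbeFilterSummary(counts)


# ---------------------------------------------------------------------------
# FASTA (thin wrappers over Biopython)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id → sequence mapping."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicated sequence id {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Module-assignment table (network, method, module_id, gene_id)
# ---------------------------------------------------------------------------


def write_module_table(rows: Iterable[tuple[str, str, str, str]], path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=["network", "method", "module_id", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


def read_module_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["network", "method", "module_id", "gene_id"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df
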