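"""Synthetic study-condition generator.

Emulates the inputs the analysis expects — tissue-grouped expression with
planted co-expressed modules, a toy genome carrying genes and planted
conserved elements, regulatory-motif fixtures and duplicate-pair labels —
with every piece of ground truth recorded, so each pipeline stage can be
tested against a known answer without external downloads.

Planted co-expression follows a one-factor Gaussian model: for a module
with target correlation rho, each member gene is

    x_g = sqrt(rho) * f_m + sqrt(1 - rho) * eps_g

with f_m a shared module factor and eps_g i.i.d. N(0, 1) noise, so the
expected pairwise Pearson correlation within the module is exactly rho.
Background genes are independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionMatrix, GeneModel

_BASES = np.array(list("ACGT"))

# Drought response element, a canonical plant cis-regulatory motif; default
# fixture motif for the GRN-mapping stage.
DRE_MOTIF = "GCCGAC"


@dataclass
class ScenarioTruth:
    """Ground truth for a generated scenario (everything is recorded)."""

    seed: int
    planted_modules: list[dict] = field(default_factory=list)
    # each: {"module_id", "genes": [...], "rho": float}
    planted_elements: list[dict] = field(default_factory=list)
    # each: {"element_id", "chrom", "start", "end", "strand", "gene_ids": [...],
    #        "enriched": bool}
    element_assignments: list[tuple[str, str]] = field(default_factory=list)
    # (element_id, gene_id) pairs within the proximity window
    alpha_pairs: list[tuple[str, str]] = field(default_factory=list)
    cre_motifs: dict[str, str] = field(default_factory=dict)
    embedded_motifs: list[tuple[str, str]] = field(default_factory=list)
    # (cre_id, element_id) pairs embedded verbatim
    tf_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    n_genes: int,
    n_samples: int,
    modules: list[tuple[int, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
    group_label: str = "synthetic",
    gene_prefix: str = "G",
) -> tuple[ExpressionMatrix, ScenarioTruth]:
    """Expression matrix with planted correlated modules.

    ``modules`` lists (size, rho) pairs; planted modules occupy the first
    genes in order and are disjoint.  Remaining genes are independent
    N(0, noise_sd^2) background.
    """
    total = sum(size for size, _ in modules)
    if total > n_genes:
        raise ValueError(f"module sizes sum to {total} > n_genes={n_genes}")
    for _, rho in modules:
        if not (0.0 <= rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {rho}")

    rng = np.random.default_rng(seed)
    values = rng.normal(scale=noise_sd, size=(n_genes, n_samples))
    gene_ids = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    truth = ScenarioTruth(seed=seed)
    idx = 0
    for m, (size, rho) in enumerate(modules):
        factor = rng.normal(size=n_samples)
        eps = rng.normal(size=(size, n_samples))
        values[idx : idx + size] = noise_sd * (
            np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps
        )
        truth.planted_modules.append(
            {"module_id": f"M{m:03d}", "genes": gene_ids[idx : idx + size], "rho": rho}
        )
        idx += size
    matrix = ExpressionMatrix(gene_ids, [f"S{j:04d}" for j in range(n_samples)], values, group_label)
    return matrix, truth


def generate_tissue_groups(
    n_genes: int,
    groups: dict[str, int],
    modules: list[tuple[int, float]],
    seed: int = 0,
) -> tuple[dict[str, ExpressionMatrix], ScenarioTruth]:
    """One expression matrix per tissue group over a shared gene universe.

    The same modules are planted in every group (module structure robust
    across tissues); each group gets its own factor and noise draws.
    """
    truth = ScenarioTruth(seed=seed)
    out: dict[str, ExpressionMatrix] = {}
    for i, (label, n_samples) in enumerate(sorted(groups.items())):
        mat, t = generate_expression(
            n_genes, n_samples, modules, seed=seed + 7919 * (i + 1), group_label=label
        )
        out[label] = mat
        if not truth.planted_modules:
            truth.planted_modules = t.planted_modules
    return out, truth


# ---------------------------------------------------------------------------
# Genome, genes and planted elements
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def generate_genome_and_elements(
    n_chrom: int = 2,
    genes_per_chrom: int = 10,
    element_specs: list[dict] | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    gene_length: int = 900,
    intergenic: int = 5000,
    element_length: int = 60,
    window: int = 2000,
    min_exact: int = 15,
    max_attempts: int = 50,
) -> tuple[dict[str, str], list[GeneModel], dict[str, str], ScenarioTruth]:
    """Toy genome with genes and elements planted verbatim near them.

    ``element_specs`` entries describe one element each:
    ``{"element_id", "gene_ids": [targets], "background_gene_ids": [...],
    "enriched": bool}`` — the element is planted once within ``window`` bp
    of every listed gene.  Element sequences are generated unique at the
    ``min_exact``-mer level against the genome background and each other,
    so the exact scanner has no spurious hits by construction (checked;
    regenerated on collision).

    Returns (genome, gene models, element sequences, truth).
    """
    if element_length < min_exact:
        raise ValueError(f"element length {element_length} < minimal exact unit {min_exact}")
    rng = np.random.default_rng(seed)
    truth = ScenarioTruth(seed=seed)

    # gene grid: fixed slots with wide intergenic gaps so element placement
    # next to one gene cannot fall within the window of another
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    slot = gene_length + 2 * (window + element_length + 200) + intergenic
    gid_iter = iter(gene_ids) if gene_ids is not None else None
    n = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        chrom_len = genes_per_chrom * slot + intergenic
        genome[chrom] = _random_sequence(rng, chrom_len)
        for g in range(genes_per_chrom):
            start = intergenic + g * slot + (window + element_length + 200)
            gid = next(gid_iter) if gid_iter else f"G{n:05d}"
            genes.append(GeneModel(gid, chrom, start, start + gene_length - 1, "+" if n % 2 == 0 else "-"))
            n += 1
    gene_by_id = {g.gene_id: g for g in genes}

    # background k-mer inventory for collision checking
    background = set()
    for seq in genome.values():
        background |= _kmers(seq, min_exact)
        background |= _kmers(_revcomp(seq), min_exact)

    elements: dict[str, str] = {}
    specs = element_specs or []
    for spec in specs:
        eid = spec["element_id"]
        for attempt in range(max_attempts):
            seq = _random_sequence(rng, spec.get("length", element_length))
            kmers = _kmers(seq, min_exact) | _kmers(_revcomp(seq), min_exact)
            if not (kmers & background):
                break
        else:
            raise RuntimeError(f"could not generate collision-free element {eid}")
        background |= kmers
        elements[eid] = seq

    # plant each element next to its target genes
    for spec in specs:
        eid = spec["element_id"]
        seq = elements[eid]
        targets = list(spec.get("gene_ids", [])) + list(spec.get("background_gene_ids", []))
        for gid in targets:
            gene = gene_by_id[gid]
            gap = int(rng.integers(10, window - len(seq)))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = seq if strand == "+" else _revcomp(seq)
            # upstream of gene start (1-based): element occupies
            # [gene.start - gap - len, gene.start - gap - 1]
            start = gene.start - gap - len(seq)  # 1-based inclusive
            if start < 1:
                raise RuntimeError(f"element {eid} placement before chromosome start")
            chrom_seq = genome[gene.chrom]
            genome[gene.chrom] = (
                chrom_seq[: start - 1] + planted + chrom_seq[start - 1 + len(seq) :]
            )
            truth.planted_elements.append(
                {
                    "element_id": eid,
                    "chrom": gene.chrom,
                    "start": start,
                    "end": start + len(seq) - 1,
                    "strand": strand,
                    "gene_ids": [gid],
                    "enriched": bool(spec.get("enriched", False)),
                }
            )
            truth.element_assignments.append((eid, gid))

    # re-check uniqueness after planting (a splice can create new k-mers)
    for eid, seq in elements.items():
        occurrences = 0
        for chrom_seq in genome.values():
            occurrences += _count_occurrences(chrom_seq, seq)
            occurrences += _count_occurrences(chrom_seq, _revcomp(seq))
        expected = sum(1 for e, _ in truth.element_assignments if e == eid)
        if occurrences != expected:
            raise RuntimeError(
                f"element {eid}: {occurrences} genome occurrences, expected {expected}"
            )
    truth.element_assignments = sorted(set(truth.element_assignments))
    return genome, genes, elements, truth


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def make_enriched_element_specs(
    module_genes: list[str],
    background_genes: list[str],
    enrichment_fraction: float = 0.8,
    background_rate: float = 0.05,
    seed: int = 0,
    element_id: str = "CNSx_0001",
) -> list[dict]:
    """Placement description for one module-enriched element.

    The element is planted near ``enrichment_fraction`` of the module's
    genes (rounded to nearest) and near each background gene independently
    with probability ``background_rate``.
    """
    rng = np.random.default_rng(seed)
    k = int(round(enrichment_fraction * len(module_genes)))
    carriers = list(rng.choice(module_genes, size=k, replace=False))
    bg = [g for g in background_genes if rng.random() < background_rate]
    return [
        {
            "element_id": element_id,
            "gene_ids": carriers,
            "background_gene_ids": bg,
            "enriched": True,
        }
    ]


# ---------------------------------------------------------------------------
# GRN fixture: CRE motifs, target table, TF genes
# ---------------------------------------------------------------------------


def generate_grn_fixture(
    elements: dict[str, str],
    n_motifs: int = 3,
    seed: int = 0,
    motif_length: int = 6,
    embed_fraction: float = 0.5,
    gene_universe: list[str] | None = None,
    n_factors: int = 2,
    targets_per_factor: int = 5,
    n_tf_genes: int = 3,
) -> tuple[dict[str, str], dict[str, list[str]], list[str], ScenarioTruth]:
    """CRE motifs (first one the DRE, GCCGAC), embedded into a subset of
    elements, plus a factor→target-gene table and a TF gene list.

    Returns (cre_motifs, target_table, tf_genes, elements, truth) where
    ``elements`` carries the sequences with motifs spliced in.
    """
    if not (4 <= motif_length <= 12):
        raise ValueError("motif length must be 4-12 bp")
    rng = np.random.default_rng(seed)
    motifs: dict[str, str] = {}
    for i in range(n_motifs):
        if i == 0:
            motifs["CRE_DRE"] = DRE_MOTIF
        else:
            motifs[f"CRE_{i:03d}"] = _random_sequence(rng, motif_length)

    truth = ScenarioTruth(seed=seed, cre_motifs=dict(motifs))
    elements = dict(elements)
    element_ids = sorted(elements)
    n_embed = int(round(embed_fraction * len(element_ids)))
    chosen = list(rng.choice(element_ids, size=n_embed, replace=False)) if n_embed else []
    for j, eid in enumerate(chosen):
        cre_id = list(motifs)[j % len(motifs)]
        motif = motifs[cre_id]
        seq = elements[eid]
        if len(motif) > len(seq):
            continue
        offset = int(rng.integers(0, len(seq) - len(motif) + 1))
        elements[eid] = seq[:offset] + motif + seq[offset + len(motif) :]
        truth.embedded_motifs.append((cre_id, eid))

    target_table: dict[str, list[str]] = {}
    tf_genes: list[str] = []
    if gene_universe:
        pool = list(gene_universe)
        for f in range(n_factors):
            k = min(targets_per_factor, len(pool))
            targets = sorted(rng.choice(pool, size=k, replace=False))
            target_table[f"TF{f:03d}"] = list(targets)
        tf_genes = sorted(rng.choice(pool, size=min(n_tf_genes, len(pool)), replace=False))
    truth.tf_genes = tf_genes
    return motifs, target_table, tf_genes, elements, truth


def label_alpha_pairs(gene_ids: list[str], fraction: float = 0.3, seed: int = 0) -> list[tuple[str, str]]:
    """Pair off a fraction of genes as surviving whole-genome-duplication
    (alpha) duplicates; returns disjoint gene-id pairs."""
    rng = np.random.default_rng(seed)
    n_pairs = int(fraction * len(gene_ids) / 2)
    chosen = rng.choice(gene_ids, size=2 * n_pairs, replace=False)
    return [(chosen[2 * i], chosen[2 * i + 1]) for i in range(n_pairs)]
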