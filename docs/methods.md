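# Methods

## Scope and model

`cnsnet` associates conserved non-coding elements with co-expressed gene
modules. The statistical chain is: Pearson co-expression networks with an
RMT-selected hard threshold → modules by Markov clustering (MCL) and link
communities (LCM) → genome-wide element occurrence and gene assignment →
node-based over-representation (Fisher / Bonferroni / BH) → edge-based
shared-regulatory-edge (SRE) permutation testing → mapping onto known
regulatory-network components. Each stage is implemented against domain
types with explicit invariants, and the synthetic-data module generates
fully labelled inputs so that every stage has a ground truth to test
against.

## Correlation and missing data

Similarity is the pairwise Pearson correlation over pairwise-complete
samples (pandas `DataFrame.corr` with `min_periods`). Pairs with fewer
than `min_overlap` complete sample pairs (default 30) or zero variance
are *invalid* (NaN), never coerced to 0, so sparse coverage cannot
masquerade as absence of correlation. Thresholding applies to |PCC| by
default — both strongly positive and strongly negative correlations form
edges, with the signed value kept as the edge weight; a positive-only
mode is available. Edge sets are invariant to gene ordering.

## RMT hard threshold

Candidate thresholds are scanned upward (default start 0.70, step 0.01).
At each candidate the sub-threshold entries of the correlation matrix are
zeroed (diagonal 1) and the eigenvalues computed. Degenerate eigenvalues
are collapsed (tolerance 1e-8) — a near-empty thresholded matrix
therefore collapses to a handful of distinct values and is reported as
*insufficient* (minimum 100 distinct eigenvalues by default) rather than
yielding a spurious fit. The spectrum is unfolded by a least-squares
cubic spline fitted to the empirical cumulative eigenvalue distribution
with 20 quantile-placed interior knots; nearest-neighbour spacings are
normalized to unit mean. Goodness of fit to the Poisson form e^(−s) is a
chi-square over 60 bins on s ∈ [0, 3] plus an overflow bin, with bins
pooled from the right until each pooled expected count is ≥ 5. The
selected threshold is the lowest candidate whose fit is not rejected
(p ≥ 0.001) and that stays non-rejected one further grid step; when no
candidate passes, a no-threshold signal (None) is returned and callers
may fall back to a fixed cutoff.

These unfolding and binning choices are validated by simulation: dense
Gaussian-orthogonal-ensemble matrices are rejected and block-diagonal
collections of independent small blocks accepted in ≥ 8/10 replicates
each (the acceptance suite runs exactly this check).

## MCL

Column-stochastic flow with self loops at each node's maximum incident
weight, alternating expansion (M ← M²) and inflation (entry-wise power
2.0, column renormalization) with pruning below 1e-5, until the flow
matrix changes by < 1e-6 or 200 iterations. Clusters are read from
attractor rows (positive return flow); attractors with overlapping
support merge into one attractor system, a node attracted by several
systems is resolved to the larger cluster (tie: the system with the
smallest leading node), and numerically starved nodes attach to the
system holding most of their column mass — so the result is always a
disjoint cover of all nodes. Topology is binary by default (weights
ignored), with a weighted mode available.

## Link communities

For edges sharing exactly one node k, similarity is the Jaccard index of
the *inclusive* neighbourhoods of the non-shared endpoints,
|n⁺(a) ∩ n⁺(b)| / |n⁺(a) ∪ n⁺(b)| with n⁺(x) = {x} ∪ neighbours(x);
non-adjacent edge pairs have similarity 0. Edges are clustered by
single linkage (scipy), and the dendrogram is cut at the height
maximizing partition density

D_c = (m_c − (n_c − 1)) / (n_c(n_c − 1)/2 − (n_c − 1)),  D_c := 0 for n_c = 2,

with the overall D the m_c-weighted mean of D_c; ties between heights
resolve to the lowest height (strict-improvement rule), making the cut
deterministic. Modules are the node sets induced by each edge community;
singleton edge communities are discarded by default. Node overlap
between modules is expected and preserved.

## Genome screen and assignment

The built-in scanner indexes genome 15-mers and extends seeds to maximal
exact matches on both strands (N never matches); it is intended for
synthetic fixtures where elements are planted verbatim, while real data
enters as external BLASTN tabular hits whose e-values are trusted, never
recomputed. Occurrences must cover ≥ 90% of the element's original
length (inclusive) at e-value ≤ 0.2. Assignment uses the boundary gap
between 1-based inclusive intervals, gap = max(0, max(startA, startB) −
min(endA, endB) − 1), with "within 2,000 bp" inclusive (gap ≤ 2000); an
occurrence overlapping the gene body is assigned with distance 0. Side
labels (upstream/downstream) are computed relative to gene strand;
duplicate (element, gene) pairs collapse to the closest occurrence.

## Enrichment

The raw p-value is the hypergeometric upper tail P(X ≥ k) (scipy); the
test family for Bonferroni and Benjamini–Hochberg is all (module, term)
tests within one network × method pair (a global-family option exists),
and significance is Bonferroni p ≤ 0.001. The default background is the
gene universe of the module set under test (for MCL this equals the
network's node set, the expressed universe); an explicit background can
be supplied for genome-wide profiling. Terms occurring in a single
module gene are still tested. The implementation is cross-checked in the
test suite against exhaustive exact-integer tail summation over every
instance with N ≤ 60 (agreement to 1e-12).

## SRE permutation test

An intramodule edge (both endpoints in the module) is an SRE when the
endpoint genes' element sets intersect. Modules with more than one
intramodule edge and at least one SRE are eligible. Each of the 10,000
permutations draws the module's edge count from all network edges
*without replacement* (a module's edges are distinct) and counts SREs
among the draw; the p-value is the fraction of draws with a count
*strictly higher* than observed — so a maximal observed count yields
p = 0 exactly. A conservative mode, (#{count ≥ obs} + 1)/(n_perm + 1),
is available. Bonferroni runs over eligible modules per network ×
method. One seeded generator is used per (network, method) with modules
visited in sorted order, so each module's p-value is reproducible
independent of execution order. Element exclusivity is computed across
networks within the same method.

Calibration: with elements assigned independently of module structure,
the permutation p over 200 synthetic modules is approximately uniform
(Kolmogorov–Smirnov statistic < 0.1; fraction ≤ 0.05 within 0.05 ± 0.02).
The calibration scenario uses a 3,000-edge network of disjoint gene
pairs with 50% SRE rate and 300-edge modules — sizes chosen so the
discrete SRE-count distribution is fine-grained enough for the uniformity
check to be meaningful, while the strict-> rule's sub-uniformity stays
within the stated band.

## GRN mapping

Because the acceptance criterion for CRE-to-element matching is 100%
identity over 100% of the shorter sequence, exact substring containment
on both strands is the faithful, deterministic equivalent of a
short-word alignment search and is used directly. Palindromic
double-hits deduplicate by offset with strand "+" preferred. Known/novel
classification of module-associated elements is by presence/absence of
any CRE match, and always partitions the associated set. The
targets-per-module average is reported both over all modules and
conditionally over modules with ≥ 1 target, explicitly labelled, since
either convention is defensible.

## Synthetic data

Planted co-expression uses a one-factor Gaussian model, x_g = √ρ·f_m +
√(1 − ρ)·ε_g, chosen because the expected within-module PCC is exactly ρ
(closed form to test against); background genes are independent noise.
Default study conditions for the recovery and power scenarios: ρ = 0.9,
20 (recovery) or 10 (power) genes per module, 200 samples, element
enrichment fraction 0.8 against a 5% background carrier rate —
calibration and power checks run at n_perm = 2,000 with the remaining
suites at the 10,000-draw default. Toy genomes place genes on a fixed
grid with intergenic spacing wide enough that an element planted near
one gene cannot fall in another's window; element sequences are
generated unique at the 15-mer level against the genome and each other
(checked after planting; regenerated on collision), so the exact scanner
recovers exactly the planted occurrences (precision = recall = 1). What
the generator does **not** emulate: probe-level microarray noise,
normalization artifacts, correlated background structure, repeat-rich
genomes, or inexact (diverged) element occurrences — so passing tests
demonstrate correctness of the machinery under its stated model, not
robustness to real-data pathologies.

## Probe filtering

ATH1-style probe→locus tables are classified in rule order control
(AFFX prefix) → non-genic → ambiguous (≥ 2 loci) → redundant (≥ 2 probes
uniquely on one gene). "Redundant" removal drops *all* probes sharing a
gene by default — the stated removal, with no tie-break — with an
optional keep-first-per-gene alternative, since published descriptions
of such filters are ambiguous on whether one representative survives.

## Numerical and degenerate-input choices

- Percentages and ⟨k⟩ = 2E/N display with half-up rounding to one
  decimal (matches every reference value checked).
- An empty thresholded network is a valid object with a warning;
  ⟨k⟩ of an empty network is reported as undefined, not 0.
- Two-proportion contrasts use chi-square with continuity correction,
  falling back to Fisher's exact test when any expected cell is < 5.
- Seeds: a single run seed fans out to per-stage, per-network substreams
  by CRC-hashing stage names; all derived seeds stay below 2³¹.

## Known limitations

- The RMT scan assumes enough distinct eigenvalues (≥ 100 by default) to
  form a spacing distribution; very small networks always fall back to a
  fixed threshold.
- The LCM implementation builds a dense condensed distance matrix over
  edge pairs, O(E²) memory — appropriate for the few-thousand-edge
  networks this package targets, not for millions of edges.
- The exact scanner is a test-path tool; diverged element occurrences in
  real genomes require the external alignment route.
- MCL convergence is declared at a fixed tolerance; pathological graphs
  may oscillate, in which case the current flow matrix is interpreted
  with a warning.
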