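# Methods

## Scope and model

`lncevo` treats a plant lncRNA study as four linked inference problems:
placing redundant multi-database transcript sets on genomes, grouping
cross-species homologues into dated orthologous families, summarising
expression by tissue specificity, and transferring function to lncRNAs
through a co-expression network.  No step fits a parametric model to data;
each is a deterministic procedure with a small number of interpretable
thresholds, so correctness is established by worked examples, invariants
and planted-truth recovery rather than by estimator theory.

## Integration

A transcript's candidate placements are clusters of its genome hits:
fragments on one chromosome and strand, sorted by subject start, split
where the gap to the running subject end exceeds `max_gap` (default
4000 bp, the scale of plant introns).  Two scores summarise a cluster:

* *effective coverage* — length of the union of the member query
  intervals divided by the query length.  The union (not the sum)
  prevents overlapping fragments from double-counting, so coverage never
  exceeds 1.
* *weighted identity* — Σ(identityᵢ × lengthᵢ) / Σ lengthᵢ over member
  fragments, the natural length weighting.

Clusters must exceed 70 % coverage **and** 80 % identity (strict
inequalities, read literally from "greater than"); among survivors the
optimum is chosen lexicographically, weighted identity before coverage,
with float ties at 10⁻⁹ tolerance.  All tied optima are kept and flagged
as paralogous copies.  Transcripts with no surviving cluster are excluded
from the catalogue and logged — the catalogue counts genome-placed
lncRNAs only.

Redundancy between databases is resolved on genomic spans: two placements
on one chromosome/strand are the same locus when their span overlap
exceeds 80 % of the shorter span, closed under single linkage (A~B and
B~C merge all three even if A and C overlap less).  An exon-overlap mode
(`mode="exon"`) is available; span mode is the default because database
entries of one locus differ mostly in end trimming, not exon structure.
The merged record carries the fused exon union and, as representative
sequence, the longest member (ties to the lexicographically first id, so
reruns are stable).

The length filter is strict (`length > 200`), and transcripts without an
external coding verdict pass through — the coding call belongs to
upstream tools (CPC2 and the like), which this package deliberately does
not reimplement.

## Orthology and dating

Directed best hits keep, per (query gene, target species), the hit with
the smallest E-value at E ≤ 10⁻⁵; ties break by higher bitscore, then
lexicographic subject id — the tie order is not meaningful biologically
but makes the scan reproducible.  Within-species hits are ignored here
(paralogy is handled at integration).  Reciprocal best hits form pairs;
families are connected components of the pair graph.  Single linkage can
pull several genes of one species into a family; they are kept, since
they remain distinguishable by id.

A family's branch point is the MRCA of its species set — the smallest
clade containing every member species — computed by intersecting
leaf-to-root paths on the dated tree.  Node age is the maximum path
length to a descendant leaf; leaves are age 0 and ages are monotone
toward the root, which holds for any branch-length assignment.  Dated
exports of public timescale trees are near- but not exactly ultrametric,
so leaf-depth spread beyond a relative 10⁻⁶ warns instead of failing.

Conservation categories are configuration, not code: an ordered list of
strictly nested clades, each labelled; a focal lncRNA takes the label of
the smallest clade containing its family's branch point, or
"non_conserved" when it sits in no family.  The two deepest labels can be
pooled in reports (their counts are typically small).

## Expression

Upper-quartile normalisation divides each sample by the 75th percentile
of its nonzero values (linear interpolation between order statistics —
the convention is fixed and documented because different quantile rules
shift the factor) and rescales by the mean factor so overall magnitude is
preserved.  Normalisation happens per sample, before replicate
collapsing.  Components are then the median over biological replicates of
the mean over technical replicates, per tissue; even-count medians use
the mean of the middle two.

AEL is the arithmetic mean of the components and τ is Σ(1 − xᵢ)/(N − 1)
with xᵢ the components over their maximum.  N is the profile length, not
a hard-coded 9 — the 12-component worked example in the README relies on
that.  Both are undefined (NaN, gene logged and skipped) unless some
component reaches 0.5 FPKM; below that, rank noise dominates.

The variation filter keeps the top 75 % of genes by variance of
log₂(x + 1) across samples, ties inclusive ("top 75 %" is read as keeping
75 % of genes; `keep_fraction=0.25` gives the stricter above-75th-
percentile reading).  Tissue classes: τ ≥ 0.9 assigns the argmax tissue,
exact ties resolve to the fixed tissue order with a warning; below
threshold the gene is "broad".

## Network and GO tests

Edges are Spearman correlations (Pearson on mid-ranks); P-values come
from the Fisher transformation z = atanh(ρ) with statistic z·√(n − 3)
against a standard normal.  The Spearman-specific variance 1.06/(n − 3)
is available as an option; the plain normal approximation is the default.
Bonferroni correction is per gene: each raw P is multiplied by the number
of candidate pairs of that gene, capped at 1, and an edge survives only
when the adjusted P from **both** endpoints is ≤ 0.05 — the conservative
reading of a per-gene correction.  Edge lists are byte-stable across
reruns: iteration follows the row order of the input matrix.

GO annotation of a lncRNA is term-specific neighbour voting: for each
term on its immediate neighbours, P(X ≥ k) under a hypergeometric with
N = network genes, M = network genes carrying the term, n = neighbours,
k = neighbours carrying the term; terms with P < 0.05 are assigned.  A
literal "any annotation" variant (M and k counting genes with at least
one term) cannot assign specific terms and is not used for assignments.
Enrichment uses the same upper tail with N = annotated population genes,
M = genes with the term, n = annotated study genes, k = study genes with
the term, reported at raw P < 0.05 (a Benjamini–Hochberg option exists
but is off by default).  The upper tail is delegated to
`scipy.stats.hypergeom.sf`, which computes in log space; the test suite
cross-checks it against exhaustive enumeration of all feasible cases with
N ≤ 12 at 10⁻¹² tolerance.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions used throughout the
tests: 25 species on a random Yule tree rescaled to a 180 Myr root, 50
families planted uniformly over internal nodes, sequences of 201–2000 nt
evolved by per-branch substitution probability rate × branch length
(default rate 5 × 10⁻⁴ per Myr; probabilities above 0.75 are rejected as
saturated), 10 orphans per species, 2–4 database copies per locus with
coordinate jitter below 5 % of the locus length, nine tissues × 5
biological × 2 technical replicates (90 samples) over 500 genes, and GO
terms painted at probability 0.1 on a coding background of 20 terms.

Expression noise is log-normal: σ = 0.10 between biological replicates
and σ = 0.05 between technical replicates, around a 5-FPKM background.
The design point is a clean dichotomy between specific genes (one tissue
at 20 × background, 2 % leakage elsewhere) and constitutive genes: after
replicate collapsing, constitutive profiles stay below τ ≈ 0.21 and
specific profiles above 0.99, so the τ = 0.9 threshold separates them
with margin.  The σ = 0.10 default was chosen so that the collapsed
constitutive profiles respect the τ ≤ 0.3 design bound with room to
spare across seeds.

The sequence simulator makes substitutions only — no indels — so identity
and coverage are analytically predictable (pairwise mismatch probability
composes per branch as q' = q + p − 4qp/3).  The hit generator stands in
for an aligner: it emits tabular rows for true homolog pairs with
identity equal to the observed divergence and an E-value that is a fixed
monotone function of identity × length with an integer exponent (only the
ordering matters downstream), plus spurious single-direction low-identity
rows at a configurable rate.  An adapter that shells out to a real
BLASTN binary can replace it, but nothing in the tests requires one.

Because of these simplifications, passing tests demonstrate that the
*procedures* are correct — thresholds, tie-breaks, clustering, dating,
index arithmetic, test statistics — on inputs whose truth is known.  They
do not demonstrate robustness to real-data phenomena the generator omits:
indels and splice variation, GC/codon structure, shared repeat content
producing dense spurious homology, expression batch effects, or
incomplete and biased GO annotation.

## Numerical conventions

* Percentages are rounded half-up at the printed precision, via decimal
  arithmetic; every reported share keeps its numerator and denominator.
* Quantiles interpolate linearly between order statistics.
* All alignment and genomic coordinates are 0-based half-open internally;
  BLAST-tabular 1-based inclusive (with reversed minus-strand subject
  coordinates) exists only at the parse/serialise boundary, and the
  conversion is an exact involution.
* Optimal-cluster ties compare at 10⁻⁹ absolute tolerance; family ids,
  merged ids and edge lists use fixed sort orders so identical inputs
  give identical outputs.
* `run_all` is deterministic under a fixed seed; on rerun, stages whose
  `_done` marker exists keep their existing files (recomputation and
  reload agree by determinism).

## Problem sizes

The default end-to-end configuration (25 taxa, 50 families, 500 genes ×
90 samples) runs in about a second on one core; the test suite, including
the exhaustive hypergeometric cross-check and a 200-seed type-I-error
study of the annotation test, completes in a few seconds.  These sizes
were chosen as the smallest at which every planted structure is
informative (families spanning multiple clades, loci with several
database copies, hundreds of network genes) while keeping the suite fast
enough to run on every change.

## Known limitations

* Orthology is sequence-similarity RBH only; no synteny, no alignment-free
  homology, and no tree inference (the dated tree is an input).
* The 80 % merge rule compares spans by default; exon-mode is available
  but untested against real splice structure.
* GO terms are flat labels; the ontology DAG is not traversed, so parent
  terms do not inherit child annotations.
* The per-gene Bonferroni "both endpoints" rule is one of two defensible
  readings of a per-gene correction; the alternative (either endpoint)
  would keep strictly more edges.
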