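# lncevo

Tools for studying the evolutionary history of plant long non-coding RNAs
(lncRNAs).  Plant lncRNA catalogues are scattered across several public
databases with heavy overlap, and lncRNA sequences diverge quickly, so two
questions dominate any cross-species analysis: *which entries are the same
transcript*, and *which transcripts in different species are orthologues,
and how old is their common ancestor?*  `lncevo` implements a complete,
tested pipeline for this style of analysis:

1. **Integration** — per-species transcript sets (length > 200 nt,
   non-coding by an external verdict such as CPC2) are placed on their
   genome from BLAST-style hit tables.  Hit fragments within 4 kb on one
   chromosome/strand are clustered; each cluster is scored by *effective
   coverage* (union of query intervals over query length) and *weighted
   identity* (alignment-length-weighted mean identity); clusters exceeding
   70 % coverage and 80 % identity compete, and the winner (highest
   weighted identity, then highest coverage) becomes the placement.
   Placements overlapping by more than 80 % of the shorter span are merged
   (single linkage) into one non-redundant locus carrying the exon union.
2. **Orthology** — reciprocal best hits (E ≤ 10⁻⁵) between species define
   orthologous pairs; connected components under single-linkage
   clustering define families.  Each family is dated by the age (Myr) of
   the most recent common ancestor of its species set on a dated species
   tree, and focal-species lncRNAs are labelled by the smallest configured
   clade containing that branch point (e.g. genus-, family-,
   class-conserved, or non-conserved).
3. **Expression** — FPKM matrices are upper-quartile normalised, collapsed
   to one component per tissue (mean of technical replicates, median of
   biological replicates), and summarised by the average expression level

   AEL = (1/N) Σᵢ AELᵢ

   and the tissue-specificity index

   τ = Σᵢ (1 − xᵢ) / (N − 1),  xᵢ = AELᵢ / maxⱼ AELⱼ,

   both defined only when some component reaches 0.5.  τ = 0 means uniform
   expression, τ = 1 single-tissue expression; τ ≥ 0.9 marks a gene as
   tissue-specific.
4. **Network & function** — co-expression edges are Spearman correlations
   with Fisher-transform P-values, Bonferroni-corrected per gene (both
   endpoints must pass 0.05).  LncRNAs are annotated by neighbour voting:
   an upper-tail hypergeometric test per GO BP term over the immediate
   coding neighbours; the same test does study-vs-population term
   enrichment.
5. **Synthetic data** — a generator plants orthologous families on a dated
   tree, database redundancy with coordinate jitter, tissue-specific and
   constitutive expression, and enriched GO neighbourhoods, all with
   machine-readable truth, so the whole pipeline is testable offline.

## Worked example

The τ index for a 12-component profile with one dominant tissue:

```python
>>> from lncevo.expression import compute_tau
>>> compute_tau([0, 8, 0, 0, 0, 2, 0, 2, 0, 0, 0, 0])
0.9545454545454546
```

The maximal component is 8, so the normalised profile has one 1, two 0.25
values and nine zeros; Σ(1 − xᵢ) = 10.5 over N − 1 = 11 gives τ ≈ 0.95 — a
strongly tissue-specific gene.

A full synthetic run (25 species spanning 180 Myr, 50 planted families,
500 genes × 90 samples) takes about a second:

```python
>>> from lncevo.simulate import SimulationConfig
>>> from lncevo.pipeline import run_all
>>> art = run_all(SimulationConfig(seed=1), "out")
>>> print(art["age_summary"].to_string(index=False))
 age_gt_myr  n_families  family_share_pct  n_lncRNAs  lncRNA_share_pct
       50.0          17              34.0        154             55.80
      100.0           4               8.0         55             19.93
      150.0           1               2.0         25              9.06
      180.0           0               0.0          0              0.00
```

Here 17 of the 50 recovered families (34.0 %) predate 50 Myr, holding
154 of the 276 in-family lncRNAs (55.80 %); no family is older than the
180 Myr root.  The same run writes per-stage TSVs (catalogue, families,
expression profiles, network edges, GO annotations, summary tables) under
`out/`, and every planted family, duplicate group and tissue label is
recovered (`art["truth"]` carries the ground truth for comparison).

The same stages are available from the shell:

```bash
lncevo run --seed 1 --out out/
lncevo simulate --seed 1 --out sim/
lncevo families --hits sim/cross_species_hits.tsv \
    --tree sim/species_tree.nwk --manifest sim/manifest.tsv --out fam/
```

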