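# dysbiotrack

Longitudinal gut-microbiome dysbiosis analysis for three-group,
five-timepoint 16S study designs (naive / adjuvant-only / disease-induced
mice sampled at −2, 8, 14, 19 and 29 days post-immunization), built for the
kind of question an EAE (experimental autoimmune encephalomyelitis)
microbiome study asks: *which taxa change, when, in which direction, and how
does the community's interaction structure and imputed functional content
reorganize as disease progresses?*

The package provides three analysis arms over a shared core, plus a
synthetic-data generator with planted ground truth so every stage is
testable without sequencing data:

1. **Rank-wise differential abundance with ternary pattern mining.**
   Per-feature negative-binomial Wald tests (variance `μ + αμ²`, log link,
   median-of-ratios size factors as offsets, Cox–Reid-adjusted dispersion
   estimation with a robust `α(μ) = a₀ + a₁/μ` trend) under two pairwise
   frameworks: every treatment pair at each day (15 comparisons) and every
   post-immunization day against baseline within each group (12), at every
   taxonomic rank. Each feature's trajectory is encoded as a ternary
   pattern — digit 1 if `p_adj < 0.05` and `log₂FC > 0`, −1 if
   `p_adj < 0.05` and `log₂FC < 0`, else 0 — and one-sided Fisher tests ask
   which patterns are over-represented among the ASVs of each taxon, with
   Benjamini–Hochberg correction against the full `taxa × observed
   patterns` grid.
2. **Ensemble co-occurrence / mutual-exclusion networks.** Per treatment
   group, five association metrics (Spearman, Pearson, mutual information,
   Bray–Curtis, symmetrized Kullback–Leibler) on column-normalized
   abundances; candidate edges from top/bottom edge-number thresholding; a
   permutation-renormalization-bootstrap significance test
   (`z = (m_boot − m_null)/√(v_boot + v_null)`, BH per metric); an edge is
   kept when ≥ 2 metrics agree in direction. Louvain communities with
   Wilcoxon significance, node- and edge-type taxonomic enrichment per
   community, Jaccard matching of communities across networks, and
   community-PCA trait correlation.
3. **Signed correlation modules on functional features.** WGCNA-style
   signed adjacency `((1+cor)/2)^β`, topological overlap, UPGMA clustering
   with a static cut, minimum module size 30 and eigenfeature merging at
   r > 0.7; module eigenfeatures (unit-norm PC1) are correlated against
   clinical score, body weight and day.

## Worked example

```python
import dysbiotrack as dt
from dysbiotrack.diffabund import run_frameworks, framework_patterns

counts, taxonomy, metadata, truth = dt.default_eae_scenario(seed=1)
results = run_frameworks(counts, metadata, taxonomy, rank="family")
patterns = framework_patterns(results)["EAE/naive"]
dep = truth["scenario"]["depleted_family"]
print(patterns[dep])
```

The default scenario plants a dominant family (~35% of the community, 40%
of whose strains do not respond) depleted −4 log₂ from 14 dpi, a
near-absent family expanding +10 log₂ from 8 dpi, and a strain-concentrated
bloom that comes to dominate the diseased community. On seed 1 the family
rank comparison `EAE vs naive @ 14 dpi` gives

```
f01 EAE vs naive @14 dpi: l2fc=-1.461  p_adj=5.82e-119
f01 EAE/naive ternary pattern: 0,0,-1,-1,-1
```

— the depleted family's *observed* fold change (−1.46) is much smaller than
the planted per-strain effect (−4) because its non-responding strains hold
their share while the rest of the community is renormalized; the ternary
pattern still reads "no change, no change, down, down, down". The ASV-level
pattern enrichment then separates the strain classes:

```
taxon      pattern  a  b  c   d        p_adj
  f04    0,1,1,1,1 36  0 21 231 4.69e-29   # expansion family
  f01 0,0,-1,-1,-1 12 24  0 252 2.42e-10   # strains collapsing at onset
  f01  0,0,0,-1,-1  9 27  0 252 1.97e-07   # strains collapsing at peak
```

so one family is simultaneously enriched for several distinct trajectory
patterns — the heterogeneous strain response the ternary ORA is designed to
expose.

The same analyses run from the shell:

```bash
dysbiotrack simulate --seed 1 --outdir data/
dysbiotrack diffabund --counts data/counts.tsv --taxonomy data/taxonomy.tsv \
    --metadata data/metadata.tsv --rank family --outdir out/
dysbiotrack run-all --seed 1 --outdir out/      # the whole pipeline
```

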