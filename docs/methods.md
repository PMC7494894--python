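# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions that were genuinely open.

## Count model and differential abundance

Counts are modelled as negative binomial with variance `μ + αμ²`. Sample
depth is normalized by median-of-ratios size factors: per-feature geometric
means over samples, per-sample factor = median count/geomean ratio, rescaled
to geometric mean 1. For sparse tables with no all-positive feature, a
positive-counts variant (geometric means over nonzero entries) is used.
Size factors are estimated once on the finest available table (ASVs) and
reused after taxonomic agglomeration: agglomeration conserves per-sample
totals, and a median over hundreds of ASVs is far more stable than a median
over a handful of agglomerated taxa. When most of a community genuinely
shifts, the median-of-ratios reference itself moves; every reported fold
change is therefore relative to the community's median taxon. This is an
inherent property of the normalization, not an implementation artifact, and
the synthetic generator is designed with it in mind (below).

**Dispersion.** Per-feature `α` is a Cox–Reid-adjusted profile maximum
likelihood estimate with means profiled *within design cells*
(treatment × day): with real group×time effects present, profiling against
a single global mean folds the effects into dispersion and destroys power.
The optimizer is a 43-point grid on `log α ∈ [log 1e-8, log 20]` followed
by a 25-iteration vectorized golden-section refinement; estimates are
floored at 1e-8. A robust (Huber) regression of `α` on `1/μ` over features
with normalized mean > 1 gives the trend `α(μ) = a₀ + a₁/μ`; per-feature
estimates are shrunk toward the trend as the log-space midpoint by default
(weight 0.5, configurable; 0 disables shrinkage).

**Wald test.** Each pairwise comparison is fit on its two sample cells
only (a two-level design with log size-factor offsets), rather than by
contrast extraction from a global fit — the global model is exposed
conceptually but the pairwise subset is the reproducible reading, and the
dispersions remain shared across comparisons. The two cell log-means are
profiled by Newton iteration with a weak Gaussian ridge
(sd 4 on the natural-log scale, ≈ 5.8 log₂): the ridge is negligible for
observed features but lets features seen in only one cell converge to
large, finite fold changes with honest (wide) standard errors, so an
all-absent-versus-abundant taxon is still detected. The statistic is
`z = (β_a − β_b)/√(1/I_a + 1/I_b)` with `I` the observed information; the
p-value is two-sided normal, BH-corrected within the comparison's feature
set. Features with zero counts in both cells, or non-converged fits, are
reported as NA and excluded from the BH denominator. Null calibration on
simulated data (2000 features, n = 10/group) gives a type-I rate of ~0.06
at α = 0.05 and a KS distance of the z statistic from N(0,1) of ~0.03.

**Ternary encoding.** Digit 1 for `p_adj < 0.05` and `l2fc > 0`, −1 for
`p_adj < 0.05` and `l2fc < 0`, else 0; the boundary `p_adj = 0.05` encodes
0, and NA results encode 0. Cross-treatment patterns have five digits,
within-treatment patterns four.

## Ternary over-representation

For one framework each ASV carries exactly one pattern. Every
(taxon, observed pattern) pair is tested with a one-sided (enrichment)
Fisher exact test on the 2×2 table splitting the ASV universe by taxon and
pattern membership. The BH denominator is `#taxa at the rank × #observed
patterns` — the full scan grid, larger than the number of realized
p-values; the custom-denominator step-up is implemented directly since
standard libraries fix the denominator at the vector length. Unobserved
patterns are never tested; NA-designated taxa are ordinary taxa. Taxa are
keyed on their full lineage prefix, so two families that happen to share a
genus label never merge.

## Ensemble networks

Per treatment group, all time points pooled. Features present in fewer
than 3 samples are dropped. Scores are computed on column-normalized
(relative) abundances: Spearman, Pearson, mutual information
(equal-frequency binning with ⌊√n⌋ bins), Bray–Curtis, and symmetrized
KL on pseudocount-smoothed renormalized profiles. Candidates are the
union over metrics of the strongest co-occurrence and strongest exclusion
pairs (dissimilarities inverted; ties broken lexicographically; budgets
clip to the number of pairs).

For every candidate pair and metric, a bootstrap distribution (resample
samples with replacement, re-derive the column-normalized scores) is
compared with a null distribution built by permuting each feature's counts
across samples independently and then re-normalizing columns — the
renormalization keeps the null compositionally honest, which is the entire
point of the permutation-renormalization-bootstrap construction. The test
statistic is

    z = (mean_boot − mean_null) / sqrt(var_boot + var_null),

i.e. a Z-test on the two distributions with their variances summed. The
variances are *not* divided by the iteration count: dividing them would
test the Monte-Carlo error of the means (z inflating without bound as
iterations grow) rather than the separation of the distributions, and
calibration on independent data would fail by an order of magnitude. With
the distribution-variance form the retained-edge rate on fully independent
features is ≈ 0 and planted blocks (loading 0.9, n = 45) are recovered
essentially completely. Two-sided normal p-values are BH-corrected across
candidate pairs within each metric; an edge is retained when at least two
metrics are significant *and agree in direction*. Mutual information is
unsigned: it takes its direction from Spearman and only counts toward the
two-metric quorum when a signed metric is also significant. A retained
edge's sign is the agreeing direction (correlation sign; for
dissimilarities, bootstrap mean below/above the null mean).

Louvain communities (igraph multilevel, resolution 1, unweighted, seeded)
are computed per signed subgraph. Community significance is a one-sided
Wilcoxon rank-sum comparing, over member nodes, within-community degree
against out-of-community degree — the comparison sets are this package's
concretization, as only the test itself is standard. Node and edge-type
enrichment use the same one-sided Fisher machinery with the BH denominator
`#taxa (or #edge types) × #eligible communities`; a community is eligible
at ≥ 3 nodes (configurable — smaller communities cannot carry meaningful
enrichment). Edge types are enumerated from edges present in the network;
self-pairs (`A|A`) are valid types. Cross-network community matching is
the plain Jaccard index on ASV sets.

## Module detection

Signed adjacency `a = ((1 + cor)/2)^β` (default β = 6 for synthetic-scale
data; the dataset-tuned powers 17 and 27 used for real imputed pathway and
enzyme tables are available as presets via the `beta` argument), TOM

    TOM_ij = (Σ_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

UPGMA on `1 − TOM`, static branch cut, minimum module size 30, and
iterative merging of modules whose eigenfeatures correlate above 0.7.
The static cut replaces adaptive branch pruning deliberately: it is
deterministic and directly testable, and the scientific surface is module
recovery, not cut-method identity. The default cut height is 0.85: at
β = 6 the TOM dissimilarity between unrelated or independently-driven
features concentrates in 0.93–1.0 (shared-neighbor mass keeps it below 1),
while within-module dissimilarity for a well-formed 40-feature module sits
near 0.7 — a 0.99 cut would merge everything. Eigenfeatures are unit-norm
first principal components of the standardized member profiles, sign-fixed
so the mean member correlation is non-negative, and are correlated
(Pearson, two-sided t) against clinical score, body weight and day — the
three phenotype covariates the design carries.

## Synthetic-data generator

Counts are compositional: per-ASV latent weights are multiplied by planted
group×time effects, renormalized per sample, then NB-sampled at library
sizes 30–50k (one global dispersion, default 0.1). Planted effects act on
member ASVs of a target taxon from an onset day onward; a configurable
fraction of member ASVs are non-responders. Non-responders are "anchored":
their *observed relative abundance* is held at baseline by solving the
renormalization fixed point `T = S/(1 − A)` (free effect-adjusted mass `S`,
anchored baseline mass `A`) — a flat trajectory is what non-response looks
like in 16S data, whereas a latent-static ASV would inherit the full
compositional boost. Correlation blocks add a per-sample latent Gaussian
factor (loading 0.9) to member log-weights. Clinical score follows a ramp
from onset (0 / 0.2 / 2.0 / 3.5 / 3.0 at −2/8/14/19/29 dpi, scaled by the
trait-coupling parameter) with truncation at zero; weight grows slowly and
dips after onset in the diseased group only.

The default scenario (8 families × 36 ASVs) encodes the study's reported
ecology: a dominant family (~35% baseline share) depleted −4 log₂ with its
12 high-abundance strains collapsing at onset (14 dpi), 10 mid-abundance
strains at peak (19 dpi) and the smallest 14 (40%) not responding; a
weaker −1.5 depletion of the same strains under adjuvant alone; a
near-absent family expanding +10 log₂ from 8 dpi; a second family whose
four dominant strains absorb exactly the latent mass the depleted strains
lose, producing a low-evenness bloom that drives the alpha-diversity
decline; and five background families with three response classes each
(a modest expanding minority, a depleted class solved to balance each
family's share of the community's mass gains, and an equally large
unresponsive class). Two properties of this layout are deliberate. First,
every design cell's total latent mass stays at baseline and every family
keeps a dense unresponsive class, so the median-of-ratios reference is
pinned and truly unresponsive taxa are also *observationally* stable —
without this, the normalization reference itself drifts and fold changes
conflate taxon behavior with reference movement. Second, the planted
signatures occupy distinct (onset, sign) classes, so pattern enrichment can
attribute them to the right strains. What the generator does **not**
emulate: phylogenetic signal, sequence-level error, per-mouse repeated-
measures correlation (samples are independent draws within a cell),
per-feature dispersion heterogeneity (one global α by default), and
zero-inflation beyond what NB sampling at low means produces. Passing
tests therefore demonstrate correct statistical machinery and recovery
under the stated compositional NB world, not robustness to host effects or
technical artifacts of real 16S data.

Synthetic functional tables (for module detection) are two latent factors
— one coupled +0.5 to clinical score, one +0.5 to weight (hence negatively
to score) — each loaded 0.8 by 40 features, plus optional pure-noise
features, on a Gaussian post-normalization scale.

## Numerical choices and degenerate inputs

- BH ties break by stable sort on input position; adjusted values clip to 1.
- Fisher on the empty table (all margins 0) returns 1.
- The VST is the closed form
  `log2((b + 2a₀q + 2√(a₀q(b + a₀q)))/(4a₀))`, `b = 1 + a₁`, the
  antiderivative of `1/√(v(q))` scaled to match log₂ at large counts;
  it is validated against numerical quadrature to 1e-6.
- PCA centers features, never scales to unit variance, and fixes each
  component's sign so its largest-magnitude loading is positive; a
  constant matrix yields zero scores and zero explained fractions.
- All-zero samples are hard errors naming the sample; all-zero features
  are dropped from comparisons before BH.
- ReBoot refuses `n_iter < 20`; correlation scores for constant profiles
  are NA and that pair is skipped for that metric.
- Every source of randomness flows from explicit seeds; the CLI derives
  per-stage substreams from the global seed by hashing the stage name, so
  stages are individually reproducible.

## Problem sizes

The bundled tests and the acceptance script run at the study's design
scale (3 groups × 5 days × 10 mice, 288 ASVs) for the scenario analyses,
2000 features for null calibration, 30 features × 45 samples for network
inference (edge budgets clipped to the instance), and 80 features × 75
samples × 100 replicates for module detection — sizes chosen so the whole
suite re-derives every claim in a few minutes on one core.

## Known limitations

- The Wald test's ridge makes extreme fold changes finite but their exact
  magnitude prior-dependent; significance calls are unaffected.
- The ensemble-network false-edge rate is conservative (near zero) rather
  than tight at its nominal level; the two-metric direction-agreement vote
  compounds the per-metric BH control.
- Community significance and eligibility are package concretizations of
  ideas that are standard only in outline; both are configurable.
- Agglomeration at a rank keys on the full lineage prefix, which is the
  safe reading but can split taxa that a curated taxonomy would merge.
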