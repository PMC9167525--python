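# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Generative model of the synthetic data

Counts are negative-binomial with a log-linear mean:

    log mu_gj = log s_j + b_g + lambda_g * e_{m(g),j}
                + delta_g^acc * 1[acc_j = 28] + delta_g^pop(pop_j)

- `s_j` — library-size factor, log-normal (default meanlog 0, sdlog 0.25).
- `b_g` — baseline natural-log mean, uniform on [3, 7] (counts ~20-1100, so
  most genes clear the "30 counts in 10% of individuals" filter, as in the
  emulated study).
- `e_{m,j}` — i.i.d. standard-normal latent factor per planted module;
  member genes load with `lambda_g` uniform on [0.8, 1.2]; background genes
  have no factor term.
- `phi_g` — NB dispersion, variance `mu + phi mu^2`. The study never
  parameterizes its counts; the default range [0.1, 0.5] spans dispersions
  typical of bulk RNA-seq in outbred animals and is exposed in the config.
- Differential-expression effects: a 4% fraction of genes get an
  acclimation effect and 2% per-population offsets (|log2FC| in [0.5, 2]),
  with N.Ref the baseline population so the adaptive pattern (TE differs
  from both references) can be planted by equal reference offsets.

Traits are linear in the factors: `t_kj = alpha_k + gamma_k mass_j +
sum_m w_km e_mj + eps`, so the planted module-trait correlation is
`w / sqrt(sum(w^2) + sigma^2)`; the default couplings (|w| = 0.66,
sigma = 1) plant correlations of ~0.55, the magnitude the emulated study
reports. Default sample layout is the study's heart arm (41 individuals,
3 populations x 2 acclimation temperatures).

Randomness is split into named substreams (structure, counts, traits,
outliers), so injecting outliers never perturbs counts. Identical configs
produce byte-identical datasets.

What the generator does **not** emulate: gene-length and GC biases,
count-mean-dependent dispersion trends, correlated (non-factor) residual
structure, batch or sex effects, and missing trait values. Tests passing on
this generator therefore demonstrate correctness of the algorithms under
the stated model, not performance on any particular real dataset.

## Preprocessing

Size factors are the median-of-ratios estimator computed from scratch:
genes positive in every sample contribute `count_gj / geomean_g`; the
factor is the per-sample median. Note the exact scale-equivariance property
holds for factor *ratios* (the geometric means absorb a common power of any
single-column scaling). The CV comparison between groups is a paired t-test
across shared genes by default (the same mRNA set is measured in both
acclimation groups); Welch's test is available by flag since the study does
not say which it used. The PCA screen uses log2(normalized + 1), genes
centered but not scaled, and makes the study's visual outlier removal
algorithmic: a sample is flagged when a 2-means partition of PC1 disagrees
with its tissue label.

## Differential expression

The engine is a deliberately transparent NB GLM, not a reimplementation of
shrinkage-based tools: per-gene method-of-moments dispersion after a
Poisson fit, `phi = max(1e-8, sum(((y-mu)^2 - mu)/mu^2) / (n - rank))`,
then IRLS via a NB-family GLM with log link and offset `log s_j`
(tolerance 1e-8, 100 iterations). There is no dispersion shrinkage, no
Cook's-distance outlier handling and no independent filtering, so DEG
counts on real data will not match shrinkage-based tools gene for gene.

Wald contrasts on the coefficient scale use a t reference with `n - rank`
degrees of freedom in the gene-level pipeline: with a per-gene estimated
dispersion plugged into the covariance, the standard-normal reference is
measurably anticonservative at n ~ 40 (type-I ~0.06 at nominal 0.05); the
t reference restores calibration (~0.05, measured by simulation in the
acceptance suite). BH-FDR is applied jointly across all contrasts within
one model, matching the study's "across all comparisons made within a
model". The interaction justifying the within-temperature split is
assessed per gene by a likelihood-ratio test of the full vs additive
model (df 2) — the study does not state its interaction test, and the LRT
is the standard choice.

## Network construction and module detection

Adjacency is unsigned by default (`|cor|^beta`); the study names "signed
Pearson correlation" only for the eigengene-trait step, and unsigned is
the common default for the network itself; signed is available. Expression
enters as log2(normalized + 1). TOM follows the standard formula with the
`min(k_i, k_j) + 1 - a_ij` denominator.

The dendrogram (average linkage on `1 - TOM`) is cut at a static height of
0.99 on the 1-TOM scale. A plain cut is not enough: unstructured background
genes merge just below any high cut and chain onto real modules. Each
branch is therefore pruned to its *tight core*: a member is kept only when
its median dissimilarity to the other members sits at least `min_gap`
(default 0.05) below the cut. This strips chance-correlated background
genes from module branches and dissolves pure-background branches (whose
pairwise dissimilarities all hug 1). Cores smaller than
`min_module_size = 30` are unassigned (label 0). On planted 3-module
designs (600 genes, 60 samples) this recovers labels at adjusted Rand
index ~0.95.

Eigengenes are the first right singular vector of the standardized member
matrix, scaled to unit variance and oriented so the mean member correlation
is positive. Modules merge greedily while any eigengene pair correlates
above 0.75 (highest pair first, ties to the smallest label pair; the
procedure is idempotent). A homogeneous gene set that the cut splits into
correlated halves is reunited by this merge step, which is why "module
count" is defined post-merge. Hub = member gene with max |MM|, ties broken
by smallest gene id.

## Trait association

Traits are residualized on a mass covariate before correlation: body mass
for whole-animal traits, heart mass for cardiac metabolic rates (the
blanket body-mass correction is available as a preset). Correlations are
computed within acclimation-temperature strata in the pipeline, since the
traits are temperature-specific. BH is applied across modules within each
trait.

The jack-knife screen draws `floor(0.9 n)` samples without replacement,
100 times; a replicate supports the association when its raw p < 0.05 and
its sign matches the full-sample sign; passing requires support >= 70
(the inclusive bound; the study's two statements of the threshold differ
and the inclusive reading is used, configurable). Raw p rather than
within-replicate FDR is used inside replicates — FDR over a handful of
tiny subsamples is unstable, and the screen's job is stability, not
family-wise control.

Operating characteristics, measured by simulation: under independence the
false-pass rate is ~2-4% (n = 40); with a true |r| = 0.7 at n = 20 the
pass rate exceeds 80%. Against outliers the screen is sharp exactly where
it matters: a single high-leverage sample that drags an otherwise null
correlation to marginal significance (the minimal fabrication) is rejected
in ~99% of constructed datasets. A caveat follows from the design: because
each 90% subsample retains the outlier ~90% of the time, a *dominant*
leverage point that pushes p far below 0.05 can evade the screen; such
cases are better caught by the PCA sample screen upstream.

Multiple correlation for a trait with several passing modules is the
correlation of OLS fitted values with the trait (= sqrt of the regression
R^2, hence never below the largest single |r|).

## Enrichment

Upper-tail hypergeometric `P(X >= k)` against the tissue-expressed
universe; term sets are intersected with the universe before computing the
term size, while unannotated genes remain in the universe. BH across the
terms tested per module, per ontology. Pathway roll-up counts enriched
terms per pathway; ties are flagged and broken alphabetically — the
underlying "most informative pathway" choice is editorial, so the tie is
surfaced rather than silently resolved.

## Problem sizes used in validation

The validation suite uses problem sizes chosen to exercise every code path
at comfortable desk scale: 600-gene / 60-sample designs for module and
trait-coupling recovery, 2000 null genes at n = 20 per group for Wald
calibration, 200 independent datasets for the jack-knife null, and 100
constructed datasets for the outlier screen. Scaling the generator to the
full ~10,000-gene study layout changes runtimes, not conclusions, and the
defaults of `SimulationConfig` are exactly that full layout.
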