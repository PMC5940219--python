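# Methods

## The model

rDriver asks, for every recurrent somatic mutation in a tumor cohort,
whether carrying that mutation systematically shifts genome-wide mRNA
expression. For gene *j* with (preprocessed) expression vector
*y<sub>j</sub>* across *N* samples and binary mutation indicators
*x<sub>k</sub>* for alleles *k = 1..M*,

  *y<sub>j</sub>* = Σ<sub>k</sub> β<sub>jk</sub> *x<sub>k</sub>* + ε<sub>j</sub>,

fit without intercept on centered *y* and column-standardized *X*, with
Gaussian noise ε. Since M typically exceeds N, each gene is a sparse
high-dimensional regression, solved as a weighted lasso:

  min<sub>β</sub> (1/2N)‖y<sub>j</sub> − Xβ<sub>j</sub>‖² +
  λ<sub>1j</sub> Σ<sub>k</sub> δ<sub>k</sub>|β<sub>jk</sub>| +
  λ<sub>2j</sub> Σ<sub>i</sub> w<sub>i</sub>²

The per-allele penalty scale δ<sub>k</sub> injects the functional-impact
prior: with standardized, impact-oriented scores f<sub>ki</sub> (GERP-like
conservation as-is; SIFT flipped as 1 − SIFT because low raw SIFT means
damaging) and non-negative feature weights w,

  δ<sub>k</sub> = sigmoid(−Σ<sub>i</sub> w<sub>i</sub> f<sub>ki</sub>),
  clipped to [δ_min, 1).

High predicted impact ⇒ small δ ⇒ cheaper to select. This is the
default `oriented` mode. A `literal` mode computes
sigmoid(+Σ w<sub>i</sub>f<sub>ki</sub>) — the formula exactly as it is
usually printed — which penalizes high-impact alleles *more*; the printed
sign contradicts the stated intent of favoring damaging alleles, so both
modes are exposed and `oriented` is the default. With w = 0 both give
δ = 1/2 (the uniform-prior initialization).

A mutation's **driver score** is the number of genes with a nonzero fitted
coefficient in its row of the association matrix B = (β<sub>jk</sub>).
Empirical p-values come from a permutation null (below); calls use
unadjusted p < 0.05 by default (BH-adjusted q-values are always reported
alongside).

## Fitting

Alternating block minimization, starting from w = 0 (δ = 1/2):

1. **λ selection.** Per gene, (λ₁, λ₂) by k-fold CV (default k = 10,
   minimum-MSE rule, no one-standard-error rule). The λ₁ grid is 20
   log-spaced points from λ_max = max<sub>k</sub>|x<sub>k</sub>ᵀy|/(Nδ<sub>k</sub>)
   down to 0.01·λ_max. Held-out error is invariant to λ₂ (it penalizes
   only w), so λ₂ ties across its grid {0.01, 0.1, 1}; ties are broken to
   the strongest regularization, the usual CV convention. This matters: a
   weak ridge lets the weight update drive ‖w‖ up until δ saturates at its
   floor for every allele with chance-high impact scores, and
   near-penalty-free passengers then absorb noise genes — the prior-free
   ablation outperforms the prior, which is exactly backwards.
2. **β fit.** Per-gene weighted lasso by cyclic coordinate descent on the
   Gram system (vectorized across genes, warm-started), run until the KKT
   violation is below 10⁻⁶.
3. **w update.** Projected gradient with backtracking on
   Σ<sub>j</sub>λ<sub>1j</sub>Σ<sub>k</sub>δ<sub>k</sub>(w)|β<sub>jk</sub>| +
   (Σ<sub>j</sub>λ<sub>2j</sub>)‖w‖² over w ≥ 0, followed by a β refit at
   the same λ. Only strictly decreasing steps are accepted, so the
   objective is non-increasing across the alternating steps at fixed λ
   (the λ re-selection between outer iterations may move it either way).

The outer loop stops when the relative objective change drops below 10⁻⁴
(cap: 20 iterations). CV folds are drawn once per fit from the run seed,
so λ selection is a deterministic function of δ and the alternation can
actually converge. All randomness (CV folds, permutations, simulation,
consensus resampling) flows from one user seed through named substreams.

Degenerate inputs — constant genes, never/always-mutated alleles — are
dropped with a logged warning; their rows/columns of B are zero and
constant genes report R² as missing.

Implementation notes. Eq-level ambiguities resolved as follows: δ is
indexed per allele (the impact scores are allele-level, not pair-level);
the ridge acts on one global weight per feature; the residual term uses
1/(2N) so λ grids are comparable across cohort sizes (a pure
reparameterization of λ). δ_min = 0.05 keeps any single allele from
becoming penalty-free. Per-gene fits share nothing but X, so the model is
embarrassingly parallel; the implementation is single-threaded and
deterministic given the seed.

## Permutation null and p-values

Each replicate jointly permutes the sample order of the whole expression
matrix — breaking every mutation–expression link while preserving
gene–gene correlation — and re-runs the model "with identical
parameters". Three readings of that phrase are implemented:

* `cv` (default): the learned prior (w, δ) is frozen; λ is re-determined
  on the permuted matrix by the same CV procedure used for the observed
  fit. Under the no-association null the observed and permuted scores are
  then draws of the same procedure, which is what calibrates the
  p-values.
* `fixed`: λ and δ both reused verbatim. Fast but conservative and not
  exchangeable with the observed fit: CV anchors each gene's λ at the
  observed data's own maximal correlation, so a permuted replicate (a
  fresh draw) exceeds that boundary for about half the genes and null
  scores run systematically above observed ones.
* `refit`: the entire alternation re-run per permutation (slowest).

Scores are pooled across alleles and permutations by default (a
per-allele mode exists); p-values are add-one smoothed upper-tail ranks,
p = (#{null ≥ s} + 1)/(N_null + 1), never exactly zero and non-increasing
in the score. Default 100 permutations.

## Preprocessing

Expression: log2(RPKM + 1), then quantile normalization across samples
(every sample mapped onto the mean order-statistic profile), then optional
restriction to a gene panel — subsetting after normalization so the
normalized scale reflects the full measured transcriptome. Ties within a
sample receive the mean of the reference quantiles they span; note this
tie dialect makes the transform idempotent only on tie-free data (tied
entries keep averaged quantiles, so tied rows do not carry the exact
reference profile). Mutations: one binary column per (gene, protein
change) allele, duplicates collapsed, alleles below the recurrence
threshold (default 2 carriers) dropped. Impact scores: per-feature mean
imputation of missing entries (e.g. SIFT for indels), orientation, then
standardization to zero mean and unit population variance. Samples are
aligned to the lexicographically sorted id intersection.

## Downstream analyses

* **DEG**: per-gene two-sided Mann–Whitney between carriers and
  non-carriers; exact enumeration when both groups have ≤ 8 tie-free
  values, tie-corrected normal approximation otherwise; all-tied data
  give p = 1; BH across genes, significance at FDR < 0.05.
* **Gene-set enrichment**: upper-tail hypergeometric over-representation
  against an explicit background (sets intersected with the background
  first), BH across sets.
* **Frequency baseline**: driver ⇔ cohort count ≥ cutoff, at allele level
  or summed per gene.
* **Evaluation**: ROC AUC by the rank (Mann–Whitney U) formula with tie
  handling; PPV/NPV/sensitivity/specificity with undefined ratios
  reported as missing; Fisher (2×2, exact two-sided) and Pearson χ²
  (no continuity correction) composition tests; rank-sum CCF comparisons.
* **Prognosis**: per patient the integrative prognostic score
  IPS = xᵀB y (bilinear in the mutation and expression vectors given B).
  The 1-D IPS values are consensus-clustered: exact dynamic-programming
  1-D k-means (globally optimal, no Lloyd-initialization nondeterminism)
  on 50 seeded 80% subsamples per candidate k ∈ 2..6; consensus distance
  1 − co-clustering frequency; average-linkage dendrogram; k chosen by
  maximal cophenetic correlation (ties to smaller k). Strata are compared
  with the unweighted k-group log-rank test (lifelines), with
  Kaplan–Meier medians and curves reported; data with no events return
  statistic 0, p = 1.

## The synthetic-data generator

Cohorts with known ground truth, emulating all five inputs. Defaults —
the package's standard study conditions — are 200 samples, 200 genes, 50
recurrent alleles of which 5 are drivers, each regulating 30 genes with
effects of magnitude 1 (random sign, since real drivers both raise and
lower expression) against unit Gaussian noise; allele frequencies uniform
on (0.03, 0.2) for drivers and passengers alike, so frequency carries no
driver signal and the frequency baseline is a fair null comparator;
mutation columns are redrawn until every allele has ≥ 2 carriers, so the
recurrence filter holds by construction. Effects act on standardized
indicators, so effect size is in expression-SD units. Two impact
features: a conservation-like score used as-is and a SIFT-like tolerance
score in (0,1) (low = damaging, missing for indels); drivers receive a +1
SD latent shift (the "informativeness"). Survival is exponential with
log-hazard 0.5 per SD of the true IPS, with independent exponential
censoring tuned to ~30% censored.

What the generator does *not* emulate: library-size or GC artifacts,
batch effects, copy-number confounding, gene–gene co-expression modules,
clonality/CCF structure, mutation-subtype effects, linked alleles within
a gene. Passing tests therefore demonstrate correctness of the machinery
and calibration under the model's own assumptions, not robustness to
everything real tumor data does.

## Study sizes and known limitations

Multi-seed studies (calibration, recovery) run at the standard synthetic
conditions with a reduced CV grid — 10 λ₁ values, 5 folds — chosen so a
10-seed study finishes in minutes on one core; conclusions are unchanged
versus the full grid. Known limitations:

* The min-MSE CV rule (no 1-SE rule) occasionally keeps a dense fit on
  pure noise: a fixed noise vector's chance correlations persist across
  folds. sklearn's LassoCV makes the same choice on the same draws; at
  the standard study scale the null support fraction stays below 5%, but
  at very small M·N it can be several-fold higher.
* Pooled nulls give resolution at small permutation counts but compare
  alleles against a common score distribution; with a strongly adaptive
  prior, per-allele nulls (provided) are the cleaner choice.
* In-sample variance explained is reported (held-out R² would be
  smaller); on the standard planted cohorts the mean is ≈ 33%.
* The 2×2 Fisher statistic is the odds ratio as returned by scipy; the χ²
  test requires positive expected counts.
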