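# rdriver

Driver-mutation prioritization for tumor cohorts by regressing genome-wide
gene expression on somatic mutation status with functional-impact-weighted
adaptive lasso penalties.

## The problem

Most recurrent somatic mutations in a tumor cohort are passengers. Methods
that rank mutations by frequency alone miss low-frequency drivers and
cannot separate a hotspot from a mutation with no downstream consequence.
rDriver integrates three data types — the binary mutation matrix, the
matched expression matrix, and per-mutation functional impact scores
(GERP-like conservation, SIFT deleteriousness) — under one model: for each
gene *j*,

    y_j = Σ_k β_jk x_k + ε_j

with a per-gene weighted-lasso objective

    (1/2N) ‖y_j − Xβ_j‖² + λ₁ⱼ Σ_k δ_k |β_jk| + λ₂ⱼ Σ_i w_i²,
    δ_k = sigmoid(−Σ_i w_i f_ki) ∈ [δ_min, 1)

where f_ki are standardized, impact-oriented functional scores and w ≥ 0
are learned feature weights: predicted-damaging mutations get a smaller L1
penalty and are cheaper to select. Fitting alternates per-gene 10-fold CV
for λ, coordinate-descent lasso fits, and a projected-gradient update of
w, starting from the uniform prior δ = ½. A mutation's **driver score**
is the number of genes with a nonzero coefficient in its row of the
fitted association matrix; empirical p-values rank the observed score
against scores from fits on expression matrices with permuted sample
order. Downstream tools cover per-mutation differential expression
(Mann–Whitney + BH), hypergeometric gene-set enrichment, a
frequency-only baseline, ROC/confusion evaluation against truth sets,
and prognosis: a per-patient integrative prognostic score IPS = xᵀBy,
consensus-clustered (exact 1-D k-means, cophenetic model selection) and
tested with the log-rank statistic.

A synthetic-cohort generator with planted drivers makes the entire
pipeline testable without any data download. See `docs/methods.md` for
the full model description, numerical choices and limitations.

## Worked example

Simulate a cohort of 120 tumors with 12 recurrent mutations, 3 of them
drivers regulating 10 genes each; fit, score with 50 permutations, and
evaluate against the ground-truth sidecar:

```sh
rdriver simulate --config sim.yaml --out demo/fixture
# fixture written to demo/fixture (7 files)

rdriver score --expression demo/fixture/expression.tsv \
    --mutations demo/fixture/mutations.tsv \
    --features demo/fixture/features.tsv \
    --scale log --config model.yaml --n-perm 50 --out demo/run
# 9 driver / 3 passenger calls written to demo/run

rdriver evaluate --scores demo/run/driver_scores.tsv \
    --truth demo/fixture/truth.tsv --out demo/eval.tsv
# auc=0.9815 ppv=0.3333 npv=1.0000 sensitivity=1.0000 specificity=0.3333
```

The head of `demo/run/driver_scores.tsv`:

```
allele          gene    protein_change  score  p_value   q_value   call
MUT005:p.A105V  MUT005  p.A105V         19     0.001664  0.004992  driver
MUT004:p.A104V  MUT004  p.A104V         17     0.001664  0.004992  driver
MUT003:p.A103T  MUT003  p.A103T         16     0.001664  0.004992  driver
MUT007:p.A107T  MUT007  p.A107T         16     0.001664  0.004992  driver
MUT002:p.A102T  MUT002  p.A102T         12     0.018303  0.036606  driver
MUT009:p.A109V  MUT009  p.A109V         12     0.018303  0.036606  driver
```

Reading the output: `score` counts the genes whose expression the allele
predicts (the three planted drivers top the ranking and every true driver
is recovered — sensitivity 1.0, AUC 0.98); `p_value` is its add-one
smoothed rank in the pooled permutation null; calls use unadjusted
p < 0.05, so on a small cohort some passengers with middling scores come
along (PPV 0.33 here — tighten with `--alpha` or BH adjustment). The fit
report for the same run shows the alternation converging in 3 outer
iterations with mean per-gene R² = 0.24:

```
converged: True after 3 outer iteration(s)
mean R2: 0.2405
nonzero associations: 152
```

Other subcommands: `fit` (association matrix only), `deg`, `enrich`,
`ips`, `survive` (IPS consensus clustering + Kaplan–Meier/log-rank),
`evaluate`. All accept a flat YAML config plus flag overrides; a single
`seed` drives every random substream, and identical config + seed gives
byte-identical outputs.

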