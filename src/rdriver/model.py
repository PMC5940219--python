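"""The rDriver statistical core.

Model: for each gene j, expression across N samples is a sparse linear
function of the binary mutation design matrix,

    y_j = sum_k beta_jk x_k + eps_j,

fit without intercept on centered y and standardized x. Each mutant allele
k carries a penalty scale delta_k = sigmoid(+/- sum_i w_i f_ki), a function
of its functional-impact scores f (GERP-like conservation, inverted SIFT,
...), so that the per-gene weighted-lasso objective

    (1/2n) ||y_j - X beta_j||^2 + lambda1_j sum_k delta_k |beta_jk|
                                + lambda2_j sum_i w_i^2

penalizes predicted-benign alleles more than predicted-damaging ones.
Fitting alternates (a) per-gene 10-fold CV selection of lambda1 given the
current delta, (b) per-gene weighted-lasso coordinate descent, and (c) a
projected-gradient update of the non-negative feature weights w, starting
from w = 0 (uniform prior, delta = 1/2).

Scaling note: the residual term uses 1/(2n) so lambda grids are comparable
across sample sizes; this only reparameterizes lambda relative to the
unscaled sum-of-squares form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .datatypes import ExpressionMatrix, FeatureTable, MutationMatrix
from .errors import ValidationError
from ._rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "RegularizationParams",
    "FitResult",
    "sigmoid",
    "compute_penalty_scale",
    "soft_threshold",
    "fit_weighted_lasso",
    "objective",
    "select_lambdas_cv",
    "update_weights",
    "fit_rdriver",
    "variance_explained",
]


@dataclass
class ModelConfig:
    """Tunable parameters of the alternating fit.

    delta_mode "oriented" (default) maps high standardized impact to a
    SMALL penalty via sigmoid(-w.f); "literal" uses sigmoid(+w.f) exactly
    as the penalty-scale formula is usually printed, which penalizes
    high-impact alleles more. delta_min floors the scale so no allele
    becomes penalty-free.
    """

    delta_mode: str = "oriented"
    delta_min: float = 0.05
    n_lambda1: int = 20
    lambda1_min_ratio: float = 0.01
    lambda2_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    k_folds: int = 10
    tol_cd: float = 1e-6
    max_sweeps: int = 1000
    tol_outer: float = 1e-4
    max_outer: int = 20
    cv_tol: float = 1e-4
    cv_max_sweeps: int = 200
    weight_max_iter: int = 100
    weight_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_mode not in ("oriented", "literal"):
            raise ValidationError(f"unknown delta_mode {self.delta_mode!r}")
        if not (0 < self.delta_min < 0.5):
            raise ValidationError("delta_min must lie in (0, 0.5)")


@dataclass
class RegularizationParams:
    lambda1: np.ndarray  # per gene
    lambda2: np.ndarray  # per gene

    def __post_init__(self) -> None:
        self.lambda1 = np.asarray(self.lambda1, dtype=float)
        self.lambda2 = np.asarray(self.lambda2, dtype=float)
        if np.any(self.lambda1 < 0) or np.any(self.lambda2 < 0):
            raise ValidationError("regularization parameters must be >= 0")


@dataclass
class FitResult:
    """Converged alternating-fit solution."""

    beta: np.ndarray                  # alleles x genes
    weights: np.ndarray               # per feature
    delta: np.ndarray                 # per allele
    lambdas: RegularizationParams
    objective_trace: list[float]
    lambda_epochs: list[int]          # index into trace where lambda was re-selected
    r2: np.ndarray                    # per gene, NaN for dropped genes
    residual_sd: np.ndarray           # per gene
    converged: bool
    n_outer: int
    allele_ids: list[str] | None = None
    gene_ids: list[str] | None = None
    feature_names: list[str] | None = None
    dropped_genes: list[str] = field(default_factory=list)
    dropped_alleles: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def support(self) -> np.ndarray:
        return self.beta != 0.0

    def beta_triplets(self):
        """Sparse (allele, gene, beta) rows for the nonzero coefficients."""
        import pandas as pd

        ks, js = np.nonzero(self.beta)
        alleles = (
            [self.allele_ids[k] for k in ks] if self.allele_ids else list(ks)
        )
        genes = [self.gene_ids[j] for j in js] if self.gene_ids else list(js)
        return pd.DataFrame(
            {"allele": alleles, "gene": genes, "beta": self.beta[ks, js]}
        )


def sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def compute_penalty_scale(
    w: np.ndarray,
    features: FeatureTable | np.ndarray,
    mode: str = "oriented",
    delta_min: float = 0.05,
) -> np.ndarray:
    """Per-allele L1 penalty scale delta from feature weights.

    literal:  delta_k = sigmoid(+ sum_i w_i f_ki) — the formula as printed;
    oriented: delta_k = sigmoid(- sum_i w_i f_ki) on impact-oriented
    standardized features, so predicted-damaging alleles are penalized
    LESS. Result clipped to [delta_min, 1). With w = 0 both modes give 1/2.
    """
    F = features.values if isinstance(features, FeatureTable) else np.asarray(features, float)
    w = np.asarray(w, dtype=float)
    if F.shape[1] != w.shape[0]:
        raise ValidationError(
            f"feature count {F.shape[1]} does not match weight length {w.shape[0]}"
        )
    s = F @ w
    if mode == "literal":
        delta = sigmoid(s)
    elif mode == "oriented":
        delta = sigmoid(-s)
    else:
        raise ValidationError(f"unknown penalty mode {mode!r}")
    return np.clip(delta, delta_min, np.nextafter(1.0, 0.0))


def soft_threshold(z, gamma):
    """sign(z) * max(|z| - gamma, 0)."""
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


def _kkt_violation(C, B, beta, thresh) -> float:
    """Max KKT violation of the weighted lasso in Gram form.

    grad[k, j] = x_k^T r_j / n; at a solution |grad| <= thresh where
    beta = 0 and grad = thresh * sign(beta) where beta != 0.
    """
    grad = B - C @ beta
    nz = beta != 0.0
    viol_zero = np.maximum(np.abs(np.where(nz, 0.0, grad)) - thresh, 0.0)
    viol_nz = np.abs(np.where(nz, grad - thresh * np.sign(beta), 0.0))
    return float(np.maximum(viol_zero, viol_nz).max(initial=0.0))


def _cd_gram(C, B, delta, lam1, beta, tol, max_sweeps):
    """Cyclic coordinate descent on the Gram system, vectorized over genes.

    C = X^T X / n (M x M), B = X^T Y / n (M x G); minimizes, per gene j,
    (1/2n)||y_j - X b||^2 + lam1[j] * sum_k delta[k] |b_k|. Stops when the
    KKT violation drops below ``tol``. Returns (beta, converged).
    """
    M, G = B.shape
    diag = np.diag(C).copy()
    thresh = np.outer(delta, lam1)  # M x G
    for _ in range(max_sweeps):
        for k in range(M):
            dk = diag[k]
            if dk <= 0:
                continue
            bk = beta[k]
            z = B[k] - C[k] @ beta + dk * bk
            beta[k] = soft_threshold(z, thresh[k]) / dk
        if _kkt_violation(C, B, beta, thresh) <= tol:
            return beta, True
    return beta, False


def fit_weighted_lasso(
    y: np.ndarray,
    X: np.ndarray,
    delta: np.ndarray,
    lambda1: float,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
    beta0: np.ndarray | None = None,
):
    """Fit one gene's weighted lasso by cyclic coordinate descent.

    ``y`` must be centered and the columns of ``X`` standardized (mean 0,
    unit population variance); ``delta`` scales each coefficient's L1
    penalty. Returns ``(beta, converged)``; on non-convergence the best
    iterate is returned with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValidationError("non-finite values in lasso inputs")
    delta = np.asarray(delta, dtype=float)
    if lambda1 < 0:
        raise ValidationError("lambda1 must be >= 0")
    n = len(y)
    C = X.T @ X / n
    B = (X.T @ y / n)[:, None]
    beta = np.zeros_like(B) if beta0 is None else np.asarray(beta0, float).reshape(-1, 1).copy()
    beta, converged = _cd_gram(C, B, delta, np.array([lambda1]), beta, tol, max_sweeps)
    if not converged:
        logger.warning("weighted lasso did not reach tol=%.1e in %d sweeps", tol, max_sweeps)
    return beta[:, 0], converged


def objective(Y, X, beta, delta, lambda1s, lambda2s, w) -> float:
    """Full penalized objective summed over genes (1/(2n) residual scaling)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if Y.shape[0] == X.shape[0]:
        pass
    elif Y.shape[1] == X.shape[0]:  # allow (G, n) orientation for 1-gene vectors
        Y = Y.T
    n, G = Y.shape
    lambda1s = np.broadcast_to(np.asarray(lambda1s, float), (G,))
    lambda2s = np.broadcast_to(np.asarray(lambda2s, float), (G,))
    R = Y - X @ beta
    rss = 0.5 / n * np.sum(R * R, axis=0)
    l1 = lambda1s * (np.abs(beta) * np.asarray(delta, float)[:, None]).sum(axis=0)
    l2 = lambda2s * float(np.sum(np.square(w)))
    return float(np.sum(rss + l1 + l2))


def _lambda1_path(B0: np.ndarray, delta: np.ndarray, n_lambda1: int, min_ratio: float):
    """Per-gene lambda1 grids as (ratios, per-gene lambda_max)."""
    lam_max = np.max(np.abs(B0) / delta[:, None], axis=0)
    lam_max = np.maximum(lam_max, 1e-12)
    ratios = np.logspace(0.0, np.log10(min_ratio), n_lambda1)
    return ratios, lam_max


def _cv_folds(n: int, k_folds: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return np.array_split(idx, k_folds)


def _select_lambdas_cv_multi(
    Y: np.ndarray,
    X: np.ndarray,
    delta: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    folds: list[np.ndarray] | None = None,
) -> RegularizationParams:
    """Per-gene (lambda1, lambda2) by k-fold CV, vectorized across genes.

    Held-out squared error does not depend on lambda2 (it penalizes only
    the feature weights), so every grid value ties; following the usual
    CV convention, ties are broken to the strongest regularization — the
    largest grid value — keeping the learned functional prior conservative
    (with a weak ridge the weight update saturates delta at its floor and
    chance-high-impact passengers become nearly penalty-free).
    """
    n, G = Y.shape
    if n < config.k_folds:
        raise ValidationError(
            f"n={n} samples < k_folds={config.k_folds}; reduce k_folds"
        )
    B0 = X.T @ Y / n
    ratios, lam_max = _lambda1_path(B0, delta, config.n_lambda1, config.lambda1_min_ratio)
    if folds is None:
        folds = _cv_folds(n, config.k_folds, rng)
    sse = np.zeros((len(ratios), G))
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, Ytr = X[mask], Y[mask]
        Xte, Yte = X[test_idx], Y[test_idx]
        ntr = Xtr.shape[0]
        C = Xtr.T @ Xtr / ntr
        B = Xtr.T @ Ytr / ntr
        beta = np.zeros((X.shape[1], G))
        for t, r in enumerate(ratios):  # warm start down the path
            lam1 = r * lam_max
            beta, _ = _cd_gram(C, B, delta, lam1, beta, config.cv_tol, config.cv_max_sweeps)
            Rte = Yte - Xte @ beta
            sse[t] += np.sum(Rte * Rte, axis=0)
    best = np.argmin(sse, axis=0)  # first minimum -> larger lambda on ties
    lambda1 = ratios[best] * lam_max
    lambda2 = np.full(G, max(config.lambda2_grid))
    return RegularizationParams(lambda1=lambda1, lambda2=lambda2)


def select_lambdas_cv(
    y: np.ndarray,
    X: np.ndarray,
    delta: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> RegularizationParams:
    """Select (lambda1, lambda2) for a single gene by k-fold CV.

    Minimum-mean-squared-error rule (no one-standard-error rule); fold
    assignment is a seeded shuffle, so the selection is reproducible.
    """
    cfg = config or ModelConfig()
    cfg = ModelConfig(**{**asdict(cfg), "k_folds": k_folds})
    rng = substream(seed, "cv")
    Y = np.asarray(y, dtype=float).reshape(len(y), 1)
    return _select_lambdas_cv_multi(Y, np.asarray(X, float), np.asarray(delta, float), cfg, rng)


def update_weights(
    beta: np.ndarray,
    features: FeatureTable | np.ndarray,
    lambda1s: np.ndarray,
    lambda2s: np.ndarray,
    w_current: np.ndarray,
    mode: str = "oriented",
    delta_min: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Projected-gradient update of the non-negative feature weights.

    Minimizes sum_j lambda1_j sum_k delta_k(w) |beta_jk|
    + (sum_j lambda2_j) ||w||^2 over w >= 0, with backtracking so the
    objective never increases. Returns ``(w, converged)``.
    """
    F = features.values if isinstance(features, FeatureTable) else np.asarray(features, float)
    beta = np.asarray(beta, dtype=float)
    lambda1s = np.asarray(lambda1s, dtype=float)
    l2_total = float(np.sum(lambda2s))
    w = np.maximum(np.asarray(w_current, dtype=float).copy(), 0.0)
    a = np.abs(beta) @ lambda1s  # per-allele L1 mass, sum_j lambda1_j |beta_jk|
    sign = 1.0 if mode == "literal" else -1.0

    def value(wv):
        delta = compute_penalty_scale(wv, F, mode=mode, delta_min=delta_min)
        return float(a @ delta + l2_total * wv @ wv)

    def gradient(wv):
        s = sign * (F @ wv)
        d_raw = sigmoid(s)
        active = (d_raw > delta_min) & (d_raw < 1.0)  # clip region has zero slope
        dd_ds = np.where(active, d_raw * (1.0 - d_raw), 0.0)
        return sign * (F.T @ (a * dd_ds)) + 2.0 * l2_total * wv

    step = 1.0
    converged = False
    fw = value(w)
    for _ in range(max_iter):
        g = gradient(w)
        # projected-gradient stationarity on the non-negative orthant
        pg = np.where((w <= 0) & (g > 0), 0.0, g)
        if np.linalg.norm(pg) < tol:
            converged = True
            break
        improved = False
        t = step
        for _bt in range(40):
            cand = np.maximum(w - t * g, 0.0)
            fc = value(cand)
            if fc < fw - 1e-15:
                w, fw = cand, fc
                step = min(t * 2.0, 1e3)
                improved = True
                break
            t *= 0.5
        if not improved:
            # no descent direction at machine precision: stationary enough
            converged = True
            break
    if not converged:
        logger.warning("weight update stopped at max_iter=%d", max_iter)
    return w, converged


def _as_array(obj, attr="values"):
    return getattr(obj, attr) if hasattr(obj, attr) else np.asarray(obj, dtype=float)


def standardize_columns(X: np.ndarray):
    """Center and scale columns to unit population variance.

    Returns (X_std, keep_mask): zero-variance columns are flagged for
    dropping rather than divided by zero.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # relative tolerance: a column of 4.2s has sd ~ 1e-15 from rounding
    keep = sd > 1e-10 * np.maximum(1.0, np.abs(mu))
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep


def fit_rdriver(
    Y: ExpressionMatrix | np.ndarray,
    X: MutationMatrix | np.ndarray,
    F: FeatureTable | np.ndarray,
    config: ModelConfig | None = None,
    lambdas: RegularizationParams | None = None,
    delta_fixed: np.ndarray | None = None,
) -> FitResult:
    """Alternating fit of the full model.

    ``Y`` samples x genes (preprocessed expression), ``X`` samples x alleles
    (binary), ``F`` alleles x features (standardized, impact-oriented).
    Constant genes and constant mutation columns are dropped with a logged
    warning; their rows/columns of the returned association matrix are zero
    (genes: R^2 reported as NaN).

    ``lambdas``/``delta_fixed`` bypass CV selection and the weight update —
    this is how permutation replicates are re-fit "with identical
    parameters".
    """
    cfg = config or ModelConfig()
    Yv = _as_array(Y)
    Xv = _as_array(X).astype(float)
    Fv = F.values if isinstance(F, FeatureTable) else np.asarray(F, dtype=float)
    gene_ids = list(Y.gene_ids) if isinstance(Y, ExpressionMatrix) else [
        f"g{j}" for j in range(Yv.shape[1])
    ]
    allele_ids = list(X.allele_ids) if isinstance(X, MutationMatrix) else [
        f"m{k}" for k in range(Xv.shape[1])
    ]
    feature_names = (
        list(F.feature_names) if isinstance(F, FeatureTable) else
        [f"f{i}" for i in range(Fv.shape[1])]
    )
    n, G_all = Yv.shape
    M_all = Xv.shape[1]
    if M_all < 1 or G_all < 1:
        raise ValidationError("need at least one gene and one mutation allele")
    if Xv.shape[0] != n:
        raise ValidationError("expression and mutation matrices have different sample counts")
    if Fv.shape[0] != M_all:
        raise ValidationError("feature table rows must match mutation alleles")

    Xs_all, keep_alleles = standardize_columns(Xv)
    gene_sd = Yv.std(axis=0)
    keep_genes = gene_sd > 1e-10 * np.maximum(1.0, np.abs(Yv.mean(axis=0)))
    dropped_alleles = [allele_ids[k] for k in np.flatnonzero(~keep_alleles)]
    dropped_genes = [gene_ids[j] for j in np.flatnonzero(~keep_genes)]
    if dropped_alleles:
        logger.warning("dropping %d constant mutation column(s): %s",
                       len(dropped_alleles), dropped_alleles[:5])
    if dropped_genes:
        logger.warning("dropping %d constant gene(s): %s", len(dropped_genes), dropped_genes[:5])

    Xs = Xs_all[:, keep_alleles]
    Fk = Fv[keep_alleles]
    Yc = Yv[:, keep_genes] - Yv[:, keep_genes].mean(axis=0)
    M = Xs.shape[1]
    G = Yc.shape[1]

    C = Xs.T @ Xs / n
    B = Xs.T @ Yc / n

    w = np.zeros(Fk.shape[1])
    delta = (
        np.asarray(delta_fixed, float)[keep_alleles]
        if delta_fixed is not None
        else compute_penalty_scale(w, Fk, cfg.delta_mode, cfg.delta_min)
    )
    beta = np.zeros((M, G))
    trace: list[float] = []
    epochs: list[int] = []
    rng_cv = substream(cfg.seed, "cv")
    # one fold assignment per fit: lambda selection is then a deterministic
    # function of delta, so the alternation can actually converge
    folds = _cv_folds(n, cfg.k_folds, rng_cv) if n >= cfg.k_folds else None
    fixed_params = lambdas is not None
    if fixed_params:
        lam1 = np.asarray(lambdas.lambda1, float)[keep_genes]
        lam2 = np.asarray(lambdas.lambda2, float)[keep_genes]

    # a fixed delta (e.g. the prior-free delta == 1 reduction, or permutation
    # refits) disables the weight update; fixed lambdas additionally skip CV
    update_prior = delta_fixed is None and not fixed_params
    converged = False
    n_outer = 0
    prev_obj = np.inf
    for it in range(cfg.max_outer if update_prior else 1):
        n_outer = it + 1
        if not fixed_params:
            params = _select_lambdas_cv_multi(Yc, Xs, delta, cfg, rng_cv, folds=folds)
            lam1, lam2 = params.lambda1, params.lambda2
        epochs.append(len(trace))
        beta, _ok = _cd_gram(C, B, delta, lam1, beta, cfg.tol_cd, cfg.max_sweeps)
        trace.append(objective(Yc, Xs, beta, delta, lam1, lam2, w))
        if update_prior:
            w, _wok = update_weights(
                beta, Fk, lam1, lam2, w, cfg.delta_mode, cfg.delta_min,
                cfg.weight_max_iter, cfg.weight_tol,
            )
            delta = compute_penalty_scale(w, Fk, cfg.delta_mode, cfg.delta_min)
            trace.append(objective(Yc, Xs, beta, delta, lam1, lam2, w))
            beta, _ok = _cd_gram(C, B, delta, lam1, beta, cfg.tol_cd, cfg.max_sweeps)
            trace.append(objective(Yc, Xs, beta, delta, lam1, lam2, w))
        obj = trace[-1]
        if not update_prior or (
            np.isfinite(prev_obj)
            and abs(prev_obj - obj) <= cfg.tol_outer * max(abs(prev_obj), 1e-12)
        ):
            converged = True
            break
        prev_obj = obj

    # expand back to the full allele x gene frame
    beta_full = np.zeros((M_all, G_all))
    beta_full[np.ix_(keep_alleles, keep_genes)] = beta
    delta_full = np.full(M_all, np.nan)
    delta_full[keep_alleles] = delta
    lam1_full = np.full(G_all, np.nan)
    lam2_full = np.full(G_all, np.nan)
    lam1_full[keep_genes] = lam1
    lam2_full[keep_genes] = lam2

    resid = Yc - Xs @ beta
    r2 = np.full(G_all, np.nan)
    tss = np.sum(Yc * Yc, axis=0)
    r2[keep_genes] = np.clip(1.0 - np.sum(resid * resid, axis=0) / tss, 0.0, 1.0)
    residual_sd = np.full(G_all, np.nan)
    residual_sd[keep_genes] = resid.std(axis=0)

    return FitResult(
        beta=beta_full,
        weights=w,
        delta=delta_full,
        lambdas=RegularizationParams(lambda1=lam1_full, lambda2=lam2_full),
        objective_trace=trace,
        lambda_epochs=epochs,
        r2=r2,
        residual_sd=residual_sd,
        converged=converged,
        n_outer=n_outer,
        allele_ids=allele_ids,
        gene_ids=gene_ids,
        feature_names=feature_names,
        dropped_genes=dropped_genes,
        dropped_alleles=dropped_alleles,
        config=asdict(cfg),
    )


def variance_explained(Y, X, beta) -> np.ndarray:
    """Per-gene in-sample R^2 of the fitted mutation model.

    Computed on centered y and standardized X (the model's fitting scale):
    R2_j = 1 - ||y_j - X beta_j||^2 / ||y_j - mean||^2. Zero-variance genes
    are reported as NaN. Because beta = 0 is always feasible for the
    penalized fit, in-sample R^2 lands in [0, 1].
    """
    Yv = np.asarray(_as_array(Y), dtype=float)
    Xv = np.asarray(_as_array(X), dtype=float)
    beta = np.asarray(beta, dtype=float)
    Xs, _ = standardize_columns(Xv)
    Yc = Yv - Yv.mean(axis=0)
    tss = np.sum(Yc * Yc, axis=0)
    resid = Yc - Xs @ beta
    out = np.full(Yv.shape[1], np.nan)
    ok = tss > 0
    out[ok] = 1.0 - np.sum(resid * resid, axis=0)[ok] / tss[ok]
    return out
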