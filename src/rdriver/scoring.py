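"""Driver scores, permutation null and driver/passenger calls.

A mutation's driver score is the number of genes it is associated with —
the count of nonzero coefficients in its row of the association matrix.
The null distribution comes from re-fitting the model on expression
matrices whose sample rows have been jointly permuted, which breaks every
mutation-expression link while preserving the gene-gene correlation
structure. Empirical p-values are add-one smoothed upper-tail ranks of the
observed scores within the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .errors import ValidationError
from .model import (
    FitResult,
    ModelConfig,
    _cd_gram,
    _select_lambdas_cv_multi,
    fit_rdriver,
    standardize_columns,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "driver_scores",
    "permutation_null",
    "empirical_pvalues",
    "classify_drivers",
    "driver_score_table",
]


@dataclass
class NullDistribution:
    """Driver scores observed under expression-permutation refits.

    ``scores`` has shape (n_permutations, n_alleles); ``pooled`` says
    whether p-values should pool scores across alleles (default) or use
    each allele's own column.
    """

    scores: np.ndarray
    n_permutations: int
    pooled: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.size == 0:
            raise ValidationError("null distribution is empty")
        if np.any(self.scores < 0):
            raise ValidationError("null scores must be non-negative counts")

    @property
    def pooled_scores(self) -> np.ndarray:
        return self.scores.ravel()


def driver_scores(beta: np.ndarray | FitResult) -> np.ndarray:
    """Number of genes with a nonzero association, per allele."""
    b = beta.beta if isinstance(beta, FitResult) else np.asarray(beta)
    return (b != 0.0).sum(axis=1)


def permutation_null(
    Y,
    X,
    F,
    config: ModelConfig | None = None,
    n_perm: int = 100,
    seed: int = 0,
    mode: str = "cv",
    fit: FitResult | None = None,
    pooled: bool = True,
) -> NullDistribution:
    """Null driver scores from jointly permuted expression rows.

    Each replicate applies one random permutation to the sample order of
    the whole expression matrix and re-runs the model with the observed
    fit's parameters. Modes differ in what "identical parameters" freezes:

    * ``"cv"`` (default): the learned prior (w, hence delta) is held
      fixed, while lambda is re-determined on the permuted matrix by the
      same CV procedure used for the observed fit. Observed and null
      scores are then exchangeable under the no-association null, which is
      what makes the empirical p-values calibrated.
    * ``"fixed"``: lambda and delta are both reused verbatim. Fastest, but
      conservative: CV anchors each gene's lambda at the observed data's
      own correlation maximum, so permuted refits are not exchangeable
      with the observed one.
    * ``"refit"``: the entire alternating fit (CV and weight updates) is
      repeated per permutation.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if mode not in ("fixed", "cv", "refit"):
        raise ValidationError(f"unknown permutation mode {mode!r}")
    cfg = config or ModelConfig()
    Yv = Y.values if hasattr(Y, "values") else np.asarray(Y, dtype=float)
    Xv = (X.values if hasattr(X, "values") else np.asarray(X)).astype(float)
    n, M_all = Yv.shape[0], Xv.shape[1]
    if mode in ("fixed", "cv") and fit is None:
        fit = fit_rdriver(Y, X, F, cfg)

    all_scores = np.zeros((n_perm, M_all), dtype=int)
    if mode == "refit":
        for p in range(n_perm):
            rng = substream(seed, "permutation", p)
            res = fit_rdriver(Yv[rng.permutation(n)], X, F, cfg)
            all_scores[p] = driver_scores(res)
        return NullDistribution(all_scores, n_perm, pooled=pooled)

    # lean path: X (hence its Gram) never changes across permutations
    Xs_all, keep_alleles = standardize_columns(Xv)
    Xs = Xs_all[:, keep_alleles]
    keep_genes = Yv.std(axis=0) > 1e-10 * np.maximum(1.0, np.abs(Yv.mean(axis=0)))
    delta = np.asarray(fit.delta, float)[keep_alleles]
    C = Xs.T @ Xs / n
    lam1_obs = np.asarray(fit.lambdas.lambda1, float)[keep_genes]
    for p in range(n_perm):
        rng = substream(seed, "permutation", p)
        Yp = Yv[rng.permutation(n)][:, keep_genes]
        Yc = Yp - Yp.mean(axis=0)
        if mode == "cv":
            params = _select_lambdas_cv_multi(Yc, Xs, delta, cfg, rng)
            lam1 = params.lambda1
        else:
            lam1 = lam1_obs
        beta = np.zeros((Xs.shape[1], Yc.shape[1]))
        beta, _ = _cd_gram(C, Xs.T @ Yc / n, delta, lam1, beta, cfg.tol_cd, cfg.max_sweeps)
        all_scores[p, keep_alleles] = (beta != 0.0).sum(axis=1)
    return NullDistribution(all_scores, n_perm, pooled=pooled)


def empirical_pvalues(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Add-one smoothed upper-tail empirical p-values.

    p_k = (#{null >= observed_k} + 1) / (N_null + 1); never exactly zero,
    and non-increasing in the observed score for a fixed pooled null.
    """
    observed = np.asarray(observed)
    if null.pooled:
        pool = np.sort(null.pooled_scores)
        n_null = pool.size
        # count of null >= obs via searchsorted on the sorted pool
        ge = n_null - np.searchsorted(pool, observed, side="left")
        return (ge + 1.0) / (n_null + 1.0)
    if null.scores.ndim != 2 or null.scores.shape[1] != observed.shape[0]:
        raise ValidationError("per-allele null requires scores shaped (n_perm, n_alleles)")
    ge = (null.scores >= observed[None, :]).sum(axis=0)
    return (ge + 1.0) / (null.scores.shape[0] + 1.0)


def classify_drivers(
    p_values: np.ndarray, alpha: float = 0.05, adjust: str = "none"
) -> np.ndarray:
    """Boolean driver calls: (adjusted) p strictly below alpha.

    ``adjust="bh"`` applies Benjamini-Hochberg before thresholding.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if adjust == "bh":
        p = multipletests(p, method="fdr_bh")[1]
    elif adjust != "none":
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return p < alpha


def driver_score_table(
    fit: FitResult,
    null: NullDistribution,
    allele_meta: pd.DataFrame | None = None,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Assemble the per-mutation score/p/q/call table.

    Sorted by ascending p-value then descending score; q_value is the BH
    adjustment of the empirical p regardless of which scale the call uses.
    """
    scores = driver_scores(fit)
    p = empirical_pvalues(scores, null)
    q = multipletests(p, method="fdr_bh")[1]
    calls = classify_drivers(p, alpha=alpha, adjust=adjust)
    table = pd.DataFrame(
        {
            "allele": fit.allele_ids,
            "score": scores,
            "p_value": p,
            "q_value": q,
            "call": np.where(calls, "driver", "passenger"),
        }
    )
    if allele_meta is not None:
        table.insert(1, "gene", allele_meta["gene"].reindex(table["allele"]).to_numpy())
        table.insert(
            2,
            "protein_change",
            allele_meta["protein_change"].reindex(table["allele"]).to_numpy(),
        )
    return table.sort_values(
        ["p_value", "score"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
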