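"""Post-hoc analyses around the driver calls.

Differential expression per mutation (Mann-Whitney + BH), gene-set
over-representation (hypergeometric + BH), a frequency-only baseline,
ROC/confusion evaluation against known-driver truth sets, group
composition tests (Fisher / chi-squared), clonality comparisons
(rank-sum), and prognosis: the integrative prognostic score (IPS)
``x . B . y`` per patient, consensus clustering of the 1-D IPS values with
exact dynamic-programming k-means, cophenetic model selection, and a
log-rank survival comparison of the resulting strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .datatypes import ExpressionMatrix, GeneSetCollection
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "deg_analysis",
    "mannwhitney_p",
    "gene_set_enrichment",
    "frequency_baseline",
    "roc_auc",
    "confusion_metrics",
    "group_composition_test",
    "ccf_group_comparison",
    "integrative_prognostic_score",
    "ips_scores",
    "kmeans1d",
    "kmeans1d_consensus",
    "StratificationResult",
    "logrank_test",
    "km_table",
]

EXACT_MAX_GROUP = 8  # exact Mann-Whitney enumeration up to this group size


def mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free groups, else
    tie-corrected normal approximation; degenerate all-tied data gives 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    small = max(a.size, b.size) <= EXACT_MAX_GROUP
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def deg_analysis(
    em: ExpressionMatrix | np.ndarray,
    mutation_column: np.ndarray,
    fdr: float = 0.05,
    mutation_name: str = "mutation",
) -> pd.DataFrame:
    """Differential expression between carriers and non-carriers of one allele.

    Per gene: two-sided Mann-Whitney between the two sample groups, BH
    adjustment across genes; ``significant`` flags adjusted p < ``fdr``.
    ``direction`` is the sign of (carrier median - non-carrier median).
    """
    values = em.values if isinstance(em, ExpressionMatrix) else np.asarray(em, float)
    genes = (
        list(em.gene_ids)
        if isinstance(em, ExpressionMatrix)
        else [f"g{j}" for j in range(values.shape[1])]
    )
    mut = np.asarray(mutation_column).astype(bool)
    if mut.shape[0] != values.shape[0]:
        raise ValidationError("mutation column length must match sample count")
    if mut.all() or not mut.any():
        raise ValidationError(
            f"mutation {mutation_name!r}: one of the carrier groups is empty"
        )
    carriers = values[mut]
    rest = values[~mut]
    raw = np.array([mannwhitney_p(carriers[:, j], rest[:, j]) for j in range(values.shape[1])])
    adj = multipletests(raw, method="fdr_bh")[1]
    direction = np.sign(np.median(carriers, axis=0) - np.median(rest, axis=0))
    return pd.DataFrame(
        {
            "gene": genes,
            "p_value": raw,
            "p_adjusted": adj,
            "significant": adj < fdr,
            "direction": direction,
        }
    )


def gene_set_enrichment(
    gene_list,
    background,
    sets: GeneSetCollection,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``gene_list`` in each set.

    Sets are intersected with ``background`` first; sets that become empty
    are dropped with a warning. p = P[overlap >= observed] under sampling
    ``len(gene_list)`` genes from the background without replacement.
    """
    background = list(dict.fromkeys(background))
    bg = set(background)
    gene_list = list(dict.fromkeys(gene_list))
    offenders = [g for g in gene_list if g not in bg]
    if offenders:
        raise ValidationError(f"gene_list members outside background: {offenders[:10]}")
    chosen = set(gene_list)
    N, n = len(bg), len(gene_list)
    rows = []
    for name in sets.set_names:
        members = bg & set(sets[name])
        if not members:
            logger.warning("gene set %r empty after background restriction; dropped", name)
            continue
        K = len(members)
        k = len(members & chosen)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "list_size": n,
                "background_size": N,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["p_adjusted"] < fdr
    return table


def frequency_baseline(
    counts: pd.Series,
    cutoff: int,
    level: str = "allele",
    allele_genes: pd.Series | None = None,
) -> pd.DataFrame:
    """Frequency-only driver calls: driver iff cohort count >= cutoff.

    ``level="gene"`` first sums counts over each gene's alleles, regardless
    of the individual amino-acid change (requires ``allele_genes`` mapping
    allele id -> gene).
    """
    counts = pd.Series(counts)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if level == "gene":
        if allele_genes is None:
            raise ValidationError("gene-level baseline requires allele_genes")
        counts = counts.groupby(allele_genes.reindex(counts.index)).sum()
    elif level != "allele":
        raise ValidationError(f"unknown level {level!r}")
    out = counts.sort_values(ascending=False, kind="mergesort").to_frame("count")
    out["call"] = np.where(out["count"] >= cutoff, "driver", "passenger")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def roc_auc(scores, truth) -> float:
    """AUC = P[score+ > score-] + P[tie]/2, via the rank (Mann-Whitney U) formula."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """PPV/NPV/sensitivity/specificity; undefined ratios come back as NaN."""
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    if any(v < 0 for v in counts.values()):
        raise ValidationError("confusion counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ValidationError("confusion table is all zero")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }


def group_composition_test(table, method: str = "fisher"):
    """Driver-vs-passenger composition test on a 2 x k contingency table.

    ``fisher`` (2 x 2 only): exact two-sided p summing hypergeometric
    probabilities no larger than the observed table's. ``chisq``: Pearson
    statistic without continuity correction.
    Returns ``(statistic, p)``; the Fisher statistic is the odds ratio.
    """
    table = np.asarray(table)
    if np.any(table < 0):
        raise ValidationError("counts must be non-negative")
    if method == "fisher":
        if table.shape != (2, 2):
            raise ValidationError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    if method == "chisq":
        if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
            stat, p, _, expected = stats.chi2_contingency(table, correction=False)
            if np.any(expected <= 0):
                raise ValidationError("chi-squared requires positive expected counts")
            return float(stat), float(p)
        raise ValidationError("chi-squared requires positive margins")
    raise ValidationError(f"unknown method {method!r}")


def ccf_group_comparison(ccf_driver, ccf_passenger):
    """Two-sided rank-sum comparison of cancer-cell-fraction distributions."""
    a = np.asarray(ccf_driver, dtype=float)
    b = np.asarray(ccf_passenger, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both CCF groups must be non-empty")
    for name, v in (("driver", a), ("passenger", b)):
        if np.any((v < 0) | (v > 1)):
            raise ValidationError(f"{name} CCF values must lie in [0, 1]")
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u.statistic), mannwhitney_p(a, b)


def integrative_prognostic_score(x, beta, y) -> float:
    """One patient's IPS: x . B . y with B the alleles x genes association matrix."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    if beta.shape != (x.shape[0], y.shape[0]):
        raise ValidationError(
            f"dimension mismatch: beta {beta.shape} vs x {x.shape} and y {y.shape}"
        )
    return float(x @ beta @ y)


def ips_scores(X, beta, Y) -> np.ndarray:
    """IPS for every sample: row-wise x_i . B . y_i."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[0] != Y.shape[0] or beta.shape != (X.shape[1], Y.shape[1]):
        raise ValidationError("sample counts or matrix dimensions do not align")
    return np.einsum("ij,ij->i", X @ beta, Y)


def kmeans1d(values: np.ndarray, k: int):
    """Exact 1-D k-means by dynamic programming over sorted segments.

    Returns ``(labels, centers)`` with clusters numbered 0..k-1 in
    ascending center order; globally optimal within-cluster SSE.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if k < 1 or k > n:
        raise ValidationError(f"k={k} invalid for {n} values")
    order = np.argsort(values, kind="stable")
    x = values[order]
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(i, j):  # SSE of x[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for q in range(1, k + 1):
        for j in range(q, n + 1):
            best, arg = INF, q - 1
            for i in range(q - 1, j):
                c = cost[q - 1, i] + seg_cost(i, j)
                if c < best:
                    best, arg = c, i
            cost[q, j] = best
            split[q, j] = arg
    # recover boundaries
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for q in range(k, 0, -1):
        i = split[q, j]
        labels_sorted[i:j] = q - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    centers = np.array([values[labels == c].mean() for c in range(k)])
    return labels, centers


@dataclass
class StratificationResult:
    labels: np.ndarray                      # 1..k per sample
    k: int
    cophenetic: dict[int, float]            # candidate k -> cophenetic correlation
    centers: np.ndarray
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    median_survival: dict[int, float] = field(default_factory=dict)


def kmeans1d_consensus(
    values: np.ndarray,
    k_range=range(2, 7),
    n_resample: int = 50,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> StratificationResult:
    """Consensus clustering of 1-D scores with cophenetic model selection.

    For each candidate k: exact 1-D k-means on ``n_resample`` seeded
    subsamples, a consensus co-clustering matrix over sample pairs,
    distance = 1 - co-clustering frequency, average-linkage dendrogram, and
    the cophenetic correlation between consensus distances and dendrogram
    distances. The k maximizing cophenetic correlation wins (ties to the
    smaller k); final labels come from full-data exact k-means at that k.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    k_range = list(k_range)
    if np.all(values == values[0]):
        raise ValidationError("all scores identical: no stratification possible")
    if n < 2 * max(k_range):
        raise ValidationError(f"need at least {2 * max(k_range)} samples")
    m = max(int(round(subsample_fraction * n)), max(k_range) + 1)
    coph: dict[int, float] = {}
    for k in k_range:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for r in range(n_resample):
            rng = substream(seed, "consensus", k * 100003 + r)
            idx = rng.choice(n, size=m, replace=False)
            labels, _ = kmeans1d(values[idx], k)
            same = labels[:, None] == labels[None, :]
            together[np.ix_(idx, idx)] += same
            sampled[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore"):
            consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        dist = 1.0 - consensus
        dist = (dist + dist.T) / 2.0
        condensed = squareform(dist, checks=False)
        link = hierarchy.average(condensed)
        if condensed.std() == 0:
            coph[k] = -np.inf  # degenerate consensus: all pairs identical
        else:
            coph[k] = float(hierarchy.cophenet(link, condensed)[0])
    best_k = max(k_range, key=lambda k: (coph[k], -k))
    labels, centers = kmeans1d(values, best_k)
    return StratificationResult(
        labels=labels + 1, k=best_k, cophenetic=coph, centers=centers
    )


def logrank_test(time, event, group):
    """Unweighted k-group log-rank test with Kaplan-Meier summaries.

    Returns a dict with the chi-square statistic (k-1 df), p-value and the
    per-group median survival. Data with no observed events give statistic
    0 and p = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    groups = np.unique(group)
    if groups.size < 2:
        raise ValidationError("log-rank test needs at least two groups")
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    medians: dict = {}
    for g in groups:
        sel = group == g
        kmf = KaplanMeierFitter().fit(time[sel], event[sel])
        medians[g] = float(kmf.median_survival_time_)
    if event.sum() == 0:
        return {"statistic": 0.0, "p_value": 1.0, "df": groups.size - 1,
                "median_survival": medians}
    res = multivariate_logrank_test(time, group, event)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):  # identical groups can yield 0/0
        stat, p = 0.0, 1.0
    return {
        "statistic": stat,
        "p_value": p,
        "df": int(groups.size - 1),
        "median_survival": medians,
    }


def km_table(time, event) -> pd.DataFrame:
    """Kaplan-Meier curve as a tabulated step function (time, at-risk, survival)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter().fit(np.asarray(time, float), np.asarray(event).astype(int))
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "at_risk": at_risk.to_numpy(),
         "survival": surv.to_numpy()}
    )
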