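"""Reading, validation and preprocessing of the five input tables.

File dialects (all readers transparently accept gzip):

* expression: TSV, header row of gene ids, first column sample ids
  (``orientation="genes_by_samples"`` transposes);
* mutations: MAF-like long TSV with columns sample_id, gene,
  protein_change, variant_class;
* features: TSV, first column allele id, one column per functional impact
  score, empty cells / ``NA`` denote missing;
* clinical: TSV with sample_id, survival_time (months), event (0/1);
* gene sets: standard GMT (name, description, tab-separated genes).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    FeatureTable,
    GeneSetCollection,
    MutationMatrix,
)
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ("sample_id", "gene", "protein_change", "variant_class")
_NA_STRINGS = {"", "NA", "NaN", "nan", "na", "."}

__all__ = [
    "read_expression",
    "read_clinical",
    "read_mutations",
    "read_features",
    "read_gene_sets",
    "quantile_normalize",
    "preprocess_expression",
    "build_mutation_matrix",
    "build_feature_table",
    "align_samples",
    "allele_id",
]


def allele_id(gene: str, protein_change: str) -> str:
    """Canonical mutant-allele identifier, e.g. ``"PIK3CA:E545K"``."""
    return f"{gene}:{protein_change}"


def _read_table(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", compression="infer", dtype=str, **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ParseError(f"could not parse {path}: {exc}") from exc


def _to_numeric(frame: pd.DataFrame, path) -> np.ndarray:
    """Convert a string frame to floats, naming the first bad cell."""
    converted = frame.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = converted.isna() & frame.notna()
    # cells that were literal NA strings are also rejected: expression must be complete
    bad |= frame.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} at row "
            f"{frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    return converted.to_numpy(dtype=float)


def read_expression(path, orientation: str = "samples_by_genes") -> ExpressionMatrix:
    """Read an expression TSV into an :class:`ExpressionMatrix`.

    ``orientation`` says what the header row holds: ``"samples_by_genes"``
    (default; header = gene ids, rows = samples) or ``"genes_by_samples"``
    (header = sample ids, rows = genes).
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    with pd.io.common.get_handle(path, "r", compression="infer") as handle:
        header = handle.handle.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        what = "gene" if orientation == "samples_by_genes" else "sample"
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate {what} id(s) in {path}: {dupes[:5]}")
    frame = _read_table(path, index_col=0)
    values = _to_numeric(frame, path)
    if orientation == "genes_by_samples":
        frame = frame.T
        values = values.T
    return ExpressionMatrix(
        sample_ids=list(frame.index), gene_ids=list(frame.columns), values=values
    )


def read_clinical(path) -> ClinicalTable:
    frame = _read_table(path)
    for col in ("sample_id", "survival_time", "event"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    times = pd.to_numeric(frame["survival_time"], errors="coerce")
    events = pd.to_numeric(frame["event"], errors="coerce")
    if times.isna().any() or events.isna().any():
        row = int(np.argwhere((times.isna() | events.isna()).to_numpy())[0][0])
        raise ParseError(f"{path}: non-numeric survival entry at data row {row}")
    return ClinicalTable(
        sample_ids=list(frame["sample_id"]),
        survival_time=times.to_numpy(),
        event=events.to_numpy().astype(int),
    )


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-like mutation call table (one row per sample/allele)."""
    frame = _read_table(path)
    missing = [c for c in MUTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return frame[list(MUTATION_COLUMNS)]


def read_features(path) -> pd.DataFrame:
    """Read raw allele x feature scores; missing entries become NaN."""
    frame = _read_table(path, index_col=0, na_values=sorted(_NA_STRINGS), keep_default_na=False)
    return frame.apply(lambda col: pd.to_numeric(col, errors="raise"))


def read_gene_sets(path, uppercase: bool = True) -> GeneSetCollection:
    names: list[str] = []
    sets: dict[str, list[str]] = {}
    opener = pd.io.common.get_handle(path, "r", compression="infer")
    with opener as handle:
        for lineno, line in enumerate(handle.handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise ParseError(f"{path}: line {lineno}: expected name, description "
                                 "and at least one gene")
            name = fields[0]
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if uppercase:
                genes = [g.upper() for g in genes]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene-set name {name!r}")
            names.append(name)
            sets[name] = genes
    return GeneSetCollection(set_names=names, sets=sets, source=str(path))


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows (samples) to the mean order-statistic profile.

    Ties within a sample receive the mean of the reference quantiles their
    ranks span (tie-average dialect), so the result is invariant to the
    ordering of tied entries and idempotent.
    """
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    reference = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values)
    for i in range(n):
        order = np.argsort(values[i], kind="stable")
        sv = values[i][order]
        # boundaries of tie groups in the sorted row
        brk = np.flatnonzero(np.diff(sv) != 0) + 1
        starts = np.concatenate(([0], brk))
        ends = np.concatenate((brk, [g]))
        row_sorted = np.empty(g)
        csum = np.concatenate(([0.0], np.cumsum(reference)))
        for s, e in zip(starts, ends):
            row_sorted[s:e] = (csum[e] - csum[s]) / (e - s)
        out[i][order] = row_sorted
    return out


def preprocess_expression(
    em: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    log_transform: bool = True,
) -> ExpressionMatrix:
    """log2(v + pseudocount), quantile-normalize across samples, then subset genes.

    Gene subsetting happens after normalization so the normalized scale is
    defined by the full measured transcriptome, mirroring genome-wide
    normalization followed by restriction to a cancer-related gene panel.
    """
    values = em.values
    if log_transform:
        if np.any(values < 0):
            raise ValidationError("expression values must be >= 0 before log transform")
        values = np.log2(values + pseudocount)
    values = quantile_normalize(values)
    gene_ids = list(em.gene_ids)
    if gene_subset is not None:
        wanted = set(gene_subset)
        keep = [j for j, gid in enumerate(gene_ids) if gid in wanted]
        if not keep:
            raise ValidationError("gene_subset has empty intersection with measured genes")
        values = values[:, keep]
        gene_ids = [gene_ids[j] for j in keep]
    return ExpressionMatrix(
        sample_ids=list(em.sample_ids),
        gene_ids=gene_ids,
        values=values,
        preprocessed=True,
    )


def build_mutation_matrix(
    records: pd.DataFrame,
    min_recurrence: int = 2,
    sample_ids: Sequence[str] | None = None,
) -> MutationMatrix:
    """Collapse mutation calls to a binary sample x allele matrix.

    Alleles are distinct (gene, protein_change) pairs; duplicate
    (sample, allele) rows collapse to a single carrier; alleles carried by
    fewer than ``min_recurrence`` samples are dropped, reflecting the usual
    restriction to mutations recurring in the cohort.
    """
    for col in ("sample_id", "gene", "protein_change"):
        if col not in records.columns:
            raise ValidationError(f"mutation records missing column {col!r}")
        blank = records[col].isna() | (records[col].astype(str).str.strip() == "")
        if blank.any():
            raise ValidationError(
                f"mutation record {int(np.argwhere(blank.to_numpy())[0][0])} has "
                f"missing {col}"
            )
    recs = records.copy()
    if "variant_class" not in recs.columns:
        recs["variant_class"] = "unknown"
    recs["allele_id"] = [
        allele_id(g, p) for g, p in zip(recs["gene"], recs["protein_change"])
    ]
    recs = recs.drop_duplicates(subset=["sample_id", "allele_id"])

    counts = recs.groupby("allele_id")["sample_id"].nunique()
    kept = sorted(counts.index[counts >= min_recurrence])
    if sample_ids is None:
        samples = sorted(recs["sample_id"].unique())
    else:
        samples = list(sample_ids)
    sample_index = {s: i for i, s in enumerate(samples)}
    allele_index = {a: j for j, a in enumerate(kept)}

    values = np.zeros((len(samples), len(kept)), dtype=np.int8)
    for s, a in zip(recs["sample_id"], recs["allele_id"]):
        if a in allele_index and s in sample_index:
            values[sample_index[s], allele_index[a]] = 1

    meta_rows = []
    first = recs.drop_duplicates(subset=["allele_id"]).set_index("allele_id")
    for a in kept:
        meta_rows.append(
            {
                "gene": first.loc[a, "gene"],
                "protein_change": first.loc[a, "protein_change"],
                "variant_class": first.loc[a, "variant_class"],
                "count": int(values[:, allele_index[a]].sum()),
            }
        )
    meta = pd.DataFrame(meta_rows, index=pd.Index(kept, name="allele_id"))
    dropped = len(counts) - len(kept)
    if dropped:
        logger.info("dropped %d allele(s) below recurrence threshold %d", dropped, min_recurrence)
    return MutationMatrix(samples, kept, values, meta)


def build_feature_table(
    raw: pd.DataFrame,
    invert: Mapping[str, bool] | Iterable[str] = ("SIFT",),
) -> FeatureTable:
    """Impute, orient and standardize raw functional-impact scores.

    Missing entries (e.g. SIFT for indels) are imputed with the per-feature
    mean of the available values. Features listed in ``invert`` are scored
    low-raw = high-impact (SIFT convention) and flipped as ``1 - value``
    before standardization, so that in every standardized column larger
    means more damaging. Standardization is to mean 0, unit population
    variance.
    """
    if isinstance(invert, Mapping):
        invert_set = {k for k, v in invert.items() if v}
    else:
        invert_set = set(invert)
    values = raw.to_numpy(dtype=float).copy()
    missing = ~np.isfinite(values)
    for j, name in enumerate(raw.columns):
        col = values[:, j]
        ok = ~missing[:, j]
        if not ok.any():
            raise ValidationError(f"feature {name!r} has no observed values")
        col[~ok] = col[ok].mean()
        if name in invert_set:
            col = 1.0 - col
        mu = col.mean()
        sd = col.std()  # population (ddof=0)
        values[:, j] = (col - mu) / sd if sd > 0 else 0.0
    return FeatureTable(
        allele_ids=list(raw.index.astype(str)),
        feature_names=list(raw.columns.astype(str)),
        values=values,
        missing_mask=missing,
        standardized=True,
    )


def align_samples(
    em: ExpressionMatrix,
    mm: MutationMatrix,
    ct: ClinicalTable | None = None,
):
    """Restrict all tables to the shared samples, lexicographically ordered.

    Returns ``(em, mm)`` or ``(em, mm, ct)``; dropped samples are logged.
    """
    common = set(em.sample_ids) & set(mm.sample_ids)
    if ct is not None:
        common &= set(ct.sample_ids)
    if not common:
        raise ValidationError("no samples shared between the input tables")
    order = sorted(common)
    for name, ids in (("expression", em.sample_ids), ("mutation", mm.sample_ids)) + (
        (("clinical", ct.sample_ids),) if ct is not None else ()
    ):
        dropped = sorted(set(ids) - common)
        if dropped:
            logger.info("align_samples: dropping %d %s-only sample(s): %s%s",
                        len(dropped), name, dropped[:5], "..." if len(dropped) > 5 else "")
    out = (em.subset_samples(order), mm.subset_samples(order))
    if ct is not None:
        out = out + (ct.subset_samples(order),)
    return out
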