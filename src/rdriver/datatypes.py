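"""Model-ready data containers.

All containers are thin frozen views over numpy arrays with ordered,
unique identifier lists; heavy lifting (parsing, normalization) lives in
:mod:`rdriver.io`. Conventions:

* expression is samples x genes (``Y``; RPKM-like before preprocessing,
  log2 quantile-normalized after),
* mutations are samples x mutant alleles (``X``; binary), an allele being a
  distinct (gene, protein change) pair written ``"GENE:p.change"``,
* functional-impact features are alleles x features, impact-oriented and
  standardized after :func:`rdriver.io.build_feature_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "MutationMatrix",
    "FeatureTable",
    "ClinicalTable",
    "GeneSetCollection",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Samples x genes real-valued expression matrix."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample id")
        self.gene_ids = _check_unique(self.gene_ids, "gene id")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(sample_ids), list(self.gene_ids), self.values[idx], self.preprocessed
        )


@dataclass
class MutationMatrix:
    """Samples x mutant-allele binary design matrix with allele metadata.

    ``allele_meta`` is indexed by allele id and carries gene, protein_change,
    variant_class and the cohort count (number of carriers).
    """

    sample_ids: list[str]
    allele_ids: list[str]
    values: np.ndarray
    allele_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample id")
        self.allele_ids = _check_unique(self.allele_ids, "allele id")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sample_ids), len(self.allele_ids)):
            raise ValidationError("mutation matrix shape mismatch")
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1]).all():
            raise ValidationError("mutation matrix must be binary")
        self.values = self.values.astype(np.int8)
        if list(self.allele_meta.index) != self.allele_ids:
            raise ValidationError("allele_meta index must equal allele_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.allele_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MutationMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MutationMatrix(
            list(sample_ids),
            list(self.allele_ids),
            self.values[idx],
            self.allele_meta.copy(),
        )


@dataclass
class FeatureTable:
    """Alleles x features functional-impact scores.

    After :func:`rdriver.io.build_feature_table` the values are imputed,
    impact-oriented (larger = more damaging) and standardized to zero mean,
    unit (population) variance per feature; ``missing_mask`` records which
    raw entries were imputed.
    """

    allele_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.allele_ids = _check_unique(self.allele_ids, "allele id")
        self.feature_names = _check_unique(self.feature_names, "feature name")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.allele_ids), len(self.feature_names)):
            raise ValidationError("feature table shape mismatch")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.standardized and not np.all(np.isfinite(self.values)):
            raise ValidationError("standardized feature table contains non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.allele_ids, columns=self.feature_names)


@dataclass
class ClinicalTable:
    """Per-sample overall survival: time in months, event = 1 if death observed."""

    sample_ids: list[str]
    survival_time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample id")
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        self.event = np.asarray(self.event)
        if len(self.survival_time) != len(self.sample_ids) or len(self.event) != len(
            self.sample_ids
        ):
            raise ValidationError("clinical table length mismatch")
        if np.any(self.survival_time < 0) or not np.all(np.isfinite(self.survival_time)):
            raise ValidationError("survival times must be finite and >= 0")
        if not np.isin(np.unique(self.event), [0, 1]).all():
            raise ValidationError("event indicators must be 0/1")
        self.event = self.event.astype(np.int8)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ClinicalTable(list(sample_ids), self.survival_time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"survival_time": self.survival_time, "event": self.event},
            index=self.sample_ids,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), order-preserving."""

    set_names: list[str]
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        self.set_names = _check_unique(self.set_names, "gene-set name")
        for name in self.set_names:
            if name not in self.sets or len(self.sets[name]) == 0:
                raise ValidationError(f"gene set {name!r} is missing or empty")

    def __len__(self) -> int:
        return len(self.set_names)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]
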