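"""Synthetic cohorts with planted driver effects.

The generator emulates the five input tables — binary recurrent-mutation
matrix, expression matrix, functional-impact features, clinical survival
and gene sets — under the model's own generative reading: expression is a
sparse linear function of standardized mutation indicators plus Gaussian
noise. A known subset of alleles are drivers, each regulating a fixed
number of genes with effects of magnitude ``effect_size`` and random sign
(drivers both raise and lower expression in real tumors). Driver alleles
receive a positive mean shift on the impact-oriented features, emulating
the tendency of true drivers to look damaging to conservation/deleterious-
ness scores. Survival is exponential with log-hazard proportional to the
standardized true integrative prognostic score, with independent
exponential censoring tuned to the requested censoring fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    FeatureTable,
    GeneSetCollection,
    MutationMatrix,
)
from .errors import ValidationError
from . import io as rio
from .model import standardize_columns

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset",
           "simulate_null_dataset", "write_fixture", "read_fixture"]

_VARIANT_CLASSES = ("missense", "stop_gained", "splice", "in_frame", "silent", "indel")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the planted-recovery conditions used throughout the test
    suite: 200 samples, 200 genes, 50 recurrent alleles of which 5 are
    drivers each regulating 30 genes with unit effects against unit noise.
    """

    n_samples: int = 200
    n_genes: int = 200
    n_alleles: int = 50
    n_drivers: int = 5
    genes_per_driver: int = 30
    effect_size: float = 1.0
    noise_sd: float = 1.0
    allele_frequency: tuple[float, float] = (0.03, 0.2)
    n_features: int = 2
    feature_informativeness: float = 1.0
    baseline_hazard: float = 0.01        # events per month
    log_hazard_per_ips_sd: float = 0.5   # log hazard ratio per IPS standard deviation
    censoring_fraction: float = 0.3
    min_recurrence: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drivers > self.n_alleles:
            raise ValidationError("n_drivers cannot exceed n_alleles")
        if self.genes_per_driver > self.n_genes:
            raise ValidationError("genes_per_driver cannot exceed n_genes")
        if min(self.n_samples, self.n_genes, self.n_alleles, self.n_features) < 1:
            raise ValidationError("all counts must be positive")
        lo, hi = self.allele_frequency
        if not (0 < lo <= hi < 1):
            raise ValidationError("allele frequencies must lie in (0, 1)")


@dataclass
class SyntheticDataset:
    X: MutationMatrix
    Y: ExpressionMatrix
    F: FeatureTable
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    true_beta: np.ndarray              # alleles x genes
    true_driver: np.ndarray            # bool per allele
    raw_features: pd.DataFrame         # pre-imputation scores as written to disk
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore


def _draw_mutations(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli mutation indicators; every allele resampled until it has
    at least ``min_recurrence`` carriers (the recurrence filter holds by
    construction)."""
    freqs = rng.uniform(*cfg.allele_frequency, size=cfg.n_alleles)
    X = np.zeros((cfg.n_samples, cfg.n_alleles), dtype=np.int8)
    for k in range(cfg.n_alleles):
        for attempt in range(200):
            col = (rng.random(cfg.n_samples) < freqs[k]).astype(np.int8)
            if col.sum() >= cfg.min_recurrence and col.sum() < cfg.n_samples:
                X[:, k] = col
                break
        else:
            raise ValidationError(
                f"could not draw >= {cfg.min_recurrence} carriers at frequency "
                f"{freqs[k]:.3g} with n={cfg.n_samples}"
            )
    return X


def simulate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic cohort from ``cfg`` (byte-reproducible by seed)."""
    cfg = cfg or SimulationConfig()
    rng = substream(cfg.seed, "simulation")

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    gene_ids = [f"G{j:04d}" for j in range(cfg.n_genes)]

    Xv = _draw_mutations(cfg, rng)
    driver_idx = rng.choice(cfg.n_alleles, size=cfg.n_drivers, replace=False)
    true_driver = np.zeros(cfg.n_alleles, dtype=bool)
    true_driver[driver_idx] = True

    variant_class = rng.choice(_VARIANT_CLASSES, size=cfg.n_alleles)
    genes_of_allele = [f"MUT{k:03d}" for k in range(cfg.n_alleles)]
    allele_ids = [
        rio.allele_id(genes_of_allele[k], f"p.A{100 + k}{'V' if Xv[:, k].sum() % 2 else 'T'}")
        for k in range(cfg.n_alleles)
    ]
    meta = pd.DataFrame(
        {
            "gene": genes_of_allele,
            "protein_change": [a.split(":", 1)[1] for a in allele_ids],
            "variant_class": variant_class,
            "count": Xv.sum(axis=0).astype(int),
        },
        index=pd.Index(allele_ids, name="allele_id"),
    )

    true_beta = np.zeros((cfg.n_alleles, cfg.n_genes))
    for k in driver_idx:
        targets = rng.choice(cfg.n_genes, size=cfg.genes_per_driver, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.genes_per_driver)
        true_beta[k, targets] = signs * cfg.effect_size

    Xs, _ = standardize_columns(Xv.astype(float))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, cfg.n_genes))
    Yv = Xs @ true_beta + noise

    # impact-oriented latent feature scores; drivers shifted upward
    latent = rng.normal(0.0, 1.0, size=(cfg.n_alleles, cfg.n_features))
    latent[true_driver] += cfg.feature_informativeness
    raw = pd.DataFrame(index=pd.Index(allele_ids, name="allele_id"))
    raw["GERP"] = 2.0 * latent[:, 0]  # conservation-like, higher = more impact
    if cfg.n_features > 1:
        # SIFT-like tolerance score in (0,1), LOW = damaging; indels unscored
        sift = 1.0 / (1.0 + np.exp(latent[:, 1]))
        sift[np.asarray(variant_class) == "indel"] = np.nan
        if np.isfinite(sift).sum() == 0:
            sift[0] = 0.5
        raw["SIFT"] = sift
    for extra in range(2, cfg.n_features):
        raw[f"FIS{extra}"] = latent[:, extra]
    F = rio.build_feature_table(raw, invert=("SIFT",))

    # survival: exponential, log-hazard proportional to standardized true IPS
    ips = np.einsum("ij,ij->i", Xv @ true_beta, Yv)
    sd = ips.std()
    z = (ips - ips.mean()) / sd if sd > 0 else np.zeros_like(ips)
    hazard = cfg.baseline_hazard * np.exp(cfg.log_hazard_per_ips_sd * z)
    event_time = rng.exponential(1.0 / hazard)
    cf = min(max(cfg.censoring_fraction, 1e-9), 1 - 1e-9)
    cens_rate = hazard.mean() * cf / (1.0 - cf)
    cens_time = rng.exponential(1.0 / cens_rate, size=cfg.n_samples)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)

    # gene sets: one per driver (its regulated genes) plus random decoys
    names, sets = [], {}
    for d, k in enumerate(sorted(driver_idx)):
        members = [gene_ids[j] for j in np.flatnonzero(true_beta[k])]
        if members:
            names.append(f"DRIVER_TARGETS_{d}")
            sets[names[-1]] = members
    for d in range(3):
        members = [gene_ids[j] for j in rng.choice(cfg.n_genes,
                                                   size=min(25, cfg.n_genes), replace=False)]
        names.append(f"RANDOM_SET_{d}")
        sets[names[-1]] = members
    gene_sets = GeneSetCollection(set_names=names, sets=sets, source="synthetic")

    return SyntheticDataset(
        X=MutationMatrix(sample_ids, allele_ids, Xv, meta),
        Y=ExpressionMatrix(sample_ids, gene_ids, Yv, preprocessed=True),
        F=F,
        clinical=ClinicalTable(sample_ids, time, event),
        gene_sets=gene_sets,
        true_beta=true_beta,
        true_driver=true_driver,
        raw_features=raw,
        config=cfg,
    )


def simulate_null_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Same generator with zero drivers: expression independent of mutations."""
    cfg = cfg or SimulationConfig()
    null_cfg = SimulationConfig(**{**asdict(cfg), "n_drivers": 0})
    return simulate_dataset(null_cfg)


def write_fixture(ds: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the dataset in the exact dialects the readers consume.

    Emits expression.tsv (already on the model's log scale — see
    manifest.json), mutations.tsv (MAF-like long form), features.tsv (raw,
    with NA for unscored entries), clinical.tsv, gene_sets.gmt, a
    truth.tsv ground-truth sidecar, and manifest.json.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["expression"] = directory / "expression.tsv"
    ds.Y.to_frame().to_csv(paths["expression"], sep="\t", index_label="sample_id")

    rows = []
    meta = ds.X.allele_meta
    for k, allele in enumerate(ds.X.allele_ids):
        for i in np.flatnonzero(ds.X.values[:, k]):
            rows.append(
                {
                    "sample_id": ds.X.sample_ids[i],
                    "gene": meta.loc[allele, "gene"],
                    "protein_change": meta.loc[allele, "protein_change"],
                    "variant_class": meta.loc[allele, "variant_class"],
                }
            )
    paths["mutations"] = directory / "mutations.tsv"
    pd.DataFrame(rows).to_csv(paths["mutations"], sep="\t", index=False)

    paths["features"] = directory / "features.tsv"
    ds.raw_features.to_csv(paths["features"], sep="\t", na_rep="NA")

    paths["clinical"] = directory / "clinical.tsv"
    ds.clinical.to_frame().to_csv(paths["clinical"], sep="\t", index_label="sample_id")

    paths["gene_sets"] = directory / "gene_sets.gmt"
    with open(paths["gene_sets"], "w") as fh:
        for name in ds.gene_sets.set_names:
            genes = "\t".join(ds.gene_sets[name])
            fh.write(f"{name}\tsynthetic\t{genes}\n")

    paths["truth"] = directory / "truth.tsv"
    pd.DataFrame(
        {
            "allele": ds.X.allele_ids,
            "is_driver": ds.true_driver.astype(int),
            "n_regulated_genes": (ds.true_beta != 0).sum(axis=1),
        }
    ).to_csv(paths["truth"], sep="\t", index=False)

    paths["manifest"] = directory / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "expression_scale": "log",  # already log-scale and normalized
                "config": asdict(ds.config),
            },
            fh,
            indent=2,
        )
    return paths


def read_fixture(directory):
    """Load a written fixture back through the data_io readers.

    Returns ``(X, Y, F, clinical, gene_sets, truth_frame, manifest)``.
    """
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    Y = rio.read_expression(directory / "expression.tsv")
    records = rio.read_mutations(directory / "mutations.tsv")
    X = rio.build_mutation_matrix(
        records,
        min_recurrence=manifest["config"].get("min_recurrence", 2),
        sample_ids=Y.sample_ids,
    )
    F = rio.build_feature_table(rio.read_features(directory / "features.tsv"))
    clinical = rio.read_clinical(directory / "clinical.tsv")
    gene_sets = rio.read_gene_sets(directory / "gene_sets.gmt", uppercase=False)
    truth = pd.read_csv(directory / "truth.tsv", sep="\t")
    return X, Y, F, clinical, gene_sets, truth, manifest
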