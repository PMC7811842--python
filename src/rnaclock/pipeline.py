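"""End-to-end pipeline configuration and orchestration.

A :class:`PipelineConfig` carries every stage parameter with the
protocol defaults (2M-read sample filter, mean-50 gene filter, 30/70-year
age cutoffs, 10-fold x 2-repeat CV with tune length 5, [0, 110]-year
clamp, importance threshold 1, learning-curve sizes
{50, 100, 250, 500, 1000, 3000} with 9 repeats).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import qc
from .batch_correct import fit_combat
from .clock import (
    CLAMP_BOUNDS,
    DEFAULT_TREES,
    IMPORTANCE_THRESHOLD,
    ClockModel,
    mtry_grid,
    train_clock,
)
from .errors import ConfigError
from .features import (
    GeneSet,
    differential_expression,
    top_differential_genes,
    top_variable_genes,
)
from .normalize import NormalizedMatrix, normalize_log2, tmm_factors


@dataclass
class PipelineConfig:
    """Stage parameters for a full raw-counts -> trained-clock run."""

    min_total: float = float(qc.MIN_TOTAL_READS)
    min_mean: float = qc.MIN_MEAN_COUNT
    pseudo: float = 1.0
    young_cutoff: float = qc.YOUNG_CUTOFF
    older_cutoff: float = qc.OLDER_CUTOFF
    gene_set_kind: str = "variable"      # or "differential"
    gene_set_size: int = 1000
    folds: int = 10
    repeats: int = 2
    tune_length: int = 5
    trees: int = DEFAULT_TREES
    clamp: tuple[float, float] = CLAMP_BOUNDS
    importance_threshold: float = IMPORTANCE_THRESHOLD
    subsample_sizes: tuple[int, ...] = (50, 100, 250, 500, 1000, 3000)
    n_repeats: int = 9
    batch_correct: bool = True
    health_filter: str | None = None     # e.g. "healthy"
    sex_filter: str | None = None
    tissue_filter: str | None = None
    adults_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_set_kind not in ("variable", "differential"):
            raise ConfigError("gene_set_kind must be 'variable' or 'differential'")
        if self.folds < 2 or self.repeats < 1 or self.tune_length < 1:
            raise ConfigError("folds >= 2, repeats >= 1, tune_length >= 1 required")
        if self.gene_set_size < 1 or self.trees < 1 or self.n_repeats < 1:
            raise ConfigError("gene_set_size, trees, n_repeats must be positive")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("clamp", "subsample_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, sort_keys=True)


def filter_cohort(meta: pd.DataFrame, config: PipelineConfig) -> pd.Index:
    """Sample ids passing the configured cohort filters."""
    keep = pd.Series(True, index=meta.index)
    if config.health_filter:
        keep &= meta["health"] == config.health_filter
    if config.sex_filter:
        keep &= meta["sex"] == config.sex_filter
    if config.tissue_filter:
        keep &= meta["tissue"] == config.tissue_filter
    if config.adults_only:
        keep &= meta["age"] >= config.young_cutoff
    return meta.index[keep]


def preprocess(
    counts: pd.DataFrame, meta: pd.DataFrame, config: PipelineConfig
) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """QC filters -> TMM -> log2 CPM -> (optionally) batch correction."""
    kept_counts, kept_meta = qc.apply_qc(
        counts, meta, min_total=config.min_total, min_mean=config.min_mean
    )
    sel = filter_cohort(kept_meta, config)
    kept_counts, kept_meta = kept_counts[sel], kept_meta.loc[sel]
    factors = tmm_factors(kept_counts)
    norm = normalize_log2(kept_counts, factors, pseudo=config.pseudo)
    if config.batch_correct:
        norm, _ = fit_combat(norm, kept_meta)
    return norm, kept_meta


def select_genes(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
) -> GeneSet:
    """The configured gene set: top-K variable (corrected) genes, or top-K
    differential genes between the adult and older groups (which needs the
    raw ``counts``)."""
    k = min(config.gene_set_size, norm.values.shape[0])
    if config.gene_set_kind == "variable":
        return top_variable_genes(norm, k)
    if counts is None:
        raise ConfigError("differential gene selection needs raw counts")
    result = differential_expression(counts[norm.samples], meta)
    return top_differential_genes(result, k)


def fit_pipeline_clock(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[ClockModel, NormalizedMatrix, pd.DataFrame]:
    """Full pipeline: preprocess, select genes, train the clock."""
    norm, kept_meta = preprocess(counts, meta, config)
    gene_set = select_genes(norm, kept_meta, config, counts=counts)
    grid = mtry_grid(max(len(gene_set), 2), config.tune_length)
    model = train_clock(
        norm,
        kept_meta["age"],
        gene_set=gene_set,
        folds=config.folds,
        repeats=config.repeats,
        grid=grid,
        trees=config.trees,
        seed=config.seed,
        descriptor={
            "gene_set": config.gene_set_kind,
            "k": len(gene_set),
            "health": config.health_filter,
            "sex": config.sex_filter,
            "tissue": config.tissue_filter,
        },
    )
    return model, norm, kept_meta
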