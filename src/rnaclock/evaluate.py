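"""Model evaluation: metrics, leave-one-batch-out curation, subsampling
learning curves, cross-cohort transfer, and important-gene overlaps.

Leave-one-batch-out (LOBO) curation compares the cross-validated
performance of the full-cohort clock to clocks retrained with each batch
held out; a batch is flagged for removal only when dropping it improves
RMSE, MAE, and R-squared simultaneously (strictly). The default is a
single evaluation pass against the all-batches baseline; a sequential
greedy mode re-baselines after each removal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clock import ClockModel, ImportanceTable, predict_age, train_clock
from .errors import PreconditionError
from .features import top_variable_genes
from .normalize import NormalizedMatrix
from .pipeline import PipelineConfig, fit_pipeline_clock


@dataclass
class MetricTriple:
    """RMSE (years), R-squared, MAE (years)."""

    rmse: float
    r2: float
    mae: float

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "mae": self.mae}


@dataclass
class CurationReport:
    baseline: MetricTriple
    per_batch: dict[str, MetricTriple]
    removed: list[str]
    rule: str = "remove batch iff its removal strictly improves RMSE, MAE and R2"
    mode: str = "single_pass"

    def to_frame(self) -> pd.DataFrame:
        rows = {"baseline": self.baseline.as_dict()}
        rows.update({b: m.as_dict() for b, m in self.per_batch.items()})
        df = pd.DataFrame(rows).T
        df["removed"] = [b in self.removed for b in df.index]
        return df


@dataclass
class LearningCurve:
    table: pd.DataFrame  # index n; columns mean_rmse, sd_rmse, mean_r2, sd_r2
    n_repeats: int
    splits: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)


def compute_metrics(
    predicted: np.ndarray | pd.Series,
    observed: np.ndarray | pd.Series,
    r2_mode: str = "pearson",
) -> MetricTriple:
    """RMSE, R2 (squared Pearson correlation by default) and MAE.

    R2 is reported as NaN when the observed ages are constant (undefined).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 2:
        raise PreconditionError("predicted/observed must be equal-length vectors, n >= 2")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    mae = float(np.mean(np.abs(obs - pred)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        r2 = float("nan")
    elif r2_mode == "pearson":
        r2 = float(stats.pearsonr(obs, pred)[0] ** 2)
    else:
        r2 = float(1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2))
    return MetricTriple(rmse=rmse, r2=r2, mae=mae)


def _cv_metrics(model: ClockModel) -> MetricTriple:
    row = model.cv.chosen_row
    return MetricTriple(
        rmse=float(row["mean_rmse"]), r2=float(row["mean_r2"]), mae=float(row["mean_mae"])
    )


def decide_removals(
    baseline: MetricTriple,
    per_batch: dict[str, MetricTriple],
    invert: bool = False,
) -> list[str]:
    """Batches whose removal strictly improves all three metrics (or, with
    ``invert``, every other batch — the complement)."""
    removed = [
        b
        for b, m in per_batch.items()
        if m.rmse < baseline.rmse and m.mae < baseline.mae and m.r2 > baseline.r2
    ]
    if invert:
        return [b for b in per_batch if b not in removed]
    return removed


def lobo_curation(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    config: PipelineConfig,
    mode: str = "single_pass",
    invert: bool = False,
) -> CurationReport:
    """Leave-one-batch-out curation of a multi-batch cohort.

    Baseline = cross-validated metrics of the full pipeline on all
    batches; for each batch the pipeline (normalize -> correct -> select
    -> train) is rerun without it.
    """
    batches = meta["batch"].astype(str)
    levels = sorted(batches.unique())
    if len(levels) < 3:
        raise PreconditionError(f"LOBO needs >= 3 batches, got {len(levels)}")
    if mode not in ("single_pass", "sequential"):
        raise PreconditionError(f"unknown LOBO mode {mode!r}")

    def run(sample_ids) -> MetricTriple:
        model, _, _ = fit_pipeline_clock(
            counts[sample_ids], meta.loc[sample_ids], config
        )
        return _cv_metrics(model)

    baseline = run(meta.index)
    per_batch = {}
    for b in levels:
        keep = meta.index[batches != b]
        per_batch[b] = run(keep)
    removed = decide_removals(baseline, per_batch, invert=invert)

    if mode == "sequential" and not invert:
        removed = []
        current = baseline
        remaining = list(levels)
        while True:
            candidates = {
                b: m
                for b, m in per_batch.items()
                if b in remaining
                and m.rmse < current.rmse
                and m.mae < current.mae
                and m.r2 > current.r2
            }
            if not candidates:
                break
            worst = min(candidates, key=lambda b: candidates[b].rmse)
            removed.append(worst)
            remaining.remove(worst)
            keep = meta.index[~batches.isin(removed)]
            current = run(keep)
            per_batch.update(
                {
                    b: run(meta.index[~batches.isin(removed + [b])])
                    for b in remaining
                }
            )
    return CurationReport(
        baseline=baseline, per_batch=per_batch, removed=removed, mode=mode
    )


def learning_curve(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    sizes: tuple[int, ...] | list[int],
    n_repeats: int = 9,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> LearningCurve:
    """Accuracy as a function of training-set size.

    The cohort is preprocessed once; at each size n and repeat, n samples
    are drawn uniformly without replacement for training (gene selection is
    redone on the training subset) and the model predicts all remaining
    samples.
    """
    config = config or PipelineConfig()
    from .pipeline import preprocess

    norm, kept_meta = preprocess(counts, meta, config)
    total = norm.values.shape[1]
    sizes = sorted(int(s) for s in sizes)
    if sizes[0] < 1 or sizes[-1] >= total:
        raise PreconditionError(
            f"subsample sizes must be in [1, {total - 1}], got {sizes}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    splits = []
    for n in sizes:
        rmses, r2s = [], []
        for _ in range(n_repeats):
            train_idx = rng.choice(total, size=n, replace=False)
            mask = np.zeros(total, dtype=bool)
            mask[train_idx] = True
            train_cols = norm.samples[mask]
            test_cols = norm.samples[~mask]
            splits.append((n, np.where(mask)[0], np.where(~mask)[0]))
            train_mat = NormalizedMatrix(
                values=norm.values[train_cols], provenance=norm.provenance
            )
            k = min(config.gene_set_size, train_mat.values.shape[0])
            gene_set = top_variable_genes(train_mat, k)
            model = train_clock(
                train_mat,
                kept_meta.loc[train_cols, "age"],
                gene_set=gene_set,
                folds=min(config.folds, max(2, n // 2)),
                repeats=config.repeats,
                trees=config.trees,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            pred = predict_age(
                model,
                NormalizedMatrix(
                    values=norm.values[test_cols], provenance=norm.provenance
                ),
            )
            m = compute_metrics(pred, kept_meta.loc[test_cols, "age"])
            rmses.append(m.rmse)
            r2s.append(m.r2)
        rows.append(
            {
                "n": n,
                "mean_rmse": float(np.mean(rmses)),
                "sd_rmse": float(np.std(rmses, ddof=1)) if n_repeats > 1 else 0.0,
                "mean_r2": float(np.nanmean(r2s)),
                "sd_r2": float(np.nanstd(r2s, ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    return LearningCurve(
        table=pd.DataFrame(rows).set_index("n"), n_repeats=n_repeats, splits=splits
    )


def transfer_evaluate(
    model: ClockModel,
    cohort_b: NormalizedMatrix,
    ages_b: pd.Series,
    pathway_matched: bool = True,
) -> tuple[MetricTriple, dict]:
    """Metrics of a trained clock on another cohort's (processed) matrix.

    ``pathway_matched`` records whether cohort B went through the same
    normalization/correction pathway as the training cohort; a mismatch
    (e.g. uncorrected data under a corrected-trained model) is a deliberate
    experimental condition, not an error.
    """
    pred = predict_age(model, cohort_b)
    metrics = compute_metrics(pred, ages_b.loc[pred.index])
    record = {
        "pathway_matched": bool(pathway_matched),
        "provenance": cohort_b.provenance
        if isinstance(cohort_b, NormalizedMatrix)
        else "unknown",
        "n": int(len(pred)),
    }
    return metrics, record


def importance_overlap(
    tables: list[ImportanceTable], labels: list[str] | None = None
) -> dict[tuple[str, ...], int]:
    """Counts of flagged-important genes in every intersection/difference
    region across the given importance tables (Venn-region counts).

    Keys are tuples of the labels whose sets the region belongs to; the
    key ("A",) counts genes important in A only, ("A", "B") in exactly A
    and B, etc.
    """
    if len(tables) < 2:
        raise PreconditionError("overlap needs >= 2 importance tables")
    labels = labels or [f"T{i}" for i in range(len(tables))]
    sets = {lab: set(t.flagged()) for lab, t in zip(labels, tables)}
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            region = set.intersection(*(sets[l] for l in combo))
            for other in labels:
                if other not in combo:
                    region -= sets[other]
            out[combo] = len(region)
    return out
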