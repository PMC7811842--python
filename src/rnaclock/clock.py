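"""Random-forest transcriptomic age clock.

Training follows the meta-analysis protocol: per-gene standardization on
the full training set, repeated 10-fold cross-validation (two repeats)
over a 5-value mtry grid, one-standard-error model selection on RMSE,
refit on all data, predictions clamped to [0, 110] years. R-squared is
the squared Pearson correlation between observed and predicted ages
(the resampling-framework convention); the coefficient of determination
is available as an option. Variable importance is out-of-bag permutation
importance: per tree, the increase in OOB mean squared error after
permuting one feature, averaged over trees and divided by its standard
error; genes with a score above 1 are flagged important.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .errors import GeneMismatchError, PreconditionError, ValidationError
from .features import GeneSet
from .normalize import NormalizedMatrix

CLAMP_BOUNDS = (0.0, 110.0)
DEFAULT_TREES = 500
IMPORTANCE_THRESHOLD = 1.0


def mtry_grid(p: int, length: int = 5) -> list[int]:
    """Candidate mtry values for p features: ``length`` values floored to
    integers, linearly spaced from 2 to p when p < 500, geometrically
    spaced otherwise; deduplicated ascending.

    Reproduces the printed tuning grids: {2, 9, 44, 211, 1000} at p=1000
    and {2, 26, 51, 75, 100} at p=100.
    """
    if p < 2:
        raise PreconditionError(f"mtry grid needs p >= 2, got {p}")
    if p < 500:
        vals = np.linspace(2, p, length)
    else:
        vals = np.exp(np.linspace(np.log(2), np.log(p), length))
    # nudge before flooring: the spaced endpoints are exact in intent
    # (2 and p) but not always in floating point
    grid = sorted(set(int(v) for v in np.floor(vals + 1e-9)))
    return grid


@dataclass
class CVResult:
    """Resampling summary per candidate mtry plus the one-SE choice."""

    table: pd.DataFrame  # index mtry; columns mean_rmse, se_rmse, mean_r2, mean_mae
    chosen_mtry: int
    folds: int
    repeats: int
    seed: int

    @property
    def chosen_row(self) -> pd.Series:
        return self.table.loc[self.chosen_mtry]


@dataclass
class ClockModel:
    """A trained age clock: gene list, fit-time scaling, forest, clamp."""

    genes: list[str]
    center: pd.Series
    scale: pd.Series
    forest: object                      # fitted regressor
    cv: CVResult | None
    clamp: tuple[float, float] = CLAMP_BOUNDS
    seed: int = 0
    trees: int = DEFAULT_TREES
    descriptor: dict = field(default_factory=dict)
    train_X: np.ndarray | None = None   # scaled, samples x genes (OOB bookkeeping)
    train_y: np.ndarray | None = None


@dataclass
class ImportanceTable:
    """OOB permutation importance per gene: mean dMSE / SE(dMSE)."""

    table: pd.DataFrame  # index gene_id; columns score, important
    threshold: float = IMPORTANCE_THRESHOLD

    def flagged(self) -> list[str]:
        return self.table.index[self.table["important"]].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _as_feature_frame(
    X: NormalizedMatrix | pd.DataFrame, gene_set: GeneSet | list[str] | None
) -> pd.DataFrame:
    """Genes x samples -> samples x genes, optionally restricted."""
    values = X.values if isinstance(X, NormalizedMatrix) else X
    if gene_set is not None:
        genes = list(gene_set)
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise GeneMismatchError(f"genes absent from matrix: {missing[:10]}")
        values = values.loc[genes]
    return values.T


def _metrics(obs: np.ndarray, pred: np.ndarray, r2_mode: str) -> tuple[float, float, float]:
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    mae = float(np.mean(np.abs(obs - pred)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        r2 = np.nan
    elif r2_mode == "pearson":
        r2 = float(stats.pearsonr(obs, pred)[0] ** 2)
    else:  # coefficient of determination
        r2 = float(1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2))
    return rmse, r2, mae


def select_one_se(cv: CVResult | pd.DataFrame) -> int:
    """Smallest mtry whose mean RMSE is within one standard error of the
    best model's mean RMSE (the one-SE rule; smaller mtry = simpler)."""
    table = cv.table if isinstance(cv, CVResult) else cv
    if len(table) == 0:
        raise PreconditionError("empty CV table")
    best = table["mean_rmse"].idxmin()
    threshold = table.loc[best, "mean_rmse"] + table.loc[best, "se_rmse"]
    ok = table.index[table["mean_rmse"] <= threshold]
    return int(min(ok))


def train_clock(
    X: NormalizedMatrix | pd.DataFrame,
    ages: pd.Series,
    gene_set: GeneSet | list[str] | None = None,
    folds: int = 10,
    repeats: int = 2,
    grid: list[int] | None = None,
    trees: int = DEFAULT_TREES,
    seed: int = 0,
    r2_mode: str = "pearson",
    descriptor: dict | None = None,
) -> ClockModel:
    """Train the age clock with repeated k-fold CV and one-SE selection.

    ``X`` is a normalized (typically batch-corrected) genes x samples
    matrix; ``ages`` is a sample -> years Series covering its columns.
    Deterministic given ``seed`` (fold splits, forests).
    """
    feats = _as_feature_frame(X, gene_set)
    ages = ages.loc[feats.index].astype(float)
    n = len(feats)
    if n < folds:
        raise PreconditionError(f"{n} samples < {folds} folds")
    if ((ages < CLAMP_BOUNDS[0]) | (ages > CLAMP_BOUNDS[1])).any():
        raise ValidationError("ages outside [0, 110]")
    if ages.nunique() < 2:
        raise PreconditionError("ages are constant; age regression is undefined")

    center = feats.mean(axis=0)
    scale = feats.std(axis=0, ddof=1)
    constant = scale.index[scale == 0].tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant gene(s): {constant[:5]}",
            stacklevel=2,
        )
        feats = feats.drop(columns=constant)
        center = center.drop(constant)
        scale = scale.drop(constant)
    Z = ((feats - center) / scale).to_numpy(dtype=float)
    y = ages.to_numpy(dtype=float)
    p = Z.shape[1]
    if grid is None:
        grid = mtry_grid(p) if p >= 2 else [1]
    grid = sorted({min(m, p) for m in grid})

    splitter = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(splitter.split(Z))
    rows = []
    for m in grid:
        rmses, r2s, maes = [], [], []
        for train_idx, test_idx in splits:
            rf = RandomForestRegressor(
                n_estimators=trees, max_features=m, random_state=seed, n_jobs=1
            )
            rf.fit(Z[train_idx], y[train_idx])
            pred = np.clip(rf.predict(Z[test_idx]), *CLAMP_BOUNDS)
            rmse, r2, mae = _metrics(y[test_idx], pred, r2_mode)
            rmses.append(rmse)
            r2s.append(r2)
            maes.append(mae)
        rows.append(
            {
                "mtry": m,
                "mean_rmse": float(np.mean(rmses)),
                "se_rmse": float(np.std(rmses, ddof=1) / np.sqrt(len(rmses)))
                if len(rmses) > 1
                else 0.0,
                "mean_r2": float(np.nanmean(r2s)),
                "mean_mae": float(np.mean(maes)),
            }
        )
    table = pd.DataFrame(rows).set_index("mtry")
    cv = CVResult(table=table, chosen_mtry=0, folds=folds, repeats=repeats, seed=seed)
    cv.chosen_mtry = select_one_se(cv)

    final = RandomForestRegressor(
        n_estimators=trees, max_features=cv.chosen_mtry, random_state=seed, n_jobs=1
    )
    final.fit(Z, y)
    return ClockModel(
        genes=feats.columns.tolist(),
        center=center,
        scale=scale,
        forest=final,
        cv=cv,
        clamp=CLAMP_BOUNDS,
        seed=seed,
        trees=trees,
        descriptor=descriptor or {},
        train_X=Z,
        train_y=y,
    )


def predict_age(
    model: ClockModel, corrected: NormalizedMatrix | pd.DataFrame
) -> pd.Series:
    """Predict ages (years) for the columns of a normalized matrix,
    standardized with the model's stored center/scale and clamped."""
    values = corrected.values if isinstance(corrected, NormalizedMatrix) else corrected
    missing = [g for g in model.genes if g not in values.index]
    if missing:
        raise GeneMismatchError(
            f"{len(missing)} model gene(s) absent from input: {missing[:10]}"
        )
    feats = values.loc[model.genes].T
    if not np.isfinite(feats.to_numpy(dtype=float)).all():
        raise ValidationError("non-finite expression values in prediction input")
    Z = ((feats - model.center) / model.scale).to_numpy(dtype=float)
    raw = np.asarray(model.forest.predict(Z), dtype=float)
    return pd.Series(np.clip(raw, *model.clamp), index=feats.index, name="predicted_age")


def _oob_indices_per_tree(forest: RandomForestRegressor, n_samples: int) -> list[np.ndarray]:
    """Out-of-bag sample indices for each tree of a fitted forest."""
    try:
        import inspect

        from sklearn.ensemble._forest import (
            _generate_unsampled_indices,
            _get_n_samples_bootstrap,
        )

        if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
            n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples, None)
            return [
                _generate_unsampled_indices(tree.random_state, n_samples, n_boot, None)
                for tree in forest.estimators_
            ]
        n_boot = _get_n_samples_bootstrap(n_samples, forest.max_samples)
        return [
            _generate_unsampled_indices(tree.random_state, n_samples, n_boot)
            for tree in forest.estimators_
        ]
    except ImportError:  # re-derive the bootstrap draw directly
        out = []
        for tree in forest.estimators_:
            rng = np.random.RandomState(tree.random_state)
            sampled = rng.randint(0, n_samples, n_samples)
            mask = np.ones(n_samples, dtype=bool)
            mask[sampled] = False
            out.append(np.where(mask)[0])
        return out


def importance(model: ClockModel, seed: int | None = None) -> ImportanceTable:
    """OOB permutation importance.

    For each tree: MSE on its out-of-bag samples, recomputed after
    permuting one feature among those samples; the per-tree MSE increases
    are averaged over trees and divided by their standard error. Trees
    with no OOB samples are skipped with a warning.
    """
    if model.train_X is None or model.train_y is None:
        raise PreconditionError("model was fitted without OOB bookkeeping")
    X, y = model.train_X, model.train_y
    n, p = X.shape
    rng = np.random.default_rng(model.seed if seed is None else seed)
    oob = _oob_indices_per_tree(model.forest, n)
    deltas = [[] for _ in range(p)]
    skipped = 0
    for tree, idx in zip(model.forest.estimators_, oob):
        if len(idx) == 0:
            skipped += 1
            continue
        Xo, yo = X[idx], y[idx]
        base_mse = np.mean((tree.predict(Xo) - yo) ** 2)
        for j in range(p):
            perm = rng.permutation(len(idx))
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            deltas[j].append(np.mean((tree.predict(Xp) - yo) ** 2) - base_mse)
    if skipped:
        warnings.warn(f"{skipped} tree(s) had no OOB samples and were skipped",
                      stacklevel=2)
    scores = np.zeros(p)
    for j in range(p):
        d = np.asarray(deltas[j])
        if len(d) < 2:
            scores[j] = 0.0
            continue
        se = np.std(d, ddof=1) / np.sqrt(len(d))
        scores[j] = d.mean() / se if se > 0 else 0.0
    table = pd.DataFrame(
        {"score": scores, "important": scores > IMPORTANCE_THRESHOLD},
        index=pd.Index(model.genes, name="gene_id"),
    )
    return ImportanceTable(table=table)


def save_clock(model: ClockModel, directory) -> None:
    """Serialize a clock as a directory: JSON manifest + CV table TSV +
    opaque forest blob."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "genes": model.genes,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "clamp": list(model.clamp),
        "seed": model.seed,
        "trees": model.trees,
        "descriptor": model.descriptor,
        "chosen_mtry": model.cv.chosen_mtry if model.cv else None,
        "cv": {
            "folds": model.cv.folds,
            "repeats": model.cv.repeats,
            "seed": model.cv.seed,
        }
        if model.cv
        else None,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if model.cv is not None:
        model.cv.table.to_csv(d / "cv_table.tsv", sep="\t")
    joblib.dump(
        {"forest": model.forest, "train_X": model.train_X, "train_y": model.train_y},
        d / "forest.joblib",
    )


def load_clock(directory) -> ClockModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    blob = joblib.load(d / "forest.joblib")
    cv = None
    if manifest.get("cv") is not None:
        table = pd.read_csv(d / "cv_table.tsv", sep="\t", index_col=0)
        cv = CVResult(
            table=table,
            chosen_mtry=int(manifest["chosen_mtry"]),
            folds=manifest["cv"]["folds"],
            repeats=manifest["cv"]["repeats"],
            seed=manifest["cv"]["seed"],
        )
    genes = manifest["genes"]
    return ClockModel(
        genes=genes,
        center=pd.Series(manifest["center"], index=genes),
        scale=pd.Series(manifest["scale"], index=genes),
        forest=blob["forest"],
        cv=cv,
        clamp=tuple(manifest["clamp"]),
        seed=manifest["seed"],
        trees=manifest["trees"],
        descriptor=manifest.get("descriptor", {}),
        train_X=blob.get("train_X"),
        train_y=blob.get("train_y"),
    )
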