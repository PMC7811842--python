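"""Parametric empirical-Bayes batch-effect correction (location/scale model).

Each gene g in batch i is modeled on the log2 scale as

    Y_gij = alpha_g + X beta_g + gamma_ig + delta_ig * eps_gij

with eps ~ N(0, sigma_g^2). Genes are standardized by their grand mean and
pooled variance, per-batch location (gamma) and scale (delta) effects are
estimated on the standardized data, batch-level priors (normal for gamma,
inverse-gamma for delta) are fitted by method of moments across genes, and
the coupled posterior updates are iterated to a fixed point. The
shrunken effects are removed and the data back-transformed.

``project_new_batch`` appends user samples to a reference cohort as one
extra batch and re-runs the normalization + correction pathway on the
union, mirroring how an online age-prediction service folds uploads into
its training compendium.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeneMismatchError, PreconditionError, SingletonBatchError
from .normalize import BATCH_CORRECTED, NormalizedMatrix, normalize_log2, tmm_factors


@dataclass
class BatchModel:
    """Fitted batch-correction model (for audit and serialization)."""

    grand_mean: pd.Series            # per-gene alpha (plus covariate effects folded out)
    pooled_var: pd.Series            # per-gene sigma^2
    gamma_star: pd.DataFrame         # batch x gene EB-shrunk location (log2 units)
    delta_star: pd.DataFrame         # batch x gene EB-shrunk variance ratio
    hyper: pd.DataFrame              # per-batch: gamma_bar, tau2, a_prior, b_prior
    batch_sizes: pd.Series
    zero_variance_genes: list[str] = field(default_factory=list)
    n_iter: pd.Series | None = None

    def to_json(self, path) -> None:
        obj = {
            "batches": self.batch_sizes.index.tolist(),
            "batch_sizes": self.batch_sizes.tolist(),
            "genes": self.grand_mean.index.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": self.gamma_star.to_numpy().tolist(),
            "delta_star": self.delta_star.to_numpy().tolist(),
            "hyper": self.hyper.to_dict(orient="index"),
            "zero_variance_genes": self.zero_variance_genes,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def _eb_fixed_point(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the coupled posterior-mean updates for one batch.

    z_batch: standardized data restricted to the batch (genes x n_i).
    """
    n_i = z_batch.shape[1]
    g = gamma_hat.copy()
    d = delta_hat.copy()
    for it in range(max_iter):
        g_new = (n_i * tau2 * gamma_hat + d * gamma_bar) / (n_i * tau2 + d)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (2 * b + sum2) / (n_i + 2 * a - 2)
        change = max(np.abs(g_new - g).max(), np.abs(d_new - d).max())
        g, d = g_new, d_new
        if change < tol:
            return g, d, it + 1
    return g, d, max_iter


def fit_combat(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    mean_only: bool = False,
) -> tuple[NormalizedMatrix, BatchModel]:
    """Correct batch effects in a normalized matrix.

    ``meta`` must carry a ``batch`` column covering every sample. By
    default the standardization design contains only the intercept (no
    protected biological covariates); pass a numeric ``covariates`` frame
    (samples x covariates) to shield effects from removal. With
    ``mean_only`` the scale effects are fixed at one and locations are not
    shrunk, which reduces to per-batch mean-centering plus the grand mean.
    """
    Y = norm.values
    if not np.isfinite(Y.to_numpy()).all():
        raise PreconditionError("non-finite values in input matrix")
    missing = Y.columns.difference(meta.index)
    if len(missing):
        raise PreconditionError(f"metadata missing sample(s): {missing.tolist()}")
    batch = meta.loc[Y.columns, "batch"].astype(str)
    levels = batch.unique().tolist()
    if len(levels) < 2:
        raise PreconditionError(
            "batch correction needs >=2 batches; got " + repr(levels)
        )
    sizes = batch.value_counts().reindex(levels)
    singletons = sizes.index[sizes < 2].tolist()
    if singletons:
        raise SingletonBatchError(singletons)

    y = Y.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    onehot = pd.get_dummies(batch)[levels].to_numpy(dtype=float)
    design = onehot
    if covariates is not None:
        cov = covariates.loc[Y.columns].to_numpy(dtype=float)
        design = np.hstack([onehot, cov])

    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (params x genes)
    n_batches = len(levels)
    batch_means = beta[:n_batches, :]                     # per-batch gene means
    props = sizes.to_numpy(dtype=float) / n_samples
    grand = props @ batch_means                           # per-gene grand mean

    resid = y - (design @ beta).T
    pooled = (resid**2).mean(axis=1)
    zero_var = pooled <= 1e-12
    zero_genes = Y.index[zero_var].tolist()
    pooled_safe = np.where(zero_var, 1.0, pooled)

    stand_mean = np.tile(grand[:, None], (1, n_samples))
    if covariates is not None:
        stand_mean = stand_mean + (design[:, n_batches:] @ beta[n_batches:, :]).T
    z = (y - stand_mean) / np.sqrt(pooled_safe)[:, None]

    gamma_star = np.zeros((n_batches, n_genes))
    delta_star = np.ones((n_batches, n_genes))
    hyper_rows = []
    iters = []
    corrected_z = z.copy()
    for i, lev in enumerate(levels):
        idx = np.where((batch == lev).to_numpy())[0]
        zb = z[:, idx]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1))
        m = float(delta_hat.mean())
        s2 = float(delta_hat.var(ddof=1))
        if s2 > 0:
            a = (2 * s2 + m**2) / s2
            b = (m * s2 + m**3) / s2
        else:  # degenerate spread of scale estimates: flat-ish prior at m
            a, b = 2.0 + 1e-8, m
        if mean_only:
            g_i, d_i, it = gamma_hat, np.ones(n_genes), 0
        else:
            g_i, d_i, it = _eb_fixed_point(
                zb, gamma_hat, delta_hat, gamma_bar, tau2, a, b
            )
        gamma_star[i], delta_star[i] = g_i, d_i
        hyper_rows.append((gamma_bar, tau2, a, b))
        iters.append(it)
        corrected_z[:, idx] = (zb - g_i[:, None]) / np.sqrt(d_i)[:, None]

    corrected = corrected_z * np.sqrt(pooled_safe)[:, None] + stand_mean
    corrected[zero_var, :] = y[zero_var, :]  # flagged, left untouched

    model = BatchModel(
        grand_mean=pd.Series(grand, index=Y.index, name="grand_mean"),
        pooled_var=pd.Series(pooled, index=Y.index, name="pooled_var"),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=Y.index),
        delta_star=pd.DataFrame(delta_star, index=levels, columns=Y.index),
        hyper=pd.DataFrame(
            hyper_rows, index=levels, columns=["gamma_bar", "tau2", "a_prior", "b_prior"]
        ),
        batch_sizes=sizes,
        zero_variance_genes=zero_genes,
        n_iter=pd.Series(iters, index=levels, name="n_iter"),
    )
    out = NormalizedMatrix(
        values=pd.DataFrame(corrected, index=Y.index, columns=Y.columns),
        provenance=BATCH_CORRECTED,
    )
    return out, model


NEW_BATCH_LABEL = "__new_batch__"


def project_new_batch(
    reference_counts: pd.DataFrame,
    reference_meta: pd.DataFrame,
    new_counts: pd.DataFrame,
    pseudo: float = 1.0,
) -> NormalizedMatrix:
    """Normalize and batch-correct user samples jointly with a reference
    cohort, treating them as one additional batch, and return the corrected
    values for the new samples aligned to the reference gene order.

    New samples must share at least 50% of the reference genes (hard
    error below that); genes missing from the upload are imputed as zero
    counts with a warning when the overlap is below 90%.
    """
    if new_counts.shape[1] == 0:
        raise PreconditionError("no new samples provided")
    shared = reference_counts.index.intersection(new_counts.index)
    overlap = len(shared) / len(reference_counts.index)
    if overlap < 0.5:
        raise GeneMismatchError(
            f"new samples share only {overlap:.0%} of reference genes (<50%)"
        )
    if overlap < 0.9:
        warnings.warn(
            f"new samples share {overlap:.0%} of reference genes; "
            "missing genes imputed as zero counts",
            stacklevel=2,
        )
    aligned = new_counts.reindex(reference_counts.index, fill_value=0)
    if new_counts.shape[1] == 1:
        warnings.warn(
            "single new sample: its batch scale cannot be estimated and is "
            "shrunk fully toward the prior; interpret with caution",
            stacklevel=2,
        )
    clash = reference_counts.columns.intersection(aligned.columns)
    if len(clash):
        aligned = aligned.rename(columns={c: f"{c}__new" for c in clash})

    combined = pd.concat([reference_counts, aligned], axis=1)
    meta = pd.concat(
        [
            reference_meta.loc[reference_counts.columns, ["batch"]].astype(str),
            pd.DataFrame({"batch": NEW_BATCH_LABEL}, index=aligned.columns),
        ]
    )
    factors = tmm_factors(combined)
    norm = normalize_log2(combined, factors, pseudo=pseudo)
    if aligned.shape[1] == 1:
        out = _project_single_sample(norm, meta, aligned.columns[0])
    else:
        corrected, _ = fit_combat(norm, meta)
        out = corrected.values[aligned.columns]
    if len(clash):
        out = out.rename(columns={f"{c}__new": c for c in clash})
    return NormalizedMatrix(values=out, provenance=BATCH_CORRECTED)


def _project_single_sample(
    norm: NormalizedMatrix, meta: pd.DataFrame, col: str
) -> pd.DataFrame:
    """Location-only adjustment for a one-sample batch: fit the correction
    on the reference batches, standardize the new sample with the reference
    grand mean and pooled variance, shrink its per-gene deviation toward
    the cross-gene prior mean with the scale fixed at the prior (delta*=1),
    and back-transform. With one sample, location and biology cannot be
    separated, hence the heavy shrinkage and the caller's warning."""
    ref_cols = meta.index[meta["batch"] != NEW_BATCH_LABEL]
    ref_norm = NormalizedMatrix(
        values=norm.values[ref_cols], provenance=norm.provenance
    )
    _, model = fit_combat(ref_norm, meta.loc[ref_cols])
    pooled = np.where(
        model.pooled_var.to_numpy() <= 0, 1.0, model.pooled_var.to_numpy()
    )
    z = (
        norm.values[col].to_numpy() - model.grand_mean.to_numpy()
    ) / np.sqrt(pooled)
    gamma_hat = z  # one sample: per-gene batch mean is the sample itself
    gamma_bar = float(gamma_hat.mean())
    tau2 = float(gamma_hat.var(ddof=1))
    gamma_star = (tau2 * gamma_hat + 1.0 * gamma_bar) / (tau2 + 1.0)
    corrected = (z - gamma_star) * np.sqrt(pooled) + model.grand_mean.to_numpy()
    return pd.DataFrame({col: corrected}, index=norm.values.index)
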