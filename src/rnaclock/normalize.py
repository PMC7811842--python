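"""TMM normalization factors and log2 counts-per-million expression.

The trimmed mean of M-values computes, for each library against a
reference library, gene-wise log2 expression ratios (M) and average log2
abundances (A) over genes detected in both, discards the extremes of both
distributions (30% per tail on M, 5% per tail on A by default), and
averages the surviving M values weighted by inverse delta-method
(binomial) variances. Factors are rescaled to geometric mean one, and the
effective library size of a sample is its column total times its factor.

Normalized expression is log2(pseudo + CPM), with CPM computed against
effective library sizes, so a pure depth change leaves values untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import PreconditionError, ValidationError

UNCORRECTED = "uncorrected"
BATCH_CORRECTED = "batch_corrected"


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors (geometric mean 1) and bookkeeping."""

    factors: pd.Series              # sample -> factor
    ref_sample: str
    library_sizes: pd.Series        # raw column totals

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    def to_tsv(self, path) -> None:
        self.factors.rename("factor").to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, library_sizes: pd.Series) -> "NormalizationFactors":
        f = pd.read_csv(Path(path), sep="\t", index_col=0)["factor"]
        return cls(factors=f, ref_sample="", library_sizes=library_sizes.loc[f.index])


@dataclass
class NormalizedMatrix:
    """Log2-scale expression (genes x samples) plus a provenance flag."""

    values: pd.DataFrame
    provenance: str = UNCORRECTED

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("normalized matrix contains non-finite values")
        if self.provenance not in (UNCORRECTED, BATCH_CORRECTED):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def _trimmed_weighted_mean_m(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Doubly trimmed, precision-weighted mean of M values for one library
    against the reference. Inputs are raw count vectors."""
    both = (obs > 0) & (ref > 0)
    o, r = obs[both].astype(float), ref[both].astype(float)
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)  # delta-method var
    n = m.size
    if n == 0:
        return 0.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n - np.floor(n * trim_m)
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n - np.floor(n * trim_a)
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if abs(f) < 1e-10 else float(f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> NormalizationFactors:
    """TMM factors for a genes x samples raw count table.

    The reference library is the one whose 75th-percentile count fraction
    is closest to the across-sample mean (lowest column index on ties),
    unless ``ref`` names one explicitly.
    """
    if counts.shape[1] < 2:
        raise PreconditionError("TMM needs at least two samples")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise PreconditionError(f"zero-total column(s): {bad}")

    x = counts.to_numpy(dtype=float)
    n = totals.to_numpy()
    q75 = np.quantile(x / n[None, :], 0.75, axis=0)
    if ref is None:
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
        ref = counts.columns[ref_idx]
    elif ref not in counts.columns:
        raise PreconditionError(f"reference sample {ref!r} not in table")
    ref_idx = counts.columns.get_loc(ref)

    log_f = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        log_f[j] = _trimmed_weighted_mean_m(
            x[:, j], x[:, ref_idx], n[j], n[ref_idx], trim_m, trim_a
        )
    factors = np.exp2(log_f)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.columns, name="factor"),
        ref_sample=str(ref),
        library_sizes=totals,
    )


def normalize_log2(
    counts: pd.DataFrame,
    factors: NormalizationFactors,
    pseudo: float = 1.0,
) -> NormalizedMatrix:
    """log2(pseudo + CPM) against TMM effective library sizes."""
    missing = counts.columns.difference(factors.factors.index)
    if len(missing):
        raise PreconditionError(f"no normalization factor for sample(s): {missing.tolist()}")
    eff = factors.effective_library_sizes.loc[counts.columns].to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / eff[None, :] * 1e6
    vals = np.log2(pseudo + cpm)
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        provenance=UNCORRECTED,
    )
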