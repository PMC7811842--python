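"""Gene-set construction: most-variable genes and adult-vs-older
differential expression with batch as a blocking factor.

Differential testing fits, per gene, a negative-binomial log-linear model
``count ~ group + batch + offset(log effective library size)``. The NB
dispersion is estimated per gene by matching the Pearson chi-square of a
Poisson fit to its residual degrees of freedom (a method-of-moments
estimate on Pearson residuals), optionally shrunk toward a smooth
mean-dispersion trend, and the group effect is assessed with a
likelihood-ratio test between nested NB fits at that dispersion.
P-values are Benjamini-Hochberg adjusted across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import PreconditionError
from .normalize import NormalizedMatrix, tmm_factors
from .qc import AgeGroup, assign_age_groups

DISPERSION_FLOOR = 1e-8


@dataclass
class GeneSet:
    """An ordered list of gene ids with its provenance."""

    genes: list[str]
    origin: str  # variable | differential | important
    k: int

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise PreconditionError("gene set contains duplicate ids")
        if len(self.genes) > self.k:
            raise PreconditionError("gene set larger than its K")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class DifferentialResult:
    """Per-gene table: log2FC (group B vs A), LRT statistic, p, BH FDR."""

    table: pd.DataFrame  # columns: log2fc, stat, pvalue, fdr; index gene_id
    group_a: str
    group_b: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, group_a: str = "adult", group_b: str = "older"):
        return cls(pd.read_csv(path, sep="\t", index_col=0), group_a, group_b)


def top_variable_genes(
    corrected: NormalizedMatrix | pd.DataFrame,
    k: int,
    age_binned: pd.Series | None = None,
) -> GeneSet:
    """Top-k genes by variance of (corrected) log2 values across samples,
    descending, ties broken by gene id.

    If ``age_binned`` (a sample -> bin label Series) is given, genes are
    instead ranked by the variance of their per-bin mean expression — an
    alternative reading of "variable across age".
    """
    values = corrected.values if isinstance(corrected, NormalizedMatrix) else corrected
    if k > values.shape[0]:
        raise PreconditionError(f"k={k} exceeds number of genes {values.shape[0]}")
    if age_binned is not None:
        means = values.T.groupby(age_binned.loc[values.columns]).mean().T
        var = means.var(axis=1, ddof=1)
    else:
        var = values.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "gene": var.index}).sort_values(
        ["var", "gene"], ascending=[False, True]
    )
    return GeneSet(genes=order.index[:k].tolist(), origin="variable", k=k)


def _pearson_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Solve sum((y-mu)^2 / (mu + a*mu^2)) = n - p for the NB dispersion a.

    The left side is monotone decreasing in a; if even a=0 (Poisson) is
    underdispersed the floor is returned.
    """
    df = len(y) - n_params
    if df <= 0:
        return DISPERSION_FLOOR

    def pearson(a: float) -> float:
        return float(np.sum((y - mu) ** 2 / (mu + a * mu**2)) - df)

    if pearson(DISPERSION_FLOOR) <= 0:
        return DISPERSION_FLOOR
    hi = 1.0
    while pearson(hi) > 0 and hi < 1e4:
        hi *= 10
    if pearson(hi) > 0:
        return hi
    return float(optimize.brentq(pearson, DISPERSION_FLOOR, hi, xtol=1e-10))


def _shrink_dispersions(alpha: np.ndarray, mean_count: np.ndarray, weight: float) -> np.ndarray:
    """Shrink per-gene dispersions toward a running-median trend over
    abundance (log-scale convex combination)."""
    order = np.argsort(mean_count)
    trend = np.empty_like(alpha)
    logs = np.log(alpha[order])
    k = max(5, len(alpha) // 20)
    med = pd.Series(logs).rolling(k, center=True, min_periods=1).median().to_numpy()
    trend[order] = med
    return np.exp((1 - weight) * np.log(alpha) + weight * trend)


def differential_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: AgeGroup | str = AgeGroup.ADULT,
    group_b: AgeGroup | str = AgeGroup.OLDER,
    dispersion_shrink: float = 0.0,
) -> DifferentialResult:
    """NB-GLM likelihood-ratio differential expression between two age
    groups with batch as a blocking factor.

    log2FC is the coefficient of membership in ``group_b`` (so positive =
    higher in the older group for the default comparison).
    """
    ga = group_a.value if isinstance(group_a, AgeGroup) else str(group_a)
    gb = group_b.value if isinstance(group_b, AgeGroup) else str(group_b)
    groups = assign_age_groups(meta.loc[counts.columns, "age"])
    sel = groups.isin([ga, gb])
    if not (groups == ga).any():
        raise PreconditionError(f"group {ga!r} is empty")
    if not (groups == gb).any():
        raise PreconditionError(f"group {gb!r} is empty")
    cols = counts.columns[sel.to_numpy()]
    sub = counts[cols]
    grp = (groups.loc[cols] == gb).to_numpy(dtype=float)
    batch = meta.loc[cols, "batch"].astype(str)

    levels = batch.unique().tolist()
    use_batch = len(levels) > 1
    if use_batch:
        spanning = (
            pd.crosstab(batch, grp).gt(0).sum(axis=1).ge(2)
        )
        if not spanning.any():
            pure = spanning.index[~spanning].tolist()
            raise PreconditionError(
                "batch is perfectly confounded with age group (each batch "
                f"contains a single group): {pure}"
            )
    else:
        warnings.warn("single batch: batch covariate dropped", stacklevel=2)

    factors = tmm_factors(sub)
    offset = np.log(factors.effective_library_sizes.loc[cols].to_numpy(dtype=float))

    X_parts = [np.ones((len(cols), 1)), grp[:, None]]
    if use_batch:
        dummies = pd.get_dummies(batch, drop_first=True).to_numpy(dtype=float)
        X_parts.append(dummies)
    X_full = np.hstack(X_parts)
    X_red = np.hstack([X_parts[0]] + X_parts[2:])

    rows = []
    for gene in sub.index:
        y = sub.loc[gene].to_numpy(dtype=float)
        rows.append(_test_one_gene(y, X_full, X_red, offset))
    table = pd.DataFrame(
        rows, index=sub.index, columns=["log2fc", "stat", "pvalue", "alpha"]
    )
    if dispersion_shrink > 0:
        mean_count = sub.mean(axis=1).to_numpy(dtype=float)
        shrunk = _shrink_dispersions(
            table["alpha"].to_numpy(), mean_count, dispersion_shrink
        )
        rows = []
        for gene, a in zip(sub.index, shrunk):
            y = sub.loc[gene].to_numpy(dtype=float)
            rows.append(_test_one_gene(y, X_full, X_red, offset, alpha=a))
        table = pd.DataFrame(
            rows, index=sub.index, columns=["log2fc", "stat", "pvalue", "alpha"]
        )
    table = table.drop(columns="alpha")
    table["fdr"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
    return DifferentialResult(table=table, group_a=ga, group_b=gb)


def _test_one_gene(
    y: np.ndarray,
    X_full: np.ndarray,
    X_red: np.ndarray,
    offset: np.ndarray,
    alpha: float | None = None,
) -> tuple[float, float, float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if alpha is None:
            pois = sm.GLM(
                y, X_full, family=sm.families.Poisson(), offset=offset
            ).fit()
            alpha = _pearson_dispersion(y, pois.mu, X_full.shape[1])
        fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
        try:
            full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
            red = sm.GLM(y, X_red, family=fam, offset=offset).fit()
            stat = max(0.0, 2.0 * (full.llf - red.llf))
            p = float(stats.chi2.sf(stat, df=1))
            log2fc = float(full.params[1] / np.log(2))
        except Exception:  # all-zero gene or non-convergence
            stat, p, log2fc = 0.0, 1.0, 0.0
    return log2fc, stat, p, float(alpha)


def top_differential_genes(result: DifferentialResult, k: int) -> GeneSet:
    """Top-k genes by ascending p-value; ties by |log2FC| descending, then
    gene id."""
    t = result.table
    if k > len(t):
        raise PreconditionError(f"k={k} exceeds number of tested genes {len(t)}")
    order = t.assign(abs_lfc=t["log2fc"].abs(), gene=t.index).sort_values(
        ["pvalue", "abs_lfc", "gene"], ascending=[True, False, True]
    )
    return GeneSet(genes=order.index[:k].tolist(), origin="differential", k=k)


def significant_genes(
    result: DifferentialResult, lfc: float = 1.0, fdr: float = 0.05
) -> tuple[GeneSet, GeneSet]:
    """Strictly thresholded up/down calls: |log2FC| > lfc and FDR < fdr."""
    t = result.table
    up = t.index[(t["log2fc"] > lfc) & (t["fdr"] < fdr)].tolist()
    down = t.index[(t["log2fc"] < -lfc) & (t["fdr"] < fdr)].tolist()
    n = max(len(t), 1)
    return (
        GeneSet(genes=up, origin="differential", k=n),
        GeneSet(genes=down, origin="differential", k=n),
    )
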