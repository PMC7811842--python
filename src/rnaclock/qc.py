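"""Count-table ingest, sample/gene quality filters, and age grouping.

Filters follow the meta-analysis convention: samples need at least two
million exon-mapped reads; genes need a mean raw count of at least 50
across the retained samples. Age groups are young (<30), adult (30-69)
and older (>=70) years.
"""

from __future__ import annotations

import enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, PreconditionError, ValidationError

#: default sample filter: minimum exon-mapped reads per sample
MIN_TOTAL_READS = 2_000_000
#: default gene filter: minimum mean raw count across retained samples
MIN_MEAN_COUNT = 50.0
#: age-group cutoffs in years
YOUNG_CUTOFF = 30.0
OLDER_CUTOFF = 70.0

META_COLUMNS = ("age", "sex", "health", "tissue", "batch")


class AgeGroup(enum.Enum):
    YOUNG = "young"
    ADULT = "adult"
    OLDER = "older"

    @classmethod
    def from_age(cls, age: float) -> "AgeGroup":
        return assign_age_group(age)


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect:
        return {"tsv": "\t", "csv": ","}[dialect]
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a genes x samples raw count table (TSV by default, CSV by
    extension or explicit dialect). First column is the gene id.

    Rejects ragged rows, duplicate gene or sample ids, and negative or
    non-integer cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse count table: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene id(s): {dupes[:5]}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicated sample id(s)")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in count table (ragged rows?)")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count table")
    if (values < 0).any():
        raise FormatError(f"{path}: negative counts are not allowed")
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"{path}: non-integer counts are not allowed")
    out = df.astype(np.int64)
    out.index.name = "gene_id"
    return out


def read_metadata(path, dialect: str | None = None) -> pd.DataFrame:
    """Read per-sample metadata with required columns
    ``sample_id, age, sex, health, tissue, batch``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect))
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse metadata: {exc}") from exc
    missing = [c for c in ("sample_id", *META_COLUMNS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing column(s): {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id in metadata")
    df = df.set_index("sample_id")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any() or (ages < 0).any() or (ages > 110).any():
        raise ValidationError(f"{path}: ages must be numeric and within [0, 110]")
    df["age"] = ages.astype(float)
    return df


def filter_samples(counts: pd.DataFrame, min_total: float = MIN_TOTAL_READS) -> list[str]:
    """Sample ids whose total counts are >= ``min_total`` ("fewer than the
    threshold" excluded, so the boundary is kept)."""
    totals = counts.sum(axis=0)
    return totals.index[totals >= min_total].tolist()


def filter_genes(counts: pd.DataFrame, min_mean: float = MIN_MEAN_COUNT) -> list[str]:
    """Gene ids whose mean raw count across the given samples is >=
    ``min_mean`` (means strictly below the threshold are dropped)."""
    if counts.shape[1] == 0:
        raise PreconditionError("gene filtering requires at least one sample")
    means = counts.mean(axis=1)
    return means.index[means >= min_mean].tolist()


def assign_age_group(age: float) -> AgeGroup:
    """young if age < 30, adult if 30 <= age < 70, older if age >= 70."""
    if age < 0:
        raise ValidationError(f"age must be non-negative, got {age}")
    if age < YOUNG_CUTOFF:
        return AgeGroup.YOUNG
    if age < OLDER_CUTOFF:
        return AgeGroup.ADULT
    return AgeGroup.OLDER


def assign_age_groups(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_age_group` returning a Series of labels."""
    if (ages < 0).any():
        raise ValidationError("ages must be non-negative")
    out = pd.Series(AgeGroup.ADULT.value, index=ages.index, dtype=object)
    out[ages < YOUNG_CUTOFF] = AgeGroup.YOUNG.value
    out[ages >= OLDER_CUTOFF] = AgeGroup.OLDER.value
    return out


def total_count_summary(counts: pd.DataFrame, bins: int = 30) -> pd.DataFrame:
    """Histogram summary of per-sample totals (diagnostic for the read-depth
    cut; the cut itself is the fixed threshold, not data-derived)."""
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    hist, edges = np.histogram(np.log10(np.maximum(totals, 1)), bins=bins)
    return pd.DataFrame(
        {"log10_total_lo": edges[:-1], "log10_total_hi": edges[1:], "n_samples": hist}
    )


def apply_qc(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_total: float = MIN_TOTAL_READS,
    min_mean: float = MIN_MEAN_COUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample filter, then gene filter (gene means computed on the samples
    that survived), returning the filtered counts and aligned metadata."""
    kept_samples = filter_samples(counts, min_total=min_total)
    sub = counts[kept_samples]
    kept_genes = filter_genes(sub, min_mean=min_mean)
    return sub.loc[kept_genes], meta.loc[kept_samples]
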