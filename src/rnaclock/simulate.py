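"""Synthetic multi-batch RNA-seq cohorts with known ground truth.

The generator emulates the structure of a large public-data aging
meta-analysis: many sequencing batches (studies) of unequal size, subject
ages spanning roughly 0-107 years, a subset of genes whose log2 expression
drifts linearly with age, strong per-batch location/scale effects in log
space (the empirical-Bayes batch-correction model form), negative-binomial
count noise on lognormal library sizes, an optional fraction of low-depth
junk samples, and optional "adversarial" batches whose recorded ages are
permuted and therefore carry no usable age signal.

The per-gene, per-sample log2 mean is

    x[g, j] = baseline[g] + slope[g] * age[j] + gamma[b(j), g]
              + delta[b(j), g] * eps[g, j]

with eps ~ N(0, noise_log_sd). Relative abundances 2**x are scaled to the
sample's library size and counts drawn NB with variance mu + phi * mu**2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

_TISSUES = ("blood", "brain", "retina", "heart", "bone")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Log-scale expression parameters (``baseline_log_mean``, ``baseline_log_sd``,
    ``age_slope_sd``, ``batch_shift_sd``, ``noise_log_sd``) are in log2 units;
    library-size parameters are natural-log parameters of a lognormal.
    """

    n_batches: int = 10
    samples_per_batch: int | list[int] = 30
    n_genes: int = 500
    n_age_genes: int | None = None   # default: one fifth of the genes
    age_slope_sd: float = 0.02        # log2 units per year
    baseline_log_mean: float = 5.0    # log2 units
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.30        # per-gene biological noise sd, log2 units
    nb_dispersion: float = 0.05       # phi in var = mu + phi*mu^2
    batch_shift_sd: float = 0.5       # per-batch per-gene additive log2 shift
    batch_scale_sd: float = 0.2       # log-sd of per-batch per-gene scale multiplier
    libsize_log_mean: float = 15.5    # ln units; exp(15.5) ~ 5.4e6 reads
    libsize_log_sd: float = 0.25
    frac_junk_samples: float = 0.0
    qc_min_total: int = 2_000_000
    n_adversarial_batches: int = 0
    age_range: tuple[float, float] = (0.0, 107.0)
    age_distribution: str = "uniform"  # or "truncnorm" (mean 60.5, sd 18.2)
    batch_age_heterogeneity: float = 0.0  # 0 = identical age ranges per batch;
    # at h, each batch samples ages from a random window of width (1-h)*range,
    # emulating studies that each enroll a different age span
    age_mean: float = 60.5
    age_sd: float = 18.2
    sex_fraction: float = 0.5          # fraction of samples labeled male
    unhealthy_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.n_genes < 1:
            raise ConfigError("n_batches and n_genes must be positive")
        sizes = self.batch_sizes()
        if len(sizes) != self.n_batches or any(s < 1 for s in sizes):
            raise ConfigError("samples_per_batch must give one positive size per batch")
        if self.n_age_genes is None:
            self.n_age_genes = self.n_genes // 5
        if not 0 <= self.n_age_genes <= self.n_genes:
            raise ConfigError("n_age_genes must be in [0, n_genes]")
        if not 0 <= self.n_adversarial_batches <= self.n_batches:
            raise ConfigError("n_adversarial_batches must be in [0, n_batches]")
        for name in ("frac_junk_samples", "sex_fraction", "unhealthy_fraction",
                     "batch_age_heterogeneity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a fraction in [0, 1]")
        lo, hi = self.age_range
        if not (0.0 <= lo < hi <= 110.0):
            raise ConfigError("age_range must satisfy 0 <= min < max <= 110")
        if self.age_distribution not in ("uniform", "truncnorm"):
            raise ConfigError("age_distribution must be 'uniform' or 'truncnorm'")
        for name in ("age_slope_sd", "baseline_log_sd", "noise_log_sd",
                     "nb_dispersion", "batch_shift_sd", "batch_scale_sd",
                     "libsize_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def batch_sizes(self) -> list[int]:
        if isinstance(self.samples_per_batch, int):
            return [self.samples_per_batch] * self.n_batches
        return [int(s) for s in self.samples_per_batch]

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    age_slopes: pd.Series          # gene -> log2/year slope (age genes only)
    gamma: pd.DataFrame            # batch x gene additive log2 shifts
    delta: pd.DataFrame            # batch x gene noise-scale multipliers
    library_sizes: pd.Series      # sample -> true (expected) library size
    true_ages: pd.Series          # sample -> age used to generate expression
    junk_samples: list[str] = field(default_factory=list)
    adversarial_batches: list[str] = field(default_factory=list)

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.age_slopes.rename("slope").to_csv(d / "age_slopes.tsv", sep="\t")
        self.gamma.to_csv(d / "batch_gamma.tsv", sep="\t")
        self.delta.to_csv(d / "batch_delta.tsv", sep="\t")
        pd.DataFrame(
            {
                "library_size": self.library_sizes,
                "true_age": self.true_ages,
                "junk": [s in self.junk_samples for s in self.library_sizes.index],
            }
        ).to_csv(d / "samples.tsv", sep="\t")
        (d / "adversarial_batches.txt").write_text(
            "\n".join(self.adversarial_batches) + ("\n" if self.adversarial_batches else "")
        )


def _draw_ages(
    cfg: SimulationConfig,
    batch_of: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    lo, hi = cfg.age_range
    n = len(batch_of)
    if cfg.batch_age_heterogeneity > 0:
        # each batch enrolls from its own age window
        width = (1.0 - cfg.batch_age_heterogeneity) * (hi - lo)
        starts = rng.uniform(lo, hi - width, cfg.n_batches)
        return starts[batch_of] + rng.uniform(0.0, width, n)
    if cfg.age_distribution == "uniform":
        return rng.uniform(lo, hi, n)
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort.

    Returns ``(counts, meta, truth)`` where ``counts`` is a genes x samples
    integer DataFrame, ``meta`` a per-sample table with columns
    ``age, sex, health, tissue, batch`` indexed by sample id, and ``truth``
    the generating parameters. Identical config (including seed) gives
    byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.batch_sizes()
    n_samples = sum(sizes)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    batches = [f"B{i:02d}" for i in range(cfg.n_batches)]
    batch_of = np.repeat(np.arange(cfg.n_batches), sizes)

    ages = _draw_ages(cfg, batch_of, rng)
    sex = np.where(rng.uniform(size=n_samples) < cfg.sex_fraction, "male", "female")
    health = np.where(
        rng.uniform(size=n_samples) < cfg.unhealthy_fraction, "unhealthy", "healthy"
    )
    tissue = np.array([_TISSUES[b % len(_TISSUES)] for b in batch_of])

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    slopes = np.zeros(cfg.n_genes)
    age_gene_idx = rng.choice(cfg.n_genes, size=cfg.n_age_genes, replace=False)
    age_gene_idx.sort()
    slopes[age_gene_idx] = rng.normal(0.0, cfg.age_slope_sd, cfg.n_age_genes)

    gamma = rng.normal(0.0, cfg.batch_shift_sd, (cfg.n_batches, cfg.n_genes))
    delta = np.exp(rng.normal(0.0, cfg.batch_scale_sd, (cfg.n_batches, cfg.n_genes)))

    # per-sample log2 means (genes x samples)
    eps = rng.normal(0.0, cfg.noise_log_sd, (cfg.n_genes, n_samples))
    x = (
        baseline[:, None]
        + np.outer(slopes, ages)
        + gamma[batch_of, :].T
        + delta[batch_of, :].T * eps
    )

    # library sizes: junk samples sit clearly below the QC threshold, the
    # rest clearly above it
    libsizes = np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, n_samples))
    libsizes = np.maximum(libsizes, 1.25 * cfg.qc_min_total)
    n_junk = int(round(cfg.frac_junk_samples * n_samples))
    junk_idx = rng.choice(n_samples, size=n_junk, replace=False)
    junk_idx.sort()
    libsizes[junk_idx] = cfg.qc_min_total * rng.uniform(0.3, 0.7, n_junk)

    rel = np.exp2(x)
    mu = rel / rel.sum(axis=0, keepdims=True) * libsizes[None, :]
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    # adversarial batches: expression was generated from the true ages; the
    # recorded ages are permuted within the batch so labels carry no signal
    reported = ages.copy()
    adv = batches[cfg.n_batches - cfg.n_adversarial_batches:]
    for b in range(cfg.n_batches - cfg.n_adversarial_batches, cfg.n_batches):
        idx = np.where(batch_of == b)[0]
        reported[idx] = reported[rng.permutation(idx)]

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "age": reported,
            "sex": sex,
            "health": health,
            "tissue": tissue,
            "batch": [batches[b] for b in batch_of],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = SyntheticTruth(
        age_slopes=pd.Series(
            slopes[age_gene_idx], index=[genes[i] for i in age_gene_idx], name="slope"
        ),
        gamma=pd.DataFrame(gamma, index=batches, columns=genes),
        delta=pd.DataFrame(delta, index=batches, columns=genes),
        library_sizes=pd.Series(libsizes, index=samples, name="library_size"),
        true_ages=pd.Series(ages, index=samples, name="true_age"),
        junk_samples=[samples[i] for i in junk_idx],
        adversarial_batches=list(adv),
    )
    return counts_df, meta, truth


def write_cohort(counts: pd.DataFrame, meta: pd.DataFrame, directory) -> None:
    """Write counts/metadata in the TSV layout the ingest step consumes."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    counts.to_csv(d / "counts.tsv", sep="\t")
    meta.to_csv(d / "meta.tsv", sep="\t")
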