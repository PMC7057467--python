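"""Synthetic expression time courses with a planted critical transition.

The generator is a linear-Gaussian latent-factor model.  Each sampling period
``p`` has a latent factor drawn per sample with standard deviation
``factor_sd_schedule[p]``; a designated block of genes (the planted dynamic
network biomarker, DNB) loads on that factor with strength
``factor_loading_schedule[p]``.  Both schedules attain their maximum at the
tipping period, so within the planted block the pairwise correlation and the
standard deviation rise there, while the block's correlation to the rest of
the transcriptome — carried only by a weak common background factor — falls.
Closed forms for the implied correlations make the generator its own oracle:
for a DNB gene ``x = m + L f + a g + e`` with ``f ~ N(0, s_f^2)``,
``g ~ N(0, 1)``, ``e ~ N(0, s_n^2)``, the within-block correlation is
``(L^2 s_f^2 + a^2) / (L^2 s_f^2 + a^2 + s_n^2)``.

A second disjoint block of differentially expressed (DE) genes has its mean
multiplied by ``de_fold`` for every period after the tipping period,
emulating expression shifts around the transition.

All randomness flows through a single integer seed; the same seed yields a
bit-identical matrix.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

logger = logging.getLogger("dnbdev")

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_dataset",
    "null_config",
    "evaluate_recovery",
    "dnb_block_correlation",
]


def _default_loading_schedule(n_periods: int, tipping: int) -> list[float]:
    sched = [0.5] * n_periods
    sched[tipping] = 3.0
    return sched


def _default_sd_schedule(n_periods: int, tipping: int) -> list[float]:
    sched = [1.0] * n_periods
    sched[tipping] = 200.0
    return sched


@dataclass
class SimConfig:
    """Parameters of the planted-transition generator.

    Defaults mirror an infant developmental course at desk scale: 10
    age-ordered periods with 3 replicate samples each (ages 0.05(p+1) years,
    so the planted tipping period index 3 sits at 0.2 years), 1000 genes of
    which 50 form the planted DNB block and 40 are DE with a 4-fold shift
    after the tipping period.
    """

    n_genes: int = 1000
    n_dnb: int = 50
    n_de: int = 40
    n_periods: int = 10
    samples_per_period: int = 3
    tipping_period: int = 3
    ages: Sequence[float] | None = None
    factor_loading_schedule: Sequence[float] | None = None
    factor_sd_schedule: Sequence[float] | None = None
    background_corr: float = 0.25
    de_fold: float = 4.0
    noise_sd: float = 1.0
    baseline_mean: float = 100.0
    baseline_gene_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.tipping_period < self.n_periods):
            raise ValueError("tipping_period must index a period")
        if self.ages is None:
            self.ages = [0.05 * (p + 1) for p in range(self.n_periods)]
        if self.factor_loading_schedule is None:
            self.factor_loading_schedule = _default_loading_schedule(
                self.n_periods, self.tipping_period
            )
        if self.factor_sd_schedule is None:
            self.factor_sd_schedule = _default_sd_schedule(
                self.n_periods, self.tipping_period
            )
        self.validate()

    def validate(self) -> None:
        if self.n_dnb + self.n_de > self.n_genes:
            raise ValueError("n_dnb + n_de must not exceed n_genes")
        if not (0 <= self.tipping_period < self.n_periods):
            raise ValueError("tipping_period must index a period")
        if not (1 <= self.samples_per_period <= 5):
            raise ValueError("samples_per_period must be in [1, 5]")
        for name in ("ages", "factor_loading_schedule", "factor_sd_schedule"):
            vals = list(getattr(self, name))
            if len(vals) != self.n_periods:
                raise ValueError(f"{name} must have length n_periods")
        loading = list(self.factor_loading_schedule)
        sds = list(self.factor_sd_schedule)
        if any(v < 0 for v in loading):
            raise ValueError("factor loadings must be >= 0")
        if any(v <= 0 for v in sds):
            raise ValueError("factor standard deviations must be > 0")
        # schedules must attain their maximum at the tipping period (a flat
        # schedule — the null configuration — trivially satisfies this)
        if loading[self.tipping_period] < max(loading):
            raise ValueError("loading schedule must peak at tipping_period")
        if sds[self.tipping_period] < max(sds):
            raise ValueError("factor-sd schedule must peak at tipping_period")
        if not (0 <= self.background_corr < 1):
            raise ValueError("background_corr must be in [0, 1)")
        if self.de_fold <= 1:
            raise ValueError("de_fold must be > 1")
        if self.noise_sd <= 0 or self.baseline_mean <= 0:
            raise ValueError("noise_sd and baseline_mean must be > 0")
        if self.baseline_gene_sd < 0:
            raise ValueError("baseline_gene_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("ages", "factor_loading_schedule", "factor_sd_schedule"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    dnb_gene_ids: frozenset
    de_gene_ids: frozenset
    tipping_period: int
    config: SimConfig

    @property
    def tipping_age(self) -> float:
        return float(list(self.config.ages)[self.tipping_period])


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A flat-schedule configuration: no transition is planted.

    The latent-factor loading and standard deviation are constant across
    periods (at the default off-tipping levels), so the 'DNB block' is just
    another weakly coupled gene set and any detected peak is noise.
    """
    n_periods = overrides.pop("n_periods", 10)
    cfg = SimConfig(
        n_periods=n_periods,
        factor_loading_schedule=[0.5] * n_periods,
        factor_sd_schedule=[1.0] * n_periods,
        n_de=overrides.pop("n_de", 0),  # no DE shift either: nothing changes
        seed=seed,
        **overrides,
    )
    return cfg


def dnb_block_correlation(loading: float, factor_sd: float, config: SimConfig) -> float:
    """Closed-form within-block Pearson correlation implied by the model."""
    a2 = _background_loading(config) ** 2
    sig = loading**2 * factor_sd**2 + a2
    return sig / (sig + config.noise_sd**2)


def _background_loading(config: SimConfig) -> float:
    bc = config.background_corr
    return config.noise_sd * float(np.sqrt(bc / (1.0 - bc)))


def generate_dataset(config: SimConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw one raw (unnormalised) dataset plus its ground truth.

    Gene layout is deterministic: genes ``g0000 .. g{n_dnb-1}`` form the DNB
    block, the next ``n_de`` genes the DE block, the remainder background.
    Values are clipped to a small positive floor, acting as a detection
    limit: during the tipping-period variance surge the block's downward
    excursions bottom out there, as silenced genes do on an array.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_p, spp = config.n_periods, config.samples_per_period
    n_samples = n_p * spp
    g = config.n_genes
    a_bg = _background_loading(config)

    period_of = np.repeat(np.arange(n_p), spp)
    loading = np.asarray(config.factor_loading_schedule, dtype=float)[period_of]
    factor_sd = np.asarray(config.factor_sd_schedule, dtype=float)[period_of]

    f = rng.standard_normal(n_samples) * factor_sd  # DNB latent factor
    shared = rng.standard_normal(n_samples)  # weak transcriptome-wide factor
    noise = rng.standard_normal((g, n_samples)) * config.noise_sd

    # Gene-specific expression levels: real transcriptomes are heterogeneous
    # across genes, so per-sample ranks are stable for genes without signal.
    # The DNB block sits at one common level (its genes are near-copies of
    # the latent factor, which is what makes it a coherent module); DE genes
    # are drawn from the upper tail of the level distribution so the planted
    # mean shift stays separable from the planted correlation transition.
    de_lo = config.n_dnb
    de_hi = config.n_dnb + config.n_de
    baselines = np.empty(g)
    baselines[:de_hi] = config.baseline_mean
    baselines[de_hi:] = (
        config.baseline_mean
        + rng.standard_normal(g - de_hi) * config.baseline_gene_sd
    )
    from scipy.stats import norm

    upper = rng.uniform(0.8, 0.999, size=config.n_de)
    baselines[de_lo:de_hi] = config.baseline_mean + config.baseline_gene_sd * norm.ppf(
        upper
    )

    # random-sign loadings on the shared factor: a common shift of every
    # gene would vanish under per-sample rank normalisation, so background
    # correlation must enter with heterogeneous signs
    signs = rng.choice([-1.0, 1.0], size=g)

    x = np.empty((g, n_samples))
    x[:] = baselines[:, None] + (a_bg * signs)[:, None] * shared + noise
    x[: config.n_dnb] += loading * f

    after = period_of > config.tipping_period
    x[de_lo:de_hi][:, after] += baselines[de_lo:de_hi, None] * (config.de_fold - 1.0)

    np.clip(x, 1e-6, None, out=x)

    width = len(str(g - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(g)]
    sample_ids = [f"p{p:02d}s{s}" for p in range(n_p) for s in range(spp)]
    ages = np.asarray(list(config.ages), dtype=float)[period_of]
    values = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": "synthetic",
            "age_years": ages,
        }
    )
    ds = ExpressionDataset(values, meta, normalized=False)
    truth = SyntheticTruth(
        dnb_gene_ids=frozenset(gene_ids[: config.n_dnb]),
        de_gene_ids=frozenset(gene_ids[de_lo:de_hi]),
        tipping_period=config.tipping_period,
        config=config,
    )
    return ds, truth


def evaluate_recovery(result, truth: SyntheticTruth) -> tuple[bool, int, float]:
    """Score a scan against the planted truth.

    Returns ``(hit, window_offset, jaccard)`` where ``window_offset`` is the
    index of the window whose age label is nearest the planted tipping age
    minus the detected tipping index, ``hit`` means the detected window is
    within one window of that target, and ``jaccard`` compares the recovered
    gene set with the planted block.
    """
    target_age = truth.tipping_age
    labels = np.asarray([w.age_label for w in result.windows], dtype=float)
    gaps = np.abs(labels - target_age)
    # several windows can share the nearest age label (pooled windows repeat
    # the median age); the offset is measured to the closest of them
    nearest = np.flatnonzero(gaps == gaps.min())
    offset = int(nearest[np.argmin(np.abs(nearest - result.tipping_index))]) - int(
        result.tipping_index
    )
    recovered = set(result.dnb_genes)
    planted = set(truth.dnb_gene_ids)
    union = recovered | planted
    jaccard = len(recovered & planted) / len(union) if union else 1.0
    return (abs(offset) <= 1, offset, jaccard)
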