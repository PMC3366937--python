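"""Fixed-effect inverse-variance meta-analysis and p-value calibration tools.

Per-study log-ORs are pooled with weights 1/se^2 (the METAL-style fixed
effect); Cochran's Q reports between-study heterogeneity.  Odds ratios
published only as OR [low-high] are pooled by reconstructing the log-OR and
its standard error from the confidence bounds.  Genomic control and QQ-plot
payloads summarize genome-wide p-value calibration.  Combined p-values are
computed in log space so magnitudes like 1e-13 survive without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, norm

from .errors import ValidationError

CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.4549364...


@dataclass(frozen=True)
class StudyEffect:
    study_label: str
    beta: float
    se: float
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self):
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValidationError(f"{self.study_label}: se must be positive and finite")


@dataclass(frozen=True)
class MetaResult:
    beta_c: float
    se_c: float
    z: float
    p: float
    log10_p: float
    q_stat: float
    q_df: int
    q_p: float
    weights: tuple  # normalized per-study weights

    @property
    def odds_ratio(self):
        return float(np.exp(self.beta_c))

    def ci(self, level=0.95):
        zq = norm.ppf(0.5 + level / 2.0)
        return (float(np.exp(self.beta_c - zq * self.se_c)),
                float(np.exp(self.beta_c + zq * self.se_c)))


def _two_sided_p(z):
    """(p, log10 p) for a two-sided normal test, safe for huge |z|."""
    logp = np.log(2.0) + norm.logsf(abs(z))
    return float(np.exp(logp)), float(logp / np.log(10.0))


def fixed_effect_meta(effects) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study log-ORs.

    A single study passes through (with a warning-level Q of 0).
    """
    effects = list(effects)
    if not effects:
        raise ValidationError("no study effects supplied")
    betas = np.array([e.beta for e in effects])
    ses = np.array([e.se for e in effects])
    w = 1.0 / ses ** 2
    beta_c = float(np.sum(w * betas) / np.sum(w))
    se_c = float(1.0 / np.sqrt(np.sum(w)))
    z = beta_c / se_c
    p, log10_p = _two_sided_p(z)
    q = float(np.sum(w * (betas - beta_c) ** 2))
    q_df = max(len(effects) - 1, 0)
    q_p = float(chi2.sf(q, q_df)) if q_df > 0 else 1.0
    return MetaResult(beta_c=beta_c, se_c=se_c, z=float(z), p=p, log10_p=log10_p,
                      q_stat=q, q_df=q_df, q_p=q_p,
                      weights=tuple(w / w.sum()))


def or_meta(or_ci, labels=None, level=0.95) -> MetaResult:
    """Fixed-effect meta-analysis of (OR, ci_low, ci_high) triples.

    beta = ln OR and se = (ln high - ln low) / (2 z) are reconstructed from
    each interval, then pooled with :func:`fixed_effect_meta`.
    """
    zq = norm.ppf(0.5 + level / 2.0)
    effects = []
    for k, (or_, low, high) in enumerate(or_ci):
        if not (0 < low < or_ < high):
            raise ValidationError(f"inconsistent OR/CI ordering: {(or_, low, high)}")
        label = labels[k] if labels else f"study{k + 1}"
        effects.append(StudyEffect(study_label=label, beta=float(np.log(or_)),
                                   se=float((np.log(high) - np.log(low)) / (2 * zq))))
    return fixed_effect_meta(effects)


def pvals_to_chi2(pvals) -> np.ndarray:
    """Convert two-sided p-values to 1-df chi-square statistics."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size and (pvals.min() <= 0.0 or pvals.max() > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    return chi2.isf(pvals, 1)


def genomic_control(pvals=None, chi2_stats=None, min_n=100) -> float:
    """Genomic-control inflation factor lambda = median(chi2_1) / 0.4549...

    Lambda near 1 indicates well-calibrated genome-wide statistics.
    """
    if chi2_stats is None:
        chi2_stats = pvals_to_chi2(pvals)
    chi2_stats = np.asarray(chi2_stats, dtype=float)
    if chi2_stats.size < min_n:
        raise ValidationError(f"need at least {min_n} statistics for a stable median")
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)


@dataclass(frozen=True)
class QQData:
    """Expected vs observed -log10 p order statistics with a 95% beta band."""

    expected: np.ndarray      # -log10 of i/(n+1)
    observed: np.ndarray      # -log10 of sorted p
    band_low: np.ndarray      # -log10 of Beta(i, n-i+1) 97.5% quantile
    band_high: np.ndarray     # -log10 of Beta(i, n-i+1) 2.5% quantile


def qq_data(pvals, band=0.95) -> QQData:
    """QQ-plot payload: uniform order-statistic expectations and a pointwise
    confidence band from Beta(i, n-i+1) quantiles."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0 or pvals.min() <= 0.0 or pvals.max() > 1.0:
        raise ValidationError("p-values must lie in (0, 1]")
    n = pvals.size
    obs = np.sort(pvals)
    i = np.arange(1, n + 1)
    expected = i / (n + 1.0)
    alpha = (1.0 - band) / 2.0
    low = beta_dist.ppf(1.0 - alpha, i, n - i + 1)
    high = beta_dist.ppf(alpha, i, n - i + 1)
    return QQData(
        expected=-np.log10(expected),
        observed=-np.log10(obs),
        band_low=-np.log10(low),
        band_high=-np.log10(high),
    )
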