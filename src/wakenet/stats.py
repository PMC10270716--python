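"""Paired-design inference, effect sizes, multiplicity, and behavior.

The inferential layer of the analysis: paired t tests between baseline and
post-awakening bouts (and between light and control conditions), two-sided
p from the central t distribution, Hedges' g (pooled-SD standardized mean
difference with small-sample bias correction), Benjamini-Hochberg FDR for
electrode-level families, Pearson brain-behavior correlations, and
psychomotor-vigilance summaries (mean speed = mean 1/RT, lapses = RT
strictly greater than 500 ms).

Note the deliberate asymmetry: the paired t statistic standardizes by the
SD of the paired *differences*, while Hedges' g standardizes by the pooled
SD of the two samples, so g need not equal t / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    """One paired comparison: t, df, two-sided p, Hedges' g, optional FDR flag."""

    comparison: str
    metric: str
    band: str | None
    t: float
    df: int
    p: float
    g: float
    q_significant: bool | None = None


@dataclass
class BehavioralSummary:
    subject: str
    condition: str
    bout: str
    mean_speed: float  # 1/s, mean of reciprocal reaction times
    lapses: int  # reaction times strictly > 500 ms
    kss: int


def _paired_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired samples must be equal-length 1-D arrays, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    return x, y


def paired_t(x, y) -> tuple[float, int]:
    """Paired t statistic and degrees of freedom for d = x - y.

    t = mean(d) / (sd(d) / sqrt(n)) with sd at n-1 denominators; df = n - 1.
    Zero-variance differences are a degenerate input.
    """
    x, y = _paired_arrays(x, y)
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(t), d.size - 1


def t_to_p(t: float, df: int) -> float:
    """Two-sided p under the central t distribution."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def hedges_g(x, y) -> float:
    """Hedges' g: bias-corrected pooled-SD standardized mean difference.

    g = J (mean(x) - mean(y)) / s_pooled with s_pooled from the two
    samples' n-1 variances and J = 1 - 3 / (4 (2n - 2) - 1), the usual
    small-sample correction.
    """
    x, y = _paired_arrays(x, y)
    n = x.size
    s_pooled = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    if s_pooled == 0:
        raise ValueError("zero pooled variance")
    J = 1.0 - 3.0 / (4.0 * (2 * n - 2) - 1.0)
    return float(J * (x.mean() - y.mean()) / s_pooled)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def pearson_corr(a, b) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p (df = n - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant input has undefined correlation")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def summarize_behavior(subject, condition, bout, kss: int, rt_series_ms) -> BehavioralSummary:
    """Reduce a PVT trial series (ms) and a KSS rating to summary measures."""
    rt = np.asarray(rt_series_ms, dtype=float)
    if rt.size == 0:
        raise ValueError("empty reaction-time series")
    if np.any(rt <= 0):
        raise ValueError("reaction times must be positive")
    speed = float(np.mean(1.0 / (rt / 1000.0)))
    lapses = int(np.sum(rt > 500.0))
    return BehavioralSummary(subject, condition, bout, speed, lapses, int(kss))


def paired_compare(x, y, comparison: str, metric: str, band: str | None = None) -> StatResult:
    """Full paired comparison: t, df, p, and Hedges' g in one record."""
    t, df = paired_t(x, y)
    return StatResult(comparison, metric, band, t, df, t_to_p(t, df), hedges_g(x, y))
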