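"""Offline evaluation statistics.

Nonparametric sign test with a continuity-corrected normal
approximation, box-plot descriptives, a permutation test on the
across-run slope of a performance statistic, a Jarque-Bera normality
check, and the activity-based baselines (percent signal change, CNR,
differential left-right feedback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, kurtosis, norm, skew

__all__ = [
    "SignTestResult",
    "DescriptiveStats",
    "ActivationSummary",
    "sign_test",
    "describe",
    "permutation_slope_test",
    "percent_signal_change",
    "cnr",
    "differential_feedback",
    "jarque_bera",
]


@dataclass(frozen=True)
class SignTestResult:
    k: int      # number of positive values
    n: int      # total non-zero values
    z: float    # continuity-corrected normal approximation
    p: float    # one-tailed (median > 0) tail probability


def sign_test(values=None, k: int | None = None, n: int | None = None
              ) -> SignTestResult:
    """One-tailed sign test (median > 0) with z approximation.

    Either pass a sample (exact zeros are discarded) or the counts
    ``(k, n)`` directly.  z = (k - 0.5 - n/2) / sqrt(n/4) with a 0.5
    continuity correction; p is the upper Gaussian tail of the
    *unrounded* z.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        v = v[v != 0.0]
        k = int(np.sum(v > 0))
        n = int(v.size)
    if k is None or n is None:
        raise ValueError("pass either values or both k and n")
    if n < 1:
        raise ValueError("sign test needs at least one non-zero value")
    if not (0 <= k <= n):
        raise ValueError(f"k={k} must lie in [0, n={n}]")
    z = (k - 0.5 - n / 2.0) / np.sqrt(n / 4.0)
    p = float(norm.sf(z))
    return SignTestResult(k=k, n=n, z=float(z), p=p)


@dataclass(frozen=True)
class DescriptiveStats:
    m: float    # median
    fq: float   # first quartile
    sq: float   # upper ("second") quartile as drawn in box plots
    iqr: float  # interquartile range


def describe(values) -> DescriptiveStats:
    """Median and linearly interpolated quartiles of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("describe needs at least one value")
    fq, m, sq = np.percentile(v, [25.0, 50.0, 75.0])
    return DescriptiveStats(m=float(m), fq=float(fq), sq=float(sq),
                            iqr=float(sq - fq))


def permutation_slope_test(
    values,
    run_labels,
    n_perm: int = 999,
    seed: int | None = None,
    statistic: str = "median",
) -> float:
    """Permutation test for a positive trend of a per-run statistic.

    Computes the slope of a linear regression of the per-run statistic
    ("median" of the values, or sign-test "z") against run index, then
    permutes values across runs to build the null.  One-tailed:
    p = (1 + #{permuted slope >= observed}) / (n_perm + 1).
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(run_labels)
    runs = np.unique(labels)
    if runs.size < 2:
        raise ValueError("permutation slope test needs at least two runs")

    def stat(sample) -> float:
        if statistic == "median":
            return float(np.median(sample))
        if statistic == "z":
            s = sample[sample != 0.0]
            if s.size == 0:
                return 0.0
            return sign_test(s).z
        raise ValueError(f"unknown statistic {statistic!r}")

    x = np.arange(runs.size, dtype=float)

    def slope(vals) -> float:
        y = np.array([stat(vals[labels == r]) for r in runs])
        xc = x - x.mean()
        return float(xc @ (y - y.mean()) / (xc @ xc))

    observed = slope(v)
    rng = np.random.default_rng(seed)
    count = 0
    vperm = v.copy()
    for _ in range(n_perm):
        rng.shuffle(vperm)
        if slope(vperm) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def percent_signal_change(
    window: np.ndarray, condition_scans, baseline_scans
) -> np.ndarray:
    """100 * (mean(condition) - mean(baseline)) / mean(baseline) per ROI.

    ``window`` is raw (pre-cleaned) signal, scans x regions.
    """
    w = np.atleast_2d(np.asarray(window, dtype=float))
    ci = np.asarray(condition_scans, dtype=int)
    bi = np.asarray(baseline_scans, dtype=int)
    if ci.size == 0 or bi.size == 0:
        raise ValueError("condition and baseline scan sets must be non-empty")
    if np.intersect1d(ci, bi).size:
        raise ValueError("condition and baseline scan sets must be disjoint")
    base = w[bi].mean(axis=0)
    if np.any(base == 0):
        raise ValueError("baseline mean is zero; cannot form percent change")
    return 100.0 * (w[ci].mean(axis=0) - base) / base


def cnr(window: np.ndarray, condition_scans, baseline_scans) -> np.ndarray:
    """Contrast-to-noise ratio per ROI.

    Condition-minus-baseline mean divided by the SD of the baseline
    residuals after removing a linear trend from the baseline scans.
    """
    w = np.atleast_2d(np.asarray(window, dtype=float))
    ci = np.asarray(condition_scans, dtype=int)
    bi = np.asarray(baseline_scans, dtype=int)
    if bi.size < 2:
        raise ValueError("CNR needs at least two baseline scans")
    base = w[bi]
    t = np.arange(bi.size, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    resid = base - X @ np.linalg.lstsq(X, base, rcond=None)[0]
    sd = resid.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("baseline variance is zero; CNR undefined")
    return (w[ci].mean(axis=0) - base.mean(axis=0)) / sd


@dataclass(frozen=True)
class ActivationSummary:
    psc: np.ndarray
    cnr: np.ndarray
    differential: float


def differential_feedback(
    psc_left: float,
    psc_right: float,
    condition: str,
    contralateral_positive: bool = True,
) -> tuple[float, float]:
    """Left-minus-right percent-signal-change feedback for one trial.

    Returns ``(raw, aligned)`` where ``raw = psc_left - psc_right`` and
    ``aligned`` is sign-flipped so that positive values mean
    condition-appropriate lateralization.  With the default convention
    attention engages the contralateral hemisphere, so an aL trial is
    successful when the right hemisphere leads (raw < 0).
    """
    if not (np.isfinite(psc_left) and np.isfinite(psc_right)):
        raise ValueError("percent signal changes must be finite")
    raw = float(psc_left - psc_right)
    if condition not in ("aL", "aR"):
        raise ValueError(f"unknown condition {condition!r}")
    flip = (condition == "aL") == contralateral_positive
    return raw, -raw if flip else raw


def jarque_bera(values) -> tuple[float, float]:
    """Jarque-Bera normality statistic and its chi^2(2) p-value.

    JB = n/6 * (S^2 + K^2/4) with sample skewness S and excess
    kurtosis K.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 8:
        raise ValueError("Jarque-Bera needs at least 8 observations")
    if v.std() == 0:
        raise ValueError("degenerate sample: zero variance")
    S = skew(v)
    K = kurtosis(v)  # excess kurtosis
    jb = n / 6.0 * (S ** 2 + K ** 2 / 4.0)
    return float(jb), float(chi2.sf(jb, df=2))
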