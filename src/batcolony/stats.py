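"""Circular and nonparametric tests used across the analyses.

Every test returns a uniform :class:`StatResult` record (test name,
statistic, df where applicable, p-value, sample size).  Kuiper's test — the
rotation-invariant circular analogue of the Kolmogorov-Smirnov test — is
implemented here with the standard asymptotic series and small-sample
correction factor; the remaining tests wrap scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, InsufficientSampleError, ValidationError


@dataclass(frozen=True)
class StatResult:
    """Uniform record of one statistical test."""

    test: str
    statistic: float
    p_value: float
    n: int
    df: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValidationError("non-finite test statistic")


# ---------------------------------------------------------------------------
# Kuiper's test
# ---------------------------------------------------------------------------


def _kuiper_fpp(lam: float, tol: float = 1e-12) -> float:
    """Asymptotic tail probability of the Kuiper statistic.

    ``Q(lam) = 2 * sum_{j>=1} (4 j^2 lam^2 - 1) exp(-2 j^2 lam^2)``,
    truncated when terms fall below ``tol``.
    """
    if lam < 0.4:  # series converges too slowly; probability is ~1
        return 1.0
    total = 0.0
    for j in range(1, 200):
        a = 2.0 * (j * lam) ** 2
        term = 2.0 * (2.0 * a - 1.0) * math.exp(-a)
        total += term
        if abs(term) < tol:
            break
    return float(min(max(total, 0.0), 1.0))


def _kuiper_v(u: np.ndarray) -> float:
    """Kuiper V for sorted values u in [0, 1) against the uniform CDF."""
    n = u.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(d_plus + d_minus)


def kuiper_uniform(
    angles_deg, *, period: float = 360.0, mc_below_n: int = 8, mc_reps: int = 10000
) -> StatResult:
    """Kuiper's test of angles against the uniform circular distribution.

    V = D+ + D-, invariant to rotation of all angles.  The p-value uses the
    asymptotic series evaluated at ``V * (sqrt(n) + 0.155 + 0.24/sqrt(n))``;
    below ``mc_below_n`` observations a seeded Monte-Carlo null (10,000
    resamples) replaces the asymptotic formula.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[~np.isnan(a)]
    n = a.size
    if n < 5:
        raise InsufficientSampleError("Kuiper's test needs n >= 5")
    u = np.sort((a % period) / period)
    v = _kuiper_v(u)
    if n < mc_below_n:
        rng = np.random.default_rng(0)
        null = np.sort(rng.random((mc_reps, n)), axis=1)
        i = np.arange(1, n + 1)
        v_null = (i / n - null).max(axis=1) + (null - (i - 1) / n).max(axis=1)
        p = float((np.sum(v_null >= v - 1e-12) + 1) / (mc_reps + 1))
    else:
        lam = v * (math.sqrt(n) + 0.155 + 0.24 / math.sqrt(n))
        p = _kuiper_fpp(lam)
    return StatResult("kuiper_uniform", v, p, n)


def kuiper_two_sample(a_deg, b_deg, *, period: float = 360.0) -> StatResult:
    """Two-sample Kuiper test comparing two circular samples.

    V = max(F1 - F2) + max(F2 - F1); the p-value uses the one-sample
    asymptotic series with effective size ``n1 n2 / (n1 + n2)``.
    """
    a = np.sort(np.asarray(a_deg, dtype=float) % period) / period
    b = np.sort(np.asarray(b_deg, dtype=float) % period) / period
    n1, n2 = a.size, b.size
    if min(n1, n2) < 5:
        raise InsufficientSampleError("two-sample Kuiper needs n >= 5 per sample")
    grid = np.concatenate([a, b])
    f1 = np.searchsorted(a, grid, side="right") / n1
    f2 = np.searchsorted(b, grid, side="right") / n2
    v = float(np.max(f1 - f2) + np.max(f2 - f1))
    ne = n1 * n2 / (n1 + n2)
    lam = v * (math.sqrt(ne) + 0.155 + 0.24 / math.sqrt(ne))
    return StatResult("kuiper_two_sample", v, _kuiper_fpp(lam), n1 + n2)


# ---------------------------------------------------------------------------
# chi-square uniformity, KS, Wilcoxon
# ---------------------------------------------------------------------------


def chi2_uniform(values, n_bins: int, value_range: tuple[float, float]) -> StatResult:
    """Chi-square test of equal occupancy over equal-width bins."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    lo, hi = value_range
    if not hi > lo:
        raise ConfigError("empty value range")
    if x.size / n_bins < 1.0:
        raise InsufficientSampleError(
            f"expected count per bin < 1 (n={x.size}, bins={n_bins})"
        )
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    stat, p = sps.chisquare(counts)
    return StatResult("chi2_uniform", float(stat), float(p), int(x.size), df=n_bins - 1)


def chi2_counts(counts) -> StatResult:
    """Chi-square of observed category counts against equal expectation."""
    counts = np.asarray(counts, dtype=float)
    stat, p = sps.chisquare(counts)
    return StatResult(
        "chi2_counts", float(stat), float(p), int(counts.sum()), df=counts.size - 1
    )


def ks_two_sample(x, y) -> StatResult:
    """Two-sided two-sample Kolmogorov-Smirnov test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientSampleError("KS test needs nonempty samples")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="auto")
    return StatResult(
        "ks_two_sample", float(res.statistic), float(res.pvalue), x.size + y.size
    )


def wilcoxon(
    x,
    y=None,
    *,
    mode: str = "rank_sum",
    correction_factor: float = 1.0,
    null_value: float = 0.0,
) -> StatResult:
    """Wilcoxon tests with an explicit multiple-comparison factor.

    ``rank_sum`` compares two independent samples; the reported W is the
    smaller of the two rank sums (other conventions rescale W).  ``signed_rank``
    is paired when ``y`` is given, else one-sample against ``null_value``.
    Exact p-values are used for small samples without ties (n <= 25 per
    group), the tie-corrected normal approximation otherwise.  The p-value is
    multiplied by ``correction_factor`` and capped at 1.
    """
    if correction_factor < 1.0:
        raise ConfigError("correction_factor must be >= 1")
    x = np.asarray(x, dtype=float)
    if mode == "rank_sum":
        if y is None:
            raise ConfigError("rank_sum mode needs two samples")
        y = np.asarray(y, dtype=float)
        if x.size == 0 or y.size == 0:
            raise InsufficientSampleError("rank-sum test needs nonempty samples")
        combined = np.concatenate([x, y])
        ranks = sps.rankdata(combined)
        w = float(min(ranks[: x.size].sum(), ranks[x.size :].sum()))
        method = "exact" if max(x.size, y.size) <= 25 else "asymptotic"
        if method == "exact" and np.unique(combined).size < combined.size:
            method = "asymptotic"  # ties: exact null enumeration is invalid
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        p = float(res.pvalue)
        n = x.size + y.size
    elif mode == "signed_rank":
        d = x - (np.asarray(y, dtype=float) if y is not None else null_value)
        d = d[~np.isnan(d)]
        if d.size == 0 or np.all(d == 0):
            raise InsufficientSampleError("signed-rank test undefined: all differences zero")
        method = "exact" if d.size <= 25 else "approx"
        try:
            res = sps.wilcoxon(d, alternative="two-sided", method=method)
        except ValueError:
            res = sps.wilcoxon(d, alternative="two-sided", method="approx")
        w = float(res.statistic)
        p = float(res.pvalue)
        n = int(d.size)
    else:
        raise ConfigError(f"unknown wilcoxon mode {mode!r}")
    return StatResult(f"wilcoxon_{mode}", w, min(1.0, p * correction_factor), n)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def pearson(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientSampleError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return StatResult("pearson_r", float(r), float(p), int(x.size))


def spearman(x, y) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientSampleError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman_rho", float(rho), float(p), int(x.size))
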