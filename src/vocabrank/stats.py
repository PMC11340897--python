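"""Statistical machinery for categorical and quantile summaries.

Implements the four estimators the rating analysis leans on:

* Sison-Glaz simultaneous confidence intervals for multinomial proportions,
  built from doubly truncated Poisson moments with an Edgeworth-corrected
  central-limit factor;
* the exact (conditional binomial) McNemar test with the mid-p adjustment,
  and the conditional odds ratio with a mid-p Clopper-Pearson interval;
* order-statistic quantiles with bootstrap percentile confidence intervals;
* Gaussian kernel density profiles on the bounded 0-100 response scale,
  with boundary reflection so no probability mass leaks off the scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "IntervalEstimate",
    "PairedMatchTable",
    "PercentileSummary",
    "DensityProfile",
    "sison_glaz_ci",
    "mcnemar_exact_p",
    "mcnemar_or_ci",
    "midp_clopper_pearson",
    "quantile",
    "bootstrap_quantile_ci",
    "percentile_summary",
    "density_profile",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with a confidence interval.

    ``lower <= point <= upper`` after clamping to the parameter's domain;
    ``method`` tags the construction (e.g. ``"sison-glaz"``).
    """

    point: float
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValidationError(
                f"interval [{self.lower}, {self.upper}] does not bracket point {self.point}"
            )


@dataclass(frozen=True)
class PairedMatchTable:
    """2x2 within-participant match table for two vocabularies on one dimension.

    ``n11`` participants matched the intended ranking under both vocabularies,
    ``n10`` under the first only, ``n01`` under the second only, ``n00`` under
    neither.  The discordant counts ``b = n10`` and ``c = n01`` drive the
    McNemar test.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValidationError("paired match counts must be non-negative")

    @property
    def b(self) -> int:
        return self.n10

    @property
    def c(self) -> int:
        return self.n01

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class PercentileSummary:
    """Quartile summary for one phrase: q25, median (with CI), q75."""

    phrase: str
    q25: float
    median: IntervalEstimate
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median.point <= self.q75):
            raise ValidationError(
                f"{self.phrase!r}: quartiles not ordered "
                f"({self.q25}, {self.median.point}, {self.q75})"
            )


@dataclass(frozen=True)
class DensityProfile:
    """A kernel density estimate evaluated on a grid spanning [0, 100]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


# ---------------------------------------------------------------------------
# Sison-Glaz simultaneous multinomial confidence intervals


def _truncated_poisson_moments(c: int, lam: float) -> tuple[float, float, float, float, float]:
    """First four central moments and normalisation of a Poisson(lam) variable
    doubly truncated to [lam - c, lam + c]."""
    if lam <= 0:
        return 0.0, 0.0, 0.0, 0.0, 1.0
    a, b = lam + c, max(lam - c, 0.0)
    den = sps.poisson.cdf(a, lam) - sps.poisson.cdf(b - 1, lam)
    mu = np.zeros(4)
    for r in range(1, 5):
        pois_a = sps.poisson.cdf(a, lam)
        if a - r >= 0:
            pois_a -= sps.poisson.cdf(a - r, lam)
        if b - r - 1 >= 0:
            pois_b = sps.poisson.cdf(b - 1, lam) - sps.poisson.cdf(b - r - 1, lam)
        elif b - 1 >= 0:
            pois_b = sps.poisson.cdf(b - 1, lam)
        else:
            pois_b = 0.0
        mu[r - 1] = lam**r * (1.0 - (pois_a - pois_b) / den)
    m1 = mu[0]
    m2 = mu[1] + mu[0] - mu[0] ** 2
    m3 = mu[2] + mu[1] * (3 - 3 * mu[0]) + (mu[0] - 3 * mu[0] ** 2 + 2 * mu[0] ** 3)
    m4 = (
        mu[3]
        + mu[2] * (6 - 4 * mu[0])
        + mu[1] * (7 - 12 * mu[0] + 6 * mu[0] ** 2)
        + mu[0] - 4 * mu[0] ** 2 + 6 * mu[0] ** 3 - 3 * mu[0] ** 4
    )
    return m1, m2, m3, m4, den


def _simultaneous_coverage(c: int, counts: np.ndarray) -> float:
    """Estimated probability that every cell count lies within +-c of its
    observed value, via the truncated-Poisson representation of the multinomial
    with an Edgeworth correction for conditioning on the total."""
    n = int(counts.sum())
    mom = np.array([_truncated_poisson_moments(c, float(x)) for x in counts])
    s1 = mom[:, 0].sum()
    s2 = mom[:, 1].sum()
    s3 = mom[:, 2].sum()
    s4 = (mom[:, 3] - 3 * mom[:, 1] ** 2).sum()
    prob_n = 1.0 / (sps.poisson.cdf(n, n) - sps.poisson.cdf(n - 1, n))
    z = (n - s1) / math.sqrt(s2)
    g1 = s3 / s2**1.5
    g2 = s4 / s2**2
    poly = (
        1.0
        + g1 * (z**3 - 3 * z) / 6.0
        + g2 * (z**4 - 6 * z**2 + 3) / 24.0
        + g1**2 * (z**6 - 15 * z**4 + 45 * z**2 - 15) / 72.0
    )
    edgeworth = poly * math.exp(-(z**2) / 2.0) / math.sqrt(2.0 * math.pi)
    prob_x = float(np.prod(mom[:, 4]))
    return prob_n * prob_x * edgeworth / math.sqrt(s2)


def sison_glaz_ci(
    counts: Sequence[int], alpha: float = 0.05
) -> list[IntervalEstimate]:
    """Simultaneous (1 - alpha) confidence intervals for multinomial proportions.

    Finds the largest integer ``c`` whose estimated simultaneous coverage
    falls short of ``1 - alpha``, then interpolates with
    ``gamma = (1 - alpha - nu(c)) / (nu(c+1) - nu(c))`` and returns, for every
    category, ``[p_i - c/N, p_i + c/N + 2*gamma/N]`` clamped to [0, 1].  All
    categories share the same half-widths; coverage is estimated through
    doubly truncated Poisson moments with an Edgeworth correction.

    Parameters
    ----------
    counts
        Cell counts, at least two categories, total >= 1.
    alpha
        Simultaneous non-coverage level, in (0, 1).
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValidationError("sison_glaz_ci needs at least 2 categories")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValidationError("total count must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    p = counts / n
    cov_prev = 0.0
    cc = 1
    cov = _simultaneous_coverage(cc, counts)
    while cov <= 1.0 - alpha and cc < n:
        cov_prev = cov
        cc += 1
        cov = _simultaneous_coverage(cc, counts)
    c_star = cc - 1  # largest c with estimated coverage below 1 - alpha
    gamma = (1.0 - alpha - cov_prev) / (cov - cov_prev)

    out = []
    for pi in p:
        lower = max(0.0, pi - c_star / n)
        upper = min(1.0, pi + c_star / n + 2.0 * gamma / n)
        out.append(
            IntervalEstimate(
                point=float(pi),
                lower=float(lower),
                upper=float(upper),
                level=1.0 - alpha,
                method="sison-glaz",
            )
        )
    return out


# ---------------------------------------------------------------------------
# McNemar test and conditional odds ratio


def mcnemar_exact_p(table: PairedMatchTable, midp: bool = True) -> float:
    """Exact (conditional binomial) McNemar p-value, optionally mid-p adjusted.

    Conditional on the discordant total ``m = b + c``, the first-only count is
    Binomial(m, 1/2) under marginal homogeneity.  The exact p doubles the
    smaller tail (capped at 1); the mid-p variant subtracts the observed
    outcome's point probability once before capping, trading the exact test's
    conservatism for near-nominal error rates.  ``b + c = 0`` returns 1.
    """
    b, c = table.b, table.c
    m = b + c
    if m == 0:
        return 1.0
    lower = sps.binom.cdf(b, m, 0.5)
    upper = sps.binom.sf(b - 1, m, 0.5)
    two_sided = 2.0 * min(lower, upper)
    if midp:
        two_sided -= sps.binom.pmf(b, m, 0.5)
    return float(min(1.0, two_sided))


def midp_clopper_pearson(
    k: int, n: int, level: float = 0.95, tol: float = 1e-10
) -> tuple[float, float]:
    """Mid-p adjusted Clopper-Pearson interval for a binomial proportion.

    Bounds solve the mid-p tail equations
    ``P(X > k; pi) + 0.5 P(X = k; pi) = level_tail`` by bisection to ``tol``;
    ``k = 0`` pins the lower bound at 0 and ``k = n`` the upper at 1.
    """
    if not 0 <= k <= n or n < 1:
        raise ValidationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    half_alpha = (1.0 - level) / 2.0

    def upper_tail(pi: float) -> float:  # P(X >= k) - 0.5 P(X = k)
        return sps.binom.sf(k - 1, n, pi) - 0.5 * sps.binom.pmf(k, n, pi)

    def lower_tail(pi: float) -> float:  # P(X <= k) - 0.5 P(X = k)
        return sps.binom.cdf(k, n, pi) - 0.5 * sps.binom.pmf(k, n, pi)

    def bisect(f, target, lo, hi, increasing):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    lower = 0.0 if k == 0 else bisect(upper_tail, half_alpha, 0.0, 1.0, True)
    upper = 1.0 if k == n else bisect(lower_tail, half_alpha, 0.0, 1.0, False)
    return lower, upper


def mcnemar_or_ci(table: PairedMatchTable, alpha: float = 0.05) -> IntervalEstimate:
    """Conditional McNemar odds ratio b/c with a mid-p Clopper-Pearson CI.

    Treats ``b`` as Binomial(b + c, pi) and maps the mid-p interval for ``pi``
    through ``OR = pi / (1 - pi)``.  ``c = 0`` gives an infinite point and
    upper bound, flagged in the method tag.
    """
    b, c = table.b, table.c
    m = b + c
    if m < 1:
        raise ValidationError("odds ratio undefined with no discordant pairs")
    pi_lo, pi_hi = midp_clopper_pearson(b, m, level=1.0 - alpha)
    point = math.inf if c == 0 else b / c
    lower = pi_lo / (1.0 - pi_lo)
    upper = math.inf if pi_hi >= 1.0 else pi_hi / (1.0 - pi_hi)
    method = "mcnemar-midp-clopper-pearson"
    if not math.isfinite(upper) or not math.isfinite(point):
        method += " (upper unbounded)"
    return IntervalEstimate(
        point=point, lower=lower, upper=upper, level=1.0 - alpha, method=method
    )


# ---------------------------------------------------------------------------
# quantiles and bootstrap


def quantile(values: Sequence[float], q: float) -> float:
    """Order-statistic quantile with linear interpolation (NumPy's default rule)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("quantile of an empty sequence")
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"q must be in [0, 1], got {q}")
    return float(np.quantile(values, q, method="linear"))


def bootstrap_quantile_ci(
    values: Sequence[float],
    q: float,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> IntervalEstimate:
    """Percentile-bootstrap confidence interval for quantile ``q``.

    Resamples with replacement ``n_boot`` times, recomputes the quantile on
    each resample, and returns the (alpha/2, 1 - alpha/2) percentiles of the
    bootstrap distribution.  Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("bootstrap of an empty sequence")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = np.quantile(values[idx], q, axis=1, method="linear")
    alpha = 1.0 - level
    lower, upper = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    point = quantile(values, q)
    return IntervalEstimate(
        point=point,
        lower=float(min(lower, point)),
        upper=float(max(upper, point)),
        level=level,
        method="bootstrap-percentile",
    )


def percentile_summary(
    table,
    vocabulary,
    n_boot: int = 10_000,
    seed: int = 0,
    levels: float = 0.95,
) -> list[PercentileSummary]:
    """Quartile summaries (q25, median with bootstrap CI, q75) per phrase.

    ``table`` is a :class:`~vocabrank.io.RatingTable`; every phrase of the
    vocabulary must have at least one response.
    """
    rng = np.random.default_rng(seed)
    block = table.block(vocabulary)
    out = []
    for phrase in vocabulary.phrases:
        vals = block[phrase].dropna().to_numpy() if phrase in block else np.array([])
        if vals.size == 0:
            raise ValidationError(f"no responses for phrase {phrase!r}")
        med = bootstrap_quantile_ci(vals, 0.5, level=levels, n_boot=n_boot, seed=rng)
        out.append(
            PercentileSummary(
                phrase=phrase,
                q25=quantile(vals, 0.25),
                median=med,
                q75=quantile(vals, 0.75),
            )
        )
    return out


def summary_frame(summaries: Sequence[PercentileSummary]) -> pd.DataFrame:
    """Tabulate phrase quartile summaries (one row per phrase)."""
    return pd.DataFrame(
        [
            {
                "phrase": s.phrase,
                "q25": s.q25,
                "median": s.median.point,
                "median_ci_low": s.median.lower,
                "median_ci_high": s.median.upper,
                "q75": s.q75,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# kernel density on the bounded response scale


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(x for x in (sd, iqr / 1.34) if x > 0)
    return 0.9 * spread * values.size ** (-0.2)


def density_profile(
    values: Sequence[float],
    bandwidth_rule: str | float = "silverman",
    grid_points: int = 401,
) -> DensityProfile:
    """Gaussian kernel density on [0, 100] with boundary reflection.

    Kernel mass falling below 0 or above 100 is reflected back inside the
    scale, so the profile integrates to one over the slider's support instead
    of leaking probability outside it.  Bandwidth follows Silverman's rule
    unless a numeric override is given.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValidationError("density_profile needs at least 2 distinct values")
    if isinstance(bandwidth_rule, str):
        if bandwidth_rule != "silverman":
            raise ValidationError(f"unknown bandwidth rule {bandwidth_rule!r}")
        h = silverman_bandwidth(values)
    else:
        h = float(bandwidth_rule)
        if h <= 0:
            raise ValidationError("bandwidth must be positive")
    grid = np.linspace(0.0, 100.0, grid_points)
    # direct kernel sum plus mirror images about both boundaries
    z = grid[:, None]
    dens = (
        sps.norm.pdf(z, loc=values, scale=h)
        + sps.norm.pdf(z, loc=-values, scale=h)
        + sps.norm.pdf(z, loc=200.0 - values, scale=h)
    ).mean(axis=1)
    return DensityProfile(grid=grid, density=dens, bandwidth=h)
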