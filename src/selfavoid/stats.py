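"""Statistics for categorical collision scores, angle summaries and
closing-speed regressions.

Three procedures cover everything the morphometric outputs need:

* a 95% confidence half-width for a proportion, with a 1/(2n)
  continuity term:  1.96 * sqrt(p(1-p)/n) + 1/(2n);
* two-sample tests — a pooled z test for proportions and a Student t
  test computed from summary statistics (mean, sd, n);
* simple least-squares regression reporting Pearson R and the p value
  of the slope via t = R * sqrt((n-2) / (1 - R^2)) on n-2 df.

Both two-sample tests default to one-tailed; pass ``tails=2`` for the
two-tailed version.  The z test uses the pooled standard error with no
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ProportionCount",
    "SummaryStats",
    "RegressionFit",
    "proportion_ci_halfwidth",
    "format_ci_percent",
    "two_sample_z",
    "two_sample_t_summary",
    "linreg_r_p",
    "p_from_r",
]


@dataclass(frozen=True)
class ProportionCount:
    """k successes out of n categorical trials (e.g. collision yes/no)."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be at least 1")
        if not 0 <= self.successes <= self.trials:
            raise ValueError("need 0 <= successes <= trials")

    @property
    def p(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and sample size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or not math.isfinite(self.sd):
            raise ValueError("sd must be finite and non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_data(cls, data) -> "SummaryStats":
        arr = np.asarray(data, dtype=float)
        return cls(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float  # two-tailed p for the slope
    n: int


def proportion_ci_halfwidth(count: ProportionCount) -> float:
    """95% CI half-width for a proportion, as a fraction in [0, 1].

    Uses the normal approximation plus a 1/(2n) continuity term:
    ``1.96 * sqrt(p(1-p)/n) + 1/(2n)``.  For k = 0 or k = n the
    binomial term vanishes and the half-width is just 1/(2n).
    """
    p, n = count.p, count.trials
    return 1.96 * math.sqrt(p * (1.0 - p) / n) + 1.0 / (2.0 * n)


def format_ci_percent(halfwidth: float) -> str:
    """Render a CI half-width as a percentage string.

    Whole percent for values of 10% and above, one decimal below 10%
    (so 0.3635 -> "±36%" but 0.083 -> "±8.3%").
    """
    pct = 100.0 * halfwidth
    if pct < 10.0:
        return f"±{pct:.1f}%"
    return f"±{round(pct):.0f}%"


def ci_halfwidth_percent(count: ProportionCount) -> float:
    """Half-width on the percent scale, rounded as in ``format_ci_percent``."""
    pct = 100.0 * proportion_ci_halfwidth(count)
    return round(pct, 1) if pct < 10.0 else float(round(pct))


def two_sample_z(
    a: ProportionCount, b: ProportionCount, tails: int = 1
) -> tuple[float, float]:
    """Two-sample z test for proportions (pooled SE, no continuity correction).

    Returns ``(z, p)`` where z is signed (positive when a's proportion
    exceeds b's) and p is the one- or two-tailed normal tail probability
    of |z|.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n1, n2 = a.trials, b.trials
    pooled = (a.successes + b.successes) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0, 0.5 * tails
    z = (a.p - b.p) / se
    p = float(sps.norm.sf(abs(z))) * tails
    return z, min(p, 1.0)


def two_sample_t_summary(
    a: SummaryStats, b: SummaryStats, tails: int = 1, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics.

    Pooled-variance Student t by default (df = n1 + n2 - 2); set
    ``welch=True`` for the unequal-variance form with Welch-Satterthwaite
    df.  Returns ``(t, df, p)`` with t signed (positive when a's mean is
    larger).  If both sds are zero and the means are equal, p = 1 by
    convention.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            df = a.n + b.n - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (
            va**2 / (a.n - 1) + vb**2 / (b.n - 1)
        )
    else:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = float(a.n + b.n - 2)
    t = (a.mean - b.mean) / se
    p = float(sps.t.sf(abs(t), df)) * tails
    return t, df, min(p, 1.0)


def linreg_r_p(x, y) -> RegressionFit:
    """Simple least-squares regression with Pearson R and slope p value.

    The p value is two-tailed, from ``t = R * sqrt((n-2)/(1-R^2))`` on
    n-2 degrees of freedom — the classic spreadsheet-regression output.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("x has zero variance")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    slope = sxy / sxx
    intercept = float(y.mean()) - slope * float(x.mean())
    if syy == 0.0:
        r = 0.0
        p = 1.0
    else:
        r = sxy / math.sqrt(sxx * syy)
        r = max(-1.0, min(1.0, r))
        p = p_from_r(r, n)
    return RegressionFit(slope, intercept, r, p, n)


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson correlation r at sample size n.

    Inverts the regression t statistic ``t = R*sqrt((n-2)/(1-R^2))``
    with n-2 df, so a printed (R, n) pair can be checked without the
    raw data.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("n must be at least 3")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(t, n - 2))
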