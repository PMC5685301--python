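"""Group-comparison statistics: modified Thompson tau outlier rejection
and pooled-variance two-sample t-tests.

The Thompson tau rule removes at most one point per pass — the one with
the largest absolute deviation from the sample mean — whenever that
deviation exceeds tau * s, with

    tau = t * (n - 1) / (sqrt(n) * sqrt(n - 2 + t^2))

and t the two-sided Student quantile at alpha/2 with n-2 degrees of
freedom. Passes repeat on the reduced sample until nothing is removed
or fewer than 3 points remain. Rejection is applied per treatment group
independently, before group means and standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    kept: list[float]
    removed: list[float] = field(default_factory=list)  # in removal order
    alpha: float = 0.05

    @property
    def n_removed(self) -> int:
        return len(self.removed)


@dataclass
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    tail: str  # "two", "greater" or "less"
    method: str = "Student two-sample t (pooled variance)"


def thompson_tau_critical(n: int, alpha: float = 0.05) -> float:
    """Critical tau for sample size n at significance level alpha."""
    if n < 3:
        raise ValueError("tau undefined for n < 3")
    t = sps.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))


def thompson_tau_outliers(values, alpha: float = 0.05) -> OutlierReport:
    """Iterative modified Thompson tau outlier rejection.

    At each pass the single point with the largest |deviation| from the
    current mean is removed if the deviation strictly exceeds tau * s
    (sample standard deviation); iteration stops when no point is
    removed or fewer than 3 points remain. A constant sample (s = 0)
    never loses points.
    """
    vals = [float(v) for v in np.asarray(values, dtype=float).ravel()]
    if len(vals) < 3:
        raise ValueError(f"need at least 3 values, got {len(vals)}")
    removed: list[float] = []
    kept = list(vals)
    while len(kept) >= 3:
        arr = np.asarray(kept)
        s = float(arr.std(ddof=1))
        if s == 0.0:
            break
        dev = np.abs(arr - arr.mean())
        i = int(dev.argmax())
        if dev[i] > thompson_tau_critical(len(kept), alpha) * s:
            removed.append(kept.pop(i))
        else:
            break
    return OutlierReport(kept=kept, removed=removed, alpha=alpha)


def t_test(a, b, tail: str = "two") -> TestResult:
    """Two-sample Student t-test with pooled variance.

    ``tail`` is "two" for a two-sided test, or "greater"/"less" for a
    one-tailed test of mean(a) > mean(b) / mean(a) < mean(b) — the
    direction is supplied by the caller. Degenerate zero-variance
    samples yield the limit p-values (1 for equal means, 0 otherwise).
    """
    if tail not in ("two", "greater", "less"):
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = float(a.mean() - b.mean())
    if pooled_var == 0.0:
        if diff == 0.0:
            return TestResult(0.0, df, 1.0, tail)
        log.warning("zero pooled variance with unequal means; p -> 0 limit")
        stat = math.inf if diff > 0 else -math.inf
        if tail == "two":
            p = 0.0
        elif tail == "greater":
            p = 0.0 if diff > 0 else 1.0
        else:
            p = 0.0 if diff < 0 else 1.0
        return TestResult(stat, df, p, tail)
    stat = diff / math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if tail == "two":
        p = 2.0 * sps.t.sf(abs(stat), df)
    elif tail == "greater":
        p = sps.t.sf(stat, df)
    else:
        p = sps.t.cdf(stat, df)
    return TestResult(float(stat), float(df), float(min(p, 1.0)), tail)
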