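"""Nonparametric survival: Kaplan–Meier estimation and the log-rank test.

The product-limit estimator is computed at each distinct event time with
Greenwood's variance and a complementary log-log (Kalbfleisch–Prentice)
confidence interval, which respects the [0, 1] range.  Deaths precede
censorings at tied times, the standard convention.  The k-group log-rank
statistic uses the hypergeometric variance of the observed death counts at
each distinct event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if times.size == 0:
        raise ValueError("at least one subject is required")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("survival times must be positive and finite")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


@dataclass(frozen=True)
class KMCurve:
    """Step-function survival estimate with pointwise confidence band.

    ``median`` is the earliest event time at which survival drops to 0.5 or
    below, or ``None`` if the curve never reaches 0.5.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None
    level: float = 0.95

    def survival_at(self, t) -> np.ndarray:
        """S(t) for scalar or array t (right-continuous step function)."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(self.event_times, t, side="right") - 1
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out[0]) if scalar else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def km_estimate(times, events, level: float = 0.95) -> KMCurve:
    """Product-limit estimate of the survival function.

    An all-censored sample yields the constant curve S ≡ 1 with undefined
    median, not an error.
    """
    times, events = _check_times(times, events)
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")

    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        empty = np.array([])
        return KMCurve(empty, empty.astype(int), empty.astype(int), empty, empty, empty, None, level)

    at_risk = np.array([(times >= t).sum() for t in event_times])
    deaths = np.array([((times == t) & (events == 1)).sum() for t in event_times])
    survival = np.cumprod(1.0 - deaths / at_risk)

    # Greenwood: Var(S) = S^2 * cumsum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        green = np.cumsum(deaths / (at_risk * (at_risk - deaths)))
        var = survival**2 * green
        z = stats.norm.ppf(0.5 + level / 2.0)
        # CI on log(-log S): S^{exp(± z * se / (S log S))}
        se_cll = np.sqrt(var) / np.abs(survival * np.log(survival))
        lower = survival ** np.exp(z * se_cll)
        upper = survival ** np.exp(-z * se_cll)
    degenerate = (survival <= 0.0) | (survival >= 1.0) | ~np.isfinite(se_cll)
    lower = np.where(degenerate, survival, lower)
    upper = np.where(degenerate, survival, upper)

    below = survival <= 0.5
    median = float(event_times[below.argmax()]) if below.any() else None
    return KMCurve(event_times, at_risk, deaths, survival, lower, upper, median, level)


def logrank_test(times, events, group_labels) -> tuple[float, int, float]:
    """k-group log-rank test of survival-curve homogeneity.

    Returns ``(chi_square, df, p_value)`` with df = k − 1 and the p-value
    from the chi-square upper tail.
    """
    times, events = _check_times(times, events)
    group_labels = np.asarray(group_labels)
    if group_labels.shape != times.shape:
        raise ValueError("group_labels must match times in length")
    groups = np.unique(group_labels)
    k = groups.size
    if k < 2:
        raise ValueError("log-rank test requires at least two groups")

    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk_g = np.array([(times[group_labels == g] >= t).sum() for g in groups], dtype=float)
        n_t = at_risk_g.sum()
        d_t = float(((times == t) & (events == 1)).sum())
        d_g = np.array(
            [((times == t) & (events == 1) & (group_labels == g)).sum() for g in groups],
            dtype=float,
        )
        observed += d_g
        p_g = at_risk_g / n_t
        expected += d_t * p_g
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1.0)
            cov += factor * (np.diag(p_g) - np.outer(p_g, p_g))

    # quadratic form over the first k-1 groups (the k-th is redundant)
    diff = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(v) @ diff) if diff.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
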