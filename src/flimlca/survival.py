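"""Kaplan-Meier estimation, log-rank tests and univariable hazard ratios.

Thin, validated wrappers around lifelines that return the package's own
result containers.  Median survival confidence intervals use the log-log
(exponential Greenwood) transform; with an even number of uncensored
subjects the median is the lower of the two central event times (the first
time the survival curve reaches 0.5).  Cox ties are handled by the Efron
approximation (the lifelines default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

__all__ = ["KmCurve", "km_estimate", "logrank", "median_difference",
           "univariable_hr", "plot_km"]


@dataclass
class KmCurve:
    times: np.ndarray              # event-time grid (observed event times)
    survival: np.ndarray           # S(t) on the grid
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float                  # NaN when never reached
    median_ci: tuple               # (low, high), NaN when unavailable
    ci_low: np.ndarray
    ci_high: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_risk": self.at_risk, "n_event": self.n_events,
            "survival": self.survival, "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if (t < 0).any() or np.isnan(t).any():
        raise ValueError("times must be non-negative and non-missing")
    if not np.isin(np.unique(e), [0.0, 1.0]).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KmCurve:
    """Product-limit survival estimate with log-log median CI."""
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    ev = kmf.event_table
    grid = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    ci = kmf.confidence_interval_
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = math.nan
        med_ci = (math.nan, math.nan)
    else:
        ci_med = median_survival_times(kmf.confidence_interval_)
        lo = float(ci_med.iloc[0, 0])
        hi = float(ci_med.iloc[0, 1])
        med_ci = (lo if not math.isinf(lo) else math.nan,
                  hi if not math.isinf(hi) else math.nan)
    return KmCurve(
        times=grid,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(),
        n_events=ev["observed"].to_numpy(),
        median=median,
        median_ci=med_ci,
        ci_low=ci.iloc[:, 0].to_numpy(),
        ci_high=ci.iloc[:, 1].to_numpy(),
    )


def plot_km(curves: dict, ax=None, title: str | None = None):
    """Step-plot one or more labelled KM curves; returns the axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=str(label))
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def logrank(times, events, group) -> tuple[float, float]:
    """Two-sided log-rank test across >= 2 groups; returns (chi2, p)."""
    t, e = _as_arrays(times, events)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group labels must match times in length")
    if np.unique(g).size < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def median_difference(km_a: KmCurve, km_b: KmCurve) -> float:
    """median(B) - median(A), in days; both medians must be reached."""
    if math.isnan(km_a.median) or math.isnan(km_b.median):
        raise ValueError("median survival undefined for at least one curve")
    return km_b.median - km_a.median


def univariable_hr(times, events, binary_covariate) -> dict:
    """Cox PH hazard ratio for a single 0/1 covariate with Wald CI and p.

    Returns a dict with keys hr, ci_low, ci_high, p, flags.  When one level
    carries no events the partial likelihood is monotone and the estimate is
    flagged DEGENERATE with no CI.
    """
    t, e = _as_arrays(times, events)
    x = np.asarray(binary_covariate, dtype=float)
    levels = np.unique(x)
    if levels.size != 2:
        raise ValueError("covariate must take exactly two values")
    x01 = (x == levels[1]).astype(float)
    flags: list[str] = []
    for lev in (0.0, 1.0):
        if e[x01 == lev].sum() == 0:
            flags.append("DEGENERATE")
            return {"hr": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                    "p": math.nan, "flags": flags}
    df = pd.DataFrame({"time": t, "event": e, "x": x01})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_.iloc[0])
    se = float(cph.standard_errors_.iloc[0])
    return {
        "hr": math.exp(beta),
        "ci_low": math.exp(beta - 1.959963984540054 * se),
        "ci_high": math.exp(beta + 1.959963984540054 * se),
        "p": float(cph.summary["p"].iloc[0]),
        "flags": flags,
    }
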