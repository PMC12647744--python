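"""Progression-free and overall survival endpoints.

Product-limit (Kaplan-Meier) estimation with Greenwood variance,
log-log transformed pointwise 95% confidence bands, and the median with
its confidence interval obtained by inverting the log-log band
(Brookmeyer-Crowley).  Estimation is delegated to lifelines'
KaplanMeierFitter, whose defaults are exactly these conventions; the
Greenwood variance is assembled from the fitted risk table.

Times are in months.  Ties between events and censorings at the same
time are resolved with events first.  A median or interval bound is
``inf`` ("not estimable") when the curve or band never reaches 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

__all__ = ["KMEstimate", "km_estimate", "median_with_ci"]


@dataclass(frozen=True)
class KMEstimate:
    """Kaplan-Meier estimate with Greenwood variance and 95% bands."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood pointwise variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "greenwood_variance": self.variance,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def km_estimate(times, events, alpha: float = 0.05) -> KMEstimate:
    """Fit the product-limit estimator to (time, event) records.

    Parameters
    ----------
    times
        Follow-up times in months, one per patient.
    events
        Event indicators; True marks progression/death, False censoring.
    alpha
        Two-sided band level (0.05 gives 95% bands).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one record")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.all(times == 0) and not np.any(events):
        raise ValueError("degenerate input: all times zero with no events")

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)

    sf = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)

    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    table = kmf.event_table
    d = table["observed"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
    cum = np.cumsum(np.where(d > 0, terms, 0.0))
    var = surv**2 * cum

    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo = float(med_ci.iloc[0, 0])
    hi = float(med_ci.iloc[0, 1])

    return KMEstimate(
        times=grid,
        survival=surv,
        variance=var,
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        median=median,
        median_ci=(lo, hi),
        n=int(times.size),
        n_events=int(events.sum()),
    )


def median_with_ci(estimate: KMEstimate) -> tuple[float, float, float]:
    """Median survival with its 95% interval; ``inf`` marks not estimable."""
    return estimate.median, estimate.median_ci[0], estimate.median_ci[1]
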