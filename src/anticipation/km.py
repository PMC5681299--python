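"""Kaplan-Meier summaries of time to first Lynch-associated diagnosis.

Thin layer over :class:`lifelines.KaplanMeierFitter`: product-limit curves
with exponential-Greenwood (log-minus-log) 95% bands, medians with
band-inversion confidence intervals, and reverse-KM median follow-up.
Time is age in years, measured from birth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

__all__ = ["KmCurve", "km_estimate", "km_median", "median_followup", "survival_at"]

NOT_REACHED = math.inf


@dataclass
class KmCurve:
    """Product-limit estimate as a right-continuous step function.

    Steps are recorded at event times only; ``survival`` etc. give the value
    just after each event time.  ``median`` and the bounds of ``median_ci``
    are ``math.inf`` when the curve never reaches the corresponding level
    ("not reached").
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple[float, float]
    label: str = ""
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "stratum": self.label or "all",
            }
        )


def _empty_curve(label: str) -> KmCurve:
    z = np.array([], dtype=float)
    return KmCurve(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                   NOT_REACHED, (NOT_REACHED, NOT_REACHED), label=label, n=0)


def km_estimate(
    ages: Sequence[float],
    events: Sequence[bool],
    strata: Sequence | None = None,
    label: str = "",
) -> KmCurve | dict[str, KmCurve]:
    """Kaplan-Meier curve(s) for age at first diagnosis.

    Ties at an age are processed events-before-censorings (the product-limit
    convention).  With ``strata`` given, returns one curve per stratum value.
    """
    ages = np.asarray(ages, dtype=float)
    events = np.asarray(events, dtype=bool)
    if strata is not None:
        strata = np.asarray(strata)
        return {
            str(s): km_estimate(ages[strata == s], events[strata == s], label=str(s))
            for s in pd.unique(strata)
        }
    if ages.size == 0:
        return _empty_curve(label)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")

    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(ages, event_observed=events, label=label or "KM")
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    times = table.index.to_numpy(dtype=float)[mask]
    sf = kmf.survival_function_.iloc[:, 0].to_numpy()[mask]
    ci = kmf.confidence_interval_
    lower = ci.iloc[:, 0].to_numpy()[mask]
    upper = ci.iloc[:, 1].to_numpy()[mask]

    med = float(kmf.median_survival_time_)
    med_band = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_band.iloc[0, 0]), float(med_band.iloc[0, 1])
    return KmCurve(
        event_times=times,
        at_risk=table["at_risk"].to_numpy(dtype=float)[mask],
        events=table["observed"].to_numpy(dtype=float)[mask],
        survival=sf,
        ci_lower=lower,
        ci_upper=upper,
        median=med,
        median_ci=(lo, hi),
        label=label,
        n=int(ages.size),
    )


def km_median(curve: KmCurve) -> tuple[float, tuple[float, float]]:
    """Median onset age (smallest time with survival <= 0.5) and its 95% CI
    from inversion of the log-minus-log confidence band; ``math.inf`` marks
    "not reached" (possibly one-sided for the CI bounds)."""
    return curve.median, curve.median_ci


def median_followup(ages: Sequence[float], events: Sequence[bool]) -> float:
    """Median follow-up by reverse Kaplan-Meier (censoring as the event).

    With no censored subjects the reverse curve never drops below 1/2 and
    the result is ``math.inf`` ("not reached").
    """
    ages = np.asarray(ages, dtype=float)
    events = np.asarray(events, dtype=bool)
    if ages.size == 0:
        return NOT_REACHED
    kmf = KaplanMeierFitter()
    kmf.fit(ages, event_observed=~events)
    return float(kmf.median_survival_time_)


def survival_at(curve: KmCurve, t: float) -> float:
    """Right-continuous step-function evaluation of the survival curve."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if curve.event_times.size == 0:
        return 1.0
    idx = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])
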