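"""Tumor-growth and survival analysis for the two-arm dosing comparison.

Tumor volume follows the caliper convention ``width² × length × 0.5`` (mm³).
Survival over the 30-day follow-up is summarized with the Kaplan–Meier
product-limit estimator and groups are compared with the two-group log-rank
test; scalar endpoints (penetration AUC, accumulation, volume at a day) are
compared with a two-sided Welch t-test.  Non-death at end of follow-up is
treated as right-censoring.  At tied times deaths are processed before
censorings, so subjects censored at t remain at risk for deaths at t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .exceptions import UsageError


@dataclass
class GrowthRecord:
    """One caliper measurement: animal, group, day, tumor volume (mm³).

    ``width``/``length`` (mm) are optional; when both are present the volume
    must equal ``width² × length × 0.5``.  Direct volume entry (no calipers)
    is accepted, as growth-curve data often record volumes only.
    """

    animal_id: str
    group: str
    day: int
    volume: float
    width: float | None = None
    length: float | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise UsageError("day must be >= 0")
        if self.width is not None and self.length is not None:
            expected = tumor_volume(self.width, self.length)
            if not np.isclose(self.volume, expected, rtol=1e-6):
                raise UsageError(
                    f"volume {self.volume} inconsistent with width²×length×0.5 = {expected}")
        if not self.volume > 0:
            raise UsageError("volume must be > 0")


@dataclass
class SurvivalRecord:
    """One animal's follow-up: time (days) and whether death was observed."""

    animal_id: str
    group: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise UsageError("time must be > 0")


@dataclass
class ComparisonResult:
    """Two-group test result with per-group mean ± sd summaries."""

    name: str
    statistic: float
    p_value: float
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumor volume in mm³: ``width² × length × 0.5``."""
    if not (width > 0 and length > 0):
        raise UsageError("width and length must be > 0")
    return width ** 2 * length * 0.5


def growth_to_frame(records: Iterable[GrowthRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"animal_id": r.animal_id, "group": r.group,
                          "day": r.day, "volume_mm3": r.volume} for r in records])


def survival_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"animal_id": r.animal_id, "group": r.group,
                          "time_days": r.time, "event": int(r.event)} for r in records])


def growth_summary(records: Sequence[GrowthRecord] | pd.DataFrame,
                   groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-(group, day) mean ± sample sd of tumor volume.

    Days observed in a single animal carry sd = 0 with n = 1.  If ``groups``
    is given, groups absent from the data trigger a warning.
    """
    frame = records if isinstance(records, pd.DataFrame) else growth_to_frame(records)
    if frame.empty:
        raise UsageError("growth_summary: no records")
    if groups is not None:
        for g in groups:
            if g not in set(frame["group"]):
                warnings.warn(f"group {g!r} has no growth records", stacklevel=2)
    out = (frame.groupby(["group", "day"])["volume_mm3"]
           .agg(mean_volume_mm3="mean",
                sd_volume_mm3=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
                n="size")
           .reset_index())
    return out


def km_estimate(records: Sequence[SurvivalRecord] | pd.DataFrame,
                group: str) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier survival curve for one group.

    Returns ``(times, survival)`` step-function arrays starting at
    ``(0, 1.0)``; survival is nonincreasing and right-censoring is handled by
    the product-limit estimator.
    """
    frame = records if isinstance(records, pd.DataFrame) else survival_to_frame(records)
    sel = frame[frame["group"] == group]
    if sel.empty:
        raise UsageError(f"km_estimate: no records for group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sel["time_days"], event_observed=sel["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return times, surv


def logrank_test(records: Sequence[SurvivalRecord] | pd.DataFrame,
                 group_a: str, group_b: str) -> ComparisonResult:
    """Two-group log-rank test (chi-square with 1 df) on survival times."""
    frame = records if isinstance(records, pd.DataFrame) else survival_to_frame(records)
    a = frame[frame["group"] == group_a]
    b = frame[frame["group"] == group_b]
    if a.empty or b.empty:
        raise UsageError("logrank_test: both groups must be nonempty")
    if int(a["event"].sum() + b["event"].sum()) == 0:
        raise UsageError("logrank_test: no events in either group")
    res = _lifelines_logrank(a["time_days"], b["time_days"],
                             event_observed_A=a["event"], event_observed_B=b["event"])
    return ComparisonResult(
        name="logrank_survival", statistic=float(res.test_statistic),
        p_value=float(res.p_value), group_a=group_a, group_b=group_b,
        mean_a=float(a["time_days"].mean()), sd_a=float(a["time_days"].std(ddof=1) if len(a) > 1 else 0.0),
        n_a=len(a),
        mean_b=float(b["time_days"].mean()), sd_b=float(b["time_days"].std(ddof=1) if len(b) > 1 else 0.0),
        n_b=len(b))


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   kind: str = "auc", group_a: str = "SD", group_b: str = "FD"
                   ) -> ComparisonResult:
    """Welch two-sided t-test between two groups of scalar endpoints."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UsageError("compare_groups: need >= 2 values per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return ComparisonResult(
        name=f"welch_t_{kind}", statistic=float(t), p_value=float(p),
        group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b))
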