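"""Preclinical chemotherapy-response metrics for xenograft growth studies.

Tumor-bearing mice are enrolled at 0.2-0.5 cm3 and followed weekly for up to
84 days or until the tumor reaches 2.5 cm3.  Per mouse the module computes
relative tumor volume (RTV = V(t)/V(0)), the linearly interpolated time to
event (RTV >= 4 or volume >= 2.5 cm3), and an objective response call; per
arm it computes the Kaplan-Meier median event-free survival, the
treated/control ratios (EFS T/C and tumor volume T/C), an exact log-rank
test, a rank-sum volume comparison, and the median group response.

Response classes, from worst to best: PD1 < PD2 < PR < CR < MCR.
Progressive disease (volume increase without sufficient regression) is split
by the growth-delay value (EFS T/C): <= 1.5 -> PD1, > 1.5 -> PD2.  PR is
regression of >= 50% from baseline at some time point with measurable tumor
(>= 0.10 cm3); CR is disappearance of measurable tumor (< 0.10 cm3) at some
time point; MCR additionally requires < 0.10 cm3 at the end of the study.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import mannwhitneyu

MEASURABLE_CM3 = 0.10  # measurable-tumor floor for CR/MCR calls


class ResponseCall(IntEnum):
    PD1 = 0
    PD2 = 1
    PR = 2
    CR = 3
    MCR = 4


@dataclass
class GrowthCurve:
    """Volume time series for one mouse (days from study initiation, cm3)."""

    mouse_id: str
    model_id: str
    arm: str
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.size != self.volumes.size or self.days.size < 1:
            raise ValueError("days and volumes must be equal-length, non-empty")
        if self.days[0] != 0:
            raise ValueError("series must start at day 0")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")

    @property
    def v0(self) -> float:
        return float(self.volumes[0])


@dataclass
class StudyArm:
    """A treatment (or control) group of growth curves for one model."""

    curves: list[GrowthCurve]
    evaluation_period: float = 84.0
    event_rtv: float = 4.0
    size_cap: float = 2.5

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("arm must contain at least one curve")
        models = {c.model_id for c in self.curves}
        if len(models) > 1:
            raise ValueError(f"arm mixes models: {sorted(models)}")


def volume_from_diameter(d_cm: float) -> float:
    """Spherical tumor volume (pi/6) * d^3 from the mean diameter in cm."""
    if d_cm < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi / 6 * d_cm**3


def rtv(curve: GrowthCurve, day: float | None = None) -> float:
    """Relative tumor volume V(day)/V(0); the last recorded day by default."""
    if curve.v0 <= 0:
        raise ValueError("day-0 volume must be positive for RTV")
    if day is None:
        return float(curve.volumes[-1] / curve.v0)
    idx = np.flatnonzero(curve.days == day)
    if idx.size:
        return float(curve.volumes[idx[0]] / curve.v0)
    return volume_at(curve, day) / curve.v0


def volume_at(curve: GrowthCurve, day: float) -> float:
    """Volume at an arbitrary day, linearly interpolated between measurements."""
    if day < curve.days[0] or day > curve.days[-1]:
        raise ValueError(f"day {day} outside measured range for "
                         f"{curve.mouse_id}")
    return float(np.interp(day, curve.days, curve.volumes))


def median_final_rtv(arm: StudyArm) -> float:
    return float(np.median([rtv(c) for c in arm.curves]))


def format_rtv(value: float, cap: float = 10.0) -> str:
    """Report dialect: final RTVs beyond the cap print as '>10'."""
    return f">{cap:g}" if value > cap else f"{value:.2f}"


def time_to_event(curve: GrowthCurve, arm_spec: StudyArm
                  ) -> tuple[float, bool]:
    """Interpolated days to event (RTV threshold or size cap), else censoring.

    The event volume is min(event_rtv * V(0), size_cap).  The crossing time
    is linearly interpolated between the bracketing measurement days; a
    crossing exactly at a measurement day returns that day.  Curves that
    never cross are censored at the evaluation period (or at their last
    measurement if the series ends earlier).
    """
    threshold = min(arm_spec.event_rtv * curve.v0, arm_spec.size_cap)
    above = curve.volumes >= threshold
    above[0] = False  # day 0 cannot be an event
    if above.any():
        j = int(np.argmax(above))
        if curve.volumes[j] == threshold:
            return float(curve.days[j]), True
        d0, d1 = curve.days[j - 1], curve.days[j]
        v0, v1 = curve.volumes[j - 1], curve.volumes[j]
        t = d0 + (d1 - d0) * (threshold - v0) / (v1 - v0)
        return float(t), True
    return float(min(curve.days[-1], arm_spec.evaluation_period)), False


def km_median(arm: StudyArm) -> float:
    """Kaplan-Meier median of interpolated event times; inf when the curve
    never falls to <= 0.5 within the evaluation period (reported '>EP')."""
    if len(arm.curves) < 2:
        raise ValueError("Kaplan-Meier median needs at least 2 mice")
    times, events = zip(*(time_to_event(c, arm) for c in arm.curves))
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times), np.asarray(events, dtype=bool))
    med = float(kmf.median_survival_time_)
    if not np.isfinite(med) or med > arm.evaluation_period:
        return math.inf
    return med


def format_km_median(value: float) -> str:
    return ">EP" if math.isinf(value) else f"{value:.2f}"


def efs_tc(treated: StudyArm, control: StudyArm) -> tuple[float, bool]:
    """EFS T/C: treated over control median time-to-event.

    Returns (value, is_lower_bound).  When the treated median exceeds the
    evaluation period the ratio EP/control_median is reported as a lower
    bound (printed '> x').
    """
    mt, mc = km_median(treated), km_median(control)
    if math.isinf(mc):
        raise ValueError("control arm never reaches its median event time")
    if math.isinf(mt):
        return treated.evaluation_period / mc, True
    return mt / mc, False


def format_efs_tc(value: float, lower_bound: bool) -> str:
    return f">{value:.1f}" if lower_bound else f"{value:.1f}"


def _logrank_score(times: np.ndarray, events: np.ndarray,
                   group: np.ndarray) -> float:
    """Log-rank statistic (observed - expected in group 1), normalised."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group[order]
    n = len(t)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        at_risk = n - i
        at_risk_1 = int(g[i:].sum())
        d = int(e[i:j].sum())
        d1 = int((e[i:j] & (g[i:j] == 1)).sum())
        if d > 0 and at_risk > 1:
            frac = at_risk_1 / at_risk
            o_minus_e += d1 - d * frac
            var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        i = j
    if var <= 0:
        return 0.0
    return o_minus_e / math.sqrt(var)


def exact_logrank(treated: StudyArm, control: StudyArm,
                  max_enumerate: int = 16, n_perm: int = 10000,
                  seed: int = 0) -> float:
    """Exact (or permutation) two-sided log-rank p-value.

    Group labels are permuted over the pooled (time, event) outcomes: full
    enumeration of label assignments when the pooled size is at most
    ``max_enumerate``, otherwise ``n_perm`` random permutations with a fixed
    seed.  p is the fraction of assignments with |statistic| at least the
    observed one.
    """
    tt, te = zip(*(time_to_event(c, treated) for c in treated.curves))
    ct, ce = zip(*(time_to_event(c, control) for c in control.curves))
    times = np.asarray(tt + ct)
    events = np.asarray(te + ce, dtype=bool)
    n1, n = len(tt), len(times)
    group = np.zeros(n, dtype=int)
    group[:n1] = 1
    observed = abs(_logrank_score(times, events, group))
    if observed == 0.0:
        return 1.0
    tol = 1e-12
    if n <= max_enumerate:
        count = total = 0
        for combo in itertools.combinations(range(n), n1):
            g = np.zeros(n, dtype=int)
            g[list(combo)] = 1
            total += 1
            if abs(_logrank_score(times, events, g)) >= observed - tol:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(_logrank_score(times, events, rng.permutation(group))) \
                >= observed - tol:
            count += 1
    return (count + 1) / (n_perm + 1)


def volume_tc(treated: StudyArm, control: StudyArm,
              at_day: float | None = None) -> tuple[float, float, float]:
    """Tumor volume T/C and exact rank-sum p at the comparison day.

    Default comparison day: the last day at which every control mouse is
    still on study.  Returns (T/C, p, day).
    """
    if at_day is None:
        at_day = min(c.days[-1] for c in control.curves)
    tv = np.array([volume_at(c, at_day) for c in treated.curves])
    cv = np.array([volume_at(c, at_day) for c in control.curves])
    if cv.mean() == 0:
        raise ValueError("control mean volume is zero at comparison day")
    if np.all(tv == tv[0]) and np.all(cv == cv[0]) and tv[0] == cv[0]:
        p = 1.0  # degenerate: all observations tied
    else:
        p = float(mannwhitneyu(tv, cv, alternative="two-sided",
                               method="exact" if len(tv) + len(cv) <= 20
                               else "asymptotic").pvalue)
    return float(tv.mean() / cv.mean()), p, float(at_day)


def classify_response(curve: GrowthCurve, growth_delay: float
                      ) -> ResponseCall:
    """Objective response call for one mouse.

    Precedence MCR > CR > PR > PD.  ``growth_delay`` is the arm-level EFS
    T/C, splitting progressive disease into PD1 (<= 1.5) and PD2 (> 1.5).
    """
    if curve.days.size < 2:
        raise ValueError("response call needs at least 2 time points")
    post = curve.volumes[1:]
    if curve.volumes[-1] < MEASURABLE_CM3:
        return ResponseCall.MCR
    if post.min() < MEASURABLE_CM3:
        return ResponseCall.CR
    if post.min() <= 0.5 * curve.v0:
        return ResponseCall.PR
    return ResponseCall.PD2 if growth_delay > 1.5 else ResponseCall.PD1


def median_group_response(arm: StudyArm, growth_delay: float) -> ResponseCall:
    """Median per-mouse call under PD1 < PD2 < PR < CR < MCR ordering;
    the lower class wins on an even split."""
    calls = sorted(classify_response(c, growth_delay) for c in arm.curves)
    return calls[(len(calls) - 1) // 2]


def arm_report(treated: StudyArm, control: StudyArm,
               arm_label: str = "", seed: int = 0) -> dict:
    """All response metrics for one treated arm against its control."""
    km = km_median(treated)
    tc, lower = efs_tc(treated, control)
    vtc, vp, vday = volume_tc(treated, control)
    return {
        "arm": arm_label,
        "km_median_days": format_km_median(km),
        "logrank_p": exact_logrank(treated, control, seed=seed),
        "efs_tc": format_efs_tc(tc, lower),
        "efs_tc_value": tc,
        "median_final_rtv": format_rtv(median_final_rtv(treated)),
        "volume_tc": round(vtc, 4),
        "volume_tc_day": vday,
        "ranksum_p": vp,
        "median_group_response": median_group_response(treated, tc).name,
    }
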