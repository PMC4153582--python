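"""Dose metrics (Cmax, daily AUC) and human-equivalent-dose inversion.

Two daily-AUC conventions are used, matching the dosing calendars they
summarize.  For the 5-day/week monkey toxicity schedule the *adjusted*
daily AUC is the weekly AUC divided by 7.  For daily dosing in children
the steady-state daily AUC averages days 4-7:
``(AUC(0,168) - AUC(0,72)) / 4`` — periodicity is reached within ~3
days.  A human equivalent dose (HED) is the child dose whose
steady-state metric matches a target (e.g. the juvenile-monkey value),
found by bracketing plus bisection on the dose axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ExposureSchedule, Trajectory, simulate
from .scenarios import child, daily_bid_schedule

__all__ = [
    "DoseMetrics",
    "auc",
    "adjusted_daily_auc_monkey",
    "child_daily_auc",
    "cmax_steady_state",
    "find_hed",
    "HEDBracketError",
]

WEEK_H = 168.0


class HEDBracketError(ValueError):
    """Target metric not bracketed by the searched dose interval."""


@dataclass(frozen=True)
class DoseMetrics:
    """Summary exposure metrics over a defined steady-state window."""

    cmax: float                   # ng/mL
    daily_auc: float              # ng/mL·h per day
    window: tuple                 # (start h, end h)
    definition: str               # adjusted_weekly | steady_state_days4to7 | final_day

    def __post_init__(self):
        if self.cmax < 0 or self.daily_auc < 0:
            raise ValueError("dose metrics must be non-negative")
        if self.daily_auc > 24.0 * self.cmax * (1 + 1e-9):
            raise ValueError("daily AUC exceeds 24 h at Cmax")


def auc(traj: Trajectory, t0: float, t1: float,
        analyte: str = "total") -> float:
    """Trapezoidal AUC of plasma MPH concentration over [t0, t1], ng/mL·h."""
    if not (t0 < t1):
        raise ValueError("need t0 < t1")
    if t0 < traj.t[0] - 1e-9 or t1 > traj.t[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] outside trajectory span "
            f"[{traj.t[0]}, {traj.t[-1]}]")
    mask = (traj.t >= t0) & (traj.t <= t1)
    return float(np.trapezoid(traj.conc_plasma(analyte)[mask], traj.t[mask]))


def adjusted_daily_auc_monkey(traj: Trajectory) -> float:
    """Weekly AUC / 7 for the 5-day/week monkey schedule, ng/mL·h per day."""
    if traj.t[-1] < WEEK_H - 1e-9:
        raise ValueError("trajectory must cover a full 168 h week")
    return auc(traj, 0.0, WEEK_H) / 7.0


def child_daily_auc(traj: Trajectory) -> float:
    """Steady-state daily AUC for daily dosing: days 4-7 AUC / 4."""
    if traj.t[-1] < WEEK_H - 1e-9:
        raise ValueError("trajectory must cover a full 168 h week")
    return (auc(traj, 0.0, WEEK_H) - auc(traj, 0.0, 72.0)) / 4.0


def final_day_auc(traj: Trajectory) -> float:
    """AUC over the last 24 h of a one-week run, ng/mL·h per day."""
    if traj.t[-1] < WEEK_H - 1e-9:
        raise ValueError("trajectory must cover a full 168 h week")
    return auc(traj, WEEK_H - 24.0, WEEK_H)


def cmax_steady_state(traj: Trajectory, window: tuple | None = None) -> float:
    """Maximum total-MPH plasma concentration over a window, ng/mL.

    Default window is the full trajectory (appropriate for monkeys,
    which show no accumulation); for children pass days 4-7,
    ``(72.0, 168.0)``.
    """
    if window is None:
        mask = np.ones_like(traj.t, dtype=bool)
    else:
        t0, t1 = window
        if t0 < traj.t[0] - 1e-9 or t1 > traj.t[-1] + 1e-9:
            raise ValueError("window outside trajectory span")
        mask = (traj.t >= t0) & (traj.t <= t1)
    return float(np.max(traj.conc_plasma("total")[mask]))


def child_metrics(age: float, dose_mg_per_kg: float, sex: str = "M",
                  BW: float | None = None, rtol: float = 1e-8) -> DoseMetrics:
    """Steady-state metrics for a child on the BID 4-h-apart daily
    schedule for one week."""
    pop = child(age, route="oral", BW=BW, sex=sex)
    traj = simulate(pop, daily_bid_schedule(dose_mg_per_kg), WEEK_H,
                    rtol=rtol)
    return DoseMetrics(
        cmax=cmax_steady_state(traj, (72.0, WEEK_H)),
        daily_auc=child_daily_auc(traj),
        window=(72.0, WEEK_H),
        definition="steady_state_days4to7",
    )


def find_hed(target: float, metric: str, age: float, sex: str = "M",
             BW: float | None = None,
             dose_interval: tuple = (1e-4, 10.0),
             rel_tol: float = 1e-4, rtol: float = 1e-8,
             monotonicity_grid: int = 4) -> float:
    """Invert the child dose-metric map: the BID 4-h-apart 7-day/week
    dose (mg/kg) whose steady-state ``metric`` ("cmax" or "daily_auc")
    equals ``target``.

    Pre-checks metric monotonicity on a coarse dose grid, then bisects
    the bracketing interval to ``rel_tol`` relative width.
    """
    if target <= 0:
        raise ValueError("target metric must be positive")
    if metric not in ("cmax", "daily_auc"):
        raise ValueError(f"unknown metric {metric!r}")

    def metric_at(dose):
        m = child_metrics(age, dose, sex=sex, BW=BW, rtol=rtol)
        return m.cmax if metric == "cmax" else m.daily_auc

    lo, hi = dose_interval
    grid = np.geomspace(lo, hi, monotonicity_grid)
    vals = [metric_at(d) for d in grid]
    if not all(b > a for a, b in zip(vals, vals[1:])):
        raise RuntimeError(
            "dose metric is not strictly increasing on the search grid; "
            "bisection would be unreliable")
    if not vals[0] <= target <= vals[-1]:
        raise HEDBracketError(
            f"target {target} outside metric range [{vals[0]:.4g}, "
            f"{vals[-1]:.4g}] over doses [{lo}, {hi}] mg/kg")
    # shrink the bracket using the pre-check grid
    i = int(np.searchsorted(vals, target))
    lo, f_lo = grid[i - 1], vals[i - 1]
    hi, f_hi = grid[i], vals[i]
    while (hi - lo) / (0.5 * (hi + lo)) > rel_tol:
        mid = 0.5 * (lo + hi)
        f_mid = metric_at(mid)
        if f_mid < target:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)
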