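"""Canonical study scenarios: populations, body weights and schedules.

Body weights for the named scenarios are the study-consistent values:
70 kg adult human; 9.77 kg adult rhesus and 4.0 kg juvenile rhesus
(within the reported colony ranges and consistent with the scaled
hepatic capacities); 21.3 kg for a 6-year-old boy and 59.4 kg for a
15-year-old boy (consistent with the absolute-dose equivalents of the
per-kg therapeutic doses).
"""

from __future__ import annotations

from .model import ExposureSchedule
from .parameters import PopulationModel, load_population

ADULT_HUMAN_BW = 70.0
ADULT_MONKEY_BW = 9.77
JUVENILE_MONKEY_BW = 4.0
BOY_AGES_BW = {6: 21.3, 15: 59.4}

#: toxicity-study schedule in juvenile monkeys: BID 4 h apart, Mon-Fri
MONKEY_TOX_SCHEDULE = dict(times_of_day=(0.0, 4.0), days="weekdays",
                           duration_days=7)
#: therapeutic-style schedule: BID 4 h apart, every day
DAILY_BID_SCHEDULE = dict(times_of_day=(0.0, 4.0), days="daily",
                          duration_days=7)


def adult_human(route: str = "oral", BW: float = ADULT_HUMAN_BW,
                sex: str = "M") -> PopulationModel:
    return load_population("human", "adult", sex=sex, route=route, BW=BW)


def child(age: float, route: str = "oral", BW: float | None = None,
          sex: str = "M") -> PopulationModel:
    if BW is None:
        try:
            BW = BOY_AGES_BW[int(age)]
        except KeyError:
            raise ValueError(
                f"no canonical body weight for age {age}; pass BW explicitly"
            ) from None
    return load_population("human", "child", sex=sex, route=route,
                           BW=BW, age=age)


def adult_monkey(route: str = "oral", BW: float = ADULT_MONKEY_BW,
                 sex: str = "M") -> PopulationModel:
    return load_population("rhesus", "adult", sex=sex, route=route, BW=BW)


def juvenile_monkey(route: str = "oral", BW: float = JUVENILE_MONKEY_BW,
                    sex: str = "M") -> PopulationModel:
    return load_population("rhesus", "juvenile", sex=sex, route=route, BW=BW)


def monkey_toxicity_schedule(dose_mg_per_kg: float = 2.5) -> ExposureSchedule:
    """The juvenile-monkey toxicity dosing: oral BID 4 h apart, 5 d/wk."""
    return ExposureSchedule(route="oral", dose=dose_mg_per_kg,
                            dose_unit="mg/kg", **MONKEY_TOX_SCHEDULE)


def daily_bid_schedule(dose_mg_per_kg: float) -> ExposureSchedule:
    """Therapeutic-style oral dosing: BID 4 h apart, 7 d/wk."""
    return ExposureSchedule(route="oral", dose=dose_mg_per_kg,
                            dose_unit="mg/kg", **DAILY_BID_SCHEDULE)


def single_oral_dose(dose_mg_per_kg: float = 0.3) -> ExposureSchedule:
    """One oral dose at t = 0 (sensitivity-analysis scenario)."""
    return ExposureSchedule(route="oral", dose=dose_mg_per_kg,
                            dose_unit="mg/kg", times_of_day=(0.0,),
                            days="daily", duration_days=1)


def single_iv_dose(dose_mg: float = 10.0) -> ExposureSchedule:
    """One iv bolus at t = 0 (absolute mg dose)."""
    return ExposureSchedule(route="iv", dose=dose_mg, dose_unit="mg",
                            times_of_day=(0.0,), days="daily",
                            duration_days=1)
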