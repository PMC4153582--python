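import numpy as np
import pytest

from mph_pbpk import scenarios, simulate
from mph_pbpk.dosimetry import WEEK_H


@pytest.fixture(scope="session")
def adult_human_oral():
    return scenarios.adult_human(route="oral")


@pytest.fixture(scope="session")
def juvenile_monkey_oral():
    return scenarios.juvenile_monkey(route="oral")


@pytest.fixture(scope="session")
def jm_tox_week(juvenile_monkey_oral):
    """Juvenile monkey, 2.5 mg/kg BID 4 h apart, weekdays, one week."""
    return simulate(juvenile_monkey_oral,
                    scenarios.monkey_toxicity_schedule(2.5), WEEK_H)


@pytest.fixture(scope="session")
def adult_human_bid_week(adult_human_oral):
    """Adult human, 0.3 mg/kg BID 4 h apart, daily, one week."""
    return simulate(adult_human_oral, scenarios.daily_bid_schedule(0.3),
                    WEEK_H)


@pytest.fixture(scope="session")
def child6_bid_week():
    """6-year-old boy, 0.3 mg/kg BID 4 h apart, daily, one week."""
    pop = scenarios.child(6)
    return simulate(pop, scenarios.daily_bid_schedule(0.3), WEEK_H)


@pytest.fixture(scope="session")
def adult_human_iv_96h():
    pop = scenarios.adult_human(route="iv")
    return simulate(pop, scenarios.single_iv_dose(10.0), 96.0)
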