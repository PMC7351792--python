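import numpy as np
import pandas as pd
import pytest

from otdr import popdata
from otdr.popdata import Condition, TrialTable


def make_trial_table(n_units=6, n_trials=200, n_bins=8, seed=0,
                     rate_fn=None, offers=None, choices=None):
    """Hand-rolled small trial table with controllable rates."""
    rng = np.random.default_rng(seed)
    if offers is None:
        offers = rng.choice([0, 1, 2, 4, 8], size=n_trials)
    if choices is None:
        choices = rng.integers(0, 2, size=n_trials)
    rates = rng.gamma(2.0, 2.0, size=(n_units, n_trials, n_bins))
    if rate_fn is not None:
        rates = rate_fn(rates, offers, choices)
    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "session_id": 0,
        "offer": offers,
        "choice": choices,
        "singleton": False,
        "prev_offer": np.r_[np.nan, offers[:-1]].astype(float),
        "prev_choice": np.r_[np.nan, choices[:-1]].astype(float),
    })
    bin_starts = -0.2 + 0.1 * np.arange(n_bins)
    return TrialTable(rates, trials, list(range(n_units)), bin_starts)


@pytest.fixture
def small_table():
    return make_trial_table(seed=1)


@pytest.fixture
def small_population(small_table):
    table, _ = popdata.filter_units(small_table)
    return popdata.build_population_response(table)


@pytest.fixture
def nine_conditions():
    """The included-condition set: 0-reward accept dropped."""
    conds = [Condition(o, 0) for o in (0, 1, 2, 4, 8)]
    conds += [Condition(o, 1) for o in (1, 2, 4, 8)]
    return sorted(conds)
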