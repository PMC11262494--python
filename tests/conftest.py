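import numpy as np
import pandas as pd
import pytest

import brmcda as b
from brmcda import voyager


@pytest.fixture(scope="session")
def tree():
    return b.default_value_tree()


@pytest.fixture(scope="session")
def default_weights():
    return b.default_weight_specs()


@pytest.fixture(scope="session")
def published_rds():
    return voyager.itt_rate_differences()


@pytest.fixture(scope="session")
def published_weights():
    return voyager.itt_weight_specs()


@pytest.fixture(scope="session")
def default_trial():
    """One synthetic trial at the calibrated default configuration."""
    cfg = b.default_voyager_config(seed=20240402)
    return b.simulate_trial(cfg)


@pytest.fixture()
def hand_fixture():
    """Five patients, enumerable by hand.

    p1: two nonfatal MIs (day 30, 90) -> one MI record at 30.
    p2: fatal bleeding at day 40 -> one fatal-composite record, no bleed record.
    p3: nonfatal stroke day 20 then fatal composite day 60 -> both endpoints.
    p4: event-free.
    p5: ALI at day 100 with last dose at day 50 -> ITT only.
    """
    patients = pd.DataFrame({
        "patient_id": [1, 2, 3, 4, 5],
        "arm": ["active", "active", "control", "control", "active"],
        "followup_end_days": [365.0, 365.0, 365.0, 365.0, 365.0],
        "last_dose_days": [365.0, 365.0, 365.0, 365.0, 50.0],
    })
    events = pd.DataFrame({
        "patient_id": [1, 1, 2, 3, 3, 5],
        "endpoint": ["nonfatal_mi", "nonfatal_mi", "nonfatal_nonich_bleeding",
                     "nonfatal_stroke", "fatal_composite", "nonfatal_ali"],
        "time_days": [30.0, 90.0, 40.0, 20.0, 60.0, 100.0],
        "fatal": [False, False, True, False, True, False],
    })
    return patients, events
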