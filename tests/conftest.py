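import numpy as np
import pandas as pd
import pytest

import seasonri as sri


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated cohort shared across tests."""
    cfg = sri.default_config(seed=11, n_patients=400)
    records, encounters, truth = sri.simulate_cohort(cfg)
    return cfg, records, encounters, truth


def make_encounter(pid, start, end, codes="", death=None, sex="F", age=50):
    return {
        "patient_id": pid,
        "start": pd.Timestamp(start),
        "end": pd.Timestamp(end),
        "codes": codes,
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "sex": sex,
        "age_at_start": age,
    }


def make_record(pid, test, value, ts, sex="F", age=50, unit="mg/L",
                specimen="plasma", lab_id="LAB1"):
    return {
        "patient_id": pid, "test_name": test, "specimen": specimen,
        "unit": unit, "lab_id": lab_id, "value": float(value),
        "timestamp": pd.Timestamp(ts), "sex": sex, "age_at_draw": age,
    }


@pytest.fixture
def toy_ri_table():
    """Standard RI (10, 20) for tests A and B across all sex/age strata."""
    rows = []
    for test in ("A", "B"):
        for sex in ("F", "M"):
            for lo in range(20, 90, 10):
                rows.append({"test_name": test, "specimen": "plasma", "unit": "mg/L",
                             "lab_id": "LAB1", "sex": sex,
                             "age_group": f"[{lo},{lo + 10})",
                             "lower": 10.0, "upper": 20.0})
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
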