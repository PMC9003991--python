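"""Shared fixtures: a hand-enumerated 10-patient dataset exercising every
exclusion filter, and a mid-sized simulated dataset reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vli.cohort import select_cohorts
from vli.features import derive_features
from vli.io_model import Dataset
from vli.synthetic_data import SimulationConfig, generate_dataset


def make_patient(pid, **over):
    row = {
        "patient_id": pid,
        "age": 70.0,
        "sex": "male",
        "height_cm": 170.0,
        "weight_kg": 70.0,
        "sepsis": True,
        "bleeding_dx": False,
        "rrt": False,
        "received_blood_products": False,
        "excess_other_output": False,
        "reliable_fluid_data": True,
        "severity_score": 60.0,
        "comorbidity_score": 3.0,
        "died_in_hospital": False,
        "death_or_discharge_time_h": 200.0,
    }
    row.update(over)
    return row


def standard_events(pid, with_outcome=True):
    """A clean patient's events: hct 36 -> 30, net balance 2500 ml."""
    hct = [
        {"patient_id": pid, "time_h": 0.0, "hct_pct": 36.0},
        {"patient_id": pid, "time_h": 24.0, "hct_pct": 30.0},
    ]
    fluids = [
        {"patient_id": pid, "time_h": 1.0, "volume_ml": 3000.0,
         "direction": "intake"},
        {"patient_id": pid, "time_h": 10.0, "volume_ml": 500.0,
         "direction": "urine_output"},
    ]
    if with_outcome:
        fluids.append({"patient_id": pid, "time_h": 40.0,
                       "volume_ml": 1000.0, "direction": "intake"})
    return hct, fluids


@pytest.fixture
def cascade_dataset():
    """Ten septic patients, hand-enumerated against the exclusion cascade:

    p0, p1  renal replacement therapy            -> filter 'rrt' (2)
    p2      age 15                               -> 'erroneous_demographics' (1)
    p3      no hct in the initial window         -> 'missing_vli_data' (1)
    p4      urine exceeds intake (balance < 0)   -> 'non_positive_balance' (1)
    p5-p9   clean                                -> death cohort (5)
    p5      died at 60 h                         -> fluid filter 'died_before_84h'
    p6      no fluid event after 36 h            -> 'missing_outcome_balance'
    p7-p9   clean                                -> fluid cohort (3)
    """
    patients, hct, fluids = [], [], []
    for i in range(10):
        pid = f"p{i}"
        over = {}
        if i in (0, 1):
            over["rrt"] = True
        if i == 2:
            over["age"] = 15.0
        if i == 5:
            over.update(died_in_hospital=True, death_or_discharge_time_h=60.0)
        patients.append(make_patient(pid, **over))

        h, f = standard_events(pid, with_outcome=(i != 6))
        if i == 3:
            h = [{"patient_id": pid, "time_h": 19.0, "hct_pct": 33.0},
                 {"patient_id": pid, "time_h": 25.0, "hct_pct": 31.0}]
        if i == 4:
            f = [{"patient_id": pid, "time_h": 1.0, "volume_ml": 1000.0,
                  "direction": "intake"},
                 {"patient_id": pid, "time_h": 5.0, "volume_ml": 1500.0,
                  "direction": "urine_output"}]
        if i == 5:
            # died at 60 h: outcome event still charted before death
            f = [e for e in f if e["time_h"] <= 60.0]
        hct.extend(h)
        fluids.extend(f)

    return Dataset(
        patients=pd.DataFrame(patients),
        hct=pd.DataFrame(hct),
        fluids=pd.DataFrame(fluids),
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One mid-sized simulated dataset with features and cohort selection,
    shared across tests that only read it."""
    cfg = SimulationConfig(n_patients=2500, seed=3)
    ds, truth = generate_dataset(cfg)
    feat = derive_features(ds)
    sel = select_cohorts(ds, feat)
    return {"config": cfg, "dataset": ds, "truth": truth,
            "features": feat, "selection": sel}


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
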