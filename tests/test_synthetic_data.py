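"""The hemodilution simulator: closed-form dilution checks, conservation,
determinism, and calibration sanity against the published-cohort anchors."""

import numpy as np
import pandas as pd
import pytest

from vli.features import derive_features
from vli.cohort import select_cohorts
from vli.io_model import validate_dataset
from vli.synthetic_data import (
    SimulationConfig,
    generate_dataset,
    hct_trajectory,
    nadler_blood_volume,
    simulate_patient,
)
from vli.vli_core import build_cohort_rows


def test_closed_form_dilution_no_leak():
    # 2000 ml infusion into BV0 = 5 L at hct 40, lambda = 0:
    # hct = 100 * RCV / (BV0 + 2.0) = 100 * 2.0 / 7.0
    got = hct_trajectory([1.0], [2.0], lam=0.0, bv0_l=5.0, hct0_pct=40.0,
                         query_times=[2.0])
    assert got[0] == pytest.approx(100.0 * 2.0 / 7.0, rel=1e-12)
    # before the infusion the hematocrit is untouched
    before = hct_trajectory([1.0], [2.0], 0.0, 5.0, 40.0, [0.5])
    assert before[0] == pytest.approx(40.0)


def test_total_leak_keeps_hct_constant():
    t = [1.0, 5.0, 10.0]
    vols = [1.5, 2.0, 1.0]              # intakes only, liters
    got = hct_trajectory(t, vols, lam=1.0, bv0_l=5.0, hct0_pct=40.0,
                         query_times=[0.0, 3.0, 7.0, 20.0])
    np.testing.assert_allclose(got, 40.0, rtol=1e-12)


def test_total_leak_with_urine_raises_hct():
    got = hct_trajectory([1.0, 2.0], [2.0, -0.8], lam=1.0, bv0_l=5.0,
                         hct0_pct=40.0, query_times=[3.0])
    assert got[0] > 40.0                # blood concentrates


def test_red_cell_volume_conserved_along_trajectory(rng):
    times = np.sort(rng.uniform(-6, 84, size=25))
    vols = rng.uniform(-1.0, 1.5, size=25)
    lam = 0.35
    bv0, hct0 = 5.2, 38.0
    q = np.linspace(-6, 84, 50)
    hct = hct_trajectory(times, vols, lam, bv0, hct0, q)
    dv = np.where(vols > 0, (1 - lam) * vols, vols)
    cum = np.concatenate([[0.0], np.cumsum(dv)])
    idx = np.searchsorted(times, q, side="right")
    vol = bv0 + cum[idx]
    rcv = hct / 100.0 * vol
    np.testing.assert_allclose(rcv, bv0 * hct0 / 100.0, rtol=1e-12)


def test_nadler_volumes():
    male = nadler_blood_volume(180.0, 80.0, "male")
    assert male == pytest.approx(0.3669 * 1.8 ** 3 + 0.03219 * 80 + 0.6041)
    female = nadler_blood_volume(165.0, 65.0, "female")
    assert female == pytest.approx(0.3561 * 1.65 ** 3 + 0.03308 * 65 + 0.1833)
    assert male > female


def test_generated_dataset_passes_io_invariants(sim_bundle):
    validate_dataset(sim_bundle["dataset"])
    truth = sim_bundle["truth"].table
    assert ((truth["lambda"] >= 0) & (truth["lambda"] <= 1)).all()
    assert (truth["bv0_l"] > 0).all() and (truth["rcv_l"] > 0).all()
    assert (truth["rcv_l"] < truth["bv0_l"]).all()


def test_same_seed_reproduces_exactly():
    cfg = SimulationConfig(n_patients=40, seed=9)
    a, ta = generate_dataset(cfg)
    b, tb = generate_dataset(SimulationConfig(n_patients=40, seed=9))
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.hct, b.hct)
    pd.testing.assert_frame_equal(a.fluids, b.fluids)
    pd.testing.assert_frame_equal(ta.table, tb.table)


def test_patient_course_invariant_to_cohort_size():
    cfg_small = SimulationConfig(n_patients=10, seed=9)
    cfg_big = SimulationConfig(n_patients=25, seed=9)
    for i in (0, 4, 9):
        row_s, hct_s, fl_s, tr_s = simulate_patient(i, cfg_small)
        row_b, hct_b, fl_b, tr_b = simulate_patient(i, cfg_big)
        assert row_s == row_b
        pd.testing.assert_frame_equal(hct_s, hct_b)
        pd.testing.assert_frame_equal(fl_s, fl_b)
        assert tr_s == tr_b


def test_empty_dataset_has_headers():
    ds, truth = generate_dataset(SimulationConfig(n_patients=0, seed=0))
    assert len(ds.patients) == 0 and list(ds.patients.columns)
    assert len(ds.hct) == 0 and len(ds.fluids) == 0
    assert len(truth.table) == 0


def test_cohort_calibration_near_published_anchors(sim_bundle):
    """Loose (±20%) sanity checks of the default calibration against the
    large-ICU-cohort anchors: left-skewed index with median near -2.8,
    initial/final hematocrit near 35.8/31.1%, mortality in the 12-19%
    envelope spanned by the four source databases."""
    ds, feat, sel = (sim_bundle["dataset"], sim_bundle["features"],
                     sim_bundle["selection"])
    rows = build_cohort_rows(ds, feat, sel.death_cohort)
    v = rows["vli"].to_numpy()
    med = np.median(v)
    assert -2.79 * 1.2 <= med <= -2.79 * 0.8
    assert np.mean(v) < np.median(v)    # left skew
    assert rows["hct_initial"].mean() == pytest.approx(35.82, rel=0.2)
    assert rows["hct_final"].mean() == pytest.approx(31.08, rel=0.2)
    mort = rows["died_in_hospital"].mean()
    assert 0.12 <= mort <= 0.19
    bal = rows["net_balance_ml"]
    assert bal.skew() > 0               # positively skewed balances


def test_null_death_rate_matches_logistic_intercept():
    """With the leak coefficient at zero the empirical death rate equals
    the mean of the designed logistic probabilities (law of large numbers)."""
    cfg = SimulationConfig(n_patients=4000, seed=21, death_beta_lambda=0.0)
    ds, truth = generate_dataset(cfg)
    p = ds.patients
    eta = (cfg.death_beta0 + cfg.death_beta_severity * p["severity_score"]
           + cfg.death_beta_age * p["age"])
    expected = float(np.mean(1 / (1 + np.exp(-eta))))
    observed = float(p["died_in_hospital"].mean())
    se = np.sqrt(expected * (1 - expected) / len(p))
    assert abs(observed - expected) < 4 * se


def test_null_balance_uncorrelated_with_leak():
    cfg = SimulationConfig(n_patients=3000, seed=22, balance_slope=0.0)
    ds, truth = generate_dataset(cfg)
    feat = derive_features(ds)
    sel = select_cohorts(ds, feat)
    f = feat.set_index("patient_id").loc[sel.fluid_cohort]
    lam = truth.table.set_index("patient_id").loc[sel.fluid_cohort, "lambda"]
    r = np.corrcoef(lam, f["outcome_balance_ml"])[0, 1]
    assert abs(r) < 0.06


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=-1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(leak_alpha=0.0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(p_sepsis=1.5).validate()
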