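"""Windowed feature extraction: worked examples, brute-force window oracle,
translation invariance, BSA formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vli.config import WindowConfig
from vli.features import (
    compute_bsa,
    compute_net_balance,
    compute_outcome_balance,
    derive_features,
    extract_final_hct,
    extract_initial_hct,
)
from vli.io_model import Dataset


def hct_frame(pairs):
    return pd.DataFrame(
        {"patient_id": "p", "time_h": [t for t, _ in pairs],
         "hct_pct": [v for _, v in pairs]}
    )


def fluid_frame(triples):
    return pd.DataFrame(
        {"patient_id": "p", "time_h": [t for t, _, _ in triples],
         "volume_ml": [v for _, v, _ in triples],
         "direction": [d for _, _, d in triples]}
    )


@pytest.mark.parametrize("pairs,expected", [
    ([(-3.0, 35.0), (2.0, 33.0)], 35.0),          # earliest wins
    ([(18.0, 34.0)], 34.0),                       # closed right endpoint
    ([(19.0, 30.0), (25.0, 29.0)], np.nan),       # nothing inside
    ([(-12.0, 40.0), (0.0, 36.0)], 40.0),         # closed left endpoint
    ([(2.0, 30.0), (2.0, 34.0)], 32.0),           # tie at earliest -> mean
])
def test_initial_hct_examples(pairs, expected):
    got = extract_initial_hct(hct_frame(pairs))
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected)


@pytest.mark.parametrize("pairs,expected", [
    ([(20.0, 30.0), (30.0, 32.0)], 31.0),         # mean of window
    ([(36.0, 28.0)], 28.0),                       # right endpoint included
    ([(18.0, 29.0)], np.nan),                     # t=18 belongs to initial
])
def test_final_hct_examples(pairs, expected):
    got = extract_final_hct(hct_frame(pairs))
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected)


@pytest.mark.parametrize("triples,expected", [
    ([(1, 2000, "intake"), (30, 1500, "intake"), (10, 500, "urine_output")],
     3000.0),
    ([(-6.0, 1000, "intake")], 1000.0),           # closed left boundary
    ([(-7.0, 1000, "intake")], 0.0),              # before window
    ([(5, 800, "other_output")], 0.0),            # other output ignored
    ([], 0.0),
])
def test_net_balance_examples(triples, expected):
    assert compute_net_balance(fluid_frame(triples)) == pytest.approx(expected)


@pytest.mark.parametrize("triples,expected", [
    ([(40, 2500, "intake"), (50, 1200, "urine_output")], 1300.0),
    ([(30, 2500, "intake")], np.nan),             # events only before 36 h
    ([(36.0, 1000, "intake")], np.nan),           # t=36 belongs to first window
    ([(84.0, 700, "intake")], 700.0),             # right endpoint included
    ([(40, 500, "other_output")], np.nan),        # other output is not outcome data
])
def test_outcome_balance_examples(triples, expected):
    got = compute_outcome_balance(fluid_frame(triples))
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_event_at_36h_counted_exactly_once():
    f = fluid_frame([(36.0, 1000, "intake"), (40.0, 500, "intake")])
    assert compute_net_balance(f) == 1000.0
    assert compute_outcome_balance(f) == 500.0


def test_bsa_dubois_value():
    # direct evaluation of the Du Bois formula
    assert compute_bsa(170.0, 70.0) == pytest.approx(
        0.007184 * 70.0 ** 0.425 * 170.0 ** 0.725
    )
    assert compute_bsa(170.0, 70.0) == pytest.approx(1.810, abs=5e-4)


def test_bsa_near_published_cohort_mean():
    # mean height/weight of a large ICU cohort gives BSA close to the
    # reported mean of 1.93 m^2 (mean of function != function of means)
    assert compute_bsa(168.37, 81.07) == pytest.approx(1.93, abs=0.04)


def test_bsa_mosteller_and_errors():
    assert compute_bsa(180.0, 81.0, "mosteller") == pytest.approx(
        np.sqrt(180.0 * 81.0 / 3600.0)
    )
    with pytest.raises(ValueError):
        compute_bsa(170.0, 0.0)
    with pytest.raises(ValueError):
        compute_bsa(170.0, 70.0, "boyd")


# --- brute-force window oracle ------------------------------------------

BOUNDARY_TIMES = [-12.0, -6.0, 18.0, 36.0, 84.0]


def brute_force_features(hct_rows, fluid_rows):
    """Independent scan-filter oracle for all four windowed features."""
    init = [(t, v) for t, v in hct_rows if -12.0 <= t <= 18.0]
    if init:
        tmin = min(t for t, _ in init)
        hct_i = float(np.mean([v for t, v in init if t == tmin]))
    else:
        hct_i = np.nan
    fin = [v for t, v in hct_rows if 18.0 < t <= 36.0]
    hct_f = float(np.mean(fin)) if fin else np.nan

    net = sum(v for t, v, d in fluid_rows if -6.0 <= t <= 36.0 and d == "intake") \
        - sum(v for t, v, d in fluid_rows if -6.0 <= t <= 36.0 and d == "urine_output")
    outc = [(v, d) for t, v, d in fluid_rows
            if 36.0 < t <= 84.0 and d in ("intake", "urine_output")]
    if outc:
        out = sum(v for v, d in outc if d == "intake") \
            - sum(v for v, d in outc if d == "urine_output")
    else:
        out = np.nan
    return hct_i, hct_f, float(net), out


@st.composite
def event_stream(draw):
    time = st.one_of(
        st.sampled_from(BOUNDARY_TIMES),
        st.floats(min_value=-15.0, max_value=90.0, allow_nan=False,
                  allow_infinity=False),
    )
    hct_rows = draw(st.lists(
        st.tuples(time, st.floats(min_value=10.0, max_value=60.0)),
        max_size=12,
    ))
    fluid_rows = draw(st.lists(
        st.tuples(time, st.floats(min_value=0.0, max_value=5000.0),
                  st.sampled_from(["intake", "urine_output", "other_output"])),
        max_size=15,
    ))
    return hct_rows, fluid_rows


@settings(max_examples=150, deadline=None, derandomize=True)
@given(event_stream())
def test_window_membership_matches_brute_force(stream):
    hct_rows, fluid_rows = stream
    h = hct_frame(hct_rows) if hct_rows else hct_frame([]).astype(
        {"time_h": float, "hct_pct": float})
    f = fluid_frame(fluid_rows)
    exp = brute_force_features(hct_rows, fluid_rows)
    got = (extract_initial_hct(h), extract_final_hct(h),
           compute_net_balance(f), compute_outcome_balance(f))
    for g, e in zip(got, exp):
        if isinstance(e, float) and np.isnan(e):
            assert np.isnan(g)
        else:
            assert g == pytest.approx(e)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(event_stream(), st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_translation_invariance(stream, shift):
    """Shifting all event times and all window endpoints by a constant
    leaves every derived feature unchanged."""
    hct_rows, fluid_rows = stream
    h = hct_frame(hct_rows)
    f = fluid_frame(fluid_rows)
    h2 = h.assign(time_h=h["time_h"] + shift)
    f2 = f.assign(time_h=f["time_h"] + shift)
    pairs = [
        (extract_initial_hct(h, (-12.0, 18.0)),
         extract_initial_hct(h2, (-12.0 + shift, 18.0 + shift))),
        (extract_final_hct(h, (18.0, 36.0)),
         extract_final_hct(h2, (18.0 + shift, 36.0 + shift))),
        (compute_net_balance(f, (-6.0, 36.0)),
         compute_net_balance(f2, (-6.0 + shift, 36.0 + shift))),
        (compute_outcome_balance(f, (36.0, 84.0)),
         compute_outcome_balance(f2, (36.0 + shift, 84.0 + shift))),
    ]
    for a, b in pairs:
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert b == pytest.approx(a, rel=1e-12)


def test_vectorized_derivation_matches_scalar_ops(sim_bundle):
    """derive_features (grouped/vectorized) agrees with the per-patient
    scalar operations on simulated data."""
    ds = sim_bundle["dataset"]
    feat = sim_bundle["features"].set_index("patient_id")
    rng = np.random.default_rng(5)
    ids = rng.choice(ds.patients["patient_id"].to_numpy(), size=40,
                     replace=False)
    for pid in ids:
        h = ds.hct[ds.hct["patient_id"] == pid]
        f = ds.fluids[ds.fluids["patient_id"] == pid]
        row = feat.loc[pid]
        for got, exp in (
            (row["hct_initial"], extract_initial_hct(h)),
            (row["hct_final"], extract_final_hct(h)),
            (row["net_balance_ml"], compute_net_balance(f)),
            (row["outcome_balance_ml"], compute_outcome_balance(f)),
        ):
            if np.isnan(exp):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(exp, rel=1e-12)
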