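"""Per-patient time-windowed features entering the leak index.

Four quantities are extracted from the event streams of each ICU stay:

* initial hematocrit — the *first* measurement in the closed window
  [-12, 18] h around admission (pre-ICU emergency-department draws count);
* final hematocrit — the *mean* of measurements in (18, 36] h;
* net fluid balance — intake minus urine output over [-6, 36] h
  (other outputs are tracked only as an exclusion flag, not in the balance);
* outcome fluid balance — intake minus urine output over (36, 84] h,
  the post-resuscitation accumulation outcome.

plus body surface area from height and weight. Window endpoints are
configurable (:class:`vli.config.WindowConfig`); the defaults give each
measurement and each fluid event exactly one window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from vli.config import WindowConfig
from vli.io_model import Dataset

FEATURE_COLUMNS = [
    "patient_id",
    "hct_initial",
    "hct_final",
    "net_balance_ml",
    "outcome_balance_ml",
    "bsa_m2",
    "has_fluid_data",
]


def _in_window(t: np.ndarray, lo: float, hi: float, closed_left: bool) -> np.ndarray:
    left = (t >= lo) if closed_left else (t > lo)
    return left & (t <= hi)


def extract_initial_hct(measurements: pd.DataFrame,
                        window: tuple[float, float] = (-12.0, 18.0)) -> float:
    """First hematocrit in the closed window [lo, hi]; NaN if none.

    Ties at the identical earliest timestamp are averaged so the result is
    deterministic under row reordering.
    """
    t = measurements["time_h"].to_numpy(dtype=float)
    v = measurements["hct_pct"].to_numpy(dtype=float)
    mask = _in_window(t, window[0], window[1], closed_left=True)
    if not mask.any():
        return float("nan")
    t, v = t[mask], v[mask]
    tmin = t.min()
    return float(v[t == tmin].mean())


def extract_final_hct(measurements: pd.DataFrame,
                      window: tuple[float, float] = (18.0, 36.0)) -> float:
    """Mean hematocrit over the half-open window (lo, hi]; NaN if none.

    A measurement at exactly t = lo belongs to the initial window, keeping
    the two hematocrit windows disjoint.
    """
    t = measurements["time_h"].to_numpy(dtype=float)
    v = measurements["hct_pct"].to_numpy(dtype=float)
    mask = _in_window(t, window[0], window[1], closed_left=False)
    if not mask.any():
        return float("nan")
    return float(v[mask].mean())


def compute_net_balance(fluids: pd.DataFrame,
                        window: tuple[float, float] = (-6.0, 36.0)) -> float:
    """Intake minus urine output (ml) over the closed window [lo, hi].

    Returns 0.0 when no event falls in the window (such stays are removed
    downstream by the positive-balance inclusion rule).
    """
    t = fluids["time_h"].to_numpy(dtype=float)
    v = fluids["volume_ml"].to_numpy(dtype=float)
    d = fluids["direction"].to_numpy()
    mask = _in_window(t, window[0], window[1], closed_left=True)
    intake = v[mask & (d == "intake")].sum()
    urine = v[mask & (d == "urine_output")].sum()
    return float(intake - urine)


def compute_outcome_balance(fluids: pd.DataFrame,
                            window: tuple[float, float] = (36.0, 84.0)) -> float:
    """Intake minus urine output (ml) over the half-open window (lo, hi];
    NaN when the window contains no intake and no urine event (the outcome
    is then missing, not zero)."""
    t = fluids["time_h"].to_numpy(dtype=float)
    v = fluids["volume_ml"].to_numpy(dtype=float)
    d = fluids["direction"].to_numpy()
    mask = _in_window(t, window[0], window[1], closed_left=False)
    relevant = mask & ((d == "intake") | (d == "urine_output"))
    if not relevant.any():
        return float("nan")
    intake = v[mask & (d == "intake")].sum()
    urine = v[mask & (d == "urine_output")].sum()
    return float(intake - urine)


def compute_bsa(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m².

    Du Bois (default): 0.007184 * kg^0.425 * cm^0.725.
    Mosteller: sqrt(cm * kg / 3600).
    """
    if not (height_cm > 0 and weight_kg > 0):
        raise ValueError(
            f"height and weight must be positive (got {height_cm}, {weight_kg})"
        )
    if formula == "dubois":
        return float(0.007184 * weight_kg ** 0.425 * height_cm ** 0.725)
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula {formula!r}")


def derive_features(dataset: Dataset,
                    windows: WindowConfig | None = None,
                    bsa_formula: str = "dubois") -> pd.DataFrame:
    """Derive all per-patient features for a dataset (vectorized).

    Returns one row per patient in the patients table with columns
    :data:`FEATURE_COLUMNS`. Missing features are NaN; ``has_fluid_data``
    records whether the stay has any fluid event at all (used by the
    missing-ingredients exclusion step).
    """
    windows = windows or WindowConfig()
    p = dataset.patients
    out = pd.DataFrame({"patient_id": p["patient_id"].to_numpy()})

    h = dataset.hct
    th = h["time_h"].to_numpy(dtype=float)
    lo, hi = windows.initial_hct
    init = h[(th >= lo) & (th <= hi)]
    if len(init):
        # first measurement per patient; ties at the earliest time averaged
        tmin = init.groupby("patient_id")["time_h"].transform("min")
        first = init[init["time_h"] == tmin]
        init_val = first.groupby("patient_id")["hct_pct"].mean()
    else:
        init_val = pd.Series(dtype=float)
    lo, hi = windows.final_hct
    fin = h[(th > lo) & (th <= hi)]
    fin_val = fin.groupby("patient_id")["hct_pct"].mean()

    f = dataset.fluids
    tf = f["time_h"].to_numpy(dtype=float)
    signed = np.where(
        f["direction"].to_numpy() == "intake", 1.0,
        np.where(f["direction"].to_numpy() == "urine_output", -1.0, 0.0),
    ) * f["volume_ml"].to_numpy(dtype=float)
    bal = f.assign(signed_ml=signed)

    lo, hi = windows.net_balance
    in_w = bal[(tf >= lo) & (tf <= hi)]
    net = in_w.groupby("patient_id")["signed_ml"].sum()

    lo, hi = windows.outcome_balance
    out_w = bal[(tf > lo) & (tf <= hi)]
    out_w = out_w[out_w["direction"].isin(["intake", "urine_output"])]
    outcome = out_w.groupby("patient_id")["signed_ml"].sum()

    pid = out["patient_id"]
    out["hct_initial"] = pid.map(init_val)
    out["hct_final"] = pid.map(fin_val)
    out["net_balance_ml"] = pid.map(net).fillna(0.0)
    out["outcome_balance_ml"] = pid.map(outcome)  # NaN = missing outcome
    out["has_fluid_data"] = pid.isin(set(f["patient_id"])).to_numpy()

    valid_hw = (p["height_cm"] > 0) & (p["weight_kg"] > 0)
    bsa = np.full(len(p), np.nan)
    hw = p.loc[valid_hw.fillna(False)]
    if len(hw):
        if bsa_formula == "dubois":
            vals = 0.007184 * hw["weight_kg"] ** 0.425 * hw["height_cm"] ** 0.725
        elif bsa_formula == "mosteller":
            vals = np.sqrt(hw["height_cm"] * hw["weight_kg"] / 3600.0)
        else:
            raise ValueError(f"unknown BSA formula {bsa_formula!r}")
        bsa[valid_hw.fillna(False).to_numpy()] = vals.to_numpy()
    out["bsa_m2"] = bsa
    return out
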