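"""The vascular leak index itself: Eq.-scale arithmetic, tail imputation,
and quartile assignment.

    VLI = ((Hct_final - Hct_initial) / net fluid balance) * BSA * 1000

with hematocrit in percent points, balance in ml and BSA in m²; the factor
1000 puts typical values on a single-digit scale. The index is only defined
for strictly positive net balance (enforced upstream by the cohort filters).
Because charted fluid totals are error-prone, the extreme tails of the
index are median-imputed: values outside the central 90% (by default) are
replaced by the cohort median before quartiles are formed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

QUARTILE_LABELS = ["Q1", "Q2", "Q3", "Q4"]


def compute_vli(hct_initial, hct_final, net_balance_ml, bsa_m2):
    """Vascular leak index (vectorized over array-like inputs).

    Raises ValueError if any net balance is non-positive — the cohort
    filters must have excluded those stays already.
    """
    hct_initial = np.asarray(hct_initial, dtype=float)
    hct_final = np.asarray(hct_final, dtype=float)
    net_balance_ml = np.asarray(net_balance_ml, dtype=float)
    bsa_m2 = np.asarray(bsa_m2, dtype=float)
    if np.any(net_balance_ml <= 0):
        raise ValueError("compute_vli requires strictly positive net balance")
    out = (hct_final - hct_initial) / net_balance_ml * bsa_m2 * 1000.0
    if out.ndim == 0:
        return float(out)
    return out


def impute_tails(vli_values, tail_fraction: float = 0.05):
    """Median-impute both tails of the index distribution.

    Values strictly below the ``tail_fraction`` quantile or strictly above
    the ``1 - tail_fraction`` quantile are replaced by the median of the
    *original* vector (linear-interpolation empirical quantiles throughout,
    so the boundaries are reproducible across implementations). Values equal
    to a boundary are retained.

    Returns ``(imputed_values, imputed_mask)``. With fewer than 20 values a
    5% tail is empty on at least one side; a warning is issued and the
    vector is returned unchanged.
    """
    v = np.asarray(vli_values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("impute_tails: NaN in VLI vector")
    mask = np.zeros(v.shape, dtype=bool)
    if tail_fraction == 0:
        return v.copy(), mask
    if v.size < 20:
        warnings.warn(
            f"impute_tails: only {v.size} values; tails not imputed",
            stacklevel=2,
        )
        return v.copy(), mask
    q_lo = np.quantile(v, tail_fraction)        # linear interpolation (default)
    q_hi = np.quantile(v, 1.0 - tail_fraction)
    med = np.median(v)
    mask = (v < q_lo) | (v > q_hi)
    out = v.copy()
    out[mask] = med
    return out, mask


def assign_quartiles(vli_values) -> np.ndarray:
    """Quartile labels Q1..Q4 (Q1 = lowest index) from the 25/50/75th
    empirical percentiles of the (already imputed) vector.

    Intervals are right-closed: a value equal to a cut point goes to the
    lower quartile, so labels are deterministic and monotone under ties.
    """
    v = np.asarray(vli_values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("assign_quartiles: NaN in VLI vector")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    # right-closed: count how many cut points lie strictly below the value
    idx = np.searchsorted(cuts, v, side="left")
    # searchsorted(side='left') puts v == cut at the cut's own bin → lower quartile
    return np.asarray(QUARTILE_LABELS, dtype=object)[idx]


def build_cohort_rows(dataset, features: pd.DataFrame, cohort_ids,
                      tail_fraction: float = 0.05) -> pd.DataFrame:
    """Assemble the analysis-ready cohort table for a set of patient ids.

    Computes the index for each member, median-imputes the tails within
    this cohort, and assigns quartiles on the imputed values (quartiles are
    always formed after imputation). Returns one row per patient with the
    :data:`vli.io_model.COHORT_COLUMNS` layout.
    """
    ids = list(cohort_ids)
    feat = features.set_index("patient_id").loc[ids]
    pats = dataset.patients.set_index("patient_id").loc[ids]

    vli_raw = compute_vli(
        feat["hct_initial"].to_numpy(),
        feat["hct_final"].to_numpy(),
        feat["net_balance_ml"].to_numpy(),
        feat["bsa_m2"].to_numpy(),
    )
    vli_raw = np.atleast_1d(vli_raw)
    vli, imputed = impute_tails(vli_raw, tail_fraction=tail_fraction)
    quart = assign_quartiles(vli)

    return pd.DataFrame({
        "patient_id": ids,
        "hct_initial": feat["hct_initial"].to_numpy(),
        "hct_final": feat["hct_final"].to_numpy(),
        "net_balance_ml": feat["net_balance_ml"].to_numpy(),
        "bsa_m2": feat["bsa_m2"].to_numpy(),
        "vli": vli,
        "vli_imputed": imputed,
        "vli_quartile": quart,
        "age": pats["age"].to_numpy(),
        "sex": pats["sex"].to_numpy(),
        "severity_score": pats["severity_score"].to_numpy(),
        "comorbidity_score": pats["comorbidity_score"].to_numpy(),
        "died_in_hospital": pats["died_in_hospital"].to_numpy(),
        "outcome_balance_ml": feat["outcome_balance_ml"].to_numpy(),
    })
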