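"""Designed-cohort builders: analysis-ready rows with known true effects,
used to check estimator recovery without the event-level simulator."""

from __future__ import annotations

import numpy as np
import pandas as pd

from vli.vli_core import assign_quartiles


def designed_cohort(n: int, rng: np.random.Generator, *,
                    quartile_logits: dict[str, float] | None = None,
                    base_logit: float = -2.0,
                    balance_means: dict[str, float] | None = None,
                    balance_noise_sd: float = 1200.0) -> pd.DataFrame:
    """Cohort rows whose quartile-level effects are exactly as designed.

    ``quartile_logits`` are additive log-odds of death per quartile
    (Q1 = 0 implied); ``balance_means`` are the 36-84 h balance means per
    quartile. Covariates are drawn but carry no true effect, so adjusted
    and unadjusted fits estimate the same contrasts.
    """
    vli = np.sort(rng.normal(-3.0, 2.0, size=n))   # sorted: quartiles = blocks
    q = assign_quartiles(vli)
    logits = np.full(n, base_logit)
    for name, beta in (quartile_logits or {}).items():
        logits[q == name] += beta
    p = 1.0 / (1.0 + np.exp(-logits))
    died = rng.random(n) < p

    balance = np.zeros(n)
    means = balance_means or {}
    for name in ("Q1", "Q2", "Q3", "Q4"):
        sel = q == name
        balance[sel] = means.get(name, 0.0)
    balance = balance + rng.normal(0.0, balance_noise_sd, size=n)

    return pd.DataFrame({
        "patient_id": [f"d{i}" for i in range(n)],
        "hct_initial": np.full(n, 36.0),
        "hct_final": np.full(n, 31.0),
        "net_balance_ml": np.full(n, 3000.0),
        "bsa_m2": np.full(n, 1.9),
        "vli": vli,
        "vli_imputed": np.zeros(n, dtype=bool),
        "vli_quartile": q,
        "age": rng.uniform(30, 90, size=n),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "severity_score": rng.uniform(20, 120, size=n),
        "comorbidity_score": rng.uniform(0, 10, size=n),
        "died_in_hospital": died,
        "outcome_balance_ml": balance,
    })


def contingency_odds_ratio(rows: pd.DataFrame, q: str) -> float:
    """Closed-form (a*d)/(b*c) odds ratio of death, quartile ``q`` vs Q1."""
    d = rows.groupby("vli_quartile")["died_in_hospital"].agg(["sum", "count"])
    a = d.loc[q, "sum"]
    b = d.loc[q, "count"] - a
    c = d.loc["Q1", "sum"]
    e = d.loc["Q1", "count"] - c
    return float((a * e) / (b * c))
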