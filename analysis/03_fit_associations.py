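"""Fit the association models on the built cohorts.

Death: additive logistic model with a penalized spline for the index;
balance: the Gaussian analogue on the 36-84 h cohort. Quartile GLMs give
the Q2-Q4 vs Q1 contrasts. Writes model summaries (JSON), partial-effect
curves and quartile tables under results/analysis/.
"""

import json
from pathlib import Path

from vli.config import ModelConfig
from vli.io_model import read_cohort
from vli.models import (
    BINARY_DEATH,
    CONTINUOUS_BALANCE,
    fit_balance_gam,
    fit_death_gam,
    fit_quartile_model,
    predict_partial_effect,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    mc = ModelConfig()
    rows_d = read_cohort(OUT / "cohort_death.csv")
    rows_f = read_cohort(OUT / "cohort_fluid.csv")

    summaries = {}
    gam_d = fit_death_gam(rows_d, mc)
    predict_partial_effect(gam_d, mc.grid_size).to_frame().to_csv(
        OUT / "curve_death.csv", index=False)
    summaries["gam_death"] = gam_d.summary_dict()
    print(f"death smooth: ANOVA p = {gam_d.smooth_p_value:.3g}, "
          f"EDF {gam_d.edf:.1f}")

    gam_b = fit_balance_gam(rows_f, mc)
    predict_partial_effect(gam_b, mc.grid_size).to_frame().to_csv(
        OUT / "curve_balance.csv", index=False)
    summaries["gam_balance"] = gam_b.summary_dict()
    print(f"balance smooth: ANOVA p = {gam_b.smooth_p_value:.3g}, "
          f"EDF {gam_b.edf:.1f}")

    q_d = fit_quartile_model(rows_d, BINARY_DEATH, mc.ci_level)
    q_d.table.to_csv(OUT / "quartile_death.csv", index=False)
    summaries["quartile_death"] = q_d.to_dict()
    print("\nOdds of in-hospital death vs Q1:")
    print(q_d.table.round(3).to_string(index=False))

    q_b = fit_quartile_model(rows_f, CONTINUOUS_BALANCE, mc.ci_level)
    q_b.table.to_csv(OUT / "quartile_balance.csv", index=False)
    summaries["quartile_balance"] = q_b.to_dict()
    print("\n36-84 h fluid-balance difference vs Q1 (ml):")
    print(q_b.table.round(1).to_string(index=False))

    with open(OUT / "models.json", "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
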