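"""End-to-end orchestration: dataset -> cohorts -> index -> models ->
artifacts, plus the human-readable report.

All numeric artifacts are plain CSV/JSON written with shortest-repr float
formatting, so a rerun with identical inputs and config is byte-identical
(logs carry no timestamps into artifacts).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from vli.cohort import select_cohorts
from vli.config import RunConfig
from vli.features import derive_features
from vli.io_model import (Dataset, read_cohort, read_dataset, to_csv_exact,
                          write_cohort)
from vli.models import (
    BINARY_DEATH,
    CONTINUOUS_BALANCE,
    ModelFitError,
    fit_balance_gam,
    fit_death_gam,
    fit_quartile_model,
    predict_partial_effect,
)
from vli.vli_core import build_cohort_rows

logger = logging.getLogger(__name__)


class EmptyCohortError(RuntimeError):
    """All patients were removed by the exclusion cascade; the message
    carries the attrition table."""


def run_analysis(dataset: Dataset, config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full analysis on a dataset; optionally write artifacts.

    Returns a dict with cohort tables, attrition tables, both GAM fits and
    partial-effect curves, and both quartile-effect tables. With
    ``out_dir`` set, writes: cohort_death.csv / cohort_fluid.csv,
    attrition_death.csv / attrition_fluid.csv, model JSON summaries,
    curve CSVs (vli, fit, lo, hi) and quartile-effect CSVs.
    """
    config = config or RunConfig()
    features = derive_features(dataset, config.windows, config.bsa_formula)
    selection = select_cohorts(dataset, features, config)

    if not selection.death_cohort:
        raise EmptyCohortError(
            "no patients survive the exclusion cascade\n"
            + selection.attrition_death.to_text("death cohort")
        )

    tail = config.tail_fraction
    rows_death = build_cohort_rows(dataset, features, selection.death_cohort,
                                   tail_fraction=tail)
    if config.impute_per_cohort:
        rows_fluid = build_cohort_rows(dataset, features,
                                       selection.fluid_cohort,
                                       tail_fraction=tail)
    else:
        rows_fluid = rows_death[
            rows_death["patient_id"].isin(selection.fluid_cohort)
        ].reset_index(drop=True)

    results: dict = {
        "config": config,
        "rows_death": rows_death,
        "rows_fluid": rows_fluid,
        "selection": selection,
    }

    mc = config.model
    try:
        gam_death = fit_death_gam(rows_death, mc)
        results["gam_death"] = gam_death
        results["curve_death"] = predict_partial_effect(
            gam_death, mc.grid_size, mc.ci_level
        )
    except ModelFitError as exc:
        logger.warning("death GAM not fitted: %s", exc)
        results["gam_death"] = None
    try:
        gam_balance = fit_balance_gam(rows_fluid, mc)
        results["gam_balance"] = gam_balance
        results["curve_balance"] = predict_partial_effect(
            gam_balance, mc.grid_size, mc.ci_level
        )
    except ModelFitError as exc:
        logger.warning("balance GAM not fitted: %s", exc)
        results["gam_balance"] = None

    try:
        results["quartile_death"] = fit_quartile_model(
            rows_death, BINARY_DEATH, mc.ci_level
        )
    except ModelFitError as exc:
        logger.warning("death quartile model not fitted: %s", exc)
        results["quartile_death"] = None
    try:
        results["quartile_balance"] = fit_quartile_model(
            rows_fluid, CONTINUOUS_BALANCE, mc.ci_level
        )
    except ModelFitError as exc:
        logger.warning("balance quartile model not fitted: %s", exc)
        results["quartile_balance"] = None

    if out_dir is not None:
        write_artifacts(results, out_dir)
    return results


def write_artifacts(results: dict, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel = results["selection"]
    paths = {}

    write_cohort(results["rows_death"], out / "cohort_death.csv")
    write_cohort(results["rows_fluid"], out / "cohort_fluid.csv")
    sel.attrition_death.to_frame().to_csv(out / "attrition_death.csv", index=False)
    sel.attrition_fluid.to_frame().to_csv(out / "attrition_fluid.csv", index=False)
    paths.update({
        "cohort_death": out / "cohort_death.csv",
        "cohort_fluid": out / "cohort_fluid.csv",
        "attrition_death": out / "attrition_death.csv",
        "attrition_fluid": out / "attrition_fluid.csv",
    })

    summaries = {}
    for kind in ("death", "balance"):
        gam = results.get(f"gam_{kind}")
        if gam is not None:
            summaries[f"gam_{kind}"] = gam.summary_dict()
            curve = results[f"curve_{kind}"]
            to_csv_exact(curve.to_frame(), out / f"curve_{kind}.csv")
            paths[f"curve_{kind}"] = out / f"curve_{kind}.csv"
        q = results.get(f"quartile_{kind}")
        if q is not None:
            summaries[f"quartile_{kind}"] = q.to_dict()
            to_csv_exact(q.table, out / f"quartile_{kind}.csv")
            paths[f"quartile_{kind}"] = out / f"quartile_{kind}.csv"
    with open(out / "models.json", "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
    paths["models"] = out / "models.json"

    with open(out / "run_log.txt", "w") as fh:
        fh.write(sel.attrition_death.to_text("Death cohort") + "\n\n")
        fh.write(sel.attrition_fluid.to_text("Fluid-balance cohort") + "\n")
    paths["run_log"] = out / "run_log.txt"
    return {k: str(v) for k, v in paths.items()}


def analyze_directory(data_dir: str | Path, config: RunConfig | None = None,
                      out_dir: str | Path | None = None) -> dict:
    """Read a dataset directory (patients.csv / hct.csv / fluids.csv) and
    run the analysis."""
    d = Path(data_dir)
    ds = read_dataset(d / "patients.csv", d / "hct.csv", d / "fluids.csv")
    return run_analysis(ds, config, out_dir)


REPORT_ARTIFACTS = ["cohort_death.csv", "cohort_fluid.csv",
                    "attrition_death.csv", "attrition_fluid.csv",
                    "models.json"]


def render_report(out_dir: str | Path) -> str:
    """Assemble the markdown run report from the emitted artifacts.

    Every number in the report is recomputed from the CSV/JSON artifacts,
    so the report can be regenerated and cross-checked at any time.
    """
    out = Path(out_dir)
    missing = [a for a in REPORT_ARTIFACTS if not (out / a).exists()]
    if missing:
        raise FileNotFoundError(
            f"cannot build report; missing artifacts in {out}: {missing}"
        )
    rows_death = read_cohort(out / "cohort_death.csv")
    rows_fluid = read_cohort(out / "cohort_fluid.csv")
    att_d = pd.read_csv(out / "attrition_death.csv")
    att_f = pd.read_csv(out / "attrition_fluid.csv")
    with open(out / "models.json") as fh:
        models = json.load(fh)

    v = rows_death["vli"].to_numpy()
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    lines = [
        "# Vascular leak index — run report",
        "",
        "## Cohorts",
        f"- in-hospital-death cohort: n = {len(rows_death)}",
        f"- 36-84 h fluid-balance cohort: n = {len(rows_fluid)}",
        "",
        "### Attrition (death cohort)",
        att_d.to_string(index=False),
        "",
        "### Attrition (fluid-balance cohort)",
        att_f.to_string(index=False),
        "",
        "## VLI distribution (death cohort)",
        f"- median [IQR]: {med:.2f} [{q1:.2f}, {q3:.2f}]",
        f"- imputed tail values: {int(rows_death['vli_imputed'].sum())}",
        f"- in-hospital mortality: {100 * rows_death['died_in_hospital'].mean():.1f}%",
        "",
    ]
    for kind, label, fmt in (
        ("death", "in-hospital death (odds ratios vs Q1)", "{:.2f}"),
        ("balance", "36-84 h fluid balance (mean difference vs Q1, ml)", "{:.0f}"),
    ):
        key = f"quartile_{kind}"
        if key in models:
            lines.append(f"## Quartile effects — {label}")
            for rec in models[key]["effects"]:
                est = fmt.format(rec["estimate"])
                if rec["quartile"] == "Q1":
                    lines.append(f"- Q1: reference ({est})")
                else:
                    lines.append(
                        f"- {rec['quartile']}: {est} "
                        f"[{fmt.format(rec['ci_lo'])}, {fmt.format(rec['ci_hi'])}]"
                    )
            lines.append("")
        gkey = f"gam_{kind}"
        if gkey in models:
            g = models[gkey]
            lines.append(
                f"- smooth-term ANOVA p ({kind}): {g['smooth_p_value']:.3g} "
                f"(LRT {g['smooth_lrt_stat']:.1f} on {g['smooth_lrt_df']} df, "
                f"EDF {g['smooth_edf']:.1f})"
            )
            lines.append("")
    report = "\n".join(lines)
    with open(out / "report.md", "w") as fh:
        fh.write(report)
    return report
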