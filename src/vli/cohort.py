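"""Cohort construction: the inclusion/exclusion cascade and attrition table.

Inclusion is sepsis; exclusions follow in a fixed order with *sequential
first-match attribution* — each removed patient is counted in exactly one
attrition row (the first filter that catches them), so removed counts are
additive down the table, the presentation style of clinical attrition
diagrams. Two cohorts come out:

* the in-hospital-death cohort (all filters through the positive-balance
  rule), and
* the 36–84 h fluid-balance cohort — the subset surviving to 84 h with an
  observed outcome balance; always a subset of the death cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vli.config import RunConfig
from vli.io_model import Dataset

logger = logging.getLogger(__name__)

DEATH_FILTERS = [
    "bleeding_or_blood_products",
    "excess_other_output",
    "rrt",
    "erroneous_demographics",
    "unreliable_fluid_data",
    "missing_vli_data",
    "non_positive_balance",
]

FLUID_FILTERS = [
    "died_before_84h",
    "missing_outcome_balance",
]


@dataclass
class AttritionTable:
    """Ordered (filter_name, n_removed, n_remaining) triples."""

    n_initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_removed: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.n_initial
        self.steps.append((name, n_removed, prev - n_removed))

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["filter_name", "n_removed", "n_remaining"]
        )

    def to_text(self, title: str = "Attrition") -> str:
        lines = [f"{title}: start n={self.n_initial}"]
        for name, rem, left in self.steps:
            lines.append(f"  - {name:<28s} removed {rem:>6d}  remaining {left:>6d}")
        lines.append(f"  final n={self.n_final}")
        return "\n".join(lines)


@dataclass
class CohortSelection:
    death_cohort: list[str]
    fluid_cohort: list[str]
    attrition_death: AttritionTable
    attrition_fluid: AttritionTable


def select_death_cohort(dataset: Dataset, features: pd.DataFrame,
                        config: RunConfig | None = None
                        ) -> tuple[list[str], AttritionTable]:
    """Apply the death-cohort cascade; returns surviving ids (patients-table
    order) and the attrition table.

    Filter order (first match wins): bleeding diagnosis or blood products;
    excess other fluid output; renal replacement therapy; implausible
    demographics (age below the pediatric cutoff or height/weight outside
    plausibility ranges); unreliable fluid charting; missing any index
    ingredient (either hematocrit, BSA, or any fluid data); non-positive
    net balance. Patients without sepsis never enter the table at all.
    """
    config = config or RunConfig()
    p = dataset.patients.merge(features, on="patient_id", how="left")
    p = p[p["sepsis"]].reset_index(drop=True)
    att = AttritionTable(n_initial=len(p))

    lo_h, hi_h = config.height_range
    lo_w, hi_w = config.weight_range
    conditions = {
        "bleeding_or_blood_products":
            p["bleeding_dx"] | p["received_blood_products"],
        "excess_other_output": p["excess_other_output"],
        "rrt": p["rrt"],
        # missing height/weight is a missing-ingredient case, not an
        # implausible-value case, hence the explicit notna() guards
        "erroneous_demographics":
            (p["age"] < config.min_age)
            | (p["height_cm"].notna()
               & ~p["height_cm"].between(lo_h, hi_h, inclusive="neither"))
            | (p["weight_kg"].notna()
               & ~p["weight_kg"].between(lo_w, hi_w, inclusive="neither")),
        "unreliable_fluid_data": ~p["reliable_fluid_data"],
        "missing_vli_data":
            p["hct_initial"].isna() | p["hct_final"].isna()
            | p["bsa_m2"].isna() | ~p["has_fluid_data"],
        "non_positive_balance": p["net_balance_ml"] <= 0,
    }

    alive = np.ones(len(p), dtype=bool)
    for name in DEATH_FILTERS:
        hit = conditions[name].fillna(False).to_numpy(dtype=bool) & alive
        att.add(name, int(hit.sum()))
        alive &= ~hit

    ids = list(p.loc[alive, "patient_id"])
    if not ids:
        logger.warning("death cohort is empty after exclusions")
    return ids, att


def select_fluid_cohort(death_cohort: list[str], dataset: Dataset,
                        features: pd.DataFrame,
                        horizon_h: float = 84.0
                        ) -> tuple[list[str], AttritionTable]:
    """Restrict the death cohort to the fluid-balance outcome population.

    Removes, in order: patients who died strictly before ``horizon_h``
    (death at exactly the horizon is retained), then patients with no
    intake or urine event in the outcome window (missing outcome).
    """
    p = dataset.patients.set_index("patient_id").loc[death_cohort]
    f = features.set_index("patient_id").loc[death_cohort]
    att = AttritionTable(n_initial=len(death_cohort))

    died_early = (
        p["died_in_hospital"]
        & p["death_or_discharge_time_h"].notna()
        & (p["death_or_discharge_time_h"] < horizon_h)
    ).to_numpy()
    att.add("died_before_84h", int(died_early.sum()))
    alive = ~died_early

    missing = f["outcome_balance_ml"].isna().to_numpy() & alive
    att.add("missing_outcome_balance", int(missing.sum()))
    alive &= ~missing

    ids = [pid for pid, keep in zip(death_cohort, alive) if keep]
    if not ids:
        logger.warning("fluid-balance cohort is empty after exclusions")
    return ids, att


def select_cohorts(dataset: Dataset, features: pd.DataFrame,
                   config: RunConfig | None = None) -> CohortSelection:
    """Run both cascades; fluid cohort is by construction a subset of the
    death cohort."""
    death_ids, att_d = select_death_cohort(dataset, features, config)
    fluid_ids, att_f = select_fluid_cohort(death_ids, dataset, features)
    return CohortSelection(
        death_cohort=death_ids,
        fluid_cohort=fluid_ids,
        attrition_death=att_d,
        attrition_fluid=att_f,
    )
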