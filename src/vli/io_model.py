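"""Data model and CSV interchange format for the VLI pipeline.

Three flat tables describe one dataset: ``patients`` (one row per ICU stay),
``hct`` (timestamped hematocrit measurements, percent), and ``fluids``
(timestamped fluid events in ml, typed by direction). All event times are
hours relative to ICU admission (t = 0); negative times are legal and mean
pre-ICU events (e.g. fluids given in the emergency department). Missing
numerics are empty cells; booleans are 0/1. One row per ICU stay — sources
with repeat stays are expected to emit the first stay only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "sepsis",
    "bleeding_dx",
    "rrt",
    "received_blood_products",
    "excess_other_output",
    "reliable_fluid_data",
    "severity_score",
    "comorbidity_score",
    "died_in_hospital",
    "death_or_discharge_time_h",
]

HCT_COLUMNS = ["patient_id", "time_h", "hct_pct"]
FLUID_COLUMNS = ["patient_id", "time_h", "volume_ml", "direction"]

SEXES = frozenset({"male", "female"})
DIRECTIONS = frozenset({"intake", "urine_output", "other_output"})

_BOOL_PATIENT_FIELDS = [
    "sepsis",
    "bleeding_dx",
    "rrt",
    "received_blood_products",
    "excess_other_output",
    "reliable_fluid_data",
    "died_in_hospital",
]

COHORT_COLUMNS = [
    "patient_id",
    "hct_initial",
    "hct_final",
    "net_balance_ml",
    "bsa_m2",
    "vli",
    "vli_imputed",
    "vli_quartile",
    "age",
    "sex",
    "severity_score",
    "comorbidity_score",
    "died_in_hospital",
    "outcome_balance_ml",
]


def _float_repr(x) -> str:
    # shortest repr that round-trips float64 exactly
    return repr(float(x))


def to_csv_exact(df: pd.DataFrame, path_or_buf) -> None:
    """CSV writer whose float formatting round-trips to full precision."""
    df.to_csv(path_or_buf, index=False, float_format=_float_repr)


class DataValidationError(ValueError):
    """Raised when an input table violates the documented column dictionary
    or a typed invariant. The message carries row-indexed diagnostics."""


@dataclass
class Dataset:
    """One ICU dataset: patients plus their hematocrit and fluid events."""

    patients: pd.DataFrame
    hct: pd.DataFrame
    fluids: pd.DataFrame

    def __post_init__(self) -> None:
        validate_dataset(self)

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _check_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    got = list(df.columns)
    unknown = [c for c in got if c not in expected]
    missing = [c for c in expected if c not in got]
    if unknown or missing:
        raise DataValidationError(
            f"{name}: column mismatch (unknown={unknown}, missing={missing}); "
            f"expected exactly {expected}"
        )


def _coerce_numeric(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    """Coerce columns to float, reporting the offending rows on failure."""
    out = df.copy()
    for col in cols:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna() & (out[col].astype(str).str.strip() != "")
        if bad.any():
            rows = list(out.index[bad][:10])
            raise DataValidationError(
                f"{name}: column '{col}' has unparseable numeric values at rows {rows}"
            )
        out[col] = coerced
    return out


def _coerce_bool(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = ~vals.isin([0, 1]) | vals.isna()
        if bad.any():
            rows = list(out.index[bad][:10])
            raise DataValidationError(
                f"{name}: column '{col}' must be 0/1; bad rows {rows}"
            )
        out[col] = vals.astype(bool)
    return out


def validate_dataset(ds: Dataset) -> None:
    """Check every typed invariant; raise DataValidationError on the first
    violation with the offending rows/ids listed."""
    p, h, f = ds.patients, ds.hct, ds.fluids
    _check_columns(p, PATIENT_COLUMNS, "patients")
    _check_columns(h, HCT_COLUMNS, "hct")
    _check_columns(f, FLUID_COLUMNS, "fluids")

    dup = p["patient_id"][p["patient_id"].duplicated()]
    if len(dup):
        raise DataValidationError(f"patients: duplicate patient_id {sorted(set(dup))}")
    bad_sex = p.loc[~p["sex"].isin(list(SEXES)), "patient_id"]
    if len(bad_sex):
        raise DataValidationError(
            f"patients: sex must be male/female; bad ids {list(bad_sex[:10])}"
        )
    if (p["age"] < 0).any():
        ids = list(p.loc[p["age"] < 0, "patient_id"][:10])
        raise DataValidationError(f"patients: negative age for ids {ids}")
    for col in ("height_cm", "weight_kg"):
        nonpos = p[col].notna() & (p[col] <= 0)
        if nonpos.any():
            ids = list(p.loc[nonpos, "patient_id"][:10])
            raise DataValidationError(f"patients: non-positive {col} for ids {ids}")
    if p["severity_score"].isna().any():
        ids = list(p.loc[p["severity_score"].isna(), "patient_id"][:10])
        raise DataValidationError(f"patients: missing severity_score for ids {ids}")

    known = set(p["patient_id"])
    for name, ev in (("hct", h), ("fluids", f)):
        orphans = sorted(set(ev["patient_id"]) - known)
        if orphans:
            raise DataValidationError(
                f"{name}: events reference unknown patient_id(s) {orphans[:20]}"
            )
        if not np.isfinite(ev["time_h"].to_numpy(dtype=float)).all():
            raise DataValidationError(f"{name}: non-finite time_h")

    out_of_range = ~((h["hct_pct"] > 0) & (h["hct_pct"] < 100))
    if out_of_range.any():
        rows = list(h.index[out_of_range][:10])
        raise DataValidationError(
            f"hct: hct_pct must lie strictly in (0, 100); bad rows {rows}"
        )
    if (f["volume_ml"] < 0).any():
        rows = list(f.index[f["volume_ml"] < 0][:10])
        raise DataValidationError(f"fluids: negative volume_ml at rows {rows}")
    bad_dir = ~f["direction"].isin(list(DIRECTIONS))
    if bad_dir.any():
        rows = list(f.index[bad_dir][:10])
        raise DataValidationError(
            f"fluids: direction must be one of {sorted(DIRECTIONS)}; bad rows {rows}"
        )


def read_dataset(patients_path, hct_path, fluids_path) -> Dataset:
    """Read and validate the three-table CSV interchange format.

    Raises
    ------
    FileNotFoundError
        If any of the three files is absent.
    DataValidationError
        On unknown/missing columns, unparseable numerics (row-indexed), or
        any typed-invariant violation, including orphan events whose
        patient_id does not appear in the patients table.
    """
    patients = pd.read_csv(patients_path, dtype={"patient_id": str},
                           float_precision="round_trip")
    hct = pd.read_csv(hct_path, dtype={"patient_id": str},
                      float_precision="round_trip")
    fluids = pd.read_csv(fluids_path, dtype={"patient_id": str},
                         float_precision="round_trip")

    _check_columns(patients, PATIENT_COLUMNS, "patients")
    _check_columns(hct, HCT_COLUMNS, "hct")
    _check_columns(fluids, FLUID_COLUMNS, "fluids")

    patients = _coerce_numeric(
        patients,
        ["age", "height_cm", "weight_kg", "severity_score", "comorbidity_score",
         "death_or_discharge_time_h"],
        "patients",
    )
    patients = _coerce_bool(patients, _BOOL_PATIENT_FIELDS, "patients")
    hct = _coerce_numeric(hct, ["time_h", "hct_pct"], "hct")
    fluids = _coerce_numeric(fluids, ["time_h", "volume_ml"], "fluids")

    return Dataset(patients=patients, hct=hct, fluids=fluids)


def write_dataset(ds: Dataset, patients_path, hct_path, fluids_path) -> None:
    """Write the three tables; floats use shortest-repr so read-back is exact."""
    p = ds.patients.copy()
    for col in _BOOL_PATIENT_FIELDS:
        p[col] = p[col].astype(int)
    to_csv_exact(p, patients_path)
    to_csv_exact(ds.hct, hct_path)
    to_csv_exact(ds.fluids, fluids_path)


def write_cohort(rows: pd.DataFrame, path) -> None:
    """Write an analysis-ready cohort table (one row per patient).

    Column order is fixed (:data:`COHORT_COLUMNS`); float formatting is
    pandas' shortest repr, which round-trips to full precision.
    """
    if len(rows) == 0:
        raise ValueError("write_cohort: refusing to write an empty cohort")
    missing = [c for c in COHORT_COLUMNS if c not in rows.columns]
    if missing:
        raise DataValidationError(f"cohort rows missing columns {missing}")
    out = rows[COHORT_COLUMNS].copy()
    out["vli_imputed"] = out["vli_imputed"].astype(int)
    out["died_in_hospital"] = out["died_in_hospital"].astype(int)
    to_csv_exact(out, path)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    _check_columns(df, COHORT_COLUMNS, "cohort")
    df["vli_imputed"] = df["vli_imputed"].astype(bool)
    df["died_in_hospital"] = df["died_in_hospital"].astype(bool)
    return df


def dataset_to_csv_strings(ds: Dataset) -> dict[str, str]:
    """Serialize all three tables to in-memory CSV text (used for manifest
    hashing and byte-determinism checks)."""
    bufs: dict[str, str] = {}
    p, h, f = io.StringIO(), io.StringIO(), io.StringIO()
    write_dataset(ds, p, h, f)
    bufs["patients"] = p.getvalue()
    bufs["hct"] = h.getvalue()
    bufs["fluids"] = f.getvalue()
    return bufs
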