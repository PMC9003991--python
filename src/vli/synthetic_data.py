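"""Seeded synthetic ICU datasets with a known ground-truth leak fraction.

Each simulated patient carries a latent leak fraction λ ∈ [0, 1]: the
fraction of every infusion that immediately leaves the vasculature. The
hemodilution model is deliberately minimal — exactly the physiology the
leak index can see:

* baseline blood volume BV₀ from the Nadler sex-specific formulas
  (male: 0.3669·h³ + 0.03219·w + 0.6041 L; female: 0.3561·h³ + 0.03308·w
  + 0.1833 L, height in meters, weight in kg);
* red-cell volume RCV = BV₀ · Hct₀ / 100, conserved throughout the stay;
* every fluid event updates intravascular volume by
  ΔV = (1 − λ)·intake − urine, and hct(t) = 100 · RCV / V(t);
* measurements are the true hct plus Gaussian charting noise.

With λ = 0 all fluid dilutes (hct falls steeply); with λ = 1 infusions
never reach the vasculature, and any urine output *concentrates* the blood,
so the hematocrit can rise while fluids are being given — the signature
the index scores as high leak.

Outcomes are generated on top with known coefficients: death is Bernoulli
on a logit linear in λ, severity and age; the 36–84 h fluid balance is
realized exactly as intercept + slope·λ + noise through generated intake
and urine events. Measurements and events after death are removed, as in
real charting. Per-patient RNG substreams are derived from the top-level
seed so patient i's course does not depend on ``n_patients``.

Default parameters are calibrated to published large-ICU-cohort summary
statistics: a
left-skewed index distribution with median near −2.8, cohort mortality in
the 12–19% band, initial/final hematocrit means near 35.8/31.1%, and
positively skewed fluid balances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vli.io_model import Dataset, PATIENT_COLUMNS, to_csv_exact, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """All knobs of the generator, with calibrated defaults (units noted)."""

    n_patients: int = 1000
    seed: int = 0

    # demographics
    age_mean: float = 66.0           # years
    age_sd: float = 16.0
    age_range: tuple[float, float] = (18.0, 95.0)
    p_male: float = 0.53
    height_mean: dict = field(default_factory=lambda: {"male": 175.0, "female": 162.0})
    height_sd: float = 7.0           # cm
    weight_mean: dict = field(default_factory=lambda: {"male": 87.0, "female": 74.0})
    weight_sd: float = 16.0          # kg
    height_clip: tuple[float, float] = (120.0, 215.0)
    weight_clip: tuple[float, float] = (35.0, 200.0)

    # baseline physiology
    hct0_mean: float = 36.5          # percent
    hct0_sd: float = 5.0
    hct0_clip: tuple[float, float] = (18.0, 55.0)

    # latent leak fraction λ ~ Beta(a, b); calibrated so the cohort index
    # distribution is left-skewed with median near -2.8
    leak_alpha: float = 1.8
    leak_beta: float = 1.05

    # fluid regimen, first window [-6, 36] h
    intake_total_log_mean: float = np.log(4000.0)   # lognormal total intake, ml
    intake_total_log_sd: float = 0.45
    intake_total_min: float = 500.0                 # ml
    intake_events_mean: float = 12.0                # Poisson, +1
    # resuscitation is front-loaded and starts after ICU admission: event
    # times are Beta-distributed over (0.5, 18) h, so the admission hct
    # draw precedes the first infusion and all volume is in before the
    # final-hct window opens (pre-admission fluids would attenuate the
    # index; see the methods note)
    intake_time_range: tuple[float, float] = (0.5, 18.0)
    intake_time_beta: tuple[float, float] = (1.3, 1.8)
    urine_fraction: float = 0.45     # of retained (1-λ)-scaled intake
    urine_log_noise_sd: float = 0.15
    urine_events_mean: float = 10.0

    # hematocrit measurement model
    hct_schedule: tuple = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0,
                           48.0, 60.0, 72.0, 84.0)
    p_ed_draw: float = 0.3           # extra pre-ICU draw
    ed_draw_window: tuple[float, float] = (-8.0, -1.0)
    hct_noise_sd: float = 0.9        # percent points (analyzer + short-term)
    hct_meas_clip: tuple[float, float] = (5.0, 70.0)
    p_measurement_kept: float = 0.97
    p_no_hct_data: float = 0.02      # patient-level: no hct charted at all
    p_no_fluid_data: float = 0.01    # patient-level: no fluids charted at all

    # severity / comorbidity scores (APACHE-like, CCI-like scales)
    severity_mean: float = 73.0
    severity_sd: float = 26.0
    severity_clip: tuple[float, float] = (0.0, 200.0)
    comorbidity_mean: float = 4.3
    comorbidity_sd: float = 2.9

    # exclusion-flag prevalences
    p_sepsis: float = 0.93
    p_bleeding: float = 0.04
    p_blood_products: float = 0.04
    p_rrt: float = 0.05
    p_excess_other_output: float = 0.02
    p_reliable_fluid_data: float = 0.95

    # outcome models
    death_beta0: float = -4.8        # logit intercept
    death_beta_lambda: float = 1.5   # per unit λ
    death_beta_severity: float = 0.018
    death_beta_age: float = 0.012
    death_time_range: tuple[float, float] = (12.0, 250.0)   # h, if died
    discharge_time_range: tuple[float, float] = (96.0, 600.0)
    balance_intercept: float = 0.0   # ml, 36-84 h balance = a + b·λ + ε
    balance_slope: float = 1200.0
    balance_noise_sd: float = 1800.0
    outcome_urine_log_mean: float = np.log(1500.0)
    outcome_urine_log_sd: float = 0.5
    outcome_intake_events_mean: float = 5.0
    outcome_urine_events_mean: float = 6.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.leak_alpha <= 0 or self.leak_beta <= 0:
            raise ValueError("Beta parameters for λ must be positive")
        sds = [self.age_sd, self.height_sd, self.weight_sd, self.hct0_sd,
               self.hct_noise_sd, self.severity_sd, self.comorbidity_sd,
               self.balance_noise_sd]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        probs = [self.p_male, self.p_ed_draw, self.p_measurement_kept,
                 self.p_no_hct_data, self.p_no_fluid_data, self.p_sepsis,
                 self.p_bleeding, self.p_blood_products, self.p_rrt,
                 self.p_excess_other_output, self.p_reliable_fluid_data]
        if any(not 0 <= q <= 1 for q in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class GroundTruth:
    """Per-patient latent truth: leak fraction and blood/red-cell volumes."""

    table: pd.DataFrame  # patient_id, lambda, bv0_l, rcv_l

    def to_csv(self, path) -> None:
        to_csv_exact(self.table, path)


def nadler_blood_volume(height_cm: float, weight_kg: float, sex: str) -> float:
    """Total blood volume in liters (Nadler's sex-specific estimates)."""
    h_m = height_cm / 100.0
    if sex == "male":
        return 0.3669 * h_m ** 3 + 0.03219 * weight_kg + 0.6041
    if sex == "female":
        return 0.3561 * h_m ** 3 + 0.03308 * weight_kg + 0.1833
    raise ValueError(f"unknown sex {sex!r}")


def hct_trajectory(event_times, signed_volumes_l, lam, bv0_l, hct0_pct,
                   query_times):
    """Noiseless hematocrit at ``query_times``, given fluid events.

    ``signed_volumes_l`` are +intake / −urine in liters; a fraction λ of
    every intake leaks immediately, urine is drawn entirely from the
    vasculature. Red-cell volume is constant by construction, so this is
    the closed-form dilution curve the measurement model samples from.
    """
    order = np.argsort(event_times, kind="stable")
    t = np.asarray(event_times, dtype=float)[order]
    dv = np.asarray(signed_volumes_l, dtype=float)[order]
    dv = np.where(dv > 0, (1.0 - lam) * dv, dv)
    cum = np.concatenate([[0.0], np.cumsum(dv)])
    rcv = bv0_l * hct0_pct / 100.0
    idx = np.searchsorted(t, np.asarray(query_times, dtype=float), side="right")
    vol = bv0_l + cum[idx]
    return 100.0 * rcv / vol


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # substream derivation: course of patient i is invariant to n_patients
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_patient_course(demographics: dict, lam: float,
                            config: SimulationConfig,
                            rng: np.random.Generator):
    """Simulate the first-window course: fluid events over [-6, 36] h and
    hematocrit measurements up to 36 h.

    Returns ``(hct_times, hct_values, fluid_times, fluid_volumes_ml,
    fluid_directions, v36_l)`` where ``v36_l`` is the intravascular volume
    at 36 h (handed to the outcome simulator so post-36 h measurements stay
    on the same trajectory).

    If an urine event would draw the intravascular volume below the
    red-cell volume, its volume is resampled to half the available plasma
    (logged); the trajectory can therefore never hit zero plasma.
    """
    bv0 = demographics["bv0_l"]
    hct0 = demographics["hct0_pct"]
    rcv = bv0 * hct0 / 100.0

    # intake events in [-6, 36]
    n_in = 1 + rng.poisson(config.intake_events_mean)
    total_in = max(
        float(np.exp(rng.normal(config.intake_total_log_mean,
                                config.intake_total_log_sd))),
        config.intake_total_min,
    )
    lo_t, hi_t = config.intake_time_range
    t_in = np.sort(
        lo_t + (hi_t - lo_t) * rng.beta(*config.intake_time_beta, size=n_in)
    )
    v_in = rng.dirichlet(np.ones(n_in)) * total_in

    # urine events in [0, 36]; expected total tracks retained fluid
    n_ur = 1 + rng.poisson(config.urine_events_mean)
    total_ur = (
        config.urine_fraction * (1.0 - lam) * total_in
        * float(np.exp(rng.normal(0.0, config.urine_log_noise_sd)))
    )
    t_ur = np.sort(rng.uniform(0.0, 36.0, size=n_ur))
    v_ur = rng.dirichlet(np.ones(n_ur)) * total_ur

    times = np.concatenate([t_in, t_ur])
    vols = np.concatenate([v_in, -v_ur])  # signed, ml
    order = np.argsort(times, kind="stable")
    times, vols = times[order], vols[order]

    # walk the trajectory, guarding V > RCV
    vol_l = bv0
    for j in range(len(vols)):
        dv = (1.0 - lam) * vols[j] / 1000.0 if vols[j] > 0 else vols[j] / 1000.0
        if vol_l + dv <= rcv:
            new_v = -0.5 * (vol_l - rcv) * 1000.0  # take half the plasma left
            logger.debug("urine event resampled to keep plasma positive")
            vols[j] = new_v
            dv = new_v / 1000.0
        vol_l += dv

    # measurement times: scheduled draws ≤ 36 h plus an optional ED draw
    sched = np.asarray([t for t in config.hct_schedule if t <= 36.0])
    keep = rng.random(sched.size) < config.p_measurement_kept
    m_times = sched[keep]
    if rng.random() < config.p_ed_draw:
        m_times = np.concatenate(
            [[rng.uniform(*config.ed_draw_window)], m_times]
        )
    true_hct = hct_trajectory(times, vols / 1000.0, lam, bv0, hct0, m_times)
    noise = rng.normal(0.0, config.hct_noise_sd, size=m_times.size)
    m_values = np.clip(true_hct + noise, *config.hct_meas_clip)

    dirs = np.where(vols >= 0, "intake", "urine_output")
    v36 = bv0 + np.sum(
        np.where(vols > 0, (1.0 - lam) * vols, vols)
    ) / 1000.0
    return m_times, m_values, times, np.abs(vols), dirs, v36


def simulate_outcomes(demographics: dict, lam: float,
                      config: SimulationConfig, rng: np.random.Generator):
    """Draw the death outcome and the post-36 h fluid events.

    Death is Bernoulli on logit⁻¹(β₀ + β_λ·λ + β_sev·severity + β_age·age);
    if death occurs its time is uniform over the configured range,
    otherwise a discharge time is drawn. The 36–84 h events are constructed
    so the realized balance equals intercept + slope·λ + Gaussian noise
    exactly (urine total adjusts to close the identity).
    """
    eta = (config.death_beta0
           + config.death_beta_lambda * lam
           + config.death_beta_severity * demographics["severity_score"]
           + config.death_beta_age * demographics["age"])
    p_death = 1.0 / (1.0 + np.exp(-eta))
    died = bool(rng.random() < p_death)
    if died:
        end_time = float(rng.uniform(*config.death_time_range))
    else:
        end_time = float(rng.uniform(*config.discharge_time_range))

    balance = (config.balance_intercept
               + config.balance_slope * lam
               + rng.normal(0.0, config.balance_noise_sd))
    u_target = float(np.exp(rng.normal(config.outcome_urine_log_mean,
                                       config.outcome_urine_log_sd)))
    total_in = max(balance, 0.0) + u_target
    total_ur = total_in - balance  # ≥ 0 by construction

    n_in = 1 + rng.poisson(config.outcome_intake_events_mean)
    n_ur = 1 + rng.poisson(config.outcome_urine_events_mean)
    t_in = rng.uniform(36.0, 84.0, size=n_in)
    t_ur = rng.uniform(36.0, 84.0, size=n_ur)
    v_in = rng.dirichlet(np.ones(n_in)) * total_in
    v_ur = rng.dirichlet(np.ones(n_ur)) * total_ur

    times = np.concatenate([t_in, t_ur])
    vols = np.concatenate([v_in, v_ur])
    dirs = np.concatenate([np.repeat("intake", n_in),
                           np.repeat("urine_output", n_ur)])
    return died, end_time, times, vols, dirs


def _draw_demographics(config: SimulationConfig, rng: np.random.Generator) -> dict:
    sex = "male" if rng.random() < config.p_male else "female"
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                        *config.age_range))
    height = float(np.clip(rng.normal(config.height_mean[sex], config.height_sd),
                           *config.height_clip))
    weight = float(np.clip(rng.normal(config.weight_mean[sex], config.weight_sd),
                           *config.weight_clip))
    hct0 = float(np.clip(rng.normal(config.hct0_mean, config.hct0_sd),
                         *config.hct0_clip))
    severity = float(np.clip(rng.normal(config.severity_mean, config.severity_sd),
                             *config.severity_clip))
    comorbidity = float(max(rng.normal(config.comorbidity_mean,
                                       config.comorbidity_sd), 0.0))
    return {
        "sex": sex,
        "age": age,
        "height_cm": height,
        "weight_kg": weight,
        "hct0_pct": hct0,
        "severity_score": severity,
        "comorbidity_score": comorbidity,
        "bv0_l": nadler_blood_volume(height, weight, sex),
    }


def simulate_patient(index: int, config: SimulationConfig):
    """Full course + outcomes for one patient on its own RNG substream.

    Returns (patient_row_dict, hct_frame, fluid_frame, truth_dict). Events
    and measurements after the death/discharge time are dropped, as in
    real charting.
    """
    rng = _patient_rng(config.seed, index)
    pid = f"p{index:06d}"
    demo = _draw_demographics(config, rng)
    lam = float(rng.beta(config.leak_alpha, config.leak_beta))

    flags = {
        "sepsis": rng.random() < config.p_sepsis,
        "bleeding_dx": rng.random() < config.p_bleeding,
        "received_blood_products": rng.random() < config.p_blood_products,
        "rrt": rng.random() < config.p_rrt,
        "excess_other_output": rng.random() < config.p_excess_other_output,
        "reliable_fluid_data": rng.random() < config.p_reliable_fluid_data,
    }
    no_hct = rng.random() < config.p_no_hct_data
    no_fluids = rng.random() < config.p_no_fluid_data

    m_t, m_v, f_t, f_v, f_d, v36 = simulate_patient_course(demo, lam, config, rng)
    died, end_time, ot, ov, od = simulate_outcomes(demo, lam, config, rng)

    # post-36 h scheduled measurements continue the same trajectory
    post_sched = np.asarray([t for t in config.hct_schedule if t > 36.0])
    if post_sched.size:
        keep = rng.random(post_sched.size) < config.p_measurement_kept
        post_t = post_sched[keep]
        signed = np.where(od == "intake", ov, -ov) / 1000.0
        rcv = demo["bv0_l"] * demo["hct0_pct"] / 100.0
        hct36 = 100.0 * rcv / v36
        true_post = hct_trajectory(ot, signed, lam, v36, hct36, post_t)
        post_v = np.clip(
            true_post + rng.normal(0.0, config.hct_noise_sd, size=post_t.size),
            *config.hct_meas_clip,
        )
        m_t = np.concatenate([m_t, post_t])
        m_v = np.concatenate([m_v, post_v])

    f_t = np.concatenate([f_t, ot])
    f_v = np.concatenate([f_v, ov])
    f_d = np.concatenate([f_d, od])

    # charting stops at death/discharge
    keep_f = f_t <= end_time
    keep_m = m_t <= end_time
    f_t, f_v, f_d = f_t[keep_f], f_v[keep_f], f_d[keep_f]
    m_t, m_v = m_t[keep_m], m_v[keep_m]
    if no_hct:
        m_t, m_v = m_t[:0], m_v[:0]
    if no_fluids:
        f_t, f_v, f_d = f_t[:0], f_v[:0], f_d[:0]

    row = {
        "patient_id": pid,
        "age": demo["age"],
        "sex": demo["sex"],
        "height_cm": demo["height_cm"],
        "weight_kg": demo["weight_kg"],
        **flags,
        "severity_score": demo["severity_score"],
        "comorbidity_score": demo["comorbidity_score"],
        "died_in_hospital": died,
        "death_or_discharge_time_h": end_time,
    }
    hct = pd.DataFrame({"patient_id": pid, "time_h": m_t, "hct_pct": m_v})
    fluids = pd.DataFrame({
        "patient_id": pid, "time_h": f_t, "volume_ml": f_v, "direction": f_d,
    })
    truth = {
        "patient_id": pid,
        "lambda": lam,
        "bv0_l": demo["bv0_l"],
        "rcv_l": demo["bv0_l"] * demo["hct0_pct"] / 100.0,
    }
    return row, hct, fluids, truth


def generate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a full synthetic dataset; identical config ⇒ identical output."""
    config.validate()
    rows, hcts, fluids, truths = [], [], [], []
    for i in range(config.n_patients):
        row, h, f, t = simulate_patient(i, config)
        rows.append(row)
        hcts.append(h)
        fluids.append(f)
        truths.append(t)

    if rows:
        patients = pd.DataFrame(rows)[PATIENT_COLUMNS]
        hct = pd.concat(hcts, ignore_index=True)
        fl = pd.concat(fluids, ignore_index=True)
        truth = pd.DataFrame(truths)
    else:
        patients = pd.DataFrame(columns=PATIENT_COLUMNS)
        hct = pd.DataFrame(columns=["patient_id", "time_h", "hct_pct"])
        fl = pd.DataFrame(
            columns=["patient_id", "time_h", "volume_ml", "direction"]
        )
        truth = pd.DataFrame(columns=["patient_id", "lambda", "bv0_l", "rcv_l"])
    ds = Dataset(patients=patients, hct=hct, fluids=fl)
    return ds, GroundTruth(table=truth)


def write_synthetic_dataset(config: SimulationConfig, out_dir) -> dict:
    """Generate and write the three CSVs plus ground_truth.csv and a
    manifest (seed + config); returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = generate_dataset(config)
    paths = {
        "patients": out / "patients.csv",
        "hct": out / "hct.csv",
        "fluids": out / "fluids.csv",
        "ground_truth": out / "ground_truth.csv",
        "manifest": out / "manifest.json",
    }
    write_dataset(ds, paths["patients"], paths["hct"], paths["fluids"])
    truth.to_csv(paths["ground_truth"])
    manifest = {"seed": config.seed, "n_patients": config.n_patients,
                "config": config.to_dict()}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return {k: str(v) for k, v in paths.items()}
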