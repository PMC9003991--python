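"""Adjusted association models between the leak index and the outcomes.

Two complementary views, mirroring standard clinical-epidemiology practice:

* **Additive (GAM) fits** — outcome ~ s(VLI) + severity + [comorbidity] +
  age + sex, with a penalized cubic B-spline smooth for the index (logit
  link for in-hospital death, identity link for the 36–84 h balance). The
  significance of the smooth is assessed by analysis of deviance: a
  likelihood-ratio chi-square between the nested unpenalized additive
  models with and without the spline term. The LRT is used (rather than a
  Wald test on the penalized coefficients) because its null distribution
  is standard, so the test stays calibrated in simulation.
* **Quartile contrasts** — the same covariates with the index replaced by
  its quartile (Q1, the lowest quarter, as reference): odds ratios with
  Wald 95% CIs for death, mean differences in ml for the balance.

Comorbidity enters only when the column carries any data (some source
databases do not record it); rows missing a required covariate are dropped
and logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from vli.config import ModelConfig
from vli.vli_core import QUARTILE_LABELS

logger = logging.getLogger(__name__)

ALPHA_GRID = 10.0 ** np.arange(0, 7)  # smoothing-penalty grid for GCV

BINARY_DEATH = "binary_death"
CONTINUOUS_BALANCE = "continuous_balance"


class ModelFitError(RuntimeError):
    """Non-convergence, separation, or a degenerate design; the message
    names the offending term."""


@dataclass
class GAMFit:
    """A fitted additive model for one outcome."""

    outcome_kind: str
    result: object                  # GLMGamResults (penalized fit)
    smoother: BSplines
    exog_names: list[str]
    reference_exog: np.ndarray      # covariates at reference values
    smooth_p_value: float
    smooth_lrt_stat: float
    smooth_lrt_df: int
    edf: float                      # effective dof of the smooth term
    vli_range: tuple[float, float]
    alpha: float
    n_obs: int

    def summary_dict(self) -> dict:
        params = dict(zip(self.exog_names, self.result.params[: len(self.exog_names)]))
        return {
            "outcome_kind": self.outcome_kind,
            "n_obs": self.n_obs,
            "covariate_coefficients": {k: float(v) for k, v in params.items()},
            "smooth_p_value": float(self.smooth_p_value),
            "smooth_lrt_stat": float(self.smooth_lrt_stat),
            "smooth_lrt_df": int(self.smooth_lrt_df),
            "smooth_edf": float(self.edf),
            "alpha": float(self.alpha),
            "vli_range": [float(self.vli_range[0]), float(self.vli_range[1])],
        }


@dataclass
class PartialEffectCurve:
    """Fitted outcome over a VLI grid with covariates held at reference."""

    vli: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vli": self.vli, "fit": self.fit, "lo": self.lo, "hi": self.hi}
        )


@dataclass
class QuartileEffects:
    """Per-quartile effects against Q1 (odds ratios or mean differences)."""

    outcome_kind: str
    table: pd.DataFrame  # quartile, estimate, ci_lo, ci_hi, se, p_value
    n_obs: int = 0

    def to_dict(self) -> dict:
        return {
            "outcome_kind": self.outcome_kind,
            "n_obs": int(self.n_obs),
            "effects": self.table.to_dict(orient="records"),
        }


def _design(rows: pd.DataFrame, outcome_kind: str,
            with_quartiles: bool = False):
    """Assemble outcome vector, covariate matrix and names; drop and log
    rows with missing requirements."""
    df = rows.copy()
    if outcome_kind == BINARY_DEATH:
        df["__y"] = df["died_in_hospital"].astype(float)
    elif outcome_kind == CONTINUOUS_BALANCE:
        df["__y"] = df["outcome_balance_ml"].astype(float)
    else:
        raise ValueError(f"unknown outcome kind {outcome_kind!r}")

    use_comorbidity = df["comorbidity_score"].notna().any()
    needed = ["__y", "vli", "age", "sex", "severity_score"]
    if use_comorbidity:
        needed.append("comorbidity_score")
    n0 = len(df)
    df = df.dropna(subset=needed)
    if len(df) < n0:
        logger.info("dropped %d rows with missing outcome/covariates", n0 - len(df))
    if df.empty:
        raise ModelFitError("no complete rows available for model fitting")

    cols = {"const": np.ones(len(df)),
            "severity_score": df["severity_score"].to_numpy(dtype=float)}
    if use_comorbidity:
        cols["comorbidity_score"] = df["comorbidity_score"].to_numpy(dtype=float)
    cols["age"] = df["age"].to_numpy(dtype=float)
    cols["sex_male"] = (df["sex"] == "male").to_numpy(dtype=float)
    if with_quartiles:
        present = set(df["vli_quartile"])
        for q in QUARTILE_LABELS[1:]:
            if q in present:  # absent levels would give all-zero columns
                cols[f"quartile_{q}"] = (df["vli_quartile"] == q).to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return df, X, list(cols.keys())


def _family(outcome_kind: str):
    if outcome_kind == BINARY_DEATH:
        return sm.families.Binomial()
    return sm.families.Gaussian()


def _fit_gam(rows: pd.DataFrame, outcome_kind: str,
             config: ModelConfig | None = None) -> GAMFit:
    config = config or ModelConfig()
    df, X, names = _design(rows, outcome_kind)
    if outcome_kind == CONTINUOUS_BALANCE and len(df) < len(rows):
        pass  # already logged
    y = df["__y"].to_numpy()
    x_vli = df["vli"].to_numpy(dtype=float)
    if np.ptp(x_vli) == 0:
        raise ModelFitError("vli is constant; smooth term is unidentifiable")

    smoother = BSplines(x_vli, df=[config.spline_df],
                        degree=[config.spline_degree])
    family = _family(outcome_kind)
    basis = smoother.basis

    # Analysis-of-deviance LRT for the smooth (unpenalized nested GLMs).
    # A full-size basis can quasi-separate a binary outcome when a knot
    # span holds only a handful of events; shrink the test basis until the
    # likelihood is finite (the usual "k larger than the data supports"
    # remedy), keeping the full basis for the fitted curve.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            reduced = sm.GLM(y, X, family=family).fit()
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise ModelFitError(f"covariate GLM failed: {exc}") from exc
        if not np.isfinite(reduced.llf):
            raise ModelFitError("non-finite likelihood; check for "
                                "separation in the covariates")
        full = None
        df_candidates = [config.spline_df] + [
            d for d in (8, 6, 5, 4) if d < config.spline_df
        ]
        for df_try in df_candidates:
            test_basis = (basis if df_try == config.spline_df
                          else BSplines(x_vli, df=[df_try],
                                        degree=[config.spline_degree]).basis)
            try:
                cand = sm.GLM(y, np.column_stack([X, test_basis]),
                              family=family).fit()
            except Exception:
                continue
            if np.isfinite(cand.llf) and np.all(np.isfinite(cand.params)):
                full, lrt_df = cand, test_basis.shape[1]
                if df_try != config.spline_df:
                    logger.info("smooth-term test basis shrunk to df=%d "
                                "(separation at df=%d)", df_try,
                                config.spline_df)
                break
        if full is None:
            raise ModelFitError("smooth-term test failed at every basis "
                                "dimension; check the vli distribution")
    lrt = max(2.0 * (full.llf - reduced.llf), 0.0)
    p_smooth = float(scipy.stats.chi2.sf(lrt, lrt_df))

    # penalized fit for the partial-effect curve
    def fit_alpha(a):
        gam = GLMGam(y, exog=X, smoother=smoother, family=family, alpha=[a])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return gam.fit(maxiter=100)

    if config.alpha is not None:
        alpha = float(config.alpha)
        try:
            res = fit_alpha(alpha)
        except Exception:
            res, alpha = None, 0.0
    else:
        best = None
        for a in ALPHA_GRID:
            try:
                r = fit_alpha(a)
                gcv = float(getattr(r, "gcv", np.nan))
            except Exception:
                continue
            if np.isfinite(gcv) and (best is None or gcv < best[1]):
                best = (a, gcv, r)
        if best is None:
            res, alpha = None, 0.0
        else:
            alpha, _, res = best
    if res is None:
        # degenerate penalized problem (e.g. zero residual variance trips
        # the PIRLS separation guard); the unpenalized GLM is exact there
        if len(full.params) != len(names) + basis.shape[1]:
            raise ModelFitError("penalized fit infeasible and the "
                                "full-size spline GLM separated")
        logger.warning("penalized fit infeasible; using the unpenalized "
                       "spline GLM for the curve")
        res = full
    if not np.all(np.isfinite(res.params)):
        raise ModelFitError("non-finite coefficients; possible separation")

    if hasattr(res, "edf"):
        edf_smooth = float(np.asarray(res.edf, dtype=float)[len(names):].sum())
    else:  # unpenalized fallback: every basis column counts fully
        edf_smooth = float(basis.shape[1])

    ref = _reference_exog(df, names)
    return GAMFit(
        outcome_kind=outcome_kind,
        result=res,
        smoother=smoother,
        exog_names=names,
        reference_exog=ref,
        smooth_p_value=p_smooth,
        smooth_lrt_stat=float(lrt),
        smooth_lrt_df=int(lrt_df),
        edf=edf_smooth,
        vli_range=(float(x_vli.min()), float(x_vli.max())),
        alpha=float(alpha),
        n_obs=len(df),
    )


def _reference_exog(df: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Covariate reference: numeric means, modal sex."""
    vals = []
    for name in names:
        if name == "const":
            vals.append(1.0)
        elif name == "sex_male":
            vals.append(float((df["sex"] == "male").mean() >= 0.5))
        else:
            vals.append(float(df[name].mean()))
    return np.asarray(vals)


def fit_death_gam(cohort_rows: pd.DataFrame,
                  config: ModelConfig | None = None) -> GAMFit:
    """Additive logistic model of in-hospital death on s(VLI) + covariates.

    Requires at least 200 rows with the death indicator present.
    """
    if len(cohort_rows) < 200:
        raise ModelFitError(
            f"death model needs >= 200 rows, got {len(cohort_rows)}"
        )
    return _fit_gam(cohort_rows, BINARY_DEATH, config)


def fit_balance_gam(cohort_rows: pd.DataFrame,
                    config: ModelConfig | None = None) -> GAMFit:
    """Additive Gaussian model of the 36-84 h fluid balance on s(VLI) +
    covariates; rows with a missing outcome are excluded first."""
    rows = cohort_rows[cohort_rows["outcome_balance_ml"].notna()]
    if len(rows) < 200:
        raise ModelFitError(
            f"balance model needs >= 200 rows with outcome, got {len(rows)}"
        )
    return _fit_gam(rows, CONTINUOUS_BALANCE, config)


def predict_partial_effect(gam_fit: GAMFit,
                           grid: np.ndarray | int = 100,
                           ci_level: float = 0.95) -> PartialEffectCurve:
    """Fitted outcome over a VLI grid at reference covariates, with a
    pointwise Wald CI computed on the link scale and mapped through the
    inverse link (probabilities stay inside [0, 1]).

    ``grid`` may be a point count (evenly spaced over the observed VLI
    range) or an explicit array; points outside the observed range are
    clipped with a warning.
    """
    lo, hi = gam_fit.vli_range
    if isinstance(grid, (int, np.integer)):
        xg = np.linspace(lo, hi, int(grid))
    else:
        xg = np.asarray(grid, dtype=float)
        if (xg < lo).any() or (xg > hi).any():
            warnings.warn("grid extends beyond the observed VLI range; "
                          "clipping", stacklevel=2)
            xg = np.clip(xg, lo, hi)

    basis = gam_fit.smoother.transform(xg)
    if basis.ndim == 1:
        basis = basis[None, :]
    Xref = np.tile(gam_fit.reference_exog, (len(xg), 1))
    D = np.column_stack([Xref, basis])
    res = gam_fit.result
    eta = D @ res.params
    cov = res.cov_params()
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, cov, D), 0.0))
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2.0)
    lo_eta, hi_eta = eta - z * se, eta + z * se
    link = _family(gam_fit.outcome_kind).link
    inv = link.inverse
    return PartialEffectCurve(
        vli=xg, fit=inv(eta), lo=inv(lo_eta), hi=inv(hi_eta)
    )


def fit_quartile_model(cohort_rows: pd.DataFrame, outcome_kind: str,
                       ci_level: float = 0.95,
                       adjusted: bool = True) -> QuartileEffects:
    """GLM with the VLI quartile as a 4-level factor (Q1 reference) plus
    covariates; exponentiated Wald CIs for death, mean differences for the
    balance outcome.

    ``adjusted=False`` drops all covariates (used by the contingency-table
    cross-check). For the binary outcome a quartile with zero or all
    events makes the Wald machinery meaningless, so it is a hard error
    (exact small-sample methods are out of scope here).
    """
    rows = cohort_rows
    if outcome_kind == CONTINUOUS_BALANCE:
        rows = rows[rows["outcome_balance_ml"].notna()]
    df, X, names = _design(rows, outcome_kind, with_quartiles=True)
    if not adjusted:
        keep = [i for i, n in enumerate(names)
                if n == "const" or n.startswith("quartile_")]
        X = X[:, keep]
        names = [names[i] for i in keep]
    y = df["__y"].to_numpy()

    present = sorted(set(df["vli_quartile"]))
    if outcome_kind == BINARY_DEATH:
        ev = df.groupby("vli_quartile")["__y"].agg(["sum", "count"])
        degenerate = ev[(ev["sum"] == 0) | (ev["sum"] == ev["count"])]
        if len(degenerate):
            raise ModelFitError(
                "quartile(s) with zero or all events: "
                f"{list(degenerate.index)}; Wald intervals are invalid — "
                "use exact methods (out of scope)"
            )
    family = _family(outcome_kind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=family).fit()
    if not np.all(np.isfinite(res.bse)):
        raise ModelFitError("non-finite standard errors in quartile model")

    z = scipy.stats.norm.ppf(0.5 + ci_level / 2.0)
    records = []
    is_or = outcome_kind == BINARY_DEATH
    records.append({
        "quartile": "Q1",
        "estimate": 1.0 if is_or else 0.0,
        "ci_lo": np.nan, "ci_hi": np.nan, "se": np.nan, "p_value": np.nan,
    })
    for q in QUARTILE_LABELS[1:]:
        name = f"quartile_{q}"
        if name not in names:
            records.append({"quartile": q, "estimate": np.nan,
                            "ci_lo": np.nan, "ci_hi": np.nan,
                            "se": np.nan, "p_value": np.nan})
            continue
        i = names.index(name)
        b, se = res.params[i], res.bse[i]
        lo_b, hi_b = b - z * se, b + z * se
        p = 2 * scipy.stats.norm.sf(abs(b) / se) if se > 0 else np.nan
        if is_or:
            records.append({"quartile": q, "estimate": float(np.exp(b)),
                            "ci_lo": float(np.exp(lo_b)),
                            "ci_hi": float(np.exp(hi_b)),
                            "se": float(se), "p_value": float(p)})
        else:
            records.append({"quartile": q, "estimate": float(b),
                            "ci_lo": float(lo_b), "ci_hi": float(hi_b),
                            "se": float(se), "p_value": float(p)})
    if len(present) < 4:
        logger.warning("only quartiles %s present in the data", present)
    return QuartileEffects(outcome_kind=outcome_kind,
                           table=pd.DataFrame(records), n_obs=len(df))
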