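"""Harmonic (cosinor) circadian mixed models on hourly HR/RMSSD records.

The modelling unit is a subject x clock-hour aggregate on the log scale.
The full model regresses the outcome on group, covariates (standardised
age, sex, BMI, overall activity index), first (24-h) and second (12-h)
harmonic terms of clock time, and group x harmonic interactions, with a
random intercept per subject:

    y_ij = X_ij beta + u_i + e_ij,   u_i ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

Model selection is backwards stepwise on p-values with marginality
enforced (a harmonic main effect stays while any retained interaction
contains it; the group effect is never removed).  Goodness of fit is the
conditional R-squared in the Nakagawa form,
(var(Xb) + s_u^2) / (var(Xb) + s_u^2 + s_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .features import PERIODS

__all__ = [
    "HARMONICS",
    "FULL_TERMS",
    "ModelFit",
    "harmonic_columns",
    "build_design",
    "fit_lmm",
    "backward_stepwise",
    "amplitude_summary",
    "predict_curve",
    "covariate_check",
]

HARMONICS = ["s24", "c24", "s12", "c12"]
INTERACTIONS = [f"group:{h}" for h in HARMONICS]
COVARIATES = ["age_z", "sex", "bmi_z", "activity_z"]
FULL_TERMS = ["group"] + COVARIATES + HARMONICS + INTERACTIONS
NEVER_DROP = {"const", "group"}


@dataclass
class ModelFit:
    """Summary of one fitted random-intercept harmonic model."""

    outcome: str
    terms: list[tuple[str, float, float, float]]  # (name, estimate, t, p)
    random_intercept_var: float
    residual_var: float
    conditional_r2: float
    retained_terms: list[str]
    reml: bool = True
    nobs: int = 0
    reference: dict = field(default_factory=dict)  # covariate values for prediction

    @property
    def params(self) -> dict[str, float]:
        return {name: est for name, est, _, _ in self.terms}

    def coef(self, name: str) -> float:
        return self.params.get(name, 0.0)

    def term(self, name: str) -> tuple[float, float, float]:
        for n, est, t, p in self.terms:
            if n == name:
                return est, t, p
        raise KeyError(name)


def harmonic_columns(t_hours) -> pd.DataFrame:
    """sin/cos columns of the 24-h and 12-h harmonics at clock time t."""
    t = np.asarray(t_hours, dtype=float)
    return pd.DataFrame(
        {
            "s24": np.sin(2 * np.pi * t / 24),
            "c24": np.cos(2 * np.pi * t / 24),
            "s12": np.sin(2 * np.pi * t / 12),
            "c12": np.cos(2 * np.pi * t / 12),
        }
    )


def build_design(
    records: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    standardize: bool = True,
    sleep_quality: bool = False,
) -> pd.DataFrame:
    """Merge hourly records with subject metadata into a model frame.

    `records` needs ``subject_id`` and a clock-time column (``bin`` or
    ``clock_hour``) plus the outcome columns; `meta` (one row per
    subject) supplies group/age/sex/bmi/activity.  Group is coded
    control=0 / patient=1, sex female=0 / male=1; age, BMI and activity
    are z-scored by default.  Records with missing covariates are
    dropped with a warning.
    """
    df = records.copy()
    if "clock_hour" not in df.columns:
        df["clock_hour"] = df["bin"].astype(int)
    if meta is not None:
        df = df.merge(meta, on="subject_id", how="left", suffixes=("", "_meta"))
    if "group" in df.columns and df["group"].dtype == object:
        df["group"] = (df["group"] == "patient").astype(int)
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "male").astype(int)

    def _z(col: str, out: str) -> None:
        if col in df.columns:
            x = df[col].astype(float)
            sd = x.std(ddof=0)
            df[out] = (x - x.mean()) / sd if (standardize and sd > 0) else x

    _z("age", "age_z")
    _z("bmi", "bmi_z")
    _z("activity", "activity_z")
    for c in ["age_z", "sex", "bmi_z", "activity_z"]:
        if c not in df.columns:
            df[c] = 0.0

    hc = harmonic_columns(df["clock_hour"].to_numpy())
    for h in HARMONICS:
        df[h] = hc[h].to_numpy()
        df[f"group:{h}"] = df["group"] * df[h]
    if sleep_quality and "sleep_quality" in df.columns:
        df["sleep_quality"] = df["sleep_quality"].astype(float)

    needed = ["group", "age_z", "sex", "bmi_z", "activity_z"]
    bad = df[needed].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} records with missing covariates", stacklevel=2)
        df = df[~bad]
    return df.reset_index(drop=True)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns by greedy elimination
        cols, keep = list(X.columns), []
        for c in cols:
            trial = keep + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
                keep.append(c)
        drop = sorted(set(cols) - set(keep))
        raise np.linalg.LinAlgError(f"design is singular; collinear columns: {drop}")


def fit_lmm(
    design: pd.DataFrame,
    outcome: str = "log_hr",
    terms: list[str] | None = None,
    reml: bool = True,
) -> ModelFit:
    """Fit the random-intercept model for one outcome.

    Wald t statistics use residual degrees of freedom
    (n_obs - n_fixed); the conditional R-squared follows Nakagawa.
    """
    terms = list(FULL_TERMS) if terms is None else list(terms)
    cols = ["const"] + [t for t in terms if t != "const"]
    X = design[[c for c in cols if c != "const"]].astype(float).copy()
    X.insert(0, "const", 1.0)
    _check_rank(X)
    y = design[outcome].astype(float).to_numpy()
    groups = design["subject_id"].to_numpy()

    model = sm.MixedLM(y, X.to_numpy(), groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method="bfgs")
        # guard against degenerate optima at the variance boundary
        if not res.converged or not np.all(np.isfinite(res.fe_params)):
            res = model.fit(reml=reml, method="powell")

    k = X.shape[1]
    df_resid = max(len(y) - k, 1)
    est = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    tvals = est / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    term_stats = list(zip(X.columns, est, tvals, pvals))

    var_u = float(np.asarray(res.cov_re)[0, 0])
    var_e = float(res.scale)
    var_f = float(np.var(X.to_numpy() @ est))
    cond_r2 = (var_f + var_u) / (var_f + var_u + var_e)

    ref = {c: float(design[c].mean()) for c in COVARIATES if c in design.columns}
    return ModelFit(
        outcome=outcome,
        terms=[(n, float(e), float(t), float(p)) for n, e, t, p in term_stats],
        random_intercept_var=var_u,
        residual_var=var_e,
        conditional_r2=float(cond_r2),
        retained_terms=[c for c in X.columns if c != "const"],
        reml=reml,
        nobs=len(y),
        reference=ref,
    )


def _removable(fit: ModelFit) -> list[str]:
    retained = set(fit.retained_terms)
    out = []
    for name in fit.retained_terms:
        if name in NEVER_DROP:
            continue
        if name in HARMONICS and f"group:{name}" in retained:
            continue  # marginality: main effect pinned by its interaction
        out.append(name)
    return out


def backward_stepwise(
    design: pd.DataFrame,
    outcome: str = "log_hr",
    terms: list[str] | None = None,
    alpha: float = 0.05,
) -> ModelFit:
    """Backwards stepwise selection on p-values.

    Repeatedly refits (ML) and removes the least significant removable
    term with p > alpha, then refits the selected model by REML.  The
    group effect is never removed; harmonic main effects only leave
    after every interaction containing them has left.
    """
    current = list(FULL_TERMS) if terms is None else list(terms)
    while True:
        fit = fit_lmm(design, outcome, current, reml=False)
        cand = [(p, n) for n, _, _, p in fit.terms if n in _removable(fit) and p > alpha]
        if not cand:
            break
        _, worst = max(cand)
        current.remove(worst)
    return fit_lmm(design, outcome, current, reml=True)


def amplitude_summary(fit: ModelFit, group: str = "control") -> dict[str, float]:
    """Circadian amplitudes and peak-to-trough range of the fitted curve.

    For the patient curve, group x harmonic interaction coefficients are
    added to the harmonic main effects.  amp24 = sqrt(bs24^2 + bc24^2)
    (same for amp12); peak_trough is max - min of the summed harmonic
    curve on a 1-min grid.
    """
    g = 1 if group == "patient" else 0
    b = {h: fit.coef(h) + g * fit.coef(f"group:{h}") for h in HARMONICS}
    amp24 = float(np.hypot(b["s24"], b["c24"]))
    amp12 = float(np.hypot(b["s12"], b["c12"]))
    t = np.arange(0, 24, 1 / 60)
    curve = (
        b["s24"] * np.sin(2 * np.pi * t / 24)
        + b["c24"] * np.cos(2 * np.pi * t / 24)
        + b["s12"] * np.sin(2 * np.pi * t / 12)
        + b["c12"] * np.cos(2 * np.pi * t / 12)
    )
    return {"amp24": amp24, "amp12": amp12, "peak_trough": float(np.ptp(curve))}


def predict_curve(fit: ModelFit, group: str = "control", grid: np.ndarray | None = None) -> pd.DataFrame:
    """Fitted 24-h curve at reference covariate values (sample means)."""
    t = np.arange(0, 24, 1 / 60) if grid is None else np.asarray(grid, dtype=float)
    g = 1 if group == "patient" else 0
    hc = harmonic_columns(t)
    y = np.full(t.shape, fit.coef("const") + g * fit.coef("group"))
    for cov, val in fit.reference.items():
        y = y + fit.coef(cov) * val
    for h in HARMONICS:
        y = y + (fit.coef(h) + g * fit.coef(f"group:{h}")) * hc[h].to_numpy()
    return pd.DataFrame({"clock_hour": t, fit.outcome: y})


def covariate_check(
    design: pd.DataFrame,
    fit: ModelFit,
    covariate: str = "sleep_quality",
    period: str = "day",
) -> tuple[float, float, float]:
    """Test a binary covariate within a clock-time period.

    Restricts the records to the period (``day`` = 12:00-18:00,
    ``night`` = 00:00-06:00), adds the covariate to the retained model,
    and returns its (estimate, t, p).
    """
    if covariate not in design.columns:
        raise KeyError(f"{covariate} not in design")
    lo, hi = PERIODS[period]
    sub = design[(design["clock_hour"] >= lo) & (design["clock_hour"] < hi)].copy()
    if sub[covariate].nunique() < 2:
        raise ValueError(f"{covariate} is constant in the {period} records")
    terms = [t for t in fit.retained_terms] + [covariate]
    refit = fit_lmm(sub, fit.outcome, terms, reml=True)
    return refit.term(covariate)
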