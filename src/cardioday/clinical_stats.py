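"""Descriptive group comparisons and treatment-response statistics.

Covers the clinical side of the pipeline: two-sample t tests from
summary statistics, 2x2 chi-square, responder labelling (>= 30% HRSD
reduction at 24 h), the baseline-HR outlier rule (> mean + 2 SD),
Spearman correlation of baseline physiology with symptom change, and the
pre/post treatment-phase mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circadian_model import ModelFit, fit_lmm

__all__ = [
    "ResponseRecord",
    "two_sample_t",
    "chi_square_2x2",
    "label_responders",
    "outlier_filter_hr",
    "response_correlation",
    "group_difference_bootstrap",
    "phase_model",
]

RESPONDER_THRESHOLD = 0.30


@dataclass(frozen=True)
class ResponseRecord:
    subject_id: str
    hrsd_pre: int
    hrsd_post24: int
    change: int
    pct_reduction: float
    responder: bool


def two_sample_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int) -> float:
    """Pooled-variance two-sample t statistic from printed summaries.

    With n1 = n2 this coincides with the Welch statistic.
    """
    if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
        raise ValueError("need positive SDs and n >= 2 per group")
    t, _ = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t)


def chi_square_2x2(counts: np.ndarray) -> float:
    """Pearson chi-square without continuity correction on a 2x2 table."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    chi2, _, _, _ = stats.chi2_contingency(c, correction=False)
    return float(chi2)


def label_responders(meta: pd.DataFrame) -> list[ResponseRecord]:
    """Label each patient responder/non-responder from HRSD change.

    Responder means a reduction of at least 30% between baseline and
    24 h post-treatment (partial and full responders pooled).  Patients
    without a post score are excluded with a warning.
    """
    records = []
    patients = meta[meta["group"] == "patient"]
    for _, r in patients.iterrows():
        if pd.isna(r.get("hrsd_24h_post")):
            warnings.warn(f"{r['subject_id']}: missing 24-h post HRSD, excluded", stacklevel=2)
            continue
        pre, post = int(r["hrsd_baseline"]), int(r["hrsd_24h_post"])
        if pre <= 0:
            raise ValueError(f"{r['subject_id']}: baseline HRSD must be positive")
        change = pre - post
        pct = change / pre
        records.append(
            ResponseRecord(
                subject_id=str(r["subject_id"]), hrsd_pre=pre, hrsd_post24=post,
                change=change, pct_reduction=pct, responder=pct >= RESPONDER_THRESHOLD,
            )
        )
    return records


def outlier_filter_hr(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exclude implausibly high baseline HR values (> mean + 2 SD).

    Returns (boolean keep mask, indices excluded).  The threshold uses
    the mean/SD of the supplied analysis set; a value at exactly
    mean + 2 SD is retained (strict inequality).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    thresh = x.mean() + 2 * x.std(ddof=1)
    keep = ~(x > thresh)
    return keep, np.flatnonzero(~keep)


def response_correlation(
    baseline: np.ndarray,
    hrsd_change: np.ndarray,
    apply_outlier_filter: bool = False,
    ci_method: str = "fisher",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Spearman rank correlation between baseline HR/RMSSD and HRSD change.

    Returns rho, a 95% CI (Fisher transform by default, bootstrap
    optionally), the p-value, and which points the outlier rule removed.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(hrsd_change, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired data with n >= 4")
    excluded = np.empty(0, dtype=int)
    if apply_outlier_filter:
        keep, excluded = outlier_filter_hr(x)
        x, y = x[keep], y[keep]
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    if ci_method == "fisher":
        z = np.arctanh(np.clip(rho, -0.9999, 0.9999))
        se = 1.06 / np.sqrt(n - 3)  # variance inflation for Spearman's rho
        lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if np.unique(x[idx]).size < 2 or np.unique(y[idx]).size < 2:
                continue
            reps.append(stats.spearmanr(x[idx], y[idx])[0])
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {"rho": float(rho), "ci": (float(lo), float(hi)), "p": float(p),
            "n": int(n), "excluded": excluded}


def group_difference_bootstrap(
    a: np.ndarray, b: np.ndarray, n_boot: int = 5000, seed: int = 0
) -> dict:
    """Mean difference a - b with a percentile bootstrap 95% CI."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    diffs = [
        rng.choice(a, a.size).mean() - rng.choice(b, b.size).mean() for _ in range(n_boot)
    ]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {"difference": float(a.mean() - b.mean()), "ci": (float(lo), float(hi))}


def phase_model(
    design: pd.DataFrame,
    outcome: str = "log_hr",
    terms: list[str] | None = None,
    arm_interaction: bool = False,
) -> ModelFit:
    """Pre/post treatment-phase mixed model within patients.

    `design` holds hourly records of both phases (built with
    :func:`cardioday.circadian_model.build_design`, including a
    ``phase`` column); the retained circadian terms are augmented with a
    phase fixed effect (pre=0, post=1), optionally phase x ketamine.
    """
    df = design.copy()
    if "phase" not in df.columns:
        raise ValueError("design must carry a 'phase' column")
    df["phase_post"] = (df["phase"] == "post").astype(float)
    both = df.groupby("subject_id")["phase_post"].nunique()
    if (both >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with both phases")
    base = list(terms) if terms is not None else ["group", "s24", "c24", "s12", "c12"]
    base = [t for t in base if t in df.columns and df[t].nunique() > 1]
    model_terms = base + ["phase_post"]
    if arm_interaction:
        df["phase_post:ketamine"] = df["phase_post"] * (df["arm"] == "ketamine").astype(float)
        model_terms.append("phase_post:ketamine")
    return fit_lmm(df, outcome, model_terms, reml=True)
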