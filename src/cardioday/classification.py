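"""Leave-one-out cross-validated logistic classification of group.

Each subject contributes one feature row (period means of log HR and/or
log RMSSD).  For every fold the held-out subject is predicted from a
logistic model fitted on the remaining n-1 subjects, with features
standardised inside the training fold; the confusion table is assembled
from held-out predictions only.  Agreement is summarised as accuracy and
Cohen's kappa.  With balanced classes the chance agreement is exactly
0.5, so kappa = 2*accuracy - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .features import PERIODS

__all__ = ["ClassificationResult", "loocv_logistic", "cohen_kappa", "classify_all"]

FEATURE_SETS: dict[str, list[str]] = {
    "hr": ["log_hr"],
    "rmssd": ["log_rmssd"],
    "hr+rmssd": ["log_hr", "log_rmssd"],
}


@dataclass(frozen=True)
class ClassificationResult:
    feature_set: str
    period: str
    confusion: np.ndarray  # rows: true 0/1, cols: predicted 0/1
    accuracy: float
    kappa: float
    n: int


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from a 2x2 table."""
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("confusion must be a non-negative 2x2 table")
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion table")
    p_o = np.trace(c) / n
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


def _fit_predict(X_tr: np.ndarray, y_tr: np.ndarray, x_te: np.ndarray) -> float:
    """Probability of class 1 for the held-out row; penalised fallback on
    separation or non-convergence."""
    Xc = sm.add_constant(X_tr, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y_tr, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False) or np.any(np.abs(res.params) > 30):
            raise RuntimeError("separation")
        return float(res.predict(np.concatenate(([1.0], x_te)))[0])
    except Exception:  # noqa: BLE001 - any failure falls back to ridge
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X_tr, y_tr)
        return float(clf.predict_proba(x_te.reshape(1, -1))[0, 1])


def loocv_logistic(
    features: pd.DataFrame,
    feature_cols: list[str],
    label_col: str = "group",
    feature_set: str = "",
    period: str = "",
    standardize: bool = True,
) -> ClassificationResult:
    """LOOCV binary logistic regression on per-subject features.

    Threshold 0.5 on the held-out probability; a tie at exactly 0.5
    predicts the patient class.  Standardisation statistics are computed
    on the n-1 training subjects of each fold only.
    """
    X = features[feature_cols].to_numpy(dtype=float)
    y = features[label_col].to_numpy(dtype=int)
    n = len(y)
    if n < 3 or len(np.unique(y)) < 2:
        raise ValueError("need >= 3 subjects and both classes present")
    pred = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr, x_te = X[mask], y[mask], X[i]
        if standardize:
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            X_tr = (X_tr - mu) / sd
            x_te = (x_te - mu) / sd
        if np.ptp(X_tr, axis=0).max() == 0:
            p = 0.5  # constant features carry no information: tie
        else:
            p = _fit_predict(X_tr, y_tr, x_te)
        pred[i] = int(p >= 0.5)
    confusion = np.zeros((2, 2), dtype=int)
    for yt, yp in zip(y, pred):
        confusion[yt, yp] += 1
    acc = float(np.trace(confusion) / n)
    return ClassificationResult(
        feature_set=feature_set or "+".join(feature_cols),
        period=period,
        confusion=confusion,
        accuracy=acc,
        kappa=cohen_kappa(confusion),
        n=n,
    )


def classify_all(period_features: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Run LOOCV over all feature sets x periods.

    `period_features` maps a period name (``day``, ``night``,
    ``hour_02_03``) to a per-subject frame with ``group``, ``log_hr``,
    ``log_rmssd``.  Subjects missing a feature in a period are excluded
    from that period with a warning.  Returns one row per combination
    with accuracy, kappa and confusion counts.
    """
    rows = []
    for period, df in period_features.items():
        if period not in PERIODS:
            raise ValueError(f"unknown period {period!r}")
        for fs_name, cols in FEATURE_SETS.items():
            sub = df.dropna(subset=cols)
            if len(sub) < len(df):
                dropped = sorted(set(df["subject_id"]) - set(sub["subject_id"]))
                warnings.warn(f"{period}/{fs_name}: excluding {dropped} (missing aggregate)", stacklevel=2)
            res = loocv_logistic(sub, cols, feature_set=fs_name, period=period)
            c = res.confusion
            rows.append(
                {
                    "feature_set": fs_name,
                    "period": period,
                    "accuracy": res.accuracy,
                    "kappa": res.kappa,
                    "tn": c[0, 0], "fp": c[0, 1], "fn": c[1, 0], "tp": c[1, 1],
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
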