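"""Downstream risk models and evaluation metrics.

Two model families consume the corrected phenotype: an L2-regularized
logistic classifier for the binary outcome, and a penalized Cox
proportional-hazards model h(t|Z) = h0(t) exp(beta'Z) on Z = (St, X2) for
the time-to-event outcome.  Their validation performance is both the
reported result and the reward signal for the querying policy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "MetricsReport",
    "CoxSpec",
    "fit_classifier",
    "fit_cox",
    "evaluate_classification",
    "evaluate_survival",
]


@dataclass
class MetricsReport:
    """One model's validation metrics at one iteration.

    Threshold-based metrics (F1, TPR, PPV) are computed at the largest
    achievable empirical false-positive rate not exceeding 0.1.
    """

    auc: float
    f1: float
    tpr_at_fpr10: float
    ppv_at_fpr10: float
    prob_mse: float
    c_index: float | None = None
    iteration: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CoxSpec:
    penalty_strength: float = 0.1
    screening_rule: str = "drop-constant"
    max_features: int = 50

    def __post_init__(self) -> None:
        if self.penalty_strength < 0:
            raise ValueError("penalty_strength must be nonnegative")
        if self.screening_rule not in ("none", "drop-constant", "univariate-cap"):
            raise ValueError(f"unknown screening_rule {self.screening_rule!r}")


class _LogisticPredictor:
    """Probability predictor over the (St, X2) feature block."""

    def __init__(self, model: LogisticRegression):
        self.model = model

    def predict_proba(self, s_current: np.ndarray, x2: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.asarray(s_current, float), np.asarray(x2, float)])
        return self.model.predict_proba(X)[:, 1]


def fit_classifier(
    s_current: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    penalty: float = 1.0,
) -> _LogisticPredictor:
    """L2 logistic regression of Y on (St, X2); penalty is the inverse-C
    regularization strength (C = 1/penalty).  Retrained from scratch on
    every call — the loop never warm-starts across iterations."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome has a single class")
    X = np.column_stack([np.asarray(s_current, float), np.asarray(x2, float)])
    model = LogisticRegression(C=1.0 / penalty, max_iter=2000)
    model.fit(X, y)
    return _LogisticPredictor(model)


class _CoxPredictor:
    def __init__(self, fitter: CoxPHFitter, kept_columns: np.ndarray):
        self.fitter = fitter
        self.kept_columns = kept_columns

    @property
    def coef_(self) -> np.ndarray:
        return self.fitter.params_.to_numpy()

    def risk_score(self, s_current: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Linear predictor beta'Z; higher means higher hazard."""
        Z = np.column_stack([np.asarray(s_current, float), np.asarray(x2, float)])
        Z = Z[:, self.kept_columns]
        return Z @ self.coef_


def _screen_columns(Z: np.ndarray, t: np.ndarray, e: np.ndarray, spec: CoxSpec) -> np.ndarray:
    d = Z.shape[1]
    keep = np.ones(d, dtype=bool)
    if spec.screening_rule in ("drop-constant", "univariate-cap"):
        keep &= np.ptp(Z, axis=0) > 0  # exact constancy check, no float fuzz
    if spec.screening_rule == "univariate-cap" and keep.sum() > spec.max_features:
        stats = np.zeros(d)
        for j in np.flatnonzero(keep):
            df = pd.DataFrame({"z": Z[:, j], "t": t, "e": e})
            f = CoxPHFitter(penalizer=spec.penalty_strength)
            f.fit(df, duration_col="t", event_col="e")
            stats[j] = abs(float(f.summary["z"].iloc[0]))
        order = np.argsort(-stats)
        capped = np.zeros(d, dtype=bool)
        capped[order[: spec.max_features]] = True
        keep &= capped
    if not keep.any():
        raise ValueError("feature screening removed every covariate")
    return keep


def fit_cox(
    s_current: np.ndarray,
    x2: np.ndarray,
    t_event: np.ndarray,
    event_flag: np.ndarray,
    spec: CoxSpec = CoxSpec(),
) -> _CoxPredictor:
    """Ridge-penalized Cox partial-likelihood fit on Z = (St, X2)."""
    t = np.asarray(t_event, float)
    e = np.asarray(event_flag).astype(int)
    if e.sum() == 0:
        raise ValueError("no observed events; Cox model is unidentifiable")
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    Z = np.column_stack([np.asarray(s_current, float), np.asarray(x2, float)])
    keep = _screen_columns(Z, t, e, spec)
    cols = [f"z{j}" for j in range(int(keep.sum()))]
    df = pd.DataFrame(Z[:, keep], columns=cols)
    df["t"] = t
    df["e"] = e
    fitter = CoxPHFitter(penalizer=spec.penalty_strength, l1_ratio=0.0)
    fitter.fit(df, duration_col="t", event_col="e")
    return _CoxPredictor(fitter, keep)


def _threshold_at_fpr(probs: np.ndarray, y: np.ndarray, max_fpr: float = 0.1) -> float:
    """Largest achievable empirical FPR <= max_fpr; returns its cutoff.

    Classification is prob >= cutoff.  No interpolation: the empirical FPR
    at the returned cutoff never exceeds max_fpr.
    """
    fpr, _tpr, thresholds = roc_curve(y, probs, drop_intermediate=False)
    ok = np.flatnonzero(fpr <= max_fpr)
    i = ok[-1]  # roc_curve's fpr is nondecreasing; last ok index = largest fpr
    cut = thresholds[i]
    return float(min(cut, 1.0)) if np.isfinite(cut) else 1.0


def evaluate_classification(probs: np.ndarray, y: np.ndarray, iteration: int = 0) -> MetricsReport:
    """AUC (rank/Mann-Whitney with tie correction), Brier-type probability
    MSE, and F1/TPR/PPV at the empirical FPR <= 0.1 operating point."""
    p = np.asarray(probs, float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; metrics undefined")
    auc = float(roc_auc_score(y, p))
    mse = float(np.mean((p - y) ** 2))
    cut = _threshold_at_fpr(p, y, 0.1)
    pred = p >= cut
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tpr = tp / max(tp + fn, 1)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * tp / max(2 * tp + fp + fn, 1)
    return MetricsReport(
        auc=auc,
        f1=f1,
        tpr_at_fpr10=tpr,
        ppv_at_fpr10=ppv,
        prob_mse=mse,
        iteration=iteration,
    )


def evaluate_survival(risk_scores: np.ndarray, t_event: np.ndarray, event_flag: np.ndarray) -> float:
    """Harrell's C-index: fraction of comparable pairs ordered concordantly
    by risk (risk ties count 1/2).  Higher risk should mean earlier event."""
    r = np.asarray(risk_scores, float)
    t = np.asarray(t_event, float)
    e = np.asarray(event_flag).astype(int)
    if e.sum() == 0:
        raise ValueError("no events, hence no comparable pairs")
    # lifelines' convention: higher score ~ longer survival, so negate risk
    return float(concordance_index(t, -r, e))
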