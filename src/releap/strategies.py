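"""Active-learning strategy scores: uncertainty, diversity, query-by-committee.

Each strategy assigns an informativeness score to every unlabeled patient.
Scores are min-max normalized to [0, 1] each iteration so that a mixture
weight vector on the probability simplex can combine them into a single
ranking; ties are broken by a tiny seeded uniform jitter (eps = 1e-6) and
selected patients are never re-queried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

EPS_JITTER = 1e-6

__all__ = [
    "QbcConfig",
    "StrategyScores",
    "zscore_standardize",
    "uncertainty_scores",
    "diversity_scores",
    "fit_committee",
    "committee_probs",
    "committee_disagreement",
    "qbc_scores",
    "minmax_normalize",
    "composite_rank",
]


@dataclass(frozen=True)
class QbcConfig:
    """Committee of perturbed L2 logistic models on bootstrap resamples."""

    committee_size: int = 7
    l2_jitter_sd: float = 0.1
    dropout_prob: float = 0.1
    entropy_weight: float = 0.1
    base_penalty: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.committee_size < 2:
            raise ValueError("committee_size must be at least 2")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.l2_jitter_sd < 0:
            raise ValueError("l2_jitter_sd must be nonnegative")


@dataclass
class StrategyScores:
    """Raw and normalized per-strategy scores over the unlabeled pool."""

    raw_uncertainty: np.ndarray
    raw_diversity: np.ndarray
    raw_qbc: np.ndarray
    norm_uncertainty: np.ndarray
    norm_diversity: np.ndarray
    norm_qbc: np.ndarray

    @classmethod
    def from_raw(cls, unc: np.ndarray, div: np.ndarray, qbc: np.ndarray) -> "StrategyScores":
        return cls(
            raw_uncertainty=unc,
            raw_diversity=div,
            raw_qbc=qbc,
            norm_uncertainty=minmax_normalize(unc),
            norm_diversity=minmax_normalize(div),
            norm_qbc=minmax_normalize(qbc),
        )


def zscore_standardize(features: np.ndarray, reference_rows: np.ndarray) -> np.ndarray:
    """Standardize columns by the reference rows' mean and population SD.

    Zero-variance columns are centered only (they carry no scale to divide
    by); the reference set is the current labeled training set in the loop.
    """
    X = np.asarray(features, dtype=float)
    ref = np.asarray(reference_rows, dtype=int)
    if ref.size == 0:
        raise ValueError("reference set is empty")
    mu = X[ref].mean(axis=0)
    sd = X[ref].std(axis=0)  # population convention (ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def uncertainty_scores(probs: np.ndarray) -> np.ndarray:
    """Binary entropy H(p) = -p ln p - (1-p) ln(1-p), with 0 ln 0 := 0."""
    p = np.asarray(probs, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(p < 1, (1 - p) * np.log(1 - p), 0.0)
    return h


def diversity_scores(
    unlabeled_features: np.ndarray,
    labeled_features: np.ndarray,
    variance_adjustment: str = "mean-variance",
) -> np.ndarray:
    """Distance from each unlabeled patient to its nearest labeled neighbour.

    With ``variance_adjustment="mean-variance"`` the distance is divided by
    ``1 + mean per-dimension variance of the labeled features`` — a bounded,
    order-preserving stabilizer; ``"none"`` returns the raw distance.
    """
    U = np.atleast_2d(np.asarray(unlabeled_features, dtype=float))
    L = np.atleast_2d(np.asarray(labeled_features, dtype=float))
    if L.shape[0] == 0:
        raise ValueError("labeled set is empty")
    if U.shape[1] != L.shape[1]:
        raise ValueError(f"feature dimension mismatch: {U.shape[1]} vs {L.shape[1]}")
    nn = NearestNeighbors(n_neighbors=1).fit(L)
    dist, _ = nn.kneighbors(U)
    dist = dist[:, 0]
    if variance_adjustment == "none":
        return dist
    if variance_adjustment == "mean-variance":
        denom = 1.0 + float(L.var(axis=0).mean())
        return dist / denom
    raise ValueError(f"unknown variance_adjustment {variance_adjustment!r}")


def fit_committee(
    labeled_features: np.ndarray,
    labeled_labels: np.ndarray,
    cfg: QbcConfig,
) -> list[tuple[LogisticRegression, np.ndarray]]:
    """Train the bootstrap committee; returns (model, feature mask) pairs.

    Each member sees a bootstrap resample, an independently jittered L2
    penalty (strength multiplied by exp(N(0, l2_jitter_sd^2))) and random
    feature dropout; resamples are redrawn until both classes appear.
    """
    X = np.asarray(labeled_features, dtype=float)
    yl = np.asarray(labeled_labels).astype(int)
    if len(np.unique(yl)) < 2:
        raise ValueError("labeled set must contain both phenotype classes")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x9BC)))
    n, d = X.shape
    members = []
    for _ in range(cfg.committee_size):
        for _attempt in range(20):
            rows = rng.integers(0, n, size=n)
            if len(np.unique(yl[rows])) == 2:
                break
        else:
            rows = np.arange(n)
        penalty = cfg.base_penalty * np.exp(rng.normal(0.0, cfg.l2_jitter_sd))
        keep = rng.random(d) >= cfg.dropout_prob
        if not keep.any():
            keep[rng.integers(0, d)] = True
        model = LogisticRegression(C=1.0 / penalty, max_iter=1000)
        model.fit(X[rows][:, keep], yl[rows])
        members.append((model, keep))
    return members


def committee_probs(members, features: np.ndarray) -> np.ndarray:
    """(n_members, n_patients) matrix of committee probabilities."""
    X = np.asarray(features, dtype=float)
    return np.stack([m.predict_proba(X[:, keep])[:, 1] for m, keep in members])


def committee_disagreement(prob_matrix: np.ndarray, entropy_weight: float) -> np.ndarray:
    """Population variance across members plus an entropy stabilizer.

    score_i = Var_m(p_mi) + lambda * H(mean_m p_mi).  The variance term is
    zero exactly when all members agree; the entropy term keeps patients
    near the decision boundary scored above confidently-agreed ones.
    """
    P = np.asarray(prob_matrix, dtype=float)
    var = P.var(axis=0)  # ddof=0
    return var + entropy_weight * uncertainty_scores(P.mean(axis=0))


def qbc_scores(
    labeled_features: np.ndarray,
    labeled_labels: np.ndarray,
    unlabeled_features: np.ndarray,
    cfg: QbcConfig,
) -> np.ndarray:
    members = fit_committee(labeled_features, labeled_labels, cfg)
    return committee_disagreement(committee_probs(members, unlabeled_features), cfg.entropy_weight)


def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant vector maps to all zeros."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if np.any(~np.isfinite(x)):
        raise ValueError("scores contain non-finite entries")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must be a 3-vector (uncertainty, diversity, qbc)")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def composite_rank(
    scores: StrategyScores,
    weights,
    k: int,
    seed: int,
) -> np.ndarray:
    """Top-k positions in the unlabeled pool under the weighted composite.

    composite = w_unc * unc + w_div * div + w_qbc * qbc + jitter, with
    jitter ~ U(0, 1e-6) seeded: exact ties resolve deterministically for a
    fixed seed but symmetrically across seeds.  If k exceeds the pool the
    whole pool is returned (final short batch).
    """
    w = _check_weights(weights)
    if k <= 0:
        raise ValueError("k must be positive")
    composite = (
        w[0] * scores.norm_uncertainty
        + w[1] * scores.norm_diversity
        + w[2] * scores.norm_qbc
    )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x71E)))
    composite = composite + rng.uniform(0.0, EPS_JITTER, size=composite.shape)
    k_eff = min(k, composite.size)
    top = np.argpartition(-composite, k_eff - 1)[:k_eff]
    return top[np.argsort(-composite[top], kind="stable")]
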