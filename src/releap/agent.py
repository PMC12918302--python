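"""The budget-constrained phenotype-correction loop and its RL wrapper.

Each iteration of an episode: score the unlabeled pool with the three
strategies, observe a summary state, pick mixture weights (the action),
query the reference phenotype for the top-k composite patients, retrain the
downstream model on the updated label vector, evaluate on validation, and
convert the metric movement into a shaped reward.  The episode ends when the
labeling budget is exhausted; with a learnable policy, PPO updates happen
periodically from the stored transitions.

The problem is a POMDP: the agent never sees the pool directly, only a
fixed-length summary of scores, labeled-set composition, recent performance
and remaining budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .labels import LabelState, apply_queries
from .models import (
    CoxSpec,
    MetricsReport,
    evaluate_classification,
    evaluate_survival,
    fit_classifier,
    fit_cox,
)
from .ppo import FrozenPolicy, PpoPolicy
from .strategies import (
    QbcConfig,
    StrategyScores,
    committee_disagreement,
    committee_probs,
    composite_rank,
    diversity_scores,
    fit_committee,
    minmax_normalize,
    uncertainty_scores,
)

__all__ = [
    "CohortSplit",
    "EpisodeConfig",
    "STATE_DIM",
    "build_state",
    "compute_reward",
    "episode_horizon",
    "run_episode",
]

#: 6 score summaries + 2 labeled-set composition + 3 performance trajectory
#: + budget fraction + iteration fraction
STATE_DIM = 13


@dataclass
class CohortSplit:
    """Training-pool and validation arrays carved out of one cohort."""

    x1: np.ndarray
    x2: np.ndarray
    s_proxy: np.ndarray
    s_true: np.ndarray
    y: np.ndarray
    t_event: np.ndarray
    event_flag: np.ndarray
    x1_val: np.ndarray
    x2_val: np.ndarray
    s_proxy_val: np.ndarray
    s_true_val: np.ndarray
    y_val: np.ndarray
    t_event_val: np.ndarray
    event_flag_val: np.ndarray

    @property
    def n_train(self) -> int:
        return len(self.y)

    @property
    def n_val(self) -> int:
        return len(self.y_val)

    @classmethod
    def from_cohort(cls, cohort: Cohort, train_idx: np.ndarray, val_idx: np.ndarray) -> "CohortSplit":
        tr, va = np.asarray(train_idx), np.asarray(val_idx)
        return cls(
            x1=cohort.x1[tr],
            x2=cohort.x2[tr],
            s_proxy=cohort.s_proxy[tr],
            s_true=cohort.s_true[tr],
            y=cohort.y[tr],
            t_event=cohort.t_event[tr],
            event_flag=cohort.event_flag[tr],
            x1_val=cohort.x1[va],
            x2_val=cohort.x2[va],
            s_proxy_val=cohort.s_proxy[va],
            s_true_val=cohort.s_true[va],
            y_val=cohort.y[va],
            t_event_val=cohort.t_event[va],
            event_flag_val=cohort.event_flag[va],
        )


@dataclass(frozen=True)
class EpisodeConfig:
    """Everything an episode needs besides the policy and the data."""

    run_mode: str = "classification"  # classification | survival | both
    qbc: QbcConfig = field(default_factory=QbcConfig)
    cox: CoxSpec = field(default_factory=CoxSpec)
    classifier_penalty: float = 1.0
    diversity_adjustment: str = "mean-variance"
    mirror_validation: bool = True
    reward_window: int = 3
    budget_coef: float = 0.5
    deterministic_policy: bool = False
    update_period: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.run_mode not in ("classification", "survival", "both"):
            raise ValueError(f"unknown run_mode {self.run_mode!r}")


def episode_horizon(budget: int, k: int) -> int:
    """Iterations needed to exhaust the budget in batches of k (last one
    possibly short)."""
    if budget <= 0 or k <= 0:
        raise ValueError("budget and batch size must be positive")
    return math.ceil(budget / k)


def _derived_seed(seed: int, t: int, tag: int) -> int:
    return int(np.random.SeedSequence((seed, t, tag)).generate_state(1)[0] % (2**31))


def build_state(
    scores: StrategyScores,
    label_state: LabelState,
    metric_history: list[float],
    horizon: int,
    iteration: int,
    window: int = 3,
) -> np.ndarray:
    """Fixed 13-dimensional summary state.

    Layout: mean and max of each normalized strategy score on the unlabeled
    pool (6), labeled fraction and labeled-positive fraction (2), last
    metric / one-step change / moving average over the last `window`
    metrics (3), remaining-budget fraction (1), iteration fraction t/H (1).
    """
    if len(metric_history) == 0:
        raise ValueError("at least one metric must be recorded before building a state")
    hist = np.asarray(metric_history, float)
    if np.any(~np.isfinite(hist)):
        raise ValueError("metric history contains non-finite values")
    labeled = label_state.labeled_mask
    n_lab = int(labeled.sum())
    pos_frac = float(label_state.s_current[labeled].mean()) if n_lab else 0.0
    last = hist[-1]
    delta = hist[-1] - hist[-2] if len(hist) > 1 else 0.0
    moving = float(hist[-min(window, len(hist)):].mean())
    budget_frac = label_state.budget_remaining / max(label_state.budget_total, 1)
    state = np.array(
        [
            scores.norm_uncertainty.mean(),
            scores.norm_uncertainty.max(initial=0.0),
            scores.norm_diversity.mean(),
            scores.norm_diversity.max(initial=0.0),
            scores.norm_qbc.mean(),
            scores.norm_qbc.max(initial=0.0),
            n_lab / label_state.n,
            pos_frac,
            last,
            delta,
            moving,
            budget_frac,
            iteration / max(horizon, 1),
        ],
        dtype=float,
    )
    assert state.shape == (STATE_DIM,)
    return state


def compute_reward(
    metric_history: list[float],
    budget_fraction_remaining: float,
    window: int = 3,
    budget_coef: float = 0.5,
) -> float:
    """Shaped reward: (m_t - moving baseline) * (1 + c * budget remaining).

    The baseline is the mean of the last `window` metrics before the current
    one; early in the episode (larger remaining budget) the same improvement
    earns a larger reward, encouraging gains while labels are still cheap to
    reallocate.
    """
    if len(metric_history) == 0:
        raise ValueError("metric history is empty")
    hist = np.asarray(metric_history, float)
    if np.any(~np.isfinite(hist)):
        raise ValueError("metric history contains non-finite values")
    m_t = hist[-1]
    prior = hist[:-1]
    baseline = float(prior[-window:].mean()) if prior.size else float(m_t)
    return float((m_t - baseline) * (1.0 + budget_coef * budget_fraction_remaining))


def _zstats(X: np.ndarray, ref_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X[ref_rows].mean(axis=0)
    sd = X[ref_rows].std(axis=0)
    return mu, np.where(sd > 0, sd, 1.0)


class _ValMirror:
    """Cumulative-proportional upgrade of validation phenotype features.

    After the training pool holds L reference labels, round(L * n_val /
    n_train) validation patients have had their proxy feature replaced by
    the reference phenotype, chosen by the same composite score (balanced at
    random for the seed set, before any model exists).  Disabled mirroring
    evaluates with proxy features throughout.
    """

    def __init__(self, split: CohortSplit, enabled: bool, seed: int):
        self.split = split
        self.enabled = enabled
        self.seed = seed
        self.s_current = split.s_proxy_val.astype(float).copy()
        self.mask = np.zeros(split.n_val, dtype=bool)

    def _target(self, n_labeled_train: int) -> int:
        return int(round(n_labeled_train * self.split.n_val / self.split.n_train))

    def seed_mirror(self, n_seed_labeled: int) -> None:
        if not self.enabled:
            return
        n_new = min(self._target(n_seed_labeled), self.split.n_val)
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0x314)))
        half = n_new // 2
        chosen = []
        for cls, m in ((1, half), (0, n_new - half)):
            pool = np.flatnonzero((self.split.s_true_val == cls) & ~self.mask)
            chosen.append(rng.choice(pool, size=min(m, len(pool)), replace=False))
        self._upgrade(np.concatenate(chosen))

    def _upgrade(self, ids: np.ndarray) -> None:
        self.s_current[ids] = self.split.s_true_val[ids]
        self.mask[ids] = True

    def step(self, n_labeled_train: int, score_fn, weights, t: int, random_mode: bool) -> None:
        if not self.enabled:
            return
        n_new = min(self._target(n_labeled_train), self.split.n_val) - int(self.mask.sum())
        if n_new <= 0:
            return
        pool = np.flatnonzero(~self.mask)
        if random_mode:
            rng = np.random.default_rng(
                np.random.SeedSequence((self.seed, t, 0x315))
            )
            ids = rng.choice(pool, size=min(n_new, len(pool)), replace=False)
        else:
            scores = score_fn(pool)
            pos = composite_rank(scores, weights, min(n_new, len(pool)), _derived_seed(self.seed, t, 3))
            ids = pool[pos]
        self._upgrade(ids)


def run_episode(
    split: CohortSplit,
    label_state: LabelState,
    policy,
    cfg: EpisodeConfig = EpisodeConfig(),
    selection: str = "composite",
) -> tuple[pd.DataFrame, list[MetricsReport], np.ndarray | None]:
    """Run one querying episode.

    Returns (trajectory log, per-iteration reports, final validation
    probabilities — None in survival-only mode).

    `policy` is any object with ``act(state, deterministic)`` returning
    (simplex weights, raw logits, log-prob), a ``needs_state`` flag and an
    ``update`` method (:class:`PpoPolicy` learns, :class:`FrozenPolicy`
    pins the weights).  ``selection="random"`` ignores scores and queries
    uniformly (the random-sampling comparator, outside the RL action space).

    The episode runs ceil(remaining budget / k) iterations, the last batch
    possibly short, and stops when the budget (or pool) is exhausted.
    """
    if selection not in ("composite", "random"):
        raise ValueError(f"unknown selection {selection!r}")
    state = label_state
    k = state.batch_size_k
    budget = min(state.budget_remaining, len(state.unlabeled_indices))
    if budget <= 0:
        raise ValueError("no budget (or no unlabeled patients) to run an episode")
    horizon = episode_horizon(budget, k)
    learning = isinstance(policy, PpoPolicy)
    update_period = policy.cfg.update_period if learning else 0

    mirror = _ValMirror(split, cfg.mirror_validation, cfg.seed)
    mirror.seed_mirror(int(state.labeled_mask.sum()))

    last_probs: dict = {"val": None}

    def _fit_and_eval(iteration: int) -> tuple[object, MetricsReport, float]:
        clf = None
        report = None
        c_index = None
        if cfg.run_mode in ("classification", "both"):
            clf = fit_classifier(state.s_current, split.x2, split.y, cfg.classifier_penalty)
            probs = clf.predict_proba(mirror.s_current, split.x2_val)
            last_probs["val"] = probs
            report = evaluate_classification(probs, split.y_val, iteration)
        if cfg.run_mode in ("survival", "both"):
            cox = fit_cox(state.s_current, split.x2, split.t_event, split.event_flag, cfg.cox)
            risk = cox.risk_score(mirror.s_current, split.x2_val)
            c_index = evaluate_survival(risk, split.t_event_val, split.event_flag_val)
            if report is None:
                report = MetricsReport(
                    auc=float("nan"), f1=float("nan"), tpr_at_fpr10=float("nan"),
                    ppv_at_fpr10=float("nan"), prob_mse=float("nan"), iteration=iteration,
                )
            report.c_index = c_index
        if clf is None:
            # survival-only runs still need a probability model for the
            # uncertainty strategy; reuse the classifier on the outcome
            clf = fit_classifier(state.s_current, split.x2, split.y, cfg.classifier_penalty)
        metric = report.c_index if cfg.run_mode == "survival" else report.auc
        return clf, report, float(metric)

    clf, report0, metric0 = _fit_and_eval(0)
    metric_history = [metric0]
    reports = [report0]
    traj_rows = []
    pending: list[tuple] = []  # (state, z, logp, reward)

    feat_train = np.column_stack([split.x1, split.x2])
    feat_val = np.column_stack([split.x1_val, split.x2_val])

    for t in range(1, horizon + 1):
        unl = state.unlabeled_indices
        lab = state.labeled_indices
        k_t = min(k, state.budget_remaining, len(unl))

        # feature blocks: strategy models see (X1, X2, phenotype value),
        # where labeled patients contribute Strue and unlabeled ones S*
        full_train = np.column_stack([feat_train, state.s_current])
        mu, sd = _zstats(full_train, lab)
        z_train = (full_train - mu) / sd
        x1mu, x1sd = _zstats(split.x1, lab)
        zx1_train = (split.x1 - x1mu) / x1sd

        need_all = policy.needs_state
        w_known = None if need_all else policy.weights
        zeros = np.zeros(len(unl))

        probs_unl = clf.predict_proba(state.s_current[unl], split.x2[unl])
        unc_raw = (
            uncertainty_scores(probs_unl)
            if need_all or w_known[0] > 0
            else zeros
        )
        if need_all or w_known[1] > 0:
            div_raw = diversity_scores(z_train[unl], z_train[lab], cfg.diversity_adjustment)
        else:
            div_raw = zeros
        if need_all or w_known[2] > 0:
            members = fit_committee(
                zx1_train[lab],
                state.s_current[lab].astype(int),
                replace(cfg.qbc, seed=_derived_seed(cfg.seed, t, 2)),
            )
            qbc_raw = committee_disagreement(
                committee_probs(members, zx1_train[unl]), cfg.qbc.entropy_weight
            )
        else:
            members = None
            qbc_raw = zeros
        scores = StrategyScores.from_raw(unc_raw, div_raw, qbc_raw)

        if policy.needs_state:
            s_vec = build_state(scores, state, metric_history, horizon, t, cfg.reward_window)
        else:
            s_vec = None
        weights, z_act, logp = policy.act(s_vec, deterministic=cfg.deterministic_policy)

        # PPO updates are deferred until the successor state is known
        if learning and len(pending) >= update_period:
            S, Z, LP, R = (np.array(x) for x in zip(*pending))
            policy.update(S, Z, LP, R, bootstrap_value=policy.value(s_vec))
            pending = []

        if selection == "random":
            rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, t, 0x4A)))
            ids = rng.choice(unl, size=k_t, replace=False)
        else:
            pos = composite_rank(scores, weights, k_t, _derived_seed(cfg.seed, t, 1))
            ids = unl[pos]
        apply_queries(state, ids, split.s_true)

        # mirror the replacement dynamic on the validation set
        def _val_scores(pool: np.ndarray) -> StrategyScores:
            full_val = np.column_stack([feat_val, mirror.s_current])
            zv = (full_val - mu) / sd
            zx1_val = (split.x1_val - x1mu) / x1sd
            vzeros = np.zeros(len(pool))
            if weights[0] > 0:
                pv = clf.predict_proba(mirror.s_current[pool], split.x2_val[pool])
                v_unc = uncertainty_scores(pv)
            else:
                v_unc = vzeros
            if weights[1] > 0:
                v_div = diversity_scores(zv[pool], z_train[lab], cfg.diversity_adjustment)
            else:
                v_div = vzeros
            if weights[2] > 0:
                mem = members if members is not None else fit_committee(
                    zx1_train[lab],
                    state.s_current[lab].astype(int),
                    replace(cfg.qbc, seed=_derived_seed(cfg.seed, t, 2)),
                )
                v_qbc = committee_disagreement(
                    committee_probs(mem, zx1_val[pool]), cfg.qbc.entropy_weight
                )
            else:
                v_qbc = vzeros
            return StrategyScores.from_raw(v_unc, v_div, v_qbc)

        mirror.step(
            int(state.labeled_mask.sum()), _val_scores, weights, t, selection == "random"
        )

        clf, report, metric = _fit_and_eval(t)
        metric_history.append(metric)
        reports.append(report)

        budget_frac = state.budget_remaining / max(state.budget_total, 1)
        reward = compute_reward(metric_history, budget_frac, cfg.reward_window, cfg.budget_coef)
        if learning:
            pending.append((s_vec, z_act, logp, reward))
        traj_rows.append(
            {
                "iteration": t,
                "w_unc": weights[0],
                "w_div": weights[1],
                "w_qbc": weights[2],
                "reward": reward,
                "metric": metric,
            }
        )

    if learning and pending:
        S, Z, LP, R = (np.array(x) for x in zip(*pending))
        policy.update(S, Z, LP, R, bootstrap_value=0.0)

    return pd.DataFrame(traj_rows), reports, last_probs["val"]
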