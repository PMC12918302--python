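"""Comparator arms, replications, aggregation and subgroup analysis.

Within one replication every method sees the identical stratified split and
balanced seed set, so differences between arms are attributable to the
querying behaviour and not to split variation.  Replication r derives all of
its randomness from ``master_seed`` and ``r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agent import CohortSplit, EpisodeConfig, STATE_DIM, run_episode
from .cohort import Cohort, CohortConfig, generate_cohort
from .labels import SplitSpec, init_seed_set, stratified_split
from .models import (
    MetricsReport,
    evaluate_classification,
    evaluate_survival,
    fit_classifier,
    fit_cox,
)
from .ppo import FrozenPolicy, PpoConfig, PpoPolicy

__all__ = [
    "METHODS",
    "ExperimentConfig",
    "ReplicationResult",
    "DESK_PRESET",
    "budget_percentage",
    "run_method",
    "run_replications",
    "aggregate",
    "subgroup_evaluate",
]

#: one-hot weight vectors of the fixed single-strategy arms
_ONE_HOT = {
    "uncertainty": (1.0, 0.0, 0.0),
    "diversity": (0.0, 1.0, 0.0),
    "qbc": (0.0, 0.0, 1.0),
}

METHODS = ("proxy_only", "oracle", "random", "uncertainty", "diversity", "qbc", "releap")


def budget_percentage(budget: int, cohort_size: int) -> float:
    """Labeling budget as a percentage of the full cohort."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    return 100.0 * budget / cohort_size


@dataclass(frozen=True)
class ExperimentConfig:
    """One benchmark study: cohort source, arms, budget, replications.

    The desk-scale defaults keep the training-pool budget fraction (~43%)
    of the full-scale design while staying laptop-sized.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: str | None = None  # file-based cohorts override `cohort`
    methods: tuple[str, ...] = METHODS
    n_replications: int = 10
    budget_total: int = 4_000
    batch_size_k: int = 200
    seed_set_size: int = 200
    train_fraction: float = 0.8
    run_mode: str = "classification"
    mirror_validation: bool = True
    ppo: PpoConfig = field(default_factory=PpoConfig)
    episode: EpisodeConfig = field(default_factory=EpisodeConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be nonempty")
        for m in self.methods:
            if m == "aphrodite":
                raise ValueError(
                    "the aphrodite comparator requires real clinical notes and "
                    "NLP concept extraction, which have no synthetic counterpart "
                    "here; choose from " + ", ".join(METHODS)
                )
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {METHODS}")


#: desk-scale preset mirroring the full-scale design's ~43% training-pool
#: budget fraction (scaled from 238119/82000/2000/2000/10)
DESK_PRESET = ExperimentConfig(
    cohort=CohortConfig(n_patients=20_000, outcome_prevalence=0.10),
    n_replications=5,
    budget_total=4_000,
    batch_size_k=200,
    seed_set_size=200,
)


@dataclass
class ReplicationResult:
    method: str
    replication: int
    reports: list[MetricsReport]
    final_val_probs: np.ndarray | None = None
    val_y: np.ndarray | None = None
    trajectory: pd.DataFrame | None = None
    query_positions: np.ndarray | None = None
    val_indices: np.ndarray | None = None

    @property
    def final(self) -> MetricsReport:
        return self.reports[-1]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            d = r.as_dict()
            d.update(method=self.method, replication=self.replication)
            rows.append(d)
        return pd.DataFrame(rows)


def _rep_seed(master_seed: int, r: int) -> int:
    return int(np.random.SeedSequence((master_seed, r)).generate_state(1)[0] % (2**31))


def _fit_eval_static(split: CohortSplit, phenotype_train, phenotype_val, cfg: ExperimentConfig):
    """Single fit/eval with a fixed phenotype feature (proxy-only / oracle)."""
    reports = []
    probs = None
    clf = fit_classifier(phenotype_train, split.x2, split.y, cfg.episode.classifier_penalty)
    probs = clf.predict_proba(phenotype_val, split.x2_val)
    report = evaluate_classification(probs, split.y_val, iteration=0)
    if cfg.run_mode in ("survival", "both"):
        cox = fit_cox(phenotype_train, split.x2, split.t_event, split.event_flag, cfg.episode.cox)
        risk = cox.risk_score(phenotype_val, split.x2_val)
        report.c_index = evaluate_survival(risk, split.t_event_val, split.event_flag_val)
    reports.append(report)
    return reports, probs


def run_method(
    method: str,
    cohort: Cohort,
    config: ExperimentConfig,
    replication: int = 0,
) -> ReplicationResult:
    """Run one comparator arm for one replication.

    proxy_only / oracle fit once (no queries); random queries uniformly;
    uncertainty / diversity / qbc run the episode loop with one-hot frozen
    weights; releap runs the episode loop with a learning PPO policy.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    cfg = config
    rep_seed = _rep_seed(cfg.master_seed, replication)
    spec = SplitSpec(train_fraction=cfg.train_fraction, stratify_on="y", seed=rep_seed)
    train_idx, val_idx = stratified_split(cohort, spec)
    split = CohortSplit.from_cohort(cohort, train_idx, val_idx)

    if method == "proxy_only":
        reports, probs = _fit_eval_static(split, split.s_proxy, split.s_proxy_val, cfg)
        return ReplicationResult(method, replication, reports, probs, split.y_val, val_indices=val_idx)
    if method == "oracle":
        reports, probs = _fit_eval_static(split, split.s_true, split.s_true_val, cfg)
        return ReplicationResult(method, replication, reports, probs, split.y_val, val_indices=val_idx)

    state = init_seed_set(
        split.s_true,
        split.s_proxy,
        cfg.seed_set_size,
        cfg.budget_total,
        cfg.batch_size_k,
        seed=rep_seed,
    )
    ep_cfg = replace(
        cfg.episode,
        run_mode=cfg.run_mode,
        mirror_validation=cfg.mirror_validation,
        seed=rep_seed,
    )
    if method == "releap":
        policy = PpoPolicy(STATE_DIM, replace(cfg.ppo, seed=rep_seed))
        selection = "composite"
    elif method == "random":
        policy = FrozenPolicy((1 / 3, 1 / 3, 1 / 3))
        selection = "random"
    else:
        policy = FrozenPolicy(_ONE_HOT[method])
        selection = "composite"

    traj, reports, probs = run_episode(split, state, policy, ep_cfg, selection=selection)
    return ReplicationResult(
        method,
        replication,
        reports,
        probs,
        split.y_val,
        trajectory=traj,
        query_positions=np.flatnonzero(state.labeled_mask),
        val_indices=val_idx,
    )


def run_replications(config: ExperimentConfig, cohort: Cohort | None = None) -> list[ReplicationResult]:
    """All methods x replications; methods share split and seed set within
    a replication (paired design).  Results are independent of run order."""
    cfg = config
    results = []
    for r in range(cfg.n_replications):
        if cohort is not None:
            c = cohort
        elif cfg.cohort_path is not None:
            c = Cohort.from_csv(cfg.cohort_path)
        else:
            c = generate_cohort(replace(cfg.cohort, seed=_rep_seed(cfg.master_seed, 10_000 + r)))
        for method in cfg.methods:
            results.append(run_method(method, c, cfg, replication=r))
    return results


def metrics_table(results: list[ReplicationResult]) -> pd.DataFrame:
    return pd.concat([r.metrics_frame() for r in results], ignore_index=True)


def aggregate(results: list[ReplicationResult]) -> pd.DataFrame:
    """Mean and normal-approximation 95% CI per method x iteration x metric.

    CI = mean +/- 1.96 * SD / sqrt(R); with a single replication the CI
    columns are NaN (absent), never fabricated.
    """
    df = metrics_table(results)
    metric_cols = ["auc", "f1", "tpr_at_fpr10", "ppv_at_fpr10", "prob_mse", "c_index"]
    long = df.melt(
        id_vars=["method", "iteration", "replication"],
        value_vars=metric_cols,
        var_name="metric",
        value_name="value",
    ).dropna(subset=["value"])
    rows = []
    for (method, iteration, metric), g in long.groupby(["method", "iteration", "metric"]):
        vals = g["value"].to_numpy(float)
        mean = vals.mean()
        if len(vals) >= 2:
            half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.nan
        rows.append(
            dict(method=method, iteration=iteration, metric=metric,
                 mean=mean, ci_low=lo, ci_high=hi, n_replications=len(vals))
        )
    return pd.DataFrame(rows).sort_values(["method", "metric", "iteration"]).reset_index(drop=True)


def subgroup_evaluate(results: list[ReplicationResult], group_labels: np.ndarray) -> pd.DataFrame:
    """Recompute final-model metrics within validation subgroups.

    ``group_labels`` covers the whole cohort (indexed by patient position);
    each result's stored validation predictions are re-scored per group.
    Groups with a single outcome class are skipped with a warning.
    """
    groups = np.asarray(group_labels)
    rows = []
    for res in results:
        if res.final_val_probs is None or res.val_indices is None:
            continue
        if np.any(pd.isna(groups[res.val_indices])):
            raise ValueError("missing group labels for validation patients")
        g_val = groups[res.val_indices]
        for g in np.unique(g_val):
            sel = g_val == g
            y_g = res.val_y[sel]
            if len(np.unique(y_g)) < 2:
                warnings.warn(
                    f"subgroup {g!r} has a single outcome class in replication "
                    f"{res.replication}; skipped"
                )
                continue
            rep = evaluate_classification(res.final_val_probs[sel], y_g)
            d = rep.as_dict()
            d.update(method=res.method, replication=res.replication, group=g)
            rows.append(d)
    return pd.DataFrame(rows)
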