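"""Label-state bookkeeping: the evolving phenotype vector, splits, budget.

The learner maintains a phenotype vector ``St`` over the training pool,
initialised to the continuous proxy score ``S*`` and progressively
overwritten with the binary reference phenotype ``Strue`` for queried
patients.  Queried patients are labeled without replacement and never
re-queried; the number of reference labels revealed is capped by a budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["SplitSpec", "LabelState", "stratified_split", "init_seed_set", "apply_queries"]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratify_on: str = "y"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


@dataclass
class LabelState:
    """Mutable core of the querying loop, over the training pool.

    ``s_current[i]`` equals ``s_true[i]`` where ``labeled_mask[i]`` is set
    and ``s_proxy[i]`` otherwise.  ``n_queried`` excludes the seed set.
    """

    s_current: np.ndarray
    labeled_mask: np.ndarray
    n_queried: int
    budget_total: int
    batch_size_k: int

    @property
    def n(self) -> int:
        return len(self.s_current)

    @property
    def budget_remaining(self) -> int:
        return self.budget_total - self.n_queried

    @property
    def unlabeled_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.labeled_mask)

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labeled_mask)

    def snapshot(self, iteration: int, patient_id: np.ndarray | None = None) -> pd.DataFrame:
        """Audit snapshot of the current labels, one row per pool patient."""
        pid = np.arange(self.n) if patient_id is None else patient_id
        return pd.DataFrame(
            {
                "patient_id": pid,
                "s_current": self.s_current,
                "labeled_mask": self.labeled_mask.astype(int),
                "iteration": iteration,
            }
        )


def stratified_split(cohort: Cohort, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-stratified train/validation split (largest-remainder rounding).

    Per-stratum train counts are floor(f * n_c) plus one for the strata with
    the largest fractional remainders until round(f * n) patients are
    allocated; this keeps event rates in the two splits within one patient
    of proportional allocation and is deterministic under the seed.
    """
    strata = getattr(cohort, spec.stratify_on)
    strata = np.asarray(strata)
    n = len(strata)
    values, counts = np.unique(strata, return_counts=True)
    if np.any(counts < 2):
        bad = values[counts < 2][0]
        raise ValueError(f"stratum {bad!r} has fewer than 2 members")

    n_train_total = int(round(spec.train_fraction * n))
    ideal = counts * spec.train_fraction
    base = np.floor(ideal).astype(int)
    remainder = ideal - base
    shortfall = n_train_total - base.sum()
    order = np.argsort(-remainder, kind="stable")
    take = base.copy()
    for j in order[:shortfall]:
        take[j] += 1

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x5971)))
    train_parts, val_parts = [], []
    for v, k in zip(values, take):
        members = np.flatnonzero(strata == v)
        perm = rng.permutation(members)
        train_parts.append(perm[:k])
        val_parts.append(perm[k:])
    train_idx = np.sort(np.concatenate(train_parts))
    val_idx = np.sort(np.concatenate(val_parts))
    return train_idx, val_idx


def init_seed_set(
    s_true: np.ndarray,
    s_proxy: np.ndarray,
    n_seed: int,
    budget_total: int,
    batch_size_k: int,
    seed: int,
) -> LabelState:
    """Balanced seed set: n_seed/2 patients of each phenotype class revealed.

    Arguments are training-pool arrays; all non-seed patients keep the
    continuous proxy score (the S0 = S* initialisation).
    """
    if n_seed <= 0 or n_seed % 2 != 0:
        raise ValueError("n_seed must be a positive even integer")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    s_true = np.asarray(s_true)
    half = n_seed // 2
    chosen = []
    for cls in (0, 1):
        pool = np.flatnonzero(s_true == cls)
        if len(pool) < half:
            raise ValueError(
                f"phenotype class {cls} has only {len(pool)} patients; {half} needed for a balanced seed set"
            )
        chosen.append(rng.choice(pool, size=half, replace=False))
    seed_idx = np.concatenate(chosen)

    s_current = np.asarray(s_proxy, dtype=float).copy()
    labeled_mask = np.zeros(len(s_true), dtype=bool)
    labeled_mask[seed_idx] = True
    s_current[seed_idx] = s_true[seed_idx]
    return LabelState(
        s_current=s_current,
        labeled_mask=labeled_mask,
        n_queried=0,
        budget_total=int(budget_total),
        batch_size_k=int(batch_size_k),
    )


def apply_queries(state: LabelState, ids: np.ndarray, s_true: np.ndarray) -> LabelState:
    """Reveal the reference phenotype for `ids`, spending budget. In place.

    Re-querying an already-labeled patient or overrunning the budget is an
    error: labels are acquired without replacement.
    """
    ids = np.asarray(ids, dtype=int)
    if ids.size == 0:
        return state
    if len(np.unique(ids)) != ids.size:
        raise ValueError("duplicate patient ids in a single query batch")
    if state.labeled_mask[ids].any():
        raise ValueError("attempt to re-query an already-labeled patient")
    if ids.size > state.budget_remaining:
        raise ValueError(
            f"query of {ids.size} patients exceeds remaining budget {state.budget_remaining}"
        )
    state.s_current[ids] = np.asarray(s_true)[ids]
    state.labeled_mask[ids] = True
    state.n_queried += int(ids.size)
    return state
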