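"""Synthetic patient cohorts for budget-constrained phenotype correction.

The generative structure is ``X1 -> Strue -> S* `` and ``(Strue, X2) -> Y``:
proxy features ``X1`` (e.g. diagnosis-code signals) drive a latent binary
phenotype ``Strue`` (e.g. ever-smoker); a cheap continuous proxy score ``S*``
is a degraded view of the same signal; the clinical outcome ``Y`` and the
event time ``T`` depend on the true phenotype and on separate structured
covariates ``X2``.

The proxy degradation is one-sided by design: with probability
``1 - proxy_sensitivity`` a phenotype-positive patient's signal columns are
zeroed before the proxy is scored, mimicking code-based under-ascertainment
(a smoker with no smoking-related diagnosis code looks like a never-smoker
to the proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

__all__ = [
    "CohortConfig",
    "Cohort",
    "PREVALENCE_PRESETS",
    "calibrate_intercept",
    "generate_cohort",
    "duhs_like_fixture",
]

#: Named outcome-prevalence presets for the simulation sweep.
PREVALENCE_PRESETS = {"rare": 0.01, "moderate": 0.10, "common": 0.30}

# Marginals of the motivating health-system lung-cancer cohort
# (N = 238 119): outcome rate, any-smoking-ICD coverage, never-smoker
# fraction.  Used as calibration targets by `duhs_like_fixture`.
DUHS_MARGINALS = {
    "n_total": 238_119,
    "outcome_count": 1_846,
    "icd_coverage_count": 21_505,
    "never_smoker_count": 125_556,
}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    proxy_sensitivity is the fraction of phenotype-positive patients whose
    signal the proxy can see at all; proxy_noise_sd is additive noise on the
    proxy's linear score; effect_strue_on_y is the log-odds effect of the
    true phenotype on the binary outcome.
    """

    n_patients: int = 20_000
    dim_x1: int = 5
    dim_x2: int = 4
    outcome_prevalence: float = 0.10
    phenotype_prevalence: float = 0.30
    proxy_sensitivity: float = 0.5
    proxy_noise_sd: float = 1.0
    effect_strue_on_y: float = 2.0
    censoring_rate: float = 0.7
    seed: int = 0
    # internal scale of the X1 -> Strue signal (kept fixed across studies)
    phenotype_signal: float = 1.5

    def __post_init__(self) -> None:
        if self.n_patients < 100:
            raise ValueError("n_patients must be at least 100")
        if self.dim_x1 < 1 or self.dim_x2 < 1:
            raise ValueError("feature dimensions must be positive")
        for name in ("outcome_prevalence", "phenotype_prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if not 0.0 < self.proxy_sensitivity <= 1.0:
            raise ValueError("proxy_sensitivity must lie in (0, 1]")
        if self.proxy_noise_sd < 0:
            raise ValueError("proxy_noise_sd must be nonnegative")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")


@dataclass
class Cohort:
    """One row per patient: proxy features, covariates, phenotype, outcome."""

    patient_id: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    s_proxy: np.ndarray
    s_true: np.ndarray
    y: np.ndarray
    t_event: np.ndarray
    event_flag: np.ndarray
    config: CohortConfig | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.patient_id)

    def to_frame(self) -> pd.DataFrame:
        cols = {"patient_id": self.patient_id}
        for j in range(self.x1.shape[1]):
            cols[f"x1_{j}"] = self.x1[:, j]
        for j in range(self.x2.shape[1]):
            cols[f"x2_{j}"] = self.x2[:, j]
        cols.update(
            s_proxy=self.s_proxy,
            s_true=self.s_true,
            y=self.y,
            t_event=self.t_event,
            event_flag=self.event_flag,
        )
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        x1_cols = sorted(
            (c for c in df.columns if c.startswith("x1_")),
            key=lambda c: int(c.split("_")[1]),
        )
        x2_cols = sorted(
            (c for c in df.columns if c.startswith("x2_")),
            key=lambda c: int(c.split("_")[1]),
        )
        return cls(
            patient_id=df["patient_id"].to_numpy(),
            x1=df[x1_cols].to_numpy(float),
            x2=df[x2_cols].to_numpy(float),
            s_proxy=df["s_proxy"].to_numpy(float),
            s_true=df["s_true"].to_numpy(int),
            y=df["y"].to_numpy(int),
            t_event=df["t_event"].to_numpy(float),
            event_flag=df["event_flag"].to_numpy(int),
        )

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path))


def calibrate_intercept(target_prevalence: float, linear_predictor: np.ndarray) -> float:
    """Intercept ``a`` such that ``mean(expit(a + eta))`` hits the target.

    Monotone root-finding (Brent); the population mean of the logistic is
    strictly increasing in ``a``, so the root is unique.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie strictly in (0, 1)")
    eta = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor contains non-finite entries")

    def gap(a: float) -> float:
        return float(np.mean(expit(a + eta))) - target_prevalence

    lo, hi = -10.0, 10.0
    while gap(lo) > 0 and lo > -500:
        lo *= 2
    while gap(hi) < 0 and hi < 500:
        hi *= 2
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"intercept calibration failed to bracket target prevalence {target_prevalence}"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """One independent generator per field, all derived from one seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort under ``X1 -> Strue -> S*`` and ``(Strue, X2) -> Y``.

    Event times are exponential with rate proportional to
    ``exp(effect * Strue + beta' X2)`` (the same linear predictor as the
    binary outcome), administratively censored at the empirical quantile
    that yields the configured censoring rate.
    """
    cfg = config
    rng = _streams(cfg.seed, ("x1", "s_true", "mask", "proxy", "x2", "y", "t"))
    n, d1, d2 = cfg.n_patients, cfg.dim_x1, cfg.dim_x2

    x1 = rng["x1"].standard_normal((n, d1))
    u = np.full(d1, cfg.phenotype_signal / np.sqrt(d1))
    eta1 = x1 @ u
    a1 = calibrate_intercept(cfg.phenotype_prevalence, eta1)
    s_true = (rng["s_true"].random(n) < expit(a1 + eta1)).astype(np.int64)

    # one-sided degradation: unseen positives have their signal zeroed
    hidden = (s_true == 1) & (rng["mask"].random(n) >= cfg.proxy_sensitivity)
    x1_obs = np.where(hidden[:, None], 0.0, x1)
    noise = rng["proxy"].normal(0.0, cfg.proxy_noise_sd, n)
    s_proxy = expit(a1 + x1_obs @ u + noise)

    x2 = rng["x2"].standard_normal((n, d2))
    beta2 = np.full(d2, 0.5 / np.sqrt(d2))
    eta_y = cfg.effect_strue_on_y * s_true + x2 @ beta2
    alpha = calibrate_intercept(cfg.outcome_prevalence, eta_y)
    y = (rng["y"].random(n) < expit(alpha + eta_y)).astype(np.int64)

    t_latent = rng["t"].exponential(1.0, n) / np.exp(eta_y - eta_y.mean())
    horizon = np.quantile(t_latent, 1.0 - cfg.censoring_rate)
    event_flag = (t_latent <= horizon).astype(np.int64)
    t_event = np.minimum(t_latent, horizon)
    if event_flag.sum() == 0:
        raise RuntimeError("degenerate cohort: no observed events")

    return Cohort(
        patient_id=np.arange(n, dtype=np.int64),
        x1=x1_obs,
        x2=x2,
        s_proxy=s_proxy,
        s_true=s_true,
        y=y,
        t_event=t_event,
        event_flag=event_flag,
        config=cfg,
    )


def duhs_like_fixture(seed: int, n: int = 20_000) -> Cohort:
    """Synthetic cohort calibrated to published large-health-system marginals.

    Targets (expectations, hit within Monte-Carlo error): outcome prevalence
    0.78%, any-positive-signal (smoking-code-like) coverage 9.0% of patients,
    phenotype-negative (never-smoker-like) fraction 52.7%.  X1 columns are
    sparse nonnegative code counts; the proxy score is the fitted probability
    of a code-only logistic model, mirroring how a diagnosis-code-only proxy
    phenotype is built in practice.  Entirely synthetic; no real patient data.
    """
    m = DUHS_MARGINALS
    p_pheno = 1.0 - m["never_smoker_count"] / m["n_total"]  # ~0.473
    p_cov = m["icd_coverage_count"] / m["n_total"]  # ~0.090
    p_outcome = m["outcome_count"] / m["n_total"]  # ~0.0078
    fp_rate = 0.005  # code present without the phenotype (coding noise)
    # coverage among positives solving the total-coverage identity
    sens = (p_cov - (1.0 - p_pheno) * fp_rate) / p_pheno

    rng = _streams(seed, ("s_true", "cover", "counts", "x2", "y", "t"))
    d1, d2 = 4, 4

    s_true = (rng["s_true"].random(n) < p_pheno).astype(np.int64)
    p_any_code = np.where(s_true == 1, sens, fp_rate)
    has_code = rng["cover"].random(n) < p_any_code

    x1 = np.zeros((n, d1))
    idx = np.flatnonzero(has_code)
    if idx.size:
        counts = 1 + rng["counts"].poisson(0.8, size=idx.size)
        cols = rng["counts"].integers(0, d1, size=idx.size)
        x1[idx, cols] = counts
        extra = rng["counts"].random(idx.size) < 0.3
        x1[idx[extra], rng["counts"].integers(0, d1, size=int(extra.sum()))] += 1

    proxy_model = LogisticRegression(C=1.0, max_iter=1000)
    proxy_model.fit(x1, s_true)
    s_proxy = proxy_model.predict_proba(x1)[:, 1]

    x2 = rng["x2"].standard_normal((n, d2))
    beta2 = np.full(d2, 0.5 / np.sqrt(d2))
    eta_y = 2.0 * s_true + x2 @ beta2
    alpha = calibrate_intercept(p_outcome, eta_y)
    y = (rng["y"].random(n) < expit(alpha + eta_y)).astype(np.int64)

    censoring_rate = 0.7
    t_latent = rng["t"].exponential(1.0, n) / np.exp(eta_y - eta_y.mean())
    horizon = np.quantile(t_latent, 1.0 - censoring_rate)
    event_flag = (t_latent <= horizon).astype(np.int64)
    t_event = np.minimum(t_latent, horizon)

    return Cohort(
        patient_id=np.arange(n, dtype=np.int64),
        x1=x1,
        x2=x2,
        s_proxy=s_proxy,
        s_true=s_true,
        y=y,
        t_event=t_event,
        event_flag=event_flag,
    )
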