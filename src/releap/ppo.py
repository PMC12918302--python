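"""Minimal proximal policy optimization over a simplex action head.

The policy is a small tanh MLP mapping the summary state to three
unconstrained mean logits; actions are sampled from a diagonal Gaussian over
the logits (state-independent learned log-SD) and mapped through a softmax
onto the probability simplex.  The softmax acts on the policy's mixture
logits, never on the raw per-patient strategy scores.  Training maximises
the clipped-surrogate objective with generalized advantage estimation and a
separate value-function baseline; all parameters live in plain numpy arrays
with hand-written backprop and Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PpoConfig",
    "PpoPolicy",
    "FrozenPolicy",
    "softmax",
    "clipped_surrogate",
    "gae_advantages",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class PpoConfig:
    discount: float = 0.99
    clip_epsilon: float = 0.2
    learning_rate: float = 0.01
    update_period: int = 1
    gae_lambda: float = 0.95
    entropy_bonus: float = 0.0
    hidden_sizes: tuple[int, ...] = (32,)
    epochs_per_update: int = 4
    init_log_std: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.discount <= 1.0:
            raise ValueError("discount must lie in (0, 1]")
        if self.clip_epsilon <= 0:
            raise ValueError("clip_epsilon must be positive")


class _MLP:
    """Tanh MLP with cached forward pass and manual backprop."""

    def __init__(self, sizes: tuple[int, ...], rng: np.random.Generator):
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._cache: list[np.ndarray] = []

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(x, dtype=float))
        self._cache = [a]
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            a = a @ W + b
            if i < last:
                a = np.tanh(a)
            self._cache.append(a)
        return a

    def backward(self, d_out: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. params for the cached batch, given dL/d_output."""
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        delta = np.atleast_2d(d_out)
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            a_in = self._cache[i]
            if i < last:
                delta = delta * (1.0 - self._cache[i + 1] ** 2)
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
        return gW + gb


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**self.t)
            vhat = v / (1 - beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def clipped_surrogate(ratio: np.ndarray, advantage: np.ndarray, eps: float) -> np.ndarray:
    """Per-sample PPO objective: min(r*A, clip(r, 1-eps, 1+eps)*A)."""
    r = np.asarray(ratio, float)
    a = np.asarray(advantage, float)
    return np.minimum(r * a, np.clip(r, 1.0 - eps, 1.0 + eps) * a)


def gae_advantages(
    rewards: np.ndarray,
    values: np.ndarray,
    bootstrap_value: float,
    gamma: float,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation over one trajectory segment.

    Returns (advantages, value targets); bootstrap_value is V(s_{T+1})
    (zero at true episode end).
    """
    r = np.asarray(rewards, float)
    v = np.asarray(values, float)
    T = len(r)
    v_next = np.append(v[1:], bootstrap_value)
    deltas = r + gamma * v_next - v
    adv = np.zeros(T)
    acc = 0.0
    for t in range(T - 1, -1, -1):
        acc = deltas[t] + gamma * lam * acc
        adv[t] = acc
    return adv, adv + v


class PpoPolicy:
    """Gaussian-over-logits policy with softmax simplex head and value net."""

    N_STRATEGIES = 3

    def __init__(self, state_dim: int, cfg: PpoConfig = PpoConfig()):
        self.cfg = cfg
        self.state_dim = state_dim
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x990)))
        sizes = (state_dim, *cfg.hidden_sizes, self.N_STRATEGIES)
        self.net = _MLP(sizes, rng)
        self.log_std = np.full(self.N_STRATEGIES, cfg.init_log_std)
        self.value_net = _MLP((state_dim, *cfg.hidden_sizes, 1), rng)
        self._opt = _Adam(self.net.params() + [self.log_std], cfg.learning_rate)
        self._vopt = _Adam(self.value_net.params(), cfg.learning_rate)
        self._rng = rng
        self.needs_state = True

    # -- acting ---------------------------------------------------------
    def mean_logits(self, state: np.ndarray) -> np.ndarray:
        state = np.asarray(state, float)
        if np.any(~np.isfinite(state)):
            raise ValueError("state contains non-finite entries")
        out = self.net.forward(state)
        if np.any(~np.isfinite(out)):
            raise ValueError("policy produced non-finite logits")
        return out[0] if out.shape[0] == 1 and state.ndim == 1 else out

    def act(self, state: np.ndarray, deterministic: bool = False):
        """Returns (weights on the simplex, raw logits z, log-prob of z)."""
        mu = self.mean_logits(state)
        if deterministic:
            z = mu
            logp = self._log_prob(z, mu)
        else:
            std = np.exp(self.log_std)
            z = mu + std * self._rng.standard_normal(self.N_STRATEGIES)
            logp = self._log_prob(z, mu)
        return softmax(z), z, float(logp)

    def _log_prob(self, z: np.ndarray, mu: np.ndarray) -> float:
        std = np.exp(self.log_std)
        return float(
            -0.5 * np.sum(((z - mu) / std) ** 2)
            - np.sum(self.log_std)
            - 0.5 * self.N_STRATEGIES * np.log(2 * np.pi)
        )

    def value(self, state: np.ndarray) -> float:
        return float(self.value_net.forward(state)[0, 0])

    def policy_parameters(self) -> list[np.ndarray]:
        """Copies of the policy-head parameters (excludes the value net)."""
        return [p.copy() for p in self.net.params()] + [self.log_std.copy()]

    # -- learning -------------------------------------------------------
    def update(
        self,
        states: np.ndarray,
        z_actions: np.ndarray,
        logp_old: np.ndarray,
        rewards: np.ndarray,
        bootstrap_value: float = 0.0,
    ) -> dict:
        """One PPO update on a trajectory segment (in time order).

        Runs several epochs of full-batch clipped-surrogate ascent on the
        policy and squared-error descent on the value baseline.  A batch
        whose advantages are exactly zero leaves the policy parameters
        exactly unchanged.
        """
        S = np.atleast_2d(np.asarray(states, float))
        Z = np.atleast_2d(np.asarray(z_actions, float))
        lp_old = np.asarray(logp_old, float)
        R = np.asarray(rewards, float)
        if S.shape[0] == 0:
            raise ValueError("empty trajectory batch")
        cfg = self.cfg

        values = self.value_net.forward(S)[:, 0]
        adv, v_targets = gae_advantages(R, values, bootstrap_value, cfg.discount, cfg.gae_lambda)
        if adv.size > 1 and adv.std() > 0:
            adv_n = (adv - adv.mean()) / adv.std()
        else:
            adv_n = adv
        B = S.shape[0]

        for _ in range(cfg.epochs_per_update):
            mu = self.net.forward(S)
            std = np.exp(self.log_std)
            zscore = (Z - mu) / std
            logp = (
                -0.5 * np.sum(zscore**2, axis=1)
                - np.sum(self.log_std)
                - 0.5 * self.N_STRATEGIES * np.log(2 * np.pi)
            )
            ratio = np.exp(logp - lp_old)
            surr1 = ratio * adv_n
            surr2 = np.clip(ratio, 1 - cfg.clip_epsilon, 1 + cfg.clip_epsilon) * adv_n
            # gradient flows through the ratio only where the unclipped
            # branch attains the minimum
            active = (surr1 <= surr2).astype(float)
            d_obj_dlogp = active * ratio * adv_n  # d surrogate / d logp
            # maximize objective + entropy bonus -> minimize negative
            d_loss_dlogp = -d_obj_dlogp / B
            d_mu = d_loss_dlogp[:, None] * (zscore / std)
            grads = self.net.backward(d_mu)
            d_logstd = np.sum(d_loss_dlogp[:, None] * (zscore**2 - 1.0), axis=0)
            # Gaussian entropy = sum(log_std) + const; bonus encourages it
            d_logstd -= cfg.entropy_bonus * np.ones_like(self.log_std)
            self._opt.step(grads + [d_logstd])

            v_pred = self.value_net.forward(S)[:, 0]
            d_v = (2.0 / B) * (v_pred - v_targets)[:, None]
            self._vopt.step(self.value_net.backward(d_v))

        return {
            "mean_advantage": float(adv.mean()),
            "mean_ratio": float(ratio.mean()),
        }


class FrozenPolicy:
    """Policy pinned at fixed mixture weights; used by single-strategy arms
    and as the reduction oracle for the learned agent."""

    def __init__(self, weights, compute_all_scores: bool = False):
        w = np.asarray(weights, float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be a nonnegative 3-vector summing to 1")
        self.weights = w
        # when True the episode runner scores every strategy (as the learned
        # agent would) even though only the frozen weights are used
        self.needs_state = compute_all_scores

    def act(self, state=None, deterministic: bool = True):
        return self.weights.copy(), None, 0.0

    def update(self, *args, **kwargs):
        return {}
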