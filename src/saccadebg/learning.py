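"""Actor-critic TD(lambda) learning at the basal-ganglia input.

Two independent learning modules re-weight the BG inputs: a spatial one
over the concatenated (collicular-thalamus, FEF-input) coarse channel
vector and a colour one over the three colour channels.  States are the
inputs themselves; "actions" are the actor-weighted inputs, selected by
the BG circuit downstream (which plays the role of the winner-take-all of
a classical actor-critic).

Per simulation step (1 ms):

    V_t     = w_critic . u_t
    delta_t = R_t + gamma * V_t - V_{t-1}
    E_c    <- lambda * E_c + u_{t-1};          w_critic += eta * delta * E_c
    A_t     = W_actor . u_t
    E_a    <- alpha * E_a + credit_{t-1} (x) u_{t-1}
    W_actor += eta * delta * E_a

where the credit vector is, by default, the per-channel BG disinhibition
(1 - GPi/GPi_rest): written literally with raw pallidal output, credit
would flow to the channels that were *not* selected (selected channels
have low GPi); the literal variant remains available through the config
switch ``credit="gpi"``.

The actor starts from the identity (initial "standard" behaviour: weighted
input equals input); its diagonal is floored at 0.6 so the system can
always trigger saccades, and off-diagonal weights are kept non-negative.
Critic weights start uniformly at random in [0, 0.01].

For efficiency the actor's weight matrix is applied with its value at the
start of the trial and the summed per-step updates are committed at trial
end; with eligibility traces reset between trials this trial-end commit
equals the exact per-step recursion

    sum_t delta_t * E_t = sum_s c_s * credit_s (x) u_s,
    c_s = sum_{t >= s} delta_t * alpha^(t-s)

computed by a backward pass (`TrialAccumulator`), which the test-suite
checks against the naive per-step loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, LearningConfig

__all__ = [
    "CriticState",
    "ActorState",
    "td_error",
    "critic_update",
    "actor_apply",
    "actor_update",
    "TrialAccumulator",
]


# ---------------------------------------------------------------------------
# elementary operations (per-step form)
# ---------------------------------------------------------------------------

def td_error(r: float, v_now: float, v_prev: float, gamma: float) -> float:
    """Temporal-difference error delta = R + gamma*V_t - V_{t-1}."""
    if not 0 < gamma <= 1:
        raise ConfigurationError("gamma must be in (0, 1]")
    return r + gamma * v_now - v_prev


@dataclass
class CriticState:
    """Value-function weights and eligibility trace for one module."""

    n: int
    gamma: float = 0.997
    lam: float = 0.997
    eta: float = 0.001
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    e: np.ndarray = field(default=None)  # type: ignore[assignment]
    v_prev: float = 0.0

    def __post_init__(self):
        if self.w is None:
            raise ConfigurationError(
                "critic weights must be initialised via CriticState.init")
        self.w = np.asarray(self.w, float)
        if self.e is None:
            self.e = np.zeros(self.n)

    @classmethod
    def init(cls, n: int, cfg: LearningConfig, eta: float,
             rng: np.random.Generator) -> "CriticState":
        w = rng.uniform(0.0, cfg.critic_init, size=n)
        return cls(n=n, gamma=cfg.gamma, lam=cfg.lam, eta=eta, w=w)

    def value(self, u: np.ndarray) -> float:
        """Predicted return, clipped to the attainable reward range."""
        return float(min(max(self.w @ u, 0.0), 1.0))

    def reset_trial(self) -> None:
        self.e[:] = 0.0
        self.v_prev = 0.0


def critic_update(state: CriticState, delta: float,
                  input_prev: np.ndarray) -> CriticState:
    """Trace decay-and-accumulate, then the weight update (in place)."""
    u = np.asarray(input_prev, float)
    if u.shape != state.e.shape:
        raise ConfigurationError("input/trace length mismatch")
    state.e *= state.lam
    state.e += u
    state.w += state.eta * delta * state.e
    return state


@dataclass
class ActorState:
    """Input re-weighting matrix, trace and clamps for one module."""

    n: int
    alpha: float = 0.997
    eta: float = 0.001
    w_min_diag: float = 0.6
    w_max: float = 8.0
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    e: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.w is None:
            self.w = np.eye(self.n)
        self.w = np.asarray(self.w, float)
        if self.e is None:
            self.e = np.zeros((self.n, self.n))
        #: rows that ever deviated from the identity (sparse fast apply)
        self.touched = np.zeros(self.n, dtype=bool)
        self.touched_idx = np.empty(0, dtype=np.int64)

    @classmethod
    def init(cls, n: int, cfg: LearningConfig, eta: float) -> "ActorState":
        return cls(n=n, alpha=cfg.alpha, eta=eta, w_min_diag=cfg.w_min_diag,
                   w_max=cfg.w_max)

    def clamp(self) -> None:
        np.clip(self.w, 0.0, self.w_max, out=self.w)
        d = np.einsum("ii->i", self.w)
        np.clip(d, self.w_min_diag, None, out=d)

    def reset_trial(self) -> None:
        self.e[:] = 0.0


def actor_apply(state: ActorState, input_now: np.ndarray) -> np.ndarray:
    """Weighted input vector A_t = W_actor . u_t."""
    u = np.asarray(input_now, float)
    if u.shape[0] != state.n:
        raise ConfigurationError("input length mismatch")
    return state.w @ u


def actor_update(state: ActorState, delta: float, input_prev: np.ndarray,
                 credit_prev: np.ndarray) -> ActorState:
    """One per-step actor update (in place): trace, weights, clamps.

    ``credit_prev`` is the per-channel credit signal from the BG at the
    previous step (see module docstring), already expanded to the actor's
    output dimension.
    """
    u = np.asarray(input_prev, float)
    a = np.asarray(credit_prev, float)
    if u.shape[0] != state.n or a.shape[0] != state.n:
        raise ConfigurationError("input/credit length mismatch")
    state.e *= state.alpha
    state.e += np.outer(a, u)
    state.w += state.eta * delta * state.e
    state.touched |= np.abs(state.e).max(axis=1) > 0
    state.touched_idx = np.nonzero(state.touched)[0]
    state.clamp()
    return state


# ---------------------------------------------------------------------------
# trial-level accumulator (exact trial-end commit of the per-step recursion)
# ---------------------------------------------------------------------------

class TrialAccumulator:
    """Records (input, credit, delta) per step; commits the actor at trial end.

    Equivalent to applying :func:`actor_update` every step with the weight
    matrix frozen over the trial (traces are reset between trials, so no
    eligibility crosses the commit boundary).
    """

    def __init__(self, actor: ActorState):
        self.actor = actor
        self._inputs: list[np.ndarray] = []
        self._credits: list[np.ndarray] = []
        self._deltas: list[float] = []

    def record(self, u: np.ndarray, credit: np.ndarray, delta: float) -> None:
        self._inputs.append(u)
        self._credits.append(credit)
        self._deltas.append(delta)

    def commit(self) -> None:
        """Apply the accumulated weight change and clear the trial buffers."""
        if not self._deltas:
            return
        deltas = np.asarray(self._deltas)
        alpha = self.actor.alpha
        # c_s = sum_{t>=s} delta_t alpha^{t-s}, by backward recursion
        c = np.empty_like(deltas)
        acc = 0.0
        for s in range(len(deltas) - 1, -1, -1):
            acc = deltas[s] + alpha * acc
            c[s] = acc
        U = np.asarray(self._inputs)      # (S, N)
        A = np.asarray(self._credits)     # (S, N)
        # restrict the rank-S outer-product sum to active rows/columns
        rows = np.nonzero(A.max(axis=0) > 1e-9)[0]
        cols = np.nonzero(U.max(axis=0) > 1e-9)[0]
        if rows.size and cols.size:
            dw = (A[:, rows] * c[:, None]).T @ U[:, cols]
            self.actor.w[np.ix_(rows, cols)] += self.actor.eta * dw
            self.actor.touched[rows] = True
            self.actor.touched_idx = np.nonzero(self.actor.touched)[0]
            self.actor.clamp()
        self._inputs.clear()
        self._credits.clear()
        self._deltas.clear()

    def reset(self) -> None:
        self._inputs.clear()
        self._credits.clear()
        self._deltas.clear()
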