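"""Value-learning architectures for the chain task.

Four architectures are implemented, differing only in how states are
represented:

``SimpleTD``
    Punctate (individual) state representation: each state carries its own
    learned value ``V(S_k)``, updated by the TD error
    ``delta = R(S_t) + gamma V(S_{t+1}) - V(S_t)``.

``ReducedSR`` (rigid, ``alpha_feature = 0``)
    Goal-based reduced successor representation: each state is represented
    by a single scalar feature ``x(S_k) = gamma^(n-k)``, the discounted
    future occupancy of the goal state under the Non-Resistant policy, and
    values are approximated linearly as ``V(S_k) ~ w x(S_k)`` with a single
    learned coefficient ``w``.

``ReducedSR`` (adaptive, ``alpha_feature > 0``)
    Same, but the features themselves are slowly updated by their own TD
    error ``delta_feature = gamma x(S_{t+1}) - x(S_t)``; the goal feature is
    frozen at 1 (its feature TD error is theoretically 0).

``GenuineSR``
    Full successor representation: state ``S_k`` is represented by the
    vector of discounted future occupancies of every state under the
    Non-Resistant policy, ``x_j(S_k) = gamma^(j-k)`` for ``j >= k``, with a
    learned weight per feature.  The feature matrix is fixed.

All learners share the bootstrap conventions of the task: the bootstrap
term is dropped when the current state is the goal (unless a punishment
state follows it) and at the punishment state, and the RPE generated upon
initiation of behavior equals ``gamma * V(S_1)`` (the learned cue value)
with no associated parameter update.

Initial vectors are built by backward multiplicative recursion
(``v[k] = gamma * v[k+1]``) so that the algebraic zero-RPE identities of
the task (e.g. Go-step RPE of the rigid reduced SR) hold bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .chain import ChainSpec

__all__ = [
    "true_values_nonresistant",
    "reduced_features",
    "genuine_features",
    "SimpleTD",
    "ReducedSR",
    "GenuineSR",
]


def _discount_ladder(gamma: float, n: int) -> np.ndarray:
    """Array ``d`` of length n+1 with ``d[k] = gamma**(n-k)`` for k=1..n,
    built so that ``gamma * d[k+1] == d[k]`` holds bitwise; ``d[0] = 0``."""
    d = np.zeros(n + 1)
    d[n] = 1.0
    for k in range(n - 1, 0, -1):
        d[k] = gamma * d[k + 1]
    return d


def true_values_nonresistant(spec: ChainSpec) -> np.ndarray:
    """True state values under the Non-Resistant policy,
    ``V(S_k) = R gamma^(n-k)``.

    Returns an array of length ``n+1`` indexed by state (entry 0 unused).
    """
    return spec.reward_size * _discount_ladder(spec.gamma, spec.n_states)


def reduced_features(spec: ChainSpec) -> np.ndarray:
    """Scalar features of the goal-based reduced SR,
    ``x(S_k) = gamma^(n-k)``.

    Indexed by state (entry 0 unused).  When the punishment state exists its
    feature is 0: the goal state was never visited from it under the policy
    that formed the representation.
    """
    x = _discount_ladder(spec.gamma, spec.n_states)
    if spec.has_punishment:
        x = np.append(x, 0.0)
    return x


def genuine_features(spec: ChainSpec) -> np.ndarray:
    """Feature matrix of the genuine SR under the Non-Resistant policy:
    ``m[k, j] = gamma^(j-k)`` for ``j >= k``, 0 otherwise.

    Shape ``(n+1, n+1)``, indexed by state on both axes (row/column 0
    unused, kept at 0).  Row ``k`` is the SR of state ``S_k``.
    """
    n = spec.n_states
    m = np.zeros((n + 1, n + 1))
    for j in range(1, n + 1):
        m[j, j] = 1.0
        for k in range(j - 1, 0, -1):
            m[k, j] = spec.gamma * m[k + 1, j]
    return m


class SimpleTD:
    """Punctate-state TD(0) value learner.

    Parameters
    ----------
    spec:
        Chain task specification.
    alpha:
        Learning rate (default 0.5).
    init:
        ``"zeros"`` for naive values, or ``"nonresistant"`` for the values
        at the completion of learning under the Non-Resistant policy
        (``V(S_k) = R gamma^(n-k)``; the punishment state, when present,
        starts at 0).
    """

    def __init__(self, spec: ChainSpec, alpha: float = 0.5, init: str = "zeros"):
        self.spec = spec
        self.alpha = alpha
        size = spec.n_states + 2 if spec.has_punishment else spec.n_states + 1
        self.v = np.zeros(size)
        if init == "nonresistant":
            self.v[: spec.n_states + 1] = true_values_nonresistant(spec)
        elif init != "zeros":
            raise ValueError(f"unknown init {init!r}")

    def value(self, state: int) -> float:
        return float(self.v[state])

    def cue_value(self) -> float:
        """RPE generated upon initiation of behavior, ``gamma * V(S_1)``."""
        return self.spec.gamma * float(self.v[1])

    def _drop_bootstrap(self, s_t: int) -> bool:
        if s_t == self.spec.goal:
            return not self.spec.has_punishment
        return s_t == self.spec.punishment_state

    def td_step(self, s_t: int, s_next: int | None, reward: float) -> float:
        """One TD update; returns the RPE computed from pre-update values."""
        if self._drop_bootstrap(s_t):
            boot = 0.0
        else:
            boot = self.spec.gamma * self.v[s_next]
        delta = reward + boot - self.v[s_t]
        self.v[s_t] += self.alpha * delta
        return float(delta)

    def step(self, s_t, s_next, reward):
        """Uniform learner-step interface: ``(rpe, feature_rpe=None)``."""
        return self.td_step(s_t, s_next, reward), None

    def snapshot(self) -> dict[str, float]:
        return {f"v_{k}": float(self.v[k]) for k in range(1, len(self.v))}


class ReducedSR:
    """Goal-based reduced-SR value learner (rigid or slowly adaptive).

    The value function is approximated as ``V(S_k) ~ w x(S_k)`` with scalar
    feature ``x(S_k)`` and coefficient ``w`` (initially ``R``, the exact
    representation of the Non-Resistant values).  The coefficient is updated
    by ``w += alpha_w x(S_t) delta``; with ``alpha_feature > 0`` the
    features are additionally updated by their own TD error (goal feature
    frozen at 1).  ``alpha_feature = 0`` gives the rigid representation.
    """

    def __init__(
        self,
        spec: ChainSpec,
        alpha_w: float = 0.5,
        alpha_feature: float = 0.0,
        w0: float | None = None,
    ):
        if alpha_feature < 0:
            raise ValueError("alpha_feature must be >= 0")
        self.spec = spec
        self.alpha_w = alpha_w
        self.alpha_feature = alpha_feature
        self.w = spec.reward_size if w0 is None else float(w0)
        self.x = reduced_features(spec)

    @property
    def rigid(self) -> bool:
        return self.alpha_feature == 0.0

    def value(self, state: int) -> float:
        return float(self.w * self.x[state])

    def cue_value(self) -> float:
        """Initiation RPE ``gamma * w * x(S_1)`` (= ``w gamma^n`` when rigid)."""
        return float(self.w * (self.spec.gamma * self.x[1]))

    def _drop_bootstrap(self, s_t: int) -> bool:
        if s_t == self.spec.goal:
            return not self.spec.has_punishment
        return s_t == self.spec.punishment_state

    def td_step(self, s_t: int, s_next: int | None, reward: float) -> float:
        """One coefficient update; returns the RPE. Features untouched."""
        if self._drop_bootstrap(s_t):
            boot = 0.0
        else:
            # Grouped as w * (gamma * x) so that a Go step gives exactly 0:
            # gamma * x[k+1] is bitwise equal to x[k] by construction.
            boot = self.w * (self.spec.gamma * self.x[s_next])
        delta = reward + boot - self.w * self.x[s_t]
        self.w += self.alpha_w * self.x[s_t] * delta
        return float(delta)

    def feature_td_step(self, s_t: int, s_next: int) -> float:
        """One feature update (adaptive representation only).

        Not defined for the goal state, whose feature TD error is
        theoretically 0 and whose feature stays frozen at 1.
        """
        if self.rigid:
            raise ValueError("feature update requested on a rigid representation")
        if s_t == self.spec.goal or s_t == self.spec.punishment_state:
            raise ValueError("the goal/punishment feature is not updated")
        delta_f = self.spec.gamma * self.x[s_next] - self.x[s_t]
        self.x[s_t] += self.alpha_feature * delta_f
        return float(delta_f)

    def step(self, s_t, s_next, reward):
        """Combined coefficient + feature step.

        Both TD errors are computed from the same pre-update ``(w, x)``
        snapshot, then both updates are applied, so the outcome does not
        depend on their order.  Returns ``(rpe, feature_rpe_or_None)``.
        """
        delta_f = None
        if (
            not self.rigid
            and s_t != self.spec.goal
            and s_t != self.spec.punishment_state
        ):
            delta_f = float(self.spec.gamma * self.x[s_next] - self.x[s_t])
        delta = self.td_step(s_t, s_next, reward)  # reads x pre-update
        if delta_f is not None:
            self.x[s_t] += self.alpha_feature * delta_f
        return delta, delta_f

    def snapshot(self) -> dict[str, float]:
        snap = {"w": float(self.w)}
        if not self.rigid:
            snap.update(
                {f"x_{k}": float(self.x[k]) for k in range(1, self.spec.n_states + 1)}
            )
        return snap


class GenuineSR:
    """Genuine (full) SR value learner with a fixed feature matrix.

    ``V(S_k) ~ sum_j w_j x_j(S_k)`` with ``x_j(S_k) = gamma^(j-k)`` for
    ``j >= k`` (Non-Resistant SR).  Weights start at the exact
    representation of the Non-Resistant values: ``w_j = 0`` for ``j < n``
    and ``w_n = R``.  All weights are updated on every step, each scaled by
    its feature at the current state.
    """

    def __init__(self, spec: ChainSpec, alpha: float = 0.5):
        if spec.has_punishment:
            raise ValueError("the genuine-SR learner does not model punishment")
        self.spec = spec
        self.alpha = alpha
        self.m = genuine_features(spec)
        self.w = np.zeros(spec.n_states + 1)
        self.w[spec.n_states] = spec.reward_size

    def value(self, state: int) -> float:
        return float(self.m[state] @ self.w)

    def cue_value(self) -> float:
        return self.spec.gamma * self.value(1)

    def td_step(self, s_t: int, s_next: int | None, reward: float) -> float:
        if s_t == self.spec.goal:
            boot = 0.0
        else:
            # (gamma * row) is bitwise the predecessor's row on a Go step,
            # making Non-Resistant transition RPEs exactly 0 at the initial
            # weights.
            boot = float((self.spec.gamma * self.m[s_next]) @ self.w)
        delta = reward + boot - self.value(s_t)
        self.w += self.alpha * self.m[s_t] * delta
        return float(delta)

    def step(self, s_t, s_next, reward):
        return self.td_step(s_t, s_next, reward), None

    def snapshot(self) -> dict[str, float]:
        return {f"w_{j}": float(self.w[j]) for j in range(1, self.spec.n_states + 1)}
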