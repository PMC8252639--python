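"""Dual-system model: action-value learning with a spiraling state-value RPE.

A punctate action-value system maintains Q values for "Go" and "No-Go" at
every pre-goal state and updates the value of the *previously taken* action
with a mixture of two RPEs: its own action RPE (Q-learning or SARSA type)
and the RPE generated by a companion state-value system (the rigid
goal-based reduced SR, or, as a control, the punctate-state TD learner).
The mixing weight ``kappa`` models the influence of the ventral/dorsomedial
("spiraling") striatum-midbrain circuit on the dorsolateral action circuit:

    Q(A_{t-1}, S_{t-1}) += alpha * [(1 - kappa) * delta_action
                                    + kappa * delta_companion]

Conventions: the bootstrap (middle) term of the action RPE is dropped when
the current state is the goal, and the previous-action (last) term is
dropped at the initial time step of an episode, at which no update occurs
(there is no previous action to credit).

Initial action values are the true Non-Resistant values for "Go",
``Q(Go_Sk) = R gamma^(n-1-k)``, and their one-step-discounted counterparts
for "No-Go", ``Q(No-Go_Sk) = R gamma^(n-k)``.
"""

from __future__ import annotations

import numpy as np

from .chain import GO, NO_GO, ChainSpec

__all__ = ["Q_LEARNING", "SARSA", "init_action_values", "DualSystem"]

Q_LEARNING = "q_learning"
SARSA = "sarsa"


def init_action_values(spec: ChainSpec) -> tuple[np.ndarray, np.ndarray]:
    """Initial Go / No-Go action values for states ``S_1 .. S_{n-1}``.

    Returns two arrays of length ``n`` indexed by state (entry 0 unused):
    ``q_go[k] = R gamma^(n-1-k)`` and ``q_no_go[k] = gamma * q_go[k]``,
    built by backward recursion so the Q-learning fixed point is bit-exact.
    """
    n = spec.n_states
    q_go = np.zeros(n)
    q_go[n - 1] = spec.reward_size
    for k in range(n - 2, 0, -1):
        q_go[k] = spec.gamma * q_go[k + 1]
    q_no_go = spec.gamma * q_go
    q_no_go[0] = 0.0
    return q_go, q_no_go


class DualSystem:
    """Two-system learner: punctate Go/No-Go action values driven by a
    mixture of their own RPE and a companion state-value system's RPE.

    Parameters
    ----------
    spec:
        Chain task (punishment not modelled in dual-system runs).
    companion:
        State-value learner supplying the spiraling RPE; any object with
        ``td_step(s_t, s_next, reward)`` and ``cue_value()`` (``ReducedSR``
        in the main model, ``SimpleTD`` in the control).
    kappa:
        Mixing weight of the companion RPE, in [0, 1].
    rpe_type:
        ``"q_learning"`` (off-policy max bootstrap) or ``"sarsa"``
        (on-policy, bootstraps on the action actually chosen).
    alpha:
        Learning rate of the action-value updates (default 0.5).
    """

    def __init__(
        self,
        spec: ChainSpec,
        companion,
        kappa: float = 0.0,
        rpe_type: str = Q_LEARNING,
        alpha: float = 0.5,
    ):
        if spec.has_punishment:
            raise ValueError("dual-system runs do not model punishment")
        if not 0.0 <= kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {kappa}")
        if rpe_type not in (Q_LEARNING, SARSA):
            raise ValueError(f"unknown rpe_type {rpe_type!r}")
        self.spec = spec
        self.companion = companion
        self.kappa = kappa
        self.rpe_type = rpe_type
        self.alpha = alpha
        self.q_go, self.q_no_go = init_action_values(spec)
        self._credit: tuple[int, str] | None = None

    def q(self, action: str, state: int) -> float:
        table = self.q_go if action == GO else self.q_no_go
        return float(table[state])

    @property
    def credit(self) -> tuple[int, str] | None:
        """Previous (state, action) awaiting its update, if any."""
        return self._credit

    def begin_episode(self) -> float:
        """Start an episode: clear the pending credit and return the
        companion's initiation RPE (logged only; no value is updated)."""
        self._credit = None
        return float(self.companion.cue_value())

    def action_rpe(
        self, s_t: int, reward: float, chosen_action: str | None = None
    ) -> float:
        """Type-appropriate action RPE at the current state.

        The bootstrap term is dropped at the goal; the previous-action term
        is dropped when no credit is pending (initial time step).  SARSA
        requires ``chosen_action`` at non-goal states.
        """
        if s_t == self.spec.goal:
            mid = 0.0
        elif self.rpe_type == Q_LEARNING:
            mid = self.spec.gamma * max(self.q_go[s_t], self.q_no_go[s_t])
        else:
            if chosen_action is None:
                raise ValueError("SARSA RPE requires the action chosen at s_t")
            mid = self.spec.gamma * self.q(chosen_action, s_t)
        last = self.q(self._credit[1], self._credit[0]) if self._credit else 0.0
        return float(reward + mid - last)

    def combined_update(self, action_rpe: float, companion_rpe: float) -> None:
        """Apply the mixed update to the pending previous action (no-op when
        no credit is pending)."""
        if self._credit is None:
            return
        s_prev, a_prev = self._credit
        table = self.q_go if a_prev == GO else self.q_no_go
        table[s_prev] += self.alpha * (
            (1.0 - self.kappa) * action_rpe + self.kappa * companion_rpe
        )

    def step(self, s_t: int, s_next: int, chosen_action: str) -> tuple[float, float, float]:
        """One pre-goal time step: companion TD step, action RPE, mixed
        update of the previous action, then credit the chosen action.

        Returns ``(companion_rpe, action_rpe, combined_rpe)``.
        """
        d_comp = self.companion.td_step(s_t, s_next, 0.0)
        d_act = self.action_rpe(s_t, 0.0, chosen_action)
        self.combined_update(d_act, d_comp)
        self._credit = (s_t, chosen_action)
        return d_comp, d_act, self._mix(d_act, d_comp)

    def goal_step(self) -> tuple[float, float, float]:
        """Goal-arrival step: both systems see the reward; the final Go is
        credited with the mixed RPE."""
        goal = self.spec.goal
        d_comp = self.companion.td_step(goal, None, self.spec.reward_size)
        d_act = self.action_rpe(goal, self.spec.reward_size)
        self.combined_update(d_act, d_comp)
        self._credit = None
        return d_comp, d_act, self._mix(d_act, d_comp)

    def _mix(self, d_act: float, d_comp: float) -> float:
        return (1.0 - self.kappa) * d_act + self.kappa * d_comp

    def snapshot(self) -> dict[str, float]:
        snap = {}
        for k in range(1, self.spec.n_states):
            snap[f"q_go_{k}"] = float(self.q_go[k])
            snap[f"q_no_go_{k}"] = float(self.q_no_go[k])
        return snap
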