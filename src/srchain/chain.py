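"""Linear chain task: states, behavior policies, and single-step dynamics.

The task is a chain of states ``S_1 .. S_n`` with a reward of size ``R``
delivered at the goal state ``S_n``.  At every pre-goal state the agent
chooses between "Go" (advance to the next state) and "No-Go" (stay).  Two
exogenously fixed policies are considered: the Non-Resistant policy (always
Go) and the Resistant policy (No-Go with fixed probability ``p_no_go``).
Optionally a punishment state ``S_{n+1}`` follows the goal and delivers a
negative reward, modelling an adverse consequence of reaching the goal.

State indices are 1-based (``S_1`` start, ``S_n`` goal, ``S_{n+1}``
punishment).  Index 0 is reserved for the pre-behavior cue position at which
the initiation event of each episode is logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Action / event labels used in step records.
GO = "go"
NO_GO = "no_go"
INITIATION = "initiation"
GOAL_ARRIVAL = "goal_arrival"
PUNISHMENT_ARRIVAL = "punishment_arrival"

#: Pseudo state index at which the initiation (cue) event is logged.
CUE_POSITION = 0

NON_RESISTANT = "non_resistant"
RESISTANT = "resistant"


@dataclass(frozen=True)
class ChainSpec:
    """Parameters of the chain task.

    Parameters
    ----------
    n_states:
        Number of states from start to goal (``n``), at least 2.
    reward_size:
        Reward ``R`` delivered at the goal state ``S_n`` (positive).
    gamma:
        Temporal discount factor, in (0, 1).
    has_punishment:
        Whether a post-goal punishment state ``S_{n+1}`` exists.
    punishment_size:
        Reward (<= 0) delivered at the punishment state; 0 when absent.
    """

    n_states: int = 10
    reward_size: float = 1.0
    gamma: float = 0.97
    has_punishment: bool = False
    punishment_size: float = 0.0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError(f"n_states must be >= 2, got {self.n_states}")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.reward_size <= 0:
            raise ValueError(f"reward_size must be > 0, got {self.reward_size}")
        if self.punishment_size > 0:
            raise ValueError(
                f"punishment_size must be <= 0, got {self.punishment_size}"
            )
        if not self.has_punishment and self.punishment_size != 0:
            raise ValueError("punishment_size must be 0 when has_punishment is False")

    @property
    def goal(self) -> int:
        """Index of the goal state ``S_n``."""
        return self.n_states

    @property
    def punishment_state(self) -> int | None:
        """Index of the punishment state ``S_{n+1}``, or None if absent."""
        return self.n_states + 1 if self.has_punishment else None

    @property
    def terminal_state(self) -> int:
        """Index of the state at which an episode ends."""
        return self.n_states + 1 if self.has_punishment else self.n_states

    def is_terminal(self, state: int) -> bool:
        return state == self.terminal_state


@dataclass(frozen=True)
class PolicySpec:
    """Behavior policy: Non-Resistant (always Go) or Resistant (No-Go with
    probability ``p_no_go`` at every pre-goal state)."""

    kind: str = NON_RESISTANT
    p_no_go: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (NON_RESISTANT, RESISTANT):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.p_no_go <= 1.0:
            raise ValueError(f"p_no_go must be in [0, 1], got {self.p_no_go}")
        if self.kind == NON_RESISTANT and self.p_no_go != 0.0:
            raise ValueError("non_resistant policy requires p_no_go = 0")

    @classmethod
    def non_resistant(cls) -> "PolicySpec":
        return cls(NON_RESISTANT, 0.0)

    @classmethod
    def resistant(cls, p_no_go: float = 0.75) -> "PolicySpec":
        return cls(RESISTANT, p_no_go)


def sample_action(policy: PolicySpec, rng: np.random.Generator) -> str:
    """Sample Go / No-Go from the fixed behavior policy.

    Consumes exactly one uniform draw from ``rng`` regardless of the policy,
    so that trajectories under different parameterizations of the *learners*
    share random streams (common random numbers).
    """
    return NO_GO if rng.random() < policy.p_no_go else GO


def transition(
    spec: ChainSpec, state: int, action: str | None = None
) -> tuple[int, float, bool]:
    """Single environment step.

    Returns ``(next_state, reward, terminal)`` where ``reward`` is the reward
    obtained at the arrival state: ``reward_size`` on arrival at the goal,
    ``punishment_size`` on arrival at the punishment state, 0 otherwise.

    At the goal state the move to the punishment state (when present) is
    deterministic and ``action`` is ignored.  Raises ``ValueError`` if a step
    is requested from a terminal state.
    """
    if spec.is_terminal(state):
        raise ValueError(f"no action available at terminal state S_{state}")
    if state == spec.goal:
        # Only reachable here when a punishment state exists.
        return spec.goal + 1, spec.punishment_size, True
    if not 1 <= state < spec.goal:
        raise ValueError(f"invalid state index {state}")
    if action == GO:
        nxt = state + 1
        reward = spec.reward_size if nxt == spec.goal else 0.0
        return nxt, reward, spec.is_terminal(nxt)
    if action == NO_GO:
        return state, 0.0, False
    raise ValueError(f"invalid action {action!r} at state S_{state}")
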