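"""Multi-episode, multi-simulation experiments and their aggregation.

``run_simulation`` executes a configured run (one learner architecture, or
the dual system) for ``n_sims`` independent simulations of ``episodes``
episodes each, logging every event (initiation, Go, No-Go, goal arrival,
punishment arrival) with its RPE(s), plus end-of-episode learner-parameter
snapshots.

``aggregate`` applies the across-simulation summary conventions: within a
simulation, the possibly repeated No-Go RPEs at a state within an episode
are first averaged (and, separately, summed); simulations without any
No-Go at that (episode, state) cell are excluded from that cell's
statistics; Go / initiation / goal statistics use all simulations.  Means
and sample standard deviations are then taken across simulations.

``run_scenario`` provides presets reproducing the study's figure-backing
tables (``fig2a`` .. ``fig9``); see ``list_scenarios``.

Each simulation uses its own random stream seeded ``base_seed + sim_id``,
so runs are reproducible and individual simulations independent.  Presets
that compare conditions reuse the same base seed across conditions; since
action choice never depends on learned values, the sampled trajectories
are then identical across conditions (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import (
    CUE_POSITION,
    GO,
    GOAL_ARRIVAL,
    INITIATION,
    NO_GO,
    PUNISHMENT_ARRIVAL,
    ChainSpec,
    PolicySpec,
    sample_action,
)
from .dual import Q_LEARNING, SARSA, DualSystem
from .learners import GenuineSR, ReducedSR, SimpleTD

__all__ = [
    "RunConfig",
    "DualConfig",
    "SimulationResult",
    "ScenarioResult",
    "StepCapExceeded",
    "run_simulation",
    "aggregate",
    "run_scenario",
    "list_scenarios",
]

PUNCTATE = "punctate"
REDUCED_SR = "reduced_sr"
REDUCED_SR_ADAPTIVE = "reduced_sr_adaptive"
GENUINE_SR = "genuine_sr"
DUAL = "dual"

LEARNERS = (PUNCTATE, REDUCED_SR, REDUCED_SR_ADAPTIVE, GENUINE_SR, DUAL)


class StepCapExceeded(RuntimeError):
    """An episode exceeded the configured safety cap on time steps."""


@dataclass(frozen=True)
class DualConfig:
    """Dual-system parameters: mixing weight, action-RPE type, and which
    state-value system supplies the spiraling RPE."""

    kappa: float = 0.0
    rpe_type: str = Q_LEARNING
    companion: str = REDUCED_SR
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.rpe_type not in (Q_LEARNING, SARSA):
            raise ValueError(f"unknown rpe_type {self.rpe_type!r}")
        if self.companion not in (REDUCED_SR, PUNCTATE):
            raise ValueError(f"unknown companion {self.companion!r}")


@dataclass(frozen=True)
class RunConfig:
    """Full specification of a simulation run."""

    chain: ChainSpec = field(default_factory=ChainSpec)
    policy: PolicySpec = field(default_factory=PolicySpec)
    learner: str = PUNCTATE
    alpha: float = 0.5
    alpha_feature: float = 0.05
    init: str = "nonresistant"  # "zeros" or "nonresistant"
    episodes: int = 25
    n_sims: int = 100
    base_seed: int = 0
    dual: DualConfig | None = None
    step_cap: int = 10**6

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.learner == DUAL and self.dual is None:
            object.__setattr__(self, "dual", DualConfig())
        if self.learner != DUAL and self.dual is not None:
            raise ValueError("dual parameters given for a non-dual learner")
        if self.episodes < 1 or self.n_sims < 1:
            raise ValueError("episodes and n_sims must be >= 1")
        if self.init not in ("zeros", "nonresistant"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class SimulationResult:
    """Per-step event log and end-of-episode parameter snapshots."""

    steps: pd.DataFrame
    params: pd.DataFrame
    config: RunConfig


@dataclass
class ScenarioResult:
    """Output of a scenario preset: the figure-backing summary table,
    auxiliary series, and the raw step log."""

    name: str
    summary: pd.DataFrame
    aux: dict[str, pd.DataFrame]
    steps: pd.DataFrame


# ---------------------------------------------------------------------------
# Running simulations


def _make_systems(cfg: RunConfig):
    """Build (learner, dual_or_None) for one simulation."""
    spec = cfg.chain
    if cfg.learner == PUNCTATE:
        return SimpleTD(spec, alpha=cfg.alpha, init=cfg.init), None
    if cfg.learner == REDUCED_SR:
        return ReducedSR(spec, alpha_w=cfg.alpha), None
    if cfg.learner == REDUCED_SR_ADAPTIVE:
        return ReducedSR(spec, alpha_w=cfg.alpha, alpha_feature=cfg.alpha_feature), None
    if cfg.learner == GENUINE_SR:
        return GenuineSR(spec, alpha=cfg.alpha), None
    dc = cfg.dual
    if dc.companion == REDUCED_SR:
        companion = ReducedSR(spec, alpha_w=cfg.alpha)
    else:
        companion = SimpleTD(spec, alpha=cfg.alpha, init="nonresistant")
    dual = DualSystem(
        spec, companion, kappa=dc.kappa, rpe_type=dc.rpe_type, alpha=dc.alpha
    )
    return companion, dual


def _run_single_episode(cfg, learner, dual, rng, sim_id, episode, cols):
    spec, policy = cfg.chain, cfg.policy
    is_dual = dual is not None

    def log(t, state, action, *rpes):
        cols["sim_id"].append(sim_id)
        cols["episode"].append(episode)
        cols["t"].append(t)
        cols["state"].append(state)
        cols["action"].append(action)
        if is_dual:
            cols["rpe_state"].append(rpes[0])
            cols["rpe_action"].append(rpes[1])
            cols["rpe_combined"].append(rpes[2])
        else:
            cols["rpe"].append(rpes[0])
            if "rpe_feature" in cols:
                cols["rpe_feature"].append(rpes[1] if len(rpes) > 1 else np.nan)

    t = 0
    if is_dual:
        log(t, CUE_POSITION, INITIATION, dual.begin_episode(), np.nan, np.nan)
    else:
        log(t, CUE_POSITION, INITIATION, learner.cue_value())

    s = 1
    n_steps = 0
    while s < spec.goal:
        action = sample_action(policy, rng)
        s_next = s + 1 if action == GO else s
        t += 1
        n_steps += 1
        if n_steps > cfg.step_cap:
            raise StepCapExceeded(
                f"episode {episode} of simulation {sim_id} exceeded "
                f"{cfg.step_cap} steps"
            )
        if is_dual:
            log(t, s, action, *dual.step(s, s_next, action))
        else:
            delta, delta_f = learner.step(s, s_next, 0.0)
            log(t, s, action, delta, delta_f)
        s = s_next

    t += 1
    if is_dual:
        log(t, spec.goal, GOAL_ARRIVAL, *dual.goal_step())
    else:
        delta, delta_f = learner.step(
            spec.goal, spec.punishment_state, spec.reward_size
        )
        log(t, spec.goal, GOAL_ARRIVAL, delta, delta_f)
        if spec.has_punishment:
            t += 1
            delta, delta_f = learner.step(
                spec.punishment_state, None, spec.punishment_size
            )
            log(t, spec.punishment_state, PUNISHMENT_ARRIVAL, delta, delta_f)


def run_simulation(cfg: RunConfig) -> SimulationResult:
    """Run ``cfg.n_sims`` simulations of ``cfg.episodes`` episodes each.

    Returns the complete per-step log (one row per event) and a long-format
    table of end-of-episode learner parameters (episode 0 holds the initial
    values).
    """
    is_dual = cfg.learner == DUAL
    adaptive = cfg.learner == REDUCED_SR_ADAPTIVE
    cols: dict[str, list] = {
        k: [] for k in ("sim_id", "episode", "t", "state", "action")
    }
    if is_dual:
        cols.update(rpe_state=[], rpe_action=[], rpe_combined=[])
    else:
        cols["rpe"] = []
        if adaptive:
            cols["rpe_feature"] = []

    p_sim, p_ep, p_name, p_val = [], [], [], []

    def snap(system, sim_id, episode):
        for name, value in system.snapshot().items():
            p_sim.append(sim_id)
            p_ep.append(episode)
            p_name.append(name)
            p_val.append(value)

    for sim_id in range(cfg.n_sims):
        rng = np.random.default_rng(cfg.base_seed + sim_id)
        learner, dual = _make_systems(cfg)
        system = dual if is_dual else learner
        snap(system, sim_id, 0)
        for episode in range(1, cfg.episodes + 1):
            _run_single_episode(cfg, learner, dual, rng, sim_id, episode, cols)
            snap(system, sim_id, episode)

    steps = pd.DataFrame(cols)
    params = pd.DataFrame(
        {"sim_id": p_sim, "episode": p_ep, "name": p_name, "value": p_val}
    )
    return SimulationResult(steps=steps, params=params, config=cfg)


# ---------------------------------------------------------------------------
# Aggregation

_EVENT_NAMES = {
    INITIATION: "initiation",
    GO: "go",
    GOAL_ARRIVAL: "goal",
    PUNISHMENT_ARRIVAL: "punishment",
}


def aggregate(steps: pd.DataFrame, value_col: str | None = None) -> pd.DataFrame:
    """Across-simulation mean / sample-SD summary of per-step RPEs.

    One row per (episode, state, event) with columns ``mean``, ``sd`` and
    ``n_included``.  Events: ``initiation``, ``go``, ``goal``,
    ``punishment`` (at most one occurrence per simulation-episode; all
    simulations included) and ``no_go_mean`` / ``no_go_sum`` (repeated
    No-Go RPEs at a state are first averaged / summed within each
    simulation-episode; simulations with no No-Go at that cell are
    excluded, so ``n_included`` varies by cell).  ``sd`` is NaN when fewer
    than two simulations are included.
    """
    if value_col is None:
        value_col = "rpe" if "rpe" in steps.columns else "rpe_state"

    out = []

    once = steps[steps["action"] != NO_GO]
    if len(once):
        g = once.groupby(["episode", "state", "action"])[value_col]
        stats = g.agg(mean="mean", sd="std", n_included="size").reset_index()
        stats["event"] = stats["action"].map(_EVENT_NAMES)
        out.append(stats.drop(columns="action"))

    nogo = steps[steps["action"] == NO_GO]
    if len(nogo):
        per_sim = (
            nogo.groupby(["episode", "state", "sim_id"])[value_col]
            .agg(["mean", "sum"])
            .reset_index()
        )
        for kind in ("mean", "sum"):
            g = per_sim.groupby(["episode", "state"])[kind]
            stats = g.agg(mean="mean", sd="std", n_included="size").reset_index()
            stats["event"] = f"no_go_{kind}"
            out.append(stats)

    table = pd.concat(out, ignore_index=True)
    table["n_included"] = table["n_included"].astype(int)
    table = table[["episode", "state", "event", "mean", "sd", "n_included"]]
    return table.sort_values(["episode", "state", "event"], ignore_index=True)


def _param_stats(params: pd.DataFrame) -> pd.DataFrame:
    """Across-simulation mean/SD of parameter snapshots per episode."""
    g = params.groupby(["episode", "name"])["value"]
    return g.agg(mean="mean", sd="std", n_included="size").reset_index()


# ---------------------------------------------------------------------------
# Scenario presets

_P_NO_GO_GRID = (0.5, 0.75, 0.9)
_KAPPA_GRID = (0.0, 0.2, 0.4)
_DUAL_WINDOW = (41, 60)


def _scenario_fig2a(base_seed, n_sims, episodes):
    cfg = RunConfig(
        chain=ChainSpec(),
        policy=PolicySpec.non_resistant(),
        learner=PUNCTATE,
        init="zeros",
        episodes=episodes or 30,
        n_sims=n_sims or 1,
        base_seed=base_seed,
    )
    res = run_simulation(cfg)
    return ScenarioResult("fig2a", aggregate(res.steps), {}, res.steps)


def _scenario_fig2bcd(base_seed, n_sims, episodes):
    cfg = RunConfig(
        chain=ChainSpec(),
        policy=PolicySpec.resistant(0.75),
        learner=PUNCTATE,
        init="nonresistant",
        episodes=episodes or 60,
        n_sims=n_sims or 100,
        base_seed=base_seed,
    )
    res = run_simulation(cfg)
    return ScenarioResult("fig2bcd", aggregate(res.steps), {}, res.steps)


def _scenario_fig3(base_seed, n_sims, episodes):
    cfg = RunConfig(
        chain=ChainSpec(),
        policy=PolicySpec.resistant(0.75),
        learner=REDUCED_SR,
        episodes=episodes or 60,
        n_sims=n_sims or 100,
        base_seed=base_seed,
    )
    res = run_simulation(cfg)
    w_traj = _param_stats(res.params[res.params["name"] == "w"])
    return ScenarioResult(
        "fig3", aggregate(res.steps), {"w_trajectory": w_traj}, res.steps
    )


def _scenario_fig4a(base_seed, n_sims, episodes):
    episodes = episodes or 25
    rows = []
    all_steps = []
    for learner in (PUNCTATE, REDUCED_SR):
        baseline, _ = _make_systems(
            RunConfig(learner=learner, policy=PolicySpec.non_resistant(), dual=None)
        )
        rows.append(
            {
                "learner": learner,
                "p_no_go": 0.0,
                "episode": 0,
                "cue_mean": baseline.cue_value(),
                "cue_sd": 0.0,
                "n_included": 1,
            }
        )
        for p in _P_NO_GO_GRID:
            cfg = RunConfig(
                chain=ChainSpec(),
                policy=PolicySpec.resistant(p),
                learner=learner,
                init="nonresistant",
                episodes=episodes,
                n_sims=n_sims or 100,
                base_seed=base_seed,
            )
            res = run_simulation(cfg)
            init = res.steps[
                (res.steps["action"] == INITIATION)
                & (res.steps["episode"] == episodes)
            ]["rpe"]
            rows.append(
                {
                    "learner": learner,
                    "p_no_go": p,
                    "episode": episodes,
                    "cue_mean": init.mean(),
                    "cue_sd": init.std(),
                    "n_included": len(init),
                }
            )
            steps = res.steps.copy()
            steps["learner"] = learner
            steps["p_no_go"] = p
            all_steps.append(steps)
    return ScenarioResult(
        "fig4a", pd.DataFrame(rows), {}, pd.concat(all_steps, ignore_index=True)
    )


def _scenario_fig4b(base_seed, n_sims, episodes):
    episodes = episodes or 25
    chain = ChainSpec(has_punishment=True, punishment_size=-2.0)
    rows = []
    all_steps = []
    aux = []
    for learner in (PUNCTATE, REDUCED_SR):
        cfg = RunConfig(
            chain=chain,
            policy=PolicySpec.non_resistant(),
            learner=learner,
            init="nonresistant",
            episodes=episodes,
            n_sims=n_sims or 1,
            base_seed=base_seed,
        )
        res = run_simulation(cfg)
        init = res.steps[res.steps["action"] == INITIATION]
        cue = init[init["episode"] == episodes]["rpe"]
        rows.append(
            {
                "learner": learner,
                "episode": episodes,
                "cue_mean": cue.mean(),
                "cue_sd": cue.std(),
                "n_included": len(cue),
            }
        )
        traj = (
            init.groupby("episode")["rpe"]
            .mean()
            .reset_index()
            .rename(columns={"rpe": "cue_mean"})
        )
        traj["learner"] = learner
        aux.append(traj)
        steps = res.steps.copy()
        steps["learner"] = learner
        all_steps.append(steps)
    return ScenarioResult(
        "fig4b",
        pd.DataFrame(rows),
        {"cue_trajectory": pd.concat(aux, ignore_index=True)},
        pd.concat(all_steps, ignore_index=True),
    )


def _scenario_fig5(base_seed, n_sims, episodes):
    episodes = episodes or 200
    cfg = RunConfig(
        chain=ChainSpec(),
        policy=PolicySpec.resistant(0.75),
        learner=REDUCED_SR_ADAPTIVE,
        episodes=episodes,
        n_sims=n_sims or 100,
        base_seed=base_seed,
    )
    res = run_simulation(cfg)
    feats = res.params[res.params["name"].str.startswith("x_")].copy()
    snapshots = [ep for ep in (0, 50, 100, 200) if ep <= episodes]
    feats = feats[feats["episode"].isin(snapshots)]
    feats["state"] = feats["name"].str.removeprefix("x_").astype(int)
    feat_stats = (
        feats.groupby(["episode", "state"])["value"]
        .agg(x_mean="mean", x_sd="std")
        .reset_index()
    )
    return ScenarioResult(
        "fig5", aggregate(res.steps), {"features": feat_stats}, res.steps
    )


def _scenario_fig6(base_seed, n_sims, episodes):
    cfg = RunConfig(
        chain=ChainSpec(),
        policy=PolicySpec.resistant(0.75),
        learner=GENUINE_SR,
        episodes=episodes or 25,
        n_sims=n_sims or 100,
        base_seed=base_seed,
    )
    res = run_simulation(cfg)
    w = res.params.copy()
    w["j"] = w["name"].str.removeprefix("w_").astype(int)
    w_traj = (
        w.groupby(["episode", "j"])["value"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    return ScenarioResult(
        "fig6", aggregate(res.steps), {"w_trajectory": w_traj}, res.steps
    )


def _scenario_dual(name, companion, base_seed, n_sims, episodes):
    episodes = episodes or 60
    hi = min(_DUAL_WINDOW[1], episodes)
    lo = min(_DUAL_WINDOW[0], max(1, hi - 19))
    rows = []
    traj = []
    all_steps = []
    for rpe_type in (Q_LEARNING, SARSA):
        for kappa in _KAPPA_GRID:
            cfg = RunConfig(
                chain=ChainSpec(),
                policy=PolicySpec.resistant(0.75),
                learner=DUAL,
                episodes=episodes,
                n_sims=n_sims or 100,
                base_seed=base_seed,
                dual=DualConfig(kappa=kappa, rpe_type=rpe_type, companion=companion),
            )
            res = run_simulation(cfg)
            q = res.params[
                (res.params["episode"] >= lo) & (res.params["episode"] <= hi)
            ].copy()
            q["action"] = np.where(
                q["name"].str.startswith("q_no_go"), NO_GO, GO
            )
            q["state"] = q["name"].str.extract(r"(\d+)$").astype(int)
            # mean over the episode window within each simulation first
            per_sim = (
                q.groupby(["sim_id", "state", "action"])["value"]
                .mean()
                .unstack("action")
                .reset_index()
            )
            per_sim["diff"] = per_sim[GO] - per_sim[NO_GO]
            stats = (
                per_sim.groupby("state")
                .agg(
                    q_go_mean=(GO, "mean"),
                    q_go_sd=(GO, "std"),
                    q_no_go_mean=(NO_GO, "mean"),
                    q_no_go_sd=(NO_GO, "std"),
                    diff_mean=("diff", "mean"),
                    diff_sd=("diff", "std"),
                )
                .reset_index()
            )
            stats.insert(0, "kappa", kappa)
            stats.insert(0, "rpe_type", rpe_type)
            rows.append(stats)

            ep_means = _param_stats(res.params)
            ep_means.insert(0, "kappa", kappa)
            ep_means.insert(0, "rpe_type", rpe_type)
            traj.append(ep_means)

            steps = res.steps.copy()
            steps["rpe_type"] = rpe_type
            steps["kappa"] = kappa
            all_steps.append(steps)
    return ScenarioResult(
        name,
        pd.concat(rows, ignore_index=True),
        {"q_trajectory": pd.concat(traj, ignore_index=True)},
        pd.concat(all_steps, ignore_index=True),
    )


_SCENARIOS = {
    "fig2a": _scenario_fig2a,
    "fig2bcd": _scenario_fig2bcd,
    "fig3": _scenario_fig3,
    "fig4a": _scenario_fig4a,
    "fig4b": _scenario_fig4b,
    "fig5": _scenario_fig5,
    "fig6": _scenario_fig6,
    "fig8": lambda s, n, e: _scenario_dual("fig8", REDUCED_SR, s, n, e),
    "fig9": lambda s, n, e: _scenario_dual("fig9", PUNCTATE, s, n, e),
}


def list_scenarios() -> list[str]:
    """Names of the available scenario presets."""
    return sorted(_SCENARIOS)


def run_scenario(
    name: str,
    base_seed: int = 0,
    n_sims: int | None = None,
    episodes: int | None = None,
) -> ScenarioResult:
    """Run a named scenario preset.

    ``n_sims`` and ``episodes`` override the preset defaults (the defaults
    follow the figures each preset backs: 30 episodes for the naive
    Non-Resistant run, 25 for single-episode statistics, 60 for over-episode
    curves and the dual system, 200 for the adaptive representation).
    Deterministic given ``base_seed``.
    """
    try:
        builder = _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        ) from None
    return builder(base_seed, n_sims, episodes)
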