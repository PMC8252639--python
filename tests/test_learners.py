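"""Value learners: features, TD steps, cue values, and their invariants.

Expected numbers are frozen from the closed-form arithmetic of each update
rule (the oracle is the stated formula evaluated directly).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srchain import (
    ChainSpec,
    GenuineSR,
    INITIATION,
    PolicySpec,
    ReducedSR,
    RunConfig,
    SimpleTD,
    genuine_features,
    reduced_features,
    run_simulation,
    true_values_nonresistant,
)

GAMMA = 0.97


# ---------------------------------------------------------------------------
# Features and true values


@pytest.mark.parametrize(
    "gamma,ratio", [(0.97, 0.76), (0.95, 0.63), (0.99, 0.91)]
)
def test_start_to_goal_value_ratio(gamma, ratio):
    """V(S_1)/V(S_n) = gamma^(n-1) for the Non-Resistant values."""
    v = true_values_nonresistant(ChainSpec(gamma=gamma))
    assert v[10] == 1.0
    assert round(v[1] / v[10], 2) == ratio
    np.testing.assert_allclose(v[1:], [gamma ** (10 - k) for k in range(1, 11)])


def test_reduced_features_are_goal_discounts(spec, punished_spec):
    x = reduced_features(spec)
    assert x[10] == 1.0
    assert x[1] == pytest.approx(GAMMA**9, rel=1e-12)
    assert (np.diff(x[1:]) > 0).all()  # strictly increasing towards the goal
    xp = reduced_features(punished_spec)
    assert xp[11] == 0.0  # post-goal state never preceded the goal


def test_genuine_features_matrix(spec):
    m = genuine_features(spec)
    for k in range(1, 11):
        assert m[k, k] == 1.0
    assert m[2, 1] == 0.0  # no future occupancy of predecessors
    assert m[1, 10] == pytest.approx(GAMMA**9, rel=1e-12)
    # row k of the matrix is the SR of S_k: gamma^(j-k) for j >= k
    for k in range(1, 11):
        np.testing.assert_allclose(
            m[k, k:11], [GAMMA ** (j - k) for j in range(k, 11)], rtol=1e-12
        )


# ---------------------------------------------------------------------------
# Punctate-state TD


def test_simple_td_no_rpe_at_equilibrium(spec):
    """From the Non-Resistant values, a Go step generates exactly no RPE."""
    learner = SimpleTD(spec, init="nonresistant")
    for k in range(1, 10):
        assert learner.td_step(k, k + 1, 0.0) == 0.0


def test_simple_td_no_go_step_arithmetic(spec):
    """No-Go at S_1 from equilibrium: delta = (gamma-1) gamma^9 and the
    value moves half-way (alpha = 0.5)."""
    learner = SimpleTD(spec, init="nonresistant")
    v1 = GAMMA**9
    delta = learner.td_step(1, 1, 0.0)
    assert delta == pytest.approx((GAMMA - 1) * v1, rel=1e-12)
    assert learner.value(1) == pytest.approx(v1 + 0.5 * delta, rel=1e-12)


def test_simple_td_goal_arrival_from_zero_values(spec):
    """Naive values: the first goal arrival generates delta = R."""
    learner = SimpleTD(spec, init="zeros")
    assert learner.td_step(10, None, 1.0) == 1.0
    assert learner.value(10) == 0.5


def test_simple_td_cue_value(spec):
    assert SimpleTD(spec, init="zeros").cue_value() == 0.0
    learner = SimpleTD(spec, init="nonresistant")
    assert learner.cue_value() == pytest.approx(GAMMA**10, rel=1e-12)
    # the initiation RPE is logged only: no value changes
    v_before = learner.v.copy()
    learner.cue_value()
    assert (learner.v == v_before).all()


def test_simple_td_goal_value_is_a_fixed_point(resistant):
    """Under the Resistant policy from the learned values, V(S_n) = R never
    changes, so the goal RPE is exactly 0 in every episode."""
    cfg = RunConfig(
        policy=resistant,
        learner="punctate",
        init="nonresistant",
        episodes=10,
        n_sims=5,
        base_seed=3,
    )
    steps = run_simulation(cfg).steps
    goal = steps[steps["action"] == "goal_arrival"]["rpe"]
    assert (goal == 0.0).all()


def test_simple_td_nonresistant_convergence_closed_form(spec):
    """From zero values, the goal RPE in episode m is R(1-alpha)^(m-1) and
    the initiation RPE approaches gamma^n."""
    cfg = RunConfig(
        chain=spec,
        policy=PolicySpec.non_resistant(),
        learner="punctate",
        init="zeros",
        episodes=200,
        n_sims=1,
    )
    steps = run_simulation(cfg).steps
    goal = steps[steps["action"] == "goal_arrival"].set_index("episode")["rpe"]
    for m in range(1, 31):
        assert goal[m] == pytest.approx(0.5 ** (m - 1), rel=1e-12)
    init = steps[steps["action"] == INITIATION].set_index("episode")["rpe"]
    assert (init.diff().dropna() >= 0).all()  # cue value grows monotonically
    assert init[200] == pytest.approx(GAMMA**10, rel=1e-6)


# ---------------------------------------------------------------------------
# Rigid reduced SR


@settings(derandomize=True, max_examples=50)
@given(w=st.floats(-5, 5, allow_nan=False))
def test_reduced_sr_go_step_generates_no_rpe_for_any_w(w):
    """gamma x(S_{k+1}) = x(S_k), so Go-step RPEs vanish identically in w
    (here: bit-exactly, by construction of the feature ladder)."""
    learner = ReducedSR(ChainSpec(), w0=w)
    for k in range(1, 10):
        assert learner.td_step(k, k + 1, 0.0) == 0.0
    assert learner.w == w


def test_reduced_sr_no_go_step_arithmetic(spec):
    learner = ReducedSR(spec)  # w = R = 1
    x1 = GAMMA**9
    delta = learner.td_step(1, 1, 0.0)
    assert delta == pytest.approx((GAMMA - 1) * x1, rel=1e-12)
    assert learner.w == pytest.approx(1 + 0.5 * x1 * delta, rel=1e-12)


def test_reduced_sr_goal_arrival_arithmetic(spec):
    """Goal arrival with w = 0.6: delta = R - w = 0.4 and w moves to 0.8."""
    learner = ReducedSR(spec, w0=0.6)
    delta = learner.td_step(10, None, 1.0)
    assert delta == pytest.approx(0.4, rel=1e-12)
    assert learner.w == pytest.approx(0.8, rel=1e-12)


def test_reduced_sr_punishment_does_not_update_w(punished_spec):
    """The punishment state's feature is 0, so its large negative RPE
    leaves the coefficient bit-identical."""
    learner = ReducedSR(punished_spec)
    w_before = learner.w
    delta = learner.td_step(11, None, -2.0)
    assert delta == -2.0
    assert learner.w == w_before


def test_reduced_sr_cue_value(spec):
    assert ReducedSR(spec).cue_value() == pytest.approx(GAMMA**10, rel=1e-12)
    assert ReducedSR(spec, w0=0.5).cue_value() == pytest.approx(
        0.5 * GAMMA**10, rel=1e-12
    )


# ---------------------------------------------------------------------------
# Adaptive (slowly updated) reduced SR


def test_feature_td_step_arithmetic(spec):
    learner = ReducedSR(spec, alpha_feature=0.05)
    # Go into the goal: delta_feature = gamma * 1 - gamma = 0
    assert learner.feature_td_step(9, 10) == 0.0
    # No-Go at S_1: delta_feature = (gamma - 1) x(S_1), feature nudged
    x1 = GAMMA**9
    delta_f = learner.feature_td_step(1, 1)
    assert delta_f == pytest.approx((GAMMA - 1) * x1, rel=1e-12)
    assert learner.x[1] == pytest.approx(x1 + 0.05 * delta_f, rel=1e-12)


def test_feature_update_refuses_rigid_and_goal(spec):
    with pytest.raises(ValueError):
        ReducedSR(spec).feature_td_step(1, 1)
    with pytest.raises(ValueError):
        ReducedSR(spec, alpha_feature=0.05).feature_td_step(10, 10)


def test_goal_feature_frozen_during_learning(resistant):
    """x(S_n) stays exactly 1 throughout an adaptive run."""
    cfg = RunConfig(
        policy=resistant,
        learner="reduced_sr_adaptive",
        episodes=20,
        n_sims=3,
        base_seed=11,
    )
    params = run_simulation(cfg).params
    x10 = params[params["name"] == "x_10"]["value"]
    assert (x10 == 1.0).all()


def test_adaptive_step_uses_one_snapshot(spec):
    """Both TD errors come from the same pre-update (w, x); applying the
    combined step equals computing both errors first, then updating."""
    learner = ReducedSR(spec, alpha_feature=0.05, w0=0.9)
    w0, x0 = learner.w, learner.x.copy()
    delta, delta_f = learner.step(3, 3, 0.0)  # No-Go at S_3
    exp_delta = GAMMA * w0 * x0[3] - w0 * x0[3]
    exp_delta_f = GAMMA * x0[3] - x0[3]
    assert delta == pytest.approx(exp_delta, rel=1e-12)
    assert delta_f == pytest.approx(exp_delta_f, rel=1e-12)
    assert learner.w == pytest.approx(w0 + 0.5 * x0[3] * exp_delta, rel=1e-12)
    assert learner.x[3] == pytest.approx(x0[3] + 0.05 * exp_delta_f, rel=1e-12)


def test_adaptive_features_shrink_under_resistance(resistant):
    """Discounted goal occupancies fall once goal-reaching slows down."""
    cfg = RunConfig(
        policy=resistant,
        learner="reduced_sr_adaptive",
        episodes=50,
        n_sims=10,
        base_seed=5,
    )
    params = run_simulation(cfg).params
    x1 = params[params["name"] == "x_1"]
    first = x1[x1["episode"] == 0]["value"].mean()
    last = x1[x1["episode"] == 50]["value"].mean()
    assert last < first


# ---------------------------------------------------------------------------
# Genuine SR


def test_genuine_sr_exact_at_initial_weights(spec):
    """With w_j = 0 (j<n), w_n = R, every Non-Resistant transition has
    exactly zero RPE, including goal arrival."""
    learner = GenuineSR(spec)
    for k in range(1, 10):
        assert learner.td_step(k, k + 1, 0.0) == 0.0
    assert learner.td_step(10, None, 1.0) == 0.0


def test_genuine_sr_no_go_arithmetic(spec):
    """No-Go at S_9 from the initial weights: only the goal feature
    contributes, delta = (gamma - 1) gamma."""
    learner = GenuineSR(spec)
    delta = learner.td_step(9, 9, 0.0)
    assert delta == pytest.approx((GAMMA - 1) * GAMMA, rel=1e-12)


def test_genuine_sr_updates_all_weights_scaled_by_features(spec):
    learner = GenuineSR(spec)
    m = learner.m.copy()
    delta = learner.td_step(9, 9, 0.0)
    # w_j += alpha * x_j(S_9) * delta; x_j(S_9) nonzero only for j in {9, 10}
    assert learner.w[9] == pytest.approx(0.5 * m[9, 9] * delta, rel=1e-12)
    assert learner.w[10] == pytest.approx(1 + 0.5 * m[9, 10] * delta, rel=1e-12)
    assert (learner.w[1:9] == 0.0).all()


def test_genuine_sr_cue_value(spec):
    assert GenuineSR(spec).cue_value() == pytest.approx(GAMMA**10, rel=1e-12)


def test_genuine_sr_rejects_punishment(punished_spec):
    with pytest.raises(ValueError):
        GenuineSR(punished_spec)


# ---------------------------------------------------------------------------
# Representation exactness across task parameterizations


@pytest.mark.parametrize("n", [2, 5, 10, 20])
@pytest.mark.parametrize("gamma", [0.9, 0.95, 0.97, 0.99])
def test_linear_representations_are_exact(n, gamma):
    """Both the reduced SR with w = R and the genuine SR at its initial
    weights represent the Non-Resistant values to machine precision."""
    spec = ChainSpec(n_states=n, gamma=gamma)
    v = true_values_nonresistant(spec)
    reduced = ReducedSR(spec)
    genuine = GenuineSR(spec)
    for k in range(1, n + 1):
        assert reduced.value(k) == pytest.approx(v[k], rel=1e-14)
        assert genuine.value(k) == pytest.approx(v[k], rel=1e-14)


# ---------------------------------------------------------------------------
# Punishment: insensitivity of the reduced SR vs devaluation in simple TD


def _punished_fixed_point(spec):
    """Independent oracle: value iteration on the punished chain."""
    n = spec.n_states
    v = np.zeros(n + 2)
    for _ in range(5000):
        new = v.copy()
        for k in range(1, n):
            new[k] = spec.gamma * v[k + 1]
        new[n] = spec.reward_size + spec.gamma * v[n + 1]
        new[n + 1] = spec.punishment_size
        v = new
    return v


def test_punishment_invariance_and_devaluation(punished_spec):
    """Reduced-SR w and cue value are bit-identical across punished
    episodes; the punctate cue value is non-increasing and converges to the
    value-iteration fixed point gamma^n (R + gamma * punishment)."""
    base = dict(
        chain=punished_spec,
        policy=PolicySpec.non_resistant(),
        init="nonresistant",
        episodes=300,
        n_sims=1,
    )
    red = run_simulation(RunConfig(learner="reduced_sr", **base))
    w = red.params[red.params["name"] == "w"]["value"]
    assert (w == w.iloc[0]).all()
    cues = red.steps[red.steps["action"] == INITIATION]["rpe"]
    assert (cues == cues.iloc[0]).all()

    pun = run_simulation(RunConfig(learner="punctate", **base))
    cues = pun.steps[pun.steps["action"] == INITIATION]["rpe"].to_numpy()
    assert (np.diff(cues) <= 1e-15).all()
    v_star = _punished_fixed_point(punished_spec)
    limit = punished_spec.gamma * v_star[1]
    assert limit == pytest.approx(
        punished_spec.gamma**10 * (1.0 + punished_spec.gamma * -2.0), rel=1e-9
    )
    assert cues[-1] == pytest.approx(limit, abs=1e-4)
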