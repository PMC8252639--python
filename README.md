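# srchain

A reinforcement-learning simulator of habitual reward-seeking on a linear
chain of states, built to study how the brain's *state representation*
shapes dopamine-like reward prediction errors (RPEs) — and in particular
how a **rigid, goal-based reduced successor representation (SR)** can
reproduce hallmarks of addiction (sustained RPE at a fully predicted
reward, weak devaluation of the triggering cue under resistance,
insensitivity to punishment) without any drug-induced perturbation of the
dopamine system itself.

The intended audience is computational-neuroscience / computational-
psychiatry researchers who want reproducible, tabular RPE and value
trajectories for these models rather than hand-rolled scripts.

## The task and the models

An agent traverses states `S_1 … S_n` (default `n = 10`); a reward `R = 1`
is delivered at the goal `S_n`, and values are discounted by `γ` per step
(default 0.97). At each pre-goal state the agent takes **Go** (advance) or
**No-Go** (stay). Behavior is fixed exogenously: the *Non-Resistant*
policy always goes; the *Resistant* policy (attempted cessation) takes
No-Go with probability `P_No-Go` (default 0.75). Under Non-Resistant
behavior the true values are

    V(S_k) = R γ^(n−k),

so the start state is worth `γ^9 ≈ 0.76` of the goal at `γ = 0.97`.
Four value-learning architectures are implemented, all TD(0) with
learning rate `α = 0.5`:

| learner | representation | update |
|---|---|---|
| `punctate` | one value per state | `V(S_t) += α δ` |
| `reduced_sr` | scalar feature `x(S_k) = γ^(n−k)` (discounted future goal occupancy), `V ≈ w·x`, **features frozen** | `w += α x(S_t) δ` |
| `reduced_sr_adaptive` | as above, features also learned slowly (`α_feature = 0.05`, goal feature frozen at 1) | both updates |
| `genuine_sr` | full SR `x_j(S_k) = γ^(j−k)` for `j ≥ k`, `V ≈ Σ_j w_j x_j` | `w_j += α x_j(S_t) δ` |

The RPE generated upon initiation of behavior, `γ·V(S_1)`, is the learned
value of the cue that triggers the sequence. An optional punishment state
`S_{n+1}` after the goal delivers a negative reward (default −2); its
reduced-SR feature is 0, so punishment RPEs never update `w` — the
addicted model is punishment-insensitive by construction of its state
representation.

A **dual-system** model (`learner="dual"`) additionally maintains punctate
Go/No-Go action values, initialized at their Non-Resistant optima, and
updates the *previously taken* action with a mixture of its own action RPE
(Q-learning or SARSA type) and the state-value system's RPE, weighted by
`κ ∈ [0, 1]` — a model of the ventral-to-dorsal "spiral" striatum–midbrain
influence.

## Worked example

```python
import srchain as sc

res = sc.run_scenario("fig3", base_seed=1, n_sims=100, episodes=25)
ep25 = res.summary.query(
    "episode == 25 and event in ('initiation', 'no_go_mean', 'goal')"
)
print(ep25.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
```

```
 episode  state      event    mean     sd  n_included
      25      0 initiation  0.5834 0.0283         100
      25      1 no_go_mean -0.0178 0.0009          82
      ...
      25      9 no_go_mean -0.0176 0.0022          70
      25     10       goal  0.4019 0.0765         100
```

This is the rigid reduced-SR agent after 25 episodes of resisting
(`P_No-Go = 0.75`, 100 simulations): a large positive RPE (0.58 ± 0.03)
still fires on the cue, small negative RPEs accompany each No-Go (cells
average only the simulations that actually took No-Go at that state —
hence `n_included < 100`), Go steps generate exactly zero RPE, and a
large positive RPE (0.40 ± 0.08) **persists at the fully predicted
reward** — the signature that distinguishes this "addicted" model from
the punctate learner, whose goal RPE is exactly zero here. The companion
coefficient trajectory shows why:

```python
print(res.aux["w_trajectory"].query("episode in (0, 1, 25)"))
```

```
 episode name   mean     sd  n_included
       0    w 1.0000 0.0000         100
       1    w 0.8742 0.0444         100
      25    w 0.7991 0.0383         100
```

`w` settles below 1 where the negative No-Go updates and the positive
goal update balance, so every goal arrival finds `w·x(S_10) = w < R`.

## Command line

```bash
srchain list-scenarios
srchain scenario fig4a --seed 1 --out-dir out/
srchain run --learner dual --policy resistant --p-no-go 0.75 \
        --kappa 0.4 --rpe-type sarsa --episodes 60 --n-sims 100 \
        --seed 1 --out-dir out/
```

Each run writes `steps.csv` (every event with its RPE per system),
`summary.csv` (across-simulation means/SDs), `aux_*.csv` (preset-specific
series such as coefficient trajectories) and `config.echo.json`, which
can be replayed with `srchain run --config config.echo.json` to reproduce
the outputs byte-for-byte.

Scenario presets: `fig2a` (naive punctate learning, Non-Resistant),
`fig2bcd` (punctate under resistance), `fig3` (rigid reduced SR under
resistance), `fig4a` (cue values vs `P_No-Go`), `fig4b` (punishment),
`fig5` (slowly adapting reduced SR), `fig6` (genuine SR), `fig8` / `fig9`
(dual system with reduced-SR / punctate-state companion).

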