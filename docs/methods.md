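# Methods

## Task model

The environment is a deterministic chain `S_1 … S_n` with two actions at
every pre-goal state — Go (advance) and No-Go (stay) — and a reward `R`
delivered at the goal `S_n`. Behavior policies are *fixed*: learned values
never feed back into choice. The Non-Resistant policy always goes, so an
episode is exactly `n − 1` Go steps; the Resistant policy takes No-Go with
probability `P_No-Go` independently at each time step, so the number of
No-Go repeats at a visited state is geometric with mean
`P_No-Go / (1 − P_No-Go)` and every episode terminates almost surely (a
configurable safety cap, default 10⁶ steps per episode, raises an error in
the degenerate `P_No-Go = 1` case). When the punishment option is enabled
an extra state `S_{n+1}` follows the goal deterministically and delivers a
negative reward, after which the episode ends.

Episodes begin with an initiation event, logged at pseudo-state 0: the
active learner reports the RPE `γ·V(S_1)` (its learned cue value) and no
parameter is updated, since there is no predecessor whose value or feature
could be credited.

## Learners

All learners are TD(0) with the same conventions: the RPE is computed
from pre-update quantities, then the update is applied, before the next
action is sampled; the bootstrap term `γV(S_{t+1})` is dropped when `S_t`
is the goal (unless the punishment state follows it) and at the punishment
state.

* **Punctate TD** — a table `V(S_k)`; `V(S_t) += α δ`. Initialization is
  either all-zero (naive learning) or the Non-Resistant values
  `R γ^(n−k)` (completion of learning, the starting point for resistance
  scenarios).
* **Rigid reduced SR** — scalar features `x(S_k) = γ^(n−k)` (the
  discounted future occupancy of the goal under the Non-Resistant policy),
  value `w·x(S_k)`, update `w += α x(S_t) δ`, `w` initialized at `R`
  (with which the linear form reproduces the Non-Resistant values
  exactly). The features never change — the operationalization of a
  representation formed so rigidly it cannot be updated. Its formation
  process is not modelled. The punishment state's feature is 0, so
  punishment RPEs cannot move `w`.
* **Adaptive reduced SR** — the same, plus a slow feature update
  `x(S_t) += α_feature (γ x(S_{t+1}) − x(S_t))` with `α_feature = 0.05`;
  the goal feature is frozen at 1 because its feature TD error is
  identically zero. Both the value RPE and the feature RPE are computed
  from the same pre-update `(w, x)` snapshot and then both updates are
  applied, which makes the result independent of update order (no order
  is canonically defined for the simultaneous updates). Both parameters
  keep learning: the evolving RPE patterns require a live `w` alongside
  the adapting features.
* **Genuine SR** — the full feature matrix `x_j(S_k) = γ^(j−k)` for
  `j ≥ k` (zero otherwise), fixed throughout; weights start at
  `w_j = 0 (j < n), w_n = R`, again an exact representation of the
  Non-Resistant values, and update as `w_j += α x_j(S_t) δ`.

Default learning rate `α = 0.5` everywhere; discount `γ = 0.97` (0.95 and
0.99 for the value-ratio checks); `n = 10`; `R = 1`; punishment −2.

## Dual system

The dual-system model couples a state-value companion (the rigid reduced
SR, or the punctate TD learner as a control) to punctate Go/No-Go action
values `Q(Go_Sk), Q(No-Go_Sk)`, `k = 1 … n−1`. RPEs that contain the
reward at `S_t` update the action taken at `t − 1`:

    Q(A_{t−1}, S_{t−1}) += α [(1 − κ) δ_action + κ δ_companion]

with `δ_action` of Q-learning type (bootstrap `γ max_a Q(a, S_t)`) or
SARSA type (bootstrap on the action actually chosen at `t`). The
bootstrap is dropped at the goal; the previous-action term is dropped —
and no update occurs — at the first step of an episode. The companion
keeps updating its own parameter during dual runs; the value inflation at
larger `κ` comes precisely from its sustained positive goal RPE, which
requires `w` to have settled below `R`. Initial action values are the
Non-Resistant optima `Q(Go_Sk) = R γ^(n−1−k)` with No-Go one step behind,
`Q(No-Go_Sk) = R γ^(n−k)`; this makes the κ = 0 Q-learning configuration
an exact fixed point, a useful built-in control.

Because No-Go keeps the agent at the same state, a No-Go action's own
next-step RPE is the one that credits it; this asymmetry is what makes
the punctate-state companion *shrink* the Go-minus-No-Go gap with κ while
the reduced-SR companion widens it.

## Simulations and aggregation

Stochastic (Resistant-policy) conditions run 100 simulations by default;
each simulation uses its own `numpy` Generator seeded `base_seed +
sim_id`, so runs are reproducible, simulations independent, and any
single simulation reconstructible in isolation. Presets that compare
conditions (learners, `P_No-Go`, κ) reuse the same base seed across
conditions; as choice never depends on learned values, all conditions see
identical trajectories (common random numbers), which makes the reported
contrasts paired. Deterministic Non-Resistant conditions run a single
simulation.

Aggregation across simulations: No-Go RPEs repeated at the same state
within an episode are first averaged — and, separately, summed — within
the simulation; simulations with no No-Go at a given (episode, state)
cell are excluded from that cell's statistics, so the included count
varies cell by cell. Initiation, Go, goal and punishment events occur at
most once per state per episode and use all simulations. Dispersion is
the sample SD (ddof = 1), reported as NaN when fewer than two simulations
are included.

Preset sizes follow the analyses they back: 30 episodes for naive
Non-Resistant learning, 25 for single-episode statistics (cue values,
genuine-SR weights, punishment), 60 for over-episode curves and the dual
system (whose summary windows episodes 41–60, averaged within simulation
before averaging across), and 200 for the slowly adapting representation
with feature snapshots at episodes 50/100/200. All are overridable.

## Numerical choices

Initial value/feature/action-value vectors are built by backward
multiplicative recursion (`v[k] = γ·v[k+1]`) rather than `γ**(n−k)`, and
bootstrap terms are grouped as `w·(γ·x)`; with IEEE-754 arithmetic the
algebraic identities of the model then hold *bit-exactly*: Go-step RPEs
of the rigid reduced SR vanish for every `w`, the punctate goal value is
a fixed point, the κ = 0 Q-learning action values never move, and the
genuine SR generates exactly zero RPE on Non-Resistant transitions from
its initial weights. Tests assert these as exact zeros (with a 1e−12
band where composition with arbitrary coefficients is involved). The
closed-form naive-learning curve `R(1 − α)^(m−1)` is exact in binary for
`α = 0.5`.

Degenerate inputs are rejected at construction time (chain shorter than
2, γ outside (0,1), nonpositive reward, positive punishment, No-Go
probability outside [0,1], κ outside [0,1]); the genuine-SR and
dual-system models refuse punishment-enabled chains, which the study
design reserves for the punctate and reduced-SR learners under the
Non-Resistant policy.

## What the simulations do and do not show

The generator *is* the model under study — there is no external data.
What passing tests establish is internal: that the implemented update
rules have the claimed fixed points, closed forms and contrasts under the
stated policies, seeds and sample sizes. The chain is deterministic and
linear, policies are fixed rather than value-driven (the value-driven
extension is deliberately out of scope), rewards are stationary, and the
formation of the reduced representation itself is not modelled; none of
the results speak to how such a representation arises, to richer state
spaces, or to behavior once action values are allowed to control choice.

## Known limitations

* Single-threaded pure-Python episode loop; ~1 s per 100-simulation ×
  25-episode condition. Adequate for the study sizes; not tuned for
  large-scale sweeps.
* The adaptive-representation punishment combination is not implemented:
  the scenarios that define punishment never exercise feature learning,
  and the semantics of a feature update into a terminal punished state
  are unspecified.
* SD bars use the sample convention (ddof = 1) throughout; with 100
  simulations the difference from the population convention is
  negligible but bit-level comparisons should use the package's own
  outputs.
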