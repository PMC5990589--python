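# Methods

## Model

A trial is a biased ±1 random walk observed one sample at a time.  The
up-probability u of the walk is drawn once per trial from a finite mixture
with known support and weights; u > ½ means the first alternative (*buy*)
is correct, u < ½ the second, and u = ½ means the trial carries no signal
and either answer is correct with probability ½.  The decision-maker's
within-trial state is (t, x) — samples seen and cumulative evidence
x = n_u − n_d — which lives on the lattice |x| ≤ t, t + x even.  States of
the full process additionally include two absorbing outcome labels
(correct, incorrect; plus a third outcome when the opt-out action is
enabled), each of which returns to (0, 0) after its reward and delay.

Everything is driven by the posterior over u at a state.  All sample paths
into (t, x) contain (t+x)/2 up and (t−x)/2 down steps, so the path count
cancels between numerator and denominator and

    P(u | t, x) ∝ u^((t+x)/2) (1 − u)^((t−x)/2) P(u).

The implementation never counts paths, and in particular the posterior does
not depend on the policy that shaped which paths survive.  Under *wait* the
next sample is up with the posterior-predictive probability
Σ_u u·P(u | t, x).  Under *go* the decision-maker commits to the world
state with the larger posterior mass, and is correct with probability
max{P(U ∈ 𝒰₊ | t, x), P(U ∈ 𝒰₋ | t, x)}; any mass on u = ½ is split
half-and-half between the two classes whenever ½ is in the support (not
only in a two-level parameterization).  With equal world priors this means
buy exactly when x > 0, with the tie at x = 0 broken deterministically to
buy — a value-neutral choice, since correctness probability is ½ either
way.

## Solving for the optimal policy

For a fixed policy the average-reward dynamic-programming identities hold:
every transition (wait, go, pass) takes one time step and earns nothing;
the outcome states pay R_C, R_I, or 0 (pass) and cost D_C, D_I, or the pass
delay before restarting.  Waiting at the horizon t_max is a forced
transition to the incorrect outcome.  The unknowns (relative values per
lattice state plus the gain ρ) satisfy one linear equation per state; the
system's one-dimensional shift freedom is closed by v₍₀,₀₎ = 0.  We solve
it directly as a sparse linear system (scipy `spsolve`) rather than by
iterative value relaxation: exact, and cheap at the 10³–10⁴ states
involved.  Values are computed for *all* lattice states, including ones
unreachable under the current policy, so full policy maps can be displayed.

Policy improvement is greedy one-step look-ahead under the incumbent (v, ρ):
wait is chosen only where its look-ahead value strictly exceeds the best
committing action.  Numerically, action values within a relative tolerance
of 1e-10 are treated as tied before the strict rule is applied, which
prevents floating-point flip-flop from blocking convergence; ties resolve
go before pass.  Iteration starts from the all-go policy and stops when the
policy is a fixed point (cap 500 sweeps, far above the ≤ 10 observed); the
gain ρ is non-decreasing across sweeps, which the tests assert.

## Parameters and defaults

- **R_C = 1, R_I = 0.** Reward magnitudes are a free scale of the model;
  this default makes the delay-splitting invariance (only D_C + D_p
  matters) hold and is assumed by all preset computations.
- **D_C, D_I (sample-time units), default 150.** Inter-trial delays; D_p
  optionally expresses D_I = D_C + D_p.
- **t_max, default 70 (presets: 100).** A computational horizon, not a task
  deadline: waiting there is a forced loss, which drags every boundary to
  zero just before t_max.  Boundaries are therefore read only on
  t ≤ t_max − 20, and qualitative claims on the conventional display window
  t ≤ 50.  The preset default of 100 keeps the artifact out of the display
  window even for mixtures with a weakly informative component, whose
  artifact reaches t ≈ 43 at t_max = 70.
- **Mixture construction.** `from_drifts` takes drift magnitudes and
  weights; the world prior `p_plus` is interpreted as the *total*
  P(U ∈ 𝒰₊) including half of any zero-drift mass, realized by one shared
  rising/falling split factor across drift levels.  Per-u support/prior
  pairs can be given directly when a different weighting convention is
  wanted.

## Boundary extraction

For each t the upper boundary is the smallest x at which go is optimal with
buy (weakly) preferred, the lower boundary the largest x with sell (weakly)
preferred; at exactly even posterior odds membership follows the sign of x
and x = 0 counts toward both, keeping symmetric tasks mirror-symmetric and
assigning the pure-noise task the boundary 0 rather than −t.  Boundary
values stay on the integer lattice with undefined entries marked NaN, never
interpolated; a flat bound of height h therefore alternates h, h+1 with
lattice parity, and quoted heights are the window minimum.  The boundary
slope is an ordinary least-squares fit to the upper boundary over t ∈ [5, 50]
(the fit convention is ours; only the upper boundary enters).  The collapse
time is the earliest in-window t with upper boundary 0.

## Monte-Carlo validation

`simulate_policy` replays the renewal process literally: draw u, follow the
policy step by step, score one time unit per action plus the outcome delay.
Each trial runs on its own substream spawned deterministically from the
master seed, so results are bit-reproducible and individual trials can be
replayed in isolation.  The reward-rate standard error is a per-trial
bootstrap of the ratio estimator (200 resamples).  The simulator emulates
exactly the process the solver assumes — it shares no code path with policy
evaluation, making it an independent check on ρ, but passing it says
nothing about phenomena outside the model (continuous evidence, internal
sampling noise, non-stationary environments, learning across trials).

## Design choices in genuinely open territory

- **Difficulty-posterior maps.** The posterior that a trial is easy is
  computed under class-symmetric world weights (each drift level's mass
  split equally between rising and falling), which makes the easy/difficult
  map exactly independent of the world-state prior; under a fully joint
  prior the dependence is weak but non-zero.  The world-state map
  P(U ∈ 𝒰₊ | t, x) always uses the actual prior.
- **Horizon sensitivity of mixture shapes.**  Mixtures whose difficult
  member has the *wider* single-task bound eventually bend upward toward
  it; how much of that is visible below t = 50 depends on the horizon.  The
  {0.10, 0.20} mixture matches the single-0.20 policy bit-exactly below
  t = 50 at t_max = 70, while at t_max = 100 a genuine rise appears from
  t = 37.  The fig4-family presets are pinned to t_max = 70 to reproduce
  the canonical panels; the sensitivity is inherent to the model, not a
  numerical artifact.
- **Opt-out incentives.**  With the one-step-then-delay accounting, pass
  beats go exactly when the correctness probability falls below a
  ρ-dependent threshold; at pass delay 40 (a quarter of the error delay)
  that threshold sits marginally below ½, so no state maps to pass and the
  simulated pass frequency is 0.  At pass delay 20 a pass region opens at
  long times and low evidence.
- **"17 values in [0, 0.50]"** for the distance-judgment drift set is
  realized as the evenly spaced grid {0, 0.03125, …, 0.5}; only the count
  and range are specified by the source study mapping.
- **Sweep reference mixture** defaults to drifts {0, 0.20} (configurable),
  the two-level mixture with rapidly collapsing bounds used as the
  comparison line in slope-versus-delay sweeps.
- **Degenerate states.**  If every support member has zero likelihood at a
  state (possible only when the support is exactly {0, 1}), the posterior
  falls back to the prior; such states are unreachable.

## Problem sizes

Policies are solved on lattices of 2 556 states (t_max = 70) to 5 151
states (t_max = 100); policy iteration converges in 3–10 sweeps and a full
preset run takes well under a second.  Monte-Carlo cross-checks use 10⁵
trials (a few seconds); unit-level checks use 2·10⁴.

## Known limitations

- Evidence is discrete and binary; there is no diffusion limit, no
  belief-space (POMDP) formulation, and no cost per observation.
- The environment is stationary: no learning or boundary adaptation across
  trials, and no fitting to empirical reaction-time data.
- Boundaries are reported on the evidence lattice; no parametric collapse
  shapes (Weibull/hyperbolic) are fitted.
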