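# Methods

## The user–resource model

The simulator's core is the Schaefer harvest model: a single well-mixed
stock *R(t)* with logistic renewal and harvest bilinear in stock and total
effort,

    dR/dt = μ_R R (1 − R/K) − q R F(t),      F(t) = Σᵢ Eᵢ(t),

where each of the *N* users controls an effort *Eᵢ ∈ [0, E_max]*. The
individual harvest rate is *Hᵢ = q R Eᵢ* and the return rate
*Bᵢ = p Hᵢ − c Eᵢ*. The model's standard analytics are exposed directly:
equilibrium stock *K(1 − qF/μ_R)* for *qF < μ_R* and 0 otherwise
(collapse), MSY effort *μ_R/(2q)*, MSY *μ_R K/4*, productivity peak at
*K/2*.

Assumptions worth keeping in mind: a single homogeneous stock (no space,
age or size structure), deterministic dynamics, identical catchability and
prices for all users, and efforts that act instantaneously — the model is
the one running behind continuous-time harvesting experiments, not a
stock-assessment tool.

### Default parameters

Time is in seconds, so every rate is per second.

| parameter | meaning | default |
|---|---|---|
| μ_R | max. per-capita growth rate | 0.1 /s |
| K | carrying capacity | 100 |
| q | catchability | 0.01 /(effort·s) |
| p | price per resource unit | 1 |
| c | cost per unit effort | 0.1 /(effort·s) |
| E_max | individual effort cap | 10 |
| N | number of users | 5 |

These are the package's reference configuration, chosen so the derived
quantities are round and the group is interesting: MSY effort 5 (1 per
agent), MSY 2.5/s, myopic switch point c/(pq) = 10, and full group effort
N·E_max = 50 placing the group deep in the collapse regime
(q·N·E_max = 0.5 ≫ μ_R). Anyone reproducing a specific experiment should
substitute their own calibration; nothing in the code depends on these
values being round.

## Integration: piecewise exact, with an RK4 cross-check

Between effort events *F* is constant, and the harvested logistic equation
is again logistic with growth rate *r = μ_R − qF* and crowding
*a = μ_R/K*. The propagator uses the closed form

    R(t+Δ) = R₀ e^{rΔ} / (1 + (aR₀/r)(e^{rΔ} − 1)),      r ≠ 0
    R(t+Δ) = R₀ / (1 + aR₀Δ),                            r = 0

evaluated with `expm1` in the exponential branch that cannot overflow
(divide through by `e^{rΔ}` when r > 0). R = 0 is absorbing; results are
clamped at 0 against floating-point undershoot (the analytic solution
itself cannot go negative).

Cumulative harvest over a constant-effort interval uses the exact
antiderivative: with D(s) the denominator above, R = D′/(aD), so

    ∫₀^Δ R ds = (1/a) · log1p((aR₀/r) · expm1(rΔ))       (r ≠ 0)

and the `log1p(aR₀Δ)/a` limit at r = 0. Per-agent cumulative harvest is
*q Eᵢ ∫R*, cumulative return *p·(that) − c EᵢΔ*. Because the segment
integrals are exact, refining the output sampling grid changes the
cumulative accounting only at float round-off — the refinement checks in
the tests observe relative changes ≲ 1e-15, far inside the 1e-6 documented
guarantee. This is why the package integrates analytically rather than by
trapezoidal quadrature on the sample grid, whose O(Δt²) error (~1e-4
relative at a 1 s grid for these parameters) would be visible in exactly
the statistics the platform displays to participants.

A fixed-step classical RK4 integrator is kept alongside the closed form
(default step 0.01 s, final partial step shortened to land exactly on the
target time) so that replacement resource models without a closed form can
be dropped in behind the same interface. The closed form serves as its
oracle: over randomized parameter draws the two agree to better than 1e-8
relative error, and the test suite asserts this as a property.

## Event semantics

* Efforts are piecewise constant; an accepted event takes effect at its
  submission timestamp, and a fresh integration starts there with the
  stock carried over unchanged (R is continuous; only dR/dt jumps).
* Simultaneous events by distinct agents are all applied before
  re-integration; addition commutes, so the trajectory is independent of
  their processing order. Two submissions by the same agent at the same
  timestamp keep the last by input order (logged as superseded).
* The submission lockout (default 3 s, configurable) is rejection-only:
  an event within the lockout of the agent's previous *accepted* event is
  dropped and logged; it does not delay the effect of accepted events.
  There is no transmission-latency model.
* Efforts outside [0, E_max] are rejected and recorded; events after the
  horizon are ignored with a warning.
* The output grid is 0, Δt, …, t_end (default Δt = 1 s) plus every event
  time, so segment boundaries are exact samples. At an event time a row
  reports the effort/rates in effect from that instant onward.
* The initial stock defaults to K — sessions start from an unharvested
  resource.
* Slider granularity: agent-submitted efforts are quantised to a 0.1-unit
  grid by default (configurable, 0 disables), mimicking a discrete slider.

## Synthetic agents

Policies observe what the client screen shows — the current stock, own
effort, own cumulative harvest and return — at discrete decision times
(default every 10 s, roughly the pace at which participants in
continuous-time pilots adjust), and emit a desired effort.

* *myopic*: maximises the instantaneous return rate; since Bᵢ is linear in
  Eᵢ this is bang-bang — E_max while p·q·R > c, 0 otherwise (ties to 0).
  A group of these crashes the stock and then oscillates around the switch
  point c/(pq).
* *sustainable*: the equal MSY split μ_R/(2qN), capped at E_max; a group
  holds the stock at K/2.
* *threshold*: harvest hard only above a stock floor — produces the
  "pause, brief recovery, resumed collapse" pattern characteristic of
  continuous-time CPR groups.
* *noisy*: wraps any policy with zero-mean Gaussian effort noise (clipped
  to bounds), drawn from a per-agent stream spawned off the run seed.
* *constant*, *scripted*: fixed effort / a pre-scripted step function.

The treatment emulation represents **communication** as coordination on
the MSY split with small noise (sd 0.1 effort units) and **no
communication** as myopic harvesting with larger noise (sd 1.0); both arms
of a run index share the same derived seed. These policies are test
scaffolding: only the qualitative ordering of outcomes — higher mean stock
and less volatile group effort under communication — is claimed, not any
quantitative model of human subjects.

During a run, the engine propagates the stock to each decision time with
the same closed form used afterwards by the event engine, so the
observations agents act on are exactly consistent with the final
trajectory, and the accepted-event log replays to the identical result.

## Sessions and payoffs

A session is an ordered stage list (stages may repeat): information,
questionnaire (numeric/text answer restrictions enforced on input; invalid
answers are recorded, not fatal), incentivised allocation task, model, and
waiting steps. The model stage starts simultaneously for all participants.
A stage with missing inputs halts the session with a stage-indexed error;
stage outputs never depend on later stages.

The allocation task pairs participants uniformly at random (an odd
participant is left unpaired with zero payment and a warning), then draws
one decision index per pair; each partner is paid their own chosen
option's self-amount plus the partner's chosen option's other-amount at
that index. Pair payment conservation (paid = offered by the two selected
options) holds identically.

Final payoff = model-stage cumulative return (floored at zero by default —
subjects are not charged for losses; a flag disables the floor) +
questionnaire fee (default 2 €) + allocation payments. The price parameter
doubles as the currency conversion: quoting p in €/resource unit makes the
return directly a euro amount.

## Serialization and replay

Configs are strict (unknown keys rejected with their key path, via
pydantic) and canonically serialized — sorted keys, fixed layout — so
save→load→save is byte-identical and a SHA-256 of the canonical text
identifies a configuration. Logs are plain UTF-8 CSV with floats in
shortest round-trip decimal form (`repr`), so parsing recovers the exact
binary values; consequently *replay is exactly bit-stable*: re-integrating
the accepted events of any log regenerates trajectory.csv byte for byte.
Round-trip formatting was chosen over a fixed digit budget precisely to
make that identity hold for arbitrary (not just grid-aligned) event times.
A manifest carries the parameters, engine settings, roster and a
fingerprint hash; replay against a non-matching config is refused with
both hashes.

The client/server message shapes (effort submission, per-sample state
broadcast) are documented and validated as a schema contract only; the
package contains no network code.

## Analysis choices

Run summaries use time-weighted (trapezoid) means over the possibly
irregular sample grid; effort dispersion is the population sd of the
sampled group effort; linear trends are least-squares slopes. A *recovery
episode* is a maximal rising interval of the stock that begins after a
drawdown of ≥ 10% from the running peak, counted only if the total rise
exceeds 1% of that peak (both implementer constants; the 10% threshold
operationalises the qualitative "short pause then recovery" description).
Treatment contrasts are descriptive by default — arm means, differences,
sign labels — with an optional two-sided label-permutation p-value
(seeded) on request.

## Problem sizes and determinism

The test suite and the acceptance script run at deliberately modest sizes
— horizons of 60–1000 s at 1 s sampling, 100 random schedules for
continuity/replay, 10³ draws for the RK4 oracle and allocation
conservation, 10⁴-point grids for the MSY and productivity optima, 50
matched runs for the treatment ordering — which complete in a few seconds
while leaving the measured errors many orders of magnitude inside their
bounds. Every stochastic component draws from `numpy` Generator streams
spawned from a single seed; identical (config, seed) pairs give
bit-identical trajectories, logs and payoffs.

## Known limitations

* The synthetic data emulate study conditions, not people: policies are
  simple decision rules, and passing the treatment-ordering checks shows
  the pipeline reproduces the expected *direction* of the communication
  effect under those rules — it says nothing about effect sizes in real
  groups.
* No transport layer: latency, jitter and disconnections of a real
  client/server deployment are out of scope (the lockout is the only
  throttling mechanism).
* Single-species deterministic stock; stochastic recruitment, shocks and
  multi-species extensions would require a different propagator (the RK4
  path is the intended hook).
* The permutation test treats runs as exchangeable units; it is not a
  substitute for the mixed-effects analyses used on real session data.
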