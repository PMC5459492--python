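"""Synthetic participants for the harvesting experiment.

Policies stand in for the humans who would drag the effort slider: at
discrete decision times each policy observes the displayed state (current
stock, own effort, own cumulative harvest and return) and emits a desired
effort. :func:`run_experiment` turns those decisions into effort events,
applies the submission lockout, and hands the resulting schedule to the
event engine, so a whole session is reproducible from a single seed.

The policies are deliberately simple test scaffolding, not a model of the
pilot subjects:

* ``constant`` — hold a fixed effort.
* ``myopic`` — maximise the instantaneous return rate B_i = p*q*R*E - c*E,
  which is linear in E, hence bang-bang: full effort while p*q*R > c, zero
  otherwise (switch point R* = c/(p*q)).
* ``sustainable`` — an equal split of the MSY effort, mu_R/(2*q*N); a group
  of these holds the stock near K/2.
* ``threshold`` — harvest hard only above a stock floor, producing the
  collapse/short-recovery pattern seen in continuous-time CPR pilots.
* ``noisy`` — wrap any policy with seeded Gaussian effort perturbation,
  clipped to [0, E_max].
* ``scripted`` — replay a fixed (time, effort) step function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .events import (
    EffortEvent,
    EffortSchedule,
    EventRecord,
    Trajectory,
    simulate,
)
from .schaefer import (
    ResourceState,
    SchaeferParams,
    msy_effort,
    propagate_closed_form,
    resource_integral,
)

__all__ = [
    "Observation",
    "AgentPolicy",
    "ConstantPolicy",
    "MyopicPolicy",
    "SustainablePolicy",
    "ThresholdPolicy",
    "NoisyPolicy",
    "ScriptedPolicy",
    "myopic_policy",
    "sustainable_policy",
    "ExperimentResult",
    "run_experiment",
    "TreatmentPair",
    "treatment_pair",
    "POLICY_KINDS",
]


@dataclass(frozen=True)
class Observation:
    """What the client screen shows an agent at a decision time."""

    t: float
    R: float
    own_effort: float
    own_cum_harvest: float
    own_cum_return: float


class AgentPolicy(Protocol):
    """Decision rule mapping an observation to a desired effort."""

    decision_interval: float

    def decide(self, obs: Observation, rng: np.random.Generator) -> float: ...


def myopic_policy(R: float, params: SchaeferParams) -> float:
    """Effort maximising the instantaneous return rate at stock ``R``.

    B_i is linear in E_i, so the optimum is bang-bang: ``E_max`` when the
    marginal revenue ``p*q*R`` exceeds the marginal cost ``c``, else 0 (ties
    resolve to 0).
    """
    return params.E_max if params.p * params.q * R > params.c else 0.0


def sustainable_policy(params: SchaeferParams, N: int | None = None) -> float:
    """Equal per-agent share of the MSY effort, capped at ``E_max``."""
    n = params.N if N is None else N
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    return min(msy_effort(params) / n, params.E_max)


@dataclass
class ConstantPolicy:
    effort: float
    decision_interval: float = 10.0

    def decide(self, obs: Observation, rng: np.random.Generator) -> float:
        return self.effort


@dataclass
class MyopicPolicy:
    params: SchaeferParams
    decision_interval: float = 10.0

    def decide(self, obs: Observation, rng: np.random.Generator) -> float:
        return myopic_policy(obs.R, self.params)


@dataclass
class SustainablePolicy:
    params: SchaeferParams
    N: int | None = None
    decision_interval: float = 10.0

    def decide(self, obs: Observation, rng: np.random.Generator) -> float:
        return sustainable_policy(self.params, self.N)


@dataclass
class ThresholdPolicy:
    """Harvest at ``high_effort`` while the stock is above ``floor``."""

    params: SchaeferParams
    floor: float
    high_effort: float | None = None
    low_effort: float = 0.0
    decision_interval: float = 10.0

    def decide(self, obs: Observation, rng: np.random.Generator) -> float:
        high = self.params.E_max if self.high_effort is None else self.high_effort
        return high if obs.R > self.floor else self.low_effort


@dataclass
class NoisyPolicy:
    """Base policy plus zero-mean Gaussian effort noise, clipped to bounds."""

    base: AgentPolicy
    sd: float
    E_max: float
    decision_interval: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if self.decision_interval is None:
            self.decision_interval = self.base.decision_interval

    def decide(self, obs: Observation, rng: np.random.Generator) -> float:
        e = self.base.decide(obs, rng)
        if self.sd > 0:
            e += self.sd * rng.standard_normal()
        return float(min(max(e, 0.0), self.E_max))


@dataclass
class ScriptedPolicy:
    """Step function of pre-scripted (time, effort) pairs."""

    steps: Sequence[tuple[float, float]]
    decision_interval: float = 10.0

    def decide(self, obs: Observation, rng: np.random.Generator) -> float:
        effort = 0.0
        for t_step, e in self.steps:
            if t_step <= obs.t:
                effort = e
        return effort


POLICY_KINDS = ("constant", "myopic", "sustainable", "threshold", "noisy", "scripted")


@dataclass
class ExperimentResult:
    """One model-stage run: trajectory, full event log and final payoffs.

    ``events`` contains every submission attempt with its acceptance status;
    replaying the accepted ones through the event engine reproduces
    ``trajectory`` exactly.
    """

    params: SchaeferParams
    trajectory: Trajectory
    events: list[EventRecord]
    payoffs: dict[str, float]
    seed: int | None = None
    settings: dict[str, float] = field(default_factory=dict)

    @property
    def accepted_events(self) -> list[EffortEvent]:
        return [rec.event for rec in self.events if rec.accepted]


def _quantize(effort: float, granularity: float) -> float:
    if granularity <= 0:
        return effort
    return round(effort / granularity) * granularity


def run_experiment(
    params: SchaeferParams,
    policies: Mapping[str, AgentPolicy],
    t_end: float,
    *,
    sample_dt: float = 1.0,
    lockout: float = 3.0,
    seed: int | None = 0,
    R0: float | None = None,
    granularity: float = 0.1,
) -> ExperimentResult:
    """Run a model experiment with synthetic agents.

    Each agent decides at ``0, d, 2d, ...`` (its policy's decision
    interval); the desired effort is quantised to the slider granularity,
    clipped to ``[0, E_max]``, and submitted only when it differs from the
    agent's current effort. Submissions within ``lockout`` seconds of the
    agent's previous accepted one are rejected and logged. Fully
    deterministic given the seed.
    """
    if not policies:
        raise ValueError("at least one agent is required")
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    agents = sorted(policies)
    streams = {
        aid: np.random.default_rng(ss)
        for aid, ss in zip(agents, np.random.SeedSequence(seed).spawn(len(agents)))
    }

    decisions: list[tuple[float, str]] = []
    for aid in agents:
        d = policies[aid].decision_interval
        if not d > 0:
            raise ValueError(f"decision_interval must be positive, got {d}")
        k = 0
        while k * d < t_end:
            decisions.append((k * d, aid))
            k += 1
    decisions.sort(key=lambda td: (td[0], td[1]))

    R0_eff = params.K if R0 is None else R0
    state = ResourceState(t=0.0, R=float(R0_eff))
    efforts = {aid: 0.0 for aid in agents}
    cum_h = {aid: 0.0 for aid in agents}
    cum_b = {aid: 0.0 for aid in agents}
    last_accepted: dict[str, float] = {}
    log: list[EventRecord] = []

    for t_d, aid in decisions:
        dt = t_d - state.t
        if dt > 0:
            total = sum(efforts.values())
            integral = resource_integral(state.R, dt, params, total)
            for a in agents:
                dH = params.q * efforts[a] * integral
                cum_h[a] += dH
                cum_b[a] += params.p * dH - params.c * efforts[a] * dt
            state = propagate_closed_form(state, dt, params, total)
        obs = Observation(
            t=t_d,
            R=state.R,
            own_effort=efforts[aid],
            own_cum_harvest=cum_h[aid],
            own_cum_return=cum_b[aid],
        )
        desired = policies[aid].decide(obs, streams[aid])
        desired = float(min(max(desired, 0.0), params.E_max))
        desired = _quantize(desired, granularity)
        if math.isclose(desired, efforts[aid], rel_tol=0.0, abs_tol=1e-12):
            continue
        prev = last_accepted.get(aid)
        if prev is not None and t_d - prev < lockout:
            log.append(EventRecord(t_d, aid, desired, False, "lockout"))
            continue
        log.append(EventRecord(t_d, aid, desired, True))
        efforts[aid] = desired
        last_accepted[aid] = t_d

    schedule = EffortSchedule([rec.event for rec in log if rec.accepted], agents=agents)
    traj = simulate(params, schedule, t_end, sample_dt=sample_dt, R0=R0_eff)
    payoffs = {aid: float(traj.cum_return[-1, traj.agent_index(aid)]) for aid in agents}
    return ExperimentResult(
        params=params,
        trajectory=traj,
        events=log,
        payoffs=payoffs,
        seed=seed,
        settings={
            "t_end": float(t_end),
            "sample_dt": float(sample_dt),
            "lockout": float(lockout),
            "R0": float(R0_eff),
            "granularity": float(granularity),
        },
    )


@dataclass
class TreatmentPair:
    """Matched runs emulating the with/without-communication treatments."""

    communication: list[ExperimentResult]
    no_communication: list[ExperimentResult]


def treatment_pair(
    params: SchaeferParams,
    n_runs: int,
    seed: int | None = 0,
    *,
    t_end: float = 400.0,
    n_agents: int | None = None,
    comm_noise_sd: float = 0.1,
    nocomm_noise_sd: float = 1.0,
    decision_interval: float = 10.0,
    sample_dt: float = 1.0,
    lockout: float = 3.0,
) -> TreatmentPair:
    """Emulate the two pilot treatments with matched per-run seeds.

    "Communication" is represented as coordination on the equal MSY split
    with small effort noise; "no communication" as myopic bang-bang
    harvesting with larger noise. Each run index uses the same derived seed
    in both arms, so the arms differ only in policy assignment. Only the
    qualitative ordering (higher stock, less volatile effort under
    communication) is claimed.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    n = params.N if n_agents is None else n_agents
    run_seeds = [
        int(ss.generate_state(1)[0] % (2**31))
        for ss in np.random.SeedSequence(seed).spawn(n_runs)
    ]
    comm: list[ExperimentResult] = []
    nocomm: list[ExperimentResult] = []
    for run_seed in run_seeds:
        comm_policies = {
            f"a{i}": NoisyPolicy(
                SustainablePolicy(params, N=n, decision_interval=decision_interval),
                sd=comm_noise_sd,
                E_max=params.E_max,
            )
            for i in range(n)
        }
        nocomm_policies = {
            f"a{i}": NoisyPolicy(
                MyopicPolicy(params, decision_interval=decision_interval),
                sd=nocomm_noise_sd,
                E_max=params.E_max,
            )
            for i in range(n)
        }
        common = dict(t_end=t_end, sample_dt=sample_dt, lockout=lockout, seed=run_seed)
        comm.append(run_experiment(params, comm_policies, **common))
        nocomm.append(run_experiment(params, nocomm_policies, **common))
    return TreatmentPair(communication=comm, no_communication=nocomm)
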