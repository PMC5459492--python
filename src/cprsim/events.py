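"""Event-driven simulation of the resource under piecewise-constant effort.

Participants change their effort at arbitrary times; between changes the
total effort is constant, so the stock follows the closed-form logistic
solution exactly and a fresh integration starts from each event time with
the updated effort sum. The stock is continuous across events — only its
derivative jumps.

The trajectory is sampled on a regular grid plus every event time, and
per-agent cumulative harvest/return are accumulated with the exact segment
integral of ``R(t)`` (see :func:`cprsim.schaefer.resource_integral`), so
refining the sample grid leaves the cumulative accounting unchanged to
floating-point precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schaefer import (
    ResourceState,
    SchaeferParams,
    propagate_closed_form,
    resource_integral,
)

__all__ = [
    "EffortEvent",
    "EventRecord",
    "EffortSchedule",
    "Trajectory",
    "merge_simultaneous",
    "enforce_lockout",
    "validate_events",
    "simulate",
    "cumulative_metrics",
]


@dataclass(frozen=True)
class EffortEvent:
    """A time-stamped effort submission by one agent."""

    t: float
    agent_id: str
    effort: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"event time must be non-negative, got {self.t}")


@dataclass(frozen=True)
class EventRecord:
    """An event together with its acceptance status, as logged."""

    t: float
    agent_id: str
    effort: float
    accepted: bool
    reason: str = ""

    @property
    def event(self) -> EffortEvent:
        return EffortEvent(self.t, self.agent_id, self.effort)


@dataclass
class EffortSchedule:
    """Time-ordered effort submissions for a set of agents.

    ``agents`` fixes the roster (and hence the trajectory columns); it
    defaults to the union of agents appearing in the events and in
    ``initial_efforts``. Efforts before an agent's first event default to 0.
    """

    events: list[EffortEvent] = field(default_factory=list)
    agents: Sequence[str] | None = None
    initial_efforts: Mapping[str, float] = field(default_factory=dict)

    def agent_ids(self) -> list[str]:
        if self.agents is not None:
            return sorted(self.agents)
        ids = {ev.agent_id for ev in self.events} | set(self.initial_efforts)
        return sorted(ids)


def merge_simultaneous(
    events: Iterable[EffortEvent],
) -> tuple[list[EffortEvent], list[EventRecord]]:
    """Canonically order events and collapse same-agent duplicates at equal t.

    Simultaneous events by distinct agents all apply before re-integration
    (addition commutes, so the resulting total effort is order independent);
    two submissions by the same agent at the identical timestamp keep the
    last by input order, and the superseded one is returned as a dropped
    record.
    """
    dropped: list[EventRecord] = []
    last_by_key: dict[tuple[float, str], EffortEvent] = {}
    for ev in events:
        key = (ev.t, ev.agent_id)
        if key in last_by_key:
            prev = last_by_key[key]
            dropped.append(
                EventRecord(prev.t, prev.agent_id, prev.effort, False, "superseded_same_time")
            )
            warnings.warn(
                f"agent {ev.agent_id!r} submitted twice at t={ev.t}; keeping the last",
                stacklevel=2,
            )
        last_by_key[key] = ev
    merged = sorted(last_by_key.values(), key=lambda e: (e.t, e.agent_id))
    return merged, dropped


def enforce_lockout(
    schedule: EffortSchedule, lockout: float
) -> tuple[EffortSchedule, list[EventRecord]]:
    """Drop per-agent events arriving within ``lockout`` seconds of the
    agent's previously *accepted* event.

    The first submission of each agent is always accepted. Returns the
    filtered schedule and the dropped events as rejection records.
    """
    if lockout < 0:
        raise ValueError(f"lockout must be non-negative, got {lockout}")
    ordered, dropped = merge_simultaneous(schedule.events)
    accepted: list[EffortEvent] = []
    last_accepted: dict[str, float] = {}
    for ev in ordered:
        prev = last_accepted.get(ev.agent_id)
        if prev is not None and ev.t - prev < lockout:
            dropped.append(EventRecord(ev.t, ev.agent_id, ev.effort, False, "lockout"))
            continue
        accepted.append(ev)
        last_accepted[ev.agent_id] = ev.t
    return (
        EffortSchedule(accepted, agents=schedule.agents, initial_efforts=dict(schedule.initial_efforts)),
        dropped,
    )


def validate_events(
    schedule: EffortSchedule, params: SchaeferParams, t_end: float
) -> tuple[list[EffortEvent], list[EventRecord]]:
    """Split events into applicable ones and rejected/ignored records.

    Efforts outside ``[0, E_max]`` are recorded as invalid; events after
    ``t_end`` are ignored with a warning.
    """
    valid: list[EffortEvent] = []
    rejected: list[EventRecord] = []
    for ev in schedule.events:
        if not (0.0 <= ev.effort <= params.E_max):
            rejected.append(
                EventRecord(ev.t, ev.agent_id, ev.effort, False, "effort_out_of_bounds")
            )
            continue
        if ev.t > t_end:
            warnings.warn(
                f"event at t={ev.t} is after t_end={t_end}; ignored", stacklevel=2
            )
            rejected.append(EventRecord(ev.t, ev.agent_id, ev.effort, False, "after_t_end"))
            continue
        valid.append(ev)
    return valid, rejected


@dataclass
class Trajectory:
    """Sampled time series of the resource and per-agent economics.

    Arrays are aligned on ``t`` (shape ``(n,)``); per-agent quantities are
    ``(n, m)`` with columns ordered as ``agents``. At an event time the row
    holds the continuous stock level and the effort/rates in effect from
    that instant onward.
    """

    t: np.ndarray
    R: np.ndarray
    agents: list[str]
    effort: np.ndarray
    harvest_rate: np.ndarray
    return_rate: np.ndarray
    cum_harvest: np.ndarray
    cum_return: np.ndarray

    def agent_index(self, agent_id: str) -> int:
        try:
            return self.agents.index(agent_id)
        except ValueError:
            raise KeyError(f"unknown agent {agent_id!r}") from None

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def group_effort(self) -> np.ndarray:
        return self.effort.sum(axis=1)

    @property
    def group_harvest_rate(self) -> np.ndarray:
        return self.harvest_rate.sum(axis=1)

    @property
    def group_return_rate(self) -> np.ndarray:
        return self.return_rate.sum(axis=1)

    @property
    def group_cum_harvest(self) -> np.ndarray:
        return self.cum_harvest.sum(axis=1)

    @property
    def group_cum_return(self) -> np.ndarray:
        return self.cum_return.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view matching the trajectory.csv column schema."""
        data: dict[str, np.ndarray] = {"time_s": self.t, "resource": self.R}
        for j, aid in enumerate(self.agents):
            data[f"{aid}_effort"] = self.effort[:, j]
            data[f"{aid}_harvest_rate"] = self.harvest_rate[:, j]
            data[f"{aid}_return_rate"] = self.return_rate[:, j]
            data[f"{aid}_cum_harvest"] = self.cum_harvest[:, j]
            data[f"{aid}_cum_return"] = self.cum_return[:, j]
        m = max(self.n_agents, 1)
        data["group_effort"] = self.group_effort
        data["group_harvest_rate"] = self.group_harvest_rate
        data["group_return_rate"] = self.group_return_rate
        data["group_cum_harvest"] = self.group_cum_harvest
        data["group_cum_return"] = self.group_cum_return
        data["mean_cum_harvest"] = self.group_cum_harvest / m
        data["mean_cum_return"] = self.group_cum_return / m
        return pd.DataFrame(data)


def _sample_grid(t_end: float, sample_dt: float, event_times: Iterable[float]) -> np.ndarray:
    n = int(np.floor(t_end / sample_dt))
    grid = np.arange(n + 1, dtype=float) * sample_dt
    times = np.concatenate([grid, [t_end], np.fromiter(event_times, dtype=float)])
    times = times[(times >= 0.0) & (times <= t_end)]
    return np.unique(times)


def simulate(
    params: SchaeferParams,
    schedule: EffortSchedule,
    t_end: float,
    sample_dt: float = 1.0,
    R0: float | None = None,
) -> Trajectory:
    """Drive the resource model through the effort-change timeline.

    Between consecutive events the total effort is constant and the stock
    follows the closed-form logistic solution; at each event time the new
    effort sum applies from that instant with the stock carried over
    unchanged. Output is sampled at ``0, sample_dt, ..., t_end`` plus every
    event time; cumulative harvest/return use the exact segment integral of
    ``R(t)``, so they are independent of the sampling grid.
    """
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if not sample_dt > 0:
        raise ValueError(f"sample_dt must be positive, got {sample_dt}")
    if R0 is None:
        R0 = params.K
    if R0 < 0:
        raise ValueError(f"R0 must be non-negative, got {R0}")

    valid, _rejected = validate_events(schedule, params, t_end)
    ordered, _dup = merge_simultaneous(valid)
    agents = sorted(set(schedule.agent_ids()) | {ev.agent_id for ev in ordered})
    m = len(agents)
    col = {aid: j for j, aid in enumerate(agents)}

    events_at: dict[float, list[EffortEvent]] = {}
    for ev in ordered:
        events_at.setdefault(ev.t, []).append(ev)

    times = _sample_grid(t_end, sample_dt, events_at.keys())
    n = times.size

    effort_now = np.zeros(m)
    for aid, e in schedule.initial_efforts.items():
        if aid in col:
            effort_now[col[aid]] = e

    R = np.empty(n)
    effort = np.empty((n, m))
    cum_harvest = np.zeros((n, m))
    cum_return = np.zeros((n, m))

    state = ResourceState(t=float(times[0]), R=float(R0))
    for k in range(n):
        tk = float(times[k])
        for ev in events_at.get(tk, ()):
            effort_now[col[ev.agent_id]] = ev.effort
        R[k] = state.R
        effort[k, :] = effort_now
        if k + 1 < n:
            dt = float(times[k + 1]) - tk
            total = float(effort_now.sum())
            integral = resource_integral(state.R, dt, params, total)
            dH = params.q * effort_now * integral
            cum_harvest[k + 1, :] = cum_harvest[k, :] + dH
            cum_return[k + 1, :] = cum_return[k, :] + params.p * dH - params.c * effort_now * dt
            state = propagate_closed_form(state, dt, params, total)

    harvest = params.q * R[:, None] * effort
    ret = params.p * harvest - params.c * effort
    return Trajectory(
        t=times,
        R=R,
        agents=agents,
        effort=effort,
        harvest_rate=harvest,
        return_rate=ret,
        cum_harvest=cum_harvest,
        cum_return=cum_return,
    )


def cumulative_metrics(traj: Trajectory, agent_id: str) -> dict[str, float]:
    """Final cumulative harvest and return for one agent, with group averages.

    The group average is the group total divided by the number of agents in
    the trajectory — the continuously displayed "average harvest (return)".
    """
    j = traj.agent_index(agent_id)
    m = max(traj.n_agents, 1)
    return {
        "cum_harvest": float(traj.cum_harvest[-1, j]),
        "cum_return": float(traj.cum_return[-1, j]),
        "mean_cum_harvest": float(traj.group_cum_harvest[-1] / m),
        "mean_cum_return": float(traj.group_cum_return[-1] / m),
    }
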