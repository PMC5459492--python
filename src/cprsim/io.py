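"""Bit-stable serialization: JSON configs, CSV logs, replay, message schema.

Configs are canonical JSON (sorted keys, fixed formatting) so that
``save -> load -> save`` is byte-identical and a SHA-256 over the canonical
text can guard replays. Event and trajectory logs are plain UTF-8 CSV with
a header row, "." decimals and floats in their shortest round-trip decimal
form, so parsing recovers the exact binary values; the accepted events plus
the manifest are therefore sufficient to re-run the integration and
reproduce the trajectory file bit-for-bit.

The client/server message shapes (effort submission, state broadcast) are
documented and validated here as a schema contract only — there is no
network code.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Annotated, Any, Literal, Mapping, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import agents as _agents
from . import session as _session
from .events import EffortEvent, EffortSchedule, EventRecord, Trajectory, simulate
from .schaefer import SchaeferParams

__all__ = [
    "ConfigError",
    "LogParseError",
    "ReplayError",
    "RunConfig",
    "ParamsConfig",
    "EngineConfig",
    "AgentConfig",
    "PolicyConfig",
    "load_config",
    "save_config",
    "canonical_json",
    "config_hash",
    "build_policies",
    "build_session",
    "write_logs",
    "read_logs",
    "LogBundle",
    "replay",
    "verify_replay",
    "write_session_report",
    "message_schema",
    "validate_submission",
    "validate_broadcast",
    "broadcast_from_sample",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed or invalid configuration, with the offending key path."""


class LogParseError(ValueError):
    """A CSV log could not be parsed; names the file and row."""


class ReplayError(RuntimeError):
    """Replay refused, e.g. the config hash does not match the manifest."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsConfig(_Strict):
    """Serialized form of :class:`cprsim.schaefer.SchaeferParams`."""

    mu_R: float = Field(default=0.1, gt=0)
    K: float = Field(default=100.0, gt=0)
    q: float = Field(default=0.01, gt=0)
    p: float = Field(default=1.0, ge=0)
    c: float = Field(default=0.1, ge=0)
    E_max: float = Field(default=10.0, gt=0)
    N: int = Field(default=5, ge=1)

    def to_params(self) -> SchaeferParams:
        return SchaeferParams(**self.model_dump())


class EngineConfig(_Strict):
    t_end: float = Field(default=400.0, gt=0)
    sample_dt: float = Field(default=1.0, gt=0)
    lockout: float = Field(default=3.0, ge=0)
    R0: float | None = Field(default=None, ge=0)
    granularity: float = Field(default=0.1, ge=0)


class PolicyConfig(_Strict):
    """Declaration of an agent policy by kind plus its parameters.

    ``noise_sd > 0`` wraps the declared policy in the Gaussian noisy
    wrapper.
    """

    kind: Literal["constant", "myopic", "sustainable", "threshold", "scripted"]
    effort: float | None = None
    floor: float | None = None
    high_effort: float | None = None
    low_effort: float = 0.0
    steps: list[tuple[float, float]] | None = None
    N: int | None = Field(default=None, ge=1)
    decision_interval: float = Field(default=10.0, gt=0)
    noise_sd: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _required_fields(self) -> "PolicyConfig":
        if self.kind == "constant" and self.effort is None:
            raise ValueError("constant policy requires 'effort'")
        if self.kind == "threshold" and self.floor is None:
            raise ValueError("threshold policy requires 'floor'")
        if self.kind == "scripted" and not self.steps:
            raise ValueError("scripted policy requires non-empty 'steps'")
        return self


class AgentConfig(_Strict):
    id: str
    policy: PolicyConfig


class QuestionConfig(_Strict):
    text: str
    answer_type: Literal["numeric", "text"] = "text"


class InformationStageConfig(_Strict):
    kind: Literal["information"]
    text: str
    media: str | None = None


class QuestionnaireStageConfig(_Strict):
    kind: Literal["questionnaire"]
    questions: list[QuestionConfig]
    fee: float = Field(default=_session.QUESTIONNAIRE_FEE, ge=0)


class AllocationOptionConfig(_Strict):
    self_amount: float
    other_amount: float


class AllocationDecisionConfig(_Strict):
    options: tuple[AllocationOptionConfig, AllocationOptionConfig]


class IncentivisedTaskStageConfig(_Strict):
    kind: Literal["incentivised_task"]
    decisions: list[AllocationDecisionConfig] = Field(min_length=1)


class ModelStageConfig(_Strict):
    """Model stage; resource parameters and engine settings come from the
    top-level ``params`` and ``engine`` sections."""

    kind: Literal["model"]
    floor_earnings_at_zero: bool = True


class WaitingStageConfig(_Strict):
    kind: Literal["waiting"]
    duration: float = Field(ge=0)


StageConfig = Annotated[
    Union[
        InformationStageConfig,
        QuestionnaireStageConfig,
        IncentivisedTaskStageConfig,
        ModelStageConfig,
        WaitingStageConfig,
    ],
    Field(discriminator="kind"),
]


class RunConfig(_Strict):
    """Complete run description: model, engine, agents, optional stages."""

    schema_version: Literal[1] = SCHEMA_VERSION
    seed: int = 0
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    engine: EngineConfig = Field(default_factory=EngineConfig)
    agents: list[AgentConfig] = Field(min_length=1)
    stages: list[StageConfig] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_agent_ids(self) -> "RunConfig":
        ids = [a.id for a in self.agents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate agent ids")
        return self


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def canonical_json(cfg: RunConfig) -> str:
    """Canonical text form: sorted keys, 2-space indent, trailing newline."""
    return json.dumps(cfg.model_dump(mode="json"), sort_keys=True, indent=2) + "\n"


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(canonical_json(cfg).encode("utf-8")).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    return parse_config(raw, source=str(path))


def parse_config(raw: Mapping[str, Any], source: str = "<config>") -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{source}: {_format_validation_error(exc)}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(canonical_json(cfg), encoding="utf-8")


def build_policies(cfg: RunConfig) -> dict[str, _agents.AgentPolicy]:
    """Instantiate the declared agent policies against the config's params."""
    params = cfg.params.to_params()
    out: dict[str, _agents.AgentPolicy] = {}
    for agent in cfg.agents:
        pc = agent.policy
        base: _agents.AgentPolicy
        if pc.kind == "constant":
            base = _agents.ConstantPolicy(pc.effort, decision_interval=pc.decision_interval)
        elif pc.kind == "myopic":
            base = _agents.MyopicPolicy(params, decision_interval=pc.decision_interval)
        elif pc.kind == "sustainable":
            base = _agents.SustainablePolicy(params, N=pc.N, decision_interval=pc.decision_interval)
        elif pc.kind == "threshold":
            base = _agents.ThresholdPolicy(
                params,
                floor=pc.floor,
                high_effort=pc.high_effort,
                low_effort=pc.low_effort,
                decision_interval=pc.decision_interval,
            )
        elif pc.kind == "scripted":
            base = _agents.ScriptedPolicy(pc.steps, decision_interval=pc.decision_interval)
        else:  # pragma: no cover - Literal exhausts kinds
            raise ConfigError(f"unknown policy kind {pc.kind!r}")
        if pc.noise_sd > 0:
            base = _agents.NoisyPolicy(base, sd=pc.noise_sd, E_max=params.E_max)
        out[agent.id] = base
    return out


def build_session(cfg: RunConfig, session_id: str = "session") -> _session.Session:
    """Materialise the config's stage list as a Session object."""
    params = cfg.params.to_params()
    stages: list[_session.Stage] = []
    for sc in cfg.stages:
        if isinstance(sc, InformationStageConfig):
            stages.append(_session.InformationStage(text=sc.text, media=sc.media))
        elif isinstance(sc, QuestionnaireStageConfig):
            stages.append(
                _session.QuestionnaireStage(
                    questions=[
                        _session.Question(qc.text, qc.answer_type) for qc in sc.questions
                    ],
                    fee=sc.fee,
                )
            )
        elif isinstance(sc, IncentivisedTaskStageConfig):
            stages.append(
                _session.IncentivisedTaskStage(
                    decisions=[
                        _session.AllocationDecisionSpec(
                            options=(
                                _session.AllocationOption(
                                    dc.options[0].self_amount, dc.options[0].other_amount
                                ),
                                _session.AllocationOption(
                                    dc.options[1].self_amount, dc.options[1].other_amount
                                ),
                            )
                        )
                        for dc in sc.decisions
                    ]
                )
            )
        elif isinstance(sc, ModelStageConfig):
            stages.append(
                _session.ModelStage(
                    params=params,
                    t_end=cfg.engine.t_end,
                    sample_dt=cfg.engine.sample_dt,
                    lockout=cfg.engine.lockout,
                    R0=cfg.engine.R0,
                    granularity=cfg.engine.granularity,
                    floor_earnings_at_zero=sc.floor_earnings_at_zero,
                )
            )
        elif isinstance(sc, WaitingStageConfig):
            stages.append(_session.WaitingStage(duration=sc.duration))
    return _session.Session(
        id=session_id, stages=stages, participants=[a.id for a in cfg.agents]
    )


# ---------------------------------------------------------------------------
# CSV logs

EVENT_COLUMNS = ["time_s", "agent_id", "effort", "accepted", "reason"]


def _fmt(x: float) -> str:
    # repr is the shortest decimal string that parses back to the same double
    return repr(float(x))


def _events_csv_text(events: Sequence[EventRecord]) -> str:
    lines = [",".join(EVENT_COLUMNS)]
    for rec in events:
        lines.append(
            ",".join(
                [
                    _fmt(rec.t),
                    rec.agent_id,
                    _fmt(rec.effort),
                    "true" if rec.accepted else "false",
                    rec.reason,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _trajectory_csv_text(traj: Trajectory) -> str:
    frame = traj.to_frame()
    lines = [",".join(frame.columns)]
    values = frame.to_numpy()
    for row in values:
        lines.append(",".join(_fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def _replay_fingerprint(
    params: SchaeferParams, settings: Mapping[str, float], agents: Sequence[str]
) -> str:
    payload = {
        "params": {
            "mu_R": params.mu_R,
            "K": params.K,
            "q": params.q,
            "p": params.p,
            "c": params.c,
            "E_max": params.E_max,
            "N": params.N,
        },
        "settings": {k: float(v) for k, v in sorted(settings.items())},
        "agents": list(agents),
    }
    text = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def write_logs(
    result: _agents.ExperimentResult,
    directory: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """Write events.csv, trajectory.csv and manifest.json for one run."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "events.csv").write_text(_events_csv_text(result.events), encoding="utf-8")
    (directory / "trajectory.csv").write_text(
        _trajectory_csv_text(result.trajectory), encoding="utf-8"
    )
    p = result.params
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": result.seed,
        "agents": list(result.trajectory.agents),
        "params": {
            "mu_R": p.mu_R,
            "K": p.K,
            "q": p.q,
            "p": p.p,
            "c": p.c,
            "E_max": p.E_max,
            "N": p.N,
        },
        "settings": dict(result.settings),
        "content_hash": _replay_fingerprint(p, result.settings, result.trajectory.agents),
    }
    if config is not None:
        manifest["config_hash"] = config_hash(config)
        save_config(config, directory / "config.json")
    (directory / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return directory


@dataclass
class LogBundle:
    """Parsed contents of a run-log directory."""

    events: list[EventRecord]
    trajectory: Trajectory
    manifest: dict


def _parse_float(value: str, path: Path, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise LogParseError(
            f"{path}: row {row}: column {column!r} is not a number: {value!r}"
        ) from None


def _read_events_csv(path: Path) -> list[EventRecord]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in EVENT_COLUMNS if c not in header]
        if missing:
            raise LogParseError(f"{path}: missing column(s) {missing}")
        out: list[EventRecord] = []
        for i, row in enumerate(reader, start=2):
            if row["accepted"] not in ("true", "false"):
                raise LogParseError(
                    f"{path}: row {i}: column 'accepted' must be true/false, "
                    f"got {row['accepted']!r}"
                )
            out.append(
                EventRecord(
                    t=_parse_float(row["time_s"], path, i, "time_s"),
                    agent_id=row["agent_id"],
                    effort=_parse_float(row["effort"], path, i, "effort"),
                    accepted=row["accepted"] == "true",
                    reason=row["reason"] or "",
                )
            )
    return out


def _read_trajectory_csv(path: Path, agents: Sequence[str]) -> Trajectory:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        per_agent = ["effort", "harvest_rate", "return_rate", "cum_harvest", "cum_return"]
        needed = ["time_s", "resource"] + [
            f"{aid}_{suffix}" for aid in agents for suffix in per_agent
        ]
        missing = [c for c in needed if c not in header]
        if missing:
            raise LogParseError(f"{path}: missing column(s) {missing}")
        rows: list[dict[str, float]] = []
        prev_t = -np.inf
        for i, row in enumerate(reader, start=2):
            parsed = {c: _parse_float(row[c], path, i, c) for c in needed}
            if not parsed["time_s"] > prev_t:
                raise LogParseError(f"{path}: row {i}: time_s not strictly increasing")
            prev_t = parsed["time_s"]
            rows.append(parsed)
    n, m = len(rows), len(agents)

    def col(name: str) -> np.ndarray:
        return np.array([r[name] for r in rows], dtype=float)

    def stack(suffix: str) -> np.ndarray:
        if n == 0:
            return np.empty((0, m))
        return np.column_stack([col(f"{aid}_{suffix}") for aid in agents])

    return Trajectory(
        t=col("time_s"),
        R=col("resource"),
        agents=list(agents),
        effort=stack("effort"),
        harvest_rate=stack("harvest_rate"),
        return_rate=stack("return_rate"),
        cum_harvest=stack("cum_harvest"),
        cum_return=stack("cum_return"),
    )


def read_logs(directory: str | Path) -> LogBundle:
    """Read back a directory written by :func:`write_logs`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise LogParseError(f"{manifest_path}: not found") from None
    except json.JSONDecodeError as exc:
        raise LogParseError(f"{manifest_path}: invalid JSON: {exc}") from exc
    events = _read_events_csv(directory / "events.csv")
    trajectory = _read_trajectory_csv(directory / "trajectory.csv", manifest["agents"])
    return LogBundle(events=events, trajectory=trajectory, manifest=manifest)


def replay(directory: str | Path, config: RunConfig | None = None) -> Trajectory:
    """Re-run the integration from the logged accepted events.

    If a config is supplied, its replay-relevant content (parameters, engine
    settings, roster) must hash to the manifest's fingerprint; otherwise the
    replay is refused with both hashes in the error.
    """
    bundle = read_logs(directory)
    manifest = bundle.manifest
    params = SchaeferParams(**manifest["params"])
    settings = manifest["settings"]
    if config is not None:
        expected = _replay_fingerprint(
            config.params.to_params(),
            {
                "t_end": config.engine.t_end,
                "sample_dt": config.engine.sample_dt,
                "lockout": config.engine.lockout,
                "R0": config.engine.R0 if config.engine.R0 is not None else config.params.K,
                "granularity": config.engine.granularity,
            },
            manifest["agents"],
        )
        if expected != manifest["content_hash"]:
            raise ReplayError(
                "config does not match the logged run: "
                f"config fingerprint {expected} != manifest {manifest['content_hash']}"
            )
    schedule = EffortSchedule(
        [rec.event for rec in bundle.events if rec.accepted],
        agents=manifest["agents"],
    )
    return simulate(
        params,
        schedule,
        t_end=settings["t_end"],
        sample_dt=settings["sample_dt"],
        R0=settings.get("R0", params.K),
    )


def verify_replay(directory: str | Path, config: RunConfig | None = None) -> bool:
    """True iff the replayed trajectory reproduces trajectory.csv
    bit-for-bit at the serialized precision."""
    directory = Path(directory)
    replayed = replay(directory, config)
    stored = (directory / "trajectory.csv").read_text(encoding="utf-8")
    return _trajectory_csv_text(replayed) == stored


def write_session_report(report: _session.SessionReport, directory: str | Path) -> Path:
    """Serialize a session report: payoffs.csv, report.json and per-model-stage
    log subdirectories (the downloadable results bundle)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [
        "participant_id,model_earnings,questionnaire_fee,task_active,task_passive,total"
    ]
    for pid in sorted(report.payoffs):
        rec = report.payoffs[pid]
        lines.append(
            ",".join(
                [
                    pid,
                    _fmt(rec.model_earnings),
                    _fmt(rec.questionnaire_fee),
                    _fmt(rec.task_active),
                    _fmt(rec.task_passive),
                    _fmt(rec.total),
                ]
            )
        )
    (directory / "payoffs.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    stage_dump = [
        {"index": so.index, "kind": so.kind, "payload": _jsonable(so.payload)}
        for so in report.stage_outputs
    ]
    doc = {
        "session_id": report.session_id,
        "stages": stage_dump,
        "validation_errors": report.validation_errors,
    }
    (directory / "report.json").write_text(
        json.dumps(doc, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    for k, result in enumerate(report.experiment_results):
        write_logs(result, directory / f"model_{k}")
    return directory


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Client/server message contract (schema only; no transport)

_SUBMISSION_FIELDS = {
    "session": str,
    "agent": str,
    "t": (int, float),
    "effort": (int, float),
}

_BROADCAST_AGENT_FIELDS = ("effort", "harvest_rate", "return_rate", "cum_harvest", "cum_return")


def message_schema() -> dict:
    """The JSON shapes exchanged between client and server.

    ``submission`` is what a client sends when the slider moves;
    ``broadcast`` is the per-sample state the server pushes to every client.
    """
    return {
        "submission": {
            "type": "object",
            "required": ["session", "agent", "t", "effort"],
            "properties": {
                "session": {"type": "string"},
                "agent": {"type": "string"},
                "t": {"type": "number", "minimum": 0},
                "effort": {"type": "number", "minimum": 0},
            },
        },
        "broadcast": {
            "type": "object",
            "required": ["t", "resource", "agents"],
            "properties": {
                "t": {"type": "number", "minimum": 0},
                "resource": {"type": "number", "minimum": 0},
                "agents": {
                    "type": "object",
                    "additionalProperties": {
                        "type": "object",
                        "required": list(_BROADCAST_AGENT_FIELDS),
                        "properties": {
                            k: {"type": "number"} for k in _BROADCAST_AGENT_FIELDS
                        },
                    },
                },
            },
        },
    }


def validate_submission(msg: Any) -> list[str]:
    """Field-level errors for a client effort submission; empty means valid."""
    errors: list[str] = []
    if not isinstance(msg, dict):
        return ["message must be a JSON object"]
    for name, types in _SUBMISSION_FIELDS.items():
        if name not in msg:
            errors.append(f"missing field {name!r}")
        elif not isinstance(msg[name], types) or isinstance(msg[name], bool):
            errors.append(f"field {name!r} has wrong type")
    if not errors:
        if msg["t"] < 0:
            errors.append("field 't' must be non-negative")
        if msg["effort"] < 0:
            errors.append("field 'effort' must be non-negative")
    return errors


def validate_broadcast(msg: Any) -> list[str]:
    """Field-level errors for a server state broadcast; empty means valid."""
    errors: list[str] = []
    if not isinstance(msg, dict):
        return ["message must be a JSON object"]
    for name in ("t", "resource", "agents"):
        if name not in msg:
            errors.append(f"missing field {name!r}")
    for name in ("t", "resource"):
        if name in msg and (
            not isinstance(msg[name], (int, float)) or isinstance(msg[name], bool)
        ):
            errors.append(f"field {name!r} has wrong type")
    if "agents" not in msg:
        return errors
    if not isinstance(msg["agents"], dict):
        errors.append("field 'agents' must be an object")
        return errors
    for aid, entry in msg["agents"].items():
        if not isinstance(entry, dict):
            errors.append(f"agents.{aid}: must be an object")
            continue
        for k in _BROADCAST_AGENT_FIELDS:
            if k not in entry:
                errors.append(f"agents.{aid}: missing field {k!r}")
            elif not isinstance(entry[k], (int, float)) or isinstance(entry[k], bool):
                errors.append(f"agents.{aid}: field {k!r} has wrong type")
    return errors


def broadcast_from_sample(traj: Trajectory, index: int) -> dict:
    """Build the server->client broadcast message for one trajectory sample."""
    return {
        "t": float(traj.t[index]),
        "resource": float(traj.R[index]),
        "agents": {
            aid: {
                "effort": float(traj.effort[index, j]),
                "harvest_rate": float(traj.harvest_rate[index, j]),
                "return_rate": float(traj.return_rate[index, j]),
                "cum_harvest": float(traj.cum_harvest[index, j]),
                "cum_return": float(traj.cum_return[index, j]),
            }
            for j, aid in enumerate(traj.agents)
        },
    }
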