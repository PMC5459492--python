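"""Session orchestration: stages, the incentivised allocation task, payoffs.

A session is an ordered sequence of stages — information screens,
questionnaires (optionally carrying a flat participation fee), an
incentivised allocation task, model experiments, and waiting steps — that
every registered participant walks through in order. Stages may repeat. The
model stage starts simultaneously for all participants and delegates to the
synthetic-agent layer.

The incentivised task follows the random-incentive scheme common in
distributional-preference elicitation: participants are randomly paired and
each makes the same series of binary allocation choices (how much money for
myself, how much for my anonymous partner). At the end exactly one decision
index per pair is drawn, and each partner is paid the self-amount of their
own chosen option plus the other-amount of the partner's chosen option at
that index.

Final payoffs follow the pilot scheme: model-stage earnings (cumulative
return, floored at zero by default) + questionnaire fee + incentivised-task
payments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .agents import AgentPolicy, ExperimentResult, run_experiment
from .schaefer import SchaeferParams

__all__ = [
    "InformationStage",
    "Question",
    "QuestionnaireStage",
    "AllocationOption",
    "AllocationDecisionSpec",
    "IncentivisedTaskStage",
    "ModelStage",
    "WaitingStage",
    "Stage",
    "Session",
    "PayoffRecord",
    "SessionError",
    "SessionReport",
    "validate_session",
    "random_pairing",
    "resolve_incentivised_task",
    "compute_payoff",
    "run_session",
    "SyntheticParticipant",
    "QUESTIONNAIRE_FEE",
]

#: Flat questionnaire participation fee of the pilot scheme (EUR).
QUESTIONNAIRE_FEE = 2.0


@dataclass(frozen=True)
class InformationStage:
    text: str
    media: str | None = None
    kind: str = field(default="information", init=False)


@dataclass(frozen=True)
class Question:
    text: str
    answer_type: str = "text"  # "numeric" | "text"


@dataclass(frozen=True)
class QuestionnaireStage:
    questions: Sequence[Question]
    fee: float = QUESTIONNAIRE_FEE
    kind: str = field(default="questionnaire", init=False)


@dataclass(frozen=True)
class AllocationOption:
    """One allocation: money for the decider and for the passive partner."""

    self_amount: float
    other_amount: float


@dataclass(frozen=True)
class AllocationDecisionSpec:
    """A binary choice between two allocations."""

    options: tuple[AllocationOption, AllocationOption]


@dataclass(frozen=True)
class IncentivisedTaskStage:
    decisions: Sequence[AllocationDecisionSpec]
    kind: str = field(default="incentivised_task", init=False)


@dataclass(frozen=True)
class ModelStage:
    params: SchaeferParams
    t_end: float = 400.0
    sample_dt: float = 1.0
    lockout: float = 3.0
    R0: float | None = None
    granularity: float = 0.1
    floor_earnings_at_zero: bool = True
    kind: str = field(default="model", init=False)


@dataclass(frozen=True)
class WaitingStage:
    duration: float
    kind: str = field(default="waiting", init=False)


Stage = (
    InformationStage
    | QuestionnaireStage
    | IncentivisedTaskStage
    | ModelStage
    | WaitingStage
)

_SUBSTANTIVE = ("information", "questionnaire", "incentivised_task", "model")


@dataclass
class Session:
    """Ordered stage sequence with fixed start/end times and a roster."""

    id: str
    stages: Sequence[Stage]
    participants: Sequence[str]
    start_time: float = 0.0
    end_time: float = math.inf


@dataclass
class PayoffRecord:
    """Per-participant earnings ledger; ``total`` is the sum of components."""

    participant_id: str
    model_earnings: float = 0.0
    questionnaire_fee: float = 0.0
    task_active: float = 0.0
    task_passive: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.model_earnings
            + self.questionnaire_fee
            + self.task_active
            + self.task_passive
        )


class SessionError(RuntimeError):
    """A stage failed; carries the stage index in the message."""


def validate_session(session: Session) -> list[str]:
    """Check session invariants; returns a list of violations (empty = ok)."""
    violations: list[str] = []
    if not session.stages:
        violations.append("session has no stages")
    elif not any(st.kind in _SUBSTANTIVE for st in session.stages):
        violations.append("session contains only waiting stages")
    if not session.participants:
        violations.append("session has no registered participants")
    if len(set(session.participants)) != len(session.participants):
        violations.append("duplicate participant ids")
    if session.end_time < session.start_time:
        violations.append("end_time precedes start_time")
    for i, st in enumerate(session.stages):
        if isinstance(st, WaitingStage) and st.duration < 0:
            violations.append(f"stage {i}: negative waiting duration")
        if isinstance(st, QuestionnaireStage):
            for j, qu in enumerate(st.questions):
                if qu.answer_type not in ("numeric", "text"):
                    violations.append(
                        f"stage {i}: question {j} has invalid answer_type "
                        f"{qu.answer_type!r}"
                    )
            if st.fee < 0:
                violations.append(f"stage {i}: negative questionnaire fee")
        if isinstance(st, IncentivisedTaskStage) and not st.decisions:
            violations.append(f"stage {i}: incentivised task has no decisions")
        if isinstance(st, ModelStage) and not st.t_end > 0:
            violations.append(f"stage {i}: model stage t_end must be positive")
    return violations


def random_pairing(
    participants: Sequence[str], rng: np.random.Generator
) -> tuple[list[tuple[str, str]], list[str]]:
    """Randomly pair participants; the leftover of an odd count is returned."""
    order = list(participants)
    perm = rng.permutation(len(order))
    shuffled = [order[i] for i in perm]
    pairs = [
        (shuffled[i], shuffled[i + 1]) for i in range(0, len(shuffled) - 1, 2)
    ]
    leftovers = shuffled[len(pairs) * 2 :]
    return pairs, leftovers


def resolve_incentivised_task(
    task: IncentivisedTaskStage,
    pairs: Sequence[tuple[str, str]],
    choices: Mapping[str, Sequence[int]],
    seed: int | np.random.Generator | None = 0,
    leftovers: Sequence[str] = (),
) -> dict[str, dict[str, float]]:
    """Pay out one randomly selected decision per pair.

    ``choices[pid][d]`` is the option index (0 or 1) participant ``pid``
    chose for decision ``d``. For the drawn index each partner receives the
    self-amount of their own chosen option (as active decider) plus the
    other-amount of the partner's chosen option (as passive partner). An
    unpaired participant receives zero with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_dec = len(task.decisions)
    payments: dict[str, dict[str, float]] = {}
    for a, b in pairs:
        for pid in (a, b):
            got = choices.get(pid)
            if got is None or len(got) != n_dec:
                raise SessionError(
                    f"participant {pid!r} did not complete all {n_dec} decisions"
                )
        k = int(rng.integers(n_dec))
        opt_a = task.decisions[k].options[choices[a][k]]
        opt_b = task.decisions[k].options[choices[b][k]]
        payments[a] = {
            "active": opt_a.self_amount,
            "passive": opt_b.other_amount,
            "selected_decision": float(k),
        }
        payments[b] = {
            "active": opt_b.self_amount,
            "passive": opt_a.other_amount,
            "selected_decision": float(k),
        }
    for pid in leftovers:
        warnings.warn(f"participant {pid!r} is unpaired; zero task payment", stacklevel=2)
        payments[pid] = {"active": 0.0, "passive": 0.0, "selected_decision": -1.0}
    return payments


def compute_payoff(
    participant_id: str,
    *,
    model_earnings: float = 0.0,
    questionnaire_fee: float = 0.0,
    task_active: float = 0.0,
    task_passive: float = 0.0,
    floor_model_at_zero: bool = True,
) -> PayoffRecord:
    """Assemble the final payoff per the pilot scheme.

    Model-stage earnings are the participant's cumulative return from the
    harvesting experiment, floored at zero by default (subjects are not
    charged for losses); the questionnaire fee and the incentivised-task
    payments (active + passive) are added on top.
    """
    for name, v in (
        ("model_earnings", model_earnings),
        ("questionnaire_fee", questionnaire_fee),
        ("task_active", task_active),
        ("task_passive", task_passive),
    ):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    earnings = max(model_earnings, 0.0) if floor_model_at_zero else model_earnings
    return PayoffRecord(
        participant_id=participant_id,
        model_earnings=earnings,
        questionnaire_fee=questionnaire_fee,
        task_active=task_active,
        task_passive=task_passive,
    )


@dataclass
class SyntheticParticipant:
    """Scripted stand-in for a human: a harvesting policy plus canned
    questionnaire answers and allocation choices."""

    id: str
    policy: AgentPolicy | None = None
    questionnaire_answers: Sequence[str] = ()
    allocation_choices: Sequence[int] = ()


@dataclass
class StageOutput:
    index: int
    kind: str
    payload: dict


@dataclass
class SessionReport:
    """Everything a session produced: per-stage outputs, payoffs, logs."""

    session_id: str
    stage_outputs: list[StageOutput]
    payoffs: dict[str, PayoffRecord]
    experiment_results: list[ExperimentResult]
    validation_errors: list[str]


def _answer_valid(answer: str, answer_type: str) -> bool:
    if answer_type == "numeric":
        try:
            float(answer)
            return True
        except (TypeError, ValueError):
            return False
    return isinstance(answer, str)


def run_session(
    session: Session,
    participants: Sequence[SyntheticParticipant],
    seed: int | None = 0,
) -> SessionReport:
    """Execute every stage in order with synthetic participants.

    Participants proceed together: a stage's outputs never depend on later
    stages, and the model experiment starts simultaneously for everyone. A
    stage whose inputs are missing halts the session with a stage-indexed
    :class:`SessionError`. Invalid questionnaire answers are recorded, not
    fatal.
    """
    violations = validate_session(session)
    if violations:
        raise SessionError(f"invalid session: {'; '.join(violations)}")
    roster = {p.id for p in participants}
    missing = set(session.participants) - roster
    if missing:
        raise SessionError(f"registered participants without agents: {sorted(missing)}")
    people = [p for p in participants if p.id in set(session.participants)]

    ss = np.random.SeedSequence(seed)
    stage_streams = [np.random.default_rng(s) for s in ss.spawn(len(session.stages))]
    model_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(session.stages))]

    outputs: list[StageOutput] = []
    experiment_results: list[ExperimentResult] = []
    recorded_errors: list[str] = []
    ledger = {p.id: PayoffRecord(p.id) for p in people}

    for i, stage in enumerate(session.stages):
        try:
            if isinstance(stage, InformationStage):
                outputs.append(StageOutput(i, stage.kind, {"text": stage.text}))
            elif isinstance(stage, WaitingStage):
                outputs.append(StageOutput(i, stage.kind, {"duration": stage.duration}))
            elif isinstance(stage, QuestionnaireStage):
                answers: dict[str, list[dict]] = {}
                for p in people:
                    if len(p.questionnaire_answers) != len(stage.questions):
                        raise SessionError(
                            f"stage {i}: participant {p.id!r} answered "
                            f"{len(p.questionnaire_answers)} of {len(stage.questions)} questions"
                        )
                    rows = []
                    for qu, ans in zip(stage.questions, p.questionnaire_answers):
                        ok = _answer_valid(ans, qu.answer_type)
                        if not ok:
                            recorded_errors.append(
                                f"stage {i}: participant {p.id!r} gave non-"
                                f"{qu.answer_type} answer {ans!r} to {qu.text!r}"
                            )
                        rows.append({"question": qu.text, "answer": ans, "valid": ok})
                    answers[p.id] = rows
                    ledger[p.id].questionnaire_fee += stage.fee
                outputs.append(StageOutput(i, stage.kind, {"answers": answers, "fee": stage.fee}))
            elif isinstance(stage, IncentivisedTaskStage):
                n_dec = len(stage.decisions)
                choices: dict[str, Sequence[int]] = {}
                for p in people:
                    if len(p.allocation_choices) != n_dec:
                        raise SessionError(
                            f"stage {i}: participant {p.id!r} made "
                            f"{len(p.allocation_choices)} of {n_dec} allocation choices"
                        )
                    bad = [x for x in p.allocation_choices if x not in (0, 1)]
                    if bad:
                        raise SessionError(
                            f"stage {i}: participant {p.id!r} chose invalid option(s) {bad}"
                        )
                    choices[p.id] = p.allocation_choices
                pairs, leftovers = random_pairing([p.id for p in people], stage_streams[i])
                payments = resolve_incentivised_task(
                    stage, pairs, choices, seed=stage_streams[i], leftovers=leftovers
                )
                for pid, pay in payments.items():
                    ledger[pid].task_active += pay["active"]
                    ledger[pid].task_passive += pay["passive"]
                outputs.append(
                    StageOutput(i, stage.kind, {"pairs": pairs, "payments": payments})
                )
            elif isinstance(stage, ModelStage):
                policies = {p.id: p.policy for p in people}
                if any(pol is None for pol in policies.values()):
                    lacking = sorted(pid for pid, pol in policies.items() if pol is None)
                    raise SessionError(f"stage {i}: participants without a policy: {lacking}")
                result = run_experiment(
                    stage.params,
                    policies,  # type: ignore[arg-type]
                    stage.t_end,
                    sample_dt=stage.sample_dt,
                    lockout=stage.lockout,
                    seed=model_seeds[i],
                    R0=stage.R0,
                    granularity=stage.granularity,
                )
                experiment_results.append(result)
                for pid, earn in result.payoffs.items():
                    credited = max(earn, 0.0) if stage.floor_earnings_at_zero else earn
                    ledger[pid].model_earnings += credited
                outputs.append(
                    StageOutput(
                        i,
                        stage.kind,
                        {"payoffs": dict(result.payoffs), "final_resource": float(result.trajectory.R[-1])},
                    )
                )
            else:  # pragma: no cover - exhaustive over Stage union
                raise SessionError(f"stage {i}: unknown stage kind {stage!r}")
        except SessionError:
            raise
        except Exception as exc:
            raise SessionError(f"stage {i} ({stage.kind}) failed: {exc}") from exc

    return SessionReport(
        session_id=session.id,
        stage_outputs=outputs,
        payoffs=ledger,
        experiment_results=experiment_results,
        validation_errors=recorded_errors,
    )
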