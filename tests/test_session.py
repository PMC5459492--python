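"""Stage orchestration, the allocation task and the payoff scheme."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cprsim import (
    AllocationDecisionSpec,
    AllocationOption,
    IncentivisedTaskStage,
    InformationStage,
    ModelStage,
    MyopicPolicy,
    Question,
    QuestionnaireStage,
    Session,
    SessionError,
    SustainablePolicy,
    SyntheticParticipant,
    WaitingStage,
    compute_payoff,
    resolve_incentivised_task,
    run_session,
    validate_session,
)
from cprsim.session import QUESTIONNAIRE_FEE, random_pairing


def make_task(menus=None):
    menus = menus or [((10.0, 0.0), (4.0, 6.0))]
    return IncentivisedTaskStage(
        [
            AllocationDecisionSpec((AllocationOption(*o1), AllocationOption(*o2)))
            for o1, o2 in menus
        ]
    )


class TestValidateSession:
    def test_waiting_only_session_is_flagged(self):
        s = Session("s", [WaitingStage(5.0)], ["A"])
        assert any("only waiting" in v for v in validate_session(s))

    def test_pilot_layout_is_valid(self, params):
        s = Session(
            "pilot",
            [
                ModelStage(params),
                QuestionnaireStage([Question("age", "numeric")]),
                make_task(),
            ],
            ["A", "B"],
        )
        assert validate_session(s) == []

    def test_negative_waiting_duration_flagged(self, params):
        s = Session("s", [ModelStage(params), WaitingStage(-1.0)], ["A"])
        assert any("negative waiting" in v for v in validate_session(s))

    def test_stages_may_repeat(self, params):
        s = Session("s", [ModelStage(params), WaitingStage(2.0), ModelStage(params)], ["A"])
        assert validate_session(s) == []

    def test_bad_answer_type_flagged(self):
        s = Session("s", [QuestionnaireStage([Question("q", "boolean")])], ["A"])
        assert any("answer_type" in v for v in validate_session(s))


class TestIncentivisedTask:
    def test_worked_example(self):
        """A chooses (self 10, other 0); B chooses (self 4, other 6):
        A receives 10 + 6 = 16 and B receives 4 + 0 = 4."""
        task = make_task()
        pays = resolve_incentivised_task(task, [("A", "B")], {"A": [0], "B": [1]}, seed=0)
        assert pays["A"]["active"] + pays["A"]["passive"] == pytest.approx(16.0)
        assert pays["B"]["active"] + pays["B"]["passive"] == pytest.approx(4.0)

    def test_symmetric_options_pay_two_each(self):
        task = make_task([((1.0, 1.0), (1.0, 1.0)), ((1.0, 1.0), (1.0, 1.0))])
        pays = resolve_incentivised_task(task, [("A", "B")], {"A": [0, 1], "B": [1, 0]}, seed=3)
        for pid in ("A", "B"):
            assert pays[pid]["active"] + pays[pid]["passive"] == pytest.approx(2.0)

    def test_selection_deterministic_under_seed(self):
        task = make_task([((1.0, 0.0), (0.0, 1.0))] * 8)
        choices = {"A": [0] * 8, "B": [1] * 8}
        p1 = resolve_incentivised_task(task, [("A", "B")], choices, seed=5)
        p2 = resolve_incentivised_task(task, [("A", "B")], choices, seed=5)
        assert p1 == p2

    def test_incomplete_decisions_halt(self):
        with pytest.raises(SessionError, match="did not complete"):
            resolve_incentivised_task(make_task(), [("A", "B")], {"A": [0], "B": []}, seed=0)

    def test_unpaired_participant_gets_zero_with_warning(self):
        with pytest.warns(UserWarning, match="unpaired"):
            pays = resolve_incentivised_task(
                make_task(), [], {"C": [0]}, seed=0, leftovers=["C"]
            )
        assert pays["C"]["active"] == 0.0 and pays["C"]["passive"] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.tuples(st.floats(0, 20), st.floats(0, 20)),
                st.tuples(st.floats(0, 20), st.floats(0, 20)),
            ),
            min_size=1,
            max_size=6,
        ),
        st.data(),
    )
    def test_pair_payment_conservation(self, menus, data):
        """The pair's combined payment equals self+other of the two selected
        options, whatever the menu and choices."""
        task = make_task(menus)
        n = len(menus)
        ch_a = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        ch_b = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        pays = resolve_incentivised_task(task, [("A", "B")], {"A": ch_a, "B": ch_b}, seed=1)
        k = int(pays["A"]["selected_decision"])
        opt_a = task.decisions[k].options[ch_a[k]]
        opt_b = task.decisions[k].options[ch_b[k]]
        total = sum(pays[p]["active"] + pays[p]["passive"] for p in ("A", "B"))
        expected = opt_a.self_amount + opt_a.other_amount + opt_b.self_amount + opt_b.other_amount
        assert total == pytest.approx(expected)

    def test_random_pairing_covers_everyone(self):
        rng = np.random.default_rng(0)
        pairs, leftovers = random_pairing(["A", "B", "C", "D", "E"], rng)
        seen = [p for pair in pairs for p in pair] + leftovers
        assert sorted(seen) == ["A", "B", "C", "D", "E"]
        assert len(leftovers) == 1


class TestComputePayoff:
    def test_fee_only(self):
        rec = compute_payoff("A", questionnaire_fee=QUESTIONNAIRE_FEE)
        assert rec.total == pytest.approx(2.0)

    def test_all_zero(self):
        assert compute_payoff("A").total == 0.0

    def test_component_sum(self):
        rec = compute_payoff(
            "A", model_earnings=10.0, questionnaire_fee=2.0, task_active=3.75
        )
        assert rec.total == pytest.approx(15.75)

    def test_negative_model_earnings_floored_by_default(self):
        assert compute_payoff("A", model_earnings=-4.0).total == 0.0
        rec = compute_payoff("A", model_earnings=-4.0, floor_model_at_zero=False)
        assert rec.total == pytest.approx(-4.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0, 100),
        st.floats(0, 10),
        st.floats(0, 50),
        st.floats(0, 50),
    )
    def test_total_is_exact_component_sum(self, m, f, a, p):
        rec = compute_payoff(
            "x", model_earnings=m, questionnaire_fee=f, task_active=a, task_passive=p
        )
        assert rec.total == m + f + a + p

    def test_non_finite_component_rejected(self):
        with pytest.raises(ValueError, match="model_earnings"):
            compute_payoff("A", model_earnings=float("nan"))


class TestRunSession:
    def _participants(self, params, n=4):
        return [
            SyntheticParticipant(
                f"p{i}",
                policy=SustainablePolicy(params) if i % 2 else MyopicPolicy(params),
                questionnaire_answers=["30"],
                allocation_choices=[0],
            )
            for i in range(n)
        ]

    def test_information_only_session_pays_nothing(self, params):
        s = Session("s", [InformationStage("welcome")], ["p0"])
        rep = run_session(s, [SyntheticParticipant("p0")], seed=0)
        assert rep.payoffs["p0"].total == 0.0
        assert rep.stage_outputs[0].kind == "information"

    def test_pilot_shaped_session_end_to_end(self, params):
        s = Session(
            "pilot",
            [
                ModelStage(params, t_end=120.0),
                QuestionnaireStage([Question("age", "numeric")]),
                make_task(),
            ],
            [f"p{i}" for i in range(4)],
        )
        rep = run_session(s, self._participants(params), seed=1)
        assert len(rep.experiment_results) == 1
        kinds = [so.kind for so in rep.stage_outputs]
        assert kinds == ["model", "questionnaire", "incentivised_task"]
        for pid, rec in rep.payoffs.items():
            assert rec.questionnaire_fee == QUESTIONNAIRE_FEE
            assert rec.total == pytest.approx(
                rec.model_earnings + rec.questionnaire_fee + rec.task_active + rec.task_passive
            )

    def test_invalid_numeric_answer_recorded_not_fatal(self, params):
        s = Session("s", [QuestionnaireStage([Question("age", "numeric")])], ["p0"])
        rep = run_session(
            s, [SyntheticParticipant("p0", questionnaire_answers=["abc"])], seed=0
        )
        assert any("non-numeric" in e for e in rep.validation_errors)
        assert rep.payoffs["p0"].questionnaire_fee == QUESTIONNAIRE_FEE

    def test_missing_stage_inputs_halt_with_stage_index(self, params):
        s = Session("s", [make_task()], ["p0", "p1"])
        people = [
            SyntheticParticipant("p0", allocation_choices=[0]),
            SyntheticParticipant("p1", allocation_choices=[]),
        ]
        with pytest.raises(SessionError, match="stage 0"):
            run_session(s, people, seed=0)

    def test_participant_without_policy_halts_model_stage(self, params):
        s = Session("s", [ModelStage(params, t_end=50.0)], ["p0"])
        with pytest.raises(SessionError, match="stage 0"):
            run_session(s, [SyntheticParticipant("p0")], seed=0)

    def test_stage_outputs_do_not_depend_on_later_stages(self, params):
        base = [ModelStage(params, t_end=80.0), QuestionnaireStage([Question("age", "numeric")])]
        s1 = Session("s1", base, [f"p{i}" for i in range(4)])
        s2 = Session("s2", base + [make_task()], [f"p{i}" for i in range(4)])
        r1 = run_session(s1, self._participants(params), seed=3)
        r2 = run_session(s2, self._participants(params), seed=3)
        assert r1.stage_outputs[0].payload == r2.stage_outputs[0].payload

    def test_reproducible_given_seed(self, params):
        s = Session(
            "s", [ModelStage(params, t_end=60.0), make_task()], [f"p{i}" for i in range(4)]
        )
        r1 = run_session(s, self._participants(params), seed=9)
        r2 = run_session(s, self._participants(params), seed=9)
        assert {k: v.total for k, v in r1.payoffs.items()} == {
            k: v.total for k, v in r2.payoffs.items()
        }
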