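"""Exact inference on the three-variable causal networks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discaug import (
    Assignment,
    CausalStructure,
    CbnParams,
    Condition,
    IntegrationRule,
    build_joint,
    change_prediction,
    noisy_and,
    noisy_or,
    query,
    sweep_wa,
)
from discaug.cbn import FIG5_AND_PARAMS, FIG5_OR_PARAMS

from oracles import brute_force_joint, brute_force_query


def ce_params(**kw):
    defaults = dict(structure=CausalStructure.COMMON_EFFECT, pr_p=0.5, pr_r=0.5)
    defaults.update(kw)
    return CbnParams(**defaults)


def cc_params(**kw):
    defaults = dict(structure=CausalStructure.COMMON_CAUSE, pr_q=0.5)
    defaults.update(kw)
    return CbnParams(**defaults)


unit = st.floats(0.01, 0.99)


class TestIntegrationRules:
    @pytest.mark.parametrize(
        "kw, present, expected",
        [
            # deterministic system: equivalent to inclusive OR
            (dict(w_p=1, w_r=1, w_a=0), (True, False), 1.0),
            (dict(w_p=1, w_r=1, w_a=0), (False, False), 0.0),
            (dict(w_p=0.9, w_r=0.9, w_a=0.5), (True, True), 0.995),
            (dict(w_p=0.9, w_a=0.2), (True, False), 0.92),
        ],
    )
    def test_noisy_or(self, kw, present, expected):
        assert noisy_or(ce_params(**kw), *present) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "kw, present, expected",
        [
            (dict(w_pr=0.9, w_a=0), (True, True), 0.9),
            (dict(w_pr=0.9, w_a=0), (True, False), 0.0),
            (dict(w_pr=0.9, w_a=0.5), (False, False), 0.5),
            (dict(w_pr=0.9, w_a=0.5), (True, True), 0.95),
        ],
    )
    def test_noisy_and(self, kw, present, expected):
        params = ce_params(rule=IntegrationRule.NOISY_AND, **kw)
        assert noisy_and(params, *present) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(w_p=1.2),
            dict(w_a=-0.1),
            dict(pr_p=None),
            dict(rule=IntegrationRule.NOISY_AND),  # w_pr missing
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ce_params(**kw)


class TestJoint:
    def test_fig5_joint_matches_enumeration_oracle(self):
        params = ce_params(w_a=0.5, **FIG5_OR_PARAMS)
        joint = build_joint(params)
        oracle = brute_force_joint(params)
        for cell, value in oracle.items():
            assert joint.prob[cell] == pytest.approx(value, abs=1e-14)
        assert sum(joint.prob.values()) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_common_cause_links_variables(self):
        joint = build_joint(cc_params(w_p=1, w_r=1, w_a=0))
        # p = r = q exactly: only the all-true and all-false cells carry mass
        assert joint.prob[(True, True, True)] == pytest.approx(0.5)
        assert joint.prob[(False, False, False)] == pytest.approx(0.5)
        assert sum(abs(v) for c, v in joint.prob.items()
                   if c not in [(True,) * 3, (False,) * 3]) == 0.0

    def test_deterministic_or_truth_table(self):
        joint = build_joint(ce_params(w_p=1, w_r=1, w_a=0))
        for p, r in itertools.product((False, True), repeat=2):
            expected_q = p or r
            assert joint.prob[(p, not expected_q, r)] == pytest.approx(0.0, abs=1e-15)

    @given(pr_p=unit, pr_r=unit, w_p=unit, w_r=unit, w_a=unit)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_joint_normalizes_everywhere(self, pr_p, pr_r, w_p, w_r, w_a):
        joint = build_joint(ce_params(pr_p=pr_p, pr_r=pr_r, w_p=w_p, w_r=w_r, w_a=w_a))
        assert sum(joint.prob.values()) == pytest.approx(1.0, abs=1e-12)


class TestQuery:
    def test_marginal_equals_base_rate(self):
        joint = build_joint(ce_params(pr_p=0.3, w_p=0.8, w_a=0.1))
        assert query(joint, Assignment(p=True)) == pytest.approx(0.3, abs=1e-12)

    def test_conditioning_on_impossible_event_errors(self):
        joint = build_joint(ce_params(pr_p=0.0, w_p=0.8))
        with pytest.raises(ZeroDivisionError):
            query(joint, Assignment(r=True), Assignment(p=True))

    def test_empty_target_rejected(self):
        joint = build_joint(ce_params())
        with pytest.raises(ValueError):
            query(joint, Assignment())

    @given(pr_p=unit, pr_r=unit, w_p=unit, w_r=unit, w_a=unit)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_query_matches_enumeration_oracle(self, pr_p, pr_r, w_p, w_r, w_a):
        params = ce_params(pr_p=pr_p, pr_r=pr_r, w_p=w_p, w_r=w_r, w_a=w_a)
        joint = build_joint(params)
        cells = brute_force_joint(params)
        events = [{"p": True}, {"r": True}, {"q": True}, {"r": True, "q": True}]
        givens = [{}, {"q": True}, {"p": True, "q": True}, {"p": False}]
        for target in events:
            for given in givens:
                expected = brute_force_query(cells, target, given)
                got = query(joint, Assignment(**target), Assignment(**given))
                assert got == pytest.approx(expected, abs=1e-12)


class TestChangePrediction:
    def test_noisy_or_discounting_in_cec(self):
        pred = change_prediction(ce_params(w_a=0.5, **FIG5_OR_PARAMS), Condition.CEC)
        assert pred.sign == -1 and pred.magnitude < 0

    def test_cause_independence_in_cenc(self):
        pred = change_prediction(ce_params(w_a=0.5, **FIG5_OR_PARAMS), Condition.CENC)
        assert pred.sign == 0

    def test_screening_off_in_ecc(self):
        pred = change_prediction(cc_params(w_p=0.7, w_r=0.6, w_a=0.2), Condition.ECC)
        assert pred.sign == 0

    def test_augmentation_in_ecnc(self):
        pred = change_prediction(cc_params(w_p=0.7, w_r=0.6, w_a=0.2), Condition.ECNC)
        assert pred.sign == 1

    def test_structure_condition_mismatch_rejected(self):
        with pytest.raises(ValueError):
            change_prediction(ce_params(), Condition.ECC)
        with pytest.raises(ValueError):
            change_prediction(cc_params(), Condition.CEC)


class TestSweep:
    def test_default_grid_has_101_rows(self):
        table = sweep_wa(ce_params(**FIG5_OR_PARAMS))
        assert len(table) == 101
        assert list(table.columns) == ["w_a", "pr_r_given_q", "pr_r_given_pq"]

    def test_noisy_or_no_discounting_only_at_wa_one(self):
        table = sweep_wa(ce_params(**FIG5_OR_PARAMS), [0.0, 0.5, 1.0])
        diffs = table.pr_r_given_pq - table.pr_r_given_q
        assert (diffs.iloc[:2] < -1e-6).all()
        assert diffs.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_and_no_augmentation_at_wa_extremes(self):
        params = ce_params(rule=IntegrationRule.NOISY_AND, **FIG5_AND_PARAMS)
        table = sweep_wa(params, [0.0, 0.5, 1.0])
        diffs = table.pr_r_given_pq - table.pr_r_given_q
        assert diffs.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert diffs.iloc[1] > 1e-6
        assert diffs.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_sweep_point_matches_oracle(self):
        params = ce_params(w_a=0.3, **FIG5_OR_PARAMS)
        cells = brute_force_joint(params)
        table = sweep_wa(ce_params(**FIG5_OR_PARAMS), [0.3])
        assert table.pr_r_given_q.iloc[0] == pytest.approx(
            brute_force_query(cells, {"r": True}, {"q": True}), abs=1e-12
        )
        assert table.pr_r_given_pq.iloc[0] == pytest.approx(
            brute_force_query(cells, {"r": True}, {"p": True, "q": True}), abs=1e-12
        )
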