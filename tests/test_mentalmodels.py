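"""Possibility enumeration and naive-probability change predictions."""

import itertools
from fractions import Fraction

import pytest

from discaug import (
    Condition,
    Interpretation,
    ModelSet,
    Possibility,
    Theory,
    change_prediction_mm,
    conditionalize,
    enumerate_models,
    naive_prob,
    prediction_frame,
    prediction_table,
)

I = Interpretation
C = Condition


class TestEnumeration:
    @pytest.mark.parametrize(
        "interp, count",
        [
            (I.FULLY_FLESHED_OR, 5),
            (I.FULLY_FLESHED_AND, 5),
            (I.MATERIAL, 7),
            (I.MATERIAL_SOLE_CAUSES, 6),
            (I.ENABLES, 5),
            (I.BICONDITIONAL, 4),
            (I.SHALLOW_XOR, 2),
            (I.SHALLOW_AND, 1),
            (I.INITIAL_OR, 3),
            (I.INITIAL_AND, 1),
            (I.BASIC_CONDITIONAL, 3),
        ],
    )
    def test_possibility_counts(self, interp, count):
        assert len(enumerate_models(interp)) == count

    def test_disjunctive_recoding_rows(self):
        # "if p or r then q": every row with q true, plus neither-nor
        rows = set(
            (m.p, m.r, m.q) for m in enumerate_models(I.FULLY_FLESHED_OR).possibilities
        )
        assert rows == {
            (True, True, True),
            (True, False, True),
            (False, True, True),
            (False, False, True),
            (False, False, False),
        }

    def test_biconditional_matches_truth_condition(self):
        # independent check: filter all 8 triples by (p and r) <-> q
        expected = {
            (p, r, q)
            for p, r, q in itertools.product((True, False), repeat=3)
            if (p and r) == q
        }
        rows = set(
            (m.p, m.r, m.q) for m in enumerate_models(I.BICONDITIONAL).possibilities
        )
        assert rows == expected

    def test_no_duplicates_and_subset_of_all_triples(self):
        for interp in I:
            models = enumerate_models(interp)
            rows = [(m.p, m.r, m.q) for m in models.possibilities]
            assert len(set(rows)) == len(rows)
            assert len(rows) <= 8

    def test_initial_models_carry_implicit_marker(self):
        assert enumerate_models(I.INITIAL_OR).has_implicit_model
        assert enumerate_models(I.INITIAL_AND).has_implicit_model
        assert not enumerate_models(I.FULLY_FLESHED_OR).has_implicit_model


class TestNaiveProbability:
    def test_worked_fractions_disjunctive(self):
        models = enumerate_models(I.FULLY_FLESHED_OR)
        assert naive_prob(models, r=True) == Fraction(2, 5)
        assert naive_prob(conditionalize(models, p=True), r=True) == Fraction(1, 2)

    def test_worked_fractions_conjunctive(self):
        models = enumerate_models(I.FULLY_FLESHED_AND)
        assert naive_prob(models, r=True) == Fraction(3, 5)
        assert naive_prob(conditionalize(models, p=True), r=True) == Fraction(2, 3)
        assert naive_prob(conditionalize(models, q=True), r=True) == 1

    def test_tautological_event_has_probability_one(self):
        for interp in (I.FULLY_FLESHED_OR, I.MATERIAL, I.BICONDITIONAL):
            assert naive_prob(enumerate_models(interp)) == 1

    def test_modus_ponens_on_basic_conditional(self):
        models = enumerate_models(I.BASIC_CONDITIONAL)
        assert naive_prob(conditionalize(models, p=True), q=True) == 1

    def test_conditionalize_without_survivors_errors(self):
        with pytest.raises(ValueError):
            conditionalize(enumerate_models(I.SHALLOW_AND), p=False)

    @pytest.mark.parametrize(
        "interp",
        [I.FULLY_FLESHED_OR, I.FULLY_FLESHED_AND, I.MATERIAL,
         I.MATERIAL_SOLE_CAUSES, I.ENABLES, I.BICONDITIONAL],
    )
    def test_bayes_consistency(self, interp):
        # Pr(r | given) == Pr(r and given) / Pr(given), exactly
        models = enumerate_models(interp)
        for given in ({"p": True}, {"q": True}, {"p": True, "q": True},
                      {"p": False}, {"q": False}):
            denom = naive_prob(models, **given)
            if denom == 0:
                continue
            joint = naive_prob(models, r=True, **given)
            assert naive_prob(conditionalize(models, **given), r=True) == joint / denom

    def test_custom_weights_renormalize(self):
        base = enumerate_models(I.BASIC_CONDITIONAL)
        weighted = ModelSet(
            possibilities=base.possibilities,
            weights=(Fraction(1, 2), Fraction(1, 4), Fraction(1, 4)),
            interpretation=base.interpretation,
        )
        assert naive_prob(weighted, q=True) == Fraction(3, 4)
        cut = conditionalize(weighted, q=True)
        assert naive_prob(cut, p=True) == Fraction(2, 3)


class TestChangePredictions:
    @pytest.mark.parametrize(
        "interp, condition, magnitude",
        [
            (I.FULLY_FLESHED_OR, C.CENC, Fraction(1, 10)),
            (I.FULLY_FLESHED_OR, C.CEC, Fraction(0)),
            (I.FULLY_FLESHED_AND, C.ECNC, Fraction(1, 15)),
            (I.FULLY_FLESHED_AND, C.ECC, Fraction(0)),
            (I.MATERIAL_SOLE_CAUSES, C.CENC, Fraction(-1, 6)),
            (I.MATERIAL_SOLE_CAUSES, C.CEC, Fraction(-1, 6)),
        ],
    )
    def test_worked_differences(self, interp, condition, magnitude):
        pred = change_prediction_mm(interp, condition)
        assert pred.magnitude == magnitude

    def test_material_reading_signs(self):
        assert change_prediction_mm(I.MATERIAL, C.CEC).sign == 0
        assert change_prediction_mm(I.MATERIAL, C.CENC).sign == -1

    def test_enables_reading_signs(self):
        assert change_prediction_mm(I.ENABLES, C.CEC).sign == 0
        assert change_prediction_mm(I.ENABLES, C.CENC).sign == 1

    def test_biconditional_predicts_no_change(self):
        assert change_prediction_mm(I.BICONDITIONAL, C.CEC).sign == 0
        assert change_prediction_mm(I.BICONDITIONAL, C.CENC).sign == 0

    def test_initial_models_predict_nothing(self):
        pred = change_prediction_mm(I.INITIAL_OR, C.CENC)
        assert pred.sign == 0 and pred.magnitude is None and pred.theory is Theory.IM


class TestPredictionTable:
    def test_initial_models_flat_everywhere(self):
        for experiment in (1, 2):
            assert [p.sign for p in prediction_table(Theory.IM, experiment)] == [0] * 4

    def test_shallow_patterns_mirror_between_experiments(self):
        assert [p.sign for p in prediction_table(Theory.SHALLOW, 1)] == [-1, -1, 1, 1]
        assert [p.sign for p in prediction_table(Theory.SHALLOW, 2)] == [1, 1, -1, -1]

    def test_fully_fleshed_pattern_experiment_1(self):
        assert [p.sign for p in prediction_table(Theory.FM, 1)] == [0, 1, 0, 1]

    def test_causal_model_pattern(self):
        assert [p.sign for p in prediction_table(Theory.CM, 1)] == [-1, 0, 0, 1]
        assert [p.sign for p in prediction_table(Theory.CM, 2)] == [1, 0, -1, -1]

    def test_frame_export_is_tidy(self):
        frame = prediction_frame(1)
        assert list(frame.columns) == ["theory", "condition", "sign", "magnitude"]
        assert len(frame) == 16
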