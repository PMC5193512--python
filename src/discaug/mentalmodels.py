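"""Mental-model possibility sets and naive (equiprobable) probabilities.

Mental models theory represents a compound assertion as the list of
possibilities (truth-table rows) in which it is true.  Under the naive
probability assumption every represented possibility is equiprobable, so the
probability of an event is the proportion of possibilities satisfying it,
and conditioning excises the possibilities that violate the given facts and
re-distributes the mass uniformly over the survivors.

The rule pairs of the discounting/augmentation paradigm are assumed to be
recoded as a single conditional with a compound clause -- e.g. the causal
pair "if p then q; if r then q" as "if p or r, then q", the diagnostic pair
as "if q, then p and r".  Each supported :class:`Interpretation` names one
such recoding (or a pragmatically modulated reading of it: material,
sole-causes, enables, biconditional), or a truncated/shallow representation.

All arithmetic is exact (`fractions.Fraction`), so the worked fractions of
the theory (1/10, 1/15, -1/6, ...) come out as equalities, not tolerances.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .conditions import (
    CONDITIONS,
    ChangePrediction,
    Condition,
    Theory,
    sign_of,
)

__all__ = [
    "Possibility",
    "Interpretation",
    "ModelSet",
    "enumerate_models",
    "naive_prob",
    "conditionalize",
    "change_prediction_mm",
    "prediction_table",
    "prediction_frame",
]


@dataclass(frozen=True)
class Possibility:
    """A fully specified truth assignment; ``r=None`` for two-variable sets."""

    p: bool
    q: bool
    r: Optional[bool] = None

    def satisfies(self, p: Optional[bool] = None, q: Optional[bool] = None,
                  r: Optional[bool] = None) -> bool:
        if p is not None and self.p != p:
            return False
        if q is not None and self.q != q:
            return False
        if r is not None:
            if self.r is None:
                raise ValueError("event mentions r but the model set has no r variable")
            if self.r != r:
                return False
        return True


class Interpretation(enum.Enum):
    # fully fleshed-out recodings (Experiment 1 rule pairs)
    FULLY_FLESHED_OR = "fully_fleshed_or"  # if (p or r) then q -- causal pair
    FULLY_FLESHED_AND = "fully_fleshed_and"  # if q then (p and r) -- diagnostic pair
    # truncated initial models of the same recodings
    INITIAL_OR = "initial_or"
    INITIAL_AND = "initial_and"
    # readings of the conjunctive-antecedent conditional "if (p and r) then q"
    MATERIAL = "material"
    MATERIAL_SOLE_CAUSES = "material_sole_causes"
    ENABLES = "enables"  # reverse conditional: true if q false or (p and r) true
    BICONDITIONAL = "biconditional"
    # shallow encodings over the antecedents only
    SHALLOW_XOR = "shallow_xor"
    SHALLOW_AND = "shallow_and"
    # diagnostic disjunctive recoding "if q then (p or r)" (Experiment 2 EC pairs)
    FULLY_FLESHED_OR_DIAGNOSTIC = "fully_fleshed_or_diagnostic"
    # two-variable conditional "if p then q" (basic modus ponens model)
    BASIC_CONDITIONAL = "basic_conditional"


@dataclass(frozen=True)
class ModelSet:
    """An ordered, weighted set of distinct possibilities."""

    possibilities: Tuple[Possibility, ...]
    interpretation: Interpretation
    weights: Tuple[Fraction, ...] = field(default=())
    has_implicit_model: bool = False  # truncated initial models carry an ellipsis

    def __post_init__(self) -> None:
        if len(set(self.possibilities)) != len(self.possibilities):
            raise ValueError("possibilities must be distinct")
        if not self.weights:
            n = len(self.possibilities)
            object.__setattr__(
                self, "weights", tuple(Fraction(1, n) for _ in range(n))
            )
        if len(self.weights) != len(self.possibilities):
            raise ValueError("weights and possibilities must align")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")
        if sum(self.weights) != 1:
            total = sum(float(w) for w in self.weights)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"weights sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.possibilities)


_TRIPLES = [
    (p, r, q) for p in (True, False) for r in (True, False) for q in (True, False)
]

# truth conditions over (p, r, q) for the three-variable interpretations
_TRUTH: Dict[Interpretation, Callable[[bool, bool, bool], bool]] = {
    # material conditional with compound antecedent/consequent
    Interpretation.FULLY_FLESHED_OR: lambda p, r, q: (not (p or r)) or q,
    Interpretation.FULLY_FLESHED_AND: lambda p, r, q: (not q) or (p and r),
    Interpretation.FULLY_FLESHED_OR_DIAGNOSTIC: lambda p, r, q: (not q) or (p or r),
    Interpretation.MATERIAL: lambda p, r, q: (not (p and r)) or q,
    # sole causes: additionally, the effect cannot occur without a cause
    Interpretation.MATERIAL_SOLE_CAUSES: lambda p, r, q: ((not (p and r)) or q)
    and not (q and not (p or r)),
    # reverse conditional: true if the consequent is false or the antecedent true
    Interpretation.ENABLES: lambda p, r, q: (not q) or (p and r),
    Interpretation.BICONDITIONAL: lambda p, r, q: (p and r) == q,
}
# ENABLES and FULLY_FLESHED_AND share a truth condition but order their
# variables differently (antecedent-first); both reduce to the same set here.


def _three_var(interp: Interpretation) -> ModelSet:
    cond = _TRUTH[interp]
    rows = tuple(
        Possibility(p=p, r=r, q=q) for (p, r, q) in _TRIPLES if cond(p, r, q)
    )
    return ModelSet(possibilities=rows, interpretation=interp)


def enumerate_models(interp: Interpretation) -> ModelSet:
    """Possibility set for one interpretation of the (recoded) rule pair.

    Three-variable interpretations are produced by filtering all eight truth
    assignments of (p, r, q) with the interpretation's truth condition;
    shallow encodings range over (p, r) only; initial models are the
    truncated explicit possibilities plus an implicit-model marker.
    """
    if interp in _TRUTH:
        return _three_var(interp)
    if interp is Interpretation.SHALLOW_XOR:
        return ModelSet(
            possibilities=(
                Possibility(p=True, q=False, r=False),
                Possibility(p=False, q=False, r=True),
            ),
            interpretation=interp,
        )
    # shallow sets carry no q variable conceptually; q is stored False and
    # never queried, because shallow encoding ignores the consequent.
    if interp is Interpretation.SHALLOW_AND:
        return ModelSet(
            possibilities=(Possibility(p=True, q=False, r=True),),
            interpretation=interp,
        )
    if interp is Interpretation.INITIAL_OR:
        # explicit true-antecedent rows of "if (p or r) then q"
        return ModelSet(
            possibilities=(
                Possibility(p=True, r=True, q=True),
                Possibility(p=True, r=False, q=True),
                Possibility(p=False, r=True, q=True),
            ),
            interpretation=interp,
            has_implicit_model=True,
        )
    if interp is Interpretation.INITIAL_AND:
        return ModelSet(
            possibilities=(Possibility(p=True, r=True, q=True),),
            interpretation=interp,
            has_implicit_model=True,
        )
    if interp is Interpretation.BASIC_CONDITIONAL:
        # "if p then q" with the false-conditional row (p, not-q) excised
        return ModelSet(
            possibilities=(
                Possibility(p=True, q=True),
                Possibility(p=False, q=True),
                Possibility(p=False, q=False),
            ),
            interpretation=interp,
        )
    raise ValueError(f"unknown interpretation {interp}")


def naive_prob(models: ModelSet, p: Optional[bool] = None, q: Optional[bool] = None,
               r: Optional[bool] = None) -> Fraction:
    """Weighted proportion of possibilities satisfying the event."""
    if len(models) == 0:
        raise ValueError("empty model set")
    return sum(
        (w for poss, w in zip(models.possibilities, models.weights)
         if poss.satisfies(p=p, q=q, r=r)),
        Fraction(0),
    )


def conditionalize(models: ModelSet, p: Optional[bool] = None,
                   q: Optional[bool] = None, r: Optional[bool] = None) -> ModelSet:
    """Excise possibilities violating the given facts; renormalize the rest.

    With the default equiprobable weights the survivors are again
    equiprobable, which is the theory's re-distribution assumption.
    """
    kept = [
        (poss, w)
        for poss, w in zip(models.possibilities, models.weights)
        if poss.satisfies(p=p, q=q, r=r)
    ]
    if not kept:
        raise ValueError("conditioning event excludes every possibility")
    total = sum(w for _, w in kept)
    return ModelSet(
        possibilities=tuple(poss for poss, _ in kept),
        weights=tuple(w / total for _, w in kept),
        interpretation=models.interpretation,
        has_implicit_model=models.has_implicit_model,
    )


_SHALLOW = (Interpretation.SHALLOW_XOR, Interpretation.SHALLOW_AND)
_INITIAL = (Interpretation.INITIAL_OR, Interpretation.INITIAL_AND)


def _theory_tag(interp: Interpretation) -> Theory:
    if interp in _SHALLOW:
        return Theory.SHALLOW
    if interp in _INITIAL:
        return Theory.IM
    return Theory.FM


def change_prediction_mm(interp: Interpretation, condition: Condition) -> ChangePrediction:
    """Naive-probability change prediction for one design cell.

    magnitude = Pr(r | p [, q]) - Pr(r [| q]): the proportion of r-possibilities
    after additionally learning p, minus the proportion before, with q held in
    the condition whenever the consequent is stated to have occurred.
    """
    theory = _theory_tag(interp)
    if interp in _INITIAL:
        # Truncated models support no quantitative naive-probability change;
        # the theory's stated prediction is "no effect" in every cell.
        return ChangePrediction(condition=condition, sign=0, magnitude=None, theory=theory)
    if interp in _SHALLOW:
        return _shallow_prediction(interp, condition)
    models = enumerate_models(interp)
    if condition.consequent == "C":
        before = naive_prob(conditionalize(models, q=True), r=True)
        after = naive_prob(conditionalize(models, p=True, q=True), r=True)
    else:
        before = naive_prob(models, r=True)
        after = naive_prob(conditionalize(models, p=True), r=True)
    magnitude = after - before
    return ChangePrediction(
        condition=condition, sign=sign_of(magnitude), magnitude=magnitude, theory=theory
    )


def _shallow_prediction(interp: Interpretation, condition: Condition) -> ChangePrediction:
    # Shallow encoding ignores the consequent, so C and NC cells agree.
    # The exclusive-or reading says the antecedents exclude each other
    # (learning p rules out r -> discounting); the conjunctive reading says
    # they co-occur (learning p demands r -> augmenting).  The conjunctive
    # set's single possibility makes the literal naive difference degenerate
    # (Pr(r) = Pr(r|p) = 1), so signs carry the prediction.
    if interp is Interpretation.SHALLOW_XOR:
        models = enumerate_models(interp)
        magnitude = naive_prob(conditionalize(models, p=True), r=True) - naive_prob(
            models, r=True
        )  # 0 - 1/2 = -1/2
        return ChangePrediction(
            condition=condition, sign=sign_of(magnitude), magnitude=magnitude,
            theory=Theory.SHALLOW,
        )
    return ChangePrediction(
        condition=condition, sign=1, magnitude=None, theory=Theory.SHALLOW
    )


# Which interpretation represents each rule pair, per experiment.
# Experiment 1: causal pairs recode with OR, diagnostic pairs with AND.
# Experiment 2 reverses the recodings (conjunctive causes, disjunctive diagnoses).
_FM_INTERP = {
    (1, "CE"): Interpretation.FULLY_FLESHED_OR,
    (1, "EC"): Interpretation.FULLY_FLESHED_AND,
    (2, "CE"): Interpretation.MATERIAL,
    (2, "EC"): Interpretation.FULLY_FLESHED_OR_DIAGNOSTIC,
}
_SHALLOW_INTERP = {
    (1, "CE"): Interpretation.SHALLOW_XOR,
    (1, "EC"): Interpretation.SHALLOW_AND,
    (2, "CE"): Interpretation.SHALLOW_AND,
    (2, "EC"): Interpretation.SHALLOW_XOR,
}


def prediction_table(theory: Theory, experiment: int = 1) -> List[ChangePrediction]:
    """Four ChangePredictions (CEC, CENC, ECC, ECNC) for one theory.

    CM signs come from the causal Bayes net engine at a canonical
    parameterisation (base rates .2, powers .9, w_a = .5); only the signs are
    theory-level claims -- magnitudes depend on unreported parameters.  For
    Experiment 2's diagnostic pairs the mutually exclusive antecedents put
    any network implementation on the discounting side in both cells, so the
    signs are -1 regardless of the consequent.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    if theory is Theory.CM:
        return _cm_table(experiment)
    if theory is Theory.IM:
        return [
            ChangePrediction(condition=c, sign=0, magnitude=None, theory=Theory.IM)
            for c in CONDITIONS
        ]
    table = []
    interp_map = _SHALLOW_INTERP if theory is Theory.SHALLOW else _FM_INTERP
    for c in CONDITIONS:
        interp = interp_map[(experiment, c.causal_direction)]
        table.append(change_prediction_mm(interp, c))
    return table


def _cm_table(experiment: int) -> List[ChangePrediction]:
    from . import cbn  # local import to avoid a cycle at package import time

    canonical_or = cbn.CbnParams(
        structure=cbn.CausalStructure.COMMON_EFFECT,
        w_a=0.5, **cbn.FIG5_OR_PARAMS,
    )
    canonical_cc = cbn.CbnParams(
        structure=cbn.CausalStructure.COMMON_CAUSE,
        pr_q=0.5, w_p=0.9, w_r=0.9, w_a=0.2,
    )
    canonical_and = cbn.CbnParams(
        structure=cbn.CausalStructure.COMMON_EFFECT,
        w_a=0.5, w_p=0.0, w_r=0.0, rule=cbn.IntegrationRule.NOISY_AND,
        **cbn.FIG5_AND_PARAMS,
    )
    table = []
    for c in CONDITIONS:
        if c.causal_direction == "CE":
            params = canonical_or if experiment == 1 else canonical_and
            pred = cbn.change_prediction(params, c)
            table.append(
                ChangePrediction(condition=c, sign=pred.sign, magnitude=None,
                                 theory=Theory.CM)
            )
        elif experiment == 1:
            pred = cbn.change_prediction(canonical_cc, c)
            table.append(
                ChangePrediction(condition=c, sign=pred.sign, magnitude=None,
                                 theory=Theory.CM)
            )
        else:
            # Exp 2 diagnostic pairs: exclusive alternatives (e.g. glasses vs
            # contact lenses) -> discounting whether or not q is known.
            table.append(
                ChangePrediction(condition=c, sign=-1, magnitude=None, theory=Theory.CM)
            )
    return table


def prediction_frame(experiment: int = 1,
                     theories: Sequence[Theory] = tuple(Theory)) -> pd.DataFrame:
    """All theories' sign predictions as a tidy frame (theory, condition, sign, magnitude)."""
    rows = []
    for theory in theories:
        for pred in prediction_table(theory, experiment):
            rows.append(
                {
                    "theory": theory.value,
                    "condition": pred.condition.value,
                    "sign": pred.sign,
                    "magnitude": None if pred.magnitude is None else float(pred.magnitude),
                }
            )
    return pd.DataFrame(rows)
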