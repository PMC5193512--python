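"""Exact inference on three-variable causal Bayes nets.

Two network structures carry the theory's predictions:

* **common effect** -- two independent (or conjunctive) causes p and r of an
  effect q, integrated by a noisy-OR (or noisy-AND) rule.  Learning that one
  cause holds, given the effect occurred, lowers (noisy-OR: *discounting*,
  explaining away) or raises (noisy-AND: *augmentation*) the probability of
  the other cause.
* **common cause** -- one cause q of two effects p and r.  Given q the effects
  are screened off (independent); with q unknown, one effect raises the
  probability of the other (*augmentation*).

The networks are small enough that everything is computed by exact
enumeration of the eight joint assignments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .conditions import ChangePrediction, Condition, Theory, sign_of

__all__ = [
    "CausalStructure",
    "IntegrationRule",
    "CbnParams",
    "Assignment",
    "JointTable",
    "noisy_or",
    "noisy_and",
    "build_joint",
    "query",
    "change_prediction",
    "sweep_wa",
    "FIG5_OR_PARAMS",
    "FIG5_AND_PARAMS",
]

VARS = ("p", "q", "r")


class CausalStructure(enum.Enum):
    COMMON_EFFECT = "common_effect"  # p -> q <- r
    COMMON_CAUSE = "common_cause"  # p <- q -> r


class IntegrationRule(enum.Enum):
    NOISY_OR = "noisy_or"
    NOISY_AND = "noisy_and"


def _check_prob(name: str, value: Optional[float], required: bool) -> None:
    if value is None:
        if required:
            raise ValueError(f"parameter {name!r} is required")
        return
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"parameter {name!r} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class CbnParams:
    """Parameters of a three-variable causal network.

    ``w_p``/``w_r`` are causal powers: the probability that the single cause
    produces its effect absent all other causes.  ``w_a`` aggregates
    unmodelled background causes.  For the noisy-AND rule the conjunction
    p-and-r acts through a single conjunctive power ``w_pr``.
    """

    structure: CausalStructure
    w_p: float = 0.0
    w_r: float = 0.0
    w_a: float = 0.0
    pr_p: Optional[float] = None  # base rate of cause p (common effect)
    pr_r: Optional[float] = None  # base rate of cause r (common effect)
    pr_q: Optional[float] = None  # base rate of cause q (common cause)
    w_pr: Optional[float] = None  # conjunctive power (noisy-AND only)
    rule: IntegrationRule = IntegrationRule.NOISY_OR

    def __post_init__(self) -> None:
        common_effect = self.structure is CausalStructure.COMMON_EFFECT
        _check_prob("w_p", self.w_p, required=True)
        _check_prob("w_r", self.w_r, required=True)
        _check_prob("w_a", self.w_a, required=True)
        _check_prob("pr_p", self.pr_p, required=common_effect)
        _check_prob("pr_r", self.pr_r, required=common_effect)
        _check_prob("pr_q", self.pr_q, required=not common_effect)
        _check_prob(
            "w_pr", self.w_pr, required=self.rule is IntegrationRule.NOISY_AND
        )
        if self.rule is IntegrationRule.NOISY_AND and not common_effect:
            raise ValueError("noisy-AND integration applies to the common-effect structure")


#: Parameterisation used for the discounting/augmentation sweep figures:
#: base rates .2, causal powers .9, background weight varied.
FIG5_OR_PARAMS = dict(pr_p=0.2, pr_r=0.2, w_p=0.9, w_r=0.9)
FIG5_AND_PARAMS = dict(pr_p=0.2, pr_r=0.2, w_pr=0.9)


@dataclass(frozen=True)
class Assignment:
    """A (partial) truth assignment over (p, q, r); ``None`` = unqueried."""

    p: Optional[bool] = None
    q: Optional[bool] = None
    r: Optional[bool] = None

    def is_empty(self) -> bool:
        return self.p is None and self.q is None and self.r is None

    def matches(self, triple: Tuple[bool, bool, bool]) -> bool:
        p, q, r = triple
        for want, have in ((self.p, p), (self.q, q), (self.r, r)):
            if want is not None and want != have:
                return False
        return True


class JointTable:
    """Exact 8-cell joint distribution over (p, q, r)."""

    def __init__(self, prob: Dict[Tuple[bool, bool, bool], float]):
        if set(prob) != {
            (p, q, r) for p in (False, True) for q in (False, True) for r in (False, True)
        }:
            raise ValueError("joint table must cover all 8 assignments of (p, q, r)")
        total = 0.0
        for cell, value in prob.items():
            if value < -1e-15:
                raise ValueError(f"negative probability {value} at cell {cell}")
            total += value
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"joint table sums to {total}, not 1")
        self.prob = dict(prob)

    def mass(self, event: Assignment) -> float:
        return sum(v for cell, v in self.prob.items() if event.matches(cell))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"p": p, "q": q, "r": r, "prob": v}
            for (p, q, r), v in sorted(self.prob.items(), reverse=True)
        ]
        return pd.DataFrame(rows)


def noisy_or(params: CbnParams, p_present: bool, r_present: bool) -> float:
    """Pr(q | p, r) under independent causes: 1 - (1-w_a) * prod(1-w_i) over present causes."""
    if params.rule is not IntegrationRule.NOISY_OR:
        raise ValueError("noisy_or requires rule=NOISY_OR")
    if params.structure is not CausalStructure.COMMON_EFFECT:
        raise ValueError("noisy_or integrates causes of a common effect")
    leak = 1.0 - params.w_a
    if p_present:
        leak *= 1.0 - params.w_p
    if r_present:
        leak *= 1.0 - params.w_r
    return 1.0 - leak


def noisy_and(params: CbnParams, p_present: bool, r_present: bool) -> float:
    """Pr(q | p, r) under conjunctive causes: 1 - (1-w_a)(1-w_pr)^[p and r]."""
    if params.w_pr is None:
        raise ValueError("noisy_and requires the conjunctive power w_pr")
    if p_present and r_present:
        return 1.0 - (1.0 - params.w_a) * (1.0 - params.w_pr)
    return params.w_a


def _cpd_effect_given_cause(cause_present: bool, power: float, w_a: float) -> float:
    # single-parent noisy-OR: background plus, if present, the one cause
    if cause_present:
        return 1.0 - (1.0 - w_a) * (1.0 - power)
    return w_a


def build_joint(params: CbnParams) -> JointTable:
    """Multiply out the network's factorization into the exact 8-cell joint.

    Common effect: Pr(p,q,r) = Pr(p) Pr(r) Pr(q|p,r), with Pr(q|p,r) given by
    the integration rule.  Common cause: Pr(q) Pr(p|q) Pr(r|q), each effect a
    single-parent noisy-OR with power w_p / w_r and background w_a.
    """
    prob: Dict[Tuple[bool, bool, bool], float] = {}
    if params.structure is CausalStructure.COMMON_EFFECT:
        integrate = (
            noisy_or if params.rule is IntegrationRule.NOISY_OR else noisy_and
        )
        for p in (False, True):
            for r in (False, True):
                pq = integrate(params, p, r)
                base = (params.pr_p if p else 1.0 - params.pr_p) * (
                    params.pr_r if r else 1.0 - params.pr_r
                )
                prob[(p, True, r)] = base * pq
                prob[(p, False, r)] = base * (1.0 - pq)
    else:
        for q in (False, True):
            base = params.pr_q if q else 1.0 - params.pr_q
            pp = _cpd_effect_given_cause(q, params.w_p, params.w_a)
            pr = _cpd_effect_given_cause(q, params.w_r, params.w_a)
            for p in (False, True):
                for r in (False, True):
                    prob[(p, q, r)] = (
                        base
                        * (pp if p else 1.0 - pp)
                        * (pr if r else 1.0 - pr)
                    )
    return JointTable(prob)


def query(joint: JointTable, target: Assignment, given: Assignment = Assignment()) -> float:
    """Conditional probability Pr(target | given) by summation over the 8 cells."""
    if target.is_empty():
        raise ValueError("target assignment must set at least one variable")
    denom = joint.mass(given) if not given.is_empty() else 1.0
    if denom <= 0.0:
        raise ZeroDivisionError("conditioning event has probability 0")
    joint_event = Assignment(
        p=target.p if target.p is not None else given.p,
        q=target.q if target.q is not None else given.q,
        r=target.r if target.r is not None else given.r,
    )
    for var in VARS:
        t, g = getattr(target, var), getattr(given, var)
        if t is not None and g is not None and t != g:
            return 0.0
    return joint.mass(joint_event) / denom


def change_prediction(params: CbnParams, condition: Condition) -> ChangePrediction:
    """Causal-model prediction for one design cell.

    Consequent-present cells compare Pr(r | p, q) with Pr(r | q);
    consequent-absent cells compare Pr(r | p) with Pr(r).  The target/other
    roles of p and r are symmetric; r is used as the target throughout.
    """
    ce = params.structure is CausalStructure.COMMON_EFFECT
    if condition.causal_direction == "CE" and not ce:
        raise ValueError(f"{condition.name} requires a common-effect network")
    if condition.causal_direction == "EC" and ce:
        raise ValueError(f"{condition.name} requires a common-cause network")
    joint = build_joint(params)
    if condition.consequent == "C":
        after = query(joint, Assignment(r=True), Assignment(p=True, q=True))
        before = query(joint, Assignment(r=True), Assignment(q=True))
    else:
        after = query(joint, Assignment(r=True), Assignment(p=True))
        before = query(joint, Assignment(r=True))
    magnitude = after - before
    return ChangePrediction(
        condition=condition,
        sign=sign_of(magnitude),
        magnitude=magnitude,
        theory=Theory.CM,
    )


def sweep_wa(params: CbnParams, grid: Optional[Iterable[float]] = None) -> pd.DataFrame:
    """Trace Pr(r|q) and Pr(r|p,q) as the background-cause weight w_a varies.

    Returns a frame with columns ``w_a``, ``pr_r_given_q``, ``pr_r_given_pq``.
    Defaults to 101 evenly spaced values on [0, 1].
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    rows: List[dict] = []
    for w_a in grid:
        if not (0.0 <= w_a <= 1.0):
            raise ValueError(f"grid value {w_a} outside [0, 1]")
        p = CbnParams(
            structure=params.structure,
            w_p=params.w_p,
            w_r=params.w_r,
            w_a=float(w_a),
            pr_p=params.pr_p,
            pr_r=params.pr_r,
            pr_q=params.pr_q,
            w_pr=params.w_pr,
            rule=params.rule,
        )
        joint = build_joint(p)
        rows.append(
            {
                "w_a": float(w_a),
                "pr_r_given_q": query(joint, Assignment(r=True), Assignment(q=True)),
                "pr_r_given_pq": query(
                    joint, Assignment(r=True), Assignment(p=True, q=True)
                ),
            }
        )
    return pd.DataFrame(rows)
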