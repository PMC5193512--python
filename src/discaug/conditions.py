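"""Shared vocabulary for the 2x2 within-subject design and theory predictions.

The experimental paradigm crosses causal direction of a rule pair -- causal
(CE: ``if p then q``, ``if r then q``) versus diagnostic (EC: ``if q then p``,
``if q then r``) -- with whether the consequent q is stated to have occurred
(C) or left unknown (NC).  In every condition the reasoner first entertains
the target cause/effect, then learns that the other antecedent holds, and
reports whether the target became more, equally, or less likely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

Magnitude = Union[float, Fraction]

#: Numerical noise floor below which a predicted change counts as "no change".
SIGN_EPS = 1e-12


class Condition(enum.Enum):
    """One cell of the causal-direction x consequent design."""

    CEC = "CEC"  # causal rules, consequent (effect) known
    CENC = "CENC"  # causal rules, consequent unknown
    ECC = "ECC"  # diagnostic rules, consequent (cause) known
    ECNC = "ECNC"  # diagnostic rules, consequent unknown

    @property
    def causal_direction(self) -> str:
        return "CE" if self.name.startswith("CE") else "EC"

    @property
    def consequent(self) -> str:
        return "NC" if self.name.endswith("NC") else "C"


class Theory(enum.Enum):
    """Competing accounts of the change-rating pattern."""

    CM = "CM"  # causal model theory (causal Bayes nets)
    FM = "FM"  # fully fleshed-out mental models
    IM = "IM"  # initial (truncated) mental models
    SHALLOW = "SHALLOW"  # shallow encoding of the recoded antecedents


CONDITIONS = (Condition.CEC, Condition.CENC, Condition.ECC, Condition.ECNC)


def sign_of(magnitude: Magnitude, eps: float = SIGN_EPS) -> int:
    """Map a signed change magnitude to {-1, 0, +1}, treating |m| < eps as 0."""
    m = float(magnitude)
    if abs(m) < eps:
        return 0
    return 1 if m > 0 else -1


@dataclass(frozen=True)
class ChangePrediction:
    """Predicted direction (and, when defined, size) of the likelihood change.

    ``magnitude`` is the probability difference the theory computes for the
    condition (e.g. Pr(r|p,q) - Pr(r|q) in a consequent-present condition);
    ``None`` marks predictions the theory states only qualitatively.
    """

    condition: Condition
    sign: int
    magnitude: Optional[Magnitude]
    theory: Theory

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be in {{-1,0,1}}, got {self.sign}")
        if self.magnitude is not None and sign_of(self.magnitude) != self.sign:
            raise ValueError(
                f"sign {self.sign} inconsistent with magnitude {self.magnitude}"
            )
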