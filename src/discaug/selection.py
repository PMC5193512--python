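"""Model ladders, BIC-approximation Bayes factors, and theory adjudication.

Each published analysis compares a sequence ("ladder") of cumulative-link
mixed models, each to its predecessor, by the G^2 likelihood ratio and a
Bayes factor approximated from the BIC difference.  The Bayes factor here
follows the form the source tables print, BF = exp(BIC_prev - BIC_curr)
(no 1/2 factor); the conventional Schwarz approximation
exp((BIC_prev - BIC_curr)/2) is available behind a flag.

The ladder rows double as theory tests: the null model is the initial
mental-models prediction (no effects), a causal-direction + consequent
model is the causal-model prediction, and a consequent-only model is the
fully fleshed-out mental-models prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .clmm import (
    ClmFit,
    ClmSpec,
    RandomTerm,
    fit_clm,
    loglik_ratio_test,
)
from .conditions import Theory
from .simulate import TrialRecord

__all__ = [
    "ComparisonRow",
    "bayes_factor_bic",
    "format_bf",
    "run_ladder",
    "ladder_frame",
    "theory_adjudication",
    "AdjudicationReport",
    "ADJUDICATION_LADDER",
]


def bayes_factor_bic(bic_prev: float, bic_curr: float, schwarz: bool = False) -> float:
    """Evidence for the current model over the previous one from their BICs.

    Default is the printed-table form exp(bic_prev - bic_curr); ``schwarz``
    selects the standard approximation exp((bic_prev - bic_curr) / 2).
    """
    if not (math.isfinite(bic_prev) and math.isfinite(bic_curr)):
        raise ValueError("BIC values must be finite")
    delta = bic_prev - bic_curr
    return math.exp(delta / 2.0) if schwarz else math.exp(delta)


def format_bf(bf: float) -> str:
    """Two decimals below 100, scientific notation (m.d x 10^k) above."""
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    if 0.005 <= bf < 100.0:
        return f"{bf:.2f}"
    exponent = math.floor(math.log10(bf))
    mantissa = bf / 10 ** exponent
    return f"{mantissa:.1f}x10^{exponent}"


@dataclass
class ComparisonRow:
    """One ladder row: a fit plus its comparison to the previous row."""

    label: str
    pars: int
    aic: float
    bic: float
    loglik: float
    lr_g2: Optional[float]  # None for the first row
    df: Optional[int]
    p: Optional[float]
    bf: Optional[float]
    fit: ClmFit


def run_ladder(
    records: Sequence[TrialRecord],
    ladder: Sequence[Tuple[str, ClmSpec]],
    schwarz: bool = False,
    method: str = "auto",
) -> List[ComparisonRow]:
    """Fit every spec in order and compare each to its predecessor."""
    if len(ladder) < 2:
        raise ValueError("a ladder needs at least 2 specifications")
    rows: List[ComparisonRow] = []
    prev: Optional[ClmFit] = None
    for label, spec in ladder:
        try:
            fit = fit_clm(records, spec, method=method)
        except Exception as exc:
            raise RuntimeError(f"ladder fit failed at {label!r}: {exc}") from exc
        if prev is None:
            g2 = df = p = bf = None
        else:
            g2, df, p = loglik_ratio_test(prev, fit, allow_nonnested=True)
            bf = bayes_factor_bic(prev.bic, fit.bic, schwarz=schwarz)
        rows.append(
            ComparisonRow(
                label=label,
                pars=fit.n_params,
                aic=fit.aic,
                bic=fit.bic,
                loglik=fit.loglik,
                lr_g2=g2,
                df=df,
                p=p,
                bf=bf,
                fit=fit,
            )
        )
        prev = fit
    return rows


def ladder_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Tabular view in the published column order: Model, Pars, AIC, BIC, LR, df, BF."""
    return pd.DataFrame(
        [
            {
                "Model": r.label,
                "Pars": r.pars,
                "AIC": round(r.aic, 1),
                "BIC": round(r.bic, 1),
                "LR": None if r.lr_g2 is None else round(r.lr_g2, 2),
                "df": r.df,
                "BF": None if r.bf is None else format_bf(r.bf),
            }
            for r in rows
        ]
    )


def _adjudication_specs() -> Tuple[Tuple[str, Theory, ClmSpec], ...]:
    base = (RandomTerm(factor="participant"), RandomTerm(factor="item"))
    return (
        ("CR ~ 1 + (1|P) + (1|I)", Theory.IM, ClmSpec(fixed=(), random=base)),
        ("CR ~ C + (1|P) + (1|I)", Theory.FM, ClmSpec(fixed=("C",), random=base)),
        (
            "CR ~ CD + C + (1|P) + (1|I)",
            Theory.CM,
            ClmSpec(fixed=("CD", "C"), random=base),
        ),
    )


ADJUDICATION_LADDER = tuple((label, spec) for label, _, spec in _adjudication_specs())


@dataclass
class AdjudicationReport:
    """Which theory's fixed-effect structure the BIC favors."""

    favored: Theory
    bic_by_theory: Dict[Theory, float]
    table: pd.DataFrame


def theory_adjudication(
    records: Sequence[TrialRecord], method: str = "auto"
) -> AdjudicationReport:
    """Fit the theory-indexed models and rank them by BIC.

    IM maps to the null (no-effect) model, FM to a consequent-only model,
    CM to causal-direction + consequent.  The favored theory is the one
    whose model minimizes BIC.
    """
    rows = []
    bics: Dict[Theory, float] = {}
    for label, theory, spec in _adjudication_specs():
        fit = fit_clm(records, spec, method=method)
        bics[theory] = fit.bic
        rows.append(
            {
                "theory": theory.value,
                "model": label,
                "pars": fit.n_params,
                "aic": fit.aic,
                "bic": fit.bic,
            }
        )
    favored = min(bics, key=bics.get)
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    return AdjudicationReport(favored=favored, bic_by_theory=bics, table=table)
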