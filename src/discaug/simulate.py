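"""Synthetic ordinal change-rating data with the experiments' design.

The generator is the exact generative dual of the cumulative-probit mixed
model used downstream: each participant x item trial has a latent value

    y* = effect_scale * sign(theory, condition) + u_participant + v_item + eps

with crossed Gaussian random effects u ~ N(0, sigma_participant^2),
v ~ N(0, sigma_item^2) and a standard-normal residual (the probit scale
convention), thresholded at theta1 < theta2 into the three ordered change
ratings -1 / 0 / +1.

Design structure: items (scenarios) are nested within design cells --
participants see different materials in the consequent and no-consequent
tasks -- and every participant rates every item once.  Default item counts
follow the two studies' surviving material pools: 10 causal + 7 diagnostic
scenarios (Experiment 1), 6 + 6 (Experiment 2), split as evenly as possible
between the C and NC cells.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, Condition, Theory

__all__ = [
    "TrialRecord",
    "SimConfig",
    "simulate_experiment",
    "write_trials",
    "read_trials",
    "records_to_frame",
    "frame_to_records",
    "EXPT1_ITEMS",
    "EXPT2_ITEMS",
]

#: Scenarios surviving the material pre-tests, per causal direction.
EXPT1_ITEMS: Dict[str, int] = {"CE": 10, "EC": 7}
EXPT2_ITEMS: Dict[str, int] = {"CE": 6, "EC": 6}

CSV_COLUMNS = ("participant_id", "item_id", "causal_direction", "consequent", "rating")


@dataclass(frozen=True)
class TrialRecord:
    """One participant x item x condition ordinal change rating."""

    participant_id: str
    item_id: str
    causal_direction: str  # "CE" or "EC"
    consequent: str  # "C" or "NC"
    rating: int  # -1 less likely, 0 equally likely, +1 more likely

    def __post_init__(self) -> None:
        if self.causal_direction not in ("CE", "EC"):
            raise ValueError(f"causal_direction must be CE/EC, got {self.causal_direction!r}")
        if self.consequent not in ("C", "NC"):
            raise ValueError(f"consequent must be C/NC, got {self.consequent!r}")
        if self.rating not in (-1, 0, 1):
            raise ValueError(f"rating must be -1/0/+1, got {self.rating!r}")

    @property
    def condition(self) -> Condition:
        return Condition(self.causal_direction + self.consequent)


def _theory_signs(theory: Theory, experiment: int) -> Dict[Condition, int]:
    from .mentalmodels import prediction_table

    return {p.condition: p.sign for p in prediction_table(theory, experiment)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    ``items_per_direction`` counts scenarios per causal direction (split
    across the C/NC cells).  ``cell_means`` overrides the theory-driven
    latent means directly when given, in latent-SD units.
    """

    n_participants: int = 40
    items_per_direction: Mapping[str, int] = field(
        default_factory=lambda: dict(EXPT1_ITEMS)
    )
    theory: Theory = Theory.CM
    experiment: int = 1
    effect_scale: float = 1.0
    sigma_participant: float = 0.5
    sigma_item: float = 0.3
    thresholds: Tuple[float, float] = (-0.43, 0.43)
    seed: int = 0
    cell_means: Optional[Mapping[Condition, float]] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for d in ("CE", "EC"):
            if self.items_per_direction.get(d, 0) < 1:
                raise ValueError(f"need at least one item in direction {d}")
        if self.sigma_participant < 0 or self.sigma_item < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must satisfy theta1 < theta2")
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")

    def latent_means(self) -> Dict[Condition, float]:
        if self.cell_means is not None:
            return {c: float(self.cell_means.get(c, 0.0)) for c in CONDITIONS}
        signs = _theory_signs(self.theory, self.experiment)
        return {c: self.effect_scale * signs[c] for c in CONDITIONS}


def _item_layout(config: SimConfig) -> List[Tuple[str, str, str]]:
    """(item_id, direction, consequent) triples; items nested in cells."""
    layout = []
    for direction in ("CE", "EC"):
        n = config.items_per_direction[direction]
        n_c = (n + 1) // 2  # odd pools put the extra item in the C cell
        for j in range(n):
            consequent = "C" if j < n_c else "NC"
            layout.append((f"{direction}{j + 1:02d}", direction, consequent))
    return layout


def simulate_experiment(config: SimConfig) -> List[TrialRecord]:
    """Draw one full dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    layout = _item_layout(config)
    means = config.latent_means()
    theta1, theta2 = config.thresholds

    u = rng.normal(0.0, config.sigma_participant, size=config.n_participants)
    v = rng.normal(0.0, config.sigma_item, size=len(layout))

    records: List[TrialRecord] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        eps = rng.normal(0.0, 1.0, size=len(layout))
        for j, (item_id, direction, consequent) in enumerate(layout):
            cond = Condition(direction + consequent)
            y = means[cond] + u[i] + v[j] + eps[j]
            rating = -1 if y <= theta1 else (0 if y <= theta2 else 1)
            records.append(
                TrialRecord(
                    participant_id=pid,
                    item_id=item_id,
                    causal_direction=direction,
                    consequent=consequent,
                    rating=rating,
                )
            )
    return records


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(CSV_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> List[TrialRecord]:
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                TrialRecord(
                    participant_id=str(row.participant_id),
                    item_id=str(row.item_id),
                    causal_direction=str(row.causal_direction),
                    consequent=str(row.consequent),
                    rating=int(row.rating),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"bad trial at row {idx + 1}: {exc}") from exc
    seen = set()
    for idx, r in enumerate(records):
        key = (r.participant_id, r.item_id, r.causal_direction, r.consequent)
        if key in seen:
            raise ValueError(f"duplicate participant/item/condition at row {idx + 1}")
        seen.add(key)
    return records


def write_trials(records: Sequence[TrialRecord], path) -> None:
    """Write trials as CSV with the canonical header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.participant_id, r.item_id, r.causal_direction, r.consequent, r.rating]
            )


def read_trials(path, column_map: Optional[Mapping[str, str]] = None,
                rating_map: Optional[Mapping[Union[str, int], int]] = None) -> List[TrialRecord]:
    """Read a trial CSV, optionally adapting a foreign schema.

    ``column_map`` maps canonical names to the file's column names (e.g.
    ``{"participant_id": "Subject"}``); ``rating_map`` recodes rating labels
    (e.g. ``{"less": -1, "same": 0, "more": 1}``).  Malformed rows are
    rejected with their row number.
    """
    frame = pd.read_csv(path, dtype=str)
    if column_map:
        missing = [src for src in column_map.values() if src not in frame.columns]
        if missing:
            raise ValueError(f"columns {missing} not found in {path}")
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    absent = [c for c in CSV_COLUMNS if c not in frame.columns]
    if absent:
        raise ValueError(f"missing required columns {absent} in {path}")
    if rating_map:
        norm = {str(k): v for k, v in rating_map.items()}
        try:
            frame["rating"] = frame["rating"].map(lambda s: norm[str(s)])
        except KeyError as exc:
            raise ValueError(f"rating value {exc} not covered by rating_map") from exc
    return frame_to_records(frame[list(CSV_COLUMNS)])
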