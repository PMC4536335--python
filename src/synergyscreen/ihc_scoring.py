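"""Immunohistochemistry product scoring (intensity x cellularity) and prevalence."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

__all__ = [
    "IHCObservation",
    "cellularity_grade",
    "expression_score",
    "prevalence",
    "PrevalenceSummary",
]

_VALID_GRADES = (0, 1, 2, 3)


def cellularity_grade(percent: float) -> int:
    """Band a stained-cell percentage into a cellularity grade.

    0% maps to grade 0; otherwise <=33% is 1, 34-65% is 2 and >=66% is 3.
    Fractional percentages are rounded half-up before banding.
    """
    if not (0 <= percent <= 100):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if percent == 0:
        return 0
    pct = math.floor(percent + 0.5)  # round half-up
    if pct <= 33:
        return 1 if pct > 0 else 0
    if pct <= 65:
        return 2
    return 3


def expression_score(intensity: int, cellularity: int) -> int:
    """Product score intensity x cellularity, each graded in {0, 1, 2, 3}."""
    for name, grade in (("intensity", intensity), ("cellularity", cellularity)):
        if not (isinstance(grade, (int,)) or float(grade).is_integer()):
            raise ValueError(f"{name} grade must be integral, got {grade}")
        if int(grade) not in _VALID_GRADES:
            raise ValueError(f"{name} grade must be in {_VALID_GRADES}, got {grade}")
    return int(intensity) * int(cellularity)


@dataclass(frozen=True)
class IHCObservation:
    """One scored sample.

    Either both grades are present (score derived as their product) or only a
    pre-computed product score is available. ``cellularity_is_percent`` marks
    raw staining percentages, which are banded with :func:`cellularity_grade`.
    Non-evaluable records (acellular / not assessable) carry ``evaluable=False``.
    """

    sample: str
    intensity: int | None = None
    cellularity: float | None = None
    evaluable: bool = True
    precomputed_score: int | None = None
    cellularity_is_percent: bool = False

    @property
    def score(self) -> int | None:
        if not self.evaluable:
            return None
        if self.precomputed_score is not None:
            return int(self.precomputed_score)
        if self.intensity is None or self.cellularity is None:
            return None
        cell = (
            cellularity_grade(self.cellularity)
            if self.cellularity_is_percent
            else int(self.cellularity)
        )
        return expression_score(int(self.intensity), cell)


class PrevalenceSummary(NamedTuple):
    positive: int
    evaluable: int
    fraction: float


def prevalence(
    observations: Iterable[IHCObservation],
    *,
    include_non_evaluable: bool = False,
) -> PrevalenceSummary:
    """Count score >= 1 records among evaluable ones.

    The denominator is evaluable records by default; set
    ``include_non_evaluable=True`` to divide by all records instead.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("empty observation list")
    scored = [o for o in obs if o.evaluable and o.score is not None]
    if not scored:
        raise ValueError("no evaluable records")
    positive = sum(1 for o in scored if o.score >= 1)
    denominator = len(obs) if include_non_evaluable else len(scored)
    return PrevalenceSummary(
        positive=positive, evaluable=denominator, fraction=positive / denominator
    )
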