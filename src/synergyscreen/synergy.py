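"""Combination-index computation for constant-ratio drug combinations.

Uses the mutually nonexclusive isobologram form

    CI = (D)1/(Dx)1 + (D)2/(Dx)2 + (D)1(D)2 / [(Dx)1 (Dx)2]

where (D)1, (D)2 are the component doses of the mixture achieving effect x
and (Dx)1, (Dx)2 are the iso-effective single-agent doses. CI < 1 indicates
synergism, CI = 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .dose_response import MedianEffectFit, dose_for_effect

__all__ = [
    "CombinationExperiment",
    "CIResult",
    "combination_index",
    "classify_ci",
    "ci_curve",
    "SUMMARY_FA",
]

#: default effect level for a single summary CI per experiment.
SUMMARY_FA = 0.5


@dataclass(frozen=True)
class CombinationExperiment:
    """Fits for two single agents and their constant-ratio mixture.

    ``fit_combo`` is fitted on the mixture's *total* concentration;
    ``fraction_a`` is drug 1's fraction of that total dose.
    """

    fit_a: MedianEffectFit
    fit_b: MedianEffectFit
    fit_combo: MedianEffectFit
    fraction_a: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_a < 1.0:
            raise ValueError(f"fraction_a must be in (0, 1), got {self.fraction_a}")


@dataclass(frozen=True)
class CIResult:
    effect_level: float
    ci: float
    classification: str

    def __post_init__(self) -> None:
        if self.ci <= 0:
            raise ValueError(f"ci must be positive, got {self.ci}")
        if self.classification not in {"synergism", "additive", "antagonism"}:
            raise ValueError(f"unknown classification {self.classification!r}")


def classify_ci(ci: float, additive_band: float = 0.0) -> str:
    """Classify a combination index with an optional additive tolerance band."""
    if ci <= 0:
        raise ValueError(f"ci must be positive, got {ci}")
    if additive_band < 0:
        raise ValueError("additive_band must be non-negative")
    if ci < 1.0 - additive_band:
        return "synergism"
    if ci > 1.0 + additive_band:
        return "antagonism"
    return "additive"


def combination_index(
    exp: CombinationExperiment, fa: float = SUMMARY_FA, *, additive_band: float = 0.0
) -> CIResult:
    """Combination index of ``exp`` at effect level ``fa``."""
    if not 0.0 < fa < 1.0:
        raise ValueError(f"effect level out of open interval (0, 1): {fa}")
    dc = dose_for_effect(exp.fit_combo, fa)
    d1 = exp.fraction_a * dc
    d2 = (1.0 - exp.fraction_a) * dc
    dx1 = dose_for_effect(exp.fit_a, fa)
    dx2 = dose_for_effect(exp.fit_b, fa)
    ci = d1 / dx1 + d2 / dx2 + (d1 * d2) / (dx1 * dx2)
    return CIResult(effect_level=fa, ci=float(ci), classification=classify_ci(ci, additive_band))


def ci_curve(
    exp: CombinationExperiment,
    fa_grid: Sequence[float],
    *,
    additive_band: float = 0.0,
) -> list[CIResult]:
    """One :class:`CIResult` per effect level in ``fa_grid``, in grid order."""
    grid = list(fa_grid)
    if not grid:
        raise ValueError("fa_grid must be non-empty")
    return [combination_index(exp, fa, additive_band=additive_band) for fa in grid]
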