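"""Median-effect dose-response model: normalization, fitting, prediction.

The dose-effect law used throughout is the two-parameter median-effect
model ``fa/fu = (D/Dm)^m`` with ``fa = 1 - viability`` and ``fu = 1 - fa``.
It is linear in log-log coordinates, so fitting is ordinary least squares
on ``(log10 D, log10(fa/fu))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponsePoint",
    "MedianEffectFit",
    "ViabilityTable",
    "normalize_viability",
    "fit_median_effect",
    "predict_fa",
    "dose_for_effect",
    "fit_table",
    "DEFAULT_FA_BOUNDS",
    "CONTROL_LABEL",
]

#: fa values outside these bounds are excluded from the linearized fit;
#: log(fa/fu) is undefined/unstable at the boundaries.
DEFAULT_FA_BOUNDS: tuple[float, float] = (0.01, 0.99)

#: drug label marking untreated-control rows in a :class:`ViabilityTable`.
CONTROL_LABEL = "untreated"


@dataclass(frozen=True)
class DoseResponsePoint:
    """One well: a dose and the viability fraction relative to control."""

    dose: float
    viability: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not (self.dose > 0 and math.isfinite(self.dose)):
            raise ValueError(f"dose must be strictly positive, got {self.dose}")
        if not (math.isfinite(self.viability) and self.viability >= 0):
            raise ValueError(
                f"viability must be finite and non-negative, got {self.viability}"
            )


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters for one agent.

    Attributes
    ----------
    Dm
        Dose producing a 50% effect (the model's IC50), same units as input doses.
    m
        Sigmoidicity exponent of the dose-effect curve.
    n_used
        Number of dose points that entered the linearized fit.
    r_squared
        Coefficient of determination of the log-log regression line.
    """

    Dm: float
    m: float
    n_used: int = 3
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if not (self.Dm > 0 and math.isfinite(self.Dm)):
            raise ValueError(f"Dm must be positive, got {self.Dm}")
        if not (self.m > 0 and math.isfinite(self.m)):
            raise ValueError(f"m must be positive, got {self.m}")
        if self.n_used < 3:
            raise ValueError(f"n_used must be >= 3, got {self.n_used}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")


_VIABILITY_COLUMNS = ("sample", "drug", "dose", "replicate", "viability")


@dataclass
class ViabilityTable:
    """Long-format viability data: one row per (sample, drug, dose, replicate).

    Untreated-control rows carry ``drug == CONTROL_LABEL`` and dose 0; all
    treated rows have strictly positive doses.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _VIABILITY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"viability table missing columns: {missing}")
        treated = self.data["drug"] != CONTROL_LABEL
        doses = pd.to_numeric(self.data.loc[treated, "dose"], errors="coerce")
        if doses.isna().any() or (doses <= 0).any():
            bad = self.data.loc[treated].index[(doses <= 0) | doses.isna()][0]
            raise ValueError(f"non-positive or unparseable dose at row {bad}")
        if not np.isfinite(self.data["viability"].to_numpy(float)).all():
            raise ValueError("viability values must be finite")

    def points(self, sample: str, drug: str) -> list[DoseResponsePoint]:
        """Treated points for one (sample, drug) as :class:`DoseResponsePoint`s."""
        sub = self.data[(self.data["sample"] == sample) & (self.data["drug"] == drug)]
        return [
            DoseResponsePoint(
                dose=float(r.dose), viability=float(r.viability), replicate_id=str(r.replicate)
            )
            for r in sub.itertuples()
        ]

    def agents(self) -> list[tuple[str, str]]:
        """Distinct (sample, drug) pairs excluding untreated controls."""
        sub = self.data[self.data["drug"] != CONTROL_LABEL]
        return sorted({(str(s), str(d)) for s, d in zip(sub["sample"], sub["drug"])})


def normalize_viability(
    raw_signals: pd.DataFrame,
    control_label: str = CONTROL_LABEL,
    *,
    plate_col: str = "sample",
    signal_col: str = "signal",
) -> ViabilityTable:
    """Convert raw plate signals to viability fractions of the untreated control.

    Each treated well's viability is its signal divided by the mean untreated
    signal on the same plate (``plate_col`` group). Replicates are retained as
    separate rows; values above 1 are kept (affected-fraction clipping happens
    at fit time).

    Raises
    ------
    ValueError
        If a plate has no controls (the plate is named) or a control mean
        is not strictly positive ("invalid control").
    """
    required = {plate_col, "drug", "dose", "replicate", signal_col}
    missing = required - set(raw_signals.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    out_rows = []
    for plate, grp in raw_signals.groupby(plate_col, sort=True):
        controls = grp.loc[grp["drug"] == control_label, signal_col]
        if controls.empty:
            raise ValueError(f"missing untreated controls for plate {plate!r}")
        control_mean = float(controls.mean())
        if not control_mean > 0:
            raise ValueError(f"invalid control: mean {control_mean} on plate {plate!r}")
        treated = grp[grp["drug"] != control_label]
        for r in treated.itertuples():
            out_rows.append(
                {
                    "sample": plate,
                    "drug": getattr(r, "drug"),
                    "dose": float(getattr(r, "dose")),
                    "replicate": getattr(r, "replicate"),
                    "viability": float(getattr(r, signal_col)) / control_mean,
                }
            )
    return ViabilityTable(pd.DataFrame(out_rows, columns=list(_VIABILITY_COLUMNS)))


def _usable_points(
    points: Sequence[DoseResponsePoint],
    fa_bounds: tuple[float, float],
    average_replicates: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Doses and fa values surviving replicate averaging and fa clipping."""
    doses = np.array([p.dose for p in points], dtype=float)
    via = np.array([p.viability for p in points], dtype=float)
    if average_replicates:
        frame = pd.DataFrame({"dose": doses, "viability": via})
        agg = frame.groupby("dose", sort=True)["viability"].mean()
        doses = agg.index.to_numpy(float)
        via = agg.to_numpy(float)
    fa = 1.0 - via
    lo, hi = fa_bounds
    keep = (fa >= lo) & (fa <= hi)
    return doses[keep], fa[keep]


def fit_median_effect(
    points: Iterable[DoseResponsePoint],
    *,
    fa_bounds: tuple[float, float] = DEFAULT_FA_BOUNDS,
    average_replicates: bool = True,
) -> MedianEffectFit:
    """Fit (Dm, m) by least squares on the log-log median-effect plot.

    Replicates are averaged per dose before clipping (set
    ``average_replicates=False`` for per-well fitting). Points whose affected
    fraction falls outside ``fa_bounds`` are excluded; at least 3 usable
    points are required.
    """
    points = list(points)
    doses, fa = _usable_points(points, fa_bounds, average_replicates)
    if len(doses) < 3:
        raise ValueError(
            f"insufficient points: {len(doses)} usable after clipping, need >= 3"
        )
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError(f"non-monotone dose-effect: fitted slope {m:.4g} <= 0")
    dm = 10.0 ** (-float(res.intercept) / m)
    r2 = float(res.rvalue) ** 2
    return MedianEffectFit(Dm=dm, m=m, n_used=int(len(doses)), r_squared=min(r2, 1.0))


def predict_fa(fit: MedianEffectFit, dose: float) -> float:
    """Affected fraction at ``dose``: (D/Dm)^m / (1 + (D/Dm)^m); 0 at dose 0."""
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    if dose == 0:
        return 0.0
    ratio = (dose / fit.Dm) ** fit.m
    return float(ratio / (1.0 + ratio))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing affected fraction ``fa``: Dm * (fa/(1-fa))^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise ValueError(f"effect level out of open interval (0, 1): {fa}")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def fit_table(
    table: ViabilityTable,
    *,
    fa_bounds: tuple[float, float] = DEFAULT_FA_BOUNDS,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Fit every (sample, drug) in a viability table.

    Returns a frame with columns sample, drug, Dm, m, n_used, r_squared.
    """
    rows = []
    for sample, drug in table.agents():
        fit = fit_median_effect(
            table.points(sample, drug),
            fa_bounds=fa_bounds,
            average_replicates=average_replicates,
        )
        rows.append(
            {
                "sample": sample,
                "drug": drug,
                "Dm": fit.Dm,
                "m": fit.m,
                "n_used": fit.n_used,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(rows, columns=["sample", "drug", "Dm", "m", "n_used", "r_squared"])
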