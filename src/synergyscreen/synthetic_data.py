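"""Seeded generators producing inputs with known ground truth.

Every generator is fully deterministic for a fixed :class:`SimulationConfig`
seed; independent named streams are derived from the seed so regenerating
one table never perturbs another.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import CONTROL_LABEL, MedianEffectFit, ViabilityTable, dose_for_effect, predict_fa
from .pca_survival import SurvivalRecord
from .signature_screen import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "gen_dose_response",
    "gen_combination",
    "gen_expression_phenotype",
    "gen_survival",
    "solve_combo_dm",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by all generators; ``seed`` fixes every random stream."""

    seed: int = 0
    dose_grid: tuple[float, ...] | None = None
    n_replicates: int = 3
    noise_cv: float = 0.0
    n_samples: int = 30
    n_signal_genes: int = 47
    n_null_genes: int = 103
    target_r: float = 0.95
    hazard_ratio: float = 2.5
    censoring_rate: float = 0.0
    baseline_hazard: float = 0.03

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name in ("n_replicates", "n_samples", "n_signal_genes", "n_null_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.target_r < 1:
            raise ValueError("target_r must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def gen_dose_response(
    Dm: float,
    m: float,
    config: SimulationConfig,
    *,
    sample: str = "S1",
    drug: str = "drugA",
) -> ViabilityTable:
    """Viability table following the median-effect law with multiplicative noise.

    viability = (1 - fa(D)) * (1 + eps), eps ~ Normal(0, noise_cv); the table
    includes untreated-control rows at viability ~ 1. The default dose grid is
    a twofold dilution series spanning Dm.
    """
    if Dm <= 0 or m <= 0:
        raise ValueError("Dm and m must be positive")
    doses = (
        np.asarray(config.dose_grid, dtype=float)
        if config.dose_grid is not None
        else Dm * 2.0 ** np.arange(-3, 5)
    )
    if doses.min() > Dm or doses.max() < Dm:
        warnings.warn(
            f"dose grid [{doses.min():g}, {doses.max():g}] does not span Dm={Dm:g}; "
            "fit will be ill-conditioned",
            stacklevel=2,
        )
    rng = _rng(config, f"dose|{sample}|{drug}")
    fit = MedianEffectFit(Dm=Dm, m=m)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for d in doses:
            via = (1.0 - predict_fa(fit, float(d))) * (
                1.0 + rng.normal(0.0, config.noise_cv) if config.noise_cv else 1.0
            )
            rows.append(
                {
                    "sample": sample,
                    "drug": drug,
                    "dose": float(d),
                    "replicate": f"r{rep}",
                    "viability": max(float(via), 0.0),
                }
            )
        control = 1.0 + (rng.normal(0.0, config.noise_cv) if config.noise_cv else 0.0)
        rows.append(
            {
                "sample": sample,
                "drug": CONTROL_LABEL,
                "dose": 0.0,
                "replicate": f"r{rep}",
                "viability": max(float(control), 0.0),
            }
        )
    return ViabilityTable(pd.DataFrame(rows))


def solve_combo_dm(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fraction_a: float,
    target_ci: float,
    *,
    fa_anchor: float = 0.5,
) -> float:
    """Total mixture dose Dc whose combination index at ``fa_anchor`` is ``target_ci``.

    Solves the quadratic (f/Dx1 + (1-f)/Dx2) Dc + [f(1-f)/(Dx1 Dx2)] Dc^2 = CI
    for its positive root; when anchored at fa = 0.5 this root is the
    mixture's Dm.
    """
    if target_ci <= 0:
        raise ValueError("target_ci must be positive")
    if not 0 < fraction_a < 1:
        raise ValueError("fraction_a must be in (0, 1)")
    dx1 = dose_for_effect(fit_a, fa_anchor)
    dx2 = dose_for_effect(fit_b, fa_anchor)
    quad = fraction_a * (1.0 - fraction_a) / (dx1 * dx2)
    lin = fraction_a / dx1 + (1.0 - fraction_a) / dx2
    disc = lin * lin + 4.0 * quad * target_ci
    dc = (-lin + np.sqrt(disc)) / (2.0 * quad)
    assert dc > 0, "positive root must exist for target_ci > 0"
    return float(dc)


def gen_combination(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fraction_a: float,
    m_combo: float,
    target_ci: float,
    config: SimulationConfig,
    *,
    sample: str = "S1",
    drug: str = "combo",
) -> ViabilityTable:
    """Mixture viability table whose true combination index at fa=0.5 is ``target_ci``."""
    dm_combo = solve_combo_dm(fit_a, fit_b, fraction_a, target_ci)
    return gen_dose_response(dm_combo, m_combo, config, sample=sample, drug=drug)


def gen_expression_phenotype(
    config: SimulationConfig,
    *,
    signal_gene_names: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, pd.Series, list[str]]:
    """Expression matrix with genes planted at ``target_r`` against log10 IC50.

    log10 IC50 is drawn Normal and standardized to z; each signal gene is
    ``r z + sqrt(1 - r^2) noise`` and null genes are independent standard
    normal. Returns (matrix, raw-scale IC50 series, planted gene names).
    """
    if config.n_samples < 4:
        raise ValueError("need n_samples >= 4")
    rng = _rng(config, "expression")
    if signal_gene_names is not None:
        signal_names = [str(g) for g in signal_gene_names]
    else:
        signal_names = [f"SIG{i:04d}" for i in range(config.n_signal_genes)]
    null_names = [f"NULL{i:04d}" for i in range(config.n_null_genes)]
    samples = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]

    log_ic50 = rng.normal(0.0, 0.5, size=config.n_samples)
    z = (log_ic50 - log_ic50.mean()) / log_ic50.std()
    r = config.target_r
    signal = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(
        (len(signal_names), config.n_samples)
    )
    nulls = rng.standard_normal((len(null_names), config.n_samples))
    values = pd.DataFrame(
        np.vstack([signal, nulls]), index=signal_names + null_names, columns=samples
    )
    ic50 = pd.Series(10.0**log_ic50, index=samples, name="ic50")
    return ExpressionMatrix(values), ic50, list(signal_names)


def _uniform_censor_horizon(
    lam_low: float, lam_high: float, n_low: int, n_high: int, rate: float
) -> float:
    """Uniform(0, tau) horizon giving pooled expected censoring ~= rate."""

    def expected(tau: float) -> float:
        def one(lam: float) -> float:
            return (1.0 - np.exp(-lam * tau)) / (lam * tau)

        return (n_low * one(lam_low) + n_high * one(lam_high)) / (n_low + n_high) - rate

    return brentq(expected, 1e-9, 1e9)


def gen_survival(
    low_samples: Sequence[str],
    high_samples: Sequence[str],
    hazard_ratio: float,
    config: SimulationConfig,
) -> list[SurvivalRecord]:
    """Exponential survival with a high-group hazard ``hazard_ratio`` times the low.

    Censoring is independent Uniform(0, tau) with tau chosen so the expected
    censored fraction approximates ``config.censoring_rate`` (no censoring
    when the rate is 0).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not low_samples or not high_samples:
        raise ValueError("both groups must be non-empty")
    rng = _rng(config, "survival")
    lam_low = config.baseline_hazard
    lam_high = hazard_ratio * lam_low
    records = []
    if config.censoring_rate > 0:
        tau = _uniform_censor_horizon(
            lam_low, lam_high, len(low_samples), len(high_samples), config.censoring_rate
        )
    for names, lam in ((low_samples, lam_low), (high_samples, lam_high)):
        t_event = rng.exponential(1.0 / lam, size=len(names))
        if config.censoring_rate > 0:
            t_censor = rng.uniform(0.0, tau, size=len(names))
            observed = np.minimum(t_event, t_censor)
            event = (t_event <= t_censor).astype(int)
        else:
            observed = t_event
            event = np.ones(len(names), dtype=int)
        records.extend(
            SurvivalRecord(sample=str(s), time=float(t), event=int(e))
            for s, t, e in zip(names, observed, event)
        )
    return records
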