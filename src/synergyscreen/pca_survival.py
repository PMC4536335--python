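"""First-principal-component signature scoring and survival association.

A signature model holds unit-norm loadings of the first principal component
of the standardized (per-gene centered, unit-variance) expression of a gene
set. Sample scores are the PC1 projections; samples are dichotomized at the
median score and the two groups are compared with the Kaplan-Meier
product-limit estimator and the two-group log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signature_screen import ExpressionMatrix

__all__ = [
    "SignatureModel",
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "fit_pc1",
    "fix_sign",
    "score_samples",
    "median_split",
    "km_estimate",
    "logrank_test",
]


@dataclass(frozen=True)
class SignatureModel:
    """PC1 loadings with the standardization used to fit them.

    ``weights`` has unit Euclidean norm; its sign is fixed by
    :func:`fix_sign` so that the sum of loadings is non-negative.
    """

    genes: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    center: np.ndarray = field(repr=False)
    scale: np.ndarray = field(repr=False)
    sign_convention: str = "loading-sum-nonnegative"

    def __post_init__(self) -> None:
        k = len(self.genes)
        for name in ("weights", "center", "scale"):
            arr = getattr(self, name)
            if len(arr) != k:
                raise ValueError(f"{name} length {len(arr)} != {k} genes")
        norm = float(np.sum(self.weights**2))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"sum of squared weights must be 1, got {norm}")


@dataclass(frozen=True)
class SurvivalRecord:
    sample: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.event_times) == len(self.survival_prob) == len(self.at_risk)):
            raise ValueError("KM curve arrays must have equal length")
        if len(self.survival_prob) and (
            np.any(np.diff(self.survival_prob) > 1e-12) or self.survival_prob[0] > 1
        ):
            raise ValueError("survival probabilities must start <= 1 and be nonincreasing")

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S(0) = 1)."""
        if t < 0:
            raise ValueError("time must be >= 0")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


class LogRankResult(NamedTuple):
    statistic: float
    p_value: float


def fit_pc1(expr: ExpressionMatrix) -> SignatureModel:
    """Fit unit-norm PC1 loadings on per-gene standardized expression.

    Genes are centered and scaled to unit variance (sample sd, ddof=1), so
    the loadings are the leading eigenvector of the gene-gene correlation
    matrix; computed via SVD so the smaller of (genes, samples) governs cost.
    """
    X = expr.values.to_numpy(float).T  # samples x genes
    if X.shape[1] < 2:
        raise ValueError(f"need >= 2 genes, got {X.shape[1]}")
    if X.shape[0] < 3:
        raise ValueError(f"need >= 3 samples, got {X.shape[0]}")
    if np.isnan(X).any():
        raise ValueError("missing values not supported when fitting the signature")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [g for g, s in zip(expr.genes, scale) if s == 0]
        raise ValueError(f"zero-variance gene(s): {bad}")
    Z = (X - center) / scale
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    weights = vt[0]
    weights = weights / np.linalg.norm(weights)
    model = SignatureModel(
        genes=tuple(expr.genes), weights=weights, center=center, scale=scale
    )
    return fix_sign(model)


def fix_sign(model: SignatureModel) -> SignatureModel:
    """Resolve the arbitrary PC sign: negate weights if their sum is negative.

    Flipping weights (and hence scores) by -1 leaves every downstream
    statistic unchanged apart from swapping group labels; idempotent.
    """
    if float(np.sum(model.weights)) < 0:
        return replace(model, weights=-model.weights)
    return model


def score_samples(model: SignatureModel, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample signature score sum(w_i * standardized x_i).

    Genes absent from the matrix (or missing for a sample) are dropped and
    the remaining weights renormalized to unit norm; at least 50% of the
    model's genes must be available per sample.
    """
    present = [g for g in model.genes if g in expr.values.index]
    missing = [g for g in model.genes if g not in expr.values.index]
    if len(present) < 0.5 * len(model.genes):
        raise ValueError(
            f"fewer than 50% of signature genes present; missing: {missing}"
        )
    idx = [model.genes.index(g) for g in present]
    w = model.weights[idx]
    z = (
        expr.values.loc[present].to_numpy(float)
        - model.center[idx][:, None]
    ) / model.scale[idx][:, None]

    scores = np.empty(z.shape[1])
    for j in range(z.shape[1]):
        ok = ~np.isnan(z[:, j])
        if ok.sum() < 0.5 * len(model.genes):
            absent = missing + [g for g, o in zip(present, ok) if not o]
            raise ValueError(
                f"fewer than 50% of signature genes available for sample "
                f"{expr.samples[j]!r}; missing: {absent}"
            )
        wj = w[ok]
        wj = wj / np.linalg.norm(wj)
        scores[j] = float(wj @ z[ok, j])
    return pd.Series(scores, index=expr.samples, name="score")


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomize at the median score: score <= median -> "low", else "high"."""
    if len(scores) < 2:
        raise ValueError(f"need >= 2 samples, got {len(scores)}")
    vals = scores.to_numpy(float)
    if np.all(vals == vals[0]):
        raise ValueError("degenerate split: all scores identical")
    med = float(np.median(vals))
    groups = np.where(vals <= med, "low", "high")
    return pd.Series(groups, index=scores.index, name="group")


def _km_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: Iterable[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_j <= t of (1 - d_j / n_j), where d_j
    deaths occur among n_j at risk; censored subjects leave the risk set
    after their censoring time.
    """
    records = list(records)
    if not records:
        raise ValueError("no survival records")
    times, events = _km_arrays(records)
    event_times = np.unique(times[events == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_j = int(np.sum(times >= t))
        d_j = int(np.sum((times == t) & (events == 1)))
        at_risk[i] = n_j
        s *= 1.0 - d_j / n_j
        surv[i] = s
    return KMCurve(event_times=event_times, survival_prob=surv, at_risk=at_risk)


def logrank_test(
    group_a: Iterable[SurvivalRecord], group_b: Iterable[SurvivalRecord]
) -> LogRankResult:
    """Two-group log-rank test with a chi-square(1) reference.

    At each distinct event time, observed events in group a are compared to
    the hypergeometric expectation given the pooled risk set; tied event
    times are handled through the summed hypergeometric moments.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _km_arrays(a)
    tb, eb = _km_arrays(b)
    if int(ea.sum() + eb.sum()) == 0:
        raise ValueError("no events in either group")
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    event_times = np.unique(all_times[all_events == 1])

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        n = n1 + n2
        d1 = int(np.sum((ta == t) & (ea == 1)))
        d2 = int(np.sum((tb == t) & (eb == 1)))
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(statistic=float(chi2), p_value=p)
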