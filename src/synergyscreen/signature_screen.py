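"""Gene-by-gene Pearson correlation screen against an IC50 phenotype.

Per gene, Pearson's r is computed on pairwise-complete samples and the
two-sided p-value comes from the t-transform with n - 2 degrees of freedom.
Multiple testing is controlled with Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "CorrelationResult",
    "pearson_screen",
    "bh_fdr",
    "select_genes",
    "results_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression, genes as rows and samples as columns."""

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        arr = self.values.to_numpy(float)
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite (NaN allowed for missing)")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def restrict(self, genes: list[str]) -> "ExpressionMatrix":
        """Sub-matrix over ``genes`` (all must be present), preserving order."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[genes])


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    r: float
    p: float
    q: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")


def _pearson_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r via the t-transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)  # |r| == 1 -> t infinite -> p -> 0
    # keep p strictly inside (0, 1] so downstream FDR preconditions hold
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_fdr(pvalues: "list[float] | np.ndarray") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pearson_screen(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    *,
    log10_phenotype: bool = True,
) -> list[CorrelationResult]:
    """Correlate every gene with the per-sample IC50 phenotype.

    Samples are matched by label; at least 3 shared samples are required and
    the phenotype must not be constant. By default the phenotype is
    log10-transformed before correlating (dose scales are log-normal); pass
    ``log10_phenotype=False`` to correlate on the raw scale. Genes with zero
    variance (or fewer than 3 complete pairs) are skipped with a warning.
    """
    shared = [s for s in expr.samples if s in phenotype.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    y = phenotype.loc[shared].to_numpy(float)
    if log10_phenotype:
        if np.any(y <= 0):
            raise ValueError("IC50 values must be positive for log10 transform")
        y = np.log10(y)
    if np.nanstd(y) == 0:
        raise ValueError("constant phenotype")

    X = expr.values[shared].to_numpy(float)
    genes = expr.genes

    if not np.isnan(X).any():
        n = np.full(X.shape[0], len(shared))
        xc = X - X.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sx = np.sqrt((xc * xc).sum(axis=1))
        sy = float(np.sqrt((yc * yc).sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc) / (sx * sy)
        valid = sx > 0
    else:
        r = np.empty(X.shape[0])
        n = np.empty(X.shape[0], dtype=int)
        valid = np.ones(X.shape[0], dtype=bool)
        for i in range(X.shape[0]):
            mask = ~np.isnan(X[i])
            n[i] = int(mask.sum())
            if n[i] < 3 or np.std(X[i, mask]) == 0:
                valid[i] = False
                r[i] = np.nan
                continue
            r[i] = np.corrcoef(X[i, mask], y[mask])[0, 1]

    skipped = [g for g, v in zip(genes, valid) if not v]
    if skipped:
        logger.warning(
            "skipping %d gene(s) with zero variance or < 3 complete pairs: %s%s",
            len(skipped),
            skipped[:5],
            "..." if len(skipped) > 5 else "",
        )

    r_v = np.clip(r[valid], -1.0, 1.0)
    n_v = np.asarray(n)[valid]
    p_v = _pearson_pvalue(r_v, n_v)
    q_v = bh_fdr(p_v)
    kept = [g for g, v in zip(genes, valid) if v]
    return [
        CorrelationResult(gene=g, r=float(ri), p=float(pi), q=float(qi), n=int(ni))
        for g, ri, pi, qi, ni in zip(kept, r_v, p_v, q_v, n_v)
    ]


def select_genes(
    results: list[CorrelationResult],
    *,
    p_threshold: float | None = None,
    q_threshold: float | None = None,
) -> list[str]:
    """Genes passing one strict threshold, sorted by |r| descending.

    Exactly one of ``p_threshold`` / ``q_threshold`` must be given. Ties in
    |r| are broken by gene ID lexicographic order for determinism.
    """
    if (p_threshold is None) == (q_threshold is None):
        raise ValueError("set exactly one of p_threshold or q_threshold")
    if p_threshold is not None:
        hits = [res for res in results if res.p < p_threshold]
    else:
        hits = [res for res in results if res.q < q_threshold]
    hits.sort(key=lambda res: (-abs(res.r), res.gene))
    if not hits:
        logger.info("no genes passed the threshold (valid empty selection)")
    return [res.gene for res in hits]


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Screen results as a (gene, r, p, q, n) frame."""
    return pd.DataFrame(
        [{"gene": r.gene, "r": r.r, "p": r.p, "q": r.q, "n": r.n} for r in results],
        columns=["gene", "r", "p", "q", "n"],
    )
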