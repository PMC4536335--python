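"""Validated readers and writers for the flat-file interchange formats.

Delimiter is inferred from the extension (.tsv/.txt -> tab, .csv -> comma);
all files are UTF-8. Validation errors name the first offending row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dose_response import ViabilityTable
from .ihc_scoring import IHCObservation
from .pca_survival import SurvivalRecord
from .signature_screen import ExpressionMatrix

__all__ = [
    "read_plate_table",
    "read_viability_table",
    "write_viability_table",
    "read_fit_table",
    "write_fit_table",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_survival",
    "write_survival",
    "read_ihc_table",
    "read_gene_list",
    "write_gene_list",
    "read_design",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sep(path), encoding="utf-8", **kwargs)


def _write(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=False, encoding="utf-8", **kwargs)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, column: str, path: Path, *, positive: bool = False) -> pd.Series:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
        raise ValueError(f"{path}: malformed {column} {df[column][bad].iloc[0]!r} at line {row}")
    if positive and (values <= 0).any():
        row = int(np.flatnonzero(values <= 0)[0]) + 2
        raise ValueError(f"{path}: non-positive {column} at line {row}")
    return values


def read_plate_table(path: str | Path, *, signal_col: str = "signal") -> pd.DataFrame:
    """Raw plate readings: sample, drug, dose, replicate, <signal_col>."""
    path = Path(path)
    df = _read(path)
    _require_columns(df, ["sample", "drug", "dose", "replicate", signal_col], path)
    df["dose"] = _numeric(df, "dose", path)
    df[signal_col] = _numeric(df, signal_col, path)
    return df


def read_viability_table(path: str | Path) -> ViabilityTable:
    """Pre-normalized viability rows: sample, drug, dose, replicate, viability."""
    path = Path(path)
    df = _read(path)
    _require_columns(df, ["sample", "drug", "dose", "replicate", "viability"], path)
    df["dose"] = _numeric(df, "dose", path)
    df["viability"] = _numeric(df, "viability", path)
    return ViabilityTable(df)


def write_viability_table(table: ViabilityTable, path: str | Path) -> None:
    _write(table.data, path)


_FIT_COLUMNS = ["sample", "drug", "Dm", "m", "n_used", "r_squared"]


def read_fit_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read(path)
    _require_columns(df, _FIT_COLUMNS, path)
    for col in ("Dm", "m"):
        df[col] = _numeric(df, col, path, positive=True)
    return df


def write_fit_table(fits: pd.DataFrame, path: str | Path) -> None:
    _write(fits[_FIT_COLUMNS], path)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Delimited matrix, genes as rows (first column = gene ID).

    A GCT-style two-line header (``#1.2`` then dimensions) is skipped when
    present.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.") else 0
    df = pd.read_csv(path, sep=_sep(path), encoding="utf-8", skiprows=skip, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    for col in df.columns:
        df[col] = _numeric(df, col, path)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.values.rename_axis("gene").to_csv(path, sep=_sep(path), encoding="utf-8")


def read_phenotype(path: str | Path) -> pd.Series:
    """Two-column table (sample, ic50) as a sample-indexed series."""
    path = Path(path)
    df = _read(path)
    _require_columns(df, ["sample", "ic50"], path)
    values = _numeric(df, "ic50", path)
    return pd.Series(values.to_numpy(), index=df["sample"].astype(str), name="ic50")


def write_phenotype(phenotype: pd.Series, path: str | Path) -> None:
    _write(phenotype.rename_axis("sample").reset_index(name="ic50"), path)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Survival rows (sample, time, event) -> records; event must be 0/1."""
    path = Path(path)
    df = _read(path)
    _require_columns(df, ["sample", "time", "event"], path)
    times = _numeric(df, "time", path)
    events = _numeric(df, "event", path)
    records = []
    for i, (s, t, e) in enumerate(zip(df["sample"], times, events)):
        try:
            records.append(SurvivalRecord(sample=str(s), time=float(t), event=int(e)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"sample": r.sample, "time": r.time, "event": r.event} for r in records]
    )
    _write(df, path)


def _is_number(text: str) -> bool:
    try:
        return np.isfinite(float(text))
    except ValueError:
        return False


def read_ihc_table(path: str | Path) -> list[IHCObservation]:
    """Grade table -> observations.

    Accepts either grade rows (sample, cellularity, intensity[, score]) or
    score-only rows (sample, ..., score). Non-numeric grade/score cells
    (e.g. "Acellular", "n/a") mark the record non-evaluable.
    """
    path = Path(path)
    df = _read(path, dtype=str)
    _require_columns(df, ["sample"], path)
    has_grades = "cellularity" in df.columns and "intensity" in df.columns
    if not has_grades and "score" not in df.columns:
        raise ValueError(f"{path}: need either grade columns or a score column")
    observations = []
    for i, row in df.iterrows():
        sample = str(row["sample"])
        if has_grades:
            cell, inten = str(row["cellularity"]).strip(), str(row["intensity"]).strip()
            if _is_number(cell) and _is_number(inten):
                obs = IHCObservation(
                    sample=sample, cellularity=float(cell), intensity=int(float(inten))
                )
            else:
                obs = IHCObservation(sample=sample, evaluable=False)
        else:
            score = str(row["score"]).strip()
            if _is_number(score):
                obs = IHCObservation(sample=sample, precomputed_score=int(float(score)))
            else:
                obs = IHCObservation(sample=sample, evaluable=False)
        observations.append(obs)
    if not observations:
        raise ValueError(f"{path}: no records")
    return observations


def read_gene_list(path: str | Path) -> list[str]:
    """Gene symbols from a delimited file, flattened row-major.

    Handles both one-symbol-per-line lists and multi-column layouts; empty
    cells are dropped and order-preserving deduplication is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            for cell in line.rstrip("\n").split("," if path.suffix.lower() == ".csv" else "\t"):
                symbol = cell.strip()
                if symbol:
                    seen.setdefault(symbol, None)
    return list(seen)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_design(path: str | Path) -> pd.DataFrame:
    """Combination design: combo, drug_a, drug_b, fraction_a."""
    path = Path(path)
    df = _read(path)
    _require_columns(df, ["combo", "drug_a", "drug_b", "fraction_a"], path)
    df["fraction_a"] = _numeric(df, "fraction_a", path)
    bad = ~df["fraction_a"].between(0, 1, inclusive="neither")
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: fraction_a outside (0, 1) at line {row}")
    return df
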