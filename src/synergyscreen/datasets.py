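"""Bundled fixture tables: IHC grade tables and the response-signature gene list."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .ihc_scoring import IHCObservation
from .io import read_gene_list, read_ihc_table

__all__ = [
    "fixture_path",
    "load_primary_tumor_ihc",
    "load_cell_line_ihc",
    "load_signature_genes",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    path = resources.files("synergyscreen").joinpath("data", name)
    with resources.as_file(path) as p:
        return Path(p)


def load_primary_tumor_ihc() -> list[IHCObservation]:
    """Primary-tumor IHC records (79 samples, product scores only)."""
    return read_ihc_table(fixture_path("primary_tumor_ihc.tsv"))


def load_cell_line_ihc() -> list[IHCObservation]:
    """Cell-line IHC records (41 lines with cellularity/intensity grades)."""
    return read_ihc_table(fixture_path("cell_line_ihc.tsv"))


def load_signature_genes() -> list[str]:
    """The 47-symbol response-signature gene list (flattened multi-column layout)."""
    return read_gene_list(fixture_path("response_signature_genes.tsv"))
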