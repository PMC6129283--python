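"""Reading and writing the TSV/OBO dialects the tool consumes and emits.

All tabular output is plain TSV with an optional block of ``#``-prefixed
provenance header lines (version, seed, configuration); readers skip such
lines. Floats are formatted with 10 significant digits so that two runs
with identical configuration produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .ontology import OntologyGraph

FLOAT_FORMAT = "%.10g"


def provenance_header(seed=None, **config) -> list[str]:
    lines = [f"# ontoscore {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for key in sorted(config):
        lines.append(f"# {key}: {config[key]}")
    return lines


def write_tsv(
    df: pd.DataFrame,
    path,
    index: bool = False,
    index_label: str | None = None,
    header_lines: list[str] | None = None,
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(line + "\n")
        df.to_csv(
            fh,
            sep="\t",
            index=index,
            index_label=index_label,
            float_format=FLOAT_FORMAT,
            lineterminator="\n",
        )


def read_expression(path) -> pd.DataFrame:
    """Genes x samples matrix: header row of sample ids, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path, header_lines=None) -> None:
    write_tsv(expr, path, index=True, index_label="gene_id", header_lines=header_lines)


def read_mapping(path) -> pd.DataFrame:
    """Sample-to-term mapping TSV: sample_id, term_id, optional group, batch."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "term_id"):
        if col not in df.columns:
            raise ValueError(f"mapping file is missing required column {col!r}")
    return df


def write_mapping(mapping: pd.DataFrame, path, header_lines=None) -> None:
    write_tsv(mapping, path, header_lines=header_lines)


def read_matrix(path) -> pd.DataFrame:
    """Square sample x sample matrix with ids on both axes."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.index) != list(df.columns):
        raise ValueError("matrix rows and columns disagree; not a sample matrix")
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path, header_lines=None) -> None:
    write_tsv(matrix, path, index=True, index_label="sample_id", header_lines=header_lines)


def write_scores(scores: pd.DataFrame, path, header_lines=None) -> None:
    write_tsv(
        scores.reset_index(names="sample_id"), path, header_lines=header_lines
    )


def write_obo(graph: OntologyGraph, path, ontology_name: str = "toy") -> None:
    """Serialise an ontology as a minimal OBO 1.2 flat file (is_a edges only)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n")
        for term in sorted(graph.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            name = graph.names.get(term, term)
            fh.write(f"name: {name}\n")
            if term in graph.obsolete:
                fh.write("is_obsolete: true\n")
                continue
            for parent in sorted(graph.parents(term)):
                fh.write(f"is_a: {parent} ! {graph.names.get(parent, parent)}\n")
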