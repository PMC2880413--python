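"""Readers and writers for the pipeline's text formats.

Expression matrices are tab-delimited: first column gene id, remaining
columns time-ordered values; an empty cell, "NA", "NaN" or "nan" marks a
missing value.  Networks are written either as SIF
(``source<TAB>regulates<TAB>target``) or as a TSV edge table with optional
per-edge statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import ExpressionMatrix, QuantizedMatrix

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_quantized_matrix",
    "write_quantized_matrix",
    "write_network",
    "read_sif",
]

MISSING_TOKENS = {"", "NA", "NaN", "nan"}
SIF_RELATION = "regulates"


def _parse_rows(path) -> tuple[list[str], list[list[float]]]:
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ValueError(
                    f"{path}:{lineno}: expected {width} columns, got {len(fields)}"
                )
            gene = fields[0].strip()
            if gene in gene_ids:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            values = []
            for col, cell in enumerate(fields[1:], start=2):
                cell = cell.strip()
                if cell in MISSING_TOKENS:
                    values.append(np.nan)
                    continue
                try:
                    values.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                    ) from None
            gene_ids.append(gene)
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return gene_ids, rows


def read_expression_matrix(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (genes in rows by default)."""
    gene_ids, rows = _parse_rows(path)
    values = np.asarray(rows, dtype=float)
    if transpose:
        values = values.T
        gene_ids = [f"g{j + 1}" for j in range(values.shape[0])]
    return ExpressionMatrix(values, gene_ids)


def write_expression_matrix(mat: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        for gene, row in zip(mat.gene_ids, mat.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write("\t".join([gene, *cells]) + "\n")


def read_quantized_matrix(path, q: int) -> QuantizedMatrix:
    gene_ids, rows = _parse_rows(path)
    values = np.asarray(rows)
    if np.isnan(values).any():
        raise ValueError(f"{path}: quantized matrix must not have missing values")
    return QuantizedMatrix(values.astype(np.int64), q=q, gene_ids=gene_ids)


def write_quantized_matrix(mat: QuantizedMatrix, path) -> None:
    with open(path, "w") as fh:
        for gene, row in zip(mat.gene_ids, mat.values):
            fh.write("\t".join([gene, *(str(int(v)) for v in row)]) + "\n")


def _sorted_edges(
    connectivity: np.ndarray, gene_ids: Sequence[str]
) -> list[tuple[str, str, int, int]]:
    edges = [
        (gene_ids[i], gene_ids[j], int(i), int(j))
        for i, j in np.argwhere(np.asarray(connectivity) == 1)
    ]
    return sorted(edges, key=lambda e: (e[0], e[1]))


def write_network(
    connectivity: np.ndarray,
    gene_ids: Sequence[str],
    path,
    fmt: str = "sif",
    edge_stats: Mapping[tuple[int, int], Mapping] | None = None,
) -> None:
    """Write a connectivity matrix as SIF or TSV, edges in lexicographic order.

    For TSV, ``edge_stats`` (keyed by (source index, target index)) may
    supply ``mi`` and ``min_cmi`` columns.
    """
    edges = _sorted_edges(connectivity, gene_ids)
    with open(path, "w") as fh:
        if fmt == "sif":
            for src, tgt, *_ in edges:
                fh.write(f"{src}\t{SIF_RELATION}\t{tgt}\n")
        elif fmt == "tsv":
            fh.write("source\ttarget\tmi\tmin_cmi\n")
            for src, tgt, i, j in edges:
                stats = (edge_stats or {}).get((i, j), {})
                mi = stats.get("mi")
                mc = stats.get("min_cmi")
                fh.write(
                    f"{src}\t{tgt}\t"
                    f"{'' if mi is None else f'{mi:.6f}'}\t"
                    f"{'' if mc is None else f'{mc:.6f}'}\n"
                )
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_sif(path, gene_ids: Sequence[str]) -> np.ndarray:
    """Read a SIF edge list back into a connectivity matrix."""
    index = {g: i for i, g in enumerate(gene_ids)}
    conn = np.zeros((len(gene_ids), len(gene_ids)), dtype=np.int8)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            src, _, tgt = parts
            if src not in index or tgt not in index:
                raise ValueError(f"{path}:{lineno}: unknown gene id")
            conn[index[src], index[tgt]] = 1
    return conn
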