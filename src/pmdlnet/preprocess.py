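"""Missing-value filling and per-gene quantization of expression time series.

The working currency of the inference pipeline is a matrix of discrete
expression levels over the alphabet {0..q-1}.  Real microarray series are
first completed (missing points interpolated from their neighbours) and then
discretized gene by gene with an equal-frequency rule; the binary recipe
additionally discards one smallest and one largest value per gene as
outliers before locating the median split point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "QuantizedMatrix",
    "fill_missing",
    "quantize_binary",
    "quantize_qlevel",
]


@dataclass
class ExpressionMatrix:
    """Real-valued genes x time-points matrix; NaN marks a missing value."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-dimensional (genes x time points)")
        n, m = v.shape
        if n < 1 or m < 2:
            raise ValueError("need at least 1 gene and 2 time points")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length must equal the number of rows")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        all_missing = np.all(np.isnan(v), axis=1)
        if all_missing.any():
            bad = self.gene_ids[int(np.argmax(all_missing))]
            raise ValueError(f"gene {bad!r} has no observed values")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class QuantizedMatrix:
    """Integer genes x time-points matrix over the alphabet {0..q-1}."""

    values: np.ndarray
    q: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(v == np.floor(v)):
                raise ValueError("quantized values must be integers")
            v = v.astype(np.int64)
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if v.size and (v.min() < 0 or v.max() >= self.q):
            raise ValueError(f"values must lie in {{0..{self.q - 1}}}")
        if len(self.gene_ids) != v.shape[0]:
            raise ValueError("gene_ids length must equal the number of rows")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def fill_missing(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Replace missing values by the mean of their nearest observed neighbours.

    An interior missing point becomes the arithmetic mean of the closest
    observed values to its left and right; a run of consecutive missing
    points is filled by linear interpolation between the flanking observed
    values (which reduces to the neighbour mean for a single gap).  Missing
    leading/trailing points take the nearest observed value.  Idempotent.
    """
    out = mat.values.copy()
    t = np.arange(mat.m)
    for row in out:
        obs = ~np.isnan(row)
        if obs.all():
            continue
        # np.interp is linear between observed points and clamps at the ends
        row[~obs] = np.interp(t[~obs], t[obs], row[obs])
    return ExpressionMatrix(out, list(mat.gene_ids))


def _gene_boundaries(row: np.ndarray, q: int, drop_outliers: bool) -> np.ndarray:
    base = np.sort(row)
    if drop_outliers:
        # exactly one smallest and one largest sorted value are excluded
        # from the split-point computation (they are still quantized)
        base = base[1:-1]
    return np.quantile(base, np.arange(1, q) / q)


def quantize_qlevel(
    mat: ExpressionMatrix, q: int, *, drop_outliers: bool = False
) -> QuantizedMatrix:
    """Equal-frequency quantization of each gene into q levels.

    Level boundaries are the empirical 1/q..(q-1)/q quantiles of the gene's
    own values; a value maps to the number of boundaries it strictly
    exceeds, so ties at a boundary fall into the lower level.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    if q > mat.m:
        raise ValueError(f"q={q} exceeds the number of time points m={mat.m}")
    if mat.has_missing:
        raise ValueError("matrix has missing values; call fill_missing first")
    if drop_outliers and mat.m < 4:
        raise ValueError("outlier discarding requires at least 4 time points")
    levels = np.empty(mat.values.shape, dtype=np.int64)
    for i, row in enumerate(mat.values):
        bounds = _gene_boundaries(row, q, drop_outliers)
        levels[i] = (row[:, None] > bounds[None, :]).sum(axis=1)
    return QuantizedMatrix(levels, q=q, gene_ids=list(mat.gene_ids))


def quantize_binary(mat: ExpressionMatrix) -> QuantizedMatrix:
    """Binarize each gene around the median of its non-extreme values.

    Per gene: sort the m values, drop the smallest and largest as outliers,
    take the median of the rest as the split point; values above the split
    map to 1, values at or below it map to 0.
    """
    if mat.m < 4:
        raise ValueError("binary quantization requires at least 4 time points")
    return quantize_qlevel(mat, 2, drop_outliers=True)
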