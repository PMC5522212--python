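"""Quantile normalization and scale management.

One scale convention is used throughout the pipeline: normalization runs on
the linear intensity scale, fold changes use linear normalized group means,
and t-tests / correlations / clustering use log2-transformed normalized
values (with a positive floor before the log so synthetic zeros stay
finite).
"""
from __future__ import annotations

import numpy as np

from .study_io import ExpressionMatrix

DEFAULT_LOG2_FLOOR = 1.0


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share one empirical intensity distribution.

    Each column is replaced rank-wise by the reference distribution — the
    vector of row-wise means of the column-sorted matrix. Tied values within
    a column receive the mean of the reference quantiles they span, so the
    mapping is deterministic and rank-preserving (ties excepted). On
    tie-free data the sorted vector of every output column equals the
    reference exactly and the operation is idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_probes, n_samples = vals.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if np.isnan(vals).any():
        raise ValueError("matrix contains NaN")

    order = np.argsort(vals, axis=0, kind="stable")
    reference = np.take_along_axis(vals, order, axis=0).mean(axis=1)

    out = np.empty_like(vals)
    for j in range(n_samples):
        col_out = np.empty(n_probes)
        col_out[order[:, j]] = reference
        uniq, inverse, counts = np.unique(vals[:, j], return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            sums = np.zeros(len(uniq))
            np.add.at(sums, inverse, col_out)
            col_out = (sums / counts)[inverse]
        out[:, j] = col_out

    frame = matrix.values.copy()
    frame.loc[:, :] = out
    return ExpressionMatrix(frame, scale=matrix.scale, normalized=True)


def to_log2(matrix: ExpressionMatrix, floor: float = DEFAULT_LOG2_FLOOR) -> ExpressionMatrix:
    """log2-transform a linear matrix, flooring values at ``floor`` first."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if matrix.scale != "linear":
        raise ValueError("to_log2 expects a linear-scale matrix")
    frame = matrix.values.copy()
    frame.loc[:, :] = np.log2(np.maximum(frame.to_numpy(dtype=float), floor))
    return ExpressionMatrix(frame, scale="log2", normalized=matrix.normalized)


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Invert :func:`to_log2` (exact for values above the floor)."""
    if matrix.scale != "log2":
        raise ValueError("to_linear expects a log2-scale matrix")
    frame = matrix.values.copy()
    frame.loc[:, :] = np.exp2(frame.to_numpy(dtype=float))
    return ExpressionMatrix(frame, scale="linear", normalized=matrix.normalized)
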