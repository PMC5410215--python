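"""Per-dataset quantile normalization and variance-based probe filtering.

The pipeline consumes probeset-level matrices, so of the usual Affymetrix
summarization chain only the matrix-level quantile-normalization step is
performed here, applied independently within each dataset.  Probe
filtering keeps the most variable probes (sample standard deviation above
a strict threshold, default 0.9 log2 units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_SD_THRESHOLD = 0.9


@dataclass
class SdFilterResult:
    """Probes retained by the SD filter, with the per-probe SDs used."""

    retained: list[str]
    sd: pd.Series
    threshold: float

    def apply(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        return matrix.subset_probes(self.retained)


def _quantile_normalize_array(values: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Map every column onto a reference distribution by rank.

    The reference defaults to the mean of the sorted columns.  Ties
    receive the mean of the reference values over their rank span
    (midrank convention), which keeps the operation deterministic and
    makes equal input values equal on output.
    """
    p, n = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    if reference is None:
        reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(n):
        sv = sorted_vals[:, j]
        starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
        counts = np.diff(np.r_[starts, p])
        group_means = np.add.reduceat(reference, starts) / counts
        out[order[:, j], j] = np.repeat(group_means, counts)
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples jointly.

    After the transform every sample's sorted value vector equals the
    across-sample mean of sorted vectors; probe and sample IDs are
    unchanged.  A single-sample matrix passes through unchanged.
    """
    values = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("quantile_normalize requires a complete, finite matrix")
    normalized = _quantile_normalize_array(values)
    return ExpressionMatrix(
        pd.DataFrame(normalized, index=matrix.values.index, columns=matrix.values.columns),
        matrix.batch.copy(),
    )


def normalize_per_dataset(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize each batch separately onto the cohort reference.

    Every batch's samples are rank-mapped, batch by batch, onto the grand
    reference (the across-sample mean of sorted vectors), so all batches
    end up on one common distribution and a constant per-dataset shift is
    removed.  Batches are processed separately and re-concatenated in the
    original sample order.  A single-sample batch passes through unchanged
    (logged); with one multi-sample batch the operation reduces to
    :func:`quantile_normalize`.
    """
    all_values = matrix.values.to_numpy(dtype=float)
    reference = np.sort(all_values, axis=0).mean(axis=1)
    pieces: dict[str, pd.DataFrame] = {}
    for label in matrix.batch.unique():
        cols = matrix.batch.index[matrix.batch == label]
        sub = matrix.values[cols]
        if len(cols) == 1:
            logger.info("batch %r has a single sample; passed through unchanged", label)
            pieces[label] = sub
        else:
            pieces[label] = pd.DataFrame(
                _quantile_normalize_array(sub.to_numpy(dtype=float), reference),
                index=sub.index, columns=sub.columns,
            )
    out = pd.concat(pieces.values(), axis=1)[matrix.values.columns]
    return ExpressionMatrix(out, matrix.batch.copy())


def filter_by_sd(matrix: ExpressionMatrix, threshold: float = DEFAULT_SD_THRESHOLD) -> SdFilterResult:
    """Retain probes whose sample SD (n−1 denominator) strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("SD threshold must be non-negative")
    if matrix.n_samples < 2:
        raise ValueError("per-probe SD is undefined with fewer than 2 samples")
    sd = matrix.values.std(axis=1, ddof=1)
    retained = list(sd.index[sd > threshold])
    logger.info(
        "SD filter (> %.3g): retained %d of %d probes", threshold, len(retained), matrix.n_probes
    )
    return SdFilterResult(retained=retained, sd=sd, threshold=float(threshold))
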