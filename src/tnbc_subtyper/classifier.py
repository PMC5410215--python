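"""Centroid-correlation classification against subtype gene lists.

Each subtype's signed gene list defines a template vector (+1 for up
genes, −1 for down genes, 0 for signature genes of other subtypes); a
sample's score for the subtype is the Pearson correlation between its
expression over the signature genes and that template, which makes the
classifier invariant to any monotone affine rescaling of the sample.  The
winning subtype labels the sample unless the best score is too low or the
top two scores are too close, in which case the sample is left UNS
(unclassified/unstable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SignatureTable

logger = logging.getLogger(__name__)

UNS = "UNS"
DEFAULT_MIN_SCORE = 0.1
DEFAULT_AMBIGUITY_GAP = 0.02
MIN_OVERLAP = 3


def signature_score(
    sample: pd.Series,
    up: Sequence[str],
    down: Sequence[str],
    background: Sequence[str] = (),
) -> float:
    """Pearson correlation between a sample and one subtype's template.

    The template is +1 over ``up`` genes, −1 over ``down`` genes and 0
    over ``background`` genes (signature genes of the other subtypes, used
    so that all-up gene lists still yield a non-constant template).  Genes
    absent from the sample are dropped; fewer than 3 of the subtype's own
    genes present — or a constant template or sample — gives NaN.
    """
    own = [g for g in list(up) + list(down) if g in sample.index]
    if len(own) < MIN_OVERLAP:
        return float("nan")
    up_set, down_set = set(up), set(down)
    genes = own + [g for g in background if g in sample.index and g not in up_set and g not in down_set]
    template = np.array([1.0 if g in up_set else (-1.0 if g in down_set else 0.0) for g in genes])
    x = sample[genes].to_numpy(dtype=float)
    if np.std(template) == 0 or np.std(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, template)[0, 1])


@dataclass
class CrossTab:
    """Column-percentage cross-tabulation of two labelings."""

    percent: pd.DataFrame
    counts: pd.DataFrame
    column_totals: pd.Series


def classify_by_signatures(
    matrix: ExpressionMatrix,
    signatures: SignatureTable,
    min_score: float = DEFAULT_MIN_SCORE,
    ambiguity_gap: float = DEFAULT_AMBIGUITY_GAP,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label every sample by its best-correlated subtype template.

    Returns ``(labels, scores)``.  A sample is UNS when its best score is
    NaN or below ``min_score``, or when the top two scores differ by less
    than ``ambiguity_gap``.
    """
    subtypes = signatures.subtypes
    if not subtypes:
        raise ValueError("empty signature table")
    all_genes = signatures.all_genes()
    scores = pd.DataFrame(index=matrix.values.columns, columns=subtypes, dtype=float)
    for subtype in subtypes:
        up, down = signatures.genes(subtype)
        background = [g for g in all_genes if g not in set(up) | set(down)]
        present_own = [g for g in up + down if g in matrix.values.index]
        if len(present_own) < MIN_OVERLAP:
            logger.warning(
                "subtype %s has %d of its signature genes in the matrix (<%d); "
                "its scores are undefined", subtype, len(present_own), MIN_OVERLAP,
            )
        for sample in matrix.values.columns:
            scores.loc[sample, subtype] = signature_score(
                matrix.values[sample], up, down, background=background
            )

    labels = {}
    for sample, row in scores.iterrows():
        vals = row.astype(float)
        if vals.isna().all():
            labels[sample] = UNS
            continue
        ordered = vals.sort_values(ascending=False)
        best = float(ordered.iloc[0])
        if np.isnan(best) or best < min_score:
            labels[sample] = UNS
        elif len(ordered) > 1 and (best - float(ordered.iloc[1])) < ambiguity_gap:
            labels[sample] = UNS
        else:
            labels[sample] = str(ordered.index[0])
    return pd.Series(labels, name="subtype").reindex(scores.index), scores


def cross_tabulate(labels_a: pd.Series, labels_b: pd.Series) -> CrossTab:
    """Cross-tabulate labeling ``a`` (rows) against ``b`` (columns).

    Entry (r, c) is the percentage of samples labelled ``c`` by ``b`` that
    ``a`` labels ``r``; every column, UNS rows included, sums to 100.
    """
    a = labels_a.dropna()
    b = labels_b.dropna()
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("the two labelings share no samples")
    if len(common) != len(a) or len(common) != len(b):
        raise ValueError("the two labelings must cover the same sample set")
    a, b = a[common], b[common]
    counts = pd.crosstab(a, b)
    counts.index.name, counts.columns.name = "labels_a", "labels_b"
    totals = counts.sum(axis=0)
    percent = 100.0 * counts / totals
    return CrossTab(percent=percent, counts=counts, column_totals=totals)
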