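"""Subtype-specific marker selection by fold change, consistency and t-test.

A probe is declared specific to a subtype when three criteria hold
simultaneously against the pooled remaining subtypes: linear fold change
above 1.75 (up) or below 0.5 (down); more than 80% of the subtype's
samples on the expected side of the rest mean; and a Welch t-test p-value
below 1e-4.  When several probes map to one gene only the strongest probe
(largest absolute log2 fold change) is kept.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, SignatureTable

logger = logging.getLogger(__name__)

DEFAULT_FC_UP = 1.75
DEFAULT_FC_DOWN = 0.5
DEFAULT_MIN_FRACTION = 0.80
DEFAULT_MAX_P = 1e-4


def subtype_vs_rest_stats(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    subtype: str,
) -> pd.DataFrame:
    """Per-probe statistics for one subtype versus the pooled rest.

    Returns a DataFrame indexed by probe with columns:

    - ``fold_change``: linear ratio ``2**(mean_subtype − mean_rest)`` of
      the log2 values;
    - ``log2_fc``: the log2 difference itself;
    - ``frac_above`` / ``frac_below``: share of subtype samples whose log2
      value lies strictly above / below the rest mean;
    - ``p_value``: Welch two-sample t-test, subtype vs rest.

    A probe constant everywhere reports fold change 1, fractions 0 and
    p-value 1.
    """
    labels = labels.dropna()
    samples = [s for s in labels.index if s in set(matrix.sample_ids)]
    if len(samples) != len(labels):
        raise ValueError("labels refer to samples missing from the matrix")
    in_group = labels.index[labels == subtype]
    rest = labels.index[labels != subtype]
    if len(in_group) < 3 or len(rest) < 3:
        raise ValueError(
            f"subtype {subtype!r} needs >=3 samples on each side "
            f"(got {len(in_group)} vs {len(rest)})"
        )
    A = matrix.values[list(in_group)].to_numpy(dtype=float)
    B = matrix.values[list(rest)].to_numpy(dtype=float)

    mean_s = A.mean(axis=1)
    mean_r = B.mean(axis=1)
    log2_fc = mean_s - mean_r

    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(A, B, axis=1, equal_var=False).pvalue
    # degenerate variance: identical groups -> 1, separated point masses -> 0
    p = np.where(np.isnan(p), np.where(np.abs(log2_fc) > 0, 0.0, 1.0), p)

    frac_above = (A > mean_r[:, None]).mean(axis=1)
    frac_below = (A < mean_r[:, None]).mean(axis=1)

    return pd.DataFrame(
        {
            "subtype": subtype,
            "fold_change": np.exp2(log2_fc),
            "log2_fc": log2_fc,
            "frac_above": frac_above,
            "frac_below": frac_below,
            "p_value": p,
        },
        index=matrix.values.index,
    )


def select_signature(
    stats_df: pd.DataFrame,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    max_p: float = DEFAULT_MAX_P,
    probe_gene_map: Mapping[str, str] | None = None,
    bh_correct: bool = False,
) -> tuple[list[str], list[str]]:
    """Apply the three selection criteria; returns (up, down) probe lists.

    All thresholds are strict, mirroring how they are stated: FC strictly
    above ``fc_up`` / below ``fc_down``, fraction strictly above
    ``min_fraction``, p strictly below ``max_p``.  The fraction criterion
    for down-regulation mirrors the up rule (share of subtype samples
    below the rest mean).  With ``probe_gene_map``, probes of a shared
    gene keep only the strongest (max |log2 FC|); without it every probe
    is its own gene.  ``bh_correct`` applies Benjamini-Hochberg to the
    p-values first (off by default).
    """
    if not fc_up > 1.0 > fc_down > 0.0:
        raise ValueError("need fc_up > 1 > fc_down > 0")
    p = stats_df["p_value"].to_numpy(dtype=float)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, method="fdr_bh")[1]
    fc = stats_df["fold_change"]
    up_mask = (fc > fc_up) & (stats_df["frac_above"] > min_fraction) & (p < max_p)
    down_mask = (fc < fc_down) & (stats_df["frac_below"] > min_fraction) & (p < max_p)

    selected = stats_df.loc[up_mask | down_mask].copy()
    if probe_gene_map is not None and len(selected):
        genes = pd.Series(
            [probe_gene_map.get(probe, probe) for probe in selected.index],
            index=selected.index,
        )
        strongest = (
            selected["log2_fc"].abs().groupby(genes).idxmax()
        )
        selected = selected.loc[sorted(strongest, key=list(selected.index).index)]
    up = [pr for pr in selected.index if up_mask.loc[pr]]
    down = [pr for pr in selected.index if down_mask.loc[pr]]
    return up, down


def select_all_signatures(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    max_p: float = DEFAULT_MAX_P,
    probe_gene_map: Mapping[str, str] | None = None,
    bh_correct: bool = False,
) -> SignatureTable:
    """Run selection for every label present and collect a SignatureTable."""
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    for subtype in pd.unique(labels.dropna()):
        stats_df = subtype_vs_rest_stats(matrix, labels, subtype)
        up[subtype], down[subtype] = select_signature(
            stats_df, fc_up=fc_up, fc_down=fc_down,
            min_fraction=min_fraction, max_p=max_p,
            probe_gene_map=probe_gene_map, bh_correct=bh_correct,
        )
        logger.info(
            "subtype %s: %d up, %d down probes selected",
            subtype, len(up[subtype]), len(down[subtype]),
        )
    return SignatureTable(up=up, down=down)
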