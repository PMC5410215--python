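"""Synthetic multi-dataset expression cohorts with planted ground truth.

Emulates the structure the subtyping pipeline consumes: several microarray
datasets pooled into one cohort, three receptor probes whose per-sample
values follow a two-component Gaussian mixture (an "unexpressed" low mode
and an "expressed" high mode), latent subtypes among the triple-negative
samples marked by blocks of up- and down-regulated probes, a scalar
additive batch shift per dataset, and Gaussian probe noise — all on log2
scale, with every planted fact exposed through a truth channel for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import (
    DEFAULT_RECEPTOR_PROBES,
    ExpressionMatrix,
    SignatureTable,
    write_expression_tsv,
    write_signature_lists,
)

MARKERS = ("ER", "PR", "HER2")


@dataclass(frozen=True)
class ReceptorMixture:
    """Two-component mixture for one receptor probe, log2 units.

    ``positive_fraction`` is the prior probability that a sample expresses
    the receptor (draws from the high mode).
    """

    mu_neg: float = 6.0
    sd_neg: float = 1.0
    mu_pos: float = 11.0
    sd_pos: float = 1.0
    positive_fraction: float = 0.315

    def validate(self, marker: str) -> None:
        if not self.mu_pos > self.mu_neg:
            raise ValueError(f"{marker}: mu_pos must exceed mu_neg")
        if self.sd_neg <= 0 or self.sd_pos <= 0:
            raise ValueError(f"{marker}: component sds must be positive")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError(f"{marker}: positive_fraction must lie in (0, 1)")


def _default_mixtures() -> dict[str, ReceptorMixture]:
    return {m: ReceptorMixture() for m in MARKERS}


@dataclass
class SimConfig:
    """Generator settings; defaults emulate a compact multi-dataset cohort.

    ``markers_per_subtype`` counts the planted markers of each subtype,
    split evenly into an up-block (+``marker_effect`` log2 units) and a
    down-block (−``marker_effect``).  ``subtype_probs`` defaults to uniform
    assignment of TNBC samples across subtypes.  With ``tnbc_only`` every
    sample is forced triple negative, which lets stage-level tests fix the
    TNBC sample count exactly.
    """

    n_datasets: int = 3
    samples_per_dataset: int = 50
    n_probes: int = 1000
    receptor_mixture: dict[str, ReceptorMixture] = field(default_factory=_default_mixtures)
    receptor_probes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RECEPTOR_PROBES))
    n_subtypes: int = 5
    markers_per_subtype: int = 10
    marker_effect: float = 2.0
    noise_sd: float = 0.5
    batch_shift_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    subtype_probs: Sequence[float] | None = None
    tnbc_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1 or self.samples_per_dataset < 1:
            raise ValueError("need at least one dataset and one sample per dataset")
        if set(self.receptor_mixture) != set(MARKERS) or set(self.receptor_probes) != set(MARKERS):
            raise ValueError(f"receptor settings must cover exactly {MARKERS}")
        for marker in MARKERS:
            self.receptor_mixture[marker].validate(marker)
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if self.markers_per_subtype < 1:
            raise ValueError("markers_per_subtype must be >= 1")
        if self.markers_per_subtype * self.n_subtypes > self.n_probes - len(MARKERS):
            raise ValueError("markers_per_subtype * n_subtypes exceeds available probes")
        if self.noise_sd < 0 or self.batch_shift_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise/batch/baseline sds must be non-negative")
        if self.subtype_probs is not None:
            p = np.asarray(self.subtype_probs, dtype=float)
            if p.shape != (self.n_subtypes,) or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("subtype_probs must be a probability vector of length n_subtypes")


@dataclass
class GroundTruth:
    """Planted truth for one generated cohort.

    ``status`` holds per-sample receptor positivity (True = expressed) for
    ER/PR/HER2; ``tnbc`` is True iff all three are negative; ``subtype`` is
    the planted label for TNBC samples and ``None`` elsewhere;
    ``signatures`` lists each subtype's planted up/down marker probes.
    """

    status: pd.DataFrame
    tnbc: pd.Series
    subtype: pd.Series
    signatures: SignatureTable

    def __post_init__(self) -> None:
        expected = ~self.status.any(axis=1)
        if not (self.tnbc == expected).all():
            raise ValueError("tnbc flag must equal 'all three receptors negative'")
        labelled = self.subtype.notna()
        if (labelled & ~self.tnbc).any():
            raise ValueError("subtype labels are defined only for TNBC samples")


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one cohort; deterministic given ``config.seed``.

    Sampling order is fixed (statuses, receptor values, baselines, noise,
    subtype assignment, batch shifts) so identical configs reproduce
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_datasets * config.samples_per_dataset

    dataset_names = [f"D{i + 1}" for i in range(config.n_datasets)]
    sample_ids = [
        f"{ds}_s{j + 1:03d}" for ds in dataset_names for j in range(config.samples_per_dataset)
    ]
    batch = pd.Series(
        [ds for ds in dataset_names for _ in range(config.samples_per_dataset)],
        index=sample_ids,
    )

    # receptor status and probe values, marker by marker
    status = {}
    receptor_values = {}
    for marker in MARKERS:
        mix = config.receptor_mixture[marker]
        pos = np.zeros(n, bool) if config.tnbc_only else rng.random(n) < mix.positive_fraction
        neg_draw = rng.normal(mix.mu_neg, mix.sd_neg, n)
        pos_draw = rng.normal(mix.mu_pos, mix.sd_pos, n)
        status[marker] = pos
        receptor_values[marker] = np.where(pos, pos_draw, neg_draw)
    status = pd.DataFrame(status, index=sample_ids)
    tnbc = ~status.any(axis=1)

    n_background = config.n_probes - len(MARKERS)
    background_ids = [f"SYN{i + 1:05d}_at" for i in range(n_background)]
    probe_ids = [config.receptor_probes[m] for m in MARKERS] + background_ids

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_background)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, (n_background, n))
    else:
        noise = np.zeros((n_background, n))
    X = baseline[:, None] + noise

    # subtype assignment over TNBC samples, then planted marker blocks
    subtype_names = [f"T{j + 1}" for j in range(config.n_subtypes)]
    probs = None if config.subtype_probs is None else np.asarray(config.subtype_probs, float)
    assignment = rng.choice(config.n_subtypes, size=n, p=probs)
    subtype = pd.Series(
        [subtype_names[a] if is_t else None for a, is_t in zip(assignment, tnbc)],
        index=sample_ids, dtype=object,
    )

    n_up = (config.markers_per_subtype + 1) // 2
    up_lists: dict[str, list[str]] = {}
    down_lists: dict[str, list[str]] = {}
    cursor = 0
    for j, name in enumerate(subtype_names):
        block = background_ids[cursor:cursor + config.markers_per_subtype]
        cursor += config.markers_per_subtype
        up_lists[name] = block[:n_up]
        down_lists[name] = block[n_up:]
        members = (subtype == name).to_numpy()
        for probe in up_lists[name]:
            X[background_ids.index(probe)][members] += config.marker_effect
        for probe in down_lists[name]:
            X[background_ids.index(probe)][members] -= config.marker_effect

    values = np.vstack([np.vstack([receptor_values[m] for m in MARKERS]), X])

    if config.batch_shift_sd > 0:
        shifts = rng.normal(0.0, config.batch_shift_sd, config.n_datasets)
    else:
        shifts = np.zeros(config.n_datasets)
    per_sample_shift = np.repeat(shifts, config.samples_per_dataset)
    values = values + per_sample_shift[None, :]

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids), batch
    )
    truth = GroundTruth(
        status=status,
        tnbc=tnbc,
        subtype=subtype,
        signatures=SignatureTable(up=up_lists, down=down_lists),
    )
    return matrix, truth


def truth_tnbc_fraction(truth: GroundTruth) -> float:
    """Fraction of samples whose planted receptor status is triple negative."""
    if len(truth.tnbc) == 0:
        raise ValueError("empty ground truth")
    return float(truth.tnbc.mean())


def write_cohort(matrix: ExpressionMatrix, truth: GroundTruth, out_prefix: str | Path) -> dict[str, Path]:
    """Write matrix, truth table and planted signature list next to a prefix."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": Path(f"{out_prefix}.expression.tsv"),
        "truth": Path(f"{out_prefix}.truth.tsv"),
        "signatures": Path(f"{out_prefix}.signatures.tsv"),
    }
    write_expression_tsv(matrix, paths["matrix"])
    table = truth.status.copy()
    table["tnbc"] = truth.tnbc
    table["subtype"] = truth.subtype.fillna("")
    table.to_csv(paths["truth"], sep="\t", index_label="sample_id")
    write_signature_lists(truth.signatures, paths["signatures"])
    return paths
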