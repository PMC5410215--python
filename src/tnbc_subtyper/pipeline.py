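"""End-to-end orchestration: simulate/load → normalize → call receptors →
select TNBC → filter → consensus subtype → select signatures → classify.

One master seed in the config is split deterministically per stage, so a
whole run is reproducible from a single knob.  The run report is a JSON
document carrying sample counts at every stage, the chosen k, subtype
proportions and every parameter actually used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import preprocess, receptor, signatures as sig
from .classifier import (
    DEFAULT_AMBIGUITY_GAP,
    DEFAULT_MIN_SCORE,
    UNS,
    classify_by_signatures,
    cross_tabulate,
)
from .expression_io import (
    ExpressionMatrix,
    ProbeMarkerMap,
    SignatureTable,
    merge_cohorts,
    read_expression_tsv,
    read_signature_lists,
    write_signature_lists,
)
from .synthetic import GroundTruth, SimConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with the pipeline's default values.

    Inputs are either ``input_paths`` (expression TSVs, merged on load) or
    ``sim`` (a synthetic-cohort configuration).  The master ``seed`` is
    split per stage.
    """

    input_paths: list[str] = field(default_factory=list)
    sim: SimConfig | None = None
    signature_file: str | None = None
    out_dir: str | None = None

    er_probe: str = "205225_at"
    pr_probe: str = "208305_at"
    her2_probe: str = "216836_s_at"
    cutoff: float = 0.5
    negative_rule: str = "high"
    use_positive_controls: bool = True
    control_quantile: float = 0.10

    sd_threshold: float = preprocess.DEFAULT_SD_THRESHOLD
    k_min: int = 2
    k_max: int = 10
    n_resamples: int = cons.DEFAULT_N_RESAMPLES
    subsample_fraction: float = cons.DEFAULT_SUBSAMPLE_FRACTION
    delta_threshold: float = cons.DEFAULT_DELTA_THRESHOLD
    kmeans_restarts: int = cons.DEFAULT_KMEANS_RESTARTS

    fc_up: float = sig.DEFAULT_FC_UP
    fc_down: float = sig.DEFAULT_FC_DOWN
    min_fraction: float = sig.DEFAULT_MIN_FRACTION
    max_p: float = sig.DEFAULT_MAX_P

    min_score: float = DEFAULT_MIN_SCORE
    ambiguity_gap: float = DEFAULT_AMBIGUITY_GAP

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        config = cls(**raw)
        if sim_raw is not None:
            from .synthetic import ReceptorMixture
            mixtures = sim_raw.pop("receptor_mixture", None)
            sim = SimConfig(**sim_raw)
            if mixtures:
                sim.receptor_mixture = {
                    m: ReceptorMixture(**params) for m, params in mixtures.items()
                }
            config.sim = sim
        return config

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def marker_map(self) -> ProbeMarkerMap:
        return ProbeMarkerMap(er=self.er_probe, pr=self.pr_probe, her2=self.her2_probe)


def _stage_seeds(master: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def run_all(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    truth: GroundTruth | None = None,
) -> dict:
    """Execute every stage and return the machine-readable run report.

    ``matrix`` (and optionally ``truth``) may be passed directly instead of
    configuring inputs; otherwise ``input_paths`` or ``sim`` is used.
    Conservation identities maintained by construction: samples in =
    non-TNBC + demoted + final TNBC, and TNBC = sum of subtype counts
    (classified) + UNS.
    """
    t0 = time.time()
    sim_seed, gmm_seed, consensus_seed, _reserve = _stage_seeds(config.seed)
    report: dict = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": _jsonable(config.to_dict()),
        "stages": {},
    }

    # --- inputs ---------------------------------------------------------
    if matrix is None:
        if config.input_paths:
            cohorts = [read_expression_tsv(p) for p in config.input_paths]
            matrix = merge_cohorts(cohorts)
        elif config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=sim_seed)
            matrix, truth = generate_cohort(sim)
        else:
            raise ValueError("run_all needs input_paths, a sim config, or a matrix")
    report["stages"]["input"] = {
        "n_samples": matrix.n_samples,
        "n_probes": matrix.n_probes,
        "n_datasets": int(matrix.batch.nunique()),
    }
    logger.info("input: %d probes x %d samples", matrix.n_probes, matrix.n_samples)

    # --- per-dataset normalization -------------------------------------
    normalized = preprocess.normalize_per_dataset(matrix)

    # --- receptor calling ----------------------------------------------
    marker_map = config.marker_map()
    calls = receptor.call_receptor_status(
        normalized, marker_map, cutoff=config.cutoff,
        negative_rule=config.negative_rule, seed=gmm_seed,
    )
    controls = list(calls.negative.index[(~calls.negative).all(axis=1)])
    if config.use_positive_controls and controls:
        calls = receptor.confirm_against_positive_controls(
            normalized, calls, controls, marker_map, quantile=config.control_quantile
        )
    elif config.use_positive_controls:
        logger.warning("no triple-positive control samples found; confirmation skipped")
    tnbc_ids = list(calls.tnbc_final.index[calls.tnbc_final])
    n_demoted = int((calls.demoted & calls.tnbc).sum())
    report["stages"]["receptor_calling"] = {
        "n_tnbc": len(tnbc_ids),
        "n_non_tnbc": int((~calls.tnbc).sum()),
        "n_demoted": n_demoted,
        "n_controls": len(controls),
        "mixture_fits": {
            m: dataclasses.asdict(fit) for m, fit in calls.fits.items()
        },
    }
    logger.info("receptor calling: %d TNBC, %d demoted", len(tnbc_ids), n_demoted)
    if len(tnbc_ids) <= config.k_max:
        raise RuntimeError(
            f"receptor_calling left only {len(tnbc_ids)} TNBC samples; "
            f"need more than k_max={config.k_max} to subtype"
        )

    # --- SD filter ------------------------------------------------------
    tnbc_matrix = normalized.subset_samples(tnbc_ids)
    sd_result = preprocess.filter_by_sd(tnbc_matrix, config.sd_threshold)
    filtered = sd_result.apply(tnbc_matrix)
    report["stages"]["sd_filter"] = {
        "threshold": sd_result.threshold,
        "n_probes_in": tnbc_matrix.n_probes,
        "n_probes_retained": len(sd_result.retained),
    }

    # --- consensus subtyping -------------------------------------------
    result = cons.run_consensus(
        filtered, k_min=config.k_min, k_max=config.k_max,
        n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction,
        delta_threshold=config.delta_threshold,
        seed=consensus_seed, n_init=config.kmeans_restarts,
    )
    consensus_counts = result.labels.value_counts().sort_index()
    report["stages"]["consensus"] = {
        "chosen_k": result.chosen_k,
        "areas": {str(k): v for k, v in result.areas.items()},
        "delta_areas": {str(k): v for k, v in result.deltas.items()},
        "cluster_counts": {str(k): int(v) for k, v in consensus_counts.items()},
    }
    logger.info("consensus subtyping: chose k=%d", result.chosen_k)

    # --- signature selection -------------------------------------------
    selected = sig.select_all_signatures(
        tnbc_matrix, result.labels,
        fc_up=config.fc_up, fc_down=config.fc_down,
        min_fraction=config.min_fraction, max_p=config.max_p,
    )
    report["stages"]["signature_selection"] = {
        s: {"n_up": len(selected.up.get(s, [])), "n_down": len(selected.down.get(s, []))}
        for s in selected.subtypes
    }

    # --- classification and cross-tabulation ---------------------------
    if config.signature_file:
        reference = read_signature_lists(config.signature_file)
    else:
        reference = selected
    labels_sig, _scores = classify_by_signatures(
        tnbc_matrix, reference,
        min_score=config.min_score, ambiguity_gap=config.ambiguity_gap,
    )
    classified = labels_sig[labels_sig != UNS]
    proportions = (
        100.0 * classified.value_counts() / len(classified)
        if len(classified) else pd.Series(dtype=float)
    )
    crosstab = cross_tabulate(labels_sig, result.labels)
    report["stages"]["classification"] = {
        "n_classified": int(len(classified)),
        "n_uns": int((labels_sig == UNS).sum()),
        "subtype_counts": {str(k): int(v) for k, v in classified.value_counts().items()},
        "subtype_percent": {str(k): round(float(v), 2) for k, v in proportions.items()},
    }
    report["crosstab"] = {
        "percent": {
            str(c): {str(r): float(crosstab.percent.loc[r, c]) for r in crosstab.percent.index}
            for c in crosstab.percent.columns
        },
        "column_totals": {str(c): int(v) for c, v in crosstab.column_totals.items()},
    }

    # --- conservation & optional truth channel -------------------------
    report["conservation"] = {
        "samples_in": matrix.n_samples,
        "non_tnbc_plus_demoted_plus_tnbc": int((~calls.tnbc).sum()) + n_demoted + len(tnbc_ids),
        "tnbc": len(tnbc_ids),
        "classified_plus_uns": int(len(classified)) + int((labels_sig == UNS).sum()),
    }
    if truth is not None:
        agree = (calls.tnbc_final.reindex(truth.tnbc.index) == truth.tnbc)
        report["truth"] = {
            "tnbc_call_accuracy": float(agree.mean()),
            "true_tnbc": int(truth.tnbc.sum()),
        }
    report["runtime_seconds"] = round(time.time() - t0, 3)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        result.labels.to_csv(out / "consensus_labels.tsv", sep="\t", header=True)
        labels_sig.to_csv(out / "signature_labels.tsv", sep="\t", header=True)
        write_signature_lists(selected, out / "selected_signatures.tsv")
        crosstab.percent.to_csv(out / "crosstab_percent.tsv", sep="\t")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def render_heatmap(
    values: pd.DataFrame,
    path: str | Path,
    row_order: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
    cluster: bool = True,
    cmap: str = "RdBu_r",
) -> Path:
    """Write a clustered heat-map image; presentational only.

    Rows (and columns when no explicit order/labels are given) are ordered
    by average-linkage hierarchical clustering of the Euclidean distances.
    Output size is fixed, so repeated renders of the same input are
    pixel-compatible.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage

    df = values.copy()
    if row_order is not None:
        df = df.loc[list(row_order)]
    elif cluster and df.shape[0] > 2:
        df = df.iloc[leaves_list(linkage(df.to_numpy(), method="average"))]
    if col_labels is not None:
        df = df[list(col_labels)]
    elif cluster and df.shape[1] > 2:
        df = df.iloc[:, leaves_list(linkage(df.to_numpy().T, method="average"))]

    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(df.to_numpy(dtype=float), aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xlabel("samples")
    ax.set_ylabel("probes")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 expression")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
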