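"""Expression-matrix and gene-list I/O plus the shared data model.

The pipeline's working currency is a probes x samples matrix of log2
intensities with a per-sample dataset (batch) label, mirroring the
series-matrix tables GEO distributes for Affymetrix experiments.  Files are
plain TSV: one header row of sample IDs, an optional second ``#batch:`` row
carrying the per-sample dataset labels, then one row per probeset.

Signature gene lists come in either a 3-column TSV (subtype, direction,
gene) or GMT-like rows; both collapse to a :class:`SignatureTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Affymetrix probesets conventionally used to read out the three receptors.
DEFAULT_RECEPTOR_PROBES = {
    "ER": "205225_at",
    "PR": "208305_at",
    "HER2": "216836_s_at",
}

_BATCH_PREFIX = "#batch:"
_UNASSIGNED = "unassigned"


class ExpressionIOError(ValueError):
    """Raised for malformed expression or signature files."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) with per-sample batch labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with one column per sample, on log2
        scale.  Probe and sample IDs must be unique and no entry may be
        missing.
    batch
        Per-sample dataset label, indexed like ``values.columns``.  Defaults
        to a single ``"unassigned"`` label.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.shape[0] == 0:
            raise ExpressionIOError("expression matrix has no probes")
        if self.values.shape[1] == 0:
            raise ExpressionIOError("expression matrix has no samples")
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ExpressionIOError(f"duplicate probe ID: {dup[0]!r}")
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise ExpressionIOError(f"duplicate sample ID: {dup[0]!r}")
        if self.values.isna().any().any():
            raise ExpressionIOError("expression matrix contains missing values")
        if self.batch is None:
            self.batch = pd.Series(_UNASSIGNED, index=self.values.columns)
        else:
            self.batch = pd.Series(self.batch)
            if not self.batch.index.equals(self.values.columns):
                if len(self.batch) != self.values.shape[1]:
                    raise ExpressionIOError(
                        "batch labels do not align with sample IDs"
                    )
                self.batch.index = self.values.columns
        self.batch = self.batch.astype(str)

    # -- light accessors -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.batch.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.batch[ids])

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(probe_ids)
        return ExpressionMatrix(self.values.loc[ids], self.batch.copy())


@dataclass
class ProbeMarkerMap:
    """Receptor marker -> probeset ID map for ER, PR and HER2."""

    er: str = DEFAULT_RECEPTOR_PROBES["ER"]
    pr: str = DEFAULT_RECEPTOR_PROBES["PR"]
    her2: str = DEFAULT_RECEPTOR_PROBES["HER2"]

    def as_dict(self) -> dict[str, str]:
        return {"ER": self.er, "PR": self.pr, "HER2": self.her2}

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        index = set(matrix.probe_ids)
        for marker, probe in self.as_dict().items():
            if probe not in index:
                raise ExpressionIOError(
                    f"probe {probe!r} for marker {marker} not present in matrix"
                )


@dataclass
class SignatureTable:
    """Per-subtype signed gene lists (up- and down-regulated probes)."""

    up: dict[str, list[str]] = field(default_factory=dict)
    down: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for subtype in self.subtypes:
            both = set(self.up.get(subtype, ())) & set(self.down.get(subtype, ()))
            if both:
                raise ExpressionIOError(
                    f"gene {sorted(both)[0]!r} appears in both up and down "
                    f"lists of subtype {subtype!r}"
                )

    @property
    def subtypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in list(self.up) + list(self.down):
            seen.setdefault(key, None)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.up.values()) + sum(
            len(v) for v in self.down.values()
        )

    def genes(self, subtype: str) -> tuple[list[str], list[str]]:
        return list(self.up.get(subtype, [])), list(self.down.get(subtype, []))

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for lists in (self.up, self.down):
            for genes in lists.values():
                for g in genes:
                    seen.setdefault(g, None)
        return list(seen)


# ---------------------------------------------------------------------------
# expression TSV I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, log_transformed: bool = True) -> ExpressionMatrix:
    """Read a TSV expression matrix (probes x samples).

    The first row holds sample IDs; an optional second row starting with
    ``#batch:`` holds per-sample dataset labels.  Rows containing any
    non-numeric cell are dropped with a warning.  When ``log_transformed``
    is false the values are taken as linear intensities and transformed to
    ``log2(x + 1)``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ExpressionIOError(f"{path}: empty file")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        if not sample_ids:
            raise ExpressionIOError(f"{path}: header row has no sample IDs")
        seen: set[str] = set()
        for sid in sample_ids:
            if sid in seen:
                raise ExpressionIOError(f"{path}: duplicate sample ID {sid!r}")
            seen.add(sid)
        second = fh.readline()
    batch = None
    skiprows: list[int] = []
    if second.startswith(_BATCH_PREFIX):
        labels = second.rstrip("\n").split("\t")[1:]
        if len(labels) != len(sample_ids):
            raise ExpressionIOError(
                f"{path}: #batch: row has {len(labels)} labels for "
                f"{len(sample_ids)} samples"
            )
        batch = pd.Series(labels, index=sample_ids)
        skiprows = [1]

    df = pd.read_csv(path, sep="\t", index_col=0, header=0, skiprows=skiprows)
    if df.shape[0] == 0:
        raise ExpressionIOError(f"{path}: no probe rows")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ExpressionIOError(f"{path}: duplicate probe ID {dup[0]!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "%s: dropped %d probe row(s) with non-numeric values (first: %r)",
            path, int(bad.sum()), str(df.index[bad][0]),
        )
        numeric = numeric.loc[~bad]
    if numeric.shape[0] == 0:
        raise ExpressionIOError(f"{path}: no fully numeric probe rows")

    if not log_transformed:
        if (numeric.values < 0).any():
            raise ExpressionIOError(
                f"{path}: negative linear intensities cannot be log2(x+1)-transformed"
            )
        numeric = np.log2(numeric + 1.0)
    return ExpressionMatrix(numeric.astype(float), batch)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a matrix as TSV re-readable by :func:`read_expression_tsv`.

    Batch labels are preserved in a ``#batch:`` sidecar header line.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("probe_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        fh.write(_BATCH_PREFIX + "\t" + "\t".join(matrix.batch.tolist()) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False, lineterminator="\n")
    return path


def merge_cohorts(
    cohorts: Sequence[ExpressionMatrix],
    names: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Merge cohorts on the intersection of their probe sets.

    Samples are concatenated in cohort order (order preserved within each
    cohort) and keep their batch labels; pass ``names`` to relabel each
    cohort's samples with its source-cohort name.  Probe order follows the
    first cohort.  Sample-ID collisions across cohorts are an error.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise ExpressionIOError("merge_cohorts requires at least one cohort")
    if names is not None and len(names) != len(cohorts):
        raise ExpressionIOError("one name per cohort required")
    if len(cohorts) == 1 and names is None:
        return cohorts[0].copy()

    common = set(cohorts[0].probe_ids)
    for c in cohorts[1:]:
        common &= set(c.probe_ids)
    if not common:
        raise ExpressionIOError("probe intersection across cohorts is empty")
    probes = [p for p in cohorts[0].probe_ids if p in common]

    seen: dict[str, int] = {}
    for i, c in enumerate(cohorts):
        for sid in c.sample_ids:
            if sid in seen:
                raise ExpressionIOError(
                    f"sample ID {sid!r} appears in cohorts {seen[sid]} and {i}"
                )
            seen[sid] = i

    values = pd.concat([c.values.loc[probes] for c in cohorts], axis=1)
    if names is not None:
        batch = pd.concat(
            [pd.Series(str(n), index=c.values.columns) for n, c in zip(names, cohorts)]
        )
    else:
        batch = pd.concat([c.batch for c in cohorts])
    return ExpressionMatrix(values, batch)


# ---------------------------------------------------------------------------
# signature lists
# ---------------------------------------------------------------------------

_DIRECTIONS = ("up", "down")


def read_signature_lists(path: str | Path) -> SignatureTable:
    """Read subtype gene lists from a 3-column TSV or GMT-like rows.

    3-column rows are ``subtype<TAB>direction<TAB>gene`` with direction in
    {up, down}.  GMT-like rows are ``NAME<TAB>description<TAB>gene...``
    where a ``_up``/``_down`` suffix on NAME sets the direction (up when
    absent).  Duplicate (subtype, direction, gene) entries collapse with a
    warning.
    """
    path = Path(path)
    up: dict[str, dict[str, None]] = {}
    down: dict[str, dict[str, None]] = {}
    n_dupes = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExpressionIOError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields"
                )
            token = fields[1].strip().lower()
            if token in _DIRECTIONS:
                if len(fields) != 3:
                    raise ExpressionIOError(
                        f"{path}:{lineno}: 3-column signature rows take exactly one gene"
                    )
                subtype, direction, genes = fields[0].strip(), token, [fields[2].strip()]
            elif len(fields) == 3 and fields[0].strip().lower() == "subtype":
                continue  # column header
            elif len(fields) == 3:
                raise ExpressionIOError(
                    f"{path}:{lineno}: unknown direction token {fields[1]!r}"
                )
            else:
                # GMT-like: NAME  description  gene1  gene2 ...
                name = fields[0].strip()
                if name.lower().endswith("_down"):
                    subtype, direction = name[: -len("_down")], "down"
                elif name.lower().endswith("_up"):
                    subtype, direction = name[: -len("_up")], "up"
                else:
                    subtype, direction = name, "up"
                genes = [g.strip() for g in fields[2:] if g.strip()]
            target = up if direction == "up" else down
            bucket = target.setdefault(subtype, {})
            for gene in genes:
                n_rows += 1
                if gene in bucket:
                    n_dupes += 1
                else:
                    bucket[gene] = None
    if n_rows == 0:
        raise ExpressionIOError(f"{path}: no signature entries found")
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate signature entries", path, n_dupes)
    return SignatureTable(
        up={k: list(v) for k, v in up.items()},
        down={k: list(v) for k, v in down.items()},
    )


def write_signature_lists(table: SignatureTable, path: str | Path) -> Path:
    """Write a SignatureTable as the canonical 3-column TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("subtype\tdirection\tgene\n")
        for subtype in table.subtypes:
            for gene in table.up.get(subtype, []):
                fh.write(f"{subtype}\tup\t{gene}\n")
            for gene in table.down.get(subtype, []):
                fh.write(f"{subtype}\tdown\t{gene}\n")
    return path


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("tnbc_subtyper.data").joinpath(name)


def load_cohort_inventory() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the compiled-cohort bookkeeping table.

    Returns ``(per_dataset, printed_totals)``: per-dataset breast-cancer and
    TNBC sample counts for the compiled GEO series, and the column totals as
    printed in the source inventory (kept verbatim; the non-Asian TNBC
    column total is not the arithmetic sum of its cells).
    """
    with resources.as_file(_data_path("cohort_inventory.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    totals = df[df["accession"] == "TOTAL"].set_index("group")
    per_dataset = df[df["accession"] != "TOTAL"].reset_index(drop=True)
    return per_dataset, totals[["bc_cases", "tnbc_cases"]]


def load_validation_signatures() -> SignatureTable:
    """Load the packaged 47-probe five-subtype validation gene list."""
    with resources.as_file(_data_path("tnbc_validation_signatures.tsv")) as p:
        return read_signature_lists(p)
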