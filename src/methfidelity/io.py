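"""Core data types and tabular readers/writers.

Everything downstream consumes beta-value matrices (probes x samples,
values in [0, 1]), per-sample phenotype annotations, and probe-set
signatures.  This module defines those containers, validates their
invariants on construction, and reads/writes the plain-text formats:

* beta matrices: tab-separated, probe ids in the first column, sample ids
  in the header row; empty cells, ``NA`` or ``NaN`` mark missing values
  (written back as ``NA``);
* annotations: comma- or tab-separated with a header, one row per sample;
  free-text phenotype labels are normalized to controlled vocabularies
  (e.g. ``ER+`` -> ``positive``) with a logged warning for unknown tokens;
* signatures: tab-separated with a ``#name=`` header line, a ``probe_id``
  column, optional per-class prototype columns ``proto:<class>`` and
  optional derivation statistics (``statistic``, ``p_value``,
  ``adjusted_p``).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methfidelity")

MISSING_TOKENS = ("", "NA", "NaN", "nan")

ER_LEVELS = ("positive", "negative", "unknown")
SUBTYPE_LEVELS = ("luminal", "basalA", "basalB", "unknown")
SAMPLE_CLASS_LEVELS = ("cell_line", "primary_tumor")

ANNOTATION_COLUMNS = (
    "er_status",
    "her2_status",
    "expression_subtype",
    "sample_class",
    "cimp_status",
)

# Normalization maps for the label spellings seen in public cohort tables.
# Keys are lower-cased, stripped tokens; anything unmapped becomes "unknown".
_BINARY_STATUS_MAP = {
    "positive": "positive",
    "pos": "positive",
    "+": "positive",
    "p": "positive",
    "1": "positive",
    "true": "positive",
    "yes": "positive",
    "er+": "positive",
    "her2+": "positive",
    "cimp+": "positive",
    "amplified": "positive",
    "negative": "negative",
    "neg": "negative",
    "-": "negative",
    "n": "negative",
    "0": "negative",
    "false": "negative",
    "no": "negative",
    "er-": "negative",
    "her2-": "negative",
    "cimp-": "negative",
    "not amplified": "negative",
}

_SUBTYPE_MAP = {
    "luminal": "luminal",
    "lum": "luminal",
    "basala": "basalA",
    "basal a": "basalA",
    "basal_a": "basalA",
    "basal-a": "basalA",
    "basalb": "basalB",
    "basal b": "basalB",
    "basal_b": "basalB",
    "basal-b": "basalB",
}

_SAMPLE_CLASS_MAP = {
    "cell_line": "cell_line",
    "cellline": "cell_line",
    "cell line": "cell_line",
    "line": "cell_line",
    "primary_tumor": "primary_tumor",
    "primary tumor": "primary_tumor",
    "primary": "primary_tumor",
    "tumor": "primary_tumor",
    "tumour": "primary_tumor",
}


class MethFidelityError(ValueError):
    """Base class for validation errors raised by this package."""


class UndefinedBetaError(MethFidelityError):
    """Both methylated and unmethylated signals are zero for a probe."""


# ---------------------------------------------------------------------------
# Beta values from raw intensities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityPair:
    """Methylated/unmethylated signal intensities for one probe."""

    probe_id: str
    m_signal: float
    u_signal: float

    def __post_init__(self) -> None:
        if self.m_signal < 0 or self.u_signal < 0:
            raise MethFidelityError(
                f"probe {self.probe_id!r}: negative signal intensity "
                f"(M={self.m_signal}, U={self.u_signal})"
            )


def compute_beta(pair: IntensityPair) -> float:
    """Methylation fraction beta = M / (M + U) for one probe.

    Raises :class:`UndefinedBetaError` when both signals are zero, naming
    the probe.
    """
    total = pair.m_signal + pair.u_signal
    if total <= 0:
        raise UndefinedBetaError(
            f"beta undefined for probe {pair.probe_id!r}: M + U = 0"
        )
    return pair.m_signal / total


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------

def _check_unique(ids: pd.Index, kind: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise MethFidelityError(f"duplicate {kind} ids: {dupes[:5]}")


class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1]; NaN marks missing.

    Wraps a pandas DataFrame with probes as the index and samples as
    columns (probe-major, matching array-platform convention).
    """

    def __init__(self, values: pd.DataFrame, validate: bool = True):
        values = values.astype(float)
        if validate:
            _check_unique(values.index, "probe")
            _check_unique(values.columns, "sample")
            arr = values.to_numpy()
            bad = (arr < 0) | (arr > 1)
            if np.any(bad & ~np.isnan(arr)):
                r, c = np.argwhere(bad & ~np.isnan(arr))[0]
                raise MethFidelityError(
                    f"beta value {arr[r, c]!r} out of [0, 1] at probe "
                    f"{values.index[r]!r}, sample {values.columns[c]!r}"
                )
        self.values = values

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)], validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return f"BetaMatrix({p} probes x {s} samples)"


class StandardizedMatrix:
    """Per-probe z-scores (mean 0, sd 1 with the n-1 denominator)."""

    def __init__(self, zvalues: pd.DataFrame, validate: bool = True):
        zvalues = zvalues.astype(float)
        if validate:
            _check_unique(zvalues.index, "probe")
            _check_unique(zvalues.columns, "sample")
        self.zvalues = zvalues

    @property
    def probe_ids(self) -> list[str]:
        return list(self.zvalues.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.zvalues.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.zvalues.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return f"StandardizedMatrix({p} probes x {s} samples)"


# ---------------------------------------------------------------------------
# Signatures and result records
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """A named probe set, optionally with per-class centroid prototypes.

    ``prototypes`` is a probes x classes DataFrame of mean standardized
    methylation; ``probe_stats`` carries the derivation statistics
    (statistic, p_value, adjusted_p) indexed by probe_id.
    """

    name: str
    probe_ids: list[str]
    class_labels: list[str] | None = None
    prototypes: pd.DataFrame | None = None
    probe_stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise MethFidelityError(f"signature {self.name!r}: duplicate probe ids")
        if self.prototypes is not None:
            if self.class_labels is None:
                self.class_labels = list(self.prototypes.columns)
            if list(self.prototypes.index) != list(self.probe_ids):
                raise MethFidelityError(
                    f"signature {self.name!r}: prototype rows do not match probe_ids"
                )
            if list(self.prototypes.columns) != list(self.class_labels):
                raise MethFidelityError(
                    f"signature {self.name!r}: prototype columns do not match class_labels"
                )

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class NearestNeighborResult:
    """Best-matching reference sample for one query, with its distance.

    ``distance`` is the Spearman correlation distance to the nearest
    reference profile — the per-sample fidelity score.
    """

    query_id: str
    best_match_id: str
    distance: float
    all_distances: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise MethFidelityError(
                f"negative distance {self.distance} for query {self.query_id!r}"
            )
        if self.all_distances is not None:
            if not math.isclose(
                self.distance, float(self.all_distances.min()), abs_tol=1e-12
            ):
                raise MethFidelityError(
                    f"query {self.query_id!r}: distance is not the minimum "
                    "over all_distances"
                )


@dataclass
class GroupTestResult:
    """A t- or F-test on a per-sample quantity across phenotype groups."""

    statistic: float
    statistic_kind: str  # "t" or "F"
    df: float | tuple[float, float]
    p_value: float
    group_means: pd.Series
    adjusted_p: float | None = None
    alpha: float = 0.05
    variant: str | None = None  # t-tests record "welch" or "pooled"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise MethFidelityError(f"p-value {self.p_value} outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise MethFidelityError("adjusted p-value below raw p-value")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "statistic_kind": self.statistic_kind,
            "df": self.df if np.isscalar(self.df) else list(self.df),
            "p_value": float(self.p_value),
            "group_means": {str(k): float(v) for k, v in self.group_means.items()},
            "adjusted_p": None if self.adjusted_p is None else float(self.adjusted_p),
            "alpha": self.alpha,
            "variant": self.variant,
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, dialect: str = "\t") -> BetaMatrix:
    """Read a probes x samples beta matrix from tab-separated text.

    First column holds probe ids, header row holds sample ids; empty
    cells, ``NA`` and ``NaN`` mark missing.  Duplicate ids, non-numeric
    cells and out-of-range values are rejected with coordinates.
    """
    df = pd.read_csv(
        path, sep=dialect, index_col=0,
        na_values=list(MISSING_TOKENS), keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                probe = df.index[bad.to_numpy().nonzero()[0][0]]
                raise MethFidelityError(
                    f"non-numeric cell {df.loc[probe, col]!r} at probe "
                    f"{probe!r}, sample {col!r} in {path}"
                )
            df[col] = coerced
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    """Write a beta matrix as tab-separated text (missing -> ``NA``)."""
    matrix.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g",
                         index_label="probe_id")


def _normalize_binary(token: object, column: str, sample_id: str) -> str:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return "unknown"
    key = str(token).strip().lower()
    if key in ("", "na", "nan", "unknown", "?"):
        return "unknown"
    mapped = _BINARY_STATUS_MAP.get(key)
    if mapped is None:
        logger.warning(
            "unrecognized %s label %r for sample %r mapped to 'unknown'",
            column, token, sample_id,
        )
        return "unknown"
    return mapped


def _normalize_enum(token: object, mapping: dict, column: str, sample_id: str) -> str:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return "unknown"
    key = str(token).strip().lower()
    if key in ("", "na", "nan", "unknown", "?"):
        return "unknown"
    mapped = mapping.get(key)
    if mapped is None:
        logger.warning(
            "unrecognized %s label %r for sample %r mapped to 'unknown'",
            column, token, sample_id,
        )
        return "unknown"
    return mapped


def read_annotations(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a per-sample annotation table (comma- or tab-separated).

    Returns a DataFrame indexed by sample_id with the columns
    er_status, her2_status, expression_subtype, sample_class and
    cimp_status, each normalized to its controlled vocabulary; columns
    absent from the file are filled with ``unknown``.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str,
                      na_values=list(MISSING_TOKENS), keep_default_na=False)
    cols = {c.strip().lower(): c for c in raw.columns}
    if "sample_id" not in cols:
        raise MethFidelityError(f"annotation file {path} lacks a sample_id column")
    raw = raw.set_index(cols["sample_id"])
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "sample")
    raw.index.name = "sample_id"

    out = pd.DataFrame(index=raw.index)
    for column in ANNOTATION_COLUMNS:
        source = cols.get(column)
        if source is None:
            out[column] = "unknown"
            continue
        series = raw[source]
        if column == "expression_subtype":
            out[column] = [
                _normalize_enum(v, _SUBTYPE_MAP, column, s)
                for s, v in series.items()
            ]
        elif column == "sample_class":
            out[column] = [
                _normalize_enum(v, _SAMPLE_CLASS_MAP, column, s)
                for s, v in series.items()
            ]
        else:
            out[column] = [
                _normalize_binary(v, column, s) for s, v in series.items()
            ]
    return out


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    annotations.to_csv(path, sep=sep, na_rep="NA", index_label="sample_id")


def align_annotations(
    matrix: BetaMatrix, annotations: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """Restrict an annotation table to the samples of a matrix.

    Mismatched sample ids trigger a warning and the intersection is used;
    in strict mode any mismatch is an error.
    """
    matrix_ids = set(matrix.sample_ids)
    annot_ids = set(annotations.index)
    if matrix_ids != annot_ids:
        missing = sorted(matrix_ids - annot_ids)
        extra = sorted(annot_ids - matrix_ids)
        msg = (
            f"annotation/matrix sample mismatch: {len(missing)} samples "
            f"without annotation {missing[:5]}, {len(extra)} annotations "
            f"without sample {extra[:5]}"
        )
        if strict:
            raise MethFidelityError(msg)
        logger.warning(msg)
    shared = [s for s in matrix.sample_ids if s in annot_ids]
    return annotations.loc[shared]


def read_signature(path: str | Path) -> Signature:
    """Read a signature file: ``#name=`` header, then a tab-separated table.

    Recognized columns: ``probe_id`` (required), prototype columns
    ``proto:<class>``, and statistics ``statistic``/``p_value``/``adjusted_p``.
    """
    path = Path(path)
    name = path.stem
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#name="):
            name = first[len("#name="):]
            table = pd.read_csv(fh, sep="\t", dtype={"probe_id": str})
        else:
            fh.seek(0)
            table = pd.read_csv(fh, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in table.columns:
        raise MethFidelityError(f"signature file {path} lacks a probe_id column")
    probe_ids = table["probe_id"].astype(str).tolist()

    proto_cols = [c for c in table.columns if c.startswith("proto:")]
    prototypes = None
    class_labels = None
    if proto_cols:
        class_labels = [c[len("proto:"):] for c in proto_cols]
        prototypes = table[proto_cols].astype(float)
        prototypes.columns = class_labels
        prototypes.index = pd.Index(probe_ids, name="probe_id")

    stat_cols = [c for c in ("statistic", "p_value", "adjusted_p")
                 if c in table.columns]
    probe_stats = None
    if stat_cols:
        probe_stats = table[stat_cols].astype(float)
        probe_stats.index = pd.Index(probe_ids, name="probe_id")

    return Signature(name=name, probe_ids=probe_ids, class_labels=class_labels,
                     prototypes=prototypes, probe_stats=probe_stats)


def write_signature(signature: Signature, path: str | Path) -> None:
    table = pd.DataFrame({"probe_id": signature.probe_ids})
    if signature.prototypes is not None:
        for cls in signature.class_labels or []:
            table[f"proto:{cls}"] = signature.prototypes[cls].to_numpy()
    if signature.probe_stats is not None:
        for col in signature.probe_stats.columns:
            table[col] = signature.probe_stats[col].to_numpy()
    with open(path, "w") as fh:
        fh.write(f"#name={signature.name}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA",
                     float_format="%.6g")


def write_results(results: Iterable[NearestNeighborResult],
                  path: str | Path,
                  summary: dict | None = None) -> None:
    """Write nearest-neighbor results as TSV, plus a JSON summary sidecar."""
    rows = [
        {"query_id": r.query_id, "best_match_id": r.best_match_id,
         "distance": r.distance}
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=["query_id", "best_match_id", "distance"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if summary is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


def nn_results_to_frame(results: Iterable[NearestNeighborResult]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {"query_id": r.query_id, "best_match_id": r.best_match_id,
             "distance": r.distance}
            for r in results
        ],
        columns=["query_id", "best_match_id", "distance"],
    )
    return frame.set_index("query_id")
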