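"""Signature derivation and nearest-centroid phenotype transfer.

Published methylation phenotypes (binary ER, binary B-CIMP, the 6-class
methylation taxonomy) are moved between cohorts with one 3-step
procedure:

1. standardize each cohort's betas per probe *within that cohort*;
2. average the standardized values of the training cohort within each
   phenotype class to build per-class prototype profiles (centroids)
   over the signature probes;
3. Spearman-correlate every test sample's z-vector with each prototype
   over the shared signature probes and assign the best-correlated
   class.

Signatures themselves are probe subsets whose BH-adjusted p-values fall
below an FDR threshold (default 0.01, strict ``<`` per "below 0.01").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethFidelityError, Signature, StandardizedMatrix
from .scores import bh_adjust

logger = logging.getLogger("methfidelity")

#: Minimum fraction of signature probes that must be present in a cohort.
DEFAULT_MIN_SIGNATURE_COVERAGE = 0.8
DEFAULT_FDR_THRESHOLD = 0.01


@dataclass
class ClassAssignment:
    """One test sample's nearest-prototype call.

    ``correlations`` maps class label -> Spearman rho; ``margin`` is the
    best rho minus the runner-up (0 for a single class).
    """

    sample_id: str
    assigned_class: str
    correlations: pd.Series
    margin: float

    def __post_init__(self) -> None:
        best = self.correlations.max()
        if not np.isclose(self.correlations[self.assigned_class], best):
            raise MethFidelityError(
                f"sample {self.sample_id!r}: assigned class does not "
                "maximize correlation"
            )
        if self.margin < -1e-12:
            raise MethFidelityError("negative assignment margin")


def derive_fdr_signature(
    probe_stats: pd.DataFrame,
    threshold: float = DEFAULT_FDR_THRESHOLD,
    name: str = "fdr_signature",
    strict: bool = True,
) -> Signature:
    """Probes whose BH-adjusted p-value falls below an FDR threshold.

    ``probe_stats`` must carry a ``p_value`` column and either a
    ``probe_id`` column or a probe-id index.  ``strict`` selects with
    ``adjusted < threshold`` (the default, matching "false discovery
    rate below 0.01"); ``strict=False`` uses ``<=``.
    """
    if probe_stats is None or len(probe_stats) == 0:
        raise MethFidelityError("empty probe statistics table")
    if not (0 < threshold < 1):
        raise MethFidelityError(f"FDR threshold {threshold} outside (0, 1)")
    table = probe_stats.copy()
    if "probe_id" in table.columns:
        table = table.set_index("probe_id")
    if "p_value" not in table.columns:
        raise MethFidelityError("probe statistics lack a p_value column")
    table.index = table.index.astype(str)
    adjusted = bh_adjust(table["p_value"].to_numpy(float))
    table["adjusted_p"] = adjusted
    selected = adjusted < threshold if strict else adjusted <= threshold
    if not selected.any():
        logger.warning("derive_fdr_signature: no probes pass FDR %s %g",
                       "<" if strict else "<=", threshold)
    probe_ids = list(table.index[selected])
    stats_cols = [c for c in ("statistic", "p_value", "adjusted_p")
                  if c in table.columns]
    return Signature(name=name, probe_ids=probe_ids,
                     probe_stats=table.loc[selected, stats_cols])


def build_prototypes(
    train: StandardizedMatrix,
    labels: pd.Series,
    signature: Signature,
    min_signature_coverage: float = DEFAULT_MIN_SIGNATURE_COVERAGE,
) -> Signature:
    """Per-class mean standardized profiles over the signature probes.

    Signature probes absent from the training matrix are dropped
    (intersection) with the coverage fraction logged; coverage below
    ``min_signature_coverage`` is an error, as is any class with zero
    training samples.  Missing values are ignored within each class
    mean.
    """
    shared = [p for p in signature.probe_ids if p in set(train.probe_ids)]
    coverage = len(shared) / len(signature.probe_ids) if signature.probe_ids else 0.0
    logger.info("build_prototypes: %d/%d signature probes present "
                "(coverage %.3f)", len(shared), len(signature.probe_ids), coverage)
    if coverage < min_signature_coverage:
        raise MethFidelityError(
            f"signature coverage {coverage:.3f} below the "
            f"{min_signature_coverage} floor"
        )
    labels = labels.reindex(train.sample_ids)
    mask = labels.notna() & (labels != "unknown")
    classes = sorted(labels[mask].unique())
    if not classes:
        raise MethFidelityError("no labelled training samples")
    z = train.zvalues.loc[shared]
    prototypes = {}
    for cls in classes:
        members = labels.index[(labels == cls) & mask]
        if len(members) == 0:
            raise MethFidelityError(f"class {cls!r} has zero training samples")
        prototypes[cls] = z[members].mean(axis=1)
    proto = pd.DataFrame(prototypes, columns=classes)
    return Signature(name=signature.name, probe_ids=shared,
                     class_labels=classes, prototypes=proto,
                     probe_stats=(signature.probe_stats.loc[
                         [p for p in shared if p in signature.probe_stats.index]]
                         if signature.probe_stats is not None else None))


def _spearman_to_prototypes(sample: np.ndarray,
                            proto_ranks: np.ndarray,
                            present: np.ndarray,
                            classes: list[str]) -> pd.Series:
    """Spearman rho of one sample against each prototype column."""
    rho = {}
    x = sample[present]
    xr = stats.rankdata(x)
    if np.ptp(xr) == 0:
        raise MethFidelityError("sample is constant over signature probes")
    for j, cls in enumerate(classes):
        yr = stats.rankdata(proto_ranks[present, j])
        rho[cls] = float(np.corrcoef(xr, yr)[0, 1])
    return pd.Series(rho)


def assign_class(
    test: StandardizedMatrix,
    signature: Signature,
    min_signature_coverage: float = DEFAULT_MIN_SIGNATURE_COVERAGE,
) -> pd.DataFrame:
    """Assign each test sample to its best Spearman-correlated prototype.

    ``test`` must already be standardized within its own dataset.  The
    probe universe is the intersection of the signature probes with the
    test matrix (coverage floor applies); per sample, missing values are
    dropped pairwise and at least 3 shared probes are required.  Ties
    between classes are broken by class label ascending and logged.

    Returns a DataFrame indexed by sample_id with ``assigned_class``,
    ``rho_<class>`` columns and ``margin`` (best rho minus second best).
    """
    if signature.prototypes is None:
        raise MethFidelityError(
            f"signature {signature.name!r} has no prototypes; run "
            "build_prototypes first"
        )
    shared = [p for p in signature.probe_ids if p in set(test.probe_ids)]
    coverage = len(shared) / len(signature.probe_ids)
    logger.info("assign_class: %d/%d signature probes shared (coverage %.3f)",
                len(shared), len(signature.probe_ids), coverage)
    if coverage < min_signature_coverage:
        raise MethFidelityError(
            f"signature coverage {coverage:.3f} below the "
            f"{min_signature_coverage} floor"
        )
    if len(shared) < 3:
        raise MethFidelityError(
            f"only {len(shared)} shared signature probes; >=3 required"
        )
    classes = list(signature.class_labels)
    proto = signature.prototypes.loc[shared].to_numpy(float)
    z = test.zvalues.loc[shared]

    rows = []
    for sample_id in z.columns:
        vec = z[sample_id].to_numpy(float)
        present = ~np.isnan(vec)
        if present.sum() < 3:
            raise MethFidelityError(
                f"sample {sample_id!r}: fewer than 3 non-missing signature probes"
            )
        rho = _spearman_to_prototypes(vec, proto, present, classes)
        best = rho.max()
        winners = sorted(rho.index[np.isclose(rho, best, atol=1e-12)])
        if len(winners) > 1:
            logger.warning("assign_class: tie between %s for sample %r; "
                           "choosing %r", winners, sample_id, winners[0])
        assigned = winners[0]
        margin = 0.0 if len(rho) == 1 else float(best - rho.drop(assigned).max())
        row = {"assigned_class": assigned, "margin": max(margin, 0.0)}
        row.update({f"rho_{c}": rho[c] for c in classes})
        rows.append(pd.Series(row, name=sample_id))
    out = pd.DataFrame(rows)
    out.index.name = "sample_id"
    return out


def assignments_to_records(assignments: pd.DataFrame) -> list[ClassAssignment]:
    """Convert an assign_class frame into per-sample records."""
    rho_cols = [c for c in assignments.columns if c.startswith("rho_")]
    records = []
    for sample_id, row in assignments.iterrows():
        correlations = pd.Series(
            {c[len("rho_"):]: row[c] for c in rho_cols}
        )
        records.append(ClassAssignment(
            sample_id=str(sample_id),
            assigned_class=row["assigned_class"],
            correlations=correlations,
            margin=float(row["margin"]),
        ))
    return records


def _flag(er: str, cimp: str, er_want: str, cimp_want: str):
    if er == "unknown" or cimp == "unknown":
        return pd.NA
    return er == er_want and cimp == cimp_want


def composite_phenotype(
    annotations: pd.DataFrame,
    cimp_calls: pd.Series | None = None,
    er_calls: pd.Series | None = None,
    class_calls: pd.Series | None = None,
) -> pd.DataFrame:
    """One row per sample combining IHC status with transferred phenotypes.

    Columns: ``ihc_er``, ``ihc_her2``, ``predicted_cimp``,
    ``predicted_er``, ``methylation_class``, plus the two discordance
    flags ``er_plus_cimp_minus`` (IHC ER+ but predicted CIMP-) and
    ``er_minus_cimp_plus`` (IHC ER- but predicted CIMP+).  Flags use
    three-valued logic: any unknown input yields a missing flag, not
    False.
    """
    out = pd.DataFrame(index=annotations.index)
    out["ihc_er"] = annotations["er_status"]
    out["ihc_her2"] = annotations["her2_status"]

    def aligned(calls):
        if calls is None:
            return pd.Series("unknown", index=out.index)
        return calls.reindex(out.index).fillna("unknown")

    out["predicted_cimp"] = aligned(cimp_calls)
    out["predicted_er"] = aligned(er_calls)
    out["methylation_class"] = aligned(class_calls)
    out["er_plus_cimp_minus"] = [
        _flag(er, cp, "positive", "negative")
        for er, cp in zip(out["ihc_er"], out["predicted_cimp"])
    ]
    out["er_minus_cimp_plus"] = [
        _flag(er, cp, "negative", "positive")
        for er, cp in zip(out["ihc_er"], out["predicted_cimp"])
    ]
    out.index.name = "sample_id"
    return out
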