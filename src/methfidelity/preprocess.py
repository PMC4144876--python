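"""Variable-probe selection and per-probe standardization.

The shared front end of clustering, hypermethylation scoring and
signature transfer: pick the most variable CpG probes (by per-probe
standard deviation, n-1 denominator) and convert beta values to
per-probe z-scores computed within the dataset at hand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, MethFidelityError, StandardizedMatrix

logger = logging.getLogger("methfidelity")

#: Fraction of probes kept by default ("most variable 2%"); the top-1%
#: alternative used for the published heatmap is available by passing 0.01.
DEFAULT_VARIABLE_FRACTION = 0.02
DEFAULT_MIN_NONMISSING = 2


@dataclass
class VariableProbeSelection:
    """The top-variance probe subset of one dataset.

    ``sd_values`` holds the per-probe standard deviations of every
    eligible probe, sorted descending (ties broken by probe id);
    ``probe_ids`` are the selected top ``ceil(fraction * n_eligible)``.
    """

    probe_ids: list[str]
    fraction: float
    sd_values: pd.Series

    def __len__(self) -> int:
        return len(self.probe_ids)


def _frame_of(matrix) -> pd.DataFrame:
    if isinstance(matrix, BetaMatrix):
        return matrix.values
    if isinstance(matrix, StandardizedMatrix):
        return matrix.zvalues
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected a matrix container, got {type(matrix)!r}")


def select_variable_probes(
    matrix,
    fraction: float = DEFAULT_VARIABLE_FRACTION,
    min_nonmissing: int = DEFAULT_MIN_NONMISSING,
) -> VariableProbeSelection:
    """Select the most variable ``fraction`` of probes by standard deviation.

    Probes with fewer than ``min_nonmissing`` non-missing values are
    excluded before ranking (and logged).  Ties are broken by probe id
    ascending, so the selection is deterministic and invariant to sample
    order.
    """
    if not (0 < fraction <= 1):
        raise MethFidelityError(f"fraction {fraction} outside (0, 1]")
    values = _frame_of(matrix)
    counts = values.notna().sum(axis=1)
    eligible = values.loc[counts >= max(min_nonmissing, 2)]
    n_dropped = len(values) - len(eligible)
    if n_dropped:
        logger.info("select_variable_probes: excluded %d probes with <%d "
                    "non-missing values", n_dropped, max(min_nonmissing, 2))
    if eligible.empty:
        raise MethFidelityError("no probes with enough non-missing values")

    sd = eligible.std(axis=1, ddof=1)
    order = sorted(sd.index, key=lambda p: (-sd[p], p))
    sd_sorted = sd.loc[order]
    n_select = math.ceil(fraction * len(sd_sorted))
    selected = list(sd_sorted.index[:n_select])
    return VariableProbeSelection(
        probe_ids=selected, fraction=fraction, sd_values=sd_sorted
    )


def standardize(matrix, probe_subset=None) -> StandardizedMatrix:
    """Per-probe z-scores within the dataset: subtract the mean, divide by sd.

    ``probe_subset`` may be a :class:`VariableProbeSelection`, a list of
    probe ids, or None (all probes).  The mean and sd (n-1 denominator)
    are computed over each probe's non-missing entries.  Probes with
    fewer than two non-missing values or zero sd are dropped with a
    logged warning; an empty result is an error.

    Standardization is always computed within the matrix being
    processed, never from training-set moments, so test cohorts are
    directly comparable to prototypes built the same way.
    """
    values = _frame_of(matrix)
    if probe_subset is not None:
        if isinstance(probe_subset, VariableProbeSelection):
            probe_ids = probe_subset.probe_ids
        else:
            probe_ids = list(probe_subset)
        missing = [p for p in probe_ids if p not in values.index]
        if missing:
            raise MethFidelityError(
                f"{len(missing)} requested probes absent from matrix, "
                f"e.g. {missing[:5]}"
            )
        values = values.loc[probe_ids]

    counts = values.notna().sum(axis=1)
    sd = values.std(axis=1, ddof=1)
    keep = (counts >= 2) & (sd > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("standardize: dropped %d probes with <2 values or "
                       "zero standard deviation", n_dropped)
    if not keep.any():
        raise MethFidelityError("no probes left after dropping zero-sd probes")
    kept = values.loc[keep]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[keep], axis=0)
    return StandardizedMatrix(z, validate=False)
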