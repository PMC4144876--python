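"""Sample-to-sample Spearman correlation distances and fidelity scoring.

Every query profile (typically a cell line) is compared to every
reference profile (typically a primary tumor) by Spearman correlation
distance, and the distance to the nearest reference is the query's
fidelity score: how closely the cell line resembles *some* primary
tumor.  The operations are metric-generic — any sample-by-feature
matrix (methylation betas, expression intensities) works, and no
methylation-specific logic lives here.

Two distance conventions are supported: ``one_minus_rho`` (d = 1 - rho,
default) and ``one_minus_abs_rho`` (d = 1 - |rho|); the convention used
is recorded in every output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, GroupTestResult, MethFidelityError, NearestNeighborResult
from .scores import one_way_f_test

logger = logging.getLogger("methfidelity")

CONVENTIONS = ("one_minus_rho", "one_minus_abs_rho")
DEFAULT_CONVENTION = "one_minus_rho"
MIN_SHARED_VALUES = 3


@dataclass
class DistanceMatrix:
    """Query x reference Spearman correlation distances."""

    distances: pd.DataFrame
    convention: str

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise MethFidelityError(f"unknown convention {self.convention!r}")
        upper = 2.0 if self.convention == "one_minus_rho" else 1.0
        arr = self.distances.to_numpy(float)
        if np.any(arr < -1e-9) or np.any(arr > upper + 1e-9):
            raise MethFidelityError(
                f"distances outside [0, {upper}] under {self.convention}"
            )

    @property
    def query_ids(self) -> list[str]:
        return list(self.distances.index)

    @property
    def reference_ids(self) -> list[str]:
        return list(self.distances.columns)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, BetaMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected BetaMatrix or DataFrame, got {type(matrix)!r}")


def _distance_from_rho(rho: np.ndarray, convention: str) -> np.ndarray:
    if convention == "one_minus_rho":
        return np.clip(1.0 - rho, 0.0, 2.0)
    return np.clip(1.0 - np.abs(rho), 0.0, 1.0)


def spearman_distance(x, y, convention: str = DEFAULT_CONVENTION) -> float:
    """Spearman correlation distance between two paired value vectors.

    Missing entries are dropped pairwise; at least 3 paired values are
    required and neither vector may be constant over the pairing.  Ranks
    use average-rank tie handling; rho is the Pearson correlation of the
    ranks.
    """
    if convention not in CONVENTIONS:
        raise MethFidelityError(f"unknown convention {convention!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MethFidelityError("vectors have different lengths")
    paired = ~(np.isnan(x) | np.isnan(y))
    if paired.sum() < MIN_SHARED_VALUES:
        raise MethFidelityError(
            f"only {int(paired.sum())} paired non-missing values; "
            f">={MIN_SHARED_VALUES} required"
        )
    xr = stats.rankdata(x[paired])
    yr = stats.rankdata(y[paired])
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise MethFidelityError("constant vector over the pairing")
    rho = float(np.corrcoef(xr, yr)[0, 1])
    return float(_distance_from_rho(np.array(rho), convention))


def pairwise_distances(
    query,
    reference,
    convention: str = DEFAULT_CONVENTION,
    probes=None,
    min_shared_fraction: float = 0.5,
) -> DistanceMatrix:
    """Full query x reference Spearman distance matrix.

    The probe universe is the intersection of the two matrices' probe
    ids ("all shared" policy, the default) or an explicit ``probes``
    subset.  Complete matrices take a vectorized path (rank each sample
    once, correlate rank matrices); missing values fall back to
    pairwise-complete computation per pair, warning when a pair shares
    fewer than ``min_shared_fraction`` of the universe.
    """
    qf = _as_frame(query)
    rf = _as_frame(reference)
    if probes is not None:
        universe = [p for p in probes if p in qf.index and p in rf.index]
    else:
        universe = [p for p in qf.index if p in set(rf.index)]
    if len(universe) < MIN_SHARED_VALUES:
        raise MethFidelityError(
            f"only {len(universe)} shared probes between query and reference"
        )
    q = qf.loc[universe]
    r = rf.loc[universe]

    if not q.isna().any().any() and not r.isna().any().any():
        qr = np.apply_along_axis(stats.rankdata, 0, q.to_numpy(float))
        rr = np.apply_along_axis(stats.rankdata, 0, r.to_numpy(float))
        if np.any(np.ptp(qr, axis=0) == 0) or np.any(np.ptp(rr, axis=0) == 0):
            raise MethFidelityError("constant sample profile over shared probes")
        nq, nr = q.shape[1], r.shape[1]
        combined = np.corrcoef(qr, rr, rowvar=False)
        rho = combined[:nq, nq:]
        dist = _distance_from_rho(rho, convention)
    else:
        dist = np.empty((q.shape[1], r.shape[1]))
        floor = int(np.ceil(min_shared_fraction * len(universe)))
        for i, qs in enumerate(q.columns):
            xv = q[qs].to_numpy(float)
            for j, rs in enumerate(r.columns):
                yv = r[rs].to_numpy(float)
                paired = int((~(np.isnan(xv) | np.isnan(yv))).sum())
                if paired < floor:
                    logger.warning(
                        "pairwise_distances: pair (%s, %s) shares only "
                        "%d/%d values", qs, rs, paired, len(universe)
                    )
                dist[i, j] = spearman_distance(xv, yv, convention)
    frame = pd.DataFrame(dist, index=q.columns, columns=r.columns)
    frame.index.name = "query_id"
    return DistanceMatrix(distances=frame, convention=convention)


def nearest_reference(dm: DistanceMatrix) -> list[NearestNeighborResult]:
    """Per query, the argmin reference and its distance (the fidelity score).

    Ties are broken by reference id ascending and logged.
    """
    if dm.distances.empty:
        raise MethFidelityError("empty distance matrix")
    ordered = dm.distances[sorted(dm.reference_ids)]
    results = []
    for query_id, row in ordered.iterrows():
        best = row.min()
        winners = sorted(row.index[np.isclose(row, best, atol=1e-12)])
        if len(winners) > 1:
            logger.warning("nearest_reference: tie among %s for query %r; "
                           "choosing %r", winners, query_id, winners[0])
        results.append(NearestNeighborResult(
            query_id=str(query_id),
            best_match_id=str(winners[0]),
            distance=float(best),
            all_distances=row,
        ))
    return results


def group_distance_comparison(
    nn_results: list[NearestNeighborResult] | pd.Series,
    groups: pd.Series,
    alpha: float = 0.05,
) -> tuple[GroupTestResult, pd.DataFrame, float]:
    """One-way ANOVA of nearest-reference distances across phenotype groups.

    Returns the F-test, a per-group five-number summary table (n, min,
    q1, median, q3, max) and the overall median distance — the data
    behind a per-group fidelity boxplot with its all-sample reference
    line.
    """
    if isinstance(nn_results, pd.Series):
        distances = nn_results.astype(float)
    else:
        distances = pd.Series(
            {r.query_id: r.distance for r in nn_results}, dtype=float
        )
    test = one_way_f_test(distances, groups, alpha=alpha)
    groups = groups.reindex(distances.index)
    mask = groups.notna() & (groups != "unknown")
    rows = {}
    for g in sorted(groups[mask].unique()):
        vals = distances[groups == g]
        rows[g] = {
            "n": int(len(vals)),
            "min": float(vals.min()),
            "q1": float(vals.quantile(0.25)),
            "median": float(vals.median()),
            "q3": float(vals.quantile(0.75)),
            "max": float(vals.max()),
        }
    summaries = pd.DataFrame(rows).T
    summaries.index.name = "group"
    overall_median = float(distances.median())
    return test, summaries, overall_median
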