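"""Global hypermethylation score and group-level statistics.

The hypermethylation score summarizes each sample's overall promoter
methylation over the highly variable probes used for clustering: betas
are standardized per probe, then the z-scores are averaged across probes
within each sample.  A score above zero means the sample is more
frequently methylated than the dataset average.

Group-level machinery: a two-group t-test on scores (Welch by default,
pooled available), per-probe one-way fixed-effects ANOVA with per-group
mean betas, and Benjamini-Hochberg adjustment across probes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, GroupTestResult, MethFidelityError, StandardizedMatrix

logger = logging.getLogger("methfidelity")


def hypermethylation_score(std: StandardizedMatrix) -> pd.DataFrame:
    """Per-sample mean of per-probe z-scores.

    Returns a DataFrame indexed by sample_id with columns ``score`` and
    ``n_probes_used``.  Samples whose values are all missing get a NaN
    score and are logged.  On a complete matrix the scores sum to zero
    by construction (each z row sums to zero).
    """
    if std.shape[0] < 1:
        raise MethFidelityError("standardized matrix has no probes")
    z = std.zvalues
    n_used = z.notna().sum(axis=0)
    score = z.mean(axis=0)
    empty = n_used == 0
    if empty.any():
        logger.warning("hypermethylation_score: %d samples with no "
                       "non-missing values flagged (score missing): %s",
                       int(empty.sum()), list(z.columns[empty])[:5])
    out = pd.DataFrame({"score": score, "n_probes_used": n_used.astype(int)})
    out.index.name = "sample_id"
    return out


def two_group_t_test(
    scores: pd.Series,
    labels: pd.Series,
    variant: str = "welch",
    group_order: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Two-sided t-test comparing scores between two phenotype groups.

    Samples with an ``unknown`` label or a missing score are excluded.
    ``variant`` is ``"welch"`` (default) or ``"pooled"``.  The statistic
    is mean(first group) - mean(second group); by default groups are
    ordered by label descending so that "positive" leads "negative" and
    a hypermethylated positive group yields a positive t.
    """
    if variant not in ("welch", "pooled"):
        raise MethFidelityError(f"unknown t-test variant {variant!r}")
    labels = labels.reindex(scores.index)
    mask = labels.notna() & (labels != "unknown") & scores.notna()
    scores, labels = scores[mask], labels[mask]
    levels = sorted(labels.unique(), reverse=True)
    if group_order is not None:
        if set(group_order) != set(levels):
            raise MethFidelityError(
                f"group_order {group_order} does not match observed labels {levels}"
            )
        levels = list(group_order)
    if len(levels) != 2:
        raise MethFidelityError(f"expected 2 groups, found {levels}")
    a = scores[labels == levels[0]].to_numpy(float)
    b = scores[labels == levels[1]].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise MethFidelityError(
            f"both groups need >=2 samples (got {len(a)} and {len(b)})"
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(len(a) + len(b) - 2)
    else:
        df = float(res.df)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical constant groups: no evidence of difference
        t, p = 0.0, 1.0
    group_means = pd.Series({levels[0]: a.mean(), levels[1]: b.mean()})
    return GroupTestResult(statistic=t, statistic_kind="t", df=df, p_value=p,
                           group_means=group_means, alpha=alpha, variant=variant)


def one_way_f_test(values: pd.Series, groups: pd.Series,
                   alpha: float = 0.05) -> GroupTestResult:
    """One-way fixed-effects F-test of a per-sample quantity across groups."""
    groups = groups.reindex(values.index)
    mask = groups.notna() & (groups != "unknown") & values.notna()
    values, groups = values[mask], groups[mask]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise MethFidelityError(f"need >=2 groups, found {levels}")
    arrays = [values[groups == g].to_numpy(float) for g in levels]
    if any(len(a) < 2 for a in arrays):
        raise MethFidelityError("every group needs >=2 samples")
    res = stats.f_oneway(*arrays)
    f, p = float(res.statistic), float(res.pvalue)
    if np.isnan(f):  # zero within- and between-group variance
        f, p = 0.0, 1.0
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    group_means = pd.Series({g: a.mean() for g, a in zip(levels, arrays)})
    return GroupTestResult(statistic=f, statistic_kind="F",
                           df=(float(k - 1), float(n - k)), p_value=p,
                           group_means=group_means, alpha=alpha)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise MethFidelityError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise MethFidelityError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def probe_anova(
    matrix: BetaMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-probe one-way ANOVA of beta values across k >= 2 phenotype groups.

    Returns a DataFrame indexed by probe_id with columns ``F``,
    ``p_value``, ``adjusted_p`` (BH across all tested probes), ``df1``,
    ``df2`` and ``mean_<group>`` per-group mean betas.  Missing values
    are removed per probe; probes where any group falls below
    ``min_per_group`` non-missing samples are dropped with a warning.
    A probe with zero between- and zero within-group variance gets
    F = 0, p = 1 rather than an error.
    """
    groups = groups.reindex(matrix.sample_ids)
    mask = groups.notna() & (groups != "unknown")
    levels = sorted(groups[mask].unique())
    if len(levels) < 2:
        raise MethFidelityError(f"need >=2 groups, found {levels}")
    values = matrix.values.loc[:, mask.to_numpy()]
    glabels = groups[mask]

    arr = values.to_numpy(float)  # probes x samples
    present = ~np.isnan(arr)
    member = np.stack(
        [(glabels == g).to_numpy() for g in levels]
    ).astype(float)  # k x samples

    # per-probe, per-group counts and sums over non-missing entries
    counts = present.astype(float) @ member.T        # probes x k
    sums = np.where(present, arr, 0.0) @ member.T    # probes x k
    ok = (counts >= min_per_group).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("probe_anova: dropped %d probes with a group below "
                       "%d non-missing samples", n_dropped, min_per_group)
    if not ok.any():
        raise MethFidelityError("no probes testable after missing-value removal")

    arr, present = arr[ok], present[ok]
    counts, sums = counts[ok], sums[ok]
    probe_ids = values.index[ok]

    k = len(levels)
    group_means = sums / counts                       # probes x k
    n_tot = counts.sum(axis=1)
    grand = sums.sum(axis=1) / n_tot
    ss_between = (counts * (group_means - grand[:, None]) ** 2).sum(axis=1)
    # within SS: sum over samples of (x - its group mean)^2
    means_per_sample = group_means @ member           # probes x samples
    resid = np.where(present, arr - means_per_sample, 0.0)
    ss_within = (resid ** 2).sum(axis=1)

    df1 = float(k - 1)
    df2 = n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    # degenerate probes: no variance anywhere -> no evidence against the null
    degenerate = (ss_within <= 1e-24) & (ss_between <= 1e-12)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    # constant within groups but different between -> infinite F, p = 0
    p = np.where((ss_within <= 1e-24) & ~degenerate, 0.0, p)
    f = np.where((ss_within <= 1e-24) & ~degenerate, np.inf, f)

    out = pd.DataFrame({"F": f, "p_value": p}, index=probe_ids)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    out["df1"] = df1
    out["df2"] = df2.astype(float)
    for j, g in enumerate(levels):
        out[f"mean_{g}"] = group_means[:, j]
    out.index.name = "probe_id"
    out.attrs["alpha"] = alpha
    out.attrs["groups"] = levels
    return out
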