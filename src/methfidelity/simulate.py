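"""Synthetic methylation cohorts with the structure the analysis assumes.

The generator emulates HM27-style beta-value cohorts: probes have
bimodal baseline means (a mostly-unmethylated and a mostly-methylated
component), a block of ER-associated probes and a block of CIMP
(coordinated CpG-island hypermethylation) probes carry logit-scale
shifts of +delta in ER+ / CIMP+ classes, every probe carries the class's
global logit shift Delta (capturing the higher overall promoter
methylation of ER+ samples), and observed betas are Beta-distributed
around the class mean with concentration kappa.  An optional
class-specific probe block gives each methylation class its own shift
pattern, emulating a multi-class methylation taxonomy.

Paired tumor/cell-line cohorts share one probe universe; by
construction the tumor cohort lacks the ER-/CIMP+ combination while the
cell-line cohort contains it (the anomalous group) and lacks ER+/CIMP-,
reproducing the discordance patterns the fidelity analysis is built to
detect.  Everything is seed-deterministic.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy import stats

from .io import BetaMatrix, MethFidelityError

logger = logging.getLogger("methfidelity")

_BETA_EPS = 1e-6
_MU_EPS = 1e-4

#: Beta(a, 1) shape for alternative p-values in generate_probe_stats,
#: calibrated once so that BH at FDR 0.01 over 27578 probes with 3297
#: alternatives selects about 1440 probes.
DEFAULT_ALTERNATIVE_SHAPE = 0.1108


@dataclass(frozen=True)
class ClassSpec:
    """One phenotype class of a synthetic cohort.

    ``global_shift`` is the class's logit-scale shift applied to every
    probe (Delta); ``meth_class`` keys the class-specific probe-block
    pattern and defaults to the label, so classes sharing a
    ``meth_class`` share a methylation prototype across cohorts.
    """

    label: str
    n_samples: int
    er_truth: str = "unknown"
    her2_truth: str = "unknown"
    cimp_truth: str = "unknown"
    global_shift: float = 0.0
    meth_class: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise MethFidelityError(f"class {self.label!r}: n_samples must be positive")
        for name in ("er_truth", "her2_truth", "cimp_truth"):
            if getattr(self, name) not in ("positive", "negative", "unknown"):
                raise MethFidelityError(
                    f"class {self.label!r}: invalid {name} {getattr(self, name)!r}"
                )

    @property
    def anomalous(self) -> bool:
        return self.er_truth == "negative" and self.cimp_truth == "positive"

    @property
    def meth_class_key(self) -> str:
        return self.meth_class if self.meth_class is not None else self.label


@dataclass
class SyntheticCohortConfig:
    """Full generative model for one cohort.

    Block sizes must sum to at most ``n_probes``; the remainder are
    background probes.  ``separation`` is the logit shift delta shared
    by the ER and CIMP blocks; ``precision`` is the Beta concentration
    kappa (larger = less measurement noise).  ``probe_seed`` fixes the
    probe universe (ids, roles, baseline means) independently of the
    sampling seed so paired cohorts can share probes.
    """

    class_spec: list[ClassSpec]
    n_probes: int = 2000
    er_block_size: int = 200
    cimp_block_size: int = 1440
    class_block_size: int = 0
    separation: float = 1.5
    precision: float = 50.0
    anomalous_fraction: float = 0.0
    seed: int = 0
    probe_seed: int | None = None
    low_mean: float = 0.1
    high_mean: float = 0.8
    high_weight: float = 0.4
    mean_jitter_sd: float = 1.0
    sample_class: str = "cell_line"
    alternative_shape: float = DEFAULT_ALTERNATIVE_SHAPE

    def __post_init__(self) -> None:
        if not self.class_spec:
            raise MethFidelityError("class_spec must list at least one class")
        blocks = self.er_block_size + self.cimp_block_size + self.class_block_size
        if blocks > self.n_probes:
            raise MethFidelityError(
                f"block sizes sum to {blocks} > n_probes = {self.n_probes}"
            )
        if self.precision <= 0:
            raise MethFidelityError("precision (kappa) must be positive")
        if not (0 <= self.anomalous_fraction <= 1):
            raise MethFidelityError("anomalous_fraction outside [0, 1]")
        if not (0 < self.low_mean < self.high_mean < 1):
            raise MethFidelityError("need 0 < low_mean < high_mean < 1")
        if not (0 <= self.high_weight <= 1):
            raise MethFidelityError("high_weight outside [0, 1]")
        if self.sample_class not in ("cell_line", "primary_tumor"):
            raise MethFidelityError(f"invalid sample_class {self.sample_class!r}")
        labels = [c.label for c in self.class_spec]
        if len(set(labels)) != len(labels):
            raise MethFidelityError("duplicate class labels")
        if self.anomalous_fraction > 0:
            expected = round(self.anomalous_fraction * self.n_samples)
            actual = self.n_anomalous
            if actual != expected:
                raise MethFidelityError(
                    f"class_spec yields {actual} anomalous samples but "
                    f"anomalous_fraction {self.anomalous_fraction} of "
                    f"{self.n_samples} requires {expected}"
                )

    @property
    def n_samples(self) -> int:
        return sum(c.n_samples for c in self.class_spec)

    @property
    def n_anomalous(self) -> int:
        return sum(c.n_samples for c in self.class_spec if c.anomalous)

    @property
    def n_background_probes(self) -> int:
        return (self.n_probes - self.er_block_size - self.cimp_block_size
                - self.class_block_size)

    @property
    def resolved_probe_seed(self) -> int:
        return self.seed if self.probe_seed is None else self.probe_seed


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth.

    ``truth`` holds per-sample true class / ER / HER2 / CIMP and the
    anomalous flag; ``probe_roles`` partitions probe ids into
    ``er`` / ``cimp`` / ``class`` / ``background``.
    """

    beta: BetaMatrix
    annotations: pd.DataFrame
    truth: pd.DataFrame
    probe_roles: pd.Series
    config: SyntheticCohortConfig


def _probe_universe(config: SyntheticCohortConfig):
    """Probe ids, role labels and baseline logit means (probe-seed driven)."""
    rng = np.random.default_rng([config.resolved_probe_seed, 9001])
    n = config.n_probes
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    roles = np.array(
        ["er"] * config.er_block_size
        + ["cimp"] * config.cimp_block_size
        + ["class"] * config.class_block_size
        + ["background"] * config.n_background_probes
    )
    high = rng.random(n) < config.high_weight
    base = np.where(high, logit(config.high_mean), logit(config.low_mean))
    base = base + rng.normal(0.0, config.mean_jitter_sd, size=n)
    return probe_ids, roles, base


def _class_block_pattern(config: SyntheticCohortConfig, meth_class: str) -> np.ndarray:
    """Per-class logit shifts on the class-block probes (stable across runs)."""
    key = zlib.crc32(meth_class.encode("utf8")) & 0x7FFFFFFF
    rng = np.random.default_rng([config.resolved_probe_seed, 7177, key])
    return (rng.random(config.class_block_size) < 0.5) * config.separation


def _subtype_for(spec: ClassSpec) -> str:
    if spec.er_truth == "positive":
        return "luminal"
    if spec.er_truth == "negative" and spec.cimp_truth == "positive":
        return "basalA"
    if spec.er_truth == "negative":
        return "basalB"
    return "unknown"


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw one beta-valued cohort from the generative model.

    Per probe j and class c the mean is
    ``mu(c, j) = expit(baseline_j + delta * [block effects] + Delta_c)``
    and each observation is ``Beta(mu * kappa, (1 - mu) * kappa)``.
    Fully deterministic given the config's seeds.
    """
    probe_ids, roles, base = _probe_universe(config)
    er_idx = roles == "er"
    cimp_idx = roles == "cimp"
    class_idx = roles == "class"

    rng = np.random.default_rng([config.seed, 1729])
    prefix = "CL" if config.sample_class == "cell_line" else "PT"

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    truth_rows = []
    for spec in config.class_spec:
        mu_logit = base.copy()
        if spec.er_truth == "positive":
            mu_logit[er_idx] += config.separation
        if spec.cimp_truth == "positive":
            mu_logit[cimp_idx] += config.separation
        if config.class_block_size:
            mu_logit[class_idx] += _class_block_pattern(config, spec.meth_class_key)
        mu_logit += spec.global_shift
        mu = np.clip(expit(mu_logit), _MU_EPS, 1.0 - _MU_EPS)
        a = mu * config.precision
        b = (1.0 - mu) * config.precision
        draws = rng.beta(a[:, None], b[:, None],
                         size=(config.n_probes, spec.n_samples))
        blocks.append(np.clip(draws, _BETA_EPS, 1.0 - _BETA_EPS))
        for i in range(spec.n_samples):
            sid = f"{prefix}_{spec.label}_{i:03d}"
            columns.append(sid)
            truth_rows.append({
                "sample_id": sid,
                "true_class": spec.label,
                "meth_class": spec.meth_class_key,
                "er_truth": spec.er_truth,
                "her2_truth": spec.her2_truth,
                "cimp_truth": spec.cimp_truth,
                "anomalous": spec.anomalous,
            })

    values = pd.DataFrame(np.hstack(blocks),
                          index=pd.Index(probe_ids, name="probe_id"),
                          columns=columns)
    beta = BetaMatrix(values)
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    annotations = pd.DataFrame({
        "er_status": truth["er_truth"],
        "her2_status": truth["her2_truth"],
        "expression_subtype": [
            _subtype_for(spec)
            for spec in config.class_spec
            for _ in range(spec.n_samples)
        ],
        "cimp_status": "unknown",  # phenotype to be inferred, not observed
        "sample_class": config.sample_class,
    })
    annotations.index.name = "sample_id"
    probe_roles = pd.Series(roles, index=values.index, name="role")
    return SyntheticCohort(beta=beta, annotations=annotations, truth=truth,
                           probe_roles=probe_roles, config=config)


# ---------------------------------------------------------------------------
# Default study-shaped configurations
# ---------------------------------------------------------------------------

def default_cellline_config(
    seed: int = 0,
    n_samples: int = 55,
    anomalous_fraction: float = 0.2,
    n_probes: int = 2000,
    er_block_size: int = 200,
    cimp_block_size: int = 1440,
    class_block_size: int = 300,
    separation: float = 1.5,
    precision: float = 50.0,
    er_global_shift: float = 0.5,
    probe_seed: int | None = None,
) -> SyntheticCohortConfig:
    """A 55-line cohort with an anomalous ER-/CIMP+ group (~20%).

    Mirrors the four phenotype groups of the fidelity comparison:
    ER-/HER2-/CIMP-, ER-/HER2-/CIMP+ and ER-/HER2+/CIMP+ (the two
    anomalous classes share one methylation prototype), and ER+ (all
    CIMP+; the ER+/CIMP- combination is absent by construction).  ER+
    classes carry a positive global hypermethylation shift.
    """
    n_anom = round(anomalous_fraction * n_samples)
    g2 = (n_anom + 1) // 2
    g3 = n_anom - g2
    n_pos = round((n_samples - n_anom) * 0.64)
    g1 = n_samples - n_anom - n_pos
    pos_h2 = max(1, round(n_pos * 0.3))
    classes = [
        ClassSpec("ERneg_CIMPneg", g1, "negative", "negative", "negative", 0.0),
        ClassSpec("ERneg_CIMPpos", g2, "negative", "negative", "positive", 0.0,
                  meth_class="ERneg_CIMPpos"),
        ClassSpec("ERneg_CIMPpos_H2pos", g3, "negative", "positive", "positive",
                  0.0, meth_class="ERneg_CIMPpos"),
        ClassSpec("ERpos_CIMPpos", n_pos - pos_h2, "positive", "negative",
                  "positive", er_global_shift, meth_class="ERpos_CIMPpos"),
        ClassSpec("ERpos_CIMPpos_H2pos", pos_h2, "positive", "positive",
                  "positive", er_global_shift, meth_class="ERpos_CIMPpos"),
    ]
    return SyntheticCohortConfig(
        class_spec=[c for c in classes if c.n_samples > 0],
        n_probes=n_probes, er_block_size=er_block_size,
        cimp_block_size=cimp_block_size, class_block_size=class_block_size,
        separation=separation, precision=precision,
        anomalous_fraction=anomalous_fraction, seed=seed,
        probe_seed=probe_seed, sample_class="cell_line",
    )


def default_tumor_config(
    seed: int = 0,
    n_samples: int = 90,
    n_probes: int = 2000,
    er_block_size: int = 200,
    cimp_block_size: int = 1440,
    class_block_size: int = 300,
    separation: float = 1.5,
    precision: float = 50.0,
    er_global_shift: float = 0.5,
    probe_seed: int | None = None,
) -> SyntheticCohortConfig:
    """A primary-tumor cohort: ER+/CIMP+, ER+/CIMP- and ER-/CIMP- classes.

    The ER-/CIMP+ combination is absent by construction, matching the
    observed tumor pattern the anomalous cell lines violate.
    """
    n1 = n_samples // 3
    n2 = n_samples // 3
    n3 = n_samples - n1 - n2
    classes = [
        ClassSpec("ERpos_CIMPpos", n1, "positive", "negative", "positive",
                  er_global_shift, meth_class="ERpos_CIMPpos"),
        ClassSpec("ERpos_CIMPneg", n2, "positive", "negative", "negative",
                  er_global_shift, meth_class="ERpos_CIMPneg"),
        ClassSpec("ERneg_CIMPneg", n3, "negative", "negative", "negative", 0.0),
    ]
    return SyntheticCohortConfig(
        class_spec=classes, n_probes=n_probes, er_block_size=er_block_size,
        cimp_block_size=cimp_block_size, class_block_size=class_block_size,
        separation=separation, precision=precision, anomalous_fraction=0.0,
        seed=seed, probe_seed=probe_seed, sample_class="primary_tumor",
    )


def generate_paired_cohorts(
    tumor_config: SyntheticCohortConfig | None = None,
    cellline_config: SyntheticCohortConfig | None = None,
    seed: int = 0,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """A tumor reference cohort and a cell-line query cohort on one probe set.

    Defaults build the study-shaped configurations with a shared probe
    seed.  The tumor cohort must contain no ER-/CIMP+ class and the
    cell-line cohort no ER+/CIMP- class; probe-universe parameters must
    match exactly.
    """
    if tumor_config is None:
        tumor_config = default_tumor_config(seed=seed + 1, probe_seed=seed)
    if cellline_config is None:
        cellline_config = default_cellline_config(seed=seed + 2, probe_seed=seed)
    for attr in ("n_probes", "er_block_size", "cimp_block_size",
                 "class_block_size", "low_mean", "high_mean", "high_weight",
                 "mean_jitter_sd"):
        if getattr(tumor_config, attr) != getattr(cellline_config, attr):
            raise MethFidelityError(f"probe universe mismatch on {attr}")
    if tumor_config.resolved_probe_seed != cellline_config.resolved_probe_seed:
        raise MethFidelityError("paired cohorts must share probe_seed")
    if any(c.anomalous for c in tumor_config.class_spec):
        raise MethFidelityError("tumor cohort must not contain ER-/CIMP+ classes")
    if any(c.er_truth == "positive" and c.cimp_truth == "negative"
           for c in cellline_config.class_spec):
        raise MethFidelityError("cell-line cohort must not contain ER+/CIMP- classes")
    return generate_cohort(tumor_config), generate_cohort(cellline_config)


def generate_probe_stats(
    config: SyntheticCohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-probe test statistics for signature-derivation experiments.

    Null probes draw p-values uniformly; CIMP-block probes (the
    alternatives) draw from Beta(``alternative_shape``, 1), a
    right-skewed alternative whose default strength is calibrated so
    that BH selection at FDR 0.01 from 3297 alternatives among 27578
    probes yields about 1440 probes.  Returns probe_id, statistic,
    p_value and the ground-truth ``is_alternative`` flag.
    """
    probe_ids, roles, _ = _probe_universe(config)
    rng = np.random.default_rng([config.seed if seed is None else seed, 271])
    is_alt = roles == "cimp"
    p = rng.random(config.n_probes)
    n_alt = int(is_alt.sum())
    if n_alt:
        p[is_alt] = rng.beta(config.alternative_shape, 1.0, size=n_alt)
    statistic = stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    out = pd.DataFrame({
        "probe_id": probe_ids,
        "statistic": statistic,
        "p_value": p,
        "is_alternative": is_alt,
    }).set_index("probe_id")
    return out
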