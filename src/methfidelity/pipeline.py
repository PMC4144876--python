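"""End-to-end orchestration: simulate/ingest -> cluster -> score ->
classify -> neighbors -> report.

The pipeline reproduces the study design on either synthetic paired
cohorts or user-supplied matrices: cluster the query cohort on its most
variable probes, compute per-sample hypermethylation scores and their
ER/HER2 t-tests, derive phenotype signatures on the reference (tumor)
cohort and transfer CIMP and ER calls to the queries by
nearest-prototype Spearman correlation, compute every query's
nearest-reference Spearman distance (the fidelity score), and compare
those distances across the four ER/HER2/CIMP phenotype groups with a
one-way ANOVA.  The run summary is a versioned, machine-readable JSON
object; identical configs and seeds yield identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, preprocess, scores, signatures, similarity
from .io import (BetaMatrix, MethFidelityError, align_annotations,
                 nn_results_to_frame, read_annotations, read_beta_matrix,
                 read_signature, write_results)
from .simulate import generate_paired_cohorts

logger = logging.getLogger("methfidelity")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Parameters of one end-to-end run.

    With ``simulate=True`` (default) paired synthetic cohorts are
    generated from ``seed``; otherwise ``query_beta``, ``reference_beta``
    and the annotation paths must point at existing files, and
    transferred phenotypes come from the supplied ``signature_paths``
    (name -> signature file with prototypes) instead of being derived
    on the reference cohort.
    """

    seed: int = 0
    simulate: bool = True
    query_beta: str | None = None
    reference_beta: str | None = None
    query_annotations: str | None = None
    reference_annotations: str | None = None
    signature_paths: dict = field(default_factory=dict)
    variable_fraction: float = preprocess.DEFAULT_VARIABLE_FRACTION
    distance_convention: str = similarity.DEFAULT_CONVENTION
    t_test_variant: str = "welch"
    fdr_threshold: float = signatures.DEFAULT_FDR_THRESHOLD
    min_signature_coverage: float = signatures.DEFAULT_MIN_SIGNATURE_COVERAGE
    k_clusters: int = 4
    out_prefix: str | None = None
    strict: bool = False

    def validate(self) -> None:
        if not (0 < self.variable_fraction <= 1):
            raise MethFidelityError("variable_fraction outside (0, 1]")
        if not (0 < self.fdr_threshold < 1):
            raise MethFidelityError("fdr_threshold outside (0, 1)")
        if self.distance_convention not in similarity.CONVENTIONS:
            raise MethFidelityError(
                f"unknown distance convention {self.distance_convention!r}"
            )
        if self.t_test_variant not in ("welch", "pooled"):
            raise MethFidelityError(f"unknown t-test variant {self.t_test_variant!r}")
        if not self.simulate:
            required = {
                "query_beta": self.query_beta,
                "reference_beta": self.reference_beta,
            }
            for key, value in {**required, **self.signature_paths}.items():
                if value is None or not Path(value).exists():
                    raise MethFidelityError(
                        f"config path {key!r} = {value!r} does not exist"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MethFidelityError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def fig3_group(er: str, her2: str, cimp: str) -> str:
    """The four-way phenotype grouping of the fidelity comparison.

    ER and HER2 come from IHC annotation, CIMP from the methylation
    prediction: ER+ samples form one group; ER- samples split by
    HER2 and CIMP status.  Any unknown input yields ``"unknown"``.
    """
    if er == "unknown":
        return "unknown"
    if er == "positive":
        return "ER+"
    if her2 == "unknown" or cimp == "unknown":
        return "unknown"
    h2 = "+" if her2 == "positive" else "-"
    cp = "+" if cimp == "positive" else "-"
    return f"ER-/H2{h2}/CP{cp}"


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise MethFidelityError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def _derive_and_transfer(phenotype: str, labels: pd.Series,
                         reference: BetaMatrix, query: BetaMatrix,
                         config: RunConfig) -> tuple[pd.Series, dict]:
    """Derive a phenotype signature on the reference cohort and call queries.

    Per-probe ANOVA of reference betas across the phenotype levels
    yields p-values; BH-FDR thresholding defines the signature; class
    prototypes are reference-standardized group means; queries are
    standardized within their own cohort and assigned by Spearman.
    """
    anova = scores.probe_anova(reference, labels)
    sig = signatures.derive_fdr_signature(
        anova.reset_index().rename(columns={"F": "statistic"}),
        threshold=config.fdr_threshold, name=phenotype,
    )
    if len(sig) < 3:
        raise MethFidelityError(
            f"{phenotype}: only {len(sig)} probes pass FDR {config.fdr_threshold}"
        )
    ref_std = preprocess.standardize(reference, probe_subset=sig.probe_ids)
    sig = signatures.build_prototypes(
        ref_std, labels, sig,
        min_signature_coverage=config.min_signature_coverage,
    )
    query_std = preprocess.standardize(
        query, probe_subset=[p for p in sig.probe_ids
                             if p in set(query.probe_ids)],
    )
    calls = signatures.assign_class(
        query_std, sig, min_signature_coverage=config.min_signature_coverage
    )
    info = {
        "n_signature_probes": len(sig),
        "classes": list(sig.class_labels),
        "mean_margin": float(calls["margin"].mean()),
    }
    return calls["assigned_class"], info


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the JSON-ready run summary."""
    config.validate()
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            "variable_fraction": config.variable_fraction,
            "distance_convention": config.distance_convention,
            "t_test_variant": config.t_test_variant,
            "fdr_threshold": config.fdr_threshold,
            "k_clusters": config.k_clusters,
            "simulate": config.simulate,
        },
        "stages": {},
    }

    with _stage("ingest"):
        if config.simulate:
            tumors, lines = generate_paired_cohorts(seed=config.seed)
            query, reference = lines.beta, tumors.beta
            query_annot = lines.annotations
            ref_cimp_labels = tumors.truth["cimp_truth"]
            ref_er_labels = tumors.truth["er_truth"]
            summary["stages"]["ingest"] = {
                "mode": "simulate",
                "n_query_samples": query.shape[1],
                "n_reference_samples": reference.shape[1],
                "n_probes": query.shape[0],
                "n_anomalous_truth": int(lines.truth["anomalous"].sum()),
            }
        else:
            query = read_beta_matrix(config.query_beta)
            reference = read_beta_matrix(config.reference_beta)
            if config.query_annotations:
                query_annot = align_annotations(
                    query, read_annotations(config.query_annotations),
                    strict=config.strict,
                )
            else:
                query_annot = pd.DataFrame(
                    {c: "unknown" for c in
                     ("er_status", "her2_status", "expression_subtype",
                      "sample_class", "cimp_status")},
                    index=pd.Index(query.sample_ids, name="sample_id"),
                )
            ref_cimp_labels = ref_er_labels = None
            summary["stages"]["ingest"] = {
                "mode": "files",
                "n_query_samples": query.shape[1],
                "n_reference_samples": reference.shape[1],
                "n_probes": query.shape[0],
            }

    with _stage("cluster"):
        selection = preprocess.select_variable_probes(
            query, fraction=config.variable_fraction
        )
        dendrogram = clustering.ward_cluster(query, probes=selection)
        clusters = clustering.cut_tree(dendrogram, config.k_clusters)
        summary["stages"]["cluster"] = {
            "n_variable_probes": len(selection),
            "k": config.k_clusters,
            "cluster_sizes": clusters.value_counts().sort_index().tolist(),
            "leaf_order": dendrogram.leaf_order,
        }

    with _stage("score"):
        std = preprocess.standardize(query, probe_subset=selection)
        score_table = scores.hypermethylation_score(std)
        summary["stages"]["score"] = {
            "n_probes_used": int(score_table["n_probes_used"].iloc[0]),
            "mean_score": float(score_table["score"].mean()),
        }
        for status_col, key in (("er_status", "er_t_test"),
                                ("her2_status", "her2_t_test")):
            labels = query_annot[status_col]
            known = labels[labels != "unknown"]
            if known.nunique() == 2 and known.value_counts().min() >= 2:
                test = scores.two_group_t_test(
                    score_table["score"], labels, variant=config.t_test_variant
                )
                summary["stages"]["score"][key] = test.to_dict()

    with _stage("classify"):
        classify_info: dict = {}
        cimp_calls = er_calls = None
        if config.simulate:
            cimp_calls, info = _derive_and_transfer(
                "cimp", ref_cimp_labels, reference, query, config)
            classify_info["cimp"] = info
            er_calls, info = _derive_and_transfer(
                "er", ref_er_labels, reference, query, config)
            classify_info["er"] = info
        else:
            for name, path in config.signature_paths.items():
                sig = read_signature(path)
                if sig.prototypes is None:
                    raise MethFidelityError(
                        f"signature {name!r} has no prototype columns"
                    )
                shared = [p for p in sig.probe_ids if p in set(query.probe_ids)]
                query_std = preprocess.standardize(query, probe_subset=shared)
                calls = signatures.assign_class(
                    query_std, sig,
                    min_signature_coverage=config.min_signature_coverage,
                )
                classify_info[name] = {
                    "n_signature_probes": len(sig),
                    "classes": list(sig.class_labels),
                    "mean_margin": float(calls["margin"].mean()),
                }
                lowered = name.lower()
                if "cimp" in lowered:
                    cimp_calls = calls["assigned_class"]
                elif lowered.startswith("er") or "er_" in lowered:
                    er_calls = calls["assigned_class"]
        summary["stages"]["classify"] = classify_info

    with _stage("composite"):
        composite = signatures.composite_phenotype(
            query_annot, cimp_calls=cimp_calls, er_calls=er_calls,
        )
        flag_counts = {
            col: int((composite[col] == True).sum())  # noqa: E712 three-valued
            for col in ("er_plus_cimp_minus", "er_minus_cimp_plus")
        }
        summary["stages"]["composite"] = flag_counts

    with _stage("neighbors"):
        dm = similarity.pairwise_distances(
            query, reference, convention=config.distance_convention
        )
        nn = similarity.nearest_reference(dm)
        nn_frame = nn_results_to_frame(nn)
        summary["stages"]["neighbors"] = {
            "convention": config.distance_convention,
            "n_pairs": int(dm.distances.size),
            "median_nearest_distance": float(nn_frame["distance"].median()),
        }

    with _stage("group_comparison"):
        cimp_for_group = (cimp_calls if cimp_calls is not None
                          else query_annot["cimp_status"])
        groups = pd.Series(
            [
                fig3_group(
                    query_annot.loc[s, "er_status"],
                    query_annot.loc[s, "her2_status"],
                    cimp_for_group.get(s, "unknown"),
                )
                for s in nn_frame.index
            ],
            index=nn_frame.index,
        )
        test, summaries, overall_median = similarity.group_distance_comparison(
            nn_frame["distance"], groups
        )
        summary["stages"]["group_comparison"] = {
            "anova": test.to_dict(),
            "overall_median": overall_median,
            "group_medians": {g: float(summaries.loc[g, "median"])
                              for g in summaries.index},
            "group_summaries": summaries.to_dict(orient="index"),
        }

    if config.out_prefix:
        with _stage("report"):
            prefix = str(config.out_prefix)
            score_table.to_csv(f"{prefix}.scores.tsv", sep="\t",
                               float_format="%.6g")
            composite.to_csv(f"{prefix}.composite.tsv", sep="\t", na_rep="NA")
            clusters.to_csv(f"{prefix}.clusters.tsv", sep="\t")
            write_results(nn, f"{prefix}.neighbors.tsv")
            with open(f"{prefix}.summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)

    return summary
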