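import numpy as np
import pandas as pd
import pytest

from methfidelity.io import BetaMatrix, MethFidelityError, Signature
from methfidelity.preprocess import standardize
from methfidelity.signatures import (
    assign_class,
    assignments_to_records,
    build_prototypes,
    composite_phenotype,
    derive_fdr_signature,
)
from methfidelity.simulate import ClassSpec, SyntheticCohortConfig, generate_cohort


class TestDeriveFdrSignature:
    def test_all_null_gives_empty_signature(self):
        stats = pd.DataFrame({"probe_id": ["a", "b"], "p_value": [1.0, 1.0]})
        sig = derive_fdr_signature(stats)
        assert len(sig) == 0

    def test_five_probe_hand_example_strict_vs_lenient(self):
        # BH-adjusted: (0.005, 0.010, 0.333, 0.625, 0.9)
        stats = pd.DataFrame({
            "probe_id": list("abcde"),
            "p_value": [0.001, 0.004, 0.2, 0.5, 0.9],
        })
        strict = derive_fdr_signature(stats, threshold=0.01, strict=True)
        assert strict.probe_ids == ["a"]
        lenient = derive_fdr_signature(stats, threshold=0.01, strict=False)
        assert lenient.probe_ids == ["a", "b"]
        np.testing.assert_allclose(
            lenient.probe_stats["adjusted_p"], [0.005, 0.010], atol=1e-12
        )

    def test_empty_table_is_error(self):
        with pytest.raises(MethFidelityError):
            derive_fdr_signature(pd.DataFrame(columns=["probe_id", "p_value"]))


class TestBuildPrototypes:
    @pytest.fixture
    def train(self, rng):
        values = pd.DataFrame(
            rng.random((4, 6)),
            index=["cg1", "cg2", "cg3", "cg4"],
            columns=[f"S{j}" for j in range(6)],
        )
        return standardize(BetaMatrix(values))

    def test_single_sample_class_prototype_is_that_sample(self, train):
        labels = pd.Series(["x", "y", "y", "y", "y", "y"],
                           index=train.sample_ids)
        sig = Signature("s", ["cg1", "cg2", "cg3", "cg4"])
        out = build_prototypes(train, labels, sig)
        np.testing.assert_allclose(out.prototypes["x"],
                                   train.zvalues["S0"], atol=1e-12)

    def test_matches_group_mean_oracle(self, train):
        labels = pd.Series(["a", "a", "b", "b", "c", "c"],
                           index=train.sample_ids)
        sig = Signature("s", ["cg1", "cg2", "cg3", "cg4"])
        out = build_prototypes(train, labels, sig)
        assert out.class_labels == ["a", "b", "c"]
        for cls, members in (("a", ["S0", "S1"]), ("b", ["S2", "S3"]),
                             ("c", ["S4", "S5"])):
            expected = train.zvalues[members].mean(axis=1)
            np.testing.assert_allclose(out.prototypes[cls], expected,
                                       atol=1e-12)

    def test_coverage_floor_enforced(self, train):
        labels = pd.Series(["a"] * 6, index=train.sample_ids)
        sig = Signature("s", ["cg1", "cg2", "cgMISSING1", "cgMISSING2",
                              "cgMISSING3"])
        with pytest.raises(MethFidelityError, match="coverage"):
            build_prototypes(train, labels, sig, min_signature_coverage=0.8)


class TestAssignClass:
    def make_signature(self, protos: dict) -> Signature:
        proto = pd.DataFrame(protos)
        proto.index = [f"cg{i}" for i in range(len(proto))]
        return Signature("s", list(proto.index), prototypes=proto)

    def as_std(self, vectors: dict) -> "StandardizedMatrix":
        from methfidelity.io import StandardizedMatrix

        df = pd.DataFrame(vectors)
        df.index = [f"cg{i}" for i in range(len(df))]
        return StandardizedMatrix(df, validate=False)

    def test_sample_equal_to_prototype_selfmatches(self):
        sig = self.make_signature({"A": [0.0, 1.0, 2.0, 3.0],
                                   "B": [3.0, 2.0, 1.0, 0.0]})
        std = self.as_std({"q": [0.0, 1.0, 2.0, 3.0]})
        calls = assign_class(std, sig)
        assert calls.loc["q", "assigned_class"] == "A"
        assert calls.loc["q", "rho_A"] == pytest.approx(1.0)

    def test_monotone_transform_preserves_assignment(self):
        sig = self.make_signature({"A": [0.0, 1.0, 2.0, 3.0],
                                   "B": [3.0, 2.0, 1.0, 0.0]})
        std = self.as_std({"q": [np.exp(v) for v in [0.0, 1.0, 2.0, 3.0]]})
        calls = assign_class(std, sig)
        assert calls.loc["q", "assigned_class"] == "A"
        assert calls.loc["q", "rho_A"] == pytest.approx(1.0)

    def test_hand_computed_rhos(self):
        sig = self.make_signature({"A": [1.0, 2.0, 4.0, 3.0],
                                   "B": [4.0, 3.0, 2.0, 1.0]})
        std = self.as_std({"q": [1.0, 2.0, 3.0, 4.0]})
        calls = assign_class(std, sig)
        assert calls.loc["q", "assigned_class"] == "A"
        assert calls.loc["q", "rho_A"] == pytest.approx(0.8)
        assert calls.loc["q", "rho_B"] == pytest.approx(-1.0)
        assert calls.loc["q", "margin"] == pytest.approx(1.8)

    def test_scaling_z_scores_leaves_assignment_unchanged(self, rng):
        proto = {c: rng.normal(size=20) for c in ("A", "B", "C")}
        sig = self.make_signature(proto)
        vec = rng.normal(size=20)
        calls1 = assign_class(self.as_std({"q": vec}), sig)
        calls2 = assign_class(self.as_std({"q": 7.3 * vec}), sig)
        pd.testing.assert_frame_equal(calls1, calls2)

    def test_constant_sample_is_error(self):
        sig = self.make_signature({"A": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(MethFidelityError, match="constant"):
            assign_class(self.as_std({"q": [0.5] * 4}), sig)

    def test_missing_prototypes_is_error(self):
        sig = Signature("s", ["cg0", "cg1", "cg2"])
        with pytest.raises(MethFidelityError, match="prototype"):
            assign_class(self.as_std({"q": [0.1, 0.2, 0.3]}), sig)

    def test_records_round_trip(self):
        sig = self.make_signature({"A": [0.0, 1.0, 2.0, 3.0],
                                   "B": [3.0, 2.0, 1.0, 0.0]})
        calls = assign_class(self.as_std({"q": [0.0, 1.0, 2.0, 3.0]}), sig)
        records = assignments_to_records(calls)
        assert records[0].sample_id == "q"
        assert records[0].assigned_class == "A"
        assert records[0].margin >= 0


class TestParameterRecovery:
    @staticmethod
    def two_class_config(seed, probe_seed):
        return SyntheticCohortConfig(
            class_spec=[
                ClassSpec("ERpos", 30, "positive", "negative", "negative"),
                ClassSpec("ERneg", 30, "negative", "negative", "negative"),
            ],
            n_probes=2000, er_block_size=200, cimp_block_size=0,
            separation=1.5, precision=50.0, seed=seed, probe_seed=probe_seed,
        )

    def test_prototype_self_consistency_on_training_data(self):
        config = self.two_class_config(seed=11, probe_seed=7)
        cohort = generate_cohort(config)
        sig_probes = list(cohort.probe_roles.index[cohort.probe_roles == "er"])
        std = standardize(cohort.beta, probe_subset=sig_probes)
        sig = build_prototypes(std, cohort.truth["true_class"],
                               Signature("er", sig_probes))
        calls = assign_class(std, sig)
        acc = (calls["assigned_class"]
               == cohort.truth["true_class"].reindex(calls.index)).mean()
        assert acc >= 0.90


class TestCompositePhenotype:
    def test_flags_and_three_valued_logic(self):
        annotations = pd.DataFrame(
            {
                "er_status": ["negative", "positive", "unknown", "positive"],
                "her2_status": ["negative"] * 4,
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
        cimp = pd.Series(
            {"s1": "positive", "s2": "negative", "s3": "positive",
             "s4": "unknown"}
        )
        table = composite_phenotype(annotations, cimp_calls=cimp)
        assert table.loc["s1", "er_minus_cimp_plus"] == True  # noqa: E712
        assert table.loc["s1", "er_plus_cimp_minus"] == False  # noqa: E712
        assert table.loc["s2", "er_plus_cimp_minus"] == True  # noqa: E712
        assert pd.isna(table.loc["s3", "er_minus_cimp_plus"])
        assert pd.isna(table.loc["s4", "er_plus_cimp_minus"])

    def test_missing_calls_propagate_as_unknown(self):
        annotations = pd.DataFrame(
            {"er_status": ["positive"], "her2_status": ["negative"]},
            index=pd.Index(["s1"], name="sample_id"),
        )
        table = composite_phenotype(annotations)
        assert table.loc["s1", "predicted_cimp"] == "unknown"
        assert pd.isna(table.loc["s1", "er_plus_cimp_minus"])

    def test_anomalous_flag_count_matches_generator_truth(self):
        from methfidelity.simulate import default_cellline_config

        cohort = generate_cohort(default_cellline_config(seed=3))
        table = composite_phenotype(
            cohort.annotations, cimp_calls=cohort.truth["cimp_truth"]
        )
        n_flagged = int((table["er_minus_cimp_plus"] == True).sum())  # noqa: E712
        assert n_flagged == int(cohort.truth["anomalous"].sum()) == 11
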