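import numpy as np
import pandas as pd
import pytest

from hltme.containers import ClinicalTable, EnrichmentMatrix
from hltme.prognostic import (
    FrozenModel,
    ModelConfig,
    classify,
    compute_model_score,
    evaluate_model,
    roc_cutpoint,
)


def _enrichment(values: pd.DataFrame) -> EnrichmentMatrix:
    return EnrichmentMatrix(raw_es=values, nes=values,
                            empirical_p=values * 0 + 0.5,
                            effective_set_size=pd.Series(5, index=values.index))


@pytest.fixture
def two_component_enrichment():
    # components x patients: medians 2 and 4, centered mean scores -1 and +1
    vals = pd.DataFrame([[1.0, 3.0], [3.0, 5.0]],
                        index=["c1", "c2"], columns=["p1", "p2"])
    return _enrichment(vals)


class TestComputeModelScore:
    def test_hand_worked_two_patient_example(self, two_component_enrichment):
        res = compute_model_score(two_component_enrichment,
                                  ModelConfig(variable_ids=("c1", "c2")))
        np.testing.assert_allclose(res.cohort_medians, [2.0, 4.0])
        np.testing.assert_allclose(res.model_score, [-1.0, 1.0])

    def test_score_equals_mean_of_centered_components(self, two_component_enrichment):
        res = compute_model_score(two_component_enrichment,
                                  ModelConfig(variable_ids=("c1", "c2")))
        np.testing.assert_allclose(res.model_score,
                                   res.component_table.mean(axis=0), atol=1e-12)

    def test_constant_shift_of_one_component_absorbed(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(3, 8)), index=["a", "b", "c"])
        cfg = ModelConfig(variable_ids=("a", "b", "c"))
        base = compute_model_score(_enrichment(vals), cfg)
        shifted = vals.copy()
        shifted.loc["b"] += 17.3
        res = compute_model_score(_enrichment(shifted), cfg)
        np.testing.assert_allclose(base.model_score, res.model_score, atol=1e-12)

    def test_flat_components_give_zero_scores(self):
        vals = pd.DataFrame(2.5, index=["a", "b"], columns=["p1", "p2", "p3"])
        res = compute_model_score(_enrichment(vals), ModelConfig(variable_ids=("a", "b")))
        np.testing.assert_allclose(res.model_score, 0.0)

    def test_missing_variable_listed(self, two_component_enrichment):
        with pytest.raises(KeyError, match="c9"):
            compute_model_score(two_component_enrichment,
                                ModelConfig(variable_ids=("c1", "c9")))

    def test_single_sample_requires_frozen_medians(self):
        vals = pd.DataFrame([[1.0], [3.0]], index=["a", "b"], columns=["p1"])
        cfg = ModelConfig(variable_ids=("a", "b"))
        with pytest.raises(ValueError, match="frozen"):
            compute_model_score(_enrichment(vals), cfg)
        frozen = pd.Series({"a": 0.0, "b": 2.0})
        res = compute_model_score(_enrichment(vals), cfg, frozen_medians=frozen)
        np.testing.assert_allclose(res.model_score, [1.0])

    def test_component_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        a = compute_model_score(_enrichment(vals), ModelConfig(variable_ids=tuple("abcd")))
        b = compute_model_score(_enrichment(vals), ModelConfig(variable_ids=tuple("dcba")))
        np.testing.assert_allclose(a.model_score, b.model_score, atol=1e-12)

    def test_raising_a_component_never_lowers_a_score_with_frozen_medians(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(size=(3, 5)), index=list("abc"))
        cfg = ModelConfig(variable_ids=tuple("abc"))
        base = compute_model_score(_enrichment(vals), cfg)
        bumped = vals.copy()
        bumped.iloc[1, 2] += 0.9
        res = compute_model_score(_enrichment(bumped), cfg,
                                  frozen_medians=base.cohort_medians)
        ref = compute_model_score(_enrichment(vals), cfg,
                                  frozen_medians=base.cohort_medians)
        assert res.model_score.iloc[2] >= ref.model_score.iloc[2]
        others = [0, 1, 3, 4]
        np.testing.assert_allclose(res.model_score.iloc[others],
                                   ref.model_score.iloc[others], atol=1e-12)


class TestRocCutpoint:
    def test_perfect_separation(self):
        res = roc_cutpoint(np.array([0.1, 0.2, 0.8, 0.9]),
                           np.array(["F", "F", "U", "U"]))
        assert res.cutpoint == pytest.approx(0.5)
        assert res.youden_j == pytest.approx(1.0)
        assert res.accuracy == pytest.approx(1.0)
        assert (res.tp, res.fp, res.tn, res.fn) == (2, 0, 2, 0)

    def test_youden_consistency_identity(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.4, "U", "F")
        res = roc_cutpoint(s, labels)
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1)
        assert res.accuracy == pytest.approx((res.tp + res.tn) / 40)

    def test_chosen_cutpoint_maximizes_j_over_all_candidates(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            s = np.round(rng.normal(size=30), 1)  # duplicates exercise tie paths
            labels = np.where(rng.random(30) < 0.5, "U", "F")
            if len(set(labels)) < 2:
                continue
            res = roc_cutpoint(s, labels)
            pos = labels == "U"
            for c in np.concatenate([np.unique(s) - 1e-6, np.unique(s) + 1e-6]):
                call = s > c
                j = (call & pos).sum() / pos.sum() + ((~call) & ~pos).sum() / (~pos).sum() - 1
                assert res.youden_j >= j - 1e-12

    def test_null_scores_give_small_j(self):
        rng = np.random.default_rng(5)
        js = []
        for _ in range(60):
            s = rng.normal(size=1000)
            labels = np.where(rng.random(1000) < 0.5, "U", "F")
            js.append(roc_cutpoint(s, labels).youden_j)
        assert np.quantile(js, 0.95) < 0.15

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_cutpoint(np.array([1.0, 2.0]), np.array(["U", "U"]))


class TestClassify:
    def test_boundary_goes_low_risk(self):
        out = classify(np.array([-1.0, 0.0, 1.0]), 0.0)
        assert out.tolist() == ["low_risk", "low_risk", "high_risk"]

    def test_monotone_transform_preserves_classes(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=20)
        cut = 0.3
        a = classify(s, cut)
        b = classify(np.exp(s), np.exp(cut))
        assert (a == b).all()


def _cohort(vals: pd.DataFrame, labels):
    clin = ClinicalTable(table=pd.DataFrame({
        "sample_id": list(vals.columns),
        "outcome": labels,
        "pfs_months": [10.0 if l == "U" else 40.0 for l in labels],
        "event": [1 if l == "U" else 0 for l in labels],
    }))
    return _enrichment(vals), clin


class TestEvaluateModel:
    def _make(self, seed, n=24, delta=2.0):
        rng = np.random.default_rng(seed)
        labels = ["F"] * (n // 2) + ["U"] * (n - n // 2)
        vals = pd.DataFrame(rng.normal(size=(4, n)), index=list("abcd"),
                            columns=[f"s{seed}_{i}" for i in range(n)])
        vals.loc[:, [l == "U" for l in labels]] += delta
        return _cohort(vals, labels)

    def test_test_cohort_identical_to_train_gives_same_accuracy(self):
        enr, clin = self._make(0)
        rep = evaluate_model((enr, clin), (enr, clin),
                             ModelConfig(variable_ids=tuple("abcd")))
        assert rep["train"]["accuracy"] == rep["test"]["accuracy"]

    def test_frozen_application_is_label_free(self):
        """Test-cohort scores must not depend on test labels (leakage guard)."""
        enr, clin = self._make(1)
        enr2, clin2 = self._make(2)
        rep = evaluate_model((enr, clin), (enr2, clin2),
                             ModelConfig(variable_ids=tuple("abcd")))
        frozen = rep["frozen"]
        direct = compute_model_score(enr2, ModelConfig(variable_ids=tuple("abcd")),
                                     frozen_medians=frozen.medians)
        pd.testing.assert_series_equal(rep["test"]["scores"], direct.model_score)

    def test_planted_effect_recovered_across_cohorts(self):
        rep = evaluate_model(self._make(3), self._make(4),
                             ModelConfig(variable_ids=tuple("abcd")))
        assert rep["test"]["accuracy"] >= 0.7
        assert rep["test"]["fu_comparison"].p_value < 0.01

    def test_single_variable_config_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ModelConfig(variable_ids=("only",))


class TestFrozenModel:
    def test_json_round_trip(self, tmp_path):
        frozen = FrozenModel(medians=pd.Series({"a": 1.5, "b": -0.25}), cutpoint=0.75)
        path = tmp_path / "frozen.json"
        frozen.to_json(path)
        back = FrozenModel.from_json(path)
        assert back.cutpoint == frozen.cutpoint
        pd.testing.assert_series_equal(back.medians, frozen.medians)
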