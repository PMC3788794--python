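"""Threshold metrics, AUC, cross-validation and external validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import metaoccu as mo


class TestConfusionCounts:
    def test_simple_split(self):
        c = mo.confusion_counts([0.9, 0.1], [1, 0], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_threshold_zero_predicts_everything_present(self):
        c = mo.confusion_counts([0.9, 0.1, 0.0], [1, 0, 0], 0.0)
        assert c.tn == 0 and c.fn == 0

    def test_direct_tally(self):
        c = mo.confusion_counts([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0], 0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(mo.AlignmentError):
            mo.confusion_counts([0.5], [1, 0], 0.5)


class TestThresholdMetrics:
    def test_perfect_classification(self):
        c = mo.confusion_counts([0.9, 0.9, 0.1], [1, 1, 0], 0.5)
        assert mo.tss(c) == 1.0
        assert mo.ccr(c) == 1.0

    def test_all_predicted_present_is_random_equivalent(self):
        c = mo.confusion_counts([0.9, 0.9], [1, 0], 0.0)
        assert mo.sensitivity(c) == 1.0
        assert mo.specificity(c) == 0.0
        assert mo.tss(c) == 0.0

    def test_hand_arithmetic(self):
        c = mo.ConfusionCounts(tp=40, fp=20, tn=30, fn=10)
        assert mo.sensitivity(c) == pytest.approx(0.8)
        assert mo.specificity(c) == pytest.approx(0.6)
        assert mo.tss(c) == pytest.approx(0.4)
        assert mo.ccr(c) == pytest.approx(0.7)

    def test_tss_identity(self):
        rng = np.random.default_rng(0)
        c = mo.confusion_counts(rng.random(50), rng.integers(0, 2, 50), 0.5)
        assert mo.tss(c) == pytest.approx(mo.sensitivity(c) + mo.specificity(c) - 1)

    def test_empty_class_named_in_error(self):
        c = mo.ConfusionCounts(tp=0, fp=1, tn=1, fn=0)
        with pytest.raises(mo.UndefinedValueError, match="presence"):
            mo.sensitivity(c)


class TestRocAuc:
    def test_perfect_separation(self):
        assert mo.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert mo.roc_auc([0.4] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_pair_enumeration(self):
        # 3 of the 4 (present, absent) pairs are concordant
        assert mo.roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(mo.UndefinedValueError):
            mo.roc_auc([0.5, 0.6], [1, 1])

    def test_against_reference_implementation(self):
        rng = np.random.default_rng(7)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert mo.roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    @given(st.integers(0, 2 ** 10 - 1))
    def test_invariant_under_monotone_transform(self, bits):
        rng = np.random.default_rng(bits)
        scores = rng.random(12)
        labels = np.array([(bits >> k) & 1 for k in range(10)] + [0, 1])
        base = mo.roc_auc(scores, labels)
        assert mo.roc_auc(np.exp(3 * scores), labels) == pytest.approx(base)

    def test_label_flip_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        assert mo.roc_auc(1 - scores, labels) == pytest.approx(1 - mo.roc_auc(scores, labels))


class TestOptimizeThreshold:
    def test_separated_scores_tie_to_lower_grid_point(self):
        scores = [0.9, 0.9, 0.1, 0.1]
        assert mo.optimize_threshold(scores, [1, 1, 0, 0]) == pytest.approx(0.11)

    def test_symmetric_scores_cross_near_half(self):
        scores = [0.2, 0.4, 0.6, 0.8]
        t = mo.optimize_threshold(scores, [0, 1, 0, 1])
        s, sp = mo.sensitivity(mo.confusion_counts(scores, [0, 1, 0, 1], t)), \
            mo.specificity(mo.confusion_counts(scores, [0, 1, 0, 1], t))
        assert abs(s - sp) == 0.0
        assert 0.0 <= t <= 1.0

    def test_ccr_at_optimised_threshold_beats_degenerate(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 200)
        scores = np.clip(labels * 0.4 + rng.random(200) * 0.6, 0, 1)
        t = mo.optimize_threshold(scores, labels)
        ccr_opt = mo.ccr(mo.confusion_counts(scores, labels, t))
        ccr_zero = mo.ccr(mo.confusion_counts(scores, labels, 0.0))
        assert ccr_opt >= ccr_zero


class TestExpectedFalseAbsence:
    def test_certain_detection(self):
        assert mo.expected_false_absence_rate([1, 1, 1, 1]) == 0.0

    def test_study_detection_bracket(self):
        assert mo.expected_false_absence_rate([0.6] * 4) == pytest.approx(0.4 ** 4)
        assert mo.expected_false_absence_rate([0.51] * 4) == pytest.approx(0.49 ** 4)

    def test_monotone_in_p_and_surveys(self):
        base = mo.expected_false_absence_rate([0.5, 0.5])
        assert mo.expected_false_absence_rate([0.6, 0.5]) < base
        assert mo.expected_false_absence_rate([0.5, 0.5, 0.5]) < base

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mo.expected_false_absence_rate([])


@pytest.fixture(scope="module")
def cv_dataset():
    patches = mo.generate_patches(mo.SimulationConfig(n_patches=240, seed=31))
    dataset, _ = mo.simulate_dataset(mo.study_truth(), patches, seed=32)
    return dataset


class TestKfoldCrossValidate:
    SPEC = mo.ModelSpec(psi=("size", "matrix"), gamma=("size",), p=("matrix",))

    def test_same_seed_identical(self, cv_dataset):
        a = mo.kfold_cross_validate(cv_dataset, self.SPEC, k=4, seed=9)
        b = mo.kfold_cross_validate(cv_dataset, self.SPEC, k=4, seed=9)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)
        assert a.overall == b.overall

    def test_folds_partition_patches(self, cv_dataset):
        report = mo.kfold_cross_validate(cv_dataset, self.SPEC, k=4, seed=9)
        # every fold contributes one row per year
        assert sorted(report.per_fold["fold"].unique()) == [0, 1, 2, 3]
        assert set(report.per_fold["year"]) == {1, 2, 3}

    def test_report_carries_false_absence_rate(self, cv_dataset):
        report = mo.kfold_cross_validate(cv_dataset, self.SPEC, k=4, seed=9)
        assert 0.0 < report.expected_false_absence < 0.2

    def test_k_bounds(self, cv_dataset):
        with pytest.raises(ValueError):
            mo.kfold_cross_validate(cv_dataset, self.SPEC, k=1, seed=0)


class TestExternalValidate:
    def make_fitted(self, cv_dataset):
        return mo.fit(cv_dataset, self.SPEC, compute_se=False)

    SPEC = TestKfoldCrossValidate.SPEC

    def test_threshold_one_gives_zero_sensitivity(self, cv_dataset):
        fitted = self.make_fitted(cv_dataset)
        report = mo.external_validate(fitted, cv_dataset, threshold=1.0)
        assert report.overall["sensitivity"] == 0.0

    def test_strata_are_the_two_matrix_types(self, cv_dataset):
        fitted = self.make_fitted(cv_dataset)
        report = mo.external_validate(fitted, cv_dataset, threshold=0.43)
        assert list(report.strata["matrix"]) == ["pasture", "tussock"]

    def test_beats_permuted_label_control(self, cv_dataset):
        """Predictions on data simulated from the fitted parameters score
        better than the same predictions against shuffled labels."""
        fitted = self.make_fitted(cv_dataset)
        new, _ = mo.simulate_dataset(
            mo.study_truth(), mo.generate_patches(mo.SimulationConfig(n_patches=240, seed=77)),
            seed=78,
        )
        report = mo.external_validate(fitted, new, threshold=0.5)
        rng = np.random.default_rng(79)
        combined = np.nansum(new.detections.reshape(new.n_patches, -1), axis=1) > 0
        psi1 = mo.predict_patch_parameters(fitted, new.covariates)["psi1"].to_numpy()
        shuffled = rng.permutation(combined.astype(float))
        control = mo.roc_auc(psi1, shuffled)
        assert report.overall["auc"] > control

    def test_report_round_trips_to_json(self, cv_dataset, tmp_path):
        fitted = self.make_fitted(cv_dataset)
        report = mo.external_validate(fitted, cv_dataset, threshold=0.43)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json
        blob = json.loads(path.read_text())
        assert blob["threshold"] == 0.43
        assert "auc" in blob["overall"]
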