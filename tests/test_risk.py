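import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from neoscreen.risk import (
    RiskCalibration,
    RiskModelError,
    TrainedDiseaseModel,
    assess_cohort,
    calibrate_threshold,
    fit_disease_model,
    map_risk_score,
    record_positive,
    select_best_model,
    split_train_test,
    zero_fn_threshold,
)


class _FixedScores:
    """Stub estimator returning predetermined scores keyed by row order."""

    classes_ = np.array([0, 1])

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        s = self.scores[: len(X)]
        return np.column_stack([1 - s, s])


def stub_model(algorithm, scores, threshold):
    return TrainedDiseaseModel(
        disease="X", algorithm=algorithm, features=("f",),
        estimator=_FixedScores(scores), seed=0, operating_threshold=threshold,
    )


class TestSplit:
    def test_eighty_twenty_sizes(self):
        frame = pd.DataFrame({"x": range(100)})
        train, test = split_train_test(frame, ratio=0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert set(train.index).isdisjoint(test.index)
        assert len(set(train.index) | set(test.index)) == 100

    def test_same_seed_same_split(self):
        frame = pd.DataFrame({"x": range(50)})
        a = split_train_test(frame, seed=9)
        b = split_train_test(frame, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_stratified_positives_split_8_to_2(self):
        labels = ["D"] * 10 + [None] * 90
        frame = pd.DataFrame({"x": range(100)})
        train, test = split_train_test(frame, ratio=0.8, stratify_by=labels, seed=1)
        train_pos = sum(1 for i in train.index if i < 10)
        test_pos = sum(1 for i in test.index if i < 10)
        assert (train_pos, test_pos) == (8, 2)

    def test_single_positive_stratum_is_an_error(self):
        labels = ["D"] + [None] * 20
        frame = pd.DataFrame({"x": range(21)})
        with pytest.raises(RiskModelError, match="simulate"):
            split_train_test(frame, stratify_by=labels, seed=0)


class TestFitting:
    def _toy(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = pd.DataFrame({"f1": y * 3 + rng.normal(0, 0.2, n), "f2": rng.normal(0, 1, n)})
        return X, y

    def test_separable_data_fits_perfectly_with_trees(self):
        X, y = self._toy()
        model = fit_disease_model(X, y, algorithm="decision_tree", seed=0)
        assert np.all((model.score(X) >= 0.5) == (y == 1))

    def test_refit_same_seed_identical_predictions(self):
        X, y = self._toy()
        a = fit_disease_model(X, y, algorithm="random_forest", seed=3).score(X)
        b = fit_disease_model(X, y, algorithm="random_forest", seed=3).score(X)
        assert np.array_equal(a, b)

    def test_shuffled_labels_score_near_chance(self):
        X, y = self._toy(n=2000, seed=4)
        rng = np.random.default_rng(5)
        y_perm = rng.permutation(y)
        train = X.iloc[:1500]
        model = fit_disease_model(train, y_perm[:1500], algorithm="logistic_regression", seed=0)
        auc = roc_auc_score(y_perm[1500:], model.score(X.iloc[1500:]))
        assert auc == pytest.approx(0.5, abs=0.1)

    def test_single_class_labels_rejected(self):
        X, _ = self._toy()
        with pytest.raises(RiskModelError):
            fit_disease_model(X, np.zeros(len(X)), seed=0)


class TestModelSelection:
    def test_zero_fn_beats_lower_fp_with_misses(self):
        X = pd.DataFrame({"f": np.zeros(6)})
        y = [1, 1, 0, 0, 0, 0]
        # A flags everything (FN=0, FP=4 at threshold .5); B misses a positive
        a = stub_model("alg_a", [0.9, 0.8, 0.7, 0.7, 0.7, 0.7], 0.5)
        b = stub_model("alg_b", [0.9, 0.2, 0.1, 0.1, 0.1, 0.1], 0.5)
        best = select_best_model([a, b], X, y, set_thresholds=False)
        assert best.algorithm == "alg_a"

    def test_min_fp_among_zero_fn(self):
        X = pd.DataFrame({"f": np.zeros(6)})
        y = [1, 1, 0, 0, 0, 0]
        a = stub_model("alg_a", [0.9, 0.8, 0.7, 0.1, 0.1, 0.1], 0.5)  # FP=1
        b = stub_model("alg_b", [0.9, 0.8, 0.7, 0.7, 0.7, 0.1], 0.5)  # FP=3
        best = select_best_model([a, b], X, y, set_thresholds=False)
        assert best.algorithm == "alg_a"

    def test_fallback_when_no_zero_fn(self):
        X = pd.DataFrame({"f": np.zeros(4)})
        y = [1, 1, 0, 0]
        a = stub_model("alg_a", [0.9, 0.2, 0.1, 0.1], 0.5)  # FN=1
        b = stub_model("alg_b", [0.2, 0.1, 0.1, 0.1], 0.5)  # FN=2
        with pytest.warns(UserWarning, match="zero false negatives"):
            best = select_best_model([a, b], X, y, set_thresholds=False)
        assert best.algorithm == "alg_a"

    def test_auto_threshold_guarantees_zero_fn(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(0, 1, 40)
        y = (scores + rng.normal(0, 0.2, 40) > 0.8).astype(int)
        if y.sum() == 0:
            y[scores.argmax()] = 1
        model = stub_model("alg", scores, None)
        X = pd.DataFrame({"f": np.zeros(40)})
        best = select_best_model([model], X, y, set_thresholds=True)
        flagged = scores >= best.operating_threshold
        assert np.all(flagged[y == 1])


class TestRiskMapping:
    @pytest.fixture
    def calibration(self):
        with pytest.warns(UserWarning):  # fewer than 1,000 calibration scores
            return RiskCalibration(np.linspace(0.01, 0.5, 101))

    def test_below_all_healthy_maps_to_zero(self, calibration):
        assert map_risk_score(0.0, calibration) == 0.0

    def test_above_all_healthy_maps_to_hundred(self, calibration):
        assert map_risk_score(0.99, calibration) == 100.0

    def test_healthy_median_maps_to_fifty(self, calibration):
        median = np.median(calibration.healthy_scores)
        assert map_risk_score(median, calibration) == pytest.approx(50.0)
        with pytest.warns(UserWarning):
            even = RiskCalibration(np.array([0.1, 0.2, 0.6, 0.9]))
        assert map_risk_score(0.4, even) == pytest.approx(50.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(raws=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    def test_mapping_is_bounded_and_monotone(self, raws):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cal = RiskCalibration(np.linspace(0.01, 0.5, 101))
        mapped = map_risk_score(np.sort(raws), cal)
        assert np.all((mapped >= 0) & (mapped <= 100))
        assert np.all(np.diff(mapped) >= 0)

    def test_empty_calibration_rejected(self):
        with pytest.raises(RiskModelError):
            RiskCalibration(np.array([]))


class TestThresholdCalibration:
    def test_uniform_scores_five_percent_target(self):
        scores = np.linspace(0, 100, 10_001)
        thr = calibrate_threshold(scores, prevalence=0.01, recall_multiplier=5)
        assert thr == pytest.approx(95.0, abs=0.2)

    def test_one_in_n_target_leaves_only_top_score(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 100, 500)
        thr = calibrate_threshold(scores, prevalence=1 / 500, recall_multiplier=1)
        assert thr == pytest.approx(np.max(scores))
        assert np.sum(scores >= thr) == 1

    def test_doubling_multiplier_never_raises_threshold(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0, 100, 2000)
        t1 = calibrate_threshold(scores, prevalence=0.005, recall_multiplier=2)
        t2 = calibrate_threshold(scores, prevalence=0.005, recall_multiplier=4)
        assert t2 <= t1

    def test_excessive_target_rejected(self):
        with pytest.raises(RiskModelError):
            calibrate_threshold([50.0], prevalence=0.5, recall_multiplier=2)


class TestAssessment:
    def test_empty_model_set_gives_empty_output(self):
        out = assess_cohort(pd.DataFrame({"f": []}), {}, {}, {}, record_ids=[])
        assert len(out) == 0

    def test_missing_model_names_disease(self):
        with pytest.raises(RiskModelError, match="PCD"):
            assess_cohort(pd.DataFrame({"f": [1.0]}), {}, {}, {}, diseases=["PCD"])

    def test_record_positive_aggregates_over_diseases(self):
        frame = pd.DataFrame(
            {
                "record_id": ["r1", "r1", "r2", "r2"],
                "disease": ["A", "B", "A", "B"],
                "raw_score": [0.9, 0.1, 0.2, 0.1],
                "mapped_score": [99.0, 10.0, 20.0, 10.0],
                "classification": ["high", "low", "low", "low"],
            }
        )
        pos = record_positive(frame)
        assert pos["r1"] and not pos["r2"]


def test_zero_fn_threshold_is_min_positive_score():
    assert zero_fn_threshold(np.array([0.4, 0.9, 0.6])) == 0.4
    with pytest.raises(RiskModelError):
        zero_fn_threshold(np.array([]))
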