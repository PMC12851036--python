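"""Architecture pinning, rule/DTW baselines, training contracts, routing,
few-shot calibration contracts, and checkpoint round-trips."""
import copy

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gazestrain import nn
from gazestrain.constants import ARTIFACT_CLASS
from gazestrain.datasets import make_gaze_dataset, recordings_to_windows
from gazestrain.models import (
    ClassifierSpec,
    EndToEndGazeModel,
    InceptionTimeTinyClassifier,
    KNeighborsDTWClassifier,
    MLPAngleRegressor,
    PolarityRuleClassifier,
    RegressorSpec,
    count_parameters,
    dtw_distance,
    evaluate_classifier,
    extract_regression_features,
    few_shot_calibrate,
    load_end_to_end,
    polarity_classify,
    save_end_to_end,
    train_classifier,
)
from gazestrain.preprocess import ChannelScaler, highpass_filter, segment
from gazestrain.simulate import GazeEvent, SensorSpec, generate_recording

from conftest import brute_force_dtw


class TestArchitecturePinning:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (ClassifierSpec(n_classes=4), 65156),
            (ClassifierSpec(n_classes=9), 65801),
            (RegressorSpec(output_dim=1), 44033),
            (RegressorSpec(output_dim=2), 44098),
        ],
    )
    def test_trainable_parameter_counts(self, spec, expected):
        assert count_parameters(spec) == expected

    def test_block_structure_sums(self):
        # hand summation over the layer list of the 4-class network
        block1 = 10 * 32 + 32 * 32 * (17 + 7 + 3) + 10 * 32 + 2 * 128
        block2 = 128 * 32 + 32 * 32 * (17 + 7 + 3) + 128 * 32 + 2 * 128
        head = 128 * 4 + 4
        assert block1 + block2 + head == 65156
        mlp = (10 * 256 + 256) + (256 * 128 + 128) + (128 * 64 + 64) + (64 * 1 + 1)
        assert mlp == 44033

    def test_convolutions_are_bias_free(self):
        net = ClassifierSpec().build(np.random.default_rng(0))
        convs = [l for l in nn.all_layers(net) if isinstance(l, nn.Conv1d)]
        assert len(convs) == 2 * (1 + 3 + 1)
        assert all(len(c.parameters()) == 1 for c in convs)


class TestPolarityRule:
    def _window(self, recording):
        return segment(highpass_filter(recording))[0]

    def test_clean_cardinal_windows(self, single_event_recordings):
        for direction, rec in single_event_recordings.items():
            assert polarity_classify(self._window(rec)) == direction

    def test_negation_flips_the_decision(self, single_event_recordings):
        w = self._window(single_event_recordings["up"])
        assert polarity_classify(-w.data) == "down"
        w = self._window(single_event_recordings["right"])
        assert polarity_classify(-w.data) == "left"

    def test_silence_is_uncertain(self):
        assert polarity_classify(np.zeros((3, 100))) == "uncertain"

    def test_eye_side_convention(self, single_event_recordings):
        w = self._window(single_event_recordings["right"])
        # same physical abduction signal belongs to opposite spatial directions
        assert polarity_classify(w.data, eye="right") == "right"
        assert polarity_classify(w.data, eye="left") == "left"


class TestDTW:
    @pytest.mark.parametrize(
        "a, b, expected",
        [([1, 2, 3], [1, 2, 3], 0.0), ([0, 1, 2], [0, 2], 1.0), ([0, 0], [3, 3], 6.0)],
    )
    def test_alignment_costs(self, a, b, expected):
        assert dtw_distance(a, b) == pytest.approx(expected)

    @given(
        st.lists(st.integers(-4, 4), min_size=1, max_size=6),
        st.lists(st.integers(-4, 4), min_size=1, max_size=6),
    )
    def test_matches_brute_force_and_symmetric(self, a, b):
        d = dtw_distance(a, b)
        assert d == pytest.approx(brute_force_dtw(a, b))
        assert d == pytest.approx(dtw_distance(b, a))
        assert d >= 0

    def test_multichannel_sums_per_channel_costs(self):
        a = np.array([[0.0, 1.0, 2.0], [0.0, 0.0, 0.0]])
        b = np.array([[0.0, 2.0, 2.0], [3.0, 3.0, 3.0]])
        expected = dtw_distance(a[0], b[0]) + dtw_distance(a[1], b[1])
        assert dtw_distance(a, b) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dtw_distance([], [1.0])


class TestKNNDTW:
    def test_exact_training_match_wins_at_k1(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 2, 12))
        y = np.array(["a", "a", "a", "b", "b", "b"])
        clf = KNeighborsDTWClassifier(k=1).fit(X, y)
        assert clf.predict_one(X[4]) == "b"

    def test_vote_tie_broken_by_total_distance(self):
        X = np.array([[[0.0, 0.0]], [[1.0, 1.0]], [[10.0, 10.0]], [[11.0, 11.0]]])
        y = np.array(["near", "near", "far", "far"])
        clf = KNeighborsDTWClassifier(k=4).fit(X, y)
        assert clf.predict_one(np.array([[2.0, 2.0]])) == "near"

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            KNeighborsDTWClassifier(k=1).fit(np.empty((0, 2, 5)), np.array([]))

    def test_k_larger_than_training_rejected(self):
        with pytest.raises(ValueError, match="k cannot exceed"):
            KNeighborsDTWClassifier(k=3).fit(np.zeros((2, 1, 4)), np.array(["a", "b"]))


@pytest.fixture(scope="module")
def tiny_dataset():
    """200 low-noise windows of two well-separated classes."""
    X, y, ang, _ = make_gaze_dataset(
        n_windows=200, n_subjects=2, seed=5,
        sensor=SensorSpec(noise_sd=2e-4, drift_amplitude=0.0),
        directions=("up", "right"),
    )
    scaler = ChannelScaler().fit(X[:100])
    return scaler.transform(X).astype(np.float32), y, ang


class TestClassifierTraining:
    def test_two_separated_classes_reach_perfect_holdout(self, tiny_dataset):
        X, y, _ = tiny_dataset
        clf, history = train_classifier(X[:100], y[:100])
        assert (clf.predict(X[100:]) == y[100:]).mean() == 1.0
        assert list(history.columns)[:4] == ["epoch", "loss", "accuracy", "macro_f1"]
        assert len(history) == 20

    def test_seeded_training_is_reproducible(self, tiny_dataset):
        X, y, _ = tiny_dataset
        a = InceptionTimeTinyClassifier(epochs=3, random_state=7).fit(X[:80], y[:80])
        b = InceptionTimeTinyClassifier(epochs=3, random_state=7).fit(X[:80], y[:80])
        for pa, pb in zip(a.net_.parameters(), b.net_.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_single_class_input_rejected(self, tiny_dataset):
        X, y, _ = tiny_dataset
        mask = y == "up"
        with pytest.raises(ValueError, match="2 classes"):
            InceptionTimeTinyClassifier(epochs=1).fit(X[mask], y[mask])

    def test_serialized_payload_is_four_bytes_per_parameter(self, tiny_dataset):
        X, y, _ = tiny_dataset
        clf = InceptionTimeTinyClassifier(epochs=1).fit(X[:60], y[:60])
        payload = sum(p.value.nbytes for p in clf.net_.parameters())
        assert payload == count_parameters(clf) * 4


class TestEvaluation:
    class _Stub:
        def __init__(self, preds):
            self._preds = np.asarray(preds, dtype=object)

        def predict(self, X):
            return self._preds

    def test_perfect_predictions(self):
        y = np.array(["a", "b", "a", "b"], dtype=object)
        report = evaluate_classifier(self._Stub(y), None, y)
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0

    def test_constant_predictor_on_balanced_four_classes(self):
        y = np.array(["up", "down", "left", "right"] * 10, dtype=object)
        report = evaluate_classifier(self._Stub(np.full(40, "up")), None, y)
        assert report.accuracy == pytest.approx(0.25)

    def test_confusion_rows_sum_to_class_counts(self):
        y = np.array(["a"] * 6 + ["b"] * 4, dtype=object)
        preds = np.array(["a", "b"] * 5, dtype=object)
        report = evaluate_classifier(self._Stub(preds), None, y)
        assert report.confusion.loc["a"].sum() == 6
        assert report.confusion.loc["b"].sum() == 4

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_classifier(self._Stub([]), None, np.array([]))

    def test_regression_report_routes_by_true_label(self):
        from gazestrain.models import evaluate_regression

        class _Const:
            def __init__(self, value):
                self.value = value

            def predict(self, X):
                return np.full(len(X), self.value)

        feats = np.zeros((6, 10))
        labels = np.array(["up"] * 3 + ["down"] * 3, dtype=object)
        angles = np.array([10.0, 10.0, 10.0, 5.0, 5.0, 8.0])
        report = evaluate_regression(
            {"up": _Const(11.0), "down": _Const(5.0)}, feats, labels, angles
        )
        assert report.mae_per_direction["up"] == pytest.approx(1.0)
        assert report.mae_per_direction["down"] == pytest.approx(1.0)
        assert report.mae_deg == pytest.approx(1.0)


class TestRegressor:
    def test_recovers_noise_free_linear_map(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(2400, 10)).astype(np.float32)
        w = rng.uniform(-2, 2, size=10)
        y = X @ w + 3.0
        reg = MLPAngleRegressor(dropout=0.0, lr=3e-3, epochs=300, random_state=0).fit(
            X[:2000], y[:2000]
        )
        mae = np.abs(reg.predict(X[2000:]) - y[2000:]).mean()
        assert mae < 0.2

    def test_minimum_sample_contract(self):
        X = np.zeros((10, 10))
        with pytest.raises(ValueError, match="at least"):
            MLPAngleRegressor().fit(X, np.zeros(10))

    def test_coordinate_mode_shapes(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 10)).astype(np.float32)
        y = rng.standard_normal((50, 2))
        reg = MLPAngleRegressor(output_dim=2, epochs=5, min_samples=20).fit(X, y)
        assert reg.predict(X).shape == (50, 2)
        assert count_parameters(reg.net_) == 44098

    def test_recalibration_fixes_affine_output_error(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(200, 10)).astype(np.float32)
        y = X @ np.ones(10) * 2.0 + 10.0
        reg = MLPAngleRegressor(dropout=0.0, epochs=300, random_state=0).fit(X, y)
        shifted = 1.5 * y + 1.0
        reg.recalibrate(X[:20], shifted[:20])
        mae = np.abs(reg.predict(X[100:]) - shifted[100:]).mean()
        assert mae < 1.0


class TestFeatureExtraction:
    def test_zero_window_gives_zero_vector(self):
        assert np.all(extract_regression_features(np.zeros((10, 40))) == 0)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 40))
        assert np.allclose(
            extract_regression_features(3.0 * x),
            3.0 * extract_regression_features(x),
        )

    def test_vertical_feature_negative_for_upward_window(self, single_event_recordings):
        from gazestrain.preprocess import expand_to_ten_channels

        w = segment(highpass_filter(single_event_recordings["up"]))[0]
        feats = extract_regression_features(expand_to_ten_channels(w))
        assert feats[2] < 0  # 90° unit channel


@pytest.fixture(scope="module")
def small_end_to_end():
    """Compact five-class (4 directions + blink/expression) pipeline."""
    X, y, ang, _ = make_gaze_dataset(
        n_windows=360, n_subjects=2, seed=8,
        sensor=SensorSpec(noise_sd=3e-4, drift_amplitude=0.001),
        artifact_fraction=0.2,
    )
    scaler = ChannelScaler().fit(X)
    Xs = scaler.transform(X).astype(np.float32)
    clf = InceptionTimeTinyClassifier(epochs=10, random_state=0).fit(Xs, y)
    feats = extract_regression_features(Xs)
    regressors = {}
    for c in np.unique(y):
        if c == ARTIFACT_CLASS:
            continue
        mask = y == c
        regressors[str(c)] = MLPAngleRegressor(epochs=150, random_state=0).fit(
            feats[mask], ang[mask]
        )
    return EndToEndGazeModel(classifier=clf, regressors=regressors, scaler=scaler)


class TestEndToEnd:
    def test_clean_upward_event_decodes_direction_and_angle(self, small_end_to_end):
        ev = GazeEvent(onset=3.0, hold_duration=0.35, direction="up", angle_deg=10.0)
        rec = generate_recording(
            [ev], sensor=SensorSpec(noise_sd=3e-4, drift_amplitude=0.001),
            duration=6.0, seed=4,
        )
        ((label, angle),) = small_end_to_end.predict(rec)
        assert label == "up"
        assert angle == pytest.approx(10.0, abs=2.0)

    def test_blink_routes_to_no_angle(self, small_end_to_end):
        ev = GazeEvent(onset=3.0, hold_duration=0.0, direction="blink")
        rec = generate_recording(
            [ev], sensor=SensorSpec(noise_sd=3e-4, drift_amplitude=0.001),
            duration=6.0, seed=4,
        )
        ((label, angle),) = small_end_to_end.predict(rec)
        assert label == ARTIFACT_CLASS
        assert angle is None

    def test_empty_recording_gives_empty_output(self, small_end_to_end):
        rec = generate_recording(
            [], sensor=SensorSpec(noise_sd=3e-4, drift_amplitude=0.001),
            duration=4.0, seed=0,
        )
        assert small_end_to_end.predict(rec) == []

    def test_missing_regressor_for_predicted_class_raises(self, small_end_to_end):
        broken = copy.deepcopy(small_end_to_end)
        broken.regressors.pop("up")
        ev = GazeEvent(onset=3.0, hold_duration=0.35, direction="up", angle_deg=12.0)
        rec = generate_recording(
            [ev], sensor=SensorSpec(noise_sd=3e-4, drift_amplitude=0.001),
            duration=6.0, seed=4,
        )
        with pytest.raises(KeyError, match="no regressor"):
            broken.predict(rec)

    def test_checkpoint_roundtrip_preserves_predictions(self, small_end_to_end, tmp_path):
        X, y, ang, _ = make_gaze_dataset(n_windows=40, n_subjects=1, seed=13,
                                         artifact_fraction=0.2)
        Xs = small_end_to_end.scaler.transform(X).astype(np.float32)
        before = small_end_to_end.predict_windows(Xs)
        path = tmp_path / "model.npz"
        save_end_to_end(path, small_end_to_end)
        after = load_end_to_end(path).predict_windows(Xs)
        assert before == after


class TestFewShotContracts:
    def test_sample_count_bounds_enforced(self, small_end_to_end):
        X, y, ang, _ = make_gaze_dataset(n_windows=80, n_subjects=1, seed=21)
        Xs = small_end_to_end.scaler.transform(X).astype(np.float32)
        idx1 = np.concatenate([np.flatnonzero(y == c)[:1] for c in np.unique(y)])
        with pytest.raises(ValueError, match="2–5"):
            few_shot_calibrate(small_end_to_end, Xs[idx1], y[idx1], ang[idx1])
        idx6 = np.concatenate([np.flatnonzero(y == c)[:6] for c in np.unique(y)])
        with pytest.raises(ValueError, match="2–5"):
            few_shot_calibrate(small_end_to_end, Xs[idx6], y[idx6], ang[idx6])

    def test_original_model_left_untouched(self, small_end_to_end):
        X, y, ang, _ = make_gaze_dataset(n_windows=80, n_subjects=1, seed=22)
        Xs = small_end_to_end.scaler.transform(X).astype(np.float32)
        idx = np.concatenate([np.flatnonzero(y == c)[:3] for c in np.unique(y)])
        before = [p.value.copy() for p in small_end_to_end.classifier.net_.parameters()]
        adapted = few_shot_calibrate(small_end_to_end, Xs[idx], y[idx], ang[idx])
        after = [p.value for p in small_end_to_end.classifier.net_.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))
        changed = any(
            not np.array_equal(a, b)
            for a, b in zip(
                (p.value for p in adapted.classifier.net_.parameters()), before
            )
        )
        assert changed
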