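"""CNN architectures, training contract, prediction, timing."""

import numpy as np
import pytest

from imugait.io import SensorSelection, ValidationError, WindowedDataset
from imugait.models import (GaitCNN, ModelSpec, TrainConfig, build_model,
                            component_branch_split, measure_inference_time,
                            predict, train)


def _spec(arch="smCNN-1D", nch=45, nc=3, wl=128, n_classes=5):
    split = (component_branch_split(nch // (3 * nc), nc)
             if arch != "sCNN-1D" else None)
    return ModelSpec(arch, (wl, nch), n_classes, split)


def _toy_dataset(n_per_class=40, n_classes=2, wl=32, nch=6, subject="tr",
                 seed=0, shuffle_labels=False):
    """Trivially separable windows: class c is a sinusoid at (c+1)*4 Hz."""
    rng = np.random.default_rng(seed)
    t = np.arange(wl) / wl
    xs, ys = [], []
    for c in range(n_classes):
        base = np.sin(2 * np.pi * (c + 1) * 4 * t)
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            win = np.stack([np.sin(2 * np.pi * (c + 1) * 4 * t + phase)
                            + 0.01 * rng.normal(size=wl)
                            for _ in range(nch)], axis=1)
            xs.append(win)
            ys.append(c)
    ys = np.array(ys)
    if shuffle_labels:
        ys = rng.permutation(ys)
    sel = SensorSelection(sensors=("S", "LP")[:nch // 3] or ("S",),
                          components=("acc",))
    # selection metadata is irrelevant to the optimizer; fabricate a legal one
    sel = SensorSelection(sensors=("S",), components=("acc", "gyro"))
    return WindowedDataset(np.stack(xs), ys,
                           np.array([subject] * len(ys), dtype=object), sel)


class TestBuildModel:
    def test_branch_structure_channel_partition(self):
        spec = _spec("smCNN-1D", nch=45, nc=3)
        assert len(spec.branch_split) == 3
        assert all(len(g) == 15 for g in spec.branch_split)

    def test_parameter_count_deterministic(self):
        spec = _spec("mCNN-1D")
        counts = {build_model(spec, seed=s).n_params for s in (0, 1, 2)}
        assert len(counts) == 1

    def test_multibranch_requires_partition(self):
        with pytest.raises(ValidationError):
            ModelSpec("smCNN-1D", (128, 45), 5, None)
        with pytest.raises(ValidationError):
            ModelSpec("smCNN-1D", (128, 45), 5, [[0, 1], [1, 2]])

    def test_sequential_takes_single_component_input(self):
        model = build_model(_spec("sCNN-1D", nch=15, nc=1))
        probs = model.predict_proba(
            np.random.default_rng(0).normal(size=(4, 128, 15)))
        assert probs.shape == (4, 5)

    @pytest.mark.parametrize("arch", ["mCNN-1D", "smCNN-1D", "sCNN-1D"])
    def test_softmax_rows_sum_to_one(self, arch):
        model = build_model(_spec(arch))
        x = np.random.default_rng(1).normal(size=(8, 128, 45))
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()


class TestTrain:
    def test_separable_toy_reaches_perfect_validation_recall(self):
        tr = _toy_dataset(seed=0, subject="a")
        va = _toy_dataset(n_per_class=10, seed=1, subject="b")
        spec = ModelSpec("sCNN-1D", (32, 6), 2)
        model = build_model(spec, seed=0)
        hist = train(model, tr, va, TrainConfig(max_epochs=30, patience=30,
                                                seed=0, batch_size=16),
                     architecture="sCNN-1D")
        assert hist["val_macro_recall"].max() == 1.0

    def test_early_stop_patience_contract(self):
        """With patience=1 and a flat metric, training stops at epoch 2."""
        tr = _toy_dataset(n_per_class=4, seed=0, subject="a")
        va = _toy_dataset(n_per_class=60, seed=1, subject="b")
        spec = ModelSpec("sCNN-1D", (32, 6), 2)
        model = build_model(spec, seed=0)
        # zero learning rate: the metric can never improve after epoch 1
        hist = train(model, tr, va,
                     TrainConfig(max_epochs=50, patience=1, seed=0,
                                 learning_rate=1e-30, batch_size=8),
                     architecture="sCNN-1D")
        assert len(hist) == 2

    def test_missing_class_in_validation_rejected(self):
        tr = _toy_dataset(seed=0, subject="a")
        va = _toy_dataset(n_per_class=5, seed=1, subject="b")
        va.labels[:] = 0  # drop class 1 from validation
        model = build_model(ModelSpec("sCNN-1D", (32, 6), 2), seed=0)
        with pytest.raises(ValidationError):
            train(model, tr, va, TrainConfig(max_epochs=2, patience=1),
                  architecture="sCNN-1D")

    def test_overlapping_subjects_rejected(self):
        tr = _toy_dataset(seed=0, subject="same")
        va = _toy_dataset(n_per_class=5, seed=1, subject="same")
        model = build_model(ModelSpec("sCNN-1D", (32, 6), 2), seed=0)
        with pytest.raises(ValidationError):
            train(model, tr, va, TrainConfig(max_epochs=2, patience=1),
                  architecture="sCNN-1D")

    def test_training_reproducible_for_fixed_seed(self):
        tr = _toy_dataset(n_per_class=10, seed=0, subject="a")
        va = _toy_dataset(n_per_class=5, seed=1, subject="b")
        hists = []
        for _ in range(2):
            model = build_model(ModelSpec("sCNN-1D", (32, 6), 2), seed=3)
            hists.append(train(model, tr, va,
                               TrainConfig(max_epochs=3, patience=3, seed=3,
                                           batch_size=8),
                               architecture="sCNN-1D"))
        np.testing.assert_array_equal(hists[0]["loss"], hists[1]["loss"])


class TestPredict:
    def test_batch_shape_and_argmax(self):
        model = build_model(_spec("sCNN-1D", nch=6, nc=2, wl=32,
                                  n_classes=3))
        x = np.random.default_rng(0).normal(size=(11, 32, 6))
        labels, probs = predict(model, x)
        assert labels.shape == (11,) and probs.shape == (11, 3)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))

    def test_tie_breaks_toward_lowest_class(self):
        probs = np.array([[0.5, 0.5, 0.0, 0.0, 0.0]])
        assert probs.argmax(axis=1)[0] == 0  # argmax convention the
        # predictor relies on: first maximal index wins

    def test_shape_mismatch_rejected(self):
        model = build_model(_spec("sCNN-1D", nch=6, nc=2, wl=32))
        with pytest.raises((ValidationError, ValueError)):
            predict(model, np.zeros((4, 32)))


class TestInferenceTime:
    def test_returns_requested_trials(self):
        model = build_model(_spec("sCNN-1D", nch=6, nc=2, wl=32))
        x = np.zeros((16, 32, 6), dtype=np.float32)
        out = measure_inference_time(model, x, n_trials=5)
        assert len(out["trial_times_s"]) == 5
        assert all(t >= 0 for t in out["trial_times_s"])
        assert out["median_s"] >= 0 and out["n_windows"] == 16

    def test_empty_input_rejected(self):
        model = build_model(_spec("sCNN-1D", nch=6, nc=2, wl=32))
        with pytest.raises(ValidationError):
            measure_inference_time(model, np.zeros((0, 32, 6)))


class TestResultsObject:
    def test_fit_returns_results_with_summary(self):
        tr = _toy_dataset(n_per_class=12, seed=0, subject="a")
        va = _toy_dataset(n_per_class=6, seed=1, subject="b")
        res = GaitCNN(tr, va, architecture="sCNN-1D", n_classes=2).fit(
            TrainConfig(max_epochs=3, patience=3, seed=0, batch_size=8))
        text = res.summary()
        assert "sCNN-1D" in text and str(res.n_params) in text
        assert res.n_epochs == len(res.history)
        assert res.predict(va.tensor).shape == (va.n_windows,)
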