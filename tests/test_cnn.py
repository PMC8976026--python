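"""U-Net construction, training behaviour, dataset splitting, inference."""

import numpy as np
import pytest

from adiposeg.cnn import UNetSegmenter, build_model, predict_volume, \
    split_dataset, volume_to_slices
from adiposeg.core import CohortManifest, SubjectRecord
from adiposeg.metrics import dice
from adiposeg.nn.layers import softmax_cross_entropy


@pytest.fixture(scope="module")
def tiny_xy(clean_volume):
    v, gt = clean_volume
    X, y = volume_to_slices(v, gt)
    return X[:8], y[:8]


class TestBuildModel:
    def test_output_shape_matches_input(self):
        net = build_model(input_size=(32, 32), encoder_channels=(4, 8, 16),
                         bottleneck_channels=32, seed=0)
        x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
        logits = net.forward(x)
        assert logits.shape == (2, 3, 32, 32)

    def test_softmax_normalized_per_pixel(self):
        net = build_model(input_size=(16, 16), encoder_channels=(2, 4),
                         bottleneck_channels=8, seed=1)
        x = np.random.default_rng(1).random((3, 1, 16, 16)).astype(np.float32)
        p = net.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_encoder_channel_progression(self):
        net = build_model(input_size=(64, 64), encoder_channels=(16, 32, 64),
                         bottleneck_channels=128, seed=0)
        widths = [blk.layers[0].params["W"].shape[0]
                  for blk in net.enc_blocks]
        assert widths == [16, 32, 64]
        assert net.bottleneck.layers[0].params["W"].shape[0] == 128

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_model(input_size=(100, 100), encoder_channels=(4, 8, 16))

    def test_gradients_match_finite_differences(self):
        """Spot-check the hand-written backprop against numerics."""
        net = build_model(input_size=(8, 8), encoder_channels=(2, 3),
                         bottleneck_channels=4, dropout_rate=0.0, seed=0)
        for ly in net._all_layers():
            for k in ly.params:
                ly.params[k] = ly.params[k].astype(np.float64)
                ly.grads[k] = np.zeros_like(ly.params[k])
        rng = np.random.default_rng(1)
        x = rng.random((2, 1, 8, 8))
        y = rng.integers(0, 3, (2, 8, 8))
        loss0, _, grad = softmax_cross_entropy(net.forward(x), y)
        net.backward(grad)
        eps = 1e-6
        check_rng = np.random.default_rng(2)
        for ly in net._all_layers():
            for k, W in ly.params.items():
                flat = W.reshape(-1)
                i = check_rng.integers(0, flat.size)
                orig = flat[i]
                flat[i] = orig + eps
                lp = softmax_cross_entropy(net.forward(x), y)[0]
                flat[i] = orig - eps
                lm = softmax_cross_entropy(net.forward(x), y)[0]
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = ly.grads[k].reshape(-1)[i]
                assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-3)


class TestTraining:
    def test_overfit_smoke_drives_loss_down(self, tiny_xy):
        X, y = tiny_xy
        m = UNetSegmenter(input_size=(64, 64), encoder_channels=(4, 8, 16),
                          bottleneck_channels=32, dropout_rate=0.0,
                          epochs=30, batch_size=2, random_state=0)
        m.fit(X, y)
        h = m.history_["loss"]
        assert h[-1] < 0.1 * h[0]
        non_monotone = sum(1 for a, b in zip(h, h[1:]) if b > a)
        assert non_monotone <= 2

    def test_same_seed_identical_weights(self, tiny_xy):
        X, y = tiny_xy
        kw = dict(input_size=(64, 64), encoder_channels=(2, 4, 8),
                  bottleneck_channels=16, epochs=2, batch_size=4,
                  random_state=7)
        m1 = UNetSegmenter(**kw).fit(X, y)
        m2 = UNetSegmenter(**kw).fit(X, y)
        for a, b in zip(m1.net_.get_weights(), m2.net_.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_wrong_mask_size_rejected_before_training(self, tiny_xy):
        X, y = tiny_xy
        m = UNetSegmenter(input_size=(64, 64), encoder_channels=(2, 4),
                          epochs=1)
        with pytest.raises(ValueError, match="mismatch"):
            m.fit(X, y[:, :32, :32])

    def test_sklearn_param_protocol(self):
        m = UNetSegmenter(epochs=3)
        assert m.get_params()["epochs"] == 3
        m.set_params(learning_rate=5e-4)
        assert m.learning_rate == 5e-4

    def test_save_load_roundtrip(self, tiny_xy, tmp_path):
        X, y = tiny_xy
        m = UNetSegmenter(input_size=(64, 64), encoder_channels=(2, 4),
                          bottleneck_channels=8, epochs=1, batch_size=4,
                          random_state=3).fit(X, y)
        m.save(tmp_path / "model")
        back = UNetSegmenter.load(tmp_path / "model")
        np.testing.assert_array_equal(m.predict(X), back.predict(X))


class TestSplitDataset:
    @staticmethod
    def _manifest(n=100, seed=0):
        rng = np.random.default_rng(seed)
        subs = [SubjectRecord(f"s{i:03d}", "control" if i % 2 else "patient",
                              float(rng.uniform(40, 75)),
                              float(rng.uniform(19, 32)))
                for i in range(n)]
        return CohortManifest(subjects=subs)

    def test_100_subjects_split_50_6_44(self):
        m = split_dataset(self._manifest(100), seed=1)
        counts = {s: len(m.by_split(s)) for s in ("train", "val", "test")}
        assert counts == {"train": 50, "val": 6, "test": 44}

    def test_every_subject_in_exactly_one_split(self):
        m = split_dataset(self._manifest(60), seed=2)
        assert all(s.split in ("train", "val", "test") for s in m.subjects)
        assert len({s.subject_id for s in m.subjects}) == 60

    def test_same_seed_reproducible(self):
        a = split_dataset(self._manifest(40), seed=5)
        b = split_dataset(self._manifest(40), seed=5)
        assert [s.split for s in a.subjects] == [s.split for s in b.subjects]

    def test_small_strata_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="stratum"):
            m = split_dataset(self._manifest(8), seed=0)
        assert len(m) == 8

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._manifest(10), fractions=(0.5, 0.5, 0.5))


class TestPredictVolume:
    def test_dims_classes_and_determinism(self, trained_experiment,
                                          clean_volume):
        v, _ = clean_volume
        model = trained_experiment.model
        out1 = predict_volume(model, v)
        out2 = predict_volume(model, v)
        assert out1.shape == v.shape
        assert set(np.unique(out1.classes)) <= {0, 1, 2}
        np.testing.assert_array_equal(out1.classes, out2.classes)

    def test_overfit_model_reproduces_training_slice(self, tiny_xy):
        X, y = tiny_xy
        m = UNetSegmenter(input_size=(64, 64), encoder_channels=(4, 8, 16),
                          bottleneck_channels=32, dropout_rate=0.0,
                          epochs=30, batch_size=2, random_state=0).fit(X, y)
        pred = m.predict(X[3:4])[0]  # central slice, full annulus
        assert dice(y[3] == 1, pred == 1) >= 0.95

    def test_resampled_inference_path(self, trained_experiment, clean_subject):
        from adiposeg.phantom import render_volume
        v, _ = render_volume(clean_subject, dims=(48, 48, 8),
                             spacing=(4.0, 4.0, 6.0))
        out = predict_volume(trained_experiment.model, v)
        assert out.shape == v.shape
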