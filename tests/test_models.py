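"""Detector construction, training contracts and score orientation."""

from types import SimpleNamespace

import numpy as np
import pytest

from fogkit import models as md
from fogkit.errors import ContractError, StateError


def make_separable_spectra(n=240, seed=0, flat=False):
    """Wide-margin synthetic spectra: class 0 has locomotion-band energy,
    class 1 freeze-band energy (bins 4 vs 20, i.e. 1.25 vs 6.25 Hz)."""
    rng = np.random.default_rng(seed)
    x = rng.random((n, 64, 3)) * 0.05
    y = rng.integers(0, 2, n)
    amp = rng.uniform(0.8, 1.2, n)
    x[y == 0, 4, :] += amp[y == 0, None]
    x[y == 1, 20, :] += amp[y == 1, None]
    if flat:
        x = x.reshape(n, -1)
    return x, y


class TestAutoencoderArchitecture:
    def test_parameter_count_matches_closed_form(self):
        ae = md.build_autoencoder(seed=0)
        dims = [192, 192, 80, 40, 20, 40, 80, 192]
        expected = sum((dims[i] + 1) * dims[i + 1] for i in range(7))
        assert ae.n_params == expected

    def test_maps_192_to_192(self):
        ae = md.build_autoencoder(seed=0)
        out = ae.forward(np.random.default_rng(0).random((4, 192),
                                                         dtype=np.float32))
        assert out.shape == (4, 192)
        assert np.all((out >= 0) & (out <= 1))  # sigmoid output

    def test_bottleneck_width_is_20(self):
        ae = md.build_autoencoder(seed=0)
        bottleneck = ae.layers[3]
        assert bottleneck.n_out == 20 and bottleneck.activation == "relu"

    def test_wrong_input_dim_rejected(self):
        ae = md.build_autoencoder(seed=0)
        with pytest.raises(ContractError):
            ae.forward(np.zeros((2, 100), dtype=np.float32))

    def test_constant_dataset_reconstruction_rmse_vanishes(self):
        # degenerate fit: no noise, constant rows -> near-perfect reconstruction
        ae = md.build_autoencoder(seed=1)
        x = np.full((64, 192), 0.5, dtype=np.float32)
        cfg = md.TrainConfig(epochs=300, batch_size=64, learning_rate=1e-3,
                             early_stop_patience=50, noise_factor=0.0, seed=1)
        det = md.train_novelty(ae, x, cfg)
        rmse = md.novelty_score(det, x)
        assert rmse.mean() < 0.02


class TestNoveltyTraining:
    def test_fog_rows_in_training_set_rejected(self):
        x = np.random.default_rng(0).random((10, 192))
        labels = np.zeros(10, dtype=int)
        labels[3] = 1
        with pytest.raises(ContractError, match="FOG"):
            md.train_novelty(md.build_autoencoder(0), x,
                             md.TrainConfig(epochs=1), labels=labels)

    def test_default_batch_size_512(self):
        assert md.default_config("mlp_autoencoder").batch_size == 512
        assert md.default_config("mlp_autoencoder").epochs == 250

    def test_score_is_rmse_of_toy_row(self):
        # 3-feature toy: stub model reconstructs a fixed row
        recon = np.array([[0.1, 0.4, 0.7]])
        stub = SimpleNamespace(predict=lambda x: recon)
        det = md.TrainedDetector("mlp_autoencoder", stub)
        x = np.array([[0.2, 0.2, 1.0]])
        expected = np.sqrt(((x - recon) ** 2).mean())
        assert md.novelty_score(det, x)[0] == pytest.approx(expected)

    def test_perfect_reconstruction_scores_zero_and_nonnegative(self):
        x = np.random.default_rng(0).random((5, 3))
        stub = SimpleNamespace(predict=lambda q: q)
        det = md.TrainedDetector("mlp_autoencoder", stub)
        scores = md.novelty_score(det, x)
        np.testing.assert_allclose(scores, 0, atol=1e-12)

    def test_untrained_detector_raises(self):
        det = md.TrainedDetector("mlp_autoencoder", None)
        with pytest.raises(StateError):
            det.score(np.zeros((1, 192)))


class TestCNN:
    def test_output_is_probability(self):
        cnn = md.build_cnn(seed=0)
        x = np.random.default_rng(0).normal(size=(6, 64, 3)).astype(np.float32)
        out = cnn.forward(x)
        assert out.shape == (6, 1)
        assert np.all((out >= 0) & (out <= 1))

    def test_pooling_halves_sequence_length(self):
        cnn = md.build_cnn(seed=0)
        x = np.random.default_rng(0).normal(size=(2, 64, 3)).astype(np.float32)
        out = cnn.layers[0].forward(x)  # conv, kernel 8: 64 -> 57
        assert out.shape == (2, 57, 32)
        out = cnn.layers[1].forward(out)  # pool 2: 57 -> 28
        assert out.shape == (2, 28, 32)

    def test_learns_wide_margin_spectra(self):
        x, y = make_separable_spectra()
        cfg = md.TrainConfig(epochs=60, batch_size=64, learning_rate=1e-3,
                             early_stop_patience=60, seed=0)
        det = md.train_supervised_deep(md.build_cnn(0), "cnn", x, y, cfg)
        from fogkit.eval import roc_metrics
        assert roc_metrics(det.score(x), y)["auc"] > 0.95


class TestCNNLSTM:
    def test_lstm_width_is_64(self):
        model = md.build_cnn_lstm(k=3, seed=0)
        assert model.layers[1].units == 64

    def test_k0_single_step_probability(self):
        model = md.build_cnn_lstm(k=0, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 1, 64, 3)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (3, 1)
        assert np.all((out >= 0) & (out <= 1))

    def test_time_steps_share_conv_weights(self):
        # perturbing one time step leaves other steps' pre-LSTM activations
        # unchanged, which can only hold if the conv weights are shared and
        # applied independently per step
        model = md.build_cnn_lstm(k=2, seed=0)
        td = model.layers[0]
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 64, 3)).astype(np.float32)
        base = td.forward(x)
        x2 = x.copy()
        x2[:, 1] += rng.normal(size=(2, 64, 3)).astype(np.float32)
        pert = td.forward(x2)
        np.testing.assert_array_equal(base[:, 0], pert[:, 0])
        np.testing.assert_array_equal(base[:, 2], pert[:, 2])
        assert np.any(base[:, 1] != pert[:, 1])

    def test_default_batch_size_1024(self):
        assert md.default_config("cnn_lstm").batch_size == 1024


class TestShallow:
    def test_random_forest_default_100_estimators(self):
        x, y = make_separable_spectra(n=60, flat=True)
        det = md.fit_shallow("random_forest", x, y)
        assert det.model.n_estimators == 100

    def test_adaboost_default_100_estimators(self):
        x, y = make_separable_spectra(n=60, flat=True)
        det = md.fit_shallow("adaboost", x, y)
        assert det.model.n_estimators == 100

    def test_svm_rbf_defaults(self):
        x, y = make_separable_spectra(n=60, flat=True)
        det = md.fit_shallow("svm", x, y)
        assert det.model.kernel == "rbf"
        assert det.model.gamma == 0.3 and det.model.C == 1.0

    def test_ocsvm_linear_kernel_default(self):
        x, _ = make_separable_spectra(n=40, flat=True)
        det = md.fit_shallow("ocsvm", x)
        assert det.model.kernel == "linear"

    def test_single_class_supervised_rejected(self):
        x = np.random.default_rng(0).random((20, 10))
        with pytest.raises(ContractError):
            md.fit_shallow("svm", x, np.zeros(20, dtype=int))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ContractError):
            md.fit_shallow("quantum_forest", np.zeros((5, 2)), np.zeros(5))

    def test_random_forest_separates_wide_margin_data(self):
        x, y = make_separable_spectra(flat=True)
        det = md.fit_shallow("random_forest", x, y)
        from fogkit.eval import roc_metrics
        assert roc_metrics(det.score(x), y)["auc"] > 0.95


class TestReproducibilityAndOrientation:
    def test_identical_seed_identical_scores(self):
        x, y = make_separable_spectra(n=120)
        cfg = md.TrainConfig(epochs=5, batch_size=64, learning_rate=1e-3, seed=7)
        s = []
        for _ in range(2):
            det = md.fit_detector("cnn", x, y, cfg=cfg)
            s.append(det.score(x))
        np.testing.assert_allclose(s[0], s[1], atol=1e-6)

    def test_scoring_does_not_mutate_detector(self):
        x, y = make_separable_spectra(n=60, flat=True)
        det = md.fit_shallow("random_forest", x, y)
        norm_before = det.norm_max
        det.score(x)
        assert det.norm_max == norm_before

    @pytest.mark.parametrize("kind", ["random_forest", "svm", "adaboost"])
    def test_higher_score_means_more_fog(self, kind):
        x, y = make_separable_spectra(flat=True)
        det = md.fit_shallow(kind, x, y)
        scores = det.score(x)
        assert scores[y == 1].mean() > scores[y == 0].mean()
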