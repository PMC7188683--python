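import math
import warnings

import numpy as np
import pytest

from afplatent import metrics as m
from afplatent.model import (
    JointModel,
    JointModelConfig,
    TrainConfig,
    TrainedModel,
    _one_hot,
    build_model,
    mse_db,
    train,
)


def blobs(n=200, dim=20, sep=6.0, seed=0):
    """Two linearly separable non-negative blobs at pair-frequency scale
    (values ~0.05, like CKSAAP descriptors) so the classification loss is
    not drowned by the reconstruction term."""
    rng = np.random.default_rng(seed)
    half = n // 2
    sd = 0.02
    X = np.vstack(
        [
            rng.normal(0.05, sd, size=(half, dim)),
            rng.normal(0.05 + sep * sd / math.sqrt(dim), sd, size=(n - half, dim)),
        ]
    )
    y = np.array([0] * half + [1] * (n - half))
    perm = rng.permutation(n)
    return np.clip(X[perm], 0, None), y[perm]


TINY = JointModelConfig(
    input_dim=7,
    latent_dim=2,
    encoder_hidden=(6, 5),
    classifier_hidden=(4,),
    dropout_rate=0.0,
    sparsity_coefficient=1e-3,
)


def numeric_gradient(net, X, Y, eps=1e-6):
    grads = []
    for p in net.parameters():
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            z, xh, pr = net.forward(X, train=False)
            lp = net.loss(X, Y, z, xh, pr, 1.0, 1.0)["total"]
            p[idx] = orig - eps
            z, xh, pr = net.forward(X, train=False)
            lm = net.loss(X, Y, z, xh, pr, 1.0, 1.0)["total"]
            p[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads


@pytest.mark.parametrize("batchnorm", [False, True])
def test_backprop_matches_finite_differences(batchnorm):
    """Analytic gradients of the combined loss agree with central differences."""
    cfg = TINY if not batchnorm else JointModelConfig(
        input_dim=7,
        latent_dim=2,
        encoder_hidden=(6, 5),
        classifier_hidden=(4,),
        dropout_rate=0.0,
        sparsity_coefficient=1e-3,
        use_batchnorm=True,
    )
    rng = np.random.default_rng(1)
    X = rng.random((12, 7))
    y = rng.integers(0, 2, 12)
    y[:2] = [0, 1]
    Y = _one_hot(y, 2)
    net = JointModel(cfg, seed=3)
    # nudge biases off their zero init: with b = 0 exactly, dead upstream
    # units put pre-activations exactly on the rectifier kink, where the
    # two-sided difference quotient and the subgradient legitimately differ
    for layer in net.layers():
        layer.b += rng.normal(0.0, 0.05, size=layer.b.shape)
    if batchnorm:
        # populate running stats; the check then differentiates the
        # (deterministic) inference-mode forward pass
        net.forward(X, train=True, rng=rng)
    z, xh, pr = net.forward(X, train=False)
    net.backward(X, Y, z, xh, pr, 1.0, 1.0)
    analytic = [g.copy() for layer in net.layers() for g in layer.grads()]
    numeric = numeric_gradient(net, X, Y)
    for a, n in zip(analytic, numeric):
        scale = max(np.abs(n).max(), 1e-8)
        np.testing.assert_allclose(a, n, atol=3e-5 * scale + 1e-9)


class TestConfig:
    def test_mirror_symmetry_enforced(self):
        with pytest.raises(ValueError, match="mirror"):
            JointModelConfig(input_dim=100, decoder_hidden=(50, 25, 25, 10))

    def test_default_decoder_is_reversed_encoder(self):
        cfg = JointModelConfig(input_dim=100)
        assert cfg.decoder_hidden == (10, 25, 25, 50)

    def test_weak_compression_warns_not_errors(self):
        with pytest.warns(UserWarning, match="compress"):
            JointModelConfig(input_dim=100, latent_dim=15)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            JointModelConfig(input_dim=0)
        with pytest.raises(ValueError):
            JointModelConfig(input_dim=10, latent_dim=0)

    def test_patience_bounded_by_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, early_stop_patience=20)


class TestBuild:
    def test_construction_is_deterministic(self):
        cfg = JointModelConfig(input_dim=60, latent_dim=4)
        p1 = build_model(cfg, seed=5).parameters()
        p2 = build_model(cfg, seed=5).parameters()
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("lv", [1, 2, 3, 4, 5, 10, 15, 20, 25])
    def test_embedding_dimension_tracks_latent_size(self, lv):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = JointModelConfig(input_dim=60, latent_dim=lv)
        net = build_model(cfg, seed=0)
        z, xhat, proba = net.forward(np.random.default_rng(0).random((3, 60)))
        assert z.shape == (3, lv)
        assert xhat.shape == (3, 60)
        assert proba.shape == (3, 2)


class TestTrain:
    def test_separable_blobs_reach_high_training_accuracy(self):
        X, y = blobs(n=200, seed=2)
        cfg = JointModelConfig(input_dim=X.shape[1], latent_dim=4)
        tm = train(build_model(cfg, seed=2), X, y, TrainConfig(max_epochs=150, early_stop_patience=50, seed=2))
        _, labels = tm.predict(X)
        assert (labels == y).mean() >= 0.95

    def test_validation_split_arithmetic(self):
        X, y = blobs(n=600, seed=3)
        cfg = JointModelConfig(input_dim=X.shape[1], latent_dim=2)
        tm = train(build_model(cfg, seed=3), X, y, TrainConfig(max_epochs=2, early_stop_patience=2, seed=3))
        assert (tm.n_train, tm.n_val) == (540, 60)

    def test_single_class_labels_rejected(self):
        X, _ = blobs(n=40, seed=4)
        cfg = JointModelConfig(input_dim=X.shape[1], latent_dim=2)
        with pytest.raises(ValueError, match="single class"):
            train(build_model(cfg, seed=0), X, np.zeros(40, dtype=int), TrainConfig(max_epochs=2, early_stop_patience=2))

    def test_degenerate_repeated_row(self):
        """A constant input is reconstructed nearly perfectly while the
        classifier can do no better than chance."""
        X = np.tile(np.linspace(0.1, 0.9, 12), (80, 1))
        y = np.array([0, 1] * 40)
        cfg = JointModelConfig(input_dim=12, latent_dim=2, encoder_hidden=(8, 6), classifier_hidden=(4,))
        tm = train(build_model(cfg, seed=5), X, y, TrainConfig(max_epochs=200, early_stop_patience=200, seed=5))
        _, mse = tm.reconstruct(X)
        assert mse < 1e-3
        _, labels = tm.predict(X)
        ba = m.compute_metrics(m.confusion(y, labels)).balanced_accuracy
        assert ba == 0.5  # identical rows force identical predictions

    def test_identical_runs_identical_histories(self):
        X, y = blobs(n=80, seed=6)
        cfg = JointModelConfig(input_dim=X.shape[1], latent_dim=2)
        tc = TrainConfig(max_epochs=15, early_stop_patience=15, seed=6)
        tm1 = train(build_model(cfg, seed=6), X, y, tc)
        tm2 = train(build_model(cfg, seed=6), X, y, tc)
        assert tm1.history == tm2.history
        p1, _ = tm1.predict(X)
        p2, _ = tm2.predict(X)
        np.testing.assert_array_equal(p1, p2)


@pytest.fixture(scope="module")
def fitted():
    X, y = blobs(n=120, seed=7)
    cfg = JointModelConfig(input_dim=X.shape[1], latent_dim=4)
    tm = train(build_model(cfg, seed=7), X, y, TrainConfig(max_epochs=60, early_stop_patience=60, seed=7))
    return tm, X, y


class TestTrainedModel:
    def test_embedding_properties(self, fitted):
        tm, X, _ = fitted
        z = tm.embed(X)
        assert z.shape == (len(X), 4)
        assert np.all(z >= 0)  # rectified latent
        np.testing.assert_array_equal(tm.embed(X[:1]), tm.embed(X[:1]))
        # identical rows embed identically
        np.testing.assert_array_equal(
            tm.embed(np.vstack([X[0], X[0]]))[0], tm.embed(np.vstack([X[0], X[0]]))[1]
        )

    def test_softmax_rows_sum_to_one(self, fitted):
        tm, X, _ = fitted
        proba, labels = tm.predict(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert set(labels) <= {0, 1}

    def test_probability_tie_breaks_to_non_afp(self, fitted):
        tm, X, _ = fitted
        # zero the classifier output layer: logits identical -> p = (.5, .5)
        out = tm.net.classifier[-1]
        out.W[...] = 0.0
        out.b[...] = 0.0
        proba, labels = tm.predict(X[:5])
        np.testing.assert_allclose(proba, 0.5)
        assert np.all(labels == 0)

    def test_training_reduces_reconstruction_error(self):
        X, y = blobs(n=100, seed=8)
        cfg = JointModelConfig(input_dim=X.shape[1], latent_dim=4)
        untrained = build_model(cfg, seed=8)
        _, xh0, _ = untrained.forward(X)
        mse0 = float(np.mean((X - xh0) ** 2))
        tm = train(build_model(cfg, seed=8), X, y, TrainConfig(max_epochs=80, early_stop_patience=80, seed=8))
        _, mse1 = tm.reconstruct(X)
        assert mse1 < mse0

    def test_dimension_mismatch_rejected(self, fitted):
        tm, X, _ = fitted
        with pytest.raises(ValueError, match="features"):
            tm.predict(X[:, :-1])

    def test_save_load_roundtrip(self, fitted, tmp_path):
        tm, X, _ = fitted
        path = tmp_path / "model.npz"
        tm.save(path)
        tm2 = TrainedModel.load(path)
        np.testing.assert_array_equal(tm.predict(X)[0], tm2.predict(X)[0])
        assert tm2.model_config == tm.model_config
        assert tm2.history == tm.history


class TestMseDb:
    @pytest.mark.parametrize("mse,expected", [(0.01, -20.0), (1.0, 0.0)])
    def test_exact_powers(self, mse, expected):
        assert mse_db(mse) == pytest.approx(expected)

    def test_published_magnitude_inverse(self):
        # -14.69 dB corresponds to a raw MSE near 0.034
        assert round(mse_db(0.034), 2) == -14.69

    def test_zero_maps_to_negative_infinity_with_warning(self):
        with pytest.warns(UserWarning, match="-inf"):
            assert mse_db(0.0) == -math.inf

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mse_db(-0.1)


def test_nan_loss_reports_epoch():
    X, y = blobs(n=60, seed=9)
    X[0, 0] = np.nan
    cfg = JointModelConfig(input_dim=X.shape[1], latent_dim=2)
    with pytest.raises(FloatingPointError, match="epoch"):
        train(build_model(cfg, seed=9), X, y, TrainConfig(max_epochs=3, early_stop_patience=3, seed=9))
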