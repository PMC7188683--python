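"""Joint sparse autoencoder + neural classifier over a shared latent space.

The network has three parts sharing one encoder:

* encoder: input -> 50 -> 25 -> 25 -> 10 -> LV (latent space, default LV=4)
* decoder: LV -> 10 -> 25 -> 25 -> 50 -> input (exact mirror of the encoder)
* classifier: LV -> 10 -> 10 -> 10 -> 2 with a softmax output

All autoencoder layers use rectifier activations (the inputs are
non-negative pair frequencies, so a rectified reconstruction is natural);
30% inverted dropout follows each hidden encoder/decoder layer during
training.  The three parts are trained *simultaneously* on

    w_recon * MSE(X, X_hat) + w_class * CE(y, y_hat) + lambda * mean(|z|)

where z is the latent activation, so the bottleneck is shaped by both the
reconstruction and the class label, and the L1 activity penalty keeps it
sparse.  Optimization is RMSprop with early stopping on the combined
validation loss (best weights restored).

Implemented directly on numpy with hand-written backpropagation; a
finite-difference gradient check in the test suite guards the derivatives.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class JointModelConfig:
    """Architecture and regularization of the joint model."""

    input_dim: int
    latent_dim: int = 4
    encoder_hidden: Tuple[int, ...] = (50, 25, 25, 10)
    decoder_hidden: Optional[Tuple[int, ...]] = None  # defaults to mirror
    classifier_hidden: Tuple[int, ...] = (10, 10, 10)
    n_classes: int = 2
    dropout_rate: float = 0.30
    sparsity_coefficient: float = 1e-4
    use_batchnorm: bool = False
    linear_decoder_output: bool = False

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        mirror = tuple(reversed(self.encoder_hidden))
        if self.decoder_hidden is None:
            object.__setattr__(self, "decoder_hidden", mirror)
        elif tuple(self.decoder_hidden) != mirror:
            raise ValueError(
                f"decoder_hidden {self.decoder_hidden} must mirror "
                f"encoder_hidden reversed {mirror}"
            )
        if self.latent_dim >= self.encoder_hidden[-1]:
            warnings.warn(
                f"latent_dim {self.latent_dim} >= last encoder hidden size "
                f"{self.encoder_hidden[-1]}: the bottleneck no longer compresses",
                stacklevel=2,
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.sparsity_coefficient < 0:
            raise ValueError("sparsity_coefficient must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (RMSprop, early stopping on validation loss)."""

    max_epochs: int = 1000
    learning_rate: float = 1e-3
    batch_size: int = 32
    val_fraction: float = 0.10
    early_stop_patience: int = 50
    w_recon: float = 1.0
    w_class: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.w_recon < 0 or self.w_class < 0:
            raise ValueError("loss weights must be non-negative")


class _Dense:
    """One dense layer: affine -> (batchnorm) -> activation -> (dropout)."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        activation: str = "relu",
        dropout: float = 0.0,
        batchnorm: bool = False,
    ):
        # He initialization, appropriate for rectifier activations
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.dropout = dropout
        self.batchnorm = batchnorm
        if batchnorm:
            self.gamma = np.ones(n_out)
            self.beta = np.zeros(n_out)
            self.run_mean = np.zeros(n_out)
            self.run_var = np.ones(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        if batchnorm:
            self.dgamma = np.zeros_like(self.gamma)
            self.dbeta = np.zeros_like(self.beta)
        self._cache: dict = {}

    def params(self) -> List[np.ndarray]:
        p = [self.W, self.b]
        if self.batchnorm:
            p += [self.gamma, self.beta]
        return p

    def grads(self) -> List[np.ndarray]:
        g = [self.dW, self.db]
        if self.batchnorm:
            g += [self.dgamma, self.dbeta]
        return g

    def forward(
        self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]
    ) -> np.ndarray:
        z = x @ self.W + self.b
        self._cache = {"x": x}
        if self.batchnorm:
            if train:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.run_mean = _BN_MOMENTUM * self.run_mean + (1 - _BN_MOMENTUM) * mu
                self.run_var = _BN_MOMENTUM * self.run_var + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = self.run_mean, self.run_var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            self._cache.update(zhat=zhat, inv_std=inv_std, bn_train=train)
            z = self.gamma * zhat + self.beta
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
            self._cache["relu_mask"] = z > 0
        else:
            a = z
        if self.dropout > 0 and train:
            assert rng is not None
            keep = rng.random(a.shape) >= self.dropout
            scale = keep / (1.0 - self.dropout)
            a = a * scale
            self._cache["drop_scale"] = scale
        return a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c = self._cache
        if "drop_scale" in c:
            grad = grad * c["drop_scale"]
        if self.activation == "relu":
            grad = grad * c["relu_mask"]
        if self.batchnorm:
            zhat, inv_std = c["zhat"], c["inv_std"]
            self.dgamma = np.sum(grad * zhat, axis=0)
            self.dbeta = np.sum(grad, axis=0)
            gz = grad * self.gamma
            if c["bn_train"]:
                n = zhat.shape[0]
                grad = (
                    inv_std
                    / n
                    * (n * gz - gz.sum(axis=0) - zhat * np.sum(gz * zhat, axis=0))
                )
            else:
                grad = gz * inv_std
        x = c["x"]
        self.dW = x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class JointModel:
    """Untrained (or in-training) joint autoencoder + classifier."""

    def __init__(self, cfg: JointModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        dr, bn = cfg.dropout_rate, cfg.use_batchnorm

        enc_dims = [cfg.input_dim, *cfg.encoder_hidden, cfg.latent_dim]
        self.encoder: List[_Dense] = []
        for i in range(len(enc_dims) - 1):
            last = i == len(enc_dims) - 2  # latent layer: no dropout/batchnorm
            self.encoder.append(
                _Dense(
                    enc_dims[i],
                    enc_dims[i + 1],
                    rng,
                    activation="relu",
                    dropout=0.0 if last else dr,
                    batchnorm=bn and not last,
                )
            )

        dec_dims = [cfg.latent_dim, *cfg.decoder_hidden, cfg.input_dim]
        self.decoder: List[_Dense] = []
        for i in range(len(dec_dims) - 1):
            last = i == len(dec_dims) - 2
            self.decoder.append(
                _Dense(
                    dec_dims[i],
                    dec_dims[i + 1],
                    rng,
                    activation="linear" if (last and cfg.linear_decoder_output) else "relu",
                    dropout=0.0 if last else dr,
                    batchnorm=bn and not last,
                )
            )

        clf_dims = [cfg.latent_dim, *cfg.classifier_hidden, cfg.n_classes]
        self.classifier: List[_Dense] = []
        for i in range(len(clf_dims) - 1):
            last = i == len(clf_dims) - 2
            self.classifier.append(
                _Dense(
                    clf_dims[i],
                    clf_dims[i + 1],
                    rng,
                    activation="linear" if last else "relu",
                )
            )

    # -- plumbing ---------------------------------------------------------
    def layers(self) -> List[_Dense]:
        return [*self.encoder, *self.decoder, *self.classifier]

    def parameters(self) -> List[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params()]

    def get_state(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: List[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward ----------------------------------------------
    def forward(
        self, X: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (latent z, reconstruction x_hat, class probabilities)."""
        h = X
        for layer in self.encoder:
            h = layer.forward(h, train, rng)
        z = h
        d = z
        for layer in self.decoder:
            d = layer.forward(d, train, rng)
        c = z
        for layer in self.classifier:
            c = layer.forward(c, train, rng)
        return z, d, _softmax(c)

    def loss(
        self,
        X: np.ndarray,
        y_onehot: np.ndarray,
        z: np.ndarray,
        xhat: np.ndarray,
        proba: np.ndarray,
        w_recon: float,
        w_class: float,
    ) -> Dict[str, float]:
        n = X.shape[0]
        mse = float(np.mean((X - xhat) ** 2))
        ce = float(-np.sum(y_onehot * np.log(np.clip(proba, 1e-12, None))) / n)
        sparsity = float(np.mean(np.abs(z)))
        lam = self.cfg.sparsity_coefficient
        return {
            "recon_mse": mse,
            "class_ce": ce,
            "sparsity": sparsity,
            "total": w_recon * mse + w_class * ce + lam * sparsity,
        }

    def backward(
        self,
        X: np.ndarray,
        y_onehot: np.ndarray,
        z: np.ndarray,
        xhat: np.ndarray,
        proba: np.ndarray,
        w_recon: float,
        w_class: float,
    ) -> None:
        """Populate every layer's gradients for the combined loss."""
        n, d = X.shape
        g = w_recon * 2.0 * (xhat - X) / (n * d)
        for layer in reversed(self.decoder):
            g = layer.backward(g)
        gz_dec = g
        g = w_class * (proba - y_onehot) / n
        for layer in reversed(self.classifier):
            g = layer.backward(g)
        gz_clf = g
        # L1 activity penalty; z >= 0 under the rectifier so sign(z) = (z > 0)
        gz_sparse = self.cfg.sparsity_coefficient * np.sign(z) / z.size
        g = gz_dec + gz_clf + gz_sparse
        for layer in reversed(self.encoder):
            g = layer.backward(g)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def build_model(cfg: JointModelConfig, seed: int = 0) -> JointModel:
    """Construct the untrained joint model (deterministic for a given seed)."""
    return JointModel(cfg, seed=seed)


@dataclass
class TrainedModel:
    """A fitted joint model with its full provenance.

    Carries the trained parameters, the architecture/optimization configs,
    the per-epoch loss history, and the seed — enough to reproduce the fit
    exactly.
    """

    net: JointModel
    model_config: JointModelConfig
    train_config: TrainConfig
    history: Dict[str, List[float]]
    seed: int
    best_epoch: int
    n_train: int
    n_val: int

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Latent coordinates (rows x LV); deterministic, dropout disabled."""
        X = self._check(X)
        z, _, _ = self.net.forward(X, train=False)
        return z

    def reconstruct(self, X: np.ndarray) -> Tuple[np.ndarray, float]:
        """Decoded features and the dataset mean squared error."""
        X = self._check(X)
        _, xhat, _ = self.net.forward(X, train=False)
        return xhat, float(np.mean((X - xhat) ** 2))

    def predict(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Class probabilities and hard labels (1 = AFP).

        Exact probability ties resolve to the non-AFP class (label 0).
        """
        X = self._check(X)
        _, _, proba = self.net.forward(X, train=False)
        labels = (proba[:, 1] > proba[:, 0]).astype(int)
        ties = int(np.sum(proba[:, 1] == proba[:, 0]))
        if ties:
            logger.info("%d probability tie(s) resolved to the non-AFP class", ties)
        return proba, labels

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.model_config.input_dim:
            raise ValueError(
                f"expected {self.model_config.input_dim} features, got {X.shape[1]}"
            )
        return X

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "model_config": _cfg_dict(self.model_config),
            "train_config": asdict(self.train_config),
            "history": self.history,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
            "n_train": self.n_train,
            "n_val": self.n_val,
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.net.parameters())}
        bn_stats = {}
        for i, layer in enumerate(self.net.layers()):
            if layer.batchnorm:
                bn_stats[f"bn_mean{i}"] = layer.run_mean
                bn_stats[f"bn_var{i}"] = layer.run_var
        np.savez(path, meta=json.dumps(meta), **arrays, **bn_stats)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            mc = meta["model_config"]
            for key in ("encoder_hidden", "decoder_hidden", "classifier_hidden"):
                if mc[key] is not None:
                    mc[key] = tuple(mc[key])
            cfg = JointModelConfig(**mc)
            net = JointModel(cfg, seed=meta["seed"])
            net.set_state([data[f"p{i}"] for i in range(len(net.parameters()))])
            for i, layer in enumerate(net.layers()):
                if layer.batchnorm:
                    layer.run_mean = data[f"bn_mean{i}"]
                    layer.run_var = data[f"bn_var{i}"]
        return cls(
            net=net,
            model_config=cfg,
            train_config=TrainConfig(**meta["train_config"]),
            history={k: list(v) for k, v in meta["history"].items()},
            seed=meta["seed"],
            best_epoch=meta["best_epoch"],
            n_train=meta["n_train"],
            n_val=meta["n_val"],
        )


def _cfg_dict(cfg: JointModelConfig) -> dict:
    d = asdict(cfg)
    for key in ("encoder_hidden", "decoder_hidden", "classifier_hidden"):
        if d[key] is not None:
            d[key] = list(d[key])
    return d


def train(
    model: JointModel, X: np.ndarray, y: np.ndarray, tc: TrainConfig
) -> TrainedModel:
    """Fit the joint model on features X and binary labels y (1 = AFP).

    The data are split into stratified train/validation subsets
    (``val_fraction``, default 90:10), optimized with RMSprop on the combined
    loss, and early-stopped when the combined validation loss has not
    improved for ``early_stop_patience`` epochs; the best-validation
    parameters are restored.  Fully deterministic for fixed (data, configs).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class {classes}")

    idx_tr, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=tc.val_fraction,
        stratify=y,
        random_state=tc.seed % (2**32),
    )
    X_tr, y_tr = X[idx_tr], y[idx_tr]
    X_val, y_val = X[idx_val], y[idx_val]
    Y_tr = _one_hot(y_tr, model.cfg.n_classes)
    Y_val = _one_hot(y_val, model.cfg.n_classes)

    rng = np.random.default_rng(tc.seed)
    params = model.parameters()
    caches = [np.zeros_like(p) for p in params]
    rho, eps = 0.9, 1e-8

    history: Dict[str, List[float]] = {
        "train_recon_mse": [],
        "train_class_ce": [],
        "train_total": [],
        "val_total": [],
    }
    best_val = math.inf
    best_state = model.get_state()
    best_epoch = 0
    wait = 0
    n_tr = len(y_tr)

    for epoch in range(tc.max_epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, tc.batch_size):
            sel = order[start : start + tc.batch_size]
            xb, yb = X_tr[sel], Y_tr[sel]
            z, xhat, proba = model.forward(xb, train=True, rng=rng)
            model.backward(xb, yb, z, xhat, proba, tc.w_recon, tc.w_class)
            grads = [g for layer in model.layers() for g in layer.grads()]
            for p, g, c in zip(params, grads, caches):
                c *= rho
                c += (1.0 - rho) * g * g
                p -= tc.learning_rate * g / (np.sqrt(c) + eps)

        z, xhat, proba = model.forward(X_tr, train=False)
        tr_loss = model.loss(X_tr, Y_tr, z, xhat, proba, tc.w_recon, tc.w_class)
        z, xhat, proba = model.forward(X_val, train=False)
        val_loss = model.loss(X_val, Y_val, z, xhat, proba, tc.w_recon, tc.w_class)
        if not (math.isfinite(tr_loss["total"]) and math.isfinite(val_loss["total"])):
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")

        history["train_recon_mse"].append(tr_loss["recon_mse"])
        history["train_class_ce"].append(tr_loss["class_ce"])
        history["train_total"].append(tr_loss["total"])
        history["val_total"].append(val_loss["total"])

        if val_loss["total"] < best_val:
            best_val = val_loss["total"]
            best_state = model.get_state()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= tc.early_stop_patience:
                logger.info(
                    "early stop at epoch %d (best validation loss %.4g at epoch %d)",
                    epoch + 1,
                    best_val,
                    best_epoch + 1,
                )
                break

    model.set_state(best_state)
    return TrainedModel(
        net=model,
        model_config=model.cfg,
        train_config=tc,
        history=history,
        seed=tc.seed,
        best_epoch=best_epoch,
        n_train=n_tr,
        n_val=len(y_val),
    )


def mse_db(mse: float) -> float:
    """Mean squared error on the decibel scale, 10*log10(mse).

    Reconstruction errors well below 1 give the negative dB values used to
    summarize autoencoder quality (e.g. raw MSE 0.034 -> -14.69 dB).
    An exact zero maps to -inf (with a warning).
    """
    if mse < 0:
        raise ValueError(f"mse must be non-negative, got {mse}")
    if mse == 0:
        warnings.warn("MSE is exactly 0; reporting -inf dB", stacklevel=2)
        return -math.inf
    return 10.0 * math.log10(mse)


def embed(tm: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`TrainedModel.embed`."""
    return tm.embed(X)


def reconstruct(tm: TrainedModel, X: np.ndarray) -> Tuple[np.ndarray, float]:
    """Functional alias for :meth:`TrainedModel.reconstruct`."""
    return tm.reconstruct(X)


def predict(tm: TrainedModel, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`TrainedModel.predict`."""
    return tm.predict(X)
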