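"""Small 1-D convolutional classifier over the 90-dim composition features.

The 90-dim feature vector is consumed as a length-90 single-channel
signal. The default architecture is two conv stages — same-padded
convolution, activation, max-pooling — followed by a dense hidden layer
with dropout and a sigmoid output giving the positive-class probability:

    input 90 → conv(32 filters, k=7, same) → maxpool(3)   → length 30
             → conv(32 filters, k=6, same) → maxpool(2)   → length 15
             → flatten → dense(32) → dropout → sigmoid

so the final conv stage emits feature maps of length 15 per filter.
Training minimizes binary cross-entropy with Adam. The implementation is
plain numpy (float64, single process) with explicit backpropagation, so
runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import (
    ClassMeanProfile,
    N_FEATURES,
    featurize_dataset,
)
from .io import Dataset

ROLE_LNCRNA = "lncRNA"
ROLE_DNA_SITE = "dna_site"

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(np.float64)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
}


class ConfigError(ValueError):
    """Inconsistent network architecture configuration."""


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters.

    All knobs of the network are exposed here; the defaults reproduce the
    two-stage architecture whose final conv feature maps have length
    ``conv_output_length`` (15).
    """

    n_conv_layers: int = 2
    filters_per_layer: tuple[int, ...] = (32, 32)
    kernel_sizes: tuple[int, ...] = (7, 6)
    pool_sizes: tuple[int, ...] = (3, 2)
    padding: str = "same"  # or "valid"
    conv_output_length: int = 15
    activation: str = "relu"
    dense_units: int = 32
    dropout_rate: float = 0.3
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    input_dim: int = N_FEATURES

    def __post_init__(self) -> None:
        for name in ("filters_per_layer", "kernel_sizes", "pool_sizes"):
            vals = getattr(self, name)
            if len(vals) != self.n_conv_layers:
                raise ConfigError(
                    f"{name} has {len(vals)} entries for n_conv_layers={self.n_conv_layers}"
                )
        if self.activation not in _ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")
        if self.padding not in ("same", "valid"):
            raise ConfigError(f"unknown padding {self.padding!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        lengths = self.stage_lengths()
        if lengths[-1] != self.conv_output_length:
            raise ConfigError(
                f"architecture yields per-stage lengths {lengths}; final length "
                f"{lengths[-1]} != conv_output_length={self.conv_output_length}"
            )

    def stage_lengths(self) -> list[int]:
        """Feature-map length after each conv+pool stage (index 0 = input)."""
        lengths = [self.input_dim]
        L = self.input_dim
        for k, p in zip(self.kernel_sizes, self.pool_sizes):
            if self.padding == "valid":
                L = L - k + 1
            if L < 1:
                raise ConfigError(f"conv kernel {k} larger than signal length")
            L = L // p
            if L < 1:
                raise ConfigError(f"pool size {p} collapses the signal")
            lengths.append(L)
        return lengths

    @classmethod
    def from_dict(cls, d: dict) -> "CNNConfig":
        d = dict(d)
        for name in ("filters_per_layer", "kernel_sizes", "pool_sizes"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


def _same_pad(k: int) -> tuple[int, int]:
    total = k - 1
    return total // 2, total - total // 2


class ConvNet:
    """Untrained/trainable network handle; weights seeded from the config."""

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, (f, k) in enumerate(zip(cfg.filters_per_layer, cfg.kernel_sizes)):
            # He initialization, appropriate for ReLU-family stages
            scale = np.sqrt(2.0 / (c_in * k))
            self.params[f"W{i}"] = rng.normal(0.0, scale, size=(f, c_in, k))
            self.params[f"b{i}"] = np.zeros(f)
            c_in = f
        flat = cfg.filters_per_layer[-1] * cfg.stage_lengths()[-1]
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, cfg.dense_units))
        self.params["bd"] = np.zeros(cfg.dense_units)
        self.params["Wo"] = rng.normal(0.0, np.sqrt(1.0 / cfg.dense_units),
                                       size=(cfg.dense_units, 1))
        self.params["bo"] = np.zeros(1)
        self.loss_history: list[float] = []

    # ---- forward pieces -------------------------------------------------

    def _conv_forward(self, x: np.ndarray, i: int) -> tuple[np.ndarray, dict]:
        W, b = self.params[f"W{i}"], self.params[f"b{i}"]
        k = W.shape[2]
        if self.cfg.padding == "same":
            pl, pr = _same_pad(k)
            xpad = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        else:
            xpad = x
        win = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=2)  # N,C,Lout,K
        out = np.einsum("fck,nclk->nfl", W, win) + b[None, :, None]
        return out, {"win": win, "xpad_shape": xpad.shape, "k": k}

    def _conv_backward(self, dout: np.ndarray, cache: dict, i: int,
                       grads: dict) -> np.ndarray:
        W = self.params[f"W{i}"]
        win, k = cache["win"], cache["k"]
        grads[f"b{i}"] = dout.sum(axis=(0, 2))
        grads[f"W{i}"] = np.einsum("nfl,nclk->fck", dout, win)
        n, c, lpad = cache["xpad_shape"]
        dxpad = np.zeros((n, c, lpad))
        l_out = dout.shape[2]
        for j in range(k):
            dxpad[:, :, j : j + l_out] += np.einsum("nfl,fc->ncl", dout, W[:, :, j])
        if self.cfg.padding == "same":
            pl, pr = _same_pad(k)
            return dxpad[:, :, pl : lpad - pr]
        return dxpad

    @staticmethod
    def _pool_forward(x: np.ndarray, p: int) -> tuple[np.ndarray, dict]:
        n, f, L = x.shape
        L_out = L // p
        xr = x[:, :, : L_out * p].reshape(n, f, L_out, p)
        arg = xr.argmax(axis=3)
        out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
        return out, {"arg": arg, "shape": x.shape, "p": p}

    @staticmethod
    def _pool_backward(dout: np.ndarray, cache: dict) -> np.ndarray:
        n, f, L = cache["shape"]
        p = cache["p"]
        L_out = dout.shape[2]
        dxr = np.zeros((n, f, L_out, p))
        np.put_along_axis(dxr, cache["arg"][..., None], dout[..., None], axis=3)
        dx = np.zeros((n, f, L))
        dx[:, :, : L_out * p] = dxr.reshape(n, f, L_out * p)
        return dx

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[np.ndarray, dict]:
        """Probabilities for a (N, input_dim) feature matrix, plus caches."""
        act, _ = _ACTIVATIONS[self.cfg.activation]
        cache: dict = {"conv": [], "acts": []}
        h = X[:, None, :]  # N, 1, L
        for i in range(self.cfg.n_conv_layers):
            z, c_conv = self._conv_forward(h, i)
            a = act(z)
            pooled, c_pool = self._pool_forward(a, self.cfg.pool_sizes[i])
            cache["conv"].append({"z": z, "pool": c_pool, **c_conv})
            cache["acts"].append(pooled)
            h = pooled
        n = h.shape[0]
        flat = h.reshape(n, -1)
        zd = flat @ self.params["Wd"] + self.params["bd"]
        ad = act(zd)
        if training and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (rng.random(ad.shape) < keep) / keep
            ad = ad * mask
            cache["mask"] = mask
        zo = (ad @ self.params["Wo"] + self.params["bo"]).ravel()
        prob = 1.0 / (1.0 + np.exp(-zo))
        cache.update(flat=flat, zd=zd, ad=ad, h_shape=h.shape)
        return prob, cache

    def backward(self, X: np.ndarray, y: np.ndarray, prob: np.ndarray,
                 cache: dict) -> dict:
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        _, dact = _ACTIVATIONS[self.cfg.activation]
        n = X.shape[0]
        grads: dict[str, np.ndarray] = {}
        dzo = ((prob - y) / n)[:, None]  # N,1
        grads["Wo"] = cache["ad"].T @ dzo
        grads["bo"] = dzo.sum(axis=0)
        dad = dzo @ self.params["Wo"].T
        if "mask" in cache:
            dad = dad * cache["mask"]
        dzd = dad * dact(cache["zd"])
        grads["Wd"] = cache["flat"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        dh = dflat.reshape(cache["h_shape"])
        for i in reversed(range(self.cfg.n_conv_layers)):
            c = cache["conv"][i]
            da = self._pool_backward(dh, c["pool"])
            dz = da * dact(c["z"])
            dh = self._conv_backward(dz, c, i, grads)
        return grads

    def feature_maps(self, X: np.ndarray, layer: int) -> np.ndarray:
        """Post-pooling activations at a conv stage (layer 1-based); layer 0 = input."""
        if layer == 0:
            return X
        if not 1 <= layer <= self.cfg.n_conv_layers:
            raise ValueError(f"layer must be in 0..{self.cfg.n_conv_layers}")
        _, cache = self.forward(X, training=False)
        return cache["acts"][layer - 1]


def build_model(cfg: CNNConfig) -> ConvNet:
    """Instantiate an untrained network with seeded initial weights."""
    return ConvNet(cfg)


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))


def train_network(net: ConvNet, X: np.ndarray, y: np.ndarray) -> ConvNet:
    """Fit the network in place with Adam on binary cross-entropy.

    Deterministic for fixed inputs and config seed. Per-epoch training
    loss is recorded in ``net.loss_history``.
    """
    cfg = net.cfg
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[1] != cfg.input_dim:
        raise ValueError(f"X must be (n, {cfg.input_dim}); got {X.shape}")
    if not np.isfinite(X).all():
        bad = np.where(~np.isfinite(X).all(axis=1))[0]
        raise ValueError(f"non-finite features in rows {bad[:5].tolist()}")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("y must be binary 0/1")
    if classes.size < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            prob, cache = net.forward(X[idx], training=True, rng=rng)
            grads = net.backward(X[idx], y[idx], prob, cache)
            epoch_loss += _bce(prob, y[idx]) * idx.size
            t += 1
            for key, g in grads.items():
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                mhat = m[key] / (1 - b1**t)
                vhat = v[key] / (1 - b2**t)
                net.params[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        net.loss_history.append(epoch_loss / n)
    return net


@dataclass
class TrainedModel:
    """A fitted classifier bundled with everything prediction needs.

    Carries the featurization profile fitted on training data, so that
    prediction on new sequences reuses training-time class means and no
    test information ever enters the kmerscore features.
    """

    config: CNNConfig
    net: ConvNet
    profile: ClassMeanProfile
    threshold: float = 0.5
    model_role: str = ROLE_LNCRNA

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        prob, _ = self.net.forward(np.asarray(X, dtype=np.float64), training=False)
        return prob


def train(net: ConvNet, X: np.ndarray, y: np.ndarray, profile: ClassMeanProfile,
          threshold: float = 0.5, model_role: str = ROLE_LNCRNA) -> TrainedModel:
    """Train ``net`` on a feature matrix and wrap it as a :class:`TrainedModel`."""
    train_network(net, X, y)
    return TrainedModel(config=net.cfg, net=net, profile=profile,
                        threshold=threshold, model_role=model_role)


def predict_proba(model: TrainedModel, data: Dataset) -> np.ndarray:
    """Positive-class probability per record, order-aligned with ``data``."""
    X = featurize_dataset(data, model.profile)
    return model.predict_proba_matrix(X)


def classify(model: TrainedModel, data: Dataset) -> np.ndarray:
    """Hard labels: positive iff probability >= model.threshold."""
    return (predict_proba(model, data) >= model.threshold).astype(int)


_FORMAT_VERSION = 1


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist a model directory: manifest, config, profile, weights."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "manifest.json").write_text(json.dumps({
        "format_version": _FORMAT_VERSION,
        "model_role": model.model_role,
        "threshold": model.threshold,
    }))
    (d / "config.json").write_text(json.dumps(asdict(model.config)))
    model.profile.save(d / "profile.json")
    np.savez(d / "weights.npz", **model.net.params)


def load_model(directory: str | Path) -> TrainedModel:
    """Load a model directory written by :func:`save_model`."""
    d = Path(directory)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{d}: not a model directory (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"{d}: unsupported model format version {manifest.get('format_version')!r}"
        )
    cfg = CNNConfig.from_dict(json.loads((d / "config.json").read_text()))
    net = ConvNet(cfg)
    with np.load(d / "weights.npz") as npz:
        for key in net.params:
            if key not in npz:
                raise ValueError(f"{d}: weights file missing parameter {key!r}")
            net.params[key] = npz[key]
    profile = ClassMeanProfile.load(d / "profile.json")
    return TrainedModel(config=cfg, net=net, profile=profile,
                        threshold=float(manifest["threshold"]),
                        model_role=manifest["model_role"])


def export_feature_maps(
    model: TrainedModel, data: Dataset, layer: int,
    out_dir: Optional[str | Path] = None,
) -> dict[str, np.ndarray]:
    """Per-class mean activations at a network stage.

    Layer 0 returns the mean 90-dim input features per class; conv layers
    return (map_length, n_filters) matrices of the post-pooling
    activations averaged over the class, suitable for heatmap plotting.
    Optionally written as one TSV per class.
    """
    data.require_labels()
    X = featurize_dataset(data, model.profile)
    labels = np.array([r.label for r in data])
    out: dict[str, np.ndarray] = {}
    for cls in sorted(set(labels)):
        sub = X[labels == cls]
        if layer == 0:
            out[cls] = sub.mean(axis=0)
        else:
            maps = model.net.feature_maps(sub, layer)  # N, F, L
            out[cls] = maps.mean(axis=0).T  # L, F
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cls, arr in out.items():
            np.savetxt(out_dir / f"layer{layer}_{cls}.tsv",
                       np.atleast_2d(arr), delimiter="\t")
    return out
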