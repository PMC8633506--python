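"""Hourglass autoencoder and variational autoencoder.

The encoder q_phi(z|x) compresses MinMax-scaled coordinate features
through a decreasing stack of dense layers to a low-dimensional latent
space (default 2-D); the decoder p_theta(x|z) mirrors it back.  The VAE
is trained by maximising the evidence lower bound

    L(phi, theta; x) = E_q[log p_theta(x|z)] - KL(q_phi(z|x) || p(z)),

with a standard-normal prior p(z), a diagonal-Gaussian posterior
reparameterised as z = mu + sigma * eps, and a Gaussian reconstruction
likelihood (mean squared error on the scaled features).  The plain AE
minimises the reconstruction term only.

Networks are small dense stacks on desk-scale inputs, so forward and
backward passes are plain NumPy matrix algebra with Adam updates; with
a fixed seed training is bit-reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix, FeatureScaler, SplitIndex

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "LatentEmbedding",
    "build_model",
    "train",
    "encode",
    "decode",
    "gaussian_kl",
    "save_model",
    "load_model",
    "scaled_architecture",
    "REFERENCE_ARCHITECTURES",
]

#: encoder layer stacks of the five reference hourglass architectures
#: (input/output width 4980, latent dimension 2)
REFERENCE_ARCHITECTURES: dict[int, tuple[int, ...]] = {
    1: (128,),
    2: (512, 32),
    3: (1024, 128, 16),
    4: (1024, 256, 64, 16),
    5: (2048, 512, 128, 32, 8),
}

_LOGVAR_CLIP = 10.0


def _relu(x):
    return np.maximum(x, 0.0)


def _drelu(x, y):
    return (x > 0.0).astype(float)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _dsigmoid(x, y):
    return y * (1.0 - y)


def _tanh(x):
    return np.tanh(x)


def _dtanh(x, y):
    return 1.0 - y * y


def _identity(x):
    return x


def _didentity(x, y):
    return np.ones_like(x)


_ACTIVATIONS = {
    "relu": (_relu, _drelu),
    "sigmoid": (_sigmoid, _dsigmoid),
    "tanh": (_tanh, _dtanh),
    "identity": (_identity, _didentity),
}


@dataclass
class ModelSpec:
    """Architecture + training hyper-parameters.

    The decoder must mirror the encoder (hourglass symmetry); by default
    it is the reverse of ``encoder_layer_sizes``.
    """

    model_kind: str = "vae"
    input_dim: int = 4980
    encoder_layer_sizes: tuple[int, ...] = (1024, 256, 64, 16)
    latent_dim: int = 2
    decoder_layer_sizes: tuple[int, ...] | None = None
    activation: str = "relu"
    output_activation: str = "sigmoid"
    kl_weight: float = 1.0
    kl_anneal_epochs: int = 50
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.model_kind = self.model_kind.lower()
        if self.model_kind not in ("ae", "vae"):
            raise ValueError("model_kind must be 'ae' or 'vae'")
        self.encoder_layer_sizes = tuple(int(s) for s in self.encoder_layer_sizes)
        if self.decoder_layer_sizes is None:
            self.decoder_layer_sizes = tuple(reversed(self.encoder_layer_sizes))
        else:
            self.decoder_layer_sizes = tuple(int(s) for s in self.decoder_layer_sizes)
        if self.decoder_layer_sizes != tuple(reversed(self.encoder_layer_sizes)):
            raise ValueError(
                "decoder_layer_sizes must mirror encoder_layer_sizes"
            )
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if any(s <= 0 for s in self.encoder_layer_sizes):
            raise ValueError("layer sizes must be positive")
        if any(s >= self.input_dim for s in self.encoder_layer_sizes):
            raise ValueError("all hidden sizes must be smaller than input_dim")
        if any(
            a <= b
            for a, b in zip(self.encoder_layer_sizes, self.encoder_layer_sizes[1:])
        ):
            raise ValueError("encoder_layer_sizes must be strictly decreasing")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.output_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown output activation {self.output_activation!r}")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be non-negative")
        if self.kl_anneal_epochs < 0:
            raise ValueError("kl_anneal_epochs must be non-negative")

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "input_dim": self.input_dim,
            "encoder_layer_sizes": list(self.encoder_layer_sizes),
            "latent_dim": self.latent_dim,
            "decoder_layer_sizes": list(self.decoder_layer_sizes),
            "activation": self.activation,
            "output_activation": self.output_activation,
            "kl_weight": self.kl_weight,
            "kl_anneal_epochs": self.kl_anneal_epochs,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["encoder_layer_sizes"] = tuple(d["encoder_layer_sizes"])
        d["decoder_layer_sizes"] = tuple(d["decoder_layer_sizes"])
        return cls(**d)


def scaled_architecture(
    input_dim: int, n_layers: int = 4, latent_dim: int = 2
) -> tuple[int, ...]:
    """Hourglass encoder sizes for an arbitrary input width, keeping a
    constant compression factor between adjacent layers (the rule the
    reference architectures follow), ending at ``latent_dim``."""
    factor = (latent_dim / input_dim) ** (1.0 / (n_layers + 1))
    sizes = []
    prev = input_dim
    for i in range(1, n_layers + 1):
        size = int(round(input_dim * factor**i))
        size = max(latent_dim + 1, min(prev - 1, size))
        sizes.append(size)
        prev = size
    return tuple(sizes)


@dataclass
class LatentEmbedding:
    """Per-frame latent coordinates (posterior means for a VAE)."""

    points: np.ndarray
    log_variances: np.ndarray | None = None
    frame_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not np.isfinite(self.points).all():
            raise ValueError("latent points contain NaN/Inf")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.points.shape[0])

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.points.shape[1]


@dataclass
class TrainedModel:
    """Model parameters plus per-epoch loss history."""

    spec: ModelSpec
    params: dict[str, np.ndarray]
    history: dict[str, list[float]] = field(
        default_factory=lambda: {
            "total": [],
            "reconstruction": [],
            "kl": [],
            "kl_weight": [],
        }
    )
    scaler: FeatureScaler | None = None
    epochs_trained: int = 0

    @property
    def is_trained(self) -> bool:
        return self.epochs_trained > 0


def _init_layer(rng, n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
    return rng.uniform(-limit, limit, size=(n_in, n_out)), np.zeros(n_out)


def build_model(spec: ModelSpec) -> TrainedModel:
    """Initialise an untrained model with seeded Glorot-uniform weights.

    The VAE encoder carries two linear heads (posterior mean and
    log-variance); the AE a single linear latent head.
    """
    rng = np.random.default_rng(spec.seed)
    params: dict[str, np.ndarray] = {}
    sizes = (spec.input_dim,) + spec.encoder_layer_sizes
    for i, (a, b) in enumerate(zip(sizes, sizes[1:])):
        params[f"enc_W{i}"], params[f"enc_b{i}"] = _init_layer(rng, a, b)
    top = sizes[-1]
    params["mu_W"], params["mu_b"] = _init_layer(rng, top, spec.latent_dim)
    if spec.model_kind == "vae":
        params["lv_W"], params["lv_b"] = _init_layer(rng, top, spec.latent_dim)
    sizes = (spec.latent_dim,) + spec.decoder_layer_sizes
    for i, (a, b) in enumerate(zip(sizes, sizes[1:])):
        params[f"dec_W{i}"], params[f"dec_b{i}"] = _init_layer(rng, a, b)
    params["out_W"], params["out_b"] = _init_layer(
        rng, sizes[-1], spec.input_dim
    )
    return TrainedModel(spec=spec, params=params)


# ---------------------------------------------------------------------------
# Forward / backward passes
# ---------------------------------------------------------------------------


def _forward_encoder(model: TrainedModel, x: np.ndarray):
    spec = model.spec
    act, _ = _ACTIVATIONS[spec.activation]
    h = x
    cache = []
    for i in range(len(spec.encoder_layer_sizes)):
        pre = h @ model.params[f"enc_W{i}"] + model.params[f"enc_b{i}"]
        out = act(pre)
        cache.append((h, pre, out))
        h = out
    mu = h @ model.params["mu_W"] + model.params["mu_b"]
    if spec.model_kind == "vae":
        lv = h @ model.params["lv_W"] + model.params["lv_b"]
        lv = np.clip(lv, -_LOGVAR_CLIP, _LOGVAR_CLIP)
    else:
        lv = None
    return mu, lv, h, cache


def _forward_decoder(model: TrainedModel, z: np.ndarray):
    spec = model.spec
    act, _ = _ACTIVATIONS[spec.activation]
    out_act, _ = _ACTIVATIONS[spec.output_activation]
    h = z
    cache = []
    for i in range(len(spec.decoder_layer_sizes)):
        pre = h @ model.params[f"dec_W{i}"] + model.params[f"dec_b{i}"]
        out = act(pre)
        cache.append((h, pre, out))
        h = out
    pre = h @ model.params["out_W"] + model.params["out_b"]
    xhat = out_act(pre)
    return xhat, pre, h, cache


def _backprop_stack(d_out, cache, prefix, model, grads, dact):
    """Backpropagate through an activation-dense stack; returns gradient
    w.r.t. the stack input."""
    for i in reversed(range(len(cache))):
        h_in, pre, out = cache[i]
        d_pre = d_out * dact(pre, out)
        grads[f"{prefix}_W{i}"] += h_in.T @ d_pre
        grads[f"{prefix}_b{i}"] += d_pre.sum(axis=0)
        d_out = d_pre @ model.params[f"{prefix}_W{i}"].T
    return d_out


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-sample KL( N(mu, diag(exp(logvar))) || N(0, I) ), closed form:
    0.5 * sum_d (mu_d^2 + sigma_d^2 - 1 - log sigma_d^2).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    return 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)


def train(
    model: TrainedModel,
    features: FeatureMatrix | np.ndarray,
    split: SplitIndex | None = None,
) -> TrainedModel:
    """Mini-batch Adam training on the train partition.

    VAE: minimises MSE reconstruction + w * KL per the ELBO with one
    reparameterised sample per datum per step; AE: reconstruction only.
    The KL weight w ramps linearly from 0 to ``kl_weight`` over the
    first ``kl_anneal_epochs`` epochs (warm-up avoids the posterior-
    collapse attractor at initialisation; the objective is the plain
    ELBO once the ramp ends).  History records per-epoch
    reconstruction, KL, the effective KL weight, and total loss
    (total = reconstruction + weight * KL by construction).
    """
    spec = model.spec
    if isinstance(features, FeatureMatrix):
        if model.scaler is None:
            model.scaler = features.scaler
        values = features.values
    else:
        values = np.asarray(features, dtype=float)
    if values.shape[1] != spec.input_dim:
        raise ValueError(
            f"feature width {values.shape[1]} != input_dim {spec.input_dim}"
        )
    train_idx = (
        np.asarray(split.train_indices) if split is not None else np.arange(len(values))
    )
    if train_idx.size == 0:
        raise ValueError("empty training set")
    x_train = values[train_idx]

    rng = np.random.default_rng(spec.seed + 1)
    dact = _ACTIVATIONS[spec.activation][1]
    d_out_act = _ACTIVATIONS[spec.output_activation][1]

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    n = len(x_train)
    for epoch in range(spec.epochs):
        global_epoch = model.epochs_trained  # continue the ramp across calls
        if spec.model_kind == "vae" and spec.kl_anneal_epochs > 0:
            w = spec.kl_weight * min(1.0, (global_epoch + 1) / spec.kl_anneal_epochs)
        else:
            w = spec.kl_weight
        order = rng.permutation(n)
        recon_sum = 0.0
        kl_sum = 0.0
        for start in range(0, n, spec.batch_size):
            batch = x_train[order[start : start + spec.batch_size]]
            B = len(batch)
            mu, lv, h_enc, enc_cache = _forward_encoder(model, batch)
            if spec.model_kind == "vae":
                epsilon = rng.standard_normal(mu.shape)
                sigma = np.exp(0.5 * lv)
                z = mu + sigma * epsilon
                kl = float(np.sum(gaussian_kl(mu, lv))) / B
            else:
                z = mu
                kl = 0.0
            xhat, out_pre, h_dec, dec_cache = _forward_decoder(model, z)
            recon = float(np.sum((xhat - batch) ** 2)) / B
            if not np.isfinite(recon) or not np.isfinite(kl):
                raise FloatingPointError(
                    "NaN/Inf loss during training; try a smaller learning rate "
                    "or check the feature scaling"
                )
            recon_sum += recon * B
            kl_sum += kl * B

            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            d_xhat = 2.0 * (xhat - batch) / B
            d_pre = d_xhat * d_out_act(out_pre, xhat)
            grads["out_W"] += h_dec.T @ d_pre
            grads["out_b"] += d_pre.sum(axis=0)
            d_h = d_pre @ model.params["out_W"].T
            d_z = _backprop_stack(d_h, dec_cache, "dec", model, grads, dact)

            if spec.model_kind == "vae":
                d_mu = d_z + w * mu / B
                # z depends on lv through sigma; KL term adds its own gradient
                d_lv = (
                    d_z * 0.5 * sigma * epsilon
                    + w * 0.5 * (np.exp(lv) - 1.0) / B
                )
                d_lv[np.abs(lv) >= _LOGVAR_CLIP] = 0.0
                grads["mu_W"] += h_enc.T @ d_mu
                grads["mu_b"] += d_mu.sum(axis=0)
                grads["lv_W"] += h_enc.T @ d_lv
                grads["lv_b"] += d_lv.sum(axis=0)
                d_h = d_mu @ model.params["mu_W"].T + d_lv @ model.params["lv_W"].T
            else:
                grads["mu_W"] += h_enc.T @ d_z
                grads["mu_b"] += d_z.sum(axis=0)
                d_h = d_z @ model.params["mu_W"].T
            _backprop_stack(d_h, enc_cache, "enc", model, grads, dact)

            step += 1
            lr_t = spec.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in model.params:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                model.params[k] -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)

        recon_epoch = recon_sum / n
        kl_epoch = kl_sum / n
        model.history["reconstruction"].append(recon_epoch)
        model.history["kl"].append(kl_epoch)
        model.history.setdefault("kl_weight", []).append(w)
        model.history["total"].append(recon_epoch + w * kl_epoch)
        model.epochs_trained += 1
    return model


def encode(
    model: TrainedModel,
    features: FeatureMatrix | np.ndarray,
    allow_untrained: bool = False,
) -> LatentEmbedding:
    """Deterministic encoding: returns the posterior mean mu(x), one
    latent point per frame (never a sample)."""
    if not model.is_trained and not allow_untrained:
        raise ValueError("model has not been trained; call train() first")
    if isinstance(features, FeatureMatrix):
        values, frame_ids = features.values, features.frame_ids
    else:
        values = np.atleast_2d(np.asarray(features, dtype=float))
        frame_ids = None
    if values.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"feature width {values.shape[1]} != input_dim {model.spec.input_dim}"
        )
    mu, lv, _, _ = _forward_encoder(model, values)
    return LatentEmbedding(points=mu, log_variances=lv, frame_ids=frame_ids)


def decode(
    model: TrainedModel, points: np.ndarray, allow_untrained: bool = False
) -> np.ndarray:
    """Deterministic mean decode of latent points to feature space."""
    if not model.is_trained and not allow_untrained:
        raise ValueError("model has not been trained; call train() first")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != model.spec.latent_dim:
        raise ValueError(
            f"latent dimension {points.shape[1]} != {model.spec.latent_dim}"
        )
    xhat, _, _, _ = _forward_decoder(model, points)
    return xhat


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_FORMAT_TAG = "mdvae-model-v1"


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Self-describing archive: spec + history as JSON, weights as arrays."""
    path = Path(path)
    meta = {
        "format": _FORMAT_TAG,
        "spec": model.spec.to_dict(),
        "history": model.history,
        "epochs_trained": model.epochs_trained,
        "has_scaler": model.scaler is not None,
    }
    arrays = dict(model.params)
    if model.scaler is not None:
        arrays["_scaler_min"] = model.scaler.mins
        arrays["_scaler_max"] = model.scaler.maxs
    buf = io.BytesIO()
    np.savez(buf, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    path.write_bytes(buf.getvalue())
    return path


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if meta.get("format") != _FORMAT_TAG:
                raise ValueError(f"{path}: not an mdvae model archive")
            params = {
                k: data[k]
                for k in data.files
                if not k.startswith("_")
            }
            scaler = None
            if meta.get("has_scaler"):
                scaler = FeatureScaler(data["_scaler_min"], data["_scaler_max"])
    except (OSError, ValueError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        if isinstance(exc, ValueError) and "mdvae model archive" in str(exc):
            raise
        raise ValueError(f"{path}: corrupt or unreadable model archive ({exc})") from exc
    return TrainedModel(
        spec=ModelSpec.from_dict(meta["spec"]),
        params=params,
        history=meta["history"],
        scaler=scaler,
        epochs_trained=int(meta["epochs_trained"]),
    )
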