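"""Weight-sharing twin 1D-CNN similarity model.

Both pulse templates pass through the *same* convolutional encoder — three
blocks of (1-D convolution, max pooling, batch normalization, ReLU) with a
common kernel size — producing one embedding each.  The elementwise
absolute difference of the two embeddings feeds a small fully connected
head whose final sigmoid unit emits the probability that the two templates
come from the same subject.  The absolute-difference merge makes the score
exactly symmetric in its two arguments.

Implemented directly on NumPy: forward and backward passes are written out
layer by layer, keeping the model tiny, dependency-light and bit-for-bit
deterministic given a seed — a property the evaluation contract relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_P_EPS = 1e-12  # keeps sigmoid output strictly inside (0, 1)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (all free choices, none prescribed)."""

    input_length: int = 50
    channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 7
    pool_size: int = 2
    hidden_units: int = 64

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding convolutions)")
        length = self.input_length
        for _ in self.channels:
            length //= self.pool_size
            if length < 1:
                raise ValueError("input too short for this pooling depth")

    @property
    def embedding_length(self) -> int:
        length = self.input_length
        for _ in self.channels:
            length //= self.pool_size
        return length * self.channels[-1]


@dataclass(frozen=True)
class FeatureVector:
    """Embedding of one processed cycle."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite embedding")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# layer primitives (batch-first: x has shape (B, C, L) or (B, D))

def _conv1d_forward(x, w, b):
    """Same-padded stride-1 1-D convolution. w: (C_out, C_in, K)."""
    c_out, c_in, k = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.stack([xp[:, :, j:j + x.shape[2]] for j in range(k)], axis=-1)  # (B,C_in,L,K)
    y = np.einsum("bclk,dck->bdl", cols, w, optimize=True) + b[None, :, None]
    return y, (cols, w, x.shape)


def _conv1d_backward(dy, cache):
    cols, w, x_shape = cache
    dw = np.einsum("bclk,bdl->dck", cols, dy, optimize=True)
    db = dy.sum(axis=(0, 2))
    dcols = np.einsum("bdl,dck->bclk", dy, w, optimize=True)
    b_, c_in, length = x_shape
    k = w.shape[2]
    pad = k // 2
    dxp = np.zeros((b_, c_in, length + 2 * pad))
    for j in range(k):
        dxp[:, :, j:j + length] += dcols[:, :, :, j]
    return dxp[:, :, pad:pad + length], dw, db


def _maxpool_forward(x, size):
    b, c, length = x.shape
    l2 = length // size
    xr = x[:, :, :l2 * size].reshape(b, c, l2, size)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape, size)


def _maxpool_backward(dy, cache):
    idx, x_shape, size = cache
    b, c, length = x_shape
    l2 = length // size
    dxr = np.zeros((b, c, l2, size))
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dx = np.zeros(x_shape)
    dx[:, :, :l2 * size] = dxr.reshape(b, c, l2 * size)
    return dx


def _batchnorm_forward(x, gamma, beta, running_mean, running_var, training):
    if training:
        mu = x.mean(axis=(0, 2))
        var = x.var(axis=(0, 2))
        running_mean *= 1.0 - _BN_MOMENTUM
        running_mean += _BN_MOMENTUM * mu
        running_var *= 1.0 - _BN_MOMENTUM
        running_var += _BN_MOMENTUM * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu[None, :, None]) * ivar[None, :, None]
    y = gamma[None, :, None] * xhat + beta[None, :, None]
    return y, (xhat, ivar, gamma, x.shape)


def _batchnorm_backward(dy, cache):
    xhat, ivar, gamma, x_shape = cache
    m = x_shape[0] * x_shape[2]
    dgamma = (dy * xhat).sum(axis=(0, 2))
    dbeta = dy.sum(axis=(0, 2))
    dxhat = dy * gamma[None, :, None]
    dx = (ivar[None, :, None] / m) * (
        m * dxhat
        - dxhat.sum(axis=(0, 2), keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
    )
    return dx, dgamma, dbeta


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _linear_forward(x, w, b):
    return x @ w.T + b, (x, w)


def _linear_backward(dy, cache):
    x, w = cache
    return dy @ w, dy.T @ x, dy.sum(axis=0)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------

class SimilarityModel:
    """Twin encoder plus FC similarity head with one shared parameter set.

    Both branches literally reuse the same arrays, so weight sharing is a
    structural identity rather than a synchronised copy.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        self.training = False
        self._init_params(np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(2,)))))

    def _init_params(self, rng):
        cfg = self.config
        c_prev = 1
        for i, c in enumerate(cfg.channels):
            fan_in = c_prev * cfg.kernel_size
            self.params[f"conv{i}_w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                                   (c, c_prev, cfg.kernel_size))
            self.params[f"conv{i}_b"] = np.zeros(c)
            self.params[f"bn{i}_gamma"] = np.ones(c)
            self.params[f"bn{i}_beta"] = np.zeros(c)
            self.running[f"bn{i}_mean"] = np.zeros(c)
            self.running[f"bn{i}_var"] = np.ones(c)
            c_prev = c
        d = cfg.embedding_length
        self.params["fc1_w"] = rng.normal(0.0, np.sqrt(2.0 / d), (cfg.hidden_units, d))
        self.params["fc1_b"] = np.zeros(cfg.hidden_units)
        self.params["fc2_w"] = rng.normal(0.0, np.sqrt(2.0 / cfg.hidden_units),
                                          (1, cfg.hidden_units))
        self.params["fc2_b"] = np.zeros(1)

    # -- modes ---------------------------------------------------------------
    def train_mode(self):
        self.training = True
        return self

    def eval_mode(self):
        self.training = False
        return self

    # -- forward -------------------------------------------------------------
    def _as_batch(self, cycles) -> np.ndarray:
        if isinstance(cycles, np.ndarray) and cycles.dtype != object:
            arr = np.atleast_2d(np.asarray(cycles, dtype=float))
        else:
            rows = [np.asarray(getattr(c, "values", c), dtype=float) for c in cycles]
            arr = np.stack(rows)
        if arr.shape[1] != self.config.input_length:
            raise ValueError(f"cycle length {arr.shape[1]} != model input length {self.config.input_length}")
        return arr[:, None, :]  # (B, 1, L)

    def _encoder_forward(self, x):
        caches = []
        for i in range(len(self.config.channels)):
            x, c_conv = _conv1d_forward(x, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"])
            x, c_pool = _maxpool_forward(x, self.config.pool_size)
            x, c_bn = _batchnorm_forward(x, self.params[f"bn{i}_gamma"], self.params[f"bn{i}_beta"],
                                         self.running[f"bn{i}_mean"], self.running[f"bn{i}_var"],
                                         self.training)
            x, c_relu = _relu_forward(x)
            caches.append((c_conv, c_pool, c_bn, c_relu))
        b = x.shape[0]
        return x.reshape(b, -1), caches

    def _encoder_backward(self, dflat, caches, grads):
        cfg = self.config
        length = cfg.input_length
        for _ in cfg.channels:
            length //= cfg.pool_size
        dx = dflat.reshape(dflat.shape[0], cfg.channels[-1], length)
        for i in reversed(range(len(cfg.channels))):
            c_conv, c_pool, c_bn, c_relu = caches[i]
            dx = dx * c_relu
            dx, dgamma, dbeta = _batchnorm_backward(dx, c_bn)
            grads[f"bn{i}_gamma"] += dgamma
            grads[f"bn{i}_beta"] += dbeta
            dx = _maxpool_backward(dx, c_pool)
            dx, dw, db = _conv1d_backward(dx, c_conv)
            grads[f"conv{i}_w"] += dw
            grads[f"conv{i}_b"] += db
        return dx

    def embed_batch(self, cycles) -> np.ndarray:
        """Embeddings for a batch of cycles, shape (B, embedding_length)."""
        emb, _ = self._encoder_forward(self._as_batch(cycles))
        return emb

    def embed(self, cycle) -> FeatureVector:
        """Embedding of one cycle (evaluation semantics are set by the mode)."""
        return FeatureVector(self.embed_batch([cycle])[0])

    def forward_pair_batch(self, a, b, return_cache: bool = False):
        """Similarity probabilities for batches of cycle pairs."""
        xa, xb = self._as_batch(a), self._as_batch(b)
        # one encoder pass over the concatenated batch: shared batch-norm
        # statistics for both branches during training
        x = np.concatenate([xa, xb], axis=0)
        emb, enc_caches = self._encoder_forward(x)
        nb = xa.shape[0]
        u, v = emb[:nb], emb[nb:]
        diff = u - v
        d = np.abs(diff)
        h_pre, c_fc1 = _linear_forward(d, self.params["fc1_w"], self.params["fc1_b"])
        h, relu_mask = _relu_forward(h_pre)
        z, c_fc2 = _linear_forward(h, self.params["fc2_w"], self.params["fc2_b"])
        z = z[:, 0]
        p = np.clip(_sigmoid(z), _P_EPS, 1.0 - _P_EPS)
        if not return_cache:
            return p
        cache = (enc_caches, np.sign(diff), relu_mask, c_fc1, c_fc2, nb)
        return p, cache

    def backward_pair_batch(self, dz, cache) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(logit) per pair."""
        enc_caches, sign_diff, relu_mask, c_fc1, c_fc2, nb = cache
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dh, dw2, db2 = _linear_backward(dz[:, None], c_fc2)
        grads["fc2_w"] += dw2
        grads["fc2_b"] += db2
        dh = dh * relu_mask
        dd, dw1, db1 = _linear_backward(dh, c_fc1)
        grads["fc1_w"] += dw1
        grads["fc1_b"] += db1
        ddiff = dd * sign_diff
        demb = np.concatenate([ddiff, -ddiff], axis=0)
        self._encoder_backward(demb, enc_caches, grads)
        return grads

    def similarity(self, a, b) -> float:
        """Probability in (0, 1) that cycles ``a`` and ``b`` share a subject."""
        return float(self.forward_pair_batch([a], [b])[0])

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint parameters, running stats and architecture to one file."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload.update({f"running_{k}": v for k, v in self.running.items()})
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "SimilarityModel":
        with np.load(path) as data:
            cfg_raw = json.loads(bytes(data["config_json"]).decode())
            cfg_raw["channels"] = tuple(cfg_raw["channels"])
            model = cls(ModelConfig(**cfg_raw))
            for k in model.params:
                model.params[k] = data[f"param_{k}"].copy()
            for k in model.running:
                model.running[k] = data[f"running_{k}"].copy()
        return model
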