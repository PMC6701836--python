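"""A small 3D grid convolutional network, implemented in numpy.

Architecture: three units of (max-pool 2x2x2 -> 3x3x3 convolution, 32
filters, padding 1 -> ReLU) followed by one fully connected layer and a
two-way softmax; the reported score is the active-class probability.
Training is plain SGD with momentum, an inverse learning-rate decay
``lr_t = lr0 * (1 + gamma * t) ** -power``, L2 weight decay, and
class-balanced mini-batches (each batch is half actives, half decoys,
resampled with replacement), for a fixed number of iterations.

The grid edge must be divisible by 8 (three pooling halvings before the
last convolution). Everything is float32; convolutions are im2col matrix
multiplications, sized for desk-scale grids (24 voxels per edge).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigError, DimensionError, TrainingError

logger = logging.getLogger(__name__)

KERNEL = 3  # conv filter edge
PAD = 1


@dataclass(frozen=True)
class CnnHyperparams:
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_power: float = 1.0
    lr_gamma: float = 0.001
    weight_decay: float = 0.001
    batch_size: int = 10
    iterations: int = 2000
    n_filters: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "momentum", "lr_power", "lr_gamma",
                     "weight_decay"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.learning_rate == 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 2 or self.batch_size % 2:
            raise ConfigError("batch_size must be even (class-balanced halves)")
        if self.iterations < 1 or self.n_filters < 1:
            raise ConfigError("iterations and n_filters must be positive")


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, N, N, N) -> (B * N^3, C * 27) patch matrix, padding 1."""
    b, c, n = x.shape[0], x.shape[1], x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD), (PAD, PAD)))
    win = sliding_window_view(xp, (KERNEL, KERNEL, KERNEL), axis=(2, 3, 4))
    # (B, C, N, N, N, 3, 3, 3) -> (B, N, N, N, C, 3, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        b * n**3, c * KERNEL**3
    )


def _col2im(dcols: np.ndarray, b: int, c: int, n: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to the input."""
    d = dcols.reshape(b, n, n, n, c, KERNEL, KERNEL, KERNEL).transpose(
        0, 4, 1, 2, 3, 5, 6, 7
    )
    dxp = np.zeros((b, c, n + 2 * PAD, n + 2 * PAD, n + 2 * PAD), dtype=dcols.dtype)
    for i in range(KERNEL):
        for j in range(KERNEL):
            for k in range(KERNEL):
                dxp[:, :, i:i + n, j:j + n, k:k + n] += d[:, :, :, :, :, i, j, k]
    return dxp[:, :, PAD:-PAD, PAD:-PAD, PAD:-PAD]


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b, c, n = x.shape[0], x.shape[1], x.shape[2]
    m = n // 2
    xr = x.reshape(b, c, m, 2, m, 2, m, 2)
    out = xr.max(axis=(3, 5, 7))
    mask = xr == out[:, :, :, None, :, None, :, None]
    # gradients split equally among tied maxima for determinism
    mask = mask / mask.sum(axis=(3, 5, 7), keepdims=True)
    return out, mask


def _maxpool_back(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    b, c, m = dout.shape[0], dout.shape[1], dout.shape[2]
    d = mask * dout[:, :, :, None, :, None, :, None]
    return d.reshape(b, c, 2 * m, 2 * m, 2 * m)


@dataclass
class CnnModel:
    """Trained weights plus the input geometry they expect.

    ``conv_weights[i]`` has shape (C_in * 27, n_filters); ``fc_weight`` maps
    the flattened last feature map to two logits.
    """

    n_channels: int
    n_voxels: int
    conv_weights: list[np.ndarray]
    conv_biases: list[np.ndarray]
    fc_weight: np.ndarray
    fc_bias: np.ndarray
    hyper: CnnHyperparams
    loss_history: list[tuple[int, float]]

    def _forward(self, x: np.ndarray, keep_cache: bool = False):
        cache = []
        for w, b in zip(self.conv_weights, self.conv_biases):
            pooled, mask = _maxpool(x)
            n = pooled.shape[2]
            cols = _im2col(pooled)
            pre = cols @ w + b
            nf = w.shape[1]
            pre = pre.reshape(x.shape[0], n, n, n, nf).transpose(0, 4, 1, 2, 3)
            post = np.maximum(pre, 0.0)
            if keep_cache:
                cache.append((mask, cols, pre, pooled.shape))
            x = post
        flat = x.reshape(x.shape[0], -1)
        logits = flat @ self.fc_weight + self.fc_bias
        if keep_cache:
            cache.append(flat)
        return logits, cache

    def predict(self, grids, batch_size: int = 64) -> np.ndarray:
        """Active-class probability for each grid, in [0, 1]."""
        x = _as_tensor(grids)
        if x.shape[1] != self.n_channels:
            raise DimensionError(
                f"model expects {self.n_channels} channels, got {x.shape[1]}"
            )
        if x.shape[2] != self.n_voxels:
            raise DimensionError(
                f"model expects {self.n_voxels} voxels per edge, got {x.shape[2]}"
            )
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[start:start + batch_size])
            out.append(_softmax(logits)[:, 1])
        return np.concatenate(out).astype(float)

    @property
    def first_layer_weights(self) -> np.ndarray:
        """First conv weights reshaped to (C_in, 27, n_filters)."""
        w = self.conv_weights[0]
        return w.reshape(self.n_channels, KERNEL**3, w.shape[1])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_tensor(grids) -> np.ndarray:
    if isinstance(grids, np.ndarray):
        x = grids
    else:
        x = np.stack([g.values if hasattr(g, "values") else g for g in grids])
    return np.asarray(x, dtype=np.float32)


def _init_model(n_channels: int, n_voxels: int, hyper: CnnHyperparams,
                rng: np.random.Generator) -> CnnModel:
    if n_voxels % 8:
        raise DimensionError(
            f"grid edge must be divisible by 8 for three pooling stages, got {n_voxels}"
        )
    nf = hyper.n_filters
    conv_w, conv_b = [], []
    c_in, n = n_channels, n_voxels
    for _ in range(3):
        n //= 2
        fan_in = c_in * KERNEL**3
        conv_w.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 size=(fan_in, nf)).astype(np.float32))
        conv_b.append(np.zeros(nf, dtype=np.float32))
        c_in = nf
    flat = nf * n**3
    fc_w = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, 2)).astype(np.float32)
    fc_b = np.zeros(2, dtype=np.float32)
    return CnnModel(n_channels, n_voxels, conv_w, conv_b, fc_w, fc_b, hyper, [])


def train_cnn(grids, labels, hyper: CnnHyperparams | None = None) -> CnnModel:
    """Train the grid CNN on labeled voxel grids.

    ``grids``: sequence of :class:`~vsbias.featurize.VoxelGrid` (or a
    pre-stacked (n, C, N, N, N) array); ``labels``: 1 = active, 0 = decoy.
    Deterministic given the data and ``hyper.seed``.
    """
    hyper = hyper or CnnHyperparams()
    x = _as_tensor(grids)
    y = np.asarray(labels).astype(int).ravel()
    if x.shape[0] != y.size:
        raise TrainingError(f"{x.shape[0]} grids vs {y.size} labels")
    act_idx = np.flatnonzero(y == 1)
    dec_idx = np.flatnonzero(y == 0)
    if act_idx.size == 0 or dec_idx.size == 0:
        raise TrainingError("training data must contain both actives and decoys")

    rng = np.random.default_rng(hyper.seed)
    model = _init_model(x.shape[1], x.shape[2], hyper, rng)
    params = model.conv_weights + model.conv_biases + [model.fc_weight, model.fc_bias]
    velocity = [np.zeros_like(p) for p in params]
    half = hyper.batch_size // 2

    for it in range(hyper.iterations):
        batch_idx = np.concatenate([
            rng.choice(act_idx, size=half, replace=True),
            rng.choice(dec_idx, size=half, replace=True),
        ])
        xb = x[batch_idx]
        yb = y[batch_idx]

        logits, cache = model._forward(xb, keep_cache=True)
        probs = _softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(yb.size), yb] + 1e-12)))
        if it % 100 == 0 or it == hyper.iterations - 1:
            model.loss_history.append((it, loss))
            logger.debug("iteration %d: loss %.4f", it, loss)

        # backward
        dlogits = probs.copy()
        dlogits[np.arange(yb.size), yb] -= 1.0
        dlogits /= yb.size
        flat = cache[-1]
        d_fc_w = flat.T @ dlogits
        d_fc_b = dlogits.sum(axis=0)
        dflat = dlogits @ model.fc_weight.T
        nf = hyper.n_filters
        n_last = model.n_voxels // 8
        dx = dflat.reshape(xb.shape[0], nf, n_last, n_last, n_last)
        d_conv_w: list[np.ndarray] = [None] * 3  # type: ignore[list-item]
        d_conv_b: list[np.ndarray] = [None] * 3  # type: ignore[list-item]
        for layer in range(2, -1, -1):
            mask, cols, pre, pooled_shape = cache[layer]
            dpre = dx * (pre > 0)
            b_sz, f, n = dpre.shape[0], dpre.shape[1], dpre.shape[2]
            dmat = dpre.transpose(0, 2, 3, 4, 1).reshape(b_sz * n**3, f)
            d_conv_w[layer] = cols.T @ dmat
            d_conv_b[layer] = dmat.sum(axis=0)
            dcols = dmat @ model.conv_weights[layer].T
            dpooled = _col2im(dcols, b_sz, pooled_shape[1], n)
            dx = _maxpool_back(dpooled, mask)

        lr = hyper.learning_rate * (1.0 + hyper.lr_gamma * it) ** (-hyper.lr_power)
        grads = d_conv_w + d_conv_b + [d_fc_w, d_fc_b]
        for p, v, g in zip(params, velocity, grads):
            v *= hyper.momentum
            v -= lr * (g.astype(np.float32) + hyper.weight_decay * p)
            p += v
    return model


def predict_cnn(model: CnnModel, grids) -> np.ndarray:
    """Functional alias for :meth:`CnnModel.predict`."""
    return model.predict(grids)


def save_checkpoint(path, model: CnnModel, type_map_hash: str = "") -> None:
    """Single-file .npz archive: weights + hyperparameters + type-map hash."""
    arrays = {f"conv_w{i}": w for i, w in enumerate(model.conv_weights)}
    arrays.update({f"conv_b{i}": b for i, b in enumerate(model.conv_biases)})
    np.savez_compressed(
        path,
        fc_w=model.fc_weight,
        fc_b=model.fc_bias,
        meta=np.array([model.n_channels, model.n_voxels]),
        hyper=np.array(list(asdict(model.hyper).items()), dtype=object),
        type_map_hash=np.array(type_map_hash),
        **arrays,
    )


def load_checkpoint(path) -> CnnModel:
    with np.load(path, allow_pickle=True) as data:
        hyper_items = {k: v for k, v in data["hyper"]}
        hyper = CnnHyperparams(
            **{k: (int(float(v)) if k in ("batch_size", "iterations", "n_filters",
                                          "seed") else float(v))
               for k, v in hyper_items.items()}
        )
        return CnnModel(
            n_channels=int(data["meta"][0]),
            n_voxels=int(data["meta"][1]),
            conv_weights=[data[f"conv_w{i}"] for i in range(3)],
            conv_biases=[data[f"conv_b{i}"] for i in range(3)],
            fc_weight=data["fc_w"],
            fc_bias=data["fc_b"],
            hyper=hyper,
            loss_history=[],
        )
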