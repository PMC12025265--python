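"""U-Net soft-tissue predictor and bone-image recovery by subtraction.

The network maps a radiograph to its soft-tissue component; the
bone-dominant image is then ``clamp(original - predicted_soft, 0, 1)``.
Architecture: an encoder of ``depth`` blocks, each two 3×3 convolutions
with ReLU followed by 2×2 max pooling; a two-convolution bottleneck; a
mirrored decoder using nearest-neighbor upsampling + 3×3 convolution and
channel-concatenating skip connections from the encoder; and a final 1×1
convolution to a single output channel. Channel width doubles per level
from ``base_channels``.

Everything — im2col convolutions, pooling, backprop, the plain SGD update
θ ← θ − η·∇J(θ) — is implemented directly on NumPy arrays, which keeps the
update rule and the MSE loss exactly as stated and makes training
bit-reproducible from a single seed. Arrays are float32 NCHW batches.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class TrainingError(RuntimeError):
    """Raised when a loss or gradient becomes non-finite during training."""


@dataclasses.dataclass(frozen=True)
class UNetSpec:
    depth: int = 3
    base_channels: int = 16
    learning_rate: float = 0.1
    epochs: int = 40
    batch_size: int = 8
    seed: int = 0
    # residual (input-anchored) head: the network predicts the deviation
    # from the input and the soft-tissue image is input − deviation. The
    # background is then reproduced exactly wherever the head is silent,
    # which conditions the optimization far better than regenerating the
    # whole scene — the standard residual-learning trick of image
    # restoration networks.
    residual_head: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")


@dataclasses.dataclass
class TrainState:
    """Loss history of one training run: (train_mse, val_mse) per epoch."""

    epoch_losses: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# layer primitives (forward returns a cache consumed by the matching backward)


def _conv_forward(x, W, b):
    """x: (N,C,H,W); W: (F,C,kh,kw) with odd kh=kw; same-padding convolution."""
    n, c, h, w = x.shape
    f, _, kh, kw = W.shape
    pad = kh // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    col = np.ascontiguousarray(col, dtype=np.float32)
    out = col @ W.reshape(f, -1).T + b
    out = out.reshape(n, h, w, f).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), (col, x.shape, W.shape)


def _conv_backward(dout, cache):
    col, x_shape, w_shape = cache
    n, c, h, w = x_shape
    f, _, kh, kw = w_shape
    dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
    dW = (dmat.T @ col).reshape(w_shape)
    db = dmat.sum(axis=0)
    return dW, db, dmat


def _conv_input_grad(dmat, W, x_shape):
    n, c, h, w = x_shape
    f, _, kh, kw = W.shape
    pad = kh // 2
    dcol = dmat @ W.reshape(f, -1)  # (N*H*W, C*kh*kw)
    dcol = dcol.reshape(n, h, w, c, kh, kw)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += dcol[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    # tie-safe gradient routing: split gradient equally among tied maxima
    eq = xr == out[:, :, :, None, :, None]
    counts = eq.sum(axis=(3, 5), keepdims=True)
    return out, eq / counts


def _pool_backward(dout, route):
    n, c, hh, _, ww, _ = route.shape
    d = route * dout[:, :, :, None, :, None]
    return d.reshape(n, c, hh * 2, ww * 2)


def _upsample_forward(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------


class UNet:
    """Trainable U-Net over float32 NCHW batches; parameters in a flat dict."""

    def __init__(self, spec: UNetSpec):
        self.spec = spec
        self.params = self._init_params(spec)

    @staticmethod
    def layer_shapes(spec: UNetSpec) -> dict[str, tuple[int, ...]]:
        """Name → weight shape for every convolution in the architecture."""
        shapes: dict[str, tuple[int, ...]] = {}
        c_in = 1
        for lvl in range(spec.depth):
            c_out = spec.base_channels * 2**lvl
            shapes[f"enc{lvl}_conv1_W"] = (c_out, c_in, 3, 3)
            shapes[f"enc{lvl}_conv2_W"] = (c_out, c_out, 3, 3)
            c_in = c_out
        c_bot = spec.base_channels * 2**spec.depth
        shapes["bot_conv1_W"] = (c_bot, c_in, 3, 3)
        shapes["bot_conv2_W"] = (c_bot, c_bot, 3, 3)
        c_in = c_bot
        for lvl in reversed(range(spec.depth)):
            c_out = spec.base_channels * 2**lvl
            shapes[f"dec{lvl}_up_W"] = (c_out, c_in, 3, 3)
            shapes[f"dec{lvl}_conv1_W"] = (c_out, 2 * c_out, 3, 3)
            shapes[f"dec{lvl}_conv2_W"] = (c_out, c_out, 3, 3)
            c_in = c_out
        shapes["out_W"] = (1, c_in, 1, 1)
        return shapes

    @classmethod
    def _init_params(cls, spec: UNetSpec) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(spec.seed)
        params: dict[str, np.ndarray] = {}
        for name, shape in cls.layer_shapes(spec).items():
            fan_in = int(np.prod(shape[1:]))
            std = np.sqrt(2.0 / fan_in)
            params[name] = (std * rng.standard_normal(shape)).astype(np.float32)
            params[name.replace("_W", "_b")] = np.zeros(shape[0], dtype=np.float32)
        # small output head: initial predictions near zero keep the first
        # SGD steps well inside the stable region at the default rate
        params["out_W"] *= 0.1
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _check_side(self, side: int) -> None:
        if side % 2**self.spec.depth:
            raise ValueError(
                f"image side {side} not divisible by 2^depth={2**self.spec.depth}"
            )

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (N,1,H,W) float32 → (N,1,H,W) prediction (unclamped)."""
        self._check_side(x.shape[2])
        self._check_side(x.shape[3])
        p = self.params
        caches = []
        skips = []
        h = np.ascontiguousarray(x, dtype=np.float32)

        def conv_relu(h, tag):
            out, ccache = _conv_forward(h, p[f"{tag}_W"], p[f"{tag}_b"])
            out, mask = _relu_forward(out)
            caches.append((tag, ccache, mask))
            return out

        for lvl in range(self.spec.depth):
            h = conv_relu(h, f"enc{lvl}_conv1")
            h = conv_relu(h, f"enc{lvl}_conv2")
            skips.append(h)
            h, route = _pool_forward(h)
            caches.append(("pool", route, None))
        h = conv_relu(h, "bot_conv1")
        h = conv_relu(h, "bot_conv2")
        for lvl in reversed(range(self.spec.depth)):
            h = _upsample_forward(h)
            h = conv_relu(h, f"dec{lvl}_up")
            skip = skips[lvl]
            h = np.concatenate([skip, h], axis=1)
            caches.append(("concat", skip.shape[1], None))
            h = conv_relu(h, f"dec{lvl}_conv1")
            h = conv_relu(h, f"dec{lvl}_conv2")
        out, ccache = _conv_forward(h, p["out_W"], p["out_b"])
        caches.append(("out", ccache, None))
        if self.spec.residual_head:
            out = x - out
        if want_cache:
            return out, caches
        return out

    def backward(self, dout: np.ndarray, caches) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. every parameter, given d(loss)/d(output)."""
        grads: dict[str, np.ndarray] = {}
        caches = list(caches)
        p = self.params
        if self.spec.residual_head:
            dout = -dout  # d(x − head)/d(head)

        tag, ccache, _ = caches.pop()
        dW, db, dmat = _conv_backward(dout, ccache)
        grads["out_W"], grads["out_b"] = dW, db
        d = _conv_input_grad(dmat, p["out_W"], ccache[1])

        skip_grads: dict[int, np.ndarray] = {}

        def conv_relu_back(d, tag, ccache, mask):
            d = d * mask
            dW, db, dmat = _conv_backward(d, ccache)
            grads[f"{tag}_W"], grads[f"{tag}_b"] = dW, db
            return _conv_input_grad(dmat, p[f"{tag}_W"], ccache[1])

        for lvl in range(self.spec.depth):
            tag, ccache, mask = caches.pop()  # decN_conv2
            d = conv_relu_back(d, tag, ccache, mask)
            tag, ccache, mask = caches.pop()  # decN_conv1
            d = conv_relu_back(d, tag, ccache, mask)
            tag, c_skip, _ = caches.pop()  # concat
            skip_grads[lvl] = d[:, :c_skip]
            d = d[:, c_skip:]
            tag, ccache, mask = caches.pop()  # decN_up
            d = conv_relu_back(d, tag, ccache, mask)
            d = _upsample_backward(d)
        for tag_name in ("bot_conv2", "bot_conv1"):
            tag, ccache, mask = caches.pop()
            d = conv_relu_back(d, tag, ccache, mask)
        for lvl in reversed(range(self.spec.depth)):
            tag, route, _ = caches.pop()  # pool
            d = _pool_backward(d, route)
            d = d + skip_grads[lvl]
            tag, ccache, mask = caches.pop()  # encN_conv2
            d = conv_relu_back(d, tag, ccache, mask)
            tag, ccache, mask = caches.pop()  # encN_conv1
            d = conv_relu_back(d, tag, ccache, mask)
        return grads


def build_unet(spec: UNetSpec) -> UNet:
    """Construct a U-Net with deterministic seeded initialization."""
    return UNet(spec)


def mse_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean of squared element-wise differences over the whole batch."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - yhat) ** 2))


def sgd_step(
    params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float
) -> dict[str, np.ndarray]:
    """Plain gradient descent: θ ← θ − η·g for every parameter. No momentum."""
    if lr <= 0:
        raise ValueError(f"learning rate must be > 0, got {lr}")
    out = {}
    for name, p in params.items():
        g = grads[name]
        if not np.all(np.isfinite(g)):
            raise TrainingError(f"non-finite gradient in parameter {name!r}")
        out[name] = p - lr * np.asarray(g, dtype=p.dtype)
    return out


def _stack(images) -> np.ndarray:
    return np.stack([np.asarray(im, dtype=np.float32) for im in images])[:, None]


def train_unet(
    model: UNet,
    samples,
    spec: UNetSpec | None = None,
    val_fraction: float = 0.2,
    restore_best: bool = True,
    augment_pairs: bool = True,
) -> TrainState:
    """Fit the soft-tissue predictor on phantom (input, soft_label) pairs.

    The last ``val_fraction`` of ``samples`` is held out for validation (a
    fixed assignment, so runs are reproducible); mini-batch order within the
    training portion is reshuffled each epoch with a seeded generator. Loss
    is the MSE between the predicted and true soft-tissue images. With
    ``restore_best`` the parameters of the best-validation epoch are kept
    (plain fixed-rate SGD oscillates late in training, so the last epoch is
    not reliably the best one).
    """
    spec = spec or model.spec
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    n_val = max(1, int(round(val_fraction * len(samples)))) if val_fraction > 0 else 0
    if n_val >= len(samples):
        raise ValueError("val_fraction leaves no training samples")
    train, val = samples[: len(samples) - n_val], samples[len(samples) - n_val :]

    x_train = _stack([s.input_image for s in train])
    y_train = _stack([s.soft_label for s in train])
    x_val = _stack([s.input_image for s in val]) if val else None
    y_val = _stack([s.soft_label for s in val]) if val else None

    rng = np.random.default_rng(spec.seed + 1)
    history: list[tuple[float, float]] = []
    best_val = np.inf
    best_params = None
    for _epoch in range(spec.epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        for start in range(0, len(train), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if augment_pairs:
                # same lossless remap on input and label; fresh draw each
                # epoch multiplies the effective training diversity
                k = int(rng.integers(4))
                flip = bool(rng.integers(2))
                xb, yb = np.rot90(xb, k, axes=(2, 3)), np.rot90(yb, k, axes=(2, 3))
                if flip:
                    xb, yb = xb[:, :, :, ::-1], yb[:, :, :, ::-1]
                xb = np.ascontiguousarray(xb)
                yb = np.ascontiguousarray(yb)
            pred, caches = model.forward(xb, want_cache=True)
            loss = mse_loss(yb, pred)
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged: loss={loss}")
            epoch_loss += loss * len(idx)
            dout = (2.0 / pred.size) * (pred - yb).astype(np.float32)
            grads = model.backward(dout, caches)
            model.params = sgd_step(model.params, grads, spec.learning_rate)
        train_mse = epoch_loss / len(train)
        if x_val is not None:
            val_mse = mse_loss(y_val, model.forward(x_val))
            if restore_best and val_mse < best_val:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in model.params.items()}
        else:
            val_mse = float("nan")
        history.append((train_mse, val_mse))
    if best_params is not None:
        model.params = best_params
    return TrainState(epoch_losses=history)


def predict_soft_tissue(model: UNet, image: np.ndarray) -> np.ndarray:
    """Predict the soft-tissue component of one image; output clamped to [0,1]."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"expected 2-D raster, got shape {image.shape}")
    out = model.forward(image[None, None])
    return np.clip(out[0, 0].astype(np.float64), 0.0, 1.0)


def subtract_soft_tissue(original: np.ndarray, soft: np.ndarray) -> np.ndarray:
    """Bone-dominant image: clamp(original − soft, 0, 1)."""
    original = np.asarray(original, dtype=np.float64)
    soft = np.asarray(soft, dtype=np.float64)
    if original.shape != soft.shape:
        raise ValueError(f"shape mismatch: {original.shape} vs {soft.shape}")
    return np.clip(original - soft, 0.0, 1.0)


def save_checkpoint(model: UNet, path: str | Path) -> None:
    """Single-file archive: parameter tensors + the spec as JSON metadata."""
    meta = json.dumps(dataclasses.asdict(model.spec))
    np.savez(path, __spec__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__spec__"]).decode())
        model = UNet(UNetSpec(**meta))
        model.params = {k: archive[k] for k in archive.files if k != "__spec__"}
    return model


def training_curve_csv(state: TrainState, path: str | Path) -> None:
    """Write the loss history as ``epoch,train_mse,val_mse``."""
    lines = ["epoch,train_mse,val_mse"]
    for epoch, (tr, va) in enumerate(state.epoch_losses):
        lines.append(f"{epoch},{tr:.8g},{va:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")
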