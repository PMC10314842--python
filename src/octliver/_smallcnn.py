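"""A compact convolutional network implemented directly on NumPy.

The network accepts a 299x299 grayscale tile replicated onto three input
channels, exactly like the large backbone, and ends in the same head:
global average pooling over the last feature maps, one fully connected
output unit and a sigmoid.  The trunk is deliberately tiny (< 10k
parameters) so the whole pipeline trains in minutes on one CPU core:

    4x4 average pooling (fixed)             3 x 299 x 299 -> 3 x 74 x 74
    conv 3x3 /2, 8 filters, ReLU            -> 8 x 36 x 36
    conv 3x3 /2, 16 filters, ReLU           -> 16 x 17 x 17
    conv 3x3 /2, 32 filters, ReLU           -> 32 x 8 x 8
    global average pooling                  -> 32
    fully connected -> 1, sigmoid           -> probability of tumor

Convolutions run as im2col matrix products; gradients are exact
(backpropagation), and optimization uses Adam.  All floating point work is
float32 for speed; there is no batch normalization or dropout, so inference
is exactly independent of how a tile list is batched.
"""

from __future__ import annotations

import numpy as np

_POOL = 4
_LAYERS = (
    # (in_channels, out_channels, kernel, stride)
    (3, 8, 3, 2),
    (8, 16, 3, 2),
    (16, 32, 3, 2),
)


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho, Wo, C*k*k) patch matrix."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]
    b, c, ho, wo, _, _ = windows.shape
    return np.ascontiguousarray(
        windows.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho, wo, c * k * k)
    )


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, stride: int) -> np.ndarray:
    b, c, h, w = x_shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    d = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, :, :, i, j
            ]
    return dx


def _avgpool(x: np.ndarray, p: int) -> np.ndarray:
    b, c, h, w = x.shape
    hp, wp = (h // p) * p, (w // p) * p
    return x[:, :, :hp, :wp].reshape(b, c, hp // p, p, wp // p, p).mean(axis=(3, 5))


class SmallCNN:
    """Seeded small CNN with the GAP -> FC(1) -> sigmoid head."""

    input_size = 299

    def __init__(self, seed: int = 0):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for i, (cin, cout, k, _) in enumerate(_LAYERS, start=1):
            fan_in = cin * k * k
            self.params[f"W{i}"] = (
                rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(cout, dtype=np.float32)
        gap_dim = _LAYERS[-1][1]
        self.params["Wf"] = (
            rng.standard_normal((gap_dim, 1)) * np.sqrt(1.0 / gap_dim)
        ).astype(np.float32)
        self.params["bf"] = np.zeros(1, dtype=np.float32)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------------ io
    @staticmethod
    def prepare(pixels: np.ndarray) -> np.ndarray:
        """uint8 tiles (B, H, W) -> float32 (B, 3, H, W) in [0, 1].

        The single grayscale channel is replicated onto all three input
        channels.
        """
        x = np.asarray(pixels)
        if x.ndim == 2:
            x = x[None]
        x = x.astype(np.float32) / 255.0
        return np.repeat(x[:, None, :, :], 3, axis=1)

    # ------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: float32 (B, 3, H, W) -> logits (B,) [and backprop cache]."""
        cache = {"pool_in_shape": x.shape}
        h = _avgpool(x, _POOL)
        for i, (_, _, k, stride) in enumerate(_LAYERS, start=1):
            cols = _im2col(h, k, stride)
            pre = cols @ self.params[f"W{i}"] + self.params[f"b{i}"]
            post = np.maximum(pre, 0.0)
            if keep_cache:
                cache[f"cols{i}"] = cols
                cache[f"pre{i}"] = pre
                cache[f"shape{i}"] = h.shape
            h = post.transpose(0, 3, 1, 2)
        gap = h.mean(axis=(2, 3))
        logits = (gap @ self.params["Wf"] + self.params["bf"]).ravel()
        if keep_cache:
            cache["gap"] = gap
            cache["fmap_shape"] = h.shape
        return (logits, cache) if keep_cache else logits

    # ------------------------------------------------------------ backward
    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dlog = dlogits[:, None].astype(np.float32)
        grads["Wf"] = cache["gap"].T @ dlog
        grads["bf"] = dlog.sum(axis=0)
        dgap = dlog @ self.params["Wf"].T                      # (B, C)
        b, c, ho, wo = cache["fmap_shape"]
        dpost = np.broadcast_to(
            dgap[:, :, None, None] / (ho * wo), (b, c, ho, wo)
        ).astype(np.float32)
        for i in range(len(_LAYERS), 0, -1):
            pre = cache[f"pre{i}"]
            dflat = dpost.transpose(0, 2, 3, 1) * (pre > 0)
            cols = cache[f"cols{i}"]
            n = dflat.shape[0] * dflat.shape[1] * dflat.shape[2]
            grads[f"W{i}"] = cols.reshape(n, -1).T @ dflat.reshape(n, -1)
            grads[f"b{i}"] = dflat.reshape(n, -1).sum(axis=0)
            if i > 1:
                k, stride = _LAYERS[i - 1][2], _LAYERS[i - 1][3]
                dcols = dflat @ self.params[f"W{i}"].T
                dpost = _col2im(dcols, cache[f"shape{i}"], k, stride)
        return grads

    # ------------------------------------------------------------- predict
    def predict_proba(self, pixels: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Tumor probabilities for uint8 tiles (B, H, W); order preserved."""
        pixels = np.asarray(pixels)
        out = np.empty(pixels.shape[0], dtype=np.float64)
        for start in range(0, pixels.shape[0], batch_size):
            chunk = self.prepare(pixels[start : start + batch_size])
            logits = self.forward(chunk)
            out[start : start + batch_size] = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        return out

    # ----------------------------------------------------------- serialize
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def bce_loss_and_dlogits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits and its gradient.

    Uses the numerically stable form softplus(z) - y*z; the gradient w.r.t.
    the logits is (sigmoid(z) - y) / B.
    """
    z = logits.astype(np.float64)
    y = y.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / z.size).astype(np.float32)


def bce_loss_from_proba(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy -[y log p + (1-y) log(1-p)] with clipping."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))
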