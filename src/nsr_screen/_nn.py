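"""Minimal CPU neural-network core for the flushing-area segmenter.

Implements exactly what the U-Net needs — 2-D convolution (a sum of
channel matmuls over kernel offsets), ReLU, 2x2 max-pooling,
nearest-neighbour upsampling, channel concatenation,
sigmoid + (Dice + BCE) loss, and Adam — as numpy arrays with hand-derived
gradients.  Layout is NHWC, float32; all randomness flows through an
explicit ``numpy.random.Generator`` so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


# --------------------------------------------------------------------------
# primitive ops (forward returns a cache consumed by the matching backward)


def conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padding stride-1 convolution. x: (B,H,W,Cin); W: (k,k,Cin,Cout).

    Computed as a sum of channel matmuls over the k*k kernel offsets, which
    avoids materialising an im2col matrix.  Returns ``(y, cache)`` where the
    cache (the zero-padded input) feeds :func:`conv2d_backward`.
    """
    k = W.shape[0]
    B, H, Wd, Cin = x.shape
    Cout = W.shape[3]
    if k == 1:
        y = x.reshape(-1, Cin) @ W.reshape(Cin, Cout) + b
        return y.reshape(B, H, Wd, Cout), x
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    y = np.empty((B, H, Wd, Cout), dtype=np.result_type(x, W))
    y[:] = b
    for i in range(k):
        for j in range(k):
            y += np.tensordot(xp[:, i:i + H, j:j + Wd, :], W[i, j], axes=([3], [0]))
    return y, xp


def conv2d_backward(dy: np.ndarray, xp: np.ndarray, W: np.ndarray):
    """Returns (dx, dW, db).  dx computed as a same-conv with the rotated kernel."""
    k, _, Cin, Cout = W.shape
    B, H, Wd, _ = dy.shape
    dy2 = dy.reshape(-1, Cout)
    db = dy2.sum(axis=0)
    if k == 1:
        x = xp  # cache is the unpadded input for 1x1
        dW = (x.reshape(-1, Cin).T @ dy2).reshape(W.shape)
        dx = (dy2 @ W.reshape(Cin, Cout).T).reshape(B, H, Wd, Cin)
        return dx, dW, db
    dW = np.empty_like(W)
    for i in range(k):
        for j in range(k):
            dW[i, j] = np.tensordot(xp[:, i:i + H, j:j + Wd, :], dy,
                                    axes=([0, 1, 2], [0, 1, 2]))
    # gradient w.r.t. input: correlate dy with the spatially flipped kernel,
    # swapping in/out channels; zero padding matches the forward same-padding
    W_flip = np.ascontiguousarray(W[::-1, ::-1].transpose(0, 1, 3, 2))
    dx, _ = conv2d(dy, W_flip, np.zeros(Cin, dtype=W.dtype))
    return dx, dW, db


def relu(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, x > 0


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def maxpool2(x: np.ndarray):
    B, H, W, C = x.shape
    xr = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    xr = xr.reshape(B, H // 2, W // 2, 4, C)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, (B, H, W, C) = cache
    dxr = np.zeros((B, H // 2, W // 2, 4, C), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
    dx = dxr.reshape(B, H // 2, W // 2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    return dx.reshape(B, H, W, C)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    B, H, W, C = dy.shape
    return dy.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# --------------------------------------------------------------------------
# loss


def dice_bce_loss(probs: np.ndarray, z: np.ndarray, y: np.ndarray,
                  mode: str = "dice+bce", eps: float = 1.0):
    """Per-batch loss and its gradient w.r.t. the logits ``z``.

    BCE is evaluated from the logits for stability; the soft Dice term is
    computed per sample then averaged.  Returns ``(loss, dz)``.
    """
    B = y.shape[0]
    n = y.size
    loss = 0.0
    dz = np.zeros_like(z)
    if "bce" in mode:
        # softplus(z) - y*z, numerically stable
        sp = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(z)))
        loss += float((sp - y * z).sum() / n)
        dz += (probs - y) / n
    if "dice" in mode:
        p2 = probs.reshape(B, -1)
        y2 = y.reshape(B, -1)
        inter = (p2 * y2).sum(axis=1)
        denom = p2.sum(axis=1) + y2.sum(axis=1) + eps
        dice = (2 * inter + eps) / denom
        loss += float((1.0 - dice).mean())
        dp = -(2 * y2 * denom[:, None] - (2 * inter + eps)[:, None]) / denom[:, None] ** 2 / B
        dz += (dp * p2 * (1 - p2)).reshape(z.shape)
    return loss, dz


# --------------------------------------------------------------------------
# optimiser


class Adam:
    def __init__(self, params: Params, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# --------------------------------------------------------------------------
# the U-Net


class UNet:
    """Encoder-decoder segmenter with skip connections.

    ``depth`` down-sampling stages of two 3x3 conv+ReLU each, a two-conv
    bottleneck, symmetric nearest-upsampling decoder stages whose inputs
    concatenate the matching encoder feature map, and a 1x1 output conv
    producing one logit per pixel.
    """

    def __init__(self, depth: int, base_channels: int, in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        if depth < 2:
            raise ValueError("encoder depth must be >= 2")
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.base = base_channels
        self.params: Params = {}

        def add_conv(name: str, k: int, cin: int, cout: int) -> None:
            std = np.sqrt(2.0 / (k * k * cin))  # He init
            self.params[f"{name}_W"] = rng.normal(0, std, (k, k, cin, cout)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        c_in = in_channels
        for i in range(depth):
            c_out = base_channels * 2 ** i
            add_conv(f"enc{i}a", 3, c_in, c_out)
            add_conv(f"enc{i}b", 3, c_out, c_out)
            c_in = c_out
        c_mid = base_channels * 2 ** depth
        add_conv("mida", 3, c_in, c_mid)
        add_conv("midb", 3, c_mid, c_mid)
        c_up = c_mid
        for i in reversed(range(depth)):
            c_skip = base_channels * 2 ** i
            add_conv(f"dec{i}a", 3, c_up + c_skip, c_skip)
            add_conv(f"dec{i}b", 3, c_skip, c_skip)
            c_up = c_skip
        add_conv("out", 1, c_up, 1)
        # start near the foreground prior (flushing covers a few % of the
        # frame) instead of p=0.5; avoids the early all-background plateau
        self.params["out_b"][:] = -3.0

    @property
    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())

    def _conv_relu(self, name: str, x, cache):
        y, cc = conv2d(x, self.params[f"{name}_W"], self.params[f"{name}_b"])
        a, m = relu(y)
        cache.append((name, cc, m))
        return a

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B,H,W,C) float32 in [0,1] -> probabilities (B,H,W,1)."""
        if x.ndim != 4:
            raise ValueError("expected a batched NHWC array")
        h, w = x.shape[1:3]
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError(
                f"spatial dims {h}x{w} not divisible by 2^{self.depth}"
            )
        cache: list = []
        skips = []
        pools = []
        a = x.astype(np.float32)
        for i in range(self.depth):
            a = self._conv_relu(f"enc{i}a", a, cache)
            a = self._conv_relu(f"enc{i}b", a, cache)
            skips.append(a)
            a, pc = maxpool2(a)
            pools.append(pc)
        a = self._conv_relu("mida", a, cache)
        a = self._conv_relu("midb", a, cache)
        concat_splits = []
        for i in reversed(range(self.depth)):
            a = upsample2(a)
            skip = skips[i]
            concat_splits.append(skip.shape[3])
            a = np.concatenate([skip, a], axis=3)
            a = self._conv_relu(f"dec{i}a", a, cache)
            a = self._conv_relu(f"dec{i}b", a, cache)
        z, out_cc = conv2d(a, self.params["out_W"], self.params["out_b"])
        p = sigmoid(z)
        if not want_cache:
            return p
        return p, (cache, pools, concat_splits, out_cc, z)

    def backward(self, dz: np.ndarray, full_cache) -> Params:
        cache, pools, concat_splits, out_cc, _ = full_cache
        grads: Params = {}
        da, dW, db = conv2d_backward(dz, out_cc, self.params["out_W"])
        grads["out_W"], grads["out_b"] = dW, db

        def back_conv_relu(da):
            name, cc, m = cache.pop()
            dy = relu_backward(da, m)
            dx, dW, db = conv2d_backward(dy, cc, self.params[f"{name}_W"])
            grads[f"{name}_W"], grads[f"{name}_b"] = dW, db
            return dx

        # decoder stages come off the cache outermost-first (stage 0 last in
        # forward); dskips[j] is the skip gradient for encoder stage j
        dskips: list = [None] * self.depth
        for i in range(self.depth):
            da = back_conv_relu(da)
            da = back_conv_relu(da)
            c_skip = concat_splits.pop()
            dskips[i] = da[..., :c_skip]
            da = upsample2_backward(da[..., c_skip:])
        da = back_conv_relu(da)
        da = back_conv_relu(da)
        for i in reversed(range(self.depth)):
            da = maxpool2_backward(da, pools.pop())
            da = da + dskips[i]
            da = back_conv_relu(da)
            da = back_conv_relu(da)
        return grads

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> Params:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Params) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(np.float32).copy()
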