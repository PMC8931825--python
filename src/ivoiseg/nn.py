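"""Minimal CNN building blocks on NumPy: layers, Adam, and soft-Dice loss.

Forward and backward passes are expressed as im2col reshapes plus BLAS matrix
products, which is fast enough for the slice-sized inputs used here.  Arrays
are channels-last ``(N, H, W, C)``.  Everything is deterministic given the
RNG passed at construction; gradients are verified against finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient and Adam moments."""

    __slots__ = ("val", "grad", "m", "v")

    def __init__(self, val: np.ndarray):
        self.val = val
        self.grad = np.zeros_like(val)
        self.m = np.zeros_like(val)
        self.v = np.zeros_like(val)


class Conv2d:
    """k x k 'same' zero-padded convolution (cross-correlation).

    Implemented as k*k shifted (rows, cin) @ (cin, cout) matrix products
    accumulated into the output — cheaper on one CPU core than a monolithic
    im2col, whose transposed copy dominates at these channel counts.
    ``zero_init`` zeroes weights and bias (used for the output head so
    training starts from an uncommitted prediction).
    """

    def __init__(self, cin, cout, k, rng, dtype=np.float32, zero_init=False):
        self.k, self.cin, self.cout = k, cin, cout
        self.pad = (k - 1) // 2
        if zero_init:
            w = np.zeros((k, k, cin, cout))
        else:
            w = rng.standard_normal((k, k, cin, cout)) * np.sqrt(2.0 / (k * k * cin))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._xp = None

    def forward(self, x):
        n, h, w, cin = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xshape = x.shape
        self._xs = []  # cached shifted views, flattened, reused for dW
        y = np.zeros((n * h * w, self.cout), dtype=x.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                xs = np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :]).reshape(-1, cin)
                self._xs.append(xs)
                y += xs @ self.W.val[di, dj]
        return y.reshape(n, h, w, self.cout) + self.b.val

    def backward(self, dy):
        n, h, w, _ = self._xshape
        p, k = self.pad, self.k
        dy2 = dy.reshape(-1, self.cout)
        self.b.grad += dy2.sum(axis=0)
        it = iter(self._xs)
        for di in range(k):
            for dj in range(k):
                self.W.grad[di, dj] += next(it).T @ dy2
        # dx is the correlation of dy with the flipped, transposed kernel,
        # realised as gathered shifts so the accumulator stays contiguous
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0))) if p else dy
        dx = np.zeros((n * h * w, self.cin), dtype=dy.dtype)
        for s in range(k):
            for t in range(k):
                ds = np.ascontiguousarray(dyp[:, s : s + h, t : t + w, :]).reshape(-1, self.cout)
                dx += ds @ self.W.val[k - 1 - s, k - 1 - t].T
        self._xs = None
        return dx.reshape(n, h, w, self.cin)

    def params(self):
        return [self.W, self.b]

    def n_params(self):
        return self.W.val.size + self.b.val.size


class LeakyReLU:
    def __init__(self, slope=0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)

    def params(self):
        return []

    def n_params(self):
        return 0


class MaxPool2:
    """2 x 2 max pooling, stride 2."""

    def __init__(self):
        self._idx = None
        self._xshape = None

    def forward(self, x):
        n, h, w, c = x.shape
        v = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        v = v.reshape(n, h // 2, w // 2, c, 4)
        self._idx = v.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._xshape
        onehot = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(onehot, self._idx[..., None], dy[..., None], axis=-1)
        v = onehot.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return v.reshape(n, h, w, c)

    def params(self):
        return []

    def n_params(self):
        return 0


class Deconv2x2:
    """2 x 2 transposed convolution, stride 2 (doubles H and W)."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        self.cin, self.cout = cin, cout
        w = rng.standard_normal((2, 2, cin, cout)) * np.sqrt(2.0 / cin)
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._x = None

    def forward(self, x):
        n, h, w, cin = x.shape
        self._x = x
        t = x.reshape(-1, cin) @ self.W.val.transpose(2, 0, 1, 3).reshape(cin, -1)
        t = t.reshape(n, h, w, 2, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        return t.reshape(n, 2 * h, 2 * w, self.cout) + self.b.val

    def backward(self, dy):
        n, h2, w2, cout = dy.shape
        h, w = h2 // 2, w2 // 2
        t = dy.reshape(n, h, 2, w, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        t = t.reshape(-1, 4 * cout)  # rows align with x rows
        x_flat = self._x.reshape(-1, self.cin)
        dw = x_flat.T @ t  # (cin, 4*cout)
        self.W.grad += dw.reshape(self.cin, 2, 2, cout).transpose(1, 2, 0, 3)
        self.b.grad += dy.reshape(-1, cout).sum(axis=0)
        dx = t @ self.W.val.transpose(2, 0, 1, 3).reshape(self.cin, -1).T
        self._x = None
        return dx.reshape(n, h, w, self.cin)

    def params(self):
        return [self.W, self.b]

    def n_params(self):
        return self.W.val.size + self.b.val.size


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, params, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.val -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.val.dtype)


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """Soft-Dice loss, ``1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)``.

    ``pred`` holds probabilities in [0, 1].  Binary form: ``pred`` and
    ``target`` share a spatial shape.  Multi-class form: ``pred`` has a
    trailing class axis (class 0 = background), ``target`` holds integer
    codes, and the loss is the mean of the per-foreground-class losses.
    The eps smoothing makes empty prediction/target pairs lossless.
    """
    pred = np.asarray(pred, dtype=np.float64)
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    target = np.asarray(target)
    if pred.shape == target.shape:  # binary
        g = target.astype(np.float64)
        num = 2.0 * (pred * g).sum() + eps
        den = pred.sum() + g.sum() + eps
        return float(1.0 - num / den)
    if pred.shape[:-1] != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    n_classes = pred.shape[-1]
    losses = []
    for c in range(1, n_classes):
        g = (target == c).astype(np.float64)
        p = pred[..., c]
        num = 2.0 * (p * g).sum() + eps
        den = p.sum() + g.sum() + eps
        losses.append(1.0 - num / den)
    return float(np.mean(losses))


def _binary_dice_grad(p, g, eps):
    """dL/dp for one sample of the binary soft-Dice loss."""
    a = (p * g).sum()
    b = p.sum() + g.sum()
    return ((2.0 * a + eps) - 2.0 * g * (b + eps)) / (b + eps) ** 2


def dice_loss_and_grad_logits(logits: np.ndarray, target: np.ndarray, task: str, eps: float = 1.0):
    """Batch-pooled soft-Dice loss and its gradient w.r.t. the logits.

    ``task='mask'``: logits (N, H, W, 1), sigmoid head, boolean/0-1 target
    (N, H, W).  ``task='ivoi'``: logits (N, H, W, C), softmax head, integer
    target (N, H, W); the loss averages over foreground classes 1..C-1.

    The overlap sums pool over the whole batch rather than per slice: a
    per-slice loss makes slices where a class is absent push that class's
    probabilities to zero with gradient ~1/eps per pixel, which swamps the
    much weaker foreground gradients and collapses training to an
    all-background prediction.  Pooled over a shuffled batch every class is
    almost always represented, so the gradient stays balanced.
    """
    z = np.asarray(logits, dtype=np.float64)
    if task == "mask":
        p = sigmoid(z[..., 0])
        g = np.asarray(target, dtype=np.float64)
        a = (p * g).sum()
        b = p.sum() + g.sum()
        loss = 1.0 - (2.0 * a + eps) / (b + eps)
        dp = _binary_dice_grad(p, g, eps)
        dz = (dp * p * (1.0 - p))[..., None]
        return loss, dz.astype(logits.dtype)
    if task == "ivoi":
        p = softmax(z)
        n_classes = z.shape[-1]
        fg = n_classes - 1
        tgt = np.asarray(target)
        loss = 0.0
        dp = np.zeros_like(p)
        for c in range(1, n_classes):
            g = (tgt == c).astype(np.float64)
            pc = p[..., c]
            a = (pc * g).sum()
            b = pc.sum() + g.sum()
            loss += (1.0 - (2.0 * a + eps) / (b + eps)) / fg
            dp[..., c] = _binary_dice_grad(pc, g, eps) / fg
        inner = (dp * p).sum(axis=-1, keepdims=True)
        dz = p * (dp - inner)
        return loss, dz.astype(logits.dtype)
    raise ValueError(f"unknown task {task!r}")
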