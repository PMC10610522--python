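"""Minimal CPU neural-network layers with manual backpropagation.

The package deliberately ships its own small layer library rather than a deep
learning framework: the segmentation network used here is compact (~2.3 M
parameters) and the only primitives it needs are 3x3 same convolutions, 2x2
max-pooling, 2x2 stride-2 transposed convolutions, batch normalization, ReLU
and a per-pixel softmax cross-entropy.

Layout convention: activations are NHWC ``float32`` arrays (batch, row,
column, channel).  Convolutions use a shift-and-accumulate scheme: the
zero-padded activation tensor is viewed as one long (pixels, channels)
matrix, and each of the k*k kernel taps contributes a single BLAS GEMM
accumulated in place at the tap's flat offset.  Interior output pixels only
ever read true neighbours (row crossings land in the zero-padding, batch
crossings in padded border rows, both cropped afterwards), so the scheme is
exact while performing no im2col copy at all.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg.blas import dgemm, dgemv, sgemm, sgemv

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "Adam",
    "softmax_cross_entropy",
    "fan_in_uniform_init",
]


def _gemm_acc(a_t, b_t, c_t, trans_a=0, trans_b=0, alpha=1.0):
    """C += alpha * op(A) @ op(B) in place via BLAS.

    All three arguments are passed as ``.T`` views of C-contiguous arrays
    (hence Fortran-contiguous), so no hidden copies occur.
    """
    fn = sgemm if a_t.dtype == np.float32 else dgemm
    fn(alpha, a_t, b_t, beta=1.0, c=c_t, overwrite_c=1, trans_a=trans_a, trans_b=trans_b)


def _colsum(xf):
    """Per-column sum of a C-contiguous (rows, cols) matrix via BLAS gemv."""
    fn = sgemv if xf.dtype == np.float32 else dgemv
    ones = np.ones(xf.shape[0], dtype=xf.dtype)
    return fn(1.0, xf.T, ones)


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return int(self.data.size)


def fan_in_uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype):
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization.

    The default fan-in-scaled uniform scheme of mainstream frameworks; used
    for both weights and biases.
    """
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    """Base layer with reusable per-shape scratch buffers.

    Buffers are written fully on every use and each layer runs forward
    and backward exactly once per optimization step, so reuse is safe
    under the strict forward -> backward -> forward call sequence.
    """

    params: list

    def __init__(self):
        self.params = []
        self._bufs = {}

    def _buffer(self, name, shape, dtype, zero=False):
        key = (name, shape, np.dtype(dtype))
        buf = self._bufs.get(key)
        if buf is None:
            buf = self._bufs[key] = np.zeros(shape, dtype=dtype)
        elif zero:
            buf.fill(0)
        return buf

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding, with bias.

    Weight layout is (kh, kw, cin, cout): each tap ``w[ky, kx]`` is the
    (cin, cout) matrix applied at that kernel offset by one GEMM.
    """

    def __init__(self, cin, cout, k=3, rng=None, dtype=np.float32):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2
        fan_in = cin * k * k
        rng = rng or np.random.default_rng(0)
        w = fan_in_uniform_init(rng, (k, k, cin, cout), fan_in, dtype)
        b = fan_in_uniform_init(rng, (cout,), fan_in, dtype)
        self.w = Param("weight", w)
        self.b = Param("bias", b)
        self.params = [self.w, self.b]
        self._xp = None
        self._xshape = None

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k, p = self.k, self.pad
        hp, wp = h + 2 * p, w + 2 * p
        if p:
            xp = self._buffer("xp", (n, hp, wp, c), x.dtype)
            xp[:, p:-p, p:-p, :] = x
        else:
            xp = np.ascontiguousarray(x)
        xf = xp.reshape(n * hp * wp, c)
        L = xf.shape[0]
        out = self._buffer("out", (L, self.cout), x.dtype)
        out[:] = self.b.data
        for ky in range(k):
            for kx in range(k):
                o = (ky - p) * wp + (kx - p)
                lo, hi = max(0, o), min(L, L + o)
                # out[i] += x[i + o] @ w[ky, kx] for the valid flat range
                _gemm_acc(self.w.data[ky, kx].T, xf[lo:hi].T, out[lo - o : hi - o].T)
        out = out.reshape(n, hp, wp, self.cout)
        if training:
            self._xp = xf
            self._xshape = x.shape
        return out[:, p : p + h, p : p + w, :] if p else out

    def backward(self, dy):
        n, h, w, c = self._xshape
        k, p = self.k, self.pad
        hp, wp = h + 2 * p, w + 2 * p
        if p:
            dyp = self._buffer("dyp", (n, hp, wp, self.cout), dy.dtype)
            dyp[:, p:-p, p:-p, :] = dy
        else:
            dyp = np.ascontiguousarray(dy)
        df = dyp.reshape(n * hp * wp, self.cout)
        self.b.grad += _colsum(df)
        xf = self._xp
        L = xf.shape[0]
        dxf = self._buffer("dxf", xf.shape, xf.dtype, zero=True)
        gw = self.w.grad
        for ky in range(k):
            for kx in range(k):
                o = (ky - p) * wp + (kx - p)
                lo, hi = max(0, o), min(L, L + o)
                xv_t = xf[lo:hi].T          # (cin, L') F-contiguous view
                dv_t = df[lo - o : hi - o].T  # (cout, L')
                # grad w[ky,kx] += x_shift.T @ dy ; computed transposed
                _gemm_acc(dv_t, xv_t, gw[ky, kx].T, trans_b=1)
                # dx_shift += dy @ w[ky,kx].T ; computed transposed in place
                _gemm_acc(self.w.data[ky, kx].T, dv_t, dxf[lo:hi].T, trans_a=1)
        dxp = dxf.reshape(n, hp, wp, c)
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 and bias (no normalization).

    Each input pixel emits a 2x2 output patch: one GEMM from (N*H*W, Cin)
    onto (Cin, 2*2*Cout), then four strided writes place the patch corners.
    """

    def __init__(self, cin, cout, k=2, rng=None, dtype=np.float32):
        super().__init__()
        if k != 2:
            raise ValueError("only the 2x2 stride-2 case is implemented")
        self.cin, self.cout, self.k = cin, cout, k
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        # layout (kh, kw, cin, cout) flattened to (cin, 4*cout) for the GEMM
        w = fan_in_uniform_init(rng, (k, k, cin, cout), fan_in, dtype)
        b = fan_in_uniform_init(rng, (cout,), fan_in, dtype)
        self.w = Param("weight", w)
        self.b = Param("bias", b)
        self.params = [self.w, self.b]
        self._x2 = None
        self._xshape = None

    def _w2d(self):
        # (kh, kw, cin, cout) -> (cin, kh*kw*cout); transpose copy is tiny
        return np.ascontiguousarray(self.w.data.transpose(2, 0, 1, 3)).reshape(
            self.cin, 4 * self.cout
        )

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        x2 = np.ascontiguousarray(x).reshape(n * h * w, c)
        t = (x2 @ self._w2d()).reshape(n, h, w, 2, 2, self.cout)
        y = self._buffer("y", (n, 2 * h, 2 * w, self.cout), x.dtype)
        for a in range(2):
            for bb in range(2):
                y[:, a::2, bb::2, :] = t[:, :, :, a, bb, :]
        y += self.b.data
        if training:
            self._x2 = x2
            self._xshape = x.shape
        return y

    def backward(self, dy):
        n, h, w, c = self._xshape
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dt = self._buffer("dt", (n, h, w, 2, 2, self.cout), dy.dtype)
        for a in range(2):
            for bb in range(2):
                dt[:, :, :, a, bb, :] = dy[:, a::2, bb::2, :]
        dt2 = dt.reshape(n * h * w, 4 * self.cout)
        dw2 = self._x2.T @ dt2  # (cin, 4*cout)
        self.w.grad += dw2.reshape(c, 2, 2, self.cout).transpose(1, 2, 0, 3)
        dx = dt2 @ self._w2d().T
        self._x2 = None
        return dx.reshape(n, h, w, c)


class BatchNorm(Layer):
    """Per-channel batch normalization with affine parameters.

    Statistics are taken over (N, H, W) during training with running
    estimates (momentum 0.1) used at inference, the standard BatchNorm2d
    behaviour.  The normalized activations are recomputed from the cached
    input during backward instead of being stored.
    """

    def __init__(self, c, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param("gamma", np.ones(c, dtype=dtype))
        self.beta = Param("beta", np.zeros(c, dtype=dtype))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._x = None
        self._mean = None
        self._inv = None

    def forward(self, x, training=False):
        if training:
            xf = x.reshape(-1, self.c)
            nel = xf.shape[0]
            mean = _colsum(xf) / nel
            sq = np.einsum("lc,lc->c", xf, xf) / nel
            var = np.maximum(sq - mean * mean, 0.0)
            m = self.momentum
            unbiased = var * (nel / max(nel - 1, 1))
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (unbiased - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            self._x, self._mean, self._inv = x, mean, inv
            scale = self.gamma.data * inv
            shift = self.beta.data - mean * scale
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            scale = self.gamma.data * inv
            shift = self.beta.data - self.running_mean * scale
        out = self._buffer("out", x.shape, x.dtype)
        np.multiply(x, scale, out=out)
        out += shift
        return out

    def backward(self, dy):
        x, mean, inv = self._x, self._mean, self._inv
        c = self.c
        dyf = dy.reshape(-1, c)
        xf = x.reshape(-1, c)
        nel = dyf.shape[0]
        dbeta = _colsum(np.ascontiguousarray(dyf))
        # sum(dy * xhat) computed from raw x to avoid storing xhat
        dgamma = (np.einsum("lc,lc->c", dyf, xf) - mean * dbeta) * inv
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data
        # dx = g*inv * (dy - mean(dy) - xhat * mean(dy*xhat))
        c1 = g * inv
        c2 = dbeta / nel
        c3 = dgamma / nel
        xhat_coeff = -c1 * c3 * inv
        const = -c1 * c2 + c1 * c3 * inv * mean
        dx = self._buffer("dx", dy.shape, dy.dtype)
        np.multiply(x, xhat_coeff, out=dx)
        t = self._buffer("t", dy.shape, dy.dtype)
        np.multiply(dy, c1, out=t)
        dx += t
        dx += const
        self._x = self._mean = self._inv = None
        return dx


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._x = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        out = self._buffer("out", x.shape, x.dtype)
        return np.maximum(x, 0, out=out)

    def backward(self, dy):
        mask = self._buffer("mask", self._x.shape, bool)
        np.greater(self._x, 0, out=mask)
        dx = self._buffer("dx", dy.shape, dy.dtype)
        np.multiply(dy, mask, out=dx)
        self._x = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even).

    Backward routes the gradient to the argmax positions via an equality
    mask, splitting it equally among exact ties inside a window (a valid
    subgradient that also matches symmetric finite differences).
    """

    def __init__(self):
        super().__init__()
        self._x = None
        self._out = None

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if training:
            self._x = x
            self._out = out
        return out

    def backward(self, dy):
        x, out = self._x, self._out
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        mask = self._buffer("mask", xr.shape, dy.dtype)
        np.equal(xr, out[:, :, None, :, None, :], out=mask)
        ties = mask.sum(axis=(2, 4))
        db = self._buffer("db", xr.shape, dy.dtype)
        np.multiply(mask, (dy / ties)[:, :, None, :, None, :], out=db)
        self._x = self._out = None
        return db.reshape(n, h, w, c)


def softmax_cross_entropy(logits, labels):
    """Mean per-pixel multiclass cross-entropy and its gradient.

    Parameters
    ----------
    logits : (N, H, W, C) float array of raw class scores.
    labels : (N, H, W) integer array of class indices.

    Returns
    -------
    loss : float
    dlogits : same shape as ``logits``.
    """
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    z = e.sum(axis=-1, keepdims=True)
    p = e / z
    n, h, w, c = logits.shape
    idx = labels[..., None]
    logp = np.take_along_axis(logits - m - np.log(z), idx, axis=-1)[..., 0]
    loss = float(-logp.mean())
    dlogits = p
    np.put_along_axis(
        dlogits, idx, np.take_along_axis(dlogits, idx, axis=-1) - 1.0, axis=-1
    )
    dlogits /= n * h * w
    return loss, dlogits


class Adam:
    """Adaptive-moment optimizer with bias correction (beta 0.9/0.999)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
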