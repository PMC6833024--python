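"""Minimal CNN building blocks with explicit forward/backward passes.

All tensors are NHWC ``(batch, height, width, channels)`` float arrays.
Layers are single-use per forward: call ``forward`` once, then
``backward`` once, in reverse order; gradients accumulate into
``Param.grad`` so branched paths can sum contributions.

Convolutions have two interchangeable evaluation paths: JIT-compiled
direct loops (float32, the training workhorse) and a NumPy im2col
formulation that also serves as the float64 reference for
finite-difference gradient checking.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "ConvBlock",
    "BilinearUp2",
    "sigmoid",
    "Adam",
]


class Param:
    """A named trainable tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


# ---------------------------------------------------------------------------
# JIT patch gather/scatter (NHWC); the arithmetic itself runs in BLAS GEMMs
# ---------------------------------------------------------------------------


@njit(cache=True)
def _im2col_jit(x, xcol, kh, kw, stride, pt, pl):  # pragma: no cover - via Conv2d
    n, h, w, ci = x.shape
    m, ho, wo = xcol.shape[0], xcol.shape[1], xcol.shape[2]
    for nn_ in range(n):
        for io in range(ho):
            ib = io * stride - pt
            for jo in range(wo):
                jb = jo * stride - pl
                for di in range(kh):
                    ii = ib + di
                    if ii < 0 or ii >= h:
                        continue
                    for dj in range(kw):
                        jj = jb + dj
                        if jj < 0 or jj >= w:
                            continue
                        for cc in range(ci):
                            xcol[nn_, io, jo, di, dj, cc] = x[nn_, ii, jj, cc]


@njit(cache=True)
def _col2im_jit(dxcol, dx, kh, kw, stride, pt, pl):  # pragma: no cover - via Conv2d
    n, h, w, ci = dx.shape
    ho, wo = dxcol.shape[1], dxcol.shape[2]
    for nn_ in range(n):
        for io in range(ho):
            ib = io * stride - pt
            for jo in range(wo):
                jb = jo * stride - pl
                for di in range(kh):
                    ii = ib + di
                    if ii < 0 or ii >= h:
                        continue
                    for dj in range(kw):
                        jj = jb + dj
                        if jj < 0 or jj >= w:
                            continue
                        for cc in range(ci):
                            dx[nn_, ii, jj, cc] += dxcol[nn_, io, jo, di, dj, cc]


def conv2d_reference(x, w, b, stride, pad):
    """Plain-NumPy convolution used as an independent check of Conv2d.

    ``x`` is (N, H, W, Ci), ``w`` is (kh, kw, Ci, Co); same semantics as
    :class:`Conv2d` but evaluated through a sliding-window einsum.
    """
    pt, pb, pl, pr = pad
    xpad = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    v = sliding_window_view(xpad, (w.shape[0], w.shape[1]), axis=(1, 2))[:, ::stride, ::stride]
    # v: (N, Ho, Wo, Ci, kh, kw); w: (kh, kw, Ci, Co)
    return np.einsum("nijcuv,uvck->nijk", v, w, optimize=True) + b


class Conv2d:
    """2-D convolution (cross-correlation) with explicit, possibly
    asymmetric, zero padding ``(top, bottom, left, right)``.

    Even kernels (4x4) preserve spatial size with padding (1, 2, 1, 2);
    3x3 kernels use (1, 1, 1, 1); stride 2 with a 3x3 kernel halves even
    input sides exactly.  Weights live as (kh, kw, in_ch, out_ch) so the
    im2col patch matrix multiplies them without any transposition.
    """

    def __init__(self, name, in_ch, out_ch, kernel, rng, stride=1, pad=None, dtype=np.float32):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if pad is None:
            if kh % 2 == 1:
                pad = ((kh - 1) // 2, (kh - 1) // 2, (kw - 1) // 2, (kw - 1) // 2)
            else:
                pad = (kh // 2 - 1, kh // 2, kw // 2 - 1, kw // 2)
        self.stride = stride
        self.pad = pad
        self.kh, self.kw = kh, kw
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.dtype = np.dtype(dtype)
        self.w = Param(f"{name}.w", _he_init(rng, (kh, kw, in_ch, out_ch), in_ch * kh * kw, dtype))
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=dtype))
        self._is_1x1 = kh == 1 and kw == 1 and stride == 1
        self._xcol = None

    def params(self):
        return [self.w, self.b]

    def _out_hw(self, h, w):
        pt, pb, pl, pr = self.pad
        s = self.stride
        return (h + pt + pb - self.kh) // s + 1, (w + pl + pr - self.kw) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        n, h, w, _ = x.shape
        self._xshape = x.shape
        ho, wo = self._out_hw(h, w)
        if self._is_1x1:
            xcol = x.reshape(n * h * w, self.in_ch)
            self._xcol = xcol
            y = xcol @ self.w.value.reshape(-1, self.out_ch)
            y += self.b.value
            return y.reshape(n, ho, wo, self.out_ch)
        if self.stride == 1:
            return self._forward_offset(x, n, h, w)
        return self._forward_im2col(x, n, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._is_1x1:
            xcol = self._xcol
            self._xcol = None
            dy_mat = np.ascontiguousarray(dy).reshape(xcol.shape[0], self.out_ch)
            self.w.grad += (xcol.T @ dy_mat).reshape(self.w.value.shape)
            self.b.grad += dy_mat.sum(axis=0)
            return (dy_mat @ self.w.value.reshape(-1, self.out_ch).T).reshape(self._xshape)
        if self.stride == 1:
            return self._backward_offset(dy)
        return self._backward_im2col(dy)

    # -- stride-1 path: GEMMs on offset views of the padded row-flattened
    # input; zero padding absorbs all cross-row and cross-image leakage ----
    def _forward_offset(self, x, n, h, w):
        pt, pb, pl, pr = self.pad
        hp, wp = h + pt + pb, w + pl + pr
        xpad = np.zeros((n, hp, wp, self.in_ch), dtype=self.dtype)
        xpad[:, pt : pt + h, pl : pl + w] = x
        xf = xpad.reshape(n * hp * wp, self.in_ch)
        self._xf = xf
        self._padgeom = (n, h, w, hp, wp)
        m = xf.shape[0]
        yf = np.zeros((m, self.out_ch), dtype=self.dtype)
        for di in range(self.kh):
            for dj in range(self.kw):
                off = (di - pt) * wp + (dj - pl)
                if off >= 0:
                    yf[: m - off] += xf[off:] @ self.w.value[di, dj]
                else:
                    yf[-off:] += xf[:off] @ self.w.value[di, dj]
        y = yf.reshape(n, hp, wp, self.out_ch)[:, pt : pt + h, pl : pl + w]
        y = np.ascontiguousarray(y)
        y += self.b.value
        return y

    def _backward_offset(self, dy):
        xf = self._xf
        self._xf = None
        n, h, w, hp, wp = self._padgeom
        pt, pl = self.pad[0], self.pad[2]
        dypad = np.zeros((n, hp, wp, self.out_ch), dtype=self.dtype)
        dypad[:, pt : pt + h, pl : pl + w] = dy
        dyf = dypad.reshape(-1, self.out_ch)
        m = dyf.shape[0]
        dxf = np.zeros((m, self.in_ch), dtype=self.dtype)
        wv = self.w.value
        for di in range(self.kh):
            for dj in range(self.kw):
                off = (di - pt) * wp + (dj - pl)
                if off >= 0:
                    self.w.grad[di, dj] += xf[off:].T @ dyf[: m - off]
                    dxf[off:] += dyf[: m - off] @ wv[di, dj].T
                else:
                    self.w.grad[di, dj] += xf[:off].T @ dyf[-off:]
                    dxf[:off] += dyf[-off:] @ wv[di, dj].T
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dx = dxf.reshape(n, hp, wp, self.in_ch)[:, pt : pt + h, pl : pl + w]
        return np.ascontiguousarray(dx)

    # -- strided path: explicit im2col gather / col2im scatter -------------
    def _forward_im2col(self, x, n, ho, wo):
        if HAVE_NUMBA:
            xcol = np.zeros((n, ho, wo, self.kh, self.kw, self.in_ch), dtype=self.dtype)
            _im2col_jit(x, xcol, self.kh, self.kw, self.stride, self.pad[0], self.pad[2])
            xcol = xcol.reshape(n * ho * wo, -1)
        else:  # pragma: no cover - numba is installed in practice
            pt, pb, pl, pr = self.pad
            xpad = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
            v = sliding_window_view(xpad, (self.kh, self.kw), axis=(1, 2))[:, :: self.stride, :: self.stride]
            xcol = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(n * ho * wo, -1)
        self._xcol = xcol
        y = xcol @ self.w.value.reshape(-1, self.out_ch)
        y += self.b.value
        return y.reshape(n, ho, wo, self.out_ch)

    def _backward_im2col(self, dy):
        xcol = self._xcol
        self._xcol = None
        n, h, w, _ = self._xshape
        ho, wo = dy.shape[1], dy.shape[2]
        dy_mat = np.ascontiguousarray(dy).reshape(n * ho * wo, self.out_ch)
        self.w.grad += (xcol.T @ dy_mat).reshape(self.w.value.shape)
        self.b.grad += dy_mat.sum(axis=0)
        dxcol = (dy_mat @ self.w.value.reshape(-1, self.out_ch).T).reshape(n, ho, wo, self.kh, self.kw, self.in_ch)
        dx = np.zeros(self._xshape, dtype=self.dtype)
        if HAVE_NUMBA:
            _col2im_jit(dxcol, dx, self.kh, self.kw, self.stride, self.pad[0], self.pad[2])
        else:  # pragma: no cover
            pt, pl = self.pad[0], self.pad[2]
            for di in range(self.kh):
                for dj in range(self.kw):
                    ii = np.arange(ho) * self.stride - pt + di
                    jj = np.arange(wo) * self.stride - pl + dj
                    iv = (ii >= 0) & (ii < h)
                    jv = (jj >= 0) & (jj < w)
                    dx[:, ii[iv][:, None], jj[jv][None, :], :] += dxcol[:, iv][:, :, jv, di, dj, :]
        return dx


class BatchNorm2d:
    """Per-channel batch normalisation over (N, H, W) with running stats."""

    def __init__(self, name, ch, dtype=np.float32, momentum=0.1, eps=1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            shape = x.shape
            x2 = x.reshape(-1, shape[-1])
            m = x2.shape[0]
            mean = x2.mean(axis=0)
            var = np.einsum("mc,mc->c", x2, x2) / m - mean * mean
            np.maximum(var, 0.0, out=var)  # guard tiny negative from cancellation
            mom = self.momentum
            self.running_mean += (mom * (mean - self.running_mean)).astype(self.running_mean.dtype)
            self.running_var += (mom * (var - self.running_var)).astype(self.running_var.dtype)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x2 - mean) * inv_std
            self._cache = (xhat, inv_std, shape)
            out = xhat * self.gamma.value
            out += self.beta.value
            return out.reshape(shape)
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * (self.gamma.value * inv_std) + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        self._cache = None
        dy2 = dy.reshape(-1, shape[-1])
        m = dy2.shape[0]
        dgamma = np.einsum("mc,mc->c", dy2, xhat)
        dbeta = dy2.sum(axis=0)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        dx = dy2 - dbeta / m
        dx -= xhat * (dgamma / m)
        dx *= self.gamma.value * inv_std
        return dx.reshape(shape)


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return dy * mask


class ConvBlock:
    """Conv -> ReLU -> BatchNorm, the repeated unit of the network."""

    def __init__(self, name, in_ch, out_ch, kernel, rng, stride=1, dtype=np.float32):
        self.conv = Conv2d(name + ".conv", in_ch, out_ch, kernel, rng, stride=stride, dtype=dtype)
        self.relu = ReLU()
        self.bn = BatchNorm2d(name + ".bn", out_ch, dtype=dtype)

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train):
        return self.bn.forward(self.relu.forward(self.conv.forward(x)), train)

    def backward(self, dy):
        return self.conv.backward(self.relu.backward(self.bn.backward(dy)))


def _up2_matrix(n: int, dtype) -> np.ndarray:
    """Dense (2n, n) linear-interpolation operator, half-pixel centres."""
    a = np.zeros((2 * n, n), dtype=dtype)
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        a[i, lo_c] += 1.0 - frac
        a[i, hi_c] += frac
    return a


class BilinearUp2:
    """Factor-2 bilinear up-sampling as separable matrix products."""

    _cache: dict = {}

    def __init__(self, dtype=np.float32):
        self.dtype = dtype

    def _mat(self, n):
        key = (n, np.dtype(self.dtype).name)
        if key not in BilinearUp2._cache:
            BilinearUp2._cache[key] = _up2_matrix(n, self.dtype)
        return BilinearUp2._cache[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ar = self._mat(x.shape[1])
        ac = self._mat(x.shape[2])
        self._mats = (ar, ac)
        # rows then cols, keeping NHWC order
        y = np.moveaxis(np.tensordot(ar, x, axes=([1], [1])), 0, 1)
        return np.moveaxis(np.tensordot(ac, y, axes=([1], [2])), 0, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ar, ac = self._mats
        self._mats = None
        dx = np.moveaxis(np.tensordot(ac.T, dy, axes=([1], [2])), 0, 2)
        return np.moveaxis(np.tensordot(ar.T, dx, axes=([1], [1])), 0, 1)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.value -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
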