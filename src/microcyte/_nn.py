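"""Compact numpy neural-network engine used by the segmentation models.

Implements exactly the pieces the cell-analytics networks need: stride-1
"same" 2-D convolutions, 2x2 max pooling, 2x2 nearest upsampling, 2x2
transposed convolutions, channel concatenation, dropout, Adam, and the
U-Net assembly. Tensors are float32 NCHW throughout.

Determinism contract: every source of randomness (weight init, dropout,
batch shuffling) flows from numpy Generators seeded by the caller, and all
ops are plain numpy, so identical seeds give bit-identical training runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _pad2d(x: np.ndarray, pb: int, pa: int) -> np.ndarray:
    if pb == 0 and pa == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa)))


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N*H*W, C*k*k) for stride-1 windows."""
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    n, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k), (n, h, w)


def conv2d(x: np.ndarray, w: np.ndarray, pb: int, pa: int) -> np.ndarray:
    """Stride-1 cross-correlation of x (N,C,H,W) with w (F,C,k,k)."""
    k = w.shape[-1]
    cols, (n, h, ww) = _im2col(_pad2d(x, pb, pa), k)
    out = cols @ w.reshape(w.shape[0], -1).T
    return np.ascontiguousarray(out.reshape(n, h, ww, -1).transpose(0, 3, 1, 2))


class Layer:
    def weights(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, d):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k stride-1 'same' convolution, He-normal init, optional ReLU."""

    def __init__(self, cin, cout, k, rng, act="relu"):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = (rng.standard_normal((cout, cin, k, k)) * std).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.k = k
        # 'same' padding: symmetric for odd k, (0, k-1) split for even k
        self.pb = (k - 1) // 2
        self.pa = k - 1 - self.pb
        self.act = act
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def weights(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=False):
        self._x = x
        z = conv2d(x, self.w, self.pb, self.pa) + self.b[None, :, None, None]
        if self.act == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0)
        return z

    def backward(self, d):
        if self.act == "relu":
            d = np.where(self._mask, d, 0)
        self.gb[:] = d.sum(axis=(0, 2, 3))
        cols, (n, h, w) = _im2col(_pad2d(self._x, self.pb, self.pa), self.k)
        dflat = d.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.gw[:] = (dflat.T @ cols).reshape(self.w.shape)
        wflip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return conv2d(d, np.ascontiguousarray(wflip), self.k - 1 - self.pb, self.k - 1 - self.pa)


class MaxPool2(Layer):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, d):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=d.dtype)
        np.put_along_axis(out, self._idx[..., None], d[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Upsample2(Layer):
    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, d):
        n, c, h, w = d.shape
        return d.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvTranspose2(Layer):
    """2x2 transposed convolution; stride 2 doubles H,W, stride 1 keeps them."""

    def __init__(self, cin, cout, rng, stride=2, act="relu"):
        std = np.sqrt(2.0 / (cin * 4))
        self.stride = stride
        self.act = act
        if stride == 2:
            self.w = (rng.standard_normal((cin, cout, 2, 2)) * std).astype(F32)
            self.b = np.zeros(cout, dtype=F32)
            self.gw = np.zeros_like(self.w)
            self.gb = np.zeros_like(self.b)
        else:
            # a stride-1 transposed conv is a plain conv with flipped taps;
            # implement directly as a 2x2 'same' conv
            self._conv = Conv2d(cin, cout, 2, rng, act=act)

    def weights(self):
        if self.stride == 1:
            return self._conv.weights()
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=False):
        if self.stride == 1:
            return self._conv.forward(x, train)
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,cfij->nfhiwj", x, self.w, optimize=True)
        y = y.reshape(n, -1, 2 * h, 2 * w) + self.b[None, :, None, None]
        if self.act == "relu":
            self._mask = y > 0
            return np.where(self._mask, y, 0)
        return y

    def backward(self, d):
        if self.stride == 1:
            return self._conv.backward(d)
        if self.act == "relu":
            d = np.where(self._mask, d, 0)
        n, f = d.shape[0], d.shape[1]
        h, w = self._x.shape[2], self._x.shape[3]
        self.gb[:] = d.sum(axis=(0, 2, 3))
        dr = d.reshape(n, f, h, 2, w, 2)
        self.gw[:] = np.einsum("nchw,nfhiwj->cfij", self._x, dr, optimize=True)
        return np.einsum("nfhiwj,cfij->nchw", dr, self.w, optimize=True)


class Dropout(Layer):
    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, d):
        if self._mask is None:
            return d
        return d * self._mask


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Stable binary cross-entropy; returns (mean loss, dloss/dz)."""
    zl = z.astype(np.float64)
    loss = np.mean(np.maximum(zl, 0) - zl * y + np.log1p(np.exp(-np.abs(zl))))
    grad = ((sigmoid(zl) - y) / z.size).astype(F32)
    return float(loss), grad


class Adam:
    def __init__(self, layers, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = []
        for lay in layers:
            for w, g in lay.weights():
                self.slots.append((w, g, np.zeros_like(w), np.zeros_like(w)))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for w, g, m, v in self.slots:
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class UNet:
    """Encoder-decoder with skip connections.

    Encoder: per block two 3x3 ReLU convs then 2x2 max pool; dropout after
    the last block. Bottleneck: two 3x3 convs + dropout. Decoder: 2x2
    upsampling, a 2x2 conv, concatenation with the matching encoder feature
    map, then two 3x3 convs. Head: a 3x3 conv with two filters (ReLU)
    followed by a 1x1 conv emitting `out_ch` raw logits/regression maps.
    """

    def __init__(self, in_ch, enc_filters, bottleneck_filters, dec_filters,
                 out_ch, dropout=0.5, seed=0, head_filters=2):
        """`head_filters` sets the width of the penultimate 3x3 ReLU conv;
        None drops that stage so the 1x1 output conv reads the last decoder
        features directly (needed when several signed maps share the head).
        """
        if len(enc_filters) != len(dec_filters):
            raise ValueError("encoder and decoder must have equal depth")
        rng = np.random.default_rng(seed)
        self.depth = len(enc_filters)
        self.enc = []
        prev = in_ch
        for f in enc_filters:
            self.enc.append((Conv2d(prev, f, 3, rng), Conv2d(f, f, 3, rng)))
            prev = f
        self.pools = [MaxPool2() for _ in enc_filters]
        self.drop_enc = Dropout(dropout, rng)
        self.bn1 = Conv2d(prev, bottleneck_filters, 3, rng)
        self.bn2 = Conv2d(bottleneck_filters, bottleneck_filters, 3, rng)
        self.drop_bn = Dropout(dropout, rng)
        self.dec = []
        prev = bottleneck_filters
        for i, f in enumerate(dec_filters):
            skip_f = enc_filters[-(i + 1)]
            self.dec.append((
                Upsample2(),
                Conv2d(prev, f, 2, rng),
                Conv2d(f + skip_f, f, 3, rng),
                Conv2d(f, f, 3, rng),
            ))
            prev = f
        self.head3 = Conv2d(prev, head_filters, 3, rng) if head_filters else None
        self.head1 = Conv2d(head_filters or prev, out_ch, 1, rng, act="linear")
        self.enc_filters = list(enc_filters)
        self.dec_filters = list(dec_filters)
        self.bottleneck_filters = bottleneck_filters
        self.out_ch = out_ch
        self.style_dim = bottleneck_filters

    # -- plumbing -------------------------------------------------------
    def layers(self):
        out = []
        for c1, c2 in self.enc:
            out += [c1, c2]
        out += [self.bn1, self.bn2]
        for up, cu, c1, c2 in self.dec:
            out += [cu, c1, c2]
        if self.head3 is not None:
            out.append(self.head3)
        out.append(self.head1)
        return out

    @property
    def n_params(self):
        return int(sum(w.size for lay in self.layers() for w, _ in lay.weights()))

    def get_weights(self):
        return [w.copy() for lay in self.layers() for w, _ in lay.weights()]

    def set_weights(self, ws):
        slots = [w for lay in self.layers() for w, _ in lay.weights()]
        for dst, src in zip(slots, ws):
            dst[:] = src

    # -- forward/backward ----------------------------------------------
    def forward(self, x, train=False):
        if x.shape[2] % (2 ** self.depth) or x.shape[3] % (2 ** self.depth):
            raise ValueError(
                f"input H,W must be divisible by {2 ** self.depth}, got {x.shape[2:]}"
            )
        h = x.astype(F32)
        self._skips = []
        for i, (c1, c2) in enumerate(self.enc):
            h = c2.forward(c1.forward(h, train), train)
            self._skips.append(h)
            h = self.pools[i].forward(h)
        h = self.drop_enc.forward(h, train)
        h = self.bn2.forward(self.bn1.forward(h, train), train)
        h = self.drop_bn.forward(h, train)
        self.bottleneck_act = h
        for i, (up, cu, c1, c2) in enumerate(self.dec):
            h = cu.forward(up.forward(h), train)
            s = self._skips[-(i + 1)]
            h = np.concatenate([s, h], axis=1)
            h = c2.forward(c1.forward(h, train), train)
        if self.head3 is not None:
            h = self.head3.forward(h, train)
        return self.head1.forward(h, train)

    def backward(self, d):
        d = self.head1.backward(d)
        if self.head3 is not None:
            d = self.head3.backward(d)
        dskips = [None] * self.depth
        for i in reversed(range(self.depth)):
            up, cu, c1, c2 = self.dec[i]
            d = c1.backward(self.dec[i][3].backward(d))
            skip_f = self.enc_filters[-(i + 1)]
            dskips[self.depth - 1 - i] = d[:, :skip_f]
            d = up.backward(cu.backward(d[:, skip_f:]))
        d = self.drop_bn.backward(d)
        d = self.bn1.backward(self.bn2.backward(d))
        d = self.drop_enc.backward(d)
        for i in reversed(range(self.depth)):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            c1, c2 = self.enc[i]
            d = c1.backward(c2.backward(d))
        return d

    def style(self):
        """L2-normalised global average pool of the bottleneck activation."""
        s = self.bottleneck_act.mean(axis=(2, 3)).astype(np.float64)
        nrm = np.linalg.norm(s, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return s / nrm


def pad_to_multiple(img2d, mult):
    """Reflect-pad a 2-D (or CHW) array so H and W are multiples of `mult`."""
    h, w = img2d.shape[-2], img2d.shape[-1]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph == 0 and pw == 0:
        return img2d, (h, w)
    pad = [(0, 0)] * (img2d.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(img2d, pad, mode="reflect"), (h, w)
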