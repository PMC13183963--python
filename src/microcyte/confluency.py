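"""Confluency measurement: U-Net cell/background segmentation of adherent
cultures and conversion of binary masks to percent surface coverage.

The full-scale network takes a 1024x1024x1 image through four encoder
blocks of paired 3x3 convolutions (64/128/256/512 filters, each followed by
2x2 max pooling, 0.5 dropout after the fourth), a 1024-filter bottleneck
with dropout, a mirrored decoder with skip concatenations (2x2 upsampling +
2x2 conv, 512 -> 256 -> 128 -> 64), and a head of one 3x3 convolution with
two filters (ReLU) plus a 1x1 sigmoid convolution. A `base_scale`
multiplier shrinks every filter count (rounded up) for desk-scale training;
the topology is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from . import _nn
from .imagesim import LUMA, apply_defocus

__all__ = [
    "UNetSpec", "ConfluencyResult", "PixelMetrics", "ConfluencyModel",
    "build_confluency_net", "train_confluency", "predict_mask",
    "pixel_metrics", "confluency_percent",
]


@dataclass
class UNetSpec:
    input_size: tuple = (1024, 1024, 1)
    encoder_filters: Sequence[int] = (64, 128, 256, 512)
    bottleneck_filters: int = 1024
    dropout_rate: float = 0.5
    decoder_filters: Sequence[int] = (512, 256, 128, 64)
    final_activation: str = "sigmoid"
    learning_rate: float = 1e-4
    loss: str = "binary_cross_entropy"
    base_scale: float = 1.0

    def __post_init__(self):
        if len(self.encoder_filters) != len(self.decoder_filters):
            raise ValueError("encoder/decoder depth mismatch")
        div = 2 ** len(self.encoder_filters)
        h, w = self.input_size[0], self.input_size[1]
        if h % div or w % div:
            raise ValueError(f"input H,W must be divisible by {div}")
        if self.final_activation != "sigmoid":
            raise ValueError("final activation must be sigmoid")
        if self.loss != "binary_cross_entropy":
            raise ValueError("loss must be binary_cross_entropy")

    def scaled_filters(self):
        s = self.base_scale
        enc = [math.ceil(f * s) for f in self.encoder_filters]
        dec = [math.ceil(f * s) for f in self.decoder_filters]
        bn = math.ceil(self.bottleneck_filters * s)
        return enc, bn, dec


@dataclass
class ConfluencyResult:
    mask: np.ndarray           # bool, native resolution
    confluency_pct: float      # exactly 100 * |mask & roi| / |roi|
    roi: Optional[np.ndarray]  # bool mask or None for full frame


@dataclass
class PixelMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate: bool = False  # some denominator was zero (metric set to 0)


class ConfluencyModel:
    """Handle bundling the network, its spec and the decision threshold."""

    def __init__(self, spec: UNetSpec, seed: int = 0, threshold: float = 0.5):
        enc, bn, dec = spec.scaled_filters()
        self.spec = spec
        self.threshold = threshold
        self.input_hw = (spec.input_size[0], spec.input_size[1])
        self.net = _nn.UNet(spec.input_size[2], enc, bn, dec, out_ch=1,
                            dropout=spec.dropout_rate, seed=seed)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def prob_map(self, img2d: np.ndarray) -> np.ndarray:
        x = img2d[None, None].astype(np.float32)
        logits = self.net.forward(x, train=False)
        return _nn.sigmoid(logits[0, 0])


def build_confluency_net(spec: UNetSpec, seed: int = 0) -> ConfluencyModel:
    return ConfluencyModel(spec, seed=seed)


def _to_luma(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image @ LUMA
    return image


def _letterbox(image: np.ndarray, hw):
    """Aspect-preserving resize + bottom/right zero pad to the model size.

    Returns (padded, (rh, rw) resized content extent, native shape)."""
    H, W = hw
    h, w = image.shape
    s = min(H / h, W / w)
    rh, rw = max(1, round(h * s)), max(1, round(w * s))
    content = resize(image, (rh, rw), anti_aliasing=(s < 1), preserve_range=True)
    out = np.zeros((H, W), dtype=np.float32)
    out[:rh, :rw] = content
    return out, (rh, rw), (h, w)


def predict_mask(model: ConfluencyModel, image: np.ndarray,
                 roi: Optional[np.ndarray] = None,
                 threshold: Optional[float] = None) -> ConfluencyResult:
    """Segment an image of any size and report confluency inside the ROI.

    The image is letterbox-resized to the network input, the probability map
    thresholded (default 0.5), and the mask mapped back to native resolution
    with nearest-neighbour interpolation; letterbox padding never enters the
    ROI. `roi` is a boolean mask at native resolution (None = full frame).
    """
    img = _to_luma(np.asarray(image, dtype=float))
    thr = model.threshold if threshold is None else threshold
    padded, (rh, rw), (h, w) = _letterbox(img, model.input_hw)
    prob = model.prob_map(padded)[:rh, :rw]
    mask_small = prob >= thr
    mask = resize(mask_small.astype(np.uint8), (h, w), order=0,
                  preserve_range=True, anti_aliasing=False).astype(bool)
    if roi is not None:
        if roi.shape != mask.shape:
            raise ValueError("roi shape must match image shape")
        if not roi.any():
            raise ValueError("roi is empty")
    pct = confluency_percent(mask, roi)
    return ConfluencyResult(mask=mask, confluency_pct=pct, roi=roi)


def confluency_percent(mask: np.ndarray, roi: Optional[np.ndarray] = None) -> float:
    """Exactly 100 * |mask AND roi| / |roi| (full frame when roi is None)."""
    mask = np.asarray(mask, dtype=bool)
    if roi is None:
        return 100.0 * int(mask.sum()) / mask.size
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("roi is empty")
    return 100.0 * int((mask & roi).sum()) / n_roi


def pixel_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray) -> PixelMetrics:
    """Exact pixel-level confusion counts and the derived Accuracy /
    Precision / Recall / F1. Zero denominators yield 0 with a flag."""
    p = np.asarray(pred_mask, dtype=bool)
    t = np.asarray(truth_mask, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("shape mismatch between prediction and truth")
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    total = tp + fp + fn + tn
    degenerate = False
    acc = (tp + tn) / total if total else 0.0
    if tp + fp:
        prec = tp / (tp + fp)
    else:
        prec, degenerate = 0.0, True
    if tp + fn:
        rec = tp / (tp + fn)
    else:
        rec, degenerate = 0.0, True
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return PixelMetrics(acc, prec, rec, f1, tp, fp, fn, tn, degenerate)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

_BLUR_GRID = [(k, s) for k in (5, 9, 13, 15) for s in (0.0, 0.5, 1.0, 1.5, 2.0)]


def _augment(img, mask, rng, blur=True):
    k = int(rng.integers(0, 4))
    img = np.rot90(img, k)
    mask = np.rot90(mask, k)
    if rng.random() < 0.5:
        img = img[:, ::-1]
        mask = mask[:, ::-1]
    if blur and rng.random() < 0.25:
        ks, sig = _BLUR_GRID[int(rng.integers(0, len(_BLUR_GRID)))]
        img = apply_defocus(np.ascontiguousarray(img), ks, sig)
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def train_confluency(model: ConfluencyModel, train_set, val_set, epochs: int,
                     seed: int = 0, lr: Optional[float] = None,
                     batch_size: int = 4, augment: bool = True, verbose=False):
    """Adam + binary cross-entropy training of the confluency U-Net.

    `train_set`/`val_set` are sequences of (image, mask) pairs at the model
    input size. Returns (model, history) where history holds one
    PixelMetrics (on the validation set) per epoch; the weights with the
    best validation F1 are restored at the end. Deterministic per seed.
    """
    if not train_set:
        raise ValueError("empty training set")
    ids_train = {id(x[0]) for x in train_set}
    if any(id(x[0]) in ids_train for x in val_set):
        raise ValueError("train and validation sets must be disjoint")
    rng = np.random.default_rng(seed)
    opt = _nn.Adam(model.net.layers(), lr=lr or model.spec.learning_rate)
    history = []
    best_f1, best_w = -1.0, None
    n = len(train_set)
    for ep in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xs, ys = [], []
            for i in idx:
                im, mk = train_set[i]
                im2 = _to_luma(np.asarray(im, dtype=float))
                if augment:
                    im2, mk = _augment(im2, np.asarray(mk), rng)
                xs.append(im2[None])
                ys.append(np.asarray(mk, dtype=np.float32)[None])
            x = np.stack(xs).astype(np.float32)
            y = np.stack(ys).astype(np.float32)
            logits = model.net.forward(x, train=True)
            loss, grad = _nn.bce_with_logits(logits, y)
            model.net.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
        m = evaluate_pixel(model, val_set) if val_set else None
        if m is not None:
            history.append(m)
            if m.f1 > best_f1:
                best_f1, best_w = m.f1, model.net.get_weights()
        if verbose:
            print(f"epoch {ep + 1}/{epochs} loss {ep_loss / n:.4f}"
                  + (f" val F1 {m.f1:.3f}" if m else ""))
    if best_w is not None:
        model.net.set_weights(best_w)
    return model, history


def evaluate_pixel(model: ConfluencyModel, dataset) -> PixelMetrics:
    """Pooled pixel metrics of thresholded predictions over a dataset."""
    tp = fp = fn = tn = 0
    for im, mk in dataset:
        prob = model.prob_map(_to_luma(np.asarray(im, dtype=float)))
        pred = prob >= model.threshold
        t = np.asarray(mk, dtype=bool)
        tp += int((pred & t).sum())
        fp += int((pred & ~t).sum())
        fn += int((~pred & t).sum())
        tn += int((~pred & ~t).sum())
    total = max(tp + fp + fn + tn, 1)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return PixelMetrics((tp + tn) / total, prec, rec, f1, tp, fp, fn, tn)
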