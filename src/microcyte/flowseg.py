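"""Flow-field instance segmentation, counting and concentration.

The count model predicts, per pixel, a cell probability plus a vector
(dy, dx) pointing toward the owning cell's centre. Ground-truth flows are
built by diffusing heat from each object's median pixel and taking the
normalised spatial gradient of the diffused field; predicted (or ideal)
flows are integrated by advecting foreground pixels along the vectors until
they cluster at fixed points, each cluster becoming one instance. Touching
cells are separated because their flows point to different centres.

Also implements the hemocytometer arithmetic (count per etched square ->
cells/mL) and object-level precision/recall/F1 with one-to-one greedy IoU
matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import _nn
from .confluency import _to_luma
from .imagesim import ChamberGeometry

__all__ = [
    "FlowField", "InstanceMap", "SegParams", "InstanceMetrics", "CountResult",
    "CountModel", "masks_to_flows", "follow_flows", "train_count_model",
    "predict_flows", "segment", "count_cells", "concentration",
    "instance_metrics",
]


@dataclass
class FlowField:
    prob: np.ndarray  # [0,1]
    dy: np.ndarray    # [-1,1]
    dx: np.ndarray    # [-1,1]


@dataclass
class InstanceMap:
    labels: np.ndarray  # int32, 0 = background

    @property
    def n_instances(self) -> int:
        return int(self.labels.max())


@dataclass
class SegParams:
    prob_threshold: float = 0.5
    max_flow_error: float = 0.4
    min_object_px: int = 12
    n_integration_steps: int = 200
    step_size: float = 0.6
    flow_error_filter: bool = True

    def __post_init__(self):
        if min(self.prob_threshold, self.max_flow_error,
               self.min_object_px, self.n_integration_steps, self.step_size) <= 0:
            raise ValueError("all segmentation parameters must be positive")


@dataclass
class InstanceMetrics:
    precision: float
    recall: float
    f1: float
    n_matched: int
    iou_threshold: float
    mean_matched_iou: float = 0.0


@dataclass
class CountResult:
    count: int
    counts_per_square: list
    concentration: float  # cells/mL
    geometry: ChamberGeometry


# --------------------------------------------------------------------------
# ground-truth flows
# --------------------------------------------------------------------------

def masks_to_flows(truth) -> FlowField:
    """Diffusion flows for a labelled instance map.

    Within each object, heat is repeatedly injected at the object's median
    pixel and averaged over the 9-neighbourhood restricted to the object;
    the flow is the unit-normalised spatial gradient of the diffused field,
    so every interior vector points toward the centre. prob is 1 inside
    objects and 0 outside.
    """
    labels = truth.labels if isinstance(truth, InstanceMap) else np.asarray(truth)
    h, w = labels.shape
    dy = np.zeros((h, w), dtype=np.float64)
    dx = np.zeros((h, w), dtype=np.float64)
    prob = (labels > 0).astype(np.float64)
    if labels.max() == 0:
        return FlowField(prob, dy, dx)
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        sh, sw = sub.shape
        pad = np.zeros((sh + 2, sw + 2), dtype=bool)
        pad[1:-1, 1:-1] = sub
        ys, xs = np.nonzero(pad)
        my = int(np.median(ys))
        mx = int(np.median(xs))
        if not pad[my, mx]:  # median fell outside a concave object
            k = np.argmin((ys - my) ** 2 + (xs - mx) ** 2)
            my, mx = int(ys[k]), int(xs[k])
        T = np.zeros_like(pad, dtype=np.float64)
        n_iter = 2 * max(sh, sw) + 10
        for _ in range(n_iter):
            T[my, mx] += 1.0
            T = (T[:-2, :-2] + T[:-2, 1:-1] + T[:-2, 2:] +
                 T[1:-1, :-2] + T[1:-1, 1:-1] + T[1:-1, 2:] +
                 T[2:, :-2] + T[2:, 1:-1] + T[2:, 2:]) / 9.0
            T = np.pad(T, 1)
            T[~pad] = 0.0
        Tl = np.log1p(T)
        # gradient-ascent direction (+dT/dy, +dT/dx) points to the centre;
        # image y axis runs downward, central differences
        gy = Tl[2:, 1:-1] - Tl[:-2, 1:-1]
        gx = Tl[1:-1, 2:] - Tl[1:-1, :-2]
        nrm = np.sqrt(gy ** 2 + gx ** 2)
        nrm[nrm == 0] = 1.0
        gy /= nrm
        gx /= nrm
        dy[sl][sub] = gy[sub]
        dx[sl][sub] = gx[sub]
    return FlowField(prob, dy, dx)


def _bilinear(a: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    h, w = a.shape
    y = np.clip(y, 0, h - 1.001)
    x = np.clip(x, 0, w - 1.001)
    y0 = y.astype(int)
    x0 = x.astype(int)
    fy = y - y0
    fx = x - x0
    return ((1 - fy) * (1 - fx) * a[y0, x0] + (1 - fy) * fx * a[y0, x0 + 1]
            + fy * (1 - fx) * a[y0 + 1, x0] + fy * fx * a[y0 + 1, x0 + 1])


def follow_flows(fieldmap: FlowField, params: Optional[SegParams] = None) -> InstanceMap:
    """Integrate the flow field into an instance segmentation.

    Foreground pixels (prob >= threshold) take `n_integration_steps` Euler
    steps of `step_size` along the bilinearly interpolated unit flow; the
    landing positions pile up at object centres. Landing bins receiving
    >= 3 arrivals are clustered (8-connectivity) into seeds, every advected
    pixel inherits its landing seed's label, holes are filled, objects below
    `min_object_px` are dropped, and (optionally) instances whose re-derived
    flow disagrees with the input flow by more than `max_flow_error` (mean
    squared vector difference) are discarded.
    """
    params = params or SegParams()
    prob, dy, dx = fieldmap.prob, fieldmap.dy, fieldmap.dx
    h, w = prob.shape
    fg = prob >= params.prob_threshold
    out = np.zeros((h, w), dtype=np.int32)
    if not fg.any():
        return InstanceMap(out)
    ys, xs = np.nonzero(fg)
    py = ys.astype(np.float64)
    px = xs.astype(np.float64)
    for _ in range(params.n_integration_steps):
        vy = _bilinear(dy, py, px)
        vx = _bilinear(dx, py, px)
        nrm = np.sqrt(vy ** 2 + vx ** 2)
        live = nrm > 0.2
        scale = np.where(live, params.step_size / np.maximum(nrm, 1e-9), 0.0)
        py += vy * scale
        px += vx * scale
        np.clip(py, 0, h - 1, out=py)
        np.clip(px, 0, w - 1, out=px)
    iy = np.rint(py).astype(int)
    ix = np.rint(px).astype(int)
    hist = np.zeros((h, w), dtype=np.int32)
    np.add.at(hist, (iy, ix), 1)
    seeds = hist >= 3
    seed_lbl, n_seeds = ndimage.label(seeds, structure=np.ones((3, 3), int))
    if n_seeds == 0:
        return InstanceMap(out)
    # let pixels landing just outside a seed bin pick up the nearest label
    grow = seed_lbl.copy()
    for _ in range(3):
        dil = ndimage.grey_dilation(grow, size=3)
        grow = np.where(grow > 0, grow, dil)
    out[ys, xs] = grow[iy, ix]
    out = _fill_holes_per_label(out)
    out = _remove_small(out, params.min_object_px)
    if params.flow_error_filter:
        out = _flow_error_filter(out, fieldmap, params.max_flow_error)
    return InstanceMap(_compact(out))


def _fill_holes_per_label(labels: np.ndarray) -> np.ndarray:
    out = labels.copy()
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        m = labels[sl] == lab
        filled = ndimage.binary_fill_holes(m)
        add = filled & ~m & (out[sl] == 0)
        out[sl][add] = lab
    return out


def _remove_small(labels: np.ndarray, min_px: int) -> np.ndarray:
    if labels.max() == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    kill = np.nonzero(sizes < min_px)[0]
    if len(kill):
        labels = labels.copy()
        labels[np.isin(labels, kill[kill > 0])] = 0
    return labels


def _flow_error_filter(labels: np.ndarray, fieldmap: FlowField, max_err: float) -> np.ndarray:
    if labels.max() == 0:
        return labels
    ideal = masks_to_flows(labels)
    err_y = (ideal.dy - fieldmap.dy) ** 2 + (ideal.dx - fieldmap.dx) ** 2
    sums = ndimage.sum_labels(err_y, labels, index=np.arange(1, labels.max() + 1))
    counts = np.bincount(labels.ravel())[1:]
    mse = sums / np.maximum(counts, 1)
    kill = np.nonzero(mse > max_err)[0] + 1
    if len(kill):
        labels = labels.copy()
        labels[np.isin(labels, kill)] = 0
    return labels


def _compact(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(labels.max() + 1 if labels.max() else 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1)
    return lut[labels]


# --------------------------------------------------------------------------
# the count model
# --------------------------------------------------------------------------

class CountModel:
    """U-Net backbone emitting (prob logits, dy, dx) maps plus a pooled
    256-ish dimensional style vector used by the size-estimation stage."""

    def __init__(self, base_scale: float = 0.125, depth_filters=(64, 128, 256, 512),
                 bottleneck: int = 1024, in_ch: int = 1, seed: int = 0):
        import math
        enc = [math.ceil(f * base_scale) for f in depth_filters]
        dec = list(reversed(enc))
        bn = math.ceil(bottleneck * base_scale)
        # the three signed output maps read the decoder features directly
        # (a narrow ReLU head cannot express them jointly)
        self.net = _nn.UNet(in_ch, enc, bn, dec, out_ch=3, dropout=0.0,
                            seed=seed, head_filters=None)
        self.native_diameter_px: float = 10.0
        self.trained = False

    @property
    def style_dim(self) -> int:
        return self.net.style_dim

    def predict(self, image2d: np.ndarray):
        # zero-centred inputs keep the ReLU stacks in their active range
        img, (h, w) = _nn.pad_to_multiple(
            image2d.astype(np.float32) - np.float32(0.5), 16)
        logits = self.net.forward(img[None, None], train=False)[0]
        prob = _nn.sigmoid(logits[0])[:h, :w]
        dy = logits[1, :h, :w].astype(np.float64)
        dx = logits[2, :h, :w].astype(np.float64)
        style = self.net.style()[0]
        return FlowField(prob, dy, dx), style


def predict_flows(model: CountModel, image: np.ndarray) -> FlowField:
    fieldmap, _ = model.predict(_to_luma(np.asarray(image, dtype=float)))
    return fieldmap


def segment(model: CountModel, image: np.ndarray,
            params: Optional[SegParams] = None,
            diameter: Optional[float] = None) -> InstanceMap:
    """Predict flows and integrate them into instances.

    If `diameter` is given the image is first rescaled so objects appear at
    the model's native training diameter, and the labels are mapped back."""
    img = _to_luma(np.asarray(image, dtype=float))
    h, w = img.shape
    if diameter is not None and diameter > 0:
        s = model.native_diameter_px / diameter
    else:
        s = 1.0
    if abs(s - 1.0) > 1e-3:
        img_r = resize(img, (max(16, round(h * s)), max(16, round(w * s))),
                       anti_aliasing=(s < 1), preserve_range=True)
    else:
        img_r = img
    fieldmap, _ = model.predict(img_r)
    inst = follow_flows(fieldmap, params)
    if inst.labels.shape != (h, w):
        lab = resize(inst.labels, (h, w), order=0, preserve_range=True,
                     anti_aliasing=False).astype(np.int32)
        inst = InstanceMap(lab)
    return inst


def train_count_model(train_set, config: Optional[dict] = None, seed: int = 0,
                      model: Optional[CountModel] = None, verbose=False):
    """Train the count model on (image, instance-map) pairs.

    Ground-truth flows are derived on the fly with `masks_to_flows`. Loss is
    binary cross-entropy on the probability map plus an L2 penalty on the
    flow maps (weight `flow_weight`). Deterministic per seed.
    """
    if not train_set:
        raise ValueError("empty training set")
    cfg = {"epochs": 20, "lr": 1e-3, "batch_size": 4, "base_scale": 0.125,
           "flow_weight": 5.0}
    cfg.update(config or {})
    rng = np.random.default_rng(seed)
    prepared = []
    diam = []
    for im, inst in train_set:
        lab = inst.labels if isinstance(inst, InstanceMap) else np.asarray(inst)
        ff = masks_to_flows(lab)
        img = _to_luma(np.asarray(im, dtype=float)).astype(np.float32) - np.float32(0.5)
        prepared.append((img, np.stack([ff.prob, ff.dy, ff.dx]).astype(np.float32)))
        for l in range(1, lab.max() + 1):
            a = (lab == l).sum()
            if a:
                diam.append(2 * np.sqrt(a / np.pi))
    if model is None:
        model = CountModel(base_scale=cfg["base_scale"], seed=seed)
    model.native_diameter_px = float(np.median(diam)) if diam else 10.0
    opt = _nn.Adam(model.net.layers(), lr=cfg["lr"])
    n = len(prepared)
    lam = cfg["flow_weight"]
    history = []
    for ep in range(cfg["epochs"]):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg["batch_size"]):
            idx = order[start:start + cfg["batch_size"]]
            x = np.stack([prepared[i][0] for i in idx])[:, None]
            t = np.stack([prepared[i][1] for i in idx])
            logits = model.net.forward(x, train=True)
            bce, gprob = _nn.bce_with_logits(logits[:, :1], t[:, :1])
            diff = (logits[:, 1:] - t[:, 1:]).astype(np.float64)
            l2 = float(np.mean(diff ** 2))
            grad = np.empty_like(logits)
            grad[:, :1] = gprob
            grad[:, 1:] = (lam * 2.0 * diff / diff.size).astype(np.float32)
            model.net.backward(grad)
            opt.step()
            ep_loss += (bce + lam * l2) * len(idx)
        history.append(ep_loss / n)
        if verbose:
            print(f"epoch {ep + 1}/{cfg['epochs']} loss {ep_loss / n:.4f}")
    model.trained = True
    model.history = history
    return model


# --------------------------------------------------------------------------
# counting, concentration, metrics
# --------------------------------------------------------------------------

def count_cells(instances: InstanceMap, roi: Optional[tuple] = None) -> int:
    """Count objects in a rectangular ROI with the hemocytometer edge rule.

    `roi` is (top, left, bottom, right), half-open, or None for the full
    frame. An object is counted when its centroid lies in the ROI and it
    does not extend past the bottom or right boundary; objects crossing the
    top or left boundary are counted (standard top/left-include practice).
    """
    labels = instances.labels if isinstance(instances, InstanceMap) else np.asarray(instances)
    h, w = labels.shape
    if roi is None:
        roi = (0, 0, h, w)
    top, left, bottom, right = roi
    if bottom <= top or right <= left:
        raise ValueError("roi is empty")
    n = 0
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        ys, xs = np.nonzero(labels[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        cy, cx = ys.mean(), xs.mean()
        if ys.max() >= bottom or xs.max() >= right:
            continue  # crosses or touches the excluded edges
        inside_centroid = (top <= cy < bottom) and (left <= cx < right)
        crosses_topleft = (ys.min() < top <= ys.max()) or (xs.min() < left <= xs.max())
        overlaps = (ys.max() >= top) and (xs.max() >= left)
        if (inside_centroid or crosses_topleft) and overlaps:
            n += 1
    return n


def concentration(counts_per_square: Sequence[float],
                  geometry: ChamberGeometry) -> float:
    """Hemocytometer formula: mean count per square divided by the square
    volume in mL, times the dilution factor."""
    counts = np.asarray(counts_per_square, dtype=float)
    if counts.size == 0:
        raise ValueError("at least one square is required")
    return float(counts.mean() / geometry.square_volume_ml * geometry.dilution_factor)


def _iou_matrix(a: np.ndarray, b: np.ndarray):
    na, nb = int(a.max()), int(b.max())
    if na == 0 or nb == 0:
        return np.zeros((na, nb))
    idx = a.astype(np.int64) * (nb + 1) + b.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=(na + 1) * (nb + 1))
    counts = counts.reshape(na + 1, nb + 1)
    inter = counts[1:, 1:].astype(float)
    area_a = counts[1:, :].sum(axis=1).astype(float)
    area_b = counts[:, 1:].sum(axis=0).astype(float)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def instance_metrics(pred, truth, iou_threshold: float = 0.5) -> InstanceMetrics:
    """Object-level precision/recall/F1 with one-to-one greedy matching by
    descending IoU; matched pairs with IoU >= threshold are true positives."""
    p = pred.labels if isinstance(pred, InstanceMap) else np.asarray(pred)
    t = truth.labels if isinstance(truth, InstanceMap) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    iou = _iou_matrix(t, p)  # rows: truth, cols: pred
    nt, npred = iou.shape
    matched = []
    if nt and npred:
        pairs = [(iou[i, j], i, j) for i in range(nt) for j in range(npred)
                 if iou[i, j] >= iou_threshold]
        pairs.sort(key=lambda z: (-z[0], z[1], z[2]))
        used_t, used_p = set(), set()
        for v, i, j in pairs:
            if i in used_t or j in used_p:
                continue
            used_t.add(i)
            used_p.add(j)
            matched.append(v)
    tp = len(matched)
    fp = npred - tp
    fn = nt - tp
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return InstanceMetrics(prec, rec, f1, tp, iou_threshold,
                           float(np.mean(matched)) if matched else 0.0)
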