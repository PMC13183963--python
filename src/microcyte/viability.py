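"""Per-object live/dead classification of dye-stained chamber images.

A small U-Net-variant maps the (RGB) image to a single-channel viability
score field in [-1, 1] (Tanh head): trained toward +1 on dead-cell pixels,
-1 on live-cell pixels and 0 on background, with an L2 loss. Classification
happens strictly after instance segmentation: each object's call is the
mean score over its pixels, thresholded at 0 (dead above, live below).

The architecture is four 3x3 ReLU convolutions (the first two each
followed by 2x2 max pooling), three 2x2 transposed convolutions, and a 1x1
Tanh head. Two poolings shrink the map by 4x while three stride-2
upsamplings would grow it by 8x, so the third transposed convolution runs
at stride 1 to return exactly to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence
import warnings

import numpy as np
from scipy import ndimage

from . import _nn
from .flowseg import InstanceMap

__all__ = ["ViabilityNetSpec", "ViabilityCall", "ViabilityNet",
           "build_viability_net", "train_viability", "classify_objects",
           "viability_percent"]


@dataclass
class ViabilityNetSpec:
    in_channels: int = 3
    conv_filters: Sequence[int] = (16, 32, 32, 16)  # four 3x3 conv layers
    up_filters: Sequence[int] = (32, 16, 8)         # three 2x2 transposed convs
    decision_threshold: float = 0.0

    def __post_init__(self):
        if len(self.conv_filters) != 4 or len(self.up_filters) != 3:
            raise ValueError("spec requires 4 conv layers and 3 upsampling layers")


@dataclass
class ViabilityCall:
    label_id: int
    score: float                      # mean Tanh output over the object
    call: Literal["live", "dead"]
    dye: str = "trypan_blue"


class ViabilityNet:
    """Numpy implementation of the viability scorer; output (H, W) in [-1, 1]."""

    def __init__(self, spec: ViabilityNetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        f = spec.conv_filters
        u = spec.up_filters
        self.spec = spec
        self.layers_ = [
            _nn.Conv2d(spec.in_channels, f[0], 3, rng),
            _nn.MaxPool2(),
            _nn.Conv2d(f[0], f[1], 3, rng),
            _nn.MaxPool2(),
            _nn.Conv2d(f[1], f[2], 3, rng),
            _nn.Conv2d(f[2], f[3], 3, rng),
            _nn.ConvTranspose2(f[3], u[0], rng, stride=2),
            _nn.ConvTranspose2(u[0], u[1], rng, stride=2),
            _nn.ConvTranspose2(u[1], u[2], rng, stride=1),
            _nn.Conv2d(u[2], 1, 1, rng, act="linear"),
        ]
        self.trained = False

    def weight_layers(self):
        return [l for l in self.layers_ if l.weights()]

    @property
    def n_params(self):
        return int(sum(w.size for lay in self.weight_layers() for w, _ in lay.weights()))

    def forward(self, x, train=False):
        h = x.astype(np.float32)
        for lay in self.layers_:
            h = lay.forward(h, train)
        self._z = h
        return np.tanh(h.astype(np.float64))

    def backward(self, dtanh):
        d = (dtanh * (1.0 - np.tanh(self._z.astype(np.float64)) ** 2)).astype(np.float32)
        for lay in reversed(self.layers_):
            d = lay.backward(d)
        return d

    def score_map(self, image) -> np.ndarray:
        img = _as_chw(image)
        x, (h, w) = _nn.pad_to_multiple(img, 4)
        return self.forward(x[None], train=False)[0, 0, :h, :w]


def _as_chw(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.stack([img] * 3)
    elif img.ndim == 3:
        img = img.transpose(2, 0, 1)
    return img


def build_viability_net(spec: Optional[ViabilityNetSpec] = None,
                        seed: int = 0) -> ViabilityNet:
    return ViabilityNet(spec or ViabilityNetSpec(), seed=seed)


def _target_map(instance_labels: np.ndarray, viability_by_label: dict) -> np.ndarray:
    t = np.zeros(instance_labels.shape, dtype=np.float32)
    for lab, v in viability_by_label.items():
        if v == "dead":
            t[instance_labels == lab] = 1.0
        elif v == "live":
            t[instance_labels == lab] = -1.0
    return t


def train_viability(model: ViabilityNet, dataset, config: Optional[dict] = None,
                    seed: int = 0, verbose=False) -> ViabilityNet:
    """Train on (image, instance_map, {label_id: 'live'|'dead'}) triples.

    The target field is +1 on dead-object pixels, -1 on live-object pixels
    and 0 elsewhere; the loss is mean squared error against the Tanh
    output. A dataset with no dead examples trains but logs a class-
    imbalance warning. Deterministic per seed.
    """
    if not dataset:
        raise ValueError("empty dataset")
    cfg = {"epochs": 12, "lr": 1e-3, "batch_size": 4}
    cfg.update(config or {})
    n_dead = sum(1 for _, _, v in dataset for c in v.values() if c == "dead")
    n_live = sum(1 for _, _, v in dataset for c in v.values() if c == "live")
    if n_dead == 0 or n_live == 0:
        warnings.warn(
            f"class imbalance: {n_dead} dead vs {n_live} live objects in the "
            "training set", stacklevel=2)
    rng = np.random.default_rng(seed)
    prepared = []
    for im, inst, viab in dataset:
        lab = inst.labels if isinstance(inst, InstanceMap) else np.asarray(inst)
        prepared.append((_as_chw(im), _target_map(lab, viab)[None]))
    opt = _nn.Adam(model.weight_layers(), lr=cfg["lr"])
    n = len(prepared)
    model.loss_history = []
    for ep in range(cfg["epochs"]):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg["batch_size"]):
            idx = order[start:start + cfg["batch_size"]]
            x = np.stack([prepared[i][0] for i in idx])
            t = np.stack([prepared[i][1] for i in idx])
            y = model.forward(x, train=True)
            diff = y - t
            loss = float(np.mean(diff ** 2))
            model.backward(2.0 * diff / diff.size)
            opt.step()
            ep_loss += loss * len(idx)
        model.loss_history.append(ep_loss / n)
        if verbose:
            print(f"epoch {ep + 1}/{cfg['epochs']} loss {ep_loss / n:.4f}")
    model.trained = True
    return model


def classify_objects(model: ViabilityNet, image: np.ndarray, instances,
                     dye: str = "trypan_blue",
                     threshold: Optional[float] = None) -> List[ViabilityCall]:
    """Score each segmented object: mean viability-map value over its
    pixels; call 'dead' iff the score exceeds the decision threshold."""
    labels = instances.labels if isinstance(instances, InstanceMap) else np.asarray(instances)
    if labels.max() == 0:
        return []
    thr = model.spec.decision_threshold if threshold is None else threshold
    smap = model.score_map(image)
    idx = np.arange(1, labels.max() + 1)
    means = ndimage.mean(smap, labels=labels, index=idx)
    calls = []
    for lab, sc in zip(idx, np.atleast_1d(means)):
        if not np.isfinite(sc):
            continue
        calls.append(ViabilityCall(int(lab), float(sc),
                                   "dead" if sc > thr else "live", dye))
    return calls


def viability_percent(calls: Sequence[ViabilityCall]) -> float:
    """100 x live / (live + dead)."""
    if not calls:
        raise ValueError("no viability calls")
    live = sum(1 for c in calls if c.call == "live")
    return 100.0 * live / len(calls)
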