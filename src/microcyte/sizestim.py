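"""Two-pass cell-size estimation from count-model style vectors.

Pass 1 segments at an assumed default diameter and pools the deepest
encoder features of the count model into a style vector; a linear
regression on the style predicts the log object diameter. Pass 2 rescales
the image so objects sit at the model's native diameter, re-segments, and
reports the median object diameter 2*sqrt(area/pi) as the final size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.transform import resize

from .confluency import _to_luma
from .flowseg import CountModel, InstanceMap, SegParams, segment

__all__ = ["SizeModel", "SizeEstimate", "style_vector", "fit_size_model",
           "predict_diameter", "median_object_diameter", "estimate_size"]


@dataclass
class SizeModel:
    weights: np.ndarray   # one per style dimension
    intercept: float
    train_mse: float      # on log-diameter

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("size model parameters must be finite")


@dataclass
class SizeEstimate:
    diameter_px: Optional[float]
    n_objects: int
    instances: InstanceMap
    flag: Optional[str] = None  # "no-objects" when nothing was segmented


def style_vector(model: CountModel, image: np.ndarray,
                 diameter: Optional[float] = None) -> np.ndarray:
    """L2-normalised global-average-pooled bottleneck features.

    If `diameter` is given the image is rescaled to the model's native
    diameter first, matching what pass 1 of `estimate_size` sees."""
    if not model.trained:
        raise ValueError("count model is untrained")
    img = _to_luma(np.asarray(image, dtype=float))
    if diameter is not None and diameter > 0:
        s = model.native_diameter_px / diameter
        if abs(s - 1.0) > 1e-3:
            h, w = img.shape
            img = resize(img, (max(16, round(h * s)), max(16, round(w * s))),
                         anti_aliasing=(s < 1), preserve_range=True)
    _, style = model.predict(img)
    return style


def fit_size_model(styles: np.ndarray, true_diameters_px: np.ndarray,
                   ridge: Optional[float] = None) -> SizeModel:
    """Least-squares regression of log-diameter on the style vector.

    Plain OLS needs at least dim+1 training pairs; with fewer, a ridge
    penalty (default lambda 1e-3) keeps the normal equations solvable —
    pass `ridge` explicitly to control it, or 0 to force OLS.
    """
    X = np.asarray(styles, dtype=float)
    d = np.asarray(true_diameters_px, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    y = np.log(d)
    n, dim = X.shape
    if ridge is None:
        ridge = 0.0 if n > dim else 1e-3
    A = np.hstack([X, np.ones((n, 1))])
    if ridge > 0:
        reg = ridge * np.eye(dim + 1)
        reg[-1, -1] = 0.0  # never shrink the intercept
        beta = np.linalg.solve(A.T @ A + reg, A.T @ y)
    else:
        gram = A.T @ A
        if np.linalg.matrix_rank(gram) < dim + 1:
            raise np.linalg.LinAlgError(
                "degenerate design matrix; supply >= dim+1 pairs or a ridge penalty")
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ beta
    return SizeModel(beta[:-1], float(beta[-1]), float(np.mean((pred - y) ** 2)))


def predict_diameter(size_model: SizeModel, style: np.ndarray) -> float:
    return float(np.exp(style @ size_model.weights + size_model.intercept))


def median_object_diameter(instances) -> Optional[float]:
    """Median over objects of the equivalent-area diameter 2*sqrt(area/pi)."""
    labels = instances.labels if isinstance(instances, InstanceMap) else np.asarray(instances)
    if labels.max() == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    areas = areas[areas > 0]
    return float(np.median(2.0 * np.sqrt(areas / np.pi)))


def estimate_size(model: CountModel, size_model: SizeModel, image: np.ndarray,
                  default_diameter_px: float = 30.0,
                  params: Optional[SegParams] = None) -> SizeEstimate:
    """Two-pass size estimation.

    Pass 1: rescale for the default diameter, compute the style vector and
    predict a diameter d_hat. Pass 2: rescale the image by
    native/d_hat, re-segment, map labels back, and return the median
    equivalent-area diameter of the segmented objects (in original-image
    pixels). Zero objects after pass 2 returns a "no-objects" flag.
    """
    style = style_vector(model, image, diameter=default_diameter_px)
    d_hat = predict_diameter(size_model, style)
    d_hat = float(np.clip(d_hat, 2.0, max(image.shape[:2])))
    inst = segment(model, image, params=params, diameter=d_hat)
    med = median_object_diameter(inst)
    if med is None:
        return SizeEstimate(None, 0, inst, flag="no-objects")
    return SizeEstimate(med, inst.n_instances, inst)
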