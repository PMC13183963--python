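"""Seeded synthetic microscopy generator with exact ground truth.

Renders two scene families:

* adherent culture fields — irregular, halo-rimmed cells on a noisy,
  unevenly illuminated background, placed to hit a target confluency;
* counting-chamber scenes — hemocytometer/KOVA-style fields with etched
  grid lines, live/dead cells (Trypan Blue or Erythrosin B staining of the
  dead population), reference beads, and debris distractors.

Every render carries its full ground truth (semantic mask, instance map,
per-object class/diameter/viability), so segmentation, counting, sizing and
viability models can be trained and scored against exact labels. Also
provides the quantitative-series generators (exponential growth,
four-parameter dose-response, Poisson dilution series).

Determinism: a scene seed feeds a `numpy.random.SeedSequence`; each object
draws from its own spawned child stream, so adding objects never reshuffles
the appearance of earlier ones, and identical specs give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ChamberGeometry", "SceneSpec", "SceneObject", "RenderedSample",
    "GrowthSeries", "DoseResponseTable",
    "render_adherent_field", "render_chamber_scene", "apply_defocus",
    "simulate_growth_series", "simulate_dose_response",
    "simulate_dilution_series",
]

# dye colours (RGB, [0,1]) for the interiors of membrane-compromised cells
_DYE_RGB = {
    "trypan_blue": (0.20, 0.25, 0.52),
    "erythrosin_b": (0.80, 0.30, 0.40),
}
_LIVE_RGB = (0.82, 0.82, 0.80)

LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class ChamberGeometry:
    """Counting-chamber square geometry; volume per square in mL is
    side^2 * depth * 1e-3 (mm^3 -> mL)."""

    square_side_mm: float = 1.0
    depth_mm: float = 0.1
    grid_pitch_mm: float = 0.25
    dilution_factor: float = 1.0

    def __post_init__(self):
        if self.square_side_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("chamber geometry must be positive")
        if self.grid_pitch_mm <= 0 or self.dilution_factor <= 0:
            raise ValueError("grid pitch and dilution factor must be positive")

    @property
    def square_volume_ml(self) -> float:
        return self.square_side_mm ** 2 * self.depth_mm * 1e-3


@dataclass
class SceneSpec:
    """Declarative description of one synthetic scene."""

    width_px: int
    height_px: int
    microns_per_px: float = 1.0
    scene_kind: Literal["adherent_field", "chamber"] = "adherent_field"
    target_confluency_pct: float = 30.0
    n_objects: int = 0
    # (class, mean diameter um, sd um, fraction); fractions must sum to 1
    object_mix: Sequence[tuple] = field(
        default_factory=lambda: [("cell", 14.0, 2.0, 1.0)])
    dead_fraction: float = 0.0
    stain: Literal["none", "trypan_blue", "erythrosin_b"] = "none"
    grid: Optional[ChamberGeometry] = None
    defocus: Optional[tuple] = None  # (kernel_size, sigma)
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")
        if not 0.0 <= self.target_confluency_pct <= 100.0:
            raise ValueError("target confluency must lie in [0, 100]")
        if self.n_objects < 0:
            raise ValueError("n_objects must be non-negative")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        frac = sum(m[3] for m in self.object_mix)
        if abs(frac - 1.0) > 1e-9:
            raise ValueError("object_mix fractions must sum to 1")
        for m in self.object_mix:
            if m[1] <= 0:
                raise ValueError("object diameters must be strictly positive")
        if self.defocus is not None and self.defocus[0] % 2 == 0:
            raise ValueError("defocus kernel size must be odd")


@dataclass
class SceneObject:
    label_id: int
    cls: Literal["cell", "bead", "debris"]
    centroid: tuple  # (y, x) pixel coordinates, origin top-left
    diameter_px: float
    viability: Literal["live", "dead", "n/a"] = "n/a"


@dataclass
class RenderedSample:
    """A synthetic image plus its exact ground truth."""

    image: np.ndarray              # (H,W) or (H,W,3), float in [0,1]
    semantic_mask: np.ndarray      # bool, cell foreground
    instance_map: np.ndarray       # int32, 0 = background, labels 1..K
    objects: list                  # SceneObject per positive label
    distractors: list              # debris SceneObjects (not in instance_map)
    spec: SceneSpec
    coverage_pct: float = 0.0

    def luma(self) -> np.ndarray:
        if self.image.ndim == 2:
            return self.image
        return self.image @ LUMA


@dataclass
class GrowthSeries:
    timepoints: np.ndarray  # hours or days; strictly increasing
    values: np.ndarray      # positive cell numbers or confluency %

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("values must be positive")

    @property
    def n0(self) -> float:
        return float(self.values[0])


@dataclass
class DoseResponseTable:
    doses: np.ndarray       # concentration (e.g. nM), non-negative
    responses: np.ndarray   # normalised viability %
    replicate: np.ndarray   # replicate index per row

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if len(np.unique(self.doses)) < 4:
            raise ValueError("at least 4 distinct doses are required")


# --------------------------------------------------------------------------
# object rasterisation
# --------------------------------------------------------------------------

def _object_mask(diameter_px, rng, cls):
    """Boolean mask + local intensity template for one object.

    Cells: ellipse (axis ratio U(1, 1.8)) with a low-order Fourier
    perturbed boundary; beads: near-circular; debris: small elongated speck.
    Returns (mask, rim, dist_norm) on a local grid.
    """
    r0 = max(diameter_px / 2.0, 1.2)
    if cls == "cell":
        ratio = rng.uniform(1.0, 1.8)
        amps = rng.normal(0.0, 0.055, size=3)
        phis = rng.uniform(0, 2 * np.pi, size=3)
    elif cls == "bead":
        ratio = 1.0
        amps = rng.normal(0.0, 0.01, size=3)
        phis = rng.uniform(0, 2 * np.pi, size=3)
    else:  # debris: high eccentricity
        ratio = rng.uniform(2.5, 4.0)
        amps = rng.normal(0.0, 0.12, size=3)
        phis = rng.uniform(0, 2 * np.pi, size=3)
    a = r0 * np.sqrt(ratio)
    b = r0 / np.sqrt(ratio)
    theta0 = rng.uniform(0, np.pi)
    n = int(np.ceil(max(a, r0) + 3))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1].astype(float)
    ct, st = np.cos(theta0), np.sin(theta0)
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    rr = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    ang = np.arctan2(v, u)
    pert = 1.0
    for k, (ak, pk) in enumerate(zip(amps, phis), start=2):
        pert = pert + ak * np.cos(k * ang + pk)
    mask = rr <= pert
    inner = rr <= pert * (1.0 - min(2.0 / r0, 0.55))
    rim = mask & ~inner
    dist = np.clip(rr / np.maximum(pert, 1e-6), 0, 1)
    return mask, rim, dist


def _paint_object(img, mask, rim, dist, top, left, cls, viability, stain, rng):
    """Blend one object into the image (grayscale or RGB view)."""
    h, w = mask.shape
    sl = (slice(top, top + h), slice(left, left + w))
    rgb = img.ndim == 3
    texture = ndimage.gaussian_filter(rng.normal(0, 1.0, mask.shape), 1.2)
    texture = 0.06 * texture / max(np.std(texture), 1e-6)
    if cls == "cell":
        if stain == "none":
            body = 0.58 + texture
            rim_val = 0.88
        elif viability == "dead":
            base = np.array(_DYE_RGB[stain])
            body = base[None, None, :] + texture[..., None] * 0.5
            rim_val = 0.55
        else:
            base = np.array(_LIVE_RGB)
            body = base[None, None, :] + texture[..., None] * 0.5
            rim_val = 0.92
    elif cls == "bead":
        val = 0.62 + texture * 0.3
        body = val[..., None].repeat(3, axis=-1) if rgb else val
        rim_val = 0.30  # dark refractive ring
    else:  # debris
        val = 0.30 + texture
        body = val[..., None].repeat(3, axis=-1) if rgb else val
        rim_val = 0.35
    if rgb and np.ndim(body) == 2:
        body = body[..., None].repeat(3, axis=-1)
    if not rgb and np.ndim(body) == 3:
        body = body[..., 0]
    region = img[sl]
    if rgb:
        region[mask] = np.clip(body[mask], 0, 1)
        region[rim] = rim_val
    else:
        region[mask] = np.clip(body if np.ndim(body) == 2 else body, 0, 1)[mask]
        region[rim] = rim_val


def _background(h, w, rng, base):
    grad_y, grad_x = rng.uniform(-0.05, 0.05, size=2)
    yy, xx = np.mgrid[0:h, 0:w]
    bg = base + grad_y * (yy / max(h - 1, 1) - 0.5) + grad_x * (xx / max(w - 1, 1) - 0.5)
    bg = bg + rng.normal(0, 0.02, size=(h, w))
    return np.clip(bg, 0, 1)


def _choose_class(mix, rng):
    fr = np.array([m[3] for m in mix])
    idx = rng.choice(len(mix), p=fr / fr.sum())
    cls, mu, sd, _ = mix[idx]
    return cls, mu, sd


# --------------------------------------------------------------------------
# adherent fields
# --------------------------------------------------------------------------

def render_adherent_field(spec: SceneSpec) -> RenderedSample:
    """Render an adherent-culture brightfield at the requested confluency.

    Cells are placed (overlap allowed, as in a confluent monolayer) until
    pixel coverage reaches the target; the final cell is shrunk when needed
    so the achieved coverage stays within +/-2 percentage points of the
    target (a target of 100% stops at geometric saturation >= 98%).
    """
    if spec.scene_kind != "adherent_field":
        raise ValueError("spec.scene_kind must be 'adherent_field'")
    h, w = spec.height_px, spec.width_px
    mean_d = spec.object_mix[0][1] / spec.microns_per_px
    if min(h, w) < mean_d:
        raise ValueError("image smaller than one cell diameter")
    ss = np.random.SeedSequence(spec.seed)
    scene_rng = np.random.default_rng(ss.spawn(1)[0])
    img = _background(h, w, scene_rng, base=0.45)
    instance = np.zeros((h, w), dtype=np.int32)
    objects: list[SceneObject] = []
    target = spec.target_confluency_pct / 100.0
    total_px = h * w
    covered = 0
    max_iter = int(max(40, 6 * target * total_px / (np.pi * (mean_d / 2) ** 2 + 1)))
    it = 0
    while covered / total_px < target and it < max_iter:
        it += 1
        obj_rng = np.random.default_rng(ss.spawn(1)[0])
        cls, mu, sd = _choose_class(spec.object_mix, obj_rng)
        d_px = max(obj_rng.normal(mu, sd), mu * 0.4) / spec.microns_per_px
        # shrink the closing cells so we do not overshoot the +/-2pt band
        remaining = (target - covered / total_px) * total_px
        cap = 2.0 * np.sqrt(max(remaining, 1.0) * 1.25 / np.pi)
        d_px = float(np.clip(d_px, 4.0, max(cap, 4.0)))
        mask, rim, dist = _object_mask(d_px, obj_rng, cls)
        mh, mw = mask.shape
        top = int(scene_rng.integers(-mh // 3, max(h - 2 * mh // 3, 1 - mh // 3)))
        left = int(scene_rng.integers(-mw // 3, max(w - 2 * mw // 3, 1 - mw // 3)))
        m, r, dn, top, left = _crop_to_frame(mask, rim, dist, top, left, h, w)
        if m is None or m.sum() == 0:
            continue
        _paint_object(img, m, r, dn, top, left, cls, "n/a", "none", obj_rng)
        sl = (slice(top, top + m.shape[0]), slice(left, left + m.shape[1]))
        new_px = int((m & (instance[sl] == 0)).sum())
        lab = len(objects) + 1
        instance[sl][m] = lab
        ys, xs = np.nonzero(m)
        objects.append(SceneObject(lab, cls, (float(ys.mean() + top), float(xs.mean() + left)),
                                   d_px, "n/a"))
        covered += new_px
    instance, objects = _relabel(instance, objects)
    semantic = instance > 0
    if spec.defocus is not None:
        img = apply_defocus(img, *spec.defocus)
    cov = 100.0 * semantic.sum() / total_px
    return RenderedSample(img, semantic, instance, objects, [], spec, cov)


def _crop_to_frame(mask, rim, dist, top, left, h, w):
    mh, mw = mask.shape
    y0, x0 = max(0, -top), max(0, -left)
    y1 = mh - max(0, top + mh - h)
    x1 = mw - max(0, left + mw - w)
    if y1 <= y0 or x1 <= x0:
        return None, None, None, top, left
    return (mask[y0:y1, x0:x1], rim[y0:y1, x0:x1], dist[y0:y1, x0:x1],
            top + y0, left + x0)


def _relabel(instance, objects):
    """Drop labels whose pixels were fully overpainted; renumber 1..K."""
    present = np.unique(instance)
    present = present[present > 0]
    out_objects = []
    relab = np.zeros((instance.max() + 1,), dtype=np.int32) if instance.max() else np.zeros(1, np.int32)
    nxt = 0
    for obj in objects:
        if obj.label_id in present:
            nxt += 1
            relab[obj.label_id] = nxt
            obj.label_id = nxt
            out_objects.append(obj)
    inst = relab[instance] if instance.max() else instance
    return inst.astype(np.int32), out_objects


# --------------------------------------------------------------------------
# chamber scenes
# --------------------------------------------------------------------------

def render_chamber_scene(spec: SceneSpec, max_overlap=0.3, max_retries=40,
                         debris_rate=0.0) -> RenderedSample:
    """Render a counting-chamber field with grid lines and labelled objects.

    Dead cells (an exact round(n_cells * dead_fraction) of them) get
    dye-filled interiors; live cells bright interiors; beads a dark
    refractive ring; debris dark specks excluded from the ground truth.
    Pairwise object overlap is capped at `max_overlap` (fraction of the new
    object's area); placement failing after bounded retries raises.
    """
    if spec.scene_kind != "chamber":
        raise ValueError("spec.scene_kind must be 'chamber'")
    h, w = spec.height_px, spec.width_px
    ss = np.random.SeedSequence(spec.seed)
    scene_rng = np.random.default_rng(ss.spawn(1)[0])
    rgb = spec.stain != "none"
    bg = _background(h, w, scene_rng, base=0.76)
    img = bg[..., None].repeat(3, axis=-1) if rgb else bg
    _draw_grid(img, spec, scene_rng)
    instance = np.zeros((h, w), dtype=np.int32)
    objects: list[SceneObject] = []
    distractors: list[SceneObject] = []

    # class counts by largest remainder so fractions are hit exactly
    counts = _exact_counts([m[3] for m in spec.object_mix], spec.n_objects)
    classes = []
    for (cls, mu, sd, _), c in zip(spec.object_mix, counts):
        classes += [(cls, mu, sd)] * c
    scene_rng.shuffle(classes)
    n_cells = sum(1 for c in classes if c[0] == "cell")
    n_dead = int(round(n_cells * spec.dead_fraction))
    dead_ids = set(scene_rng.choice(n_cells, size=n_dead, replace=False).tolist()) \
        if n_dead else set()

    cell_i = 0
    for cls, mu, sd in classes:
        obj_rng = np.random.default_rng(ss.spawn(1)[0])
        d_px = max(obj_rng.normal(mu, sd), mu * 0.4) / spec.microns_per_px
        viability = "n/a"
        if cls == "cell":
            viability = "dead" if cell_i in dead_ids else "live"
            cell_i += 1
        mask, rim, dist = _object_mask(d_px, obj_rng, cls)
        placed = False
        for _ in range(max_retries):
            mh, mw = mask.shape
            top = int(scene_rng.integers(0, max(h - mh, 1)))
            left = int(scene_rng.integers(0, max(w - mw, 1)))
            sl = (slice(top, top + mh), slice(left, left + mw))
            overlap = (mask & (instance[sl] > 0)).sum() / max(mask.sum(), 1)
            if overlap <= max_overlap:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"object placement failed after {max_retries} retries "
                f"(n_objects={spec.n_objects} too dense for the frame)")
        _paint_object(img, mask, rim, dist, top, left, cls, viability,
                      spec.stain, obj_rng)
        lab = len(objects) + 1
        instance[sl][mask] = lab
        ys, xs = np.nonzero(mask)
        objects.append(SceneObject(lab, cls,
                                   (float(ys.mean() + top), float(xs.mean() + left)),
                                   d_px, viability))

    # debris distractors, outside the labelled ground truth
    n_debris = scene_rng.poisson(debris_rate) if debris_rate else 0
    for _ in range(n_debris):
        obj_rng = np.random.default_rng(ss.spawn(1)[0])
        d_px = obj_rng.uniform(2.5, 5.0)
        mask, rim, dist = _object_mask(d_px, obj_rng, "debris")
        mh, mw = mask.shape
        if h - mh <= 1 or w - mw <= 1:
            continue
        top = int(scene_rng.integers(0, h - mh))
        left = int(scene_rng.integers(0, w - mw))
        sl = (slice(top, top + mh), slice(left, left + mw))
        if (mask & (instance[sl] > 0)).any():
            continue
        _paint_object(img, mask, rim, dist, top, left, "debris", "n/a",
                      spec.stain, obj_rng)
        ys, xs = np.nonzero(mask)
        distractors.append(SceneObject(0, "debris",
                                       (float(ys.mean() + top), float(xs.mean() + left)),
                                       d_px, "n/a"))

    instance, objects = _relabel(instance, objects)
    semantic = np.isin(instance, [o.label_id for o in objects if o.cls == "cell"]) \
        if objects else np.zeros((h, w), bool)
    if spec.defocus is not None:
        img = apply_defocus(img, *spec.defocus)
    cov = 100.0 * (instance > 0).sum() / (h * w)
    return RenderedSample(np.clip(img, 0, 1), semantic, instance, objects,
                          distractors, spec, cov)


def _exact_counts(fractions, n):
    raw = np.array(fractions) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i % len(base)]] += 1
    return base


def _draw_grid(img, spec, rng):
    if spec.grid is None:
        return
    pitch_px = spec.grid.grid_pitch_mm * 1000.0 / spec.microns_per_px
    if pitch_px < 4:
        return
    h, w = img.shape[:2]
    phase_y = rng.uniform(0, pitch_px)
    phase_x = rng.uniform(0, pitch_px)
    line_val = 0.45
    for y in np.arange(phase_y, h, pitch_px):
        yi = int(round(y))
        if 0 <= yi < h:
            img[max(yi - 1, 0):yi + 1, :] = line_val
    for x in np.arange(phase_x, w, pitch_px):
        xi = int(round(x))
        if 0 <= xi < w:
            img[:, max(xi - 1, 0):xi + 1] = line_val


# --------------------------------------------------------------------------
# defocus and quantitative series
# --------------------------------------------------------------------------

def apply_defocus(image: np.ndarray, kernel_size: int, sigma: float) -> np.ndarray:
    """Gaussian blur with an explicit truncated kernel support.

    `sigma = 0` returns the image unchanged; even kernel sizes are
    rejected. Applies separably along both spatial axes (channels intact).
    """
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel_size must be an odd positive integer")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return image.copy()
    half = kernel_size // 2
    xs = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (xs / sigma) ** 2)
    k /= k.sum()
    out = ndimage.correlate1d(image, k, axis=0, mode="nearest")
    out = ndimage.correlate1d(out, k, axis=1, mode="nearest")
    return out


def simulate_growth_series(n0: float, gr: float, timepoints, cv_noise: float = 0.0,
                           seed: int = 0) -> GrowthSeries:
    """Exponential growth N(t) = N0 * exp(gr * t) with multiplicative
    lognormal noise of the given coefficient of variation."""
    if n0 <= 0:
        raise ValueError("N0 must be positive")
    t = np.asarray(timepoints, dtype=float)
    vals = n0 * np.exp(gr * t)
    if cv_noise > 0:
        rng = np.random.default_rng(seed)
        s2 = np.log1p(cv_noise ** 2)
        noise = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=t.shape)
        vals = vals * noise
    return GrowthSeries(t, vals)


def logistic4(d, top, bottom, log_ic50, hill):
    """Four-parameter logistic, log10-dose axis; hill > 0 means the
    response falls with increasing dose (inhibition convention)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (
            1.0 + 10.0 ** ((np.log10(np.maximum(d, 1e-300)) - log_ic50) * hill))


def simulate_dose_response(top, bottom, ic50, hill, doses, sd=0.0,
                           replicates=1, seed=0) -> DoseResponseTable:
    """Sample a dose-response table from the 4-parameter logistic with
    additive Gaussian noise of standard deviation `sd`."""
    if top <= bottom:
        raise ValueError("top must exceed bottom")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    all_d, all_r, all_rep = [], [], []
    for rep in range(replicates):
        resp = logistic4(doses, top, bottom, np.log10(ic50), hill)
        if sd > 0:
            resp = resp + rng.normal(0, sd, size=doses.shape)
        all_d.append(doses)
        all_r.append(resp)
        all_rep.append(np.full(doses.shape, rep, dtype=int))
    return DoseResponseTable(np.concatenate(all_d), np.concatenate(all_r),
                             np.concatenate(all_rep))


def simulate_dilution_series(stock_conc: float, factors, chamber: ChamberGeometry,
                             fields_per_sample: int = 4, seed: int = 0,
                             microns_per_px: float = 2.0,
                             mean_diameter_um: float = 12.0):
    """Render chamber fields for a dilution series of a cell suspension.

    `factors` are successive dilution factors relative to the stock
    (concentration_i = stock / factor_i). Per-field object counts are
    Poisson with mean conc x square volume / chamber dilution factor.

    Returns a list of (RenderedSample, expected_concentration) pairs.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("dilution factors must be positive")
    side_px = int(round(chamber.square_side_mm * 1000.0 / microns_per_px))
    rng = np.random.default_rng(seed)
    out = []
    for i, f in enumerate(factors):
        conc = stock_conc / f
        lam = conc * chamber.square_volume_ml / chamber.dilution_factor
        for j in range(fields_per_sample):
            n = int(rng.poisson(lam))
            spec = SceneSpec(
                width_px=side_px, height_px=side_px,
                microns_per_px=microns_per_px, scene_kind="chamber",
                n_objects=n,
                object_mix=[("cell", mean_diameter_um, mean_diameter_um * 0.12, 1.0)],
                grid=chamber, seed=int(rng.integers(0, 2 ** 31 - 1)))
            out.append((render_chamber_scene(spec), conc))
    return out
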