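"""Shared fixtures: synthetic datasets and the (expensive) trained models.

Model training happens once per session at desk scale: small fields and a
narrow U-Net (base_scale 1/8), sized so the whole suite stays within a
routine CI budget while the thresholds under test stay at full strength.
"""

import numpy as np
import pytest

import microcyte as mc


MULTISCALE = [1, 1, 2, 2, 4, 10]


def make_adherent_set(n, seed0, size=96, diam_um=12.0, conf_lo=10, conf_hi=70,
                      multiscale=False):
    """Adherent fields at the model size; with `multiscale`, scenes are
    rendered at several native resolutions and downsampled, emulating a
    pool of mixed image qualities."""
    from skimage.transform import resize

    out = []
    for i in range(n):
        f = MULTISCALE[i % len(MULTISCALE)] if multiscale else 1
        spec = mc.SceneSpec(
            width_px=size * f, height_px=size * f,
            scene_kind="adherent_field",
            target_confluency_pct=float(conf_lo + (i * 7) % (conf_hi - conf_lo)),
            object_mix=[("cell", diam_um * f, diam_um * f / 8, 1.0)],
            seed=seed0 + i)
        s = mc.render_adherent_field(spec)
        img, mask = s.image, s.semantic_mask
        if f > 1:
            img = resize(img, (size, size), anti_aliasing=True)
            mask = resize(mask.astype(np.uint8), (size, size), order=0,
                          preserve_range=True).astype(bool)
        out.append((img, mask))
    return out


def make_chamber_samples(n, seed0, size=64, nobj=(4, 12), stain="none",
                         dead_fraction=0.0, debris_rate=1.0,
                         microns_per_px=2.0, mix=None, vary_diameter=False,
                         down=1):
    """Chamber scenes; `down > 1` renders at down*size with proportionally
    larger objects and downsamples, emulating lower-resolution imaging."""
    from skimage.transform import resize

    out = []
    rng = np.random.default_rng(seed0)
    for i in range(n):
        if mix is not None:
            this_mix = mix
        elif vary_diameter:
            cd = float(rng.uniform(14, 26)) * down
            bd = float(rng.uniform(10, 20)) * down
            this_mix = [("cell", cd, cd / 8, 0.9), ("bead", bd, 1.0, 0.1)]
        else:
            this_mix = [("cell", 20.0 * down, 2.5 * down, 1.0)]
        spec = mc.SceneSpec(
            width_px=size * down, height_px=size * down, scene_kind="chamber",
            n_objects=int(rng.integers(*nobj)), microns_per_px=microns_per_px,
            object_mix=this_mix, dead_fraction=dead_fraction, stain=stain,
            grid=mc.ChamberGeometry(grid_pitch_mm=0.1), seed=seed0 + i)
        s = mc.render_chamber_scene(spec, debris_rate=debris_rate)
        if down > 1:
            s.image = resize(s.image, (size, size), anti_aliasing=True)
            s.instance_map = resize(s.instance_map, (size, size), order=0,
                                    preserve_range=True,
                                    anti_aliasing=False).astype(np.int32)
            s.semantic_mask = resize(s.semantic_mask.astype(np.uint8),
                                     (size, size), order=0,
                                     preserve_range=True).astype(bool)
        out.append(s)
    return out


@pytest.fixture(scope="session")
def trained_confluency():
    """Confluency U-Net trained on synthetic adherent fields + its test set."""
    train = make_adherent_set(60, 1000, multiscale=True)
    val = make_adherent_set(12, 5000, multiscale=True)
    test = make_adherent_set(16, 7000, multiscale=True)
    spec = mc.UNetSpec(input_size=(96, 96, 1), base_scale=0.125, dropout_rate=0.1)
    model = mc.build_confluency_net(spec, seed=0)
    model, history = mc.train_confluency(model, train, val, epochs=28, seed=1,
                                         lr=3e-3, batch_size=4, augment=False)
    return {"model": model, "history": history, "test": test}


@pytest.fixture(scope="session")
def trained_count():
    """Count/flow model trained on chamber crops with varied object sizes
    and a share of downsampled (lower-resolution) renders."""
    train_samples = (make_chamber_samples(60, 2000, vary_diameter=True)
                     + make_chamber_samples(20, 2600, vary_diameter=True,
                                            down=2))
    test_samples = make_chamber_samples(10, 9000, size=96, nobj=(8, 20),
                                        vary_diameter=True)
    train = [(s.image, s.instance_map) for s in train_samples]
    model = mc.train_count_model(
        train, {"epochs": 30, "lr": 3e-3, "batch_size": 2}, seed=0)
    return {"model": model, "test": test_samples}


@pytest.fixture(scope="session")
def trained_viability():
    """Viability net trained on stained chamber scenes of both dyes."""
    sets = {}
    train = []
    for dye, seed0 in (("trypan_blue", 3000), ("erythrosin_b", 4000)):
        samples = make_chamber_samples(40, seed0, stain=dye, dead_fraction=0.4,
                                       debris_rate=0.0, nobj=(5, 12))
        sets[dye] = seed0 + 500
        for s in samples:
            viab = {o.label_id: o.viability for o in s.objects}
            train.append((s.image, s.instance_map, viab))
    model = mc.build_viability_net(seed=0)
    model = mc.train_viability(model, train, {"epochs": 12, "lr": 1e-3,
                                              "batch_size": 4}, seed=1)
    return {"model": model, "test_seeds": sets}
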