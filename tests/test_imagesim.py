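"""Generator contracts: coverage control, determinism, exact ground truth,
stain separability, defocus, and the quantitative series."""

import numpy as np
import pytest
from scipy import ndimage

import microcyte as mc


def adherent_spec(target, seed=7, size=256, diam=18.0):
    return mc.SceneSpec(width_px=size, height_px=size,
                        scene_kind="adherent_field",
                        target_confluency_pct=target,
                        object_mix=[("cell", diam, 2.0, 1.0)], seed=seed)


class TestAdherentField:
    @pytest.mark.parametrize("target,lo,hi", [
        (0.0, 0.0, 0.0),          # no objects placed at all
        (40.0, 38.0, 42.0),       # mid-range target hit within 2 points
        (100.0, 98.0, 100.0),     # geometric saturation
    ])
    def test_coverage_hits_target(self, target, lo, hi):
        s = mc.render_adherent_field(adherent_spec(target))
        # independent pixel-count oracle on the emitted mask
        cov = 100.0 * np.count_nonzero(s.semantic_mask) / s.semantic_mask.size
        assert lo <= cov <= hi
        assert s.coverage_pct == pytest.approx(cov, abs=1e-9)

    def test_bit_identical_for_same_seed(self):
        a = mc.render_adherent_field(adherent_spec(35.0, seed=11))
        b = mc.render_adherent_field(adherent_spec(35.0, seed=11))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.instance_map, b.instance_map)

    def test_labels_contiguous_and_listed_once(self):
        s = mc.render_adherent_field(adherent_spec(30.0, seed=3))
        labs = np.unique(s.instance_map)
        labs = labs[labs > 0]
        assert list(labs) == list(range(1, len(s.objects) + 1))
        assert sorted(o.label_id for o in s.objects) == list(labs)
        assert np.array_equal(s.semantic_mask, s.instance_map > 0)

    def test_rejects_bad_targets_and_tiny_frames(self):
        with pytest.raises(ValueError):
            mc.SceneSpec(width_px=64, height_px=64,
                         scene_kind="adherent_field",
                         target_confluency_pct=101.0)
        with pytest.raises(ValueError):
            mc.render_adherent_field(
                mc.SceneSpec(width_px=8, height_px=8,
                             scene_kind="adherent_field",
                             target_confluency_pct=10.0,
                             object_mix=[("cell", 18.0, 2.0, 1.0)]))


def chamber_spec(n, seed=0, size=256, dead=0.0, stain="none", overlap_mix=None):
    return mc.SceneSpec(width_px=size, height_px=size, scene_kind="chamber",
                        n_objects=n, microns_per_px=2.0,
                        object_mix=overlap_mix or [("cell", 20.0, 2.0, 1.0)],
                        dead_fraction=dead, stain=stain,
                        grid=mc.ChamberGeometry(), seed=seed)


class TestChamberScene:
    def test_empty_scene(self):
        s = mc.render_chamber_scene(chamber_spec(0))
        assert s.instance_map.max() == 0
        assert s.objects == []

    def test_connected_component_count_matches(self):
        # no overlap allowed: each object is its own connected component
        s = mc.render_chamber_scene(chamber_spec(50, seed=2), max_overlap=0.0)
        _, n_cc = ndimage.label(s.instance_map > 0)
        assert n_cc == 50
        assert len(s.objects) == 50

    def test_exact_dead_count(self):
        s = mc.render_chamber_scene(chamber_spec(100, seed=5, dead=0.3,
                                                 stain="trypan_blue"))
        assert sum(1 for o in s.objects if o.viability == "dead") == 30

    @pytest.mark.parametrize("stain", ["trypan_blue", "erythrosin_b"])
    def test_stain_separability(self, stain):
        s = mc.render_chamber_scene(chamber_spec(60, seed=8, dead=0.5,
                                                 stain=stain))
        luma = s.luma()
        means = {"live": [], "dead": []}
        for o in s.objects:
            means[o.viability].append(luma[s.instance_map == o.label_id].mean())
        gap = np.mean(means["live"]) - np.mean(means["dead"])
        assert gap >= 0.2

    def test_debris_outside_ground_truth(self):
        s = mc.render_chamber_scene(chamber_spec(20, seed=9), debris_rate=5.0)
        assert all(o.cls == "debris" for o in s.distractors)
        assert all(o.cls != "debris" for o in s.objects)

    def test_placement_failure_raises(self):
        with pytest.raises(RuntimeError):
            mc.render_chamber_scene(chamber_spec(500, size=96), max_retries=5)


class TestDefocus:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(0).random((32, 32))
        out = mc.apply_defocus(img, 5, 0.0)
        assert np.array_equal(out, img)
        assert out is not img

    @pytest.mark.parametrize("k,sigma", [(5, 2.0), (9, 1.0), (15, 0.5)])
    def test_blur_reduces_variance(self, k, sigma):
        img = np.random.default_rng(1).random((48, 48))
        out = mc.apply_defocus(img, k, sigma)
        assert out.var() < img.var()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            mc.apply_defocus(np.zeros((8, 8)), 4, 1.0)


class TestGrowthSeries:
    def test_doubling_definition(self):
        s = mc.simulate_growth_series(100.0, np.log(2), [0.0, 1.0], cv_noise=0)
        assert s.values[1] == pytest.approx(200.0, rel=1e-12)

    def test_noise_free_is_exactly_exponential(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        s = mc.simulate_growth_series(50.0, 0.3, t, cv_noise=0)
        resid = np.log(s.values) - (np.log(50.0) + 0.3 * t)
        assert np.max(np.abs(resid)) < 1e-12

    def test_noise_is_unbiased_in_log_rate(self):
        # Monte-Carlo: fitted growth rate unbiased within 2% at cv=5%
        t = np.array([0.0, 1.0, 2.0, 3.0])
        grs = []
        for rep in range(1000):
            s = mc.simulate_growth_series(1000.0, 0.5, t, cv_noise=0.05,
                                          seed=rep)
            grs.append(mc.doubling_time(s).gr)
        assert np.mean(grs) == pytest.approx(0.5, rel=0.02)

    def test_rejects_nonpositive_n0(self):
        with pytest.raises(ValueError):
            mc.simulate_growth_series(0.0, 0.5, [0, 1])


class TestDoseResponse:
    def test_midpoint_and_asymptotes(self):
        doses = np.array([1e-4, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 1e4])
        tab = mc.simulate_dose_response(100, 0, 1.0, 1.0, doses, sd=0)
        at_ic50 = tab.responses[tab.doses == 1.0][0]
        assert at_ic50 == pytest.approx(50.0, abs=1e-9)
        assert tab.responses[0] == pytest.approx(100.0, abs=0.1)
        assert tab.responses[-1] == pytest.approx(0.0, abs=0.1)

    def test_rejects_top_below_bottom(self):
        with pytest.raises(ValueError):
            mc.simulate_dose_response(0, 100, 1.0, 1.0, [0.1, 1, 10, 100])

    def test_requires_four_distinct_doses(self):
        with pytest.raises(ValueError):
            mc.simulate_dose_response(100, 0, 1.0, 1.0, [1.0, 1.0, 2.0, 2.0])


class TestDilutionSeries:
    def test_zero_concentration_gives_empty_fields(self):
        geom = mc.ChamberGeometry(square_side_mm=0.25, grid_pitch_mm=0.1)
        out = mc.simulate_dilution_series(0.0, [1.0], geom,
                                          fields_per_sample=3, seed=0,
                                          microns_per_px=4.0)
        assert all(len(s.objects) == 0 for s, _ in out)

    def test_poisson_mean_matches_chamber_volume(self):
        # 2.5e5 cells/mL in a 1 mm^2 x 0.1 mm square -> lambda = 25
        geom = mc.ChamberGeometry(square_side_mm=1.0, grid_pitch_mm=0.25)
        out = mc.simulate_dilution_series(2.5e5, [1.0], geom,
                                          fields_per_sample=40, seed=1,
                                          microns_per_px=8.0)
        counts = [len(s.objects) for s, _ in out]
        assert np.mean(counts) == pytest.approx(25.0, abs=3.2)  # 4 SE band

    def test_expected_concentrations_non_increasing(self):
        geom = mc.ChamberGeometry(square_side_mm=0.25, grid_pitch_mm=0.1)
        out = mc.simulate_dilution_series(
            1e6, [1, 2, 4, 8, 16, 32, 64, 128], geom, fields_per_sample=1,
            seed=2, microns_per_px=4.0)
        concs = [c for _, c in out]
        assert all(a >= b for a, b in zip(concs, concs[1:]))
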