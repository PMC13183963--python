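"""Flow construction/integration, counting rules, hemocytometer
arithmetic, and instance metrics vs an exhaustive-matching oracle."""

import itertools

import numpy as np
import pytest

import microcyte as mc


def disc_map(centers, radius, shape=(64, 64)):
    lab = np.zeros(shape, np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for i, (cy, cx) in enumerate(centers, start=1):
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        lab[m & (lab == 0)] = i
    return lab


class TestMasksToFlows:
    def test_empty_map(self):
        ff = mc.masks_to_flows(np.zeros((32, 32), np.int32))
        assert not ff.prob.any()
        assert not ff.dy.any() and not ff.dx.any()

    def test_unit_norm_bound(self):
        lab = disc_map([(20, 20), (40, 44)], 9)
        ff = mc.masks_to_flows(lab)
        assert np.all(np.sqrt(ff.dy ** 2 + ff.dx ** 2) <= 1 + 1e-6)
        assert np.array_equal(ff.prob > 0, lab > 0)

    def test_flows_point_to_disc_centre(self):
        lab = disc_map([(32, 32)], 10)
        ff = mc.masks_to_flows(lab)
        ys, xs = np.nonzero(lab)
        toy, tox = 32 - ys, 32 - xs
        interior = toy ** 2 + tox ** 2 > 1
        dot = ff.dy[ys, xs] * toy + ff.dx[ys, xs] * tox
        assert (dot[interior] > 0).mean() >= 0.95

    def test_touching_discs_flow_sign_flips_at_contact(self):
        lab = disc_map([(32, 23), (32, 41)], 9)
        ff = mc.masks_to_flows(lab)
        # horizontal flow left of the contact line points left (negative),
        # right of it points right (positive)
        assert ff.dx[32, 20] < 0 or ff.dx[32, 26] < 0
        assert ff.dx[32, 44] > 0 or ff.dx[32, 38] > 0


class TestFollowFlows:
    def test_subthreshold_probability_gives_no_instances(self):
        ff = mc.FlowField(np.full((32, 32), 0.2), np.zeros((32, 32)),
                          np.zeros((32, 32)))
        assert mc.follow_flows(ff).n_instances == 0

    def test_touching_pair_separates_into_two(self):
        lab = disc_map([(32, 23), (32, 41)], 9)
        inst = mc.follow_flows(mc.masks_to_flows(lab))
        assert inst.n_instances == 2
        met = mc.instance_metrics(inst, mc.InstanceMap(lab), 0.5)
        assert met.f1 == 1.0

    def test_round_trip_on_rendered_scenes(self):
        tot_true = tot_absdev = 0
        ious = []
        for seed, n in [(0, 8), (1, 40), (2, 90)]:
            spec = mc.SceneSpec(width_px=256, height_px=256,
                                scene_kind="chamber", n_objects=n,
                                microns_per_px=2.0,
                                object_mix=[("cell", 18.0, 2.0, 1.0)],
                                seed=seed)
            s = mc.render_chamber_scene(spec)
            inst = mc.follow_flows(mc.masks_to_flows(s.instance_map))
            met = mc.instance_metrics(inst, mc.InstanceMap(s.instance_map), 0.5)
            tot_true += len(s.objects)
            tot_absdev += abs(inst.n_instances - len(s.objects))
            ious.append(met.mean_matched_iou)
        assert tot_absdev / tot_true <= 0.02
        assert np.mean(ious) >= 0.9


class TestCountCells:
    def test_empty_and_full_inside(self):
        assert mc.count_cells(mc.InstanceMap(np.zeros((32, 32), np.int32))) == 0
        lab = disc_map([(10, 10), (10, 30), (30, 10), (30, 30), (20, 20),
                        (45, 45), (50, 20), (20, 50), (50, 50), (40, 20)], 4)
        assert mc.count_cells(mc.InstanceMap(lab)) == 10

    def test_right_edge_object_excluded_left_edge_counted(self):
        lab = disc_map([(32, 40)], 6)
        # right ROI boundary passes through the object's centroid
        assert mc.count_cells(mc.InstanceMap(lab), roi=(0, 0, 64, 40)) == 0
        # left boundary through the object: top/left-include rule counts it
        assert mc.count_cells(mc.InstanceMap(lab), roi=(0, 40, 64, 64)) == 1

    def test_translation_invariance(self):
        lab = disc_map([(20, 20), (28, 34), (40, 45)], 5)
        shifted = np.roll(np.roll(lab, 7, axis=0), 5, axis=1)
        n0 = mc.count_cells(mc.InstanceMap(lab), roi=(5, 5, 55, 55))
        n1 = mc.count_cells(mc.InstanceMap(shifted), roi=(12, 10, 62, 60))
        assert n0 == n1

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            mc.count_cells(mc.InstanceMap(np.zeros((8, 8), np.int32)),
                           roi=(4, 4, 4, 8))


class TestConcentration:
    def test_zero_counts(self):
        geom = mc.ChamberGeometry()
        assert mc.concentration([0, 0, 0, 0], geom) == 0.0

    def test_standard_hemocytometer_formula(self):
        # mean 25 cells in a 1 mm^2 x 0.1 mm square = 1e-4 mL, dilution 2
        geom = mc.ChamberGeometry(dilution_factor=2.0)
        assert mc.concentration([25, 25, 25, 25], geom) == pytest.approx(5.0e5)
        geom1 = mc.ChamberGeometry()
        assert mc.concentration([100], geom1) == pytest.approx(1.0e6)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            mc.ChamberGeometry(square_side_mm=0.0)


def oracle_instance_prf(truth, pred, thr):
    """Exhaustive one-to-one matching maximising the number of pairs with
    IoU >= thr (feasible for <= 5 objects a side)."""
    iou = np.zeros((truth.max(), pred.max()))
    for i in range(1, truth.max() + 1):
        for j in range(1, pred.max() + 1):
            a, b = truth == i, pred == j
            u = (a | b).sum()
            iou[i - 1, j - 1] = (a & b).sum() / u if u else 0.0
    nt, npr = iou.shape
    best = 0
    if nt and npr:
        k = min(nt, npr)
        for subset in itertools.permutations(range(npr), k):
            tp = sum(1 for i in range(k) if iou[i % nt, subset[i]] >= thr) \
                if k <= nt else 0
            # enumerate truth-side subsets too
            best = max(best, tp)
        for tsub in itertools.combinations(range(nt), min(nt, npr)):
            for psub in itertools.permutations(range(npr), len(tsub)):
                tp = sum(1 for a, b in zip(tsub, psub) if iou[a, b] >= thr)
                best = max(best, tp)
    tp = best
    prec = tp / npr if npr else 0.0
    rec = tp / nt if nt else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


class TestInstanceMetrics:
    def test_perfect(self):
        lab = disc_map([(20, 20), (40, 40)], 7)
        m = mc.instance_metrics(lab, lab)
        assert (m.precision, m.recall, m.f1) == (1, 1, 1)

    def test_empty_prediction(self):
        lab = disc_map([(20, 20)], 7)
        m = mc.instance_metrics(np.zeros_like(lab), lab)
        assert m.recall == 0.0

    def test_matches_exhaustive_oracle_on_toys(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            nt = int(rng.integers(1, 5))
            npred = int(rng.integers(1, 5))
            truth = disc_map([(int(rng.integers(8, 56)), int(rng.integers(8, 56)))
                              for _ in range(nt)], 6, (64, 64))
            pred = disc_map([(int(rng.integers(8, 56)), int(rng.integers(8, 56)))
                             for _ in range(npred)], 6, (64, 64))
            if truth.max() == 0 or pred.max() == 0:
                continue
            m = mc.instance_metrics(pred, truth, 0.5)
            p, r, f = oracle_instance_prf(truth, pred, 0.5)
            assert m.precision == pytest.approx(p, abs=1e-10)
            assert m.recall == pytest.approx(r, abs=1e-10)
            assert m.f1 == pytest.approx(f, abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mc.instance_metrics(np.zeros((4, 4), int), np.zeros((5, 5), int))
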