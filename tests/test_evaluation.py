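"""OKS_pod metric, calibration, matching, AP, counts, dataset statistics."""

import math

import numpy as np
import pytest

from podkit.annotations import ImageAnnotation, PodAnnotation
from podkit.detections import DetectedPod, DetectionSet, from_annotation
from podkit.evaluation import (
    DEFAULT_LAMBDA,
    OKSParams,
    count_metrics,
    dataset_statistics,
    estimate_lambda,
    estimate_sigma,
    evaluate_detections,
    greedy_match,
    oks_original,
    oks_pod,
    pod_scale,
)
from podkit.synthetic import PerturbConfig, generate_scene, perturb_annotation

from conftest import toy_scene_config


class TestOKSPod:
    def test_perfect_localization(self, three_seed_pod):
        s = pod_scale(three_seed_pod)
        assert oks_pod(three_seed_pod.seeds, three_seed_pod, s) == pytest.approx(1.0)

    def test_closed_form_inversion(self):
        """d^2 = 2 * lambda_1 * s^2 * k^2 gives exactly exp(-1)."""
        gt = PodAnnotation(0, 1, [(50.0, 50.0)])
        params = OKSParams(sigma=0.05)
        s = 20.0
        d = math.sqrt(2.0 * params.lam[0] * s * s * params.k ** 2)
        val = oks_pod([(50.0 + d, 50.0)], gt, s, params)
        assert val == pytest.approx(math.exp(-1.0), abs=1e-5)

    def test_scale_invariance(self, three_seed_pod):
        params = OKSParams()
        pred = [(x + 3.0, y - 2.0) for x, y in three_seed_pod.seeds]
        s = pod_scale(three_seed_pod)
        base = oks_pod(pred, three_seed_pod, s, params)
        c = 3.7
        scaled_gt = PodAnnotation(
            0, 3, [(c * x, c * y) for x, y in three_seed_pod.seeds]
        )
        scaled_pred = [(c * x, c * y) for x, y in pred]
        assert oks_pod(scaled_pred, scaled_gt, c * s, params) == pytest.approx(
            base, abs=1e-5
        )

    def test_n_independence_with_equal_lambda(self):
        """With lambda_n equalized, equal per-seed distances give equal
        OKS_pod regardless of seed count (the correction's purpose)."""
        params = OKSParams(lam=(1.0, 1.0, 1.0, 1.0, 1.0))
        s, d = 15.0, 4.0
        vals = []
        for n in (1, 2, 3, 4, 5):
            seeds = [(20.0 * i, 0.0) for i in range(n)]
            gt = PodAnnotation(0, n, seeds)
            pred = [(x + d, y) for x, y in seeds]
            vals.append(oks_pod(pred, gt, s, params))
        assert max(vals) - min(vals) < 1e-5

    def test_strictly_decreasing_in_distance(self, three_seed_pod):
        params = OKSParams()
        s = pod_scale(three_seed_pod)
        vals = [
            oks_pod([(x + d, y) for x, y in three_seed_pod.seeds],
                    three_seed_pod, s, params)
            for d in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_missing_prediction_contributes_zero(self, three_seed_pod):
        s = pod_scale(three_seed_pod)
        full = three_seed_pod.seeds
        val = oks_pod([full[0], None, full[2]], three_seed_pod, s)
        assert val == pytest.approx(2.0 / 3.0)

    def test_invalid_scale(self, three_seed_pod):
        with pytest.raises(ValueError):
            oks_pod(three_seed_pod.seeds, three_seed_pod, 0.0)


class TestOKSOriginal:
    def test_all_visible_perfect(self, three_seed_pod):
        val = oks_original(
            three_seed_pod.seeds, three_seed_pod, 10.0, [0.1] * 3, [1, 1, 1]
        )
        assert val == pytest.approx(1.0)

    def test_one_visible_closed_form(self):
        gt = PodAnnotation(0, 2, [(0.0, 0.0), (50.0, 0.0)])
        s, k = 10.0, 0.2
        d = math.sqrt(2.0) * s * k
        val = oks_original([(d, 0.0), (99.0, 99.0)], gt, s, [k, k], [1, 0])
        assert val == pytest.approx(math.exp(-1.0), abs=1e-9)

    def test_invisible_ignored(self, three_seed_pod):
        pred = list(three_seed_pod.seeds)
        a = oks_original(pred, three_seed_pod, 10.0, [0.1] * 3, [1, 1, 0])
        pred[2] = (999.0, 999.0)
        b = oks_original(pred, three_seed_pod, 10.0, [0.1] * 3, [1, 1, 0])
        assert a == b

    def test_no_visible_signalled(self, three_seed_pod):
        with pytest.raises(ValueError):
            oks_original(three_seed_pod.seeds, three_seed_pod, 10.0, [0.1] * 3, [0, 0, 0])


class TestEstimateSigma:
    def test_identical_positions(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        sigma, k = estimate_sigma(pts, pts, 10.0)
        assert sigma == 0.0 and k == 0.0

    def test_constant_ratio(self):
        orig = np.zeros((5, 2))
        refined = np.stack([np.full(5, 3.0), np.zeros(5)], axis=1)
        sigma, k = estimate_sigma(refined, orig, 10.0)  # d/s = 0.3 everywhere
        assert sigma == pytest.approx(0.3)
        assert k == pytest.approx(0.6)

    def test_recovers_jitter_sd(self):
        """sigma estimated from n=1,000 jittered pairs recovers the known
        jitter scale within 3 standard errors.  With per-axis jitter sd c*s,
        the 2-D squared distance satisfies E[d^2/s^2] = 2 c^2, so the
        definition yields sigma = c * sqrt(2)."""
        rng = np.random.default_rng(11)
        n, s, rel_sd = 1000, 20.0, 0.05
        orig = rng.uniform(0, 500, size=(n, 2))
        refined = orig + rng.normal(0.0, rel_sd * s, size=(n, 2))
        sigma, k = estimate_sigma(refined, orig, s)
        expected = rel_sd * math.sqrt(2.0)
        # d^2/s^2 ~ rel_sd^2 * chi2_2: delta method on sqrt of the mean
        se_sigma = rel_sd / math.sqrt(2.0 * n)
        assert abs(sigma - expected) <= 3 * se_sigma
        assert k == pytest.approx(2.0 * sigma)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros((0, 2)), np.zeros((0, 2)), 1.0)


def _square_pod(pod_id, n, side, origin=(0.0, 0.0)):
    """n-seeded pod whose padded bbox area is controlled via its span."""
    x0, y0 = origin
    if n == 1:
        seeds = [(x0, y0)]
    else:
        seeds = [(x0 + side * i / (n - 1), y0 + side * i / (n - 1)) for i in range(n)]
    return PodAnnotation(pod_id, n, seeds)


class TestEstimateLambda:
    def test_lambda3_is_one_and_defaults(self):
        lam, missing = estimate_lambda([])
        assert lam == list(DEFAULT_LAMBDA)
        assert lam[2] == 1.0
        assert set(missing) == {1, 2, 4, 5}

    def test_proportional_areas_recovered(self):
        """Pods built so the n-seeded bbox area is proportional to n yield
        lambda = (3, 1.5, 1, 0.75, 0.6)."""
        pad = 2.0
        # a 1-seeded pod's padded bbox area is pinned at (2*pad)^2, so
        # proportionality is anchored there: area(n) = (2*pad)^2 * n
        base_area = (2 * pad) ** 2
        anns = []
        for i in range(4):
            pods = []
            for n in range(1, 6):
                side = math.sqrt(base_area * n) - 2 * pad
                pods.append(_square_pod(n, n, side, origin=(50.0 * n, 10.0 * i)))
            anns.append(ImageAnnotation(f"i{i}", 1000, 1000, pods))
        lam, missing = estimate_lambda(anns, pad=pad)
        assert missing == []
        expected = [3.0, 1.5, 1.0, 0.75, 0.6]
        assert np.allclose(lam, expected, atol=1e-6)

    def test_reference_defaults(self):
        assert DEFAULT_LAMBDA == (4.752, 1.353, 1.0, 0.782, 0.673)


class TestGreedyMatch:
    def test_identical_all_matched(self, simple_annotation):
        dets = from_annotation(simple_annotation)
        table = greedy_match(dets, simple_annotation.pods)
        assert all(m.gt_index is not None for m in table.detections)
        assert all(m.oks == pytest.approx(1.0) for m in table.detections)

    def test_argmax_rule(self):
        gts = [
            PodAnnotation(0, 1, [(0.0, 0.0)]),
            PodAnnotation(1, 1, [(6.0, 0.0)]),
        ]
        det = DetectionSet("i", [DetectedPod([(1.0, 0.0)], [1.0], 1.0)])
        table = greedy_match(det, gts, OKSParams(sigma=0.2, bbox_pad=8.0), 0.1)
        assert table.detections[0].gt_index == 0

    def test_matches_brute_force_on_small_instances(self):
        """Greedy matching equals an independent brute-force enumeration on
        random instances with <= 4 detections and <= 4 ground truths."""
        rng = np.random.default_rng(21)
        params = OKSParams(sigma=0.1, bbox_pad=5.0)
        for trial in range(60):
            n_gt = int(rng.integers(1, 5))
            n_det = int(rng.integers(1, 5))
            gts = [
                PodAnnotation(j, 2, [tuple(p), tuple(p + rng.uniform(5, 15, 2))])
                for j, p in enumerate(rng.uniform(0, 80, size=(n_gt, 2)))
            ]
            dets = DetectionSet(
                "t",
                [
                    DetectedPod(
                        [tuple(p), tuple(p + rng.uniform(5, 15, 2))],
                        [1.0, 1.0],
                        float(rng.uniform(0.1, 1.0)),
                    )
                    for p in rng.uniform(0, 80, size=(n_det, 2))
                ],
            )
            table = greedy_match(dets, gts, params, 0.3)

            # independent oracle: explicit loops, no shared code path
            taken = set()
            expected = []
            order = sorted(range(n_det), key=lambda i: -dets.pods[i].pod_score)
            for i in order:
                best, best_val = None, 0.3
                for j in range(n_gt):
                    if j in taken:
                        continue
                    s = pod_scale(gts[j], 5.0)
                    val = oks_pod(dets.pods[i].seeds, gts[j], s, params)
                    if val > best_val:
                        best, best_val = j, val
                if best is not None:
                    taken.add(best)
                expected.append((i, best))
            got = {}
            for rank, i in enumerate(order):
                got[i] = table.detections[rank].gt_index
            assert got == dict(expected)


class TestAveragePrecision:
    def test_perfect_detections(self, simple_annotation):
        dets = [from_annotation(simple_annotation)]
        rep = evaluate_detections(dets, [simple_annotation])
        assert rep.ap == pytest.approx(1.0)
        assert rep.ap50 == pytest.approx(1.0)

    def test_one_tp_one_fp_gives_half(self):
        gts = ImageAnnotation(
            "i", 300, 300,
            [
                PodAnnotation(0, 1, [(50.0, 50.0)]),
                PodAnnotation(1, 1, [(250.0, 250.0)]),
            ],
        )
        dets = DetectionSet(
            "i",
            [
                DetectedPod([(50.0, 50.0)], [1.0], 0.9),  # TP
                DetectedPod([(150.0, 150.0)], [1.0], 0.8),  # FP
            ],
        )
        rep = evaluate_detections([dets], [gts], thresholds=[0.5])
        assert rep.ap50 == pytest.approx(0.5)

    def test_removing_low_score_fp_never_decreases_ap(self, simple_annotation):
        dets = from_annotation(simple_annotation)
        with_fp = DetectionSet(
            dets.image_id,
            dets.pods + [DetectedPod([(5.0, 5.0)], [0.1], 0.05)],
        )
        ap_with = evaluate_detections([with_fp], [simple_annotation], thresholds=[0.5]).ap50
        ap_without = evaluate_detections([dets], [simple_annotation], thresholds=[0.5]).ap50
        assert ap_without >= ap_with

    def test_per_type_restriction(self, simple_annotation):
        dets = from_annotation(simple_annotation)
        rep = evaluate_detections([dets], [simple_annotation], thresholds=[0.5])
        assert rep.per_type[1] == pytest.approx(1.0)
        assert rep.per_type[2] == pytest.approx(1.0)
        assert rep.per_type[3] == pytest.approx(1.0)
        assert rep.per_type[4] is None  # no 4-seeded ground truth

    def test_ap_decreases_with_jitter(self):
        """AP falls monotonically as detector localization noise grows."""
        scenes = [generate_scene(toy_scene_config(900 + i)) for i in range(6)]
        gts = [a for _, a in scenes]
        aps = []
        for loc_sd in (0.0, 1.0, 2.5, 5.0, 9.0):
            dets = [
                perturb_annotation(a, PerturbConfig(loc_sd=loc_sd, rng_seed=33))
                for a in gts
            ]
            rep = evaluate_detections(dets, gts, OKSParams(sigma=0.05, bbox_pad=4.0),
                                      thresholds=[0.5])
            aps.append(rep.ap50)
        assert all(a >= b for a, b in zip(aps, aps[1:]))
        assert aps[0] == pytest.approx(1.0)


class TestCountMetrics:
    def test_identical_series(self):
        rep = count_metrics([3, 5, 7], [3, 5, 7])
        assert rep.mae == 0.0 and rep.pcc == pytest.approx(1.0)

    def test_hand_computed_mae(self):
        rep = count_metrics([1, 2, 3], [2, 2, 5])
        assert rep.mae == pytest.approx(1.0)

    def test_shift_property(self):
        rep = count_metrics([4, 5, 6], [1, 2, 3])
        assert rep.mae == pytest.approx(3.0)
        assert rep.pcc == pytest.approx(1.0)

    def test_zero_variance_signalled(self):
        rep = count_metrics([2, 2, 2], [1, 2, 3])
        assert math.isnan(rep.pcc)


class TestDatasetStatistics:
    def test_empty(self):
        s = dataset_statistics([])
        assert s["n_images"] == 0 and s["total_pods"] == 0

    def test_round_half_up_two_decimals(self):
        # 3 images, 7 pods -> 2.333... -> 2.33 ; 8 pods -> 2.67 ; .455 -> .46
        anns = [
            ImageAnnotation(
                f"i{j}", 100, 100,
                [
                    PodAnnotation(i, 1, [(10.0 * i + 5, 50.0)])
                    for i in range(k)
                ],
            )
            for j, k in enumerate((3, 2, 2))
        ]
        s = dataset_statistics(anns)
        assert s["avg_pods_per_image"] == 2.33
        assert s["total_seeds"] == 7

    def test_histogram_by_type(self, simple_annotation):
        s = dataset_statistics([simple_annotation])
        assert s["pods_by_type"] == {1: 1, 2: 1, 3: 1, 4: 0, 5: 0}
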