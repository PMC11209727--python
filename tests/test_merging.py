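"""DTW shape matching, dedup, border candidates, and full-frame merging."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podkit.cropping import CropWindow, crop_annotation, remap_to_full, tile_image
from podkit.detections import DetectedPod, DetectionSet, from_annotation
from podkit.merging import (
    DTWResult,
    MergeConfig,
    border_candidates,
    dedupe_seeds,
    dtw_shape_distance,
    merge_full,
    merge_pair,
)
from podkit.synthetic import SceneConfig, generate_scene, split_scene_across_windows

from conftest import toy_scene_config


def brute_force_dtw(seq_a, seq_b):
    """Enumerate every monotone alignment path; return the minimal total
    cost and its per-step-normalized value.  Independent of the DP code."""
    na, nb = len(seq_a), len(seq_b)

    def dist(i, j):
        return float(np.linalg.norm(np.asarray(seq_a[i]) - np.asarray(seq_b[j])))

    best = (float("inf"), None)

    def walk(i, j, cost, length):
        cost = cost + dist(i, j)
        length += 1
        if (i, j) == (na - 1, nb - 1):
            nonlocal best
            if cost < best[0]:
                best = (cost, length)
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < na and j + dj < nb:
                walk(i + di, j + dj, cost, length)

    walk(0, 0, 0.0, 0)
    return best


class TestDTW:
    def test_identical_sequences(self):
        seq = [(0.0, 0.0), (5.0, 5.0), (10.0, 10.0)]
        res = dtw_shape_distance(seq, seq)
        assert res.distance == 0.0
        assert res.path == [(0, 0), (1, 1), (2, 2)]

    def test_two_to_one_alignment(self):
        res = dtw_shape_distance([(0.0, 0.0), (0.0, 10.0)], [(0.0, 0.0)])
        assert res.distance == pytest.approx(5.0)
        assert res.path == [(0, 0), (1, 0)]

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a = [tuple(p) for p in rng.uniform(0, 50, size=(4, 2))]
        b = [tuple(p) for p in rng.uniform(0, 50, size=(3, 2))]
        assert dtw_shape_distance(a, b).distance == pytest.approx(
            dtw_shape_distance(b, a).distance
        )

    def test_path_monotone_and_complete(self):
        rng = np.random.default_rng(4)
        a = [tuple(p) for p in rng.uniform(0, 50, size=(5, 2))]
        b = [tuple(p) for p in rng.uniform(0, 50, size=(2, 2))]
        path = dtw_shape_distance(a, b).path
        assert path[0] == (0, 0) and path[-1] == (4, 1)
        for (i0, j0), (i1, j1) in zip(path, path[1:]):
            assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}

    def test_matches_brute_force_enumeration(self):
        """DP distance equals exhaustive path enumeration on all length-<=3
        sequence pairs from a fixed random pool."""
        rng = np.random.default_rng(9)
        pool = rng.uniform(0, 30, size=(10, 2))
        for na, nb in itertools.product((1, 2, 3), repeat=2):
            for trial in range(5):
                idx = rng.integers(0, 10, size=na + nb)
                a = [tuple(pool[i]) for i in idx[:na]]
                b = [tuple(pool[i]) for i in idx[na:]]
                cost, length = brute_force_dtw(a, b)
                res = dtw_shape_distance(a, b)
                assert res.distance * len(res.path) == pytest.approx(cost, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_shape_distance([], [(0.0, 0.0)])


def _pod(seeds, score, widx=-1):
    return DetectedPod(
        seeds=[(float(x), float(y)) for x, y in seeds],
        seed_scores=[score] * len(seeds),
        pod_score=score,
        window_index=widx,
    )


class TestDedup:
    def test_identical_pods_keep_best(self):
        ds = DetectionSet("i", [
            _pod([(10, 10), (20, 20)], 0.9),
            _pod([(10.5, 10), (20.5, 20)], 0.7),
        ])
        out = dedupe_seeds(ds, dist_thresh=5.0)
        assert len(out) == 1 and out.pods[0].pod_score == 0.9

    def test_distant_pods_survive(self):
        ds = DetectionSet("i", [
            _pod([(10, 10)], 0.9),
            _pod([(100, 100)], 0.7),
        ])
        assert len(dedupe_seeds(ds, 5.0)) == 2

    def test_different_n_not_duplicates(self):
        ds = DetectionSet("i", [
            _pod([(10, 10), (20, 20)], 0.9),
            _pod([(10, 10)], 0.8),
        ])
        assert len(dedupe_seeds(ds, 5.0)) == 2

    def test_transitive_chain_matches_graph_components(self):
        """A chain of mutually-close duplicates collapses exactly as the
        connected components of the duplicate graph (networkx oracle)."""
        rng = np.random.default_rng(17)
        pods = []
        for c in range(4):  # 4 clusters of 3 near-identical pods
            base = rng.uniform(0, 300, size=2)
            for j in range(3):
                seeds = [tuple(base + [k * 15, 0] + rng.uniform(-1, 1, 2)) for k in range(2)]
                pods.append(_pod(seeds, float(rng.uniform(0.1, 1.0))))
        ds = DetectionSet("i", pods)
        out = dedupe_seeds(ds, dist_thresh=6.0)

        g = nx.Graph()
        g.add_nodes_from(range(len(pods)))
        for i in range(len(pods)):
            for j in range(i + 1, len(pods)):
                a, b = pods[i], pods[j]
                if a.n == b.n and all(
                    np.linalg.norm(np.subtract(p, q)) < 6.0
                    for p, q in zip(a.seeds, b.seeds)
                ):
                    g.add_edge(i, j)
        expected = sorted(
            max((pods[i] for i in comp), key=lambda p: p.pod_score).seeds
            for comp in nx.connected_components(g)
        )
        assert sorted(p.seeds for p in out.pods) == expected


class TestBorderCandidates:
    windows = [CropWindow(0, 0, 400, 400, "i"), CropWindow(300, 0, 700, 400, "i")]

    def test_interior_pod_in_no_pair(self):
        dets = [
            DetectionSet("i", [_pod([(50, 50)], 0.9, 0)]),
            DetectionSet("i", [_pod([(680, 200)], 0.8, 1)]),
        ]
        assert border_candidates(dets, self.windows, 50.0) == []

    def test_split_fixture_forms_pair(self):
        dets = [
            DetectionSet("i", [_pod([(340, 100), (352, 100)], 0.9, 0)]),
            DetectionSet("i", [_pod([(364, 100)], 0.8, 1)]),
        ]
        pairs = border_candidates(dets, self.windows, 100.0)
        assert len(pairs) == 1

    def test_disjoint_windows_no_pairs(self):
        far = [CropWindow(0, 0, 100, 100, "i"), CropWindow(500, 500, 600, 600, "i")]
        dets = [
            DetectionSet("i", [_pod([(50, 50)], 0.9, 0)]),
            DetectionSet("i", [_pod([(550, 550)], 0.8, 1)]),
        ]
        assert border_candidates(dets, far, 20.0) == []


class TestMergePair:
    def test_self_merge_is_idempotent(self):
        pod = _pod([(10, 10), (22, 10), (34, 10)], 0.8)
        path = [(i, i) for i in range(3)]
        out = merge_pair(pod, pod, path, match_radius=5.0)
        assert out.n == 3
        assert np.allclose(out.seeds, pod.seeds)

    def test_disjoint_parts_concatenate(self):
        a = _pod([(10, 10), (22, 10)], 0.9)
        b = _pod([(34, 10)], 0.8)
        out = merge_pair(a, b, path=None, match_radius=5.0)
        assert out.n == 3
        assert out.seeds[0] == (10.0, 10.0) and out.seeds[-1] == (34.0, 10.0)

    def test_two_matched_pairs_make_five(self):
        """4-seed and 3-seed fragments sharing 2 duplicated seeds merge to
        the 5-seed cap without dropping anything."""
        xs = [10, 22, 34, 46, 58]
        a = _pod([(x, 10) for x in xs[:4]], 0.9)
        b = _pod([(x + 0.5, 10) for x in xs[2:]], 0.7)
        dtw = dtw_shape_distance(a.seeds, b.seeds)
        out = merge_pair(a, b, dtw.path, match_radius=5.0)
        assert out.n == 5

    def test_cap_drops_lowest_confidence(self, caplog):
        a = DetectedPod([(10.0 * i, 0.0) for i in range(1, 6)], [0.9] * 5, 0.9)
        b = DetectedPod([(100.0, 0.0), (110.0, 0.0)], [0.2, 0.2], 0.2)
        out = merge_pair(a, b, path=None, match_radius=1.0)
        assert out.n == 5
        assert all(s == 0.9 for s in out.seed_scores)


class TestMergeFull:
    def test_single_window_equals_dedup(self):
        ds = DetectionSet("i", [
            _pod([(10, 10), (22, 10)], 0.9, 0),
            _pod([(10.5, 10), (22.5, 10)], 0.4, 0),
            _pod([(200, 200)], 0.8, 0),
        ])
        window = [CropWindow(0, 0, 400, 400, "i")]
        cfg = MergeConfig()
        out = merge_full([ds], window, cfg)
        expected = dedupe_seeds(ds, cfg.dup_radius)
        assert sorted(p.seeds for p in out.pods) == sorted(p.seeds for p in expected.pods)

    def test_split_pod_fixtures_recover_truth(self):
        """Tiled perfect per-crop detection merges back to the exact truth
        on seeded scenes."""
        for seed in range(8):
            cfg = SceneConfig(width=700, height=700, pods_per_image=8, rng_seed=seed)
            _, ann = generate_scene(cfg)
            windows = tile_image(700, 700, 400, 300)
            dets = [
                remap_to_full(from_annotation(crop_annotation(ann, w)), w, window_index=i)
                for i, w in enumerate(windows)
            ]
            merged = merge_full(dets, windows, MergeConfig(border_margin=100))
            assert len(merged) == ann.n_pods
            assert merged.n_seeds == ann.n_seeds

    def test_parallel_pods_not_merged(self):
        """Two genuinely distinct parallel pods closer than dist_thresh but
        with dissimilar shapes stay separate."""
        a = _pod([(100, 100), (112, 100), (124, 100)], 0.9, 0)
        # parallel pod, 8 px away vertically, opposite curvature far ends
        b = _pod([(100, 108), (112, 128), (124, 148)], 0.8, 1)
        windows = [CropWindow(0, 0, 130, 400, "i"), CropWindow(90, 0, 220, 400, "i")]
        out = merge_full(
            [DetectionSet("i", [a]), DetectionSet("i", [b])],
            windows,
            MergeConfig(dist_thresh=10.0, shape_thresh=15.0, border_margin=40.0),
        )
        assert len(out) == 2

    def test_idempotent(self):
        cfg = SceneConfig(width=700, height=700, pods_per_image=6, rng_seed=5)
        _, ann = generate_scene(cfg)
        windows = tile_image(700, 700, 400, 300)
        dets = [
            remap_to_full(from_annotation(crop_annotation(ann, w)), w, window_index=i)
            for i, w in enumerate(windows)
        ]
        mc = MergeConfig(border_margin=100)
        once = merge_full(dets, windows, mc)
        twice = merge_full([once], [CropWindow(0, 0, 700, 700, "i")], mc)
        assert sorted(p.seeds for p in once.pods) == sorted(p.seeds for p in twice.pods)

    def test_seed_count_never_increases(self):
        for seed in range(5):
            cfg = toy_scene_config(seed, width=700, height=700, pods_per_image=8,
                                   seed_spacing=25, seed_radius=8)
            _, ann = generate_scene(cfg)
            windows = tile_image(700, 700, 400, 300)
            dets = [
                remap_to_full(from_annotation(crop_annotation(ann, w)), w, window_index=i)
                for i, w in enumerate(windows)
            ]
            total_in = sum(d.n_seeds for d in dets)
            merged = merge_full(dets, windows, MergeConfig(border_margin=100))
            assert merged.n_seeds <= total_in

    def test_line_split_fixture_roundtrip(self):
        """Line-split fragments (no duplicated seeds) merge back when the
        seed spacing sits inside the pair gate."""
        for seed in range(8):
            cfg = SceneConfig(width=400, height=400, pods_per_image=5,
                              seed_spacing=8, spacing_jitter=0.5, seed_radius=3,
                              min_seed_separation=12, rng_seed=seed)
            _, ann = generate_scene(cfg)
            a, b = split_scene_across_windows(ann, "v", 200.0)
            windows = [CropWindow(0, 0, 230, 400, "s"), CropWindow(170, 0, 400, 400, "s")]
            merged = merge_full([a, b], windows,
                                MergeConfig(border_margin=60, shape_thresh=24.0))
            assert len(merged) == ann.n_pods
            assert merged.n_seeds == ann.n_seeds
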