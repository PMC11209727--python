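"""Merging per-tile detections into whole-plant results.

Tiled inference detects each pod independently per crop, so a pod lying in
the overlap of two windows is detected twice, and a pod crossing a window
edge is detected as two partial chains.  The merge procedure works in the
full-image frame:

1. *Dedup*: pods that duplicate each other (same seed count, all
   ordinal-wise seed distances below ``dist_thresh``) are collapsed onto the
   highest-scoring copy.
2. *Border candidates*: only pods with a seed inside the margin bands around
   shared window edges (the M regions) can be fragments of one pod.
3. For each candidate pair with a seed pair closer than ``dist_thresh``
   (processed in ascending seed-pair distance): a 1-seeded fragment is
   merged directly; otherwise the two chains are compared by dynamic time
   warping (Euclidean local cost, path-normalized), and merged iff the shape
   distance is below ``shape_thresh``, the DTW path supplying the seed
   correspondence.  Merging repeats to a fixed point.

Merged chains are re-ordered by projection onto their principal axis; the
base (ordinal 1) is taken from the fragment whose own base seed had the
higher confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from podkit.annotations import MAX_SEEDS
from podkit.cropping import CropWindow
from podkit.detections import DetectedPod, DetectionSet

logger = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    """Thresholds of the merge procedure (pixels, full-image frame)."""

    dist_thresh: float = 10.0
    shape_thresh: float = 15.0
    border_margin: float = 100.0  # crop_size - stride: the overlap width
    dup_radius: float | None = None  # duplicated-seed match radius; default dist_thresh/2

    def __post_init__(self) -> None:
        if self.dup_radius is None:
            # duplicated detections of one seed sit nearly on top of each
            # other; half the pair gate keeps adjacent distinct seeds apart
            self.dup_radius = 0.5 * self.dist_thresh
        if min(self.dist_thresh, self.shape_thresh, self.border_margin,
               self.dup_radius) <= 0:
            raise ValueError("all merge thresholds must be positive")


@dataclass
class DTWResult:
    """Path-normalized DTW distance and the alignment path (0-based pairs)."""

    distance: float
    path: list[tuple[int, int]]


def dtw_shape_distance(
    seq_a: list[tuple[float, float]], seq_b: list[tuple[float, float]]
) -> DTWResult:
    """Classical DTW between two ordered seed chains.

    Local cost is the Euclidean distance between seed coordinates; steps are
    {(1,0), (0,1), (1,1)}; the reported distance is the optimal path cost
    divided by the path length, so thresholds are comparable across pod
    lengths.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("DTW requires non-empty sequences")
    A = np.asarray(seq_a, float)
    B = np.asarray(seq_b, float)
    na, nb = len(A), len(B)
    local = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)

    INF = float("inf")
    acc = np.full((na + 1, nb + 1), INF)
    acc[0, 0] = 0.0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            acc[i, j] = local[i - 1, j - 1] + min(
                acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            )
    # backtrack
    path = []
    i, j = na, nb
    while i >= 1 and j >= 1:
        path.append((i - 1, j - 1))
        step = int(np.argmin([acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]]))
        if step == 0:
            i, j = i - 1, j - 1
        elif step == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return DTWResult(distance=float(acc[na, nb]) / len(path), path=path)


# ---------------------------------------------------------------------------
# Dedup
# ---------------------------------------------------------------------------

def _pods_duplicate(a: DetectedPod, b: DetectedPod, dist_thresh: float) -> bool:
    if a.n != b.n:
        return False
    pa, pb = np.asarray(a.seeds), np.asarray(b.seeds)
    return bool(np.all(np.linalg.norm(pa - pb, axis=1) < dist_thresh))


def dedupe_seeds(dets: DetectionSet, dist_thresh: float) -> DetectionSet:
    """Collapse duplicate pods, keeping the highest-scoring copy per group.

    Duplication (same n, all ordinal-wise seed distances < ``dist_thresh``)
    is grouped transitively, so a chain of mutually close copies collapses
    onto its single best-scoring member.
    """
    pods = dets.pods
    parent = list(range(len(pods)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pods)):
        for j in range(i + 1, len(pods)):
            if _pods_duplicate(pods[i], pods[j], dist_thresh):
                parent[find(i)] = find(j)

    best: dict[int, DetectedPod] = {}
    order: list[int] = []
    for i, pod in enumerate(pods):
        r = find(i)
        if r not in best:
            order.append(r)
            best[r] = pod
        elif pod.pod_score > best[r].pod_score:
            best[r] = pod
    kept = [best[r] for r in order]
    if len(kept) < len(pods):
        logger.info("dedupe: %d -> %d pods", len(pods), len(kept))
    return DetectionSet(dets.image_id, kept)


# ---------------------------------------------------------------------------
# Border candidates
# ---------------------------------------------------------------------------

def _band(
    wa: CropWindow, wb: CropWindow, margin: float
) -> tuple[float, float, float, float] | None:
    """Intersection of the two windows each expanded by ``margin``; the
    region around their shared edge where fragments of one pod can live."""
    x0 = max(wa.x_min - margin, wb.x_min - margin)
    y0 = max(wa.y_min - margin, wb.y_min - margin)
    x1 = min(wa.x_max + margin, wb.x_max + margin)
    y1 = min(wa.y_max + margin, wb.y_max + margin)
    if x0 >= x1 or y0 >= y1:
        return None
    return (x0, y0, x1, y1)


def _in_band(pod: DetectedPod, band: tuple[float, float, float, float]) -> bool:
    x0, y0, x1, y1 = band
    return any(x0 <= x < x1 and y0 <= y < y1 for x, y in pod.seeds)


def border_candidates(
    dets_per_window: list[DetectionSet],
    windows: list[CropWindow],
    border_margin: float,
) -> list[tuple[DetectedPod, DetectedPod]]:
    """Pairs of pods from different windows that could be one pod.

    Detections must already be in the full-image frame.  A pair qualifies
    when both pods have at least one seed inside the margin band around a
    shared edge of their two source windows.
    """
    if len(dets_per_window) != len(windows):
        raise ValueError("one DetectionSet per window required")
    pairs = []
    for wi in range(len(windows)):
        for wj in range(wi + 1, len(windows)):
            band = _band(windows[wi], windows[wj], border_margin)
            if band is None:
                continue
            for pa in dets_per_window[wi].pods:
                if not _in_band(pa, band):
                    continue
                for pb in dets_per_window[wj].pods:
                    if _in_band(pb, band):
                        pairs.append((pa, pb))
    return pairs


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

def merge_pair(
    pod_a: DetectedPod,
    pod_b: DetectedPod,
    path: list[tuple[int, int]] | None = None,
    match_radius: float = 10.0,
) -> DetectedPod:
    """Merge two pod fragments using a DTW alignment path.

    Path-aligned seed pairs closer than ``match_radius`` are the same
    physical seed and are averaged with score weights; all other seeds are
    kept.  Without a path (the direct merge of a 1-seeded fragment) the
    same sub-radius matching runs over all seed pairs, so duplicated
    boundary seeds still collapse.  The merged chain is ordered by
    projection onto its principal
    axis, oriented so the fragment whose base seed had the higher confidence
    supplies the base end.  The seed count is capped at 5; excess
    lowest-confidence seeds are dropped with a warning.
    """
    A = np.asarray(pod_a.seeds, float)
    B = np.asarray(pod_b.seeds, float)
    sa = np.asarray(pod_a.seed_scores, float)
    sb = np.asarray(pod_b.seed_scores, float)

    matched_a: dict[int, int] = {}
    pair_iter = (
        path if path
        else [(i, j) for i in range(len(A)) for j in range(len(B))]
    )
    # keep, per seed, only its closest sub-radius alignment (injective)
    candidates = sorted(
        ((float(np.linalg.norm(A[i] - B[j])), i, j) for i, j in pair_iter),
        key=lambda t: t[0],
    )
    used_b: set[int] = set()
    for d, i, j in candidates:
        if d >= match_radius or i in matched_a or j in used_b:
            continue
        matched_a[i] = j
        used_b.add(j)

    merged_xy: list[np.ndarray] = []
    merged_sc: list[float] = []
    for i in range(len(A)):
        if i in matched_a:
            j = matched_a[i]
            w = sa[i] + sb[j]
            merged_xy.append((sa[i] * A[i] + sb[j] * B[j]) / w)
            merged_sc.append(float(max(sa[i], sb[j])))
        else:
            merged_xy.append(A[i])
            merged_sc.append(float(sa[i]))
    used_b = set(matched_a.values())
    for j in range(len(B)):
        if j not in used_b:
            merged_xy.append(B[j])
            merged_sc.append(float(sb[j]))

    pts = np.asarray(merged_xy)
    # chain order: projection onto the principal axis of the merged cloud
    centred = pts - pts.mean(axis=0)
    if len(pts) > 1:
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt[0]
    else:
        proj = np.zeros(1)
    order = np.argsort(proj, kind="stable")

    # base end from the fragment with the more confident ordinal-1 seed
    base_xy = A[0] if sa[0] >= sb[0] else B[0]
    first, last = pts[order[0]], pts[order[-1]]
    if np.linalg.norm(last - base_xy) < np.linalg.norm(first - base_xy):
        order = order[::-1]

    seeds = [(float(x), float(y)) for x, y in pts[order]]
    scores = [merged_sc[k] for k in order]
    if len(seeds) > MAX_SEEDS:
        logger.warning(
            "merged pod has %d seeds; dropping %d lowest-confidence",
            len(seeds), len(seeds) - MAX_SEEDS,
        )
        while len(seeds) > MAX_SEEDS:
            k = int(np.argmin(scores))
            del seeds[k], scores[k]
    return DetectedPod(
        seeds=seeds,
        seed_scores=scores,
        pod_score=float(np.mean(scores)),
        window_index=-1,
    )


# ---------------------------------------------------------------------------
# Full merge
# ---------------------------------------------------------------------------

def _absorbed(a: DetectedPod, b: DetectedPod, dup_radius: float) -> bool:
    """True when the shorter pod is entirely a duplicate of part of the longer
    (every seed has its own sub-radius counterpart): same physical pod, no
    shape test needed."""
    short, long_ = (a, b) if a.n <= b.n else (b, a)
    ps = np.asarray(short.seeds)
    pl = np.asarray(long_.seeds)
    d = np.linalg.norm(ps[:, None] - pl[None, :], axis=2)
    taken: set[int] = set()
    for i in range(len(ps)):
        js = [j for j in np.argsort(d[i]) if j not in taken and d[i, j] < dup_radius]
        if not js:
            return False
        taken.add(js[0])
    return True


def _min_seed_distance(a: DetectedPod, b: DetectedPod) -> float:
    pa, pb = np.asarray(a.seeds), np.asarray(b.seeds)
    return float(np.min(np.linalg.norm(pa[:, None] - pb[None, :], axis=2)))


def merge_full(
    dets_per_window: list[DetectionSet],
    windows: list[CropWindow],
    config: MergeConfig | None = None,
) -> DetectionSet:
    """Combine per-window detections (already in the full frame) into one set.

    Runs dedup, then candidate-pair merging in ascending seed-pair distance,
    iterating the whole procedure to a fixed point.  A pod fragment can keep
    absorbing further fragments from other windows; pods originating from
    the same window are never merged with each other.
    """
    config = config or MergeConfig()
    image_id = dets_per_window[0].image_id if dets_per_window else ""

    entries: list[tuple[DetectedPod, frozenset[int]]] = []
    for widx, ds in enumerate(dets_per_window):
        for pod in ds.pods:
            entries.append((pod, frozenset([widx])))

    for _ in range(20):  # fixed-point iteration; bounded for safety
        deduped = dedupe_seeds(
            DetectionSet(image_id, [p for p, _ in entries]), config.dup_radius
        )
        kept_ids = {id(p) for p in deduped.pods}
        entries = [(p, w) for p, w in entries if id(p) in kept_ids]

        # candidate pairs: disjoint window sets, both in a shared border band
        cand: list[tuple[float, int, int]] = []
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                pi, wi = entries[i]
                pj, wj = entries[j]
                if wi & wj:
                    continue
                if not _cross_band(pi, pj, wi, wj, windows, config.border_margin):
                    continue
                d = _min_seed_distance(pi, pj)
                if d < config.dist_thresh:
                    cand.append((d, i, j))
        cand.sort(key=lambda t: t[0])

        merged_away: set[int] = set()
        new_entries = list(entries)
        changed = False
        for d, i, j in cand:
            if i in merged_away or j in merged_away:
                continue
            pi, wi = new_entries[i]
            pj, wj = new_entries[j]
            if pi.n == 1 or pj.n == 1 or _absorbed(pi, pj, config.dup_radius):
                merged = merge_pair(pi, pj, path=None,
                                    match_radius=config.dup_radius)
            else:
                dtw = dtw_shape_distance(pi.seeds, pj.seeds)
                if dtw.distance >= config.shape_thresh:
                    continue
                merged = merge_pair(
                    pi, pj, path=dtw.path, match_radius=config.dup_radius
                )
            new_entries[i] = (merged, wi | wj)
            merged_away.add(j)
            changed = True
        entries = [e for k, e in enumerate(new_entries) if k not in merged_away]
        if not changed:
            break

    return DetectionSet(image_id, [p for p, _ in entries])


def _cross_band(
    pa: DetectedPod,
    pb: DetectedPod,
    wins_a: frozenset[int],
    wins_b: frozenset[int],
    windows: list[CropWindow],
    margin: float,
) -> bool:
    for wi in wins_a:
        for wj in wins_b:
            band = _band(windows[wi], windows[wj], margin)
            if band is not None and _in_band(pa, band) and _in_band(pb, band):
                return True
    return False
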