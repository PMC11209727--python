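"""Detection evaluation: OKS_pod similarity, calibration, AP, and count metrics.

Keypoint detections are scored with an object-keypoint-similarity (OKS)
variant adapted to pods.  The classical OKS normalizes localization error by
object scale s and a per-keypoint falloff constant k_i.  For pods, bounding
box area grows with the seed count n as well as with scale, so a per-type
area-correction coefficient lambda_n divides the squared error:

    OKS_pod = (1/n) * sum_i exp( -d_i^2 / (2 * lambda_n * s^2 * k^2) )

with k = 2*sigma, sigma the relative annotation-error scale
(sigma^2 = E[d^2/s^2], estimated from relabelled images), and lambda_n the
mean bounding-box-area ratio of 3-seeded to n-seeded pods (lambda_3 = 1).
With lambda equalized, pods of different seed counts are scored by Gaussians
of identical standard deviation, which is the point of the correction.

AP follows the COCO convention: greedy score-ordered matching, all-point PR
interpolation, mean over OKS thresholds 0.50:0.05:0.95, AP50 reported
separately, plus per-type AP for n = 1..4.  Whole-plant counting quality is
summarized by MAE and Pearson correlation over images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np

from podkit.annotations import ImageAnnotation, PodAnnotation, pod_bounding_box
from podkit.detections import DetectionSet

logger = logging.getLogger(__name__)

#: Reference area-correction coefficients for n = 1..5.
DEFAULT_LAMBDA = (4.752, 1.353, 1.0, 0.782, 0.673)

#: OKS thresholds for COCO-style mean AP.
AP_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))

DEFAULT_SEED_RADIUS_PAD = 8.0


@dataclass
class OKSParams:
    """sigma (relative localization SD), k = 2*sigma, and lambda_n."""

    sigma: float = 0.05
    lam: tuple[float, ...] = DEFAULT_LAMBDA
    bbox_pad: float = DEFAULT_SEED_RADIUS_PAD

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if len(self.lam) != 5 or any(v <= 0 for v in self.lam):
            raise ValueError("lambda must be 5 positive values")

    @property
    def k(self) -> float:
        return 2.0 * self.sigma


def pod_scale(gt: PodAnnotation, pad: float = DEFAULT_SEED_RADIUS_PAD) -> float:
    """Object scale s: sqrt of the seed bounding-rectangle area, the
    rectangle expanded by one seed radius on each side."""
    x0, y0, x1, y1 = pod_bounding_box(gt, pad=pad)
    return math.sqrt((x1 - x0) * (y1 - y0))


def _paired_distances(
    pred_seeds: Sequence[tuple[float, float] | None],
    gt: PodAnnotation,
) -> list[float | None]:
    """Per-ordinal distances d_i for i = 1..gt.n_seeds; None = no pair."""
    gt_slots: list[tuple[float, float] | None] = [None] * gt.n_seeds
    for (x, y), k in zip(gt.seeds, gt.ordinals):
        gt_slots[k - 1] = (x, y)
    out: list[float | None] = []
    for i in range(gt.n_seeds):
        p = pred_seeds[i] if i < len(pred_seeds) else None
        g = gt_slots[i]
        if p is None or g is None:
            out.append(None)
        else:
            out.append(math.hypot(p[0] - g[0], p[1] - g[1]))
    return out


def oks_pod(
    pred_seeds: Sequence[tuple[float, float] | None],
    gt: PodAnnotation,
    s: float,
    params: OKSParams | None = None,
) -> float:
    """Pod-adapted OKS in [0, 1]; see the module docstring for the formula.

    ``pred_seeds`` aligns by ordinal with the ground truth (index 0 = base
    seed); a missing prediction contributes 0 (d = infinity) while the 1/n
    normalization stays at the declared seed count.
    """
    params = params or OKSParams()
    if s <= 0:
        raise ValueError("scale s must be positive")
    lam_n = params.lam[gt.n_seeds - 1]
    denom = 2.0 * lam_n * s * s * params.k ** 2
    total = 0.0
    for d in _paired_distances(pred_seeds, gt):
        if d is not None:
            total += math.exp(-(d * d) / denom)
    return total / gt.n_seeds


def oks_original(
    pred_seeds: Sequence[tuple[float, float] | None],
    gt: PodAnnotation,
    s: float,
    per_keypoint_k: Sequence[float],
    visibility: Sequence[int],
) -> float:
    """Classical OKS with per-keypoint falloff k_i and visibility flags.

    Only keypoints with v_i > 0 enter numerator and denominator; all
    invisible raises (the metric is undefined)."""
    if s <= 0:
        raise ValueError("scale s must be positive")
    vis = [v > 0 for v in visibility]
    if not any(vis):
        raise ValueError("OKS undefined: no visible keypoints")
    dists = _paired_distances(pred_seeds, gt)
    num = 0.0
    for i, (d, v) in enumerate(zip(dists, vis)):
        if not v:
            continue
        if d is not None:
            num += math.exp(-(d * d) / (2.0 * s * s * per_keypoint_k[i] ** 2))
    return num / sum(vis)


def estimate_sigma(
    refined: np.ndarray,
    original: np.ndarray,
    s_per_pair: np.ndarray | float,
) -> tuple[float, float]:
    """Calibrate sigma from a relabelled subset: sigma^2 = E[d^2 / s^2].

    ``refined`` and ``original`` are matched (N, 2) position arrays from the
    careful relabelling and the routine annotation; ``s_per_pair`` is the
    object scale of each pair (or one shared scalar).  Returns
    ``(sigma, k)`` with k = 2*sigma.
    """
    refined = np.asarray(refined, float)
    original = np.asarray(original, float)
    if refined.size == 0 or refined.shape != original.shape:
        raise ValueError("need >= 1 matched position pair")
    d2 = np.sum((refined - original) ** 2, axis=1)
    s = np.broadcast_to(np.asarray(s_per_pair, float), d2.shape)
    sigma = float(np.sqrt(np.mean(d2 / (s * s))))
    return sigma, 2.0 * sigma


def estimate_lambda(
    annotations: Sequence[ImageAnnotation],
    pad: float = DEFAULT_SEED_RADIUS_PAD,
) -> tuple[list[float], list[int]]:
    """Calibrate lambda_n as the mean per-image ratio of 3-seeded to
    n-seeded bounding-box areas; lambda_3 = 1 identically.

    Images lacking a 3-seeded pod (or the target type) do not contribute to
    that entry; an entry with no qualifying image keeps the reference
    default and is reported in the returned ``missing`` list.
    """

    def areas(ann: ImageAnnotation, n: int) -> list[float]:
        out = []
        for pod in ann.pods:
            if pod.n_seeds == n:
                x0, y0, x1, y1 = pod_bounding_box(pod, pad=pad)
                out.append((x1 - x0) * (y1 - y0))
        return out

    lam = list(DEFAULT_LAMBDA)
    missing: list[int] = []
    for n in range(1, 6):
        if n == 3:
            lam[2] = 1.0
            continue
        ratios = []
        for ann in annotations:
            a3 = areas(ann, 3)
            an = areas(ann, n)
            if a3 and an:
                ratios.append(float(np.mean(a3)) / float(np.mean(an)))
        if ratios:
            lam[n - 1] = float(np.mean(ratios))
        else:
            missing.append(n)
            logger.warning("lambda_%d: no qualifying image, default retained", n)
    return lam, missing


# ---------------------------------------------------------------------------
# Matching and AP
# ---------------------------------------------------------------------------

@dataclass
class DetMatch:
    score: float
    det_n: int
    gt_index: int | None  # index into the image's gt list, None = unmatched
    gt_n: int | None
    oks: float


@dataclass
class MatchTable:
    """Greedy match of one image's detections against its ground truth."""

    detections: list[DetMatch] = field(default_factory=list)
    gt_matched: list[bool] = field(default_factory=list)
    gt_n: list[int] = field(default_factory=list)


def greedy_match(
    dets: DetectionSet,
    gts: Sequence[PodAnnotation],
    params: OKSParams | None = None,
    oks_threshold: float = 0.5,
) -> MatchTable:
    """COCO-style greedy matching in one coordinate frame.

    Detections are processed in descending pod score; each claims the still
    unmatched ground-truth pod with the highest OKS_pod >= threshold, ties
    broken by ground-truth index.
    """
    params = params or OKSParams()
    table = MatchTable(gt_matched=[False] * len(gts), gt_n=[g.n_seeds for g in gts])
    scales = [pod_scale(g, pad=params.bbox_pad) for g in gts]
    order = sorted(range(len(dets.pods)), key=lambda i: -dets.pods[i].pod_score)
    for i in order:
        det = dets.pods[i]
        best_j, best_oks = None, 0.0
        for j, gt in enumerate(gts):
            if table.gt_matched[j]:
                continue
            val = oks_pod(det.seeds, gt, scales[j], params)
            if val >= oks_threshold and val > best_oks:
                best_j, best_oks = j, val
        if best_j is not None:
            table.gt_matched[best_j] = True
            table.detections.append(
                DetMatch(det.pod_score, det.n, best_j, gts[best_j].n_seeds, best_oks)
            )
        else:
            table.detections.append(DetMatch(det.pod_score, det.n, None, None, 0.0))
    return table


def _pr_curve(records: list[tuple[float, bool]], n_gt: int) -> tuple[np.ndarray, np.ndarray]:
    """All-point-interpolated PR curve from (score, is_tp) records."""
    if n_gt == 0:
        raise ValueError("PR curve undefined with zero ground truths")
    records = sorted(records, key=lambda r: -r[0])
    tp = np.cumsum([1.0 if t else 0.0 for _, t in records])
    fp = np.cumsum([0.0 if t else 1.0 for _, t in records])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1e-12)
    return recall, precision


def _ap_from_pr(recall: np.ndarray, precision: np.ndarray) -> float:
    """Area under the precision envelope (COCO all-point interpolation)."""
    r = np.concatenate([[0.0], recall, [recall[-1] if recall.size else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def _single_threshold_ap(
    tables: Sequence[MatchTable], restrict_n: int | None = None
) -> float | None:
    records: list[tuple[float, bool]] = []
    n_gt = 0
    for t in tables:
        if restrict_n is None:
            n_gt += len(t.gt_n)
            records.extend((d.score, d.gt_index is not None) for d in t.detections)
        else:
            n_gt += sum(1 for n in t.gt_n if n == restrict_n)
            for d in t.detections:
                if d.gt_index is not None and d.gt_n == restrict_n:
                    records.append((d.score, True))
                elif d.gt_index is None and d.det_n == restrict_n:
                    records.append((d.score, False))
    if n_gt == 0:
        return None
    if not records:
        return 0.0
    return _ap_from_pr(*_pr_curve(records, n_gt))


@dataclass
class APReport:
    ap: float | None
    ap50: float | None
    per_type: dict[int, float | None]
    pr_curve_50: tuple[np.ndarray, np.ndarray]

    def as_dict(self) -> dict:
        d = {"AP": self.ap, "AP50": self.ap50}
        for n, v in self.per_type.items():
            d[f"AP({n}-seeded)"] = v
        return d


def average_precision(
    tables_by_threshold: Mapping[float, Sequence[MatchTable]],
) -> APReport:
    """AP report from per-threshold match tables.

    AP = mean over thresholds 0.50:0.05:0.95 of the single-threshold AP;
    AP50 uses threshold 0.50 alone; per-type AP restricts ground truths (and
    their matched detections) to pods of that seed count.  Absent ground
    truth of some type makes that entry None.
    """
    thrs = sorted(tables_by_threshold)
    if 0.5 not in thrs:
        raise ValueError("threshold 0.50 required for AP50")
    aps = [_single_threshold_ap(tables_by_threshold[t]) for t in thrs]
    ap = None if any(a is None for a in aps) else float(np.mean([a for a in aps]))
    t50 = tables_by_threshold[0.5]
    per_type = {n: _single_threshold_ap(t50, restrict_n=n) for n in (1, 2, 3, 4)}
    records = [
        (d.score, d.gt_index is not None) for t in t50 for d in t.detections
    ]
    n_gt = sum(len(t.gt_n) for t in t50)
    curve = _pr_curve(records, n_gt) if n_gt and records else (np.array([]), np.array([]))
    return APReport(
        ap=ap,
        ap50=_single_threshold_ap(t50),
        per_type=per_type,
        pr_curve_50=curve,
    )


def evaluate_detections(
    dets_per_image: Sequence[DetectionSet],
    gts_per_image: Sequence[ImageAnnotation],
    params: OKSParams | None = None,
    thresholds: Sequence[float] = AP_THRESHOLDS,
) -> APReport:
    """Match every image at every OKS threshold and summarize as an APReport."""
    params = params or OKSParams()
    if len(dets_per_image) != len(gts_per_image):
        raise ValueError("one DetectionSet per annotated image required")
    tables = {
        float(t): [
            greedy_match(d, g.pods, params, oks_threshold=float(t))
            for d, g in zip(dets_per_image, gts_per_image)
        ]
        for t in thresholds
    }
    return average_precision(tables)


# ---------------------------------------------------------------------------
# Counting metrics and dataset statistics
# ---------------------------------------------------------------------------

@dataclass
class CountReport:
    mae: float
    pcc: float  # NaN when undefined (zero variance)


def count_metrics(pred_counts: Sequence[float], true_counts: Sequence[float]) -> CountReport:
    """Per-image counting quality: MAE and Pearson correlation."""
    pred = np.asarray(pred_counts, float)
    true = np.asarray(true_counts, float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("paired 1-d count lists required")
    if pred.size < 2:
        raise ValueError("need >= 2 images for the correlation")
    mae = float(np.mean(np.abs(pred - true)))
    if np.std(pred) == 0.0 or np.std(true) == 0.0:
        logger.warning("PCC undefined for zero-variance counts")
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(pred, true)[0, 1])
    return CountReport(mae=mae, pcc=pcc)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def dataset_statistics(annotations: Sequence[ImageAnnotation]) -> dict:
    """Descriptive statistics of an annotated split.

    Per-image means are reported to 2 decimals, rounding half-up.
    """
    n_images = len(annotations)
    n_pods = sum(a.n_pods for a in annotations)
    n_seeds = sum(a.n_seeds for a in annotations)
    hist = {n: 0 for n in range(1, 6)}
    for a in annotations:
        for p in a.pods:
            hist[p.n_seeds] += 1
    return {
        "n_images": n_images,
        "total_pods": n_pods,
        "total_seeds": n_seeds,
        "avg_pods_per_image": _round2(n_pods / n_images) if n_images else 0.0,
        "avg_seeds_per_image": _round2(n_seeds / n_images) if n_images else 0.0,
        "pods_by_type": hist,
    }
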