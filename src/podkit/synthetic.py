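"""Synthetic pod scenes, detection perturbations, and feature fixtures.

Real plant images show pods as near-collinear chains of 1-5 seeds, densely
packed and sometimes touching.  The generator reproduces exactly the
statistical structure the downstream method consumes — seed coordinates,
chain geometry, pod-type frequencies, controllable detector noise, and
feature maps with prescribed within/between-pod cosine similarity — while
making no attempt at photometric realism (seeds are Gaussian-profile
elliptical blobs on a noisy background).

Default pod-type frequencies are proportional to the training counts of the
reference soybean dataset (6,462 : 9,778 : 13,266 : 3,266 : 8 pods with
1..5 seeds), so five-seeded pods are appropriately rare.  All generators are
pure functions of their ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from podkit.annotations import ImageAnnotation, PodAnnotation, write_annotation
from podkit.detections import DetectedPod, DetectionSet
from podkit.sprior import FeatureMap

logger = logging.getLogger(__name__)

#: n-seeded pod counts of the reference training split, n = 1..5.
REFERENCE_POD_TYPE_COUNTS = (6462, 9778, 13266, 3266, 8)

DEFAULT_POD_TYPE_PROBS = tuple(
    c / sum(REFERENCE_POD_TYPE_COUNTS) for c in REFERENCE_POD_TYPE_COUNTS
)


@dataclass
class SceneConfig:
    """Geometry and statistics of one generated scene.

    Length scales are in pixels.  ``pods_per_image`` is either an int or an
    inclusive ``(lo, hi)`` range; ``overlap_fraction`` is the fraction of
    pods whose base is deliberately placed within one seed spacing of an
    already-placed pod, emulating touching/overlapping pods.
    """

    width: int = 512
    height: int = 512
    pods_per_image: int | tuple[int, int] = 8
    pod_type_probs: tuple[float, ...] = DEFAULT_POD_TYPE_PROBS
    seed_spacing: float = 25.0
    spacing_jitter: float = 3.0
    seed_radius: float = 8.0
    curvature_jitter: float = 2.0
    overlap_fraction: float = 0.15
    background_noise_sd: float = 0.03
    min_seed_separation: float | None = None  # default 2 * seed_radius (tangency)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pod_type_probs, float)
        if p.shape != (5,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("pod_type_probs must be 5 non-negative values summing to 1")
        for name in ("seed_spacing", "seed_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_seed_separation is None:
            # two rigid seeds of radius r can touch but not interpenetrate:
            # tangency puts their centres 2r apart
            self.min_seed_separation = 2.0 * self.seed_radius


@dataclass
class PerturbConfig:
    """Detector-noise model applied to ground truth to fabricate detections.

    Scores: surviving true pods draw from ``score_true`` (uniform range),
    spurious pods from ``score_spurious``, so spurious detections rank low.
    """

    loc_sd: float = 0.0
    p_drop_seed: float = 0.0
    p_drop_pod: float = 0.0
    p_spurious_pod: float = 0.0
    score_true: tuple[float, float] = (0.7, 1.0)
    score_spurious: tuple[float, float] = (0.1, 0.5)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_drop_seed", "p_drop_pod", "p_spurious_pod"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.loc_sd < 0:
            raise ValueError("loc_sd must be non-negative")


class PlacementError(RuntimeError):
    """Could not place the requested pods inside the image."""


def _pod_geometry(rng: np.random.Generator, config: SceneConfig, n: int,
                  anchor: tuple[float, float] | None) -> np.ndarray | None:
    """One attempt at a jittered near-collinear n-seed chain; None if out of bounds."""
    margin = config.seed_radius + 1.0
    W, H = config.width, config.height
    theta = rng.uniform(0.0, 2.0 * np.pi)
    if anchor is None:
        base = np.array([rng.uniform(margin, W - margin), rng.uniform(margin, H - margin)])
    else:
        off = rng.normal(0.0, config.seed_spacing / 2.0, size=2)
        base = np.asarray(anchor) + off
    d = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-d[1], d[0]])
    pts = [base]
    for _ in range(n - 1):
        step = config.seed_spacing + rng.normal(0.0, config.spacing_jitter)
        step = max(step, 0.25 * config.seed_spacing)
        bend = rng.normal(0.0, config.curvature_jitter)
        pts.append(pts[-1] + step * d + bend * perp)
    arr = np.array(pts)
    ok = (arr[:, 0] >= margin) & (arr[:, 0] <= W - margin) \
        & (arr[:, 1] >= margin) & (arr[:, 1] <= H - margin)
    return arr if bool(np.all(ok)) else None


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, ImageAnnotation]:
    """Generate one scene: float image in [0, 1] plus its exact annotation.

    Each pod is n Gaussian blobs along a jittered line segment; the
    annotation lists the exact blob centres ordered base-to-tip.  Placement
    of each pod is retried a bounded number of times; an image too small for
    the request raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(config.rng_seed)
    if isinstance(config.pods_per_image, tuple):
        lo, hi = config.pods_per_image
        n_pods = int(rng.integers(lo, hi + 1))
    else:
        n_pods = int(config.pods_per_image)

    pods: list[PodAnnotation] = []
    placed_seeds: list[tuple[float, float]] = []
    for pod_id in range(n_pods):
        n = 1 + int(rng.choice(5, p=np.asarray(config.pod_type_probs)))
        want_overlap = bool(placed_seeds) and rng.uniform() < config.overlap_fraction
        arr = None
        min_sep = float(config.min_seed_separation or 0.0)
        for attempt in range(200):
            anchor = None
            if want_overlap and attempt < 100:  # fall back to free placement
                anchor = placed_seeds[int(rng.integers(len(placed_seeds)))]
            cand = _pod_geometry(rng, config, n, anchor)
            if cand is None:
                continue
            if placed_seeds and min_sep > 0:
                existing = np.asarray(placed_seeds)
                d = np.linalg.norm(cand[:, None, :] - existing[None, :, :], axis=2)
                if float(d.min()) < min_sep:
                    continue
            arr = cand
            break
        if arr is None:
            raise PlacementError(
                f"could not place pod {pod_id} ({n} seeds) in a "
                f"{config.width}x{config.height} image after 200 attempts"
            )
        seeds = [(float(x), float(y)) for x, y in arr]
        placed_seeds.extend(seeds)
        pods.append(PodAnnotation(pod_id=pod_id, n_seeds=n, seeds=seeds))

    ann = ImageAnnotation(
        image_id=f"synthetic_{config.rng_seed}",
        width=config.width,
        height=config.height,
        pods=pods,
    )
    image = render_scene_image(ann, config, rng)
    return image, ann


def render_scene_image(
    ann: ImageAnnotation, config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Render seeds as elliptical Gaussian blobs elongated along the chain.

    A thin, fainter pedicel ridge extends from the base seed away from the
    chain, as on a real plant; without it the two ends of a pod are visually
    interchangeable and the base-to-tip seed ordering that the detector must
    learn would be unobservable from the image.
    """
    H, W = config.height, config.width
    img = np.zeros((H, W), dtype=float)
    sig_minor = config.seed_radius / 2.0
    sig_major = sig_minor * 1.4
    r = int(np.ceil(3.0 * sig_major))

    def splat(cx: float, cy: float, sigma: float, amp: float) -> None:
        rr = int(np.ceil(3.0 * sigma))
        x0, x1 = max(int(cx) - rr, 0), min(int(cx) + rr + 1, W)
        y0, y1 = max(int(cy) - rr, 0), min(int(cy) + rr + 1, H)
        if x0 >= x1 or y0 >= y1:
            return
        yy, xx = np.mgrid[y0:y1, x0:x1]
        g = amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma ** 2)))
        np.maximum(img[y0:y1, x0:x1], g, out=img[y0:y1, x0:x1])

    for pod in ann.pods:
        arr = np.asarray(pod.seeds)
        if len(arr) > 1:
            d = arr[-1] - arr[0]
            theta = float(np.arctan2(d[1], d[0]))
        else:
            theta = float(rng.uniform(0.0, 2.0 * np.pi))
        ct, st = np.cos(theta), np.sin(theta)

        # pedicel: from the base seed, pointing away from the chain
        base = arr[0]
        ped_len = 0.7 * config.seed_spacing
        for t in np.arange(0.8 * config.seed_radius, ped_len, 1.5):
            splat(base[0] - t * ct, base[1] - t * st,
                  config.seed_radius / 3.0, 0.55)
        for cx, cy in pod.seeds:
            x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
            y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
            x0c, x1c = max(x0, 0), min(x1, W)
            y0c, y1c = max(y0, 0), min(y1, H)
            if x0c >= x1c or y0c >= y1c:
                continue
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            dx, dy = xx - cx, yy - cy
            u = ct * dx + st * dy
            v = -st * dx + ct * dy
            g = np.exp(-0.5 * ((u / sig_major) ** 2 + (v / sig_minor) ** 2))
            np.maximum(img[y0c:y1c, x0c:x1c], g, out=img[y0c:y1c, x0c:x1c])
    if config.background_noise_sd > 0:
        img = img + rng.normal(0.0, config.background_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def perturb_annotation(truth: ImageAnnotation, config: PerturbConfig) -> DetectionSet:
    """Fabricate a detection set from ground truth under a noise model.

    Coordinates receive isotropic Gaussian jitter of sd ``loc_sd``; whole
    pods are dropped with ``p_drop_pod``, individual seeds with
    ``p_drop_seed`` (a pod losing all its seeds disappears); each true pod
    additionally spawns a spurious low-scoring pod with ``p_spurious_pod``,
    placed uniformly in the image.
    """
    rng = np.random.default_rng(config.rng_seed)
    out = DetectionSet(truth.image_id)
    for pod in truth.pods:
        if rng.uniform() < config.p_drop_pod:
            continue
        keep = [s for s in pod.seeds if rng.uniform() >= config.p_drop_seed]
        if not keep:
            continue
        arr = np.asarray(keep, float)
        if config.loc_sd > 0:
            arr = arr + rng.normal(0.0, config.loc_sd, size=arr.shape)
        score = float(rng.uniform(*config.score_true))
        out.pods.append(
            DetectedPod(
                seeds=[(float(x), float(y)) for x, y in arr],
                seed_scores=[score] * len(arr),
                pod_score=score,
            )
        )
    for _ in truth.pods:
        if rng.uniform() < config.p_spurious_pod:
            n = int(rng.integers(1, 6))
            base = np.array([rng.uniform(0, truth.width), rng.uniform(0, truth.height)])
            theta = rng.uniform(0, 2 * np.pi)
            d = np.array([np.cos(theta), np.sin(theta)])
            arr = base[None, :] + 25.0 * np.arange(n)[:, None] * d[None, :]
            arr[:, 0] = np.clip(arr[:, 0], 0, truth.width - 1)
            arr[:, 1] = np.clip(arr[:, 1], 0, truth.height - 1)
            score = float(rng.uniform(*config.score_spurious))
            out.pods.append(
                DetectedPod(
                    seeds=[(float(x), float(y)) for x, y in arr],
                    seed_scores=[score] * n,
                    pod_score=score,
                )
            )
    return out


def synthesize_features(
    truth: ImageAnnotation,
    channels: int = 32,
    within_sim: float = 0.8,
    between_sim: float = 0.2,
    rng_seed: int = 0,
    stride: float = 1.0,
    noise_sd: float = 1e-3,
) -> FeatureMap:
    """Feature-map fixture with prescribed within/between-pod cosine similarity.

    Each pod receives an identity direction u_p, all pods share a common
    direction g, and each seed adds private noise e_i; the three sets of
    directions are made mutually orthonormal (exact while the pod count and
    seed count fit in C, which keeps the prescribed cosines exact in
    expectation):

        v_i = sqrt(between) * g + sqrt(within - between) * u_p(i)
              + sqrt(1 - within) * e_i

    so same-pod pairs have cosine ``within_sim`` and different-pod pairs
    ``between_sim``.  Cells away from any seed hold small Gaussian noise.
    """
    if not 0.0 <= between_sim <= within_sim <= 1.0:
        raise ValueError("need 0 <= between_sim <= within_sim <= 1")
    if channels < 8:
        raise ValueError("channels must be >= 8")
    rng = np.random.default_rng(rng_seed)
    seeds = [(x, y) for pod in truth.pods for (x, y) in pod.seeds]
    members = [pod.pod_id for pod in truth.pods for _ in pod.seeds]
    n_pods = len(truth.pods)
    n_seeds = len(seeds)

    n_dirs = 1 + n_pods + n_seeds
    raw = rng.normal(size=(channels, max(n_dirs, 1)))
    if n_dirs <= channels:
        q, _ = np.linalg.qr(raw[:, :n_dirs])
        dirs = q.T
    else:
        # more directions than channels: fall back to near-orthogonal random
        dirs = raw.T[:n_dirs]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    g = dirs[0]
    pod_dirs = {pod.pod_id: dirs[1 + i] for i, pod in enumerate(truth.pods)}
    seed_dirs = dirs[1 + n_pods:]

    a = np.sqrt(between_sim)
    b = np.sqrt(within_sim - between_sim)
    c = np.sqrt(1.0 - within_sim)

    Hc = int(np.ceil(truth.height / stride))
    Wc = int(np.ceil(truth.width / stride))
    values = rng.normal(0.0, noise_sd, size=(Hc, Wc, channels))
    for i, ((x, y), pid) in enumerate(zip(seeds, members)):
        v = a * g + b * pod_dirs[pid] + c * seed_dirs[i]
        cy = min(int(round(y / stride)), Hc - 1)
        cx = min(int(round(x / stride)), Wc - 1)
        values[cy, cx] = v
    return FeatureMap(values=values, stride=stride)


def split_scene_across_windows(
    truth: ImageAnnotation, boundary_axis: str, boundary_pos: float
) -> tuple[DetectionSet, DetectionSet]:
    """Split ground truth at a vertical or horizontal line into two
    per-window detection sets, emulating independent per-crop detection.

    ``boundary_axis`` is ``"v"`` (split on x) or ``"h"`` (split on y).  A pod
    crossing the line contributes a partial detection to each side, seed
    ordinals implicitly renumbered from each part's own base; a pod entirely
    on one side appears there unsplit.
    """
    if boundary_axis not in ("v", "h"):
        raise ValueError("boundary_axis must be 'v' or 'h'")
    coord = 0 if boundary_axis == "v" else 1
    first = DetectionSet(truth.image_id)
    second = DetectionSet(truth.image_id)
    for pod in truth.pods:
        left = [s for s in pod.seeds if s[coord] < boundary_pos]
        right = [s for s in pod.seeds if s[coord] >= boundary_pos]
        for part, target, widx in ((left, first, 0), (right, second, 1)):
            if part:
                target.pods.append(
                    DetectedPod(
                        seeds=list(part),
                        seed_scores=[1.0] * len(part),
                        pod_score=1.0,
                        window_index=widx,
                    )
                )
    return first, second


def save_scene(
    out_dir: str | Path,
    image: np.ndarray,
    ann: ImageAnnotation,
    config: SceneConfig,
) -> dict:
    """Write PNG image + Labelme-style JSON + a manifest entry; returns the entry."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png = out / f"{ann.image_id}.png"
    Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8)).save(png)
    js = out / f"{ann.image_id}.json"
    write_annotation(ann, js)
    entry = {
        "image": png.name,
        "annotation": js.name,
        "config": asdict(config),
    }
    manifest = out / "manifest.json"
    existing = json.loads(manifest.read_text()) if manifest.exists() else []
    existing.append(entry)
    manifest.write_text(json.dumps(existing, indent=2))
    return entry
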