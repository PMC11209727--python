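"""Crop geometry: pod-centred training crops, fixed-stride inference tiling,
coordinate remapping, and the split-before-crop dataset protocol.

Full plant images are tall and narrow; pods occupy a small fraction of them,
so the detector is trained and run on fixed-size square crops (default
400 x 400 px, within which ~90% of plants fit widthwise).  Training crops
are sampled around a chosen pod with uniform-random slack; inference tiles
the image on a fixed stride.  Windows at the border are always shifted
inward — never shrunk or padded — so every crop has the exact model input
size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from podkit.annotations import ImageAnnotation, PodAnnotation, pod_bounding_box
from podkit.detections import DetectionSet

logger = logging.getLogger(__name__)

DEFAULT_CROP_SIZE = 400
DEFAULT_STRIDE = 300  # 100 px overlap: comfortably more than one seed spacing


@dataclass(frozen=True)
class CropWindow:
    """A crop's position record (LOC) within its parent image."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    image_id: str = ""

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


class CropError(ValueError):
    pass


def sample_pod_crop(
    ann: ImageAnnotation,
    pod_id: int,
    crop_size: int = DEFAULT_CROP_SIZE,
    rng: np.random.Generator | int | None = None,
) -> tuple[CropWindow, ImageAnnotation]:
    """Sample one training crop containing the chosen pod entirely.

    The pod's minimum bounding rectangle is expanded to ``crop_size`` square
    with the horizontal and vertical slack split uniformly at random between
    the two sides, then shifted (never shrunk) to stay inside the image.
    All pods with at least one seed inside the window are remapped to window
    coordinates; out-of-window seeds are dropped and such pods flagged
    truncated (their declared seed count is kept — the missing seeds are
    treated as sealed).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pods = {p.pod_id: p for p in ann.pods}
    if pod_id not in pods:
        raise CropError(f"pod {pod_id} not present in image {ann.image_id}")
    x0, y0, x1, y1 = pod_bounding_box(pods[pod_id])
    bw, bh = x1 - x0, y1 - y0
    if bw > crop_size or bh > crop_size:
        raise CropError(
            f"pod {pod_id} bounding box {bw:.0f}x{bh:.0f} exceeds crop size {crop_size}"
        )
    if ann.width < crop_size or ann.height < crop_size:
        raise CropError(
            f"image {ann.image_id} smaller than crop size {crop_size}"
        )
    slack_x = crop_size - bw
    slack_y = crop_size - bh
    left = rng.uniform(0.0, slack_x)
    top = rng.uniform(0.0, slack_y)
    wx = int(round(x0 - left))
    wy = int(round(y0 - top))
    wx = min(max(wx, 0), ann.width - crop_size)
    wy = min(max(wy, 0), ann.height - crop_size)
    window = CropWindow(wx, wy, wx + crop_size, wy + crop_size, ann.image_id)
    return window, crop_annotation(ann, window)


def crop_annotation(ann: ImageAnnotation, window: CropWindow) -> ImageAnnotation:
    """Remap all pods with >= 1 seed inside ``window`` to window coordinates."""
    out_pods: list[PodAnnotation] = []
    for pod in ann.pods:
        inside = [
            ((x - window.x_min, y - window.y_min), k)
            for (x, y), k in zip(pod.seeds, pod.ordinals)
            if window.contains(x, y)
        ]
        if not inside:
            continue
        seeds = [s for s, _ in inside]
        ordinals = [k for _, k in inside]
        truncated = ordinals != list(range(1, pod.n_seeds + 1))
        out_pods.append(
            replace(pod, seeds=seeds, ordinals=ordinals, truncated=truncated)
        )
    return ImageAnnotation(
        image_id=f"{ann.image_id}_crop_{window.x_min}_{window.y_min}",
        width=window.width,
        height=window.height,
        pods=out_pods,
    )


def tile_image(
    width: int,
    height: int,
    crop_size: int = DEFAULT_CROP_SIZE,
    stride: int = DEFAULT_STRIDE,
    image_id: str = "",
) -> list[CropWindow]:
    """Row-major fixed-stride tiling covering every pixel.

    The final row/column is shifted inward so windows never exceed the image.
    An image smaller than ``crop_size`` yields a single full-image window
    with a logged warning (the caller must handle the nonstandard size).
    """
    if stride > crop_size:
        raise ValueError("stride must not exceed crop_size")
    if width < crop_size or height < crop_size:
        logger.warning(
            "image %dx%d smaller than crop size %d: single full-image window",
            width, height, crop_size,
        )
        return [CropWindow(0, 0, width, height, image_id)]
    xs = _grid_starts(width, crop_size, stride)
    ys = _grid_starts(height, crop_size, stride)
    return [
        CropWindow(x, y, x + crop_size, y + crop_size, image_id)
        for y in ys
        for x in xs
    ]


def _grid_starts(extent: int, crop: int, stride: int) -> list[int]:
    starts = list(range(0, extent - crop + 1, stride))
    if starts[-1] + crop < extent:
        starts.append(extent - crop)
    return starts


def remap_to_full(dets: DetectionSet, window: CropWindow, window_index: int = -1) -> DetectionSet:
    """Translate window-frame detections back into the full-image frame."""
    out = DetectionSet(window.image_id or dets.image_id)
    for pod in dets.pods:
        moved = pod.translated(window.x_min, window.y_min)
        if window_index >= 0:
            moved = replace(moved, window_index=window_index)
        out.pods.append(moved)
    return out


def split_plants(
    annotations: list[ImageAnnotation],
    test_fraction: float,
    rng_seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Partition plant images into train/test BEFORE any cropping.

    Splitting at plant level guarantees no pod ever appears in both sets,
    however the crops are later sampled.  Deterministic given ``rng_seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = [a.image_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test = sorted(ids[i] for i in order[:n_test])
    train = sorted(ids[i] for i in order[n_test:])
    return train, test
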