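"""Seed-to-pod point annotations.

Every seed is a dot labelled ``"n-k(id)"``: ``n`` seeds in the pod (1-5),
``k`` the 1-based ordinal of this seed counted from the pod base, ``id`` the
pod's unique integer identifier within its image.  Labelme-style JSON point
shapes carry these labels; this module parses them, assembles the dots into
ordered pods, and writes the same dialect back bit-compatibly.

Conventions used throughout the package: coordinates are 0-based continuous
pixels, x rightward, y downward; boxes are (x_min, y_min, x_max, y_max) with
the min edge closed and the max edge open.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

MAX_SEEDS = 5

_LABEL_RE = re.compile(
    r"^\s*(?P<n>\d+)\s*-\s*(?P<k>\d+)\s*\(\s*(?P<id>\d+)\s*\)\s*$"
)


class AnnotationError(ValueError):
    """Malformed or inconsistent seed-to-pod annotation."""


@dataclass(frozen=True)
class SeedLabel:
    """Parsed ``"n-k(id)"`` label triple."""

    seeds_in_pod: int
    seed_index: int
    pod_id: int

    def __post_init__(self) -> None:
        if not 1 <= self.seeds_in_pod <= MAX_SEEDS:
            raise AnnotationError(
                f"seeds_in_pod must be in 1..{MAX_SEEDS}, got {self.seeds_in_pod}"
            )
        if not 1 <= self.seed_index <= self.seeds_in_pod:
            raise AnnotationError(
                f"seed_index {self.seed_index} outside 1..{self.seeds_in_pod}"
            )
        if self.pod_id < 0:
            raise AnnotationError(f"pod_id must be non-negative, got {self.pod_id}")

    def __str__(self) -> str:
        return f"{self.seeds_in_pod}-{self.seed_index}({self.pod_id})"


@dataclass(frozen=True)
class SeedKeypoint:
    """One annotated seed dot: continuous pixel position plus its label."""

    x: float
    y: float
    label: SeedLabel


@dataclass
class PodAnnotation:
    """One pod: ordered base-to-tip seed coordinates.

    ``seeds`` holds ``(x, y)`` pairs sorted by seed ordinal; ``ordinals``
    records which 1-based slots those seeds occupy.  A pod whose ordinals are
    not the full run ``1..n_seeds`` is *truncated* (cropping or occlusion
    removed some seeds); it keeps its declared ``n_seeds``.
    """

    pod_id: int
    n_seeds: int
    seeds: list[tuple[float, float]]
    ordinals: list[int] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.n_seeds <= MAX_SEEDS:
            raise AnnotationError(f"n_seeds must be in 1..{MAX_SEEDS}")
        if not self.ordinals:
            self.ordinals = list(range(1, len(self.seeds) + 1))
        if len(self.ordinals) != len(self.seeds):
            raise AnnotationError("ordinals and seeds length mismatch")
        if any(not 1 <= o <= self.n_seeds for o in self.ordinals):
            raise AnnotationError("seed ordinal outside 1..n_seeds")
        if len(set(self.ordinals)) != len(self.ordinals):
            raise AnnotationError(f"duplicate seed ordinal in pod {self.pod_id}")
        complete = self.ordinals == list(range(1, self.n_seeds + 1))
        if not complete and not self.truncated:
            raise AnnotationError(
                f"pod {self.pod_id} has ordinals {self.ordinals} but declares "
                f"n={self.n_seeds}; flag it truncated or supply all seeds"
            )

    @property
    def n_present(self) -> int:
        return len(self.seeds)


@dataclass
class ImageAnnotation:
    """All pods of one image."""

    image_id: str
    width: int
    height: int
    pods: list[PodAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pod_id for p in self.pods]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"duplicate pod_id in image {self.image_id}")

    @property
    def n_pods(self) -> int:
        return len(self.pods)

    @property
    def n_seeds(self) -> int:
        return sum(p.n_present for p in self.pods)

    def iter_keypoints(self) -> Iterable[SeedKeypoint]:
        for pod in self.pods:
            for (x, y), k in zip(pod.seeds, pod.ordinals):
                yield SeedKeypoint(x, y, SeedLabel(pod.n_seeds, k, pod.pod_id))


def parse_seed_label(text: str) -> SeedLabel:
    """Parse a ``"n-k(id)"`` label string.

    Whitespace around tokens is tolerated; no other dialect is accepted.
    Raises :class:`AnnotationError` for malformed strings or labels violating
    ``1 <= k <= n <= 5``.
    """
    m = _LABEL_RE.match(text)
    if m is None:
        raise AnnotationError(
            f"label {text!r} does not match the grammar '<n>-<k>(<id>)'"
        )
    return SeedLabel(
        seeds_in_pod=int(m.group("n")),
        seed_index=int(m.group("k")),
        pod_id=int(m.group("id")),
    )


def assemble_pods(points: Sequence[SeedKeypoint]) -> list[PodAnnotation]:
    """Group labelled seed dots of one image into ordered pods.

    Points are grouped by pod id and sorted by seed ordinal; the result is
    invariant to the input order.  A group with missing ordinals (e.g. seeds
    1 and 3 but not 2) is returned flagged truncated rather than rejected,
    because cropping legitimately produces such pods.  Duplicate
    ``(pod_id, seed_index)`` pairs or disagreement about the group's seed
    count are errors.
    """
    groups: dict[int, list[SeedKeypoint]] = {}
    for kp in points:
        groups.setdefault(kp.label.pod_id, []).append(kp)

    pods = []
    for pod_id in sorted(groups):
        members = sorted(groups[pod_id], key=lambda kp: kp.label.seed_index)
        counts = {kp.label.seeds_in_pod for kp in members}
        if len(counts) != 1:
            raise AnnotationError(
                f"pod {pod_id}: members disagree on seed count {sorted(counts)}"
            )
        n = counts.pop()
        ordinals = [kp.label.seed_index for kp in members]
        if len(set(ordinals)) != len(ordinals):
            raise AnnotationError(f"pod {pod_id}: duplicate seed ordinal")
        truncated = ordinals != list(range(1, n + 1))
        pods.append(
            PodAnnotation(
                pod_id=pod_id,
                n_seeds=n,
                seeds=[(kp.x, kp.y) for kp in members],
                ordinals=ordinals,
                truncated=truncated,
            )
        )
    return pods


def pod_bounding_box(
    pod: PodAnnotation,
    pad: float = 0.0,
    image_size: tuple[int, int] | None = None,
) -> tuple[float, float, float, float]:
    """Minimal axis-aligned box containing all seeds, expanded by ``pad``.

    Returns ``(x_min, y_min, x_max, y_max)``.  When ``image_size=(width,
    height)`` is supplied the box is clamped to the image.
    """
    if not pod.seeds:
        raise AnnotationError(f"pod {pod.pod_id} has no seeds")
    xs = [x for x, _ in pod.seeds]
    ys = [y for _, y in pod.seeds]
    x0, y0 = min(xs) - pad, min(ys) - pad
    x1, y1 = max(xs) + pad, max(ys) + pad
    if image_size is not None:
        w, h = image_size
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, float(w)), min(y1, float(h))
    return (x0, y0, x1, y1)


# ---------------------------------------------------------------------------
# Labelme-style JSON I/O
# ---------------------------------------------------------------------------

def load_annotation(document: dict | str | Path, image_id: str | None = None) -> ImageAnnotation:
    """Read a Labelme-style JSON document (dict, path or JSON string).

    Every point shape's label is parsed with :func:`parse_seed_label` and the
    dots are assembled into pods.  Non-point shapes are skipped with a logged
    warning; an unparsable label is an error naming the shape index.
    """
    doc = _coerce_document(document)
    points: list[SeedKeypoint] = []
    for i, shape in enumerate(doc.get("shapes", [])):
        if shape.get("shape_type", "point") != "point":
            logger.warning("shape %d: skipping non-point shape %r", i, shape.get("shape_type"))
            continue
        try:
            label = parse_seed_label(shape["label"])
        except AnnotationError as exc:
            raise AnnotationError(f"shape {i}: {exc}") from exc
        (x, y), = shape["points"]
        points.append(SeedKeypoint(float(x), float(y), label))
    return ImageAnnotation(
        image_id=image_id or doc.get("imagePath", "image"),
        width=int(doc["imageWidth"]),
        height=int(doc["imageHeight"]),
        pods=assemble_pods(points),
    )


def write_annotation(ann: ImageAnnotation, path: str | Path | None = None) -> dict:
    """Serialize to the Labelme point-shape dialect read by :func:`load_annotation`.

    ``write(load(doc))`` reproduces ``doc``'s point set and labels exactly.
    """
    shapes = [
        {
            "label": str(kp.label),
            "points": [[kp.x, kp.y]],
            "group_id": None,
            "shape_type": "point",
            "flags": {},
        }
        for kp in ann.iter_keypoints()
    ]
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": shapes,
        "imagePath": ann.image_id,
        "imageData": None,
        "imageHeight": ann.height,
        "imageWidth": ann.width,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def to_coco(anns: Sequence[ImageAnnotation]) -> dict:
    """Export to a COCO-keypoints-style dict.

    Each pod becomes one entity with a 5-slot keypoint array ``[x, y, v]*5``;
    absent (sealed or truncated-away) slots are zero-filled with visibility 0.
    """
    images, annotations = [], []
    next_id = 1
    for img_idx, ann in enumerate(anns):
        images.append(
            {"id": img_idx, "file_name": ann.image_id, "width": ann.width, "height": ann.height}
        )
        for pod in ann.pods:
            slots = [[0.0, 0.0, 0] for _ in range(MAX_SEEDS)]
            for (x, y), k in zip(pod.seeds, pod.ordinals):
                slots[k - 1] = [x, y, 2]
            x0, y0, x1, y1 = pod_bounding_box(pod)
            annotations.append(
                {
                    "id": next_id,
                    "image_id": img_idx,
                    "category_id": 1,
                    "keypoints": [v for slot in slots for v in slot],
                    "num_keypoints": pod.n_present,
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "pod_id": pod.pod_id,
                    "n_seeds": pod.n_seeds,
                }
            )
            next_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [
            {
                "id": 1,
                "name": "pod",
                "keypoints": [f"seed_{i}" for i in range(1, MAX_SEEDS + 1)],
                "skeleton": [[i, i + 1] for i in range(1, MAX_SEEDS)],
            }
        ],
    }


def _coerce_document(document: dict | str | Path) -> dict:
    if isinstance(document, dict):
        return document
    if isinstance(document, Path) or (isinstance(document, str) and "{" not in document):
        return json.loads(Path(document).read_text())
    return json.loads(document)


def translate_pod(pod: PodAnnotation, dx: float, dy: float) -> PodAnnotation:
    """Return a copy of ``pod`` with every seed shifted by ``(dx, dy)``."""
    return replace(pod, seeds=[(x + dx, y + dy) for x, y in pod.seeds])
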