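"""Scored pod detections — the currency of decoding, merging and evaluation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

from podkit.annotations import MAX_SEEDS, ImageAnnotation


@dataclass
class DetectedPod:
    """A detected pod: ordered seeds with per-seed confidences and a score.

    ``seeds`` are ``(x, y)`` in some common frame, ordered by seed type
    (ordinal 1 = pod base).  ``window_index`` records the source crop during
    tiled inference, -1 when not applicable.
    """

    seeds: list[tuple[float, float]]
    seed_scores: list[float]
    pod_score: float
    window_index: int = -1

    def __post_init__(self) -> None:
        if not 1 <= len(self.seeds) <= MAX_SEEDS:
            raise ValueError(f"a pod has 1..{MAX_SEEDS} seeds, got {len(self.seeds)}")
        if len(self.seed_scores) != len(self.seeds):
            raise ValueError("seed_scores and seeds length mismatch")

    @property
    def n(self) -> int:
        return len(self.seeds)

    def translated(self, dx: float, dy: float) -> "DetectedPod":
        return replace(self, seeds=[(x + dx, y + dy) for x, y in self.seeds])


@dataclass
class DetectionSet:
    """All detected pods of one image (or one crop)."""

    image_id: str
    pods: list[DetectedPod] = field(default_factory=list)

    def __iter__(self) -> Iterator[DetectedPod]:
        return iter(self.pods)

    def __len__(self) -> int:
        return len(self.pods)

    @property
    def n_seeds(self) -> int:
        return sum(p.n for p in self.pods)

    def sorted_by_score(self) -> "DetectionSet":
        return DetectionSet(
            self.image_id, sorted(self.pods, key=lambda p: -p.pod_score)
        )


def from_annotation(ann: ImageAnnotation, score: float = 1.0) -> DetectionSet:
    """Treat ground truth as perfect detections (useful in fixtures)."""
    pods = [
        DetectedPod(
            seeds=list(p.seeds),
            seed_scores=[score] * p.n_present,
            pod_score=score,
        )
        for p in ann.pods
    ]
    return DetectionSet(ann.image_id, pods)


def to_coco_results(dets: Sequence[DetectionSet], path: str | Path | None = None) -> list[dict]:
    """COCO-keypoints-results-style export: one record per detected pod."""
    records = []
    for img_idx, ds in enumerate(dets):
        for pod in ds.pods:
            slots = [[0.0, 0.0, 0.0] for _ in range(MAX_SEEDS)]
            for i, ((x, y), c) in enumerate(zip(pod.seeds, pod.seed_scores)):
                slots[i] = [x, y, c]
            records.append(
                {
                    "image_id": img_idx,
                    "image_name": ds.image_id,
                    "category_id": 1,
                    "keypoints": [v for s in slots for v in s],
                    "score": pod.pod_score,
                }
            )
    if path is not None:
        Path(path).write_text(json.dumps(records, indent=2))
    return records


def from_coco_results(records: Sequence[dict] | str | Path) -> dict[str, DetectionSet]:
    """Inverse of :func:`to_coco_results`, keyed by image name."""
    if not isinstance(records, (list, tuple)):
        records = json.loads(Path(records).read_text())
    sets: dict[str, DetectionSet] = {}
    for rec in records:
        name = rec.get("image_name", str(rec["image_id"]))
        kps = rec["keypoints"]
        seeds, scores = [], []
        for i in range(0, len(kps), 3):
            x, y, c = kps[i], kps[i + 1], kps[i + 2]
            if c > 0:
                seeds.append((x, y))
                scores.append(c)
        if not seeds:
            continue
        sets.setdefault(name, DetectionSet(name)).pods.append(
            DetectedPod(seeds=seeds, seed_scores=scores, pod_score=rec["score"])
        )
    return sets
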