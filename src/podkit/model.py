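"""Prediction-tensor layout, target rendering, decoding, and a toy trainer.

The detector follows the disentangled-keypoint-regression layout: on an
output grid at a fixed stride it predicts 6 heatmap channels (five seed
types ordered from the pod base, one background) and a 10-channel offset
field regressing, from a candidate centre pixel, the 2-D displacement to
each of the K = 5 seeds of that pod.  A pod with n < 5 seeds has its
missing seed slots *sealed*: their heatmap targets stay empty and their
offset slots are masked out of the loss.

The training harness is a deliberately small plain convolutional
encoder-plus-heads network written on numpy (see :mod:`podkit._nn`): the
machinery under test is the loss, metric, and merging pipeline, not a
full-scale backbone.  The structural-prior branch taps the trunk mid-way
by default (see TrainConfig.sprior_tap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import maximum_filter

from podkit._nn import DTYPE, Adam, Conv2d, ReLU, sigmoid
from podkit.annotations import MAX_SEEDS, ImageAnnotation
from podkit.detections import DetectedPod, DetectionSet
from podkit.sprior import (
    FeatureMap,
    PointVectorSet,
    cosine_affinity,
    smooth_l1,
    sprior_loss_normalized,
    sprior_target,
)

logger = logging.getLogger(__name__)

K = MAX_SEEDS  # 5 keypoint types
N_HEAT = K + 1  # channel K is background


@dataclass
class PredictionTensors:
    """heatmaps (H', W', 6), offsets (H', W', 10) in output-cell units."""

    heatmaps: np.ndarray
    offsets: np.ndarray
    stride: int = 2

    def __post_init__(self) -> None:
        if self.heatmaps.shape[-1] != N_HEAT or self.offsets.shape[-1] != 2 * K:
            raise ValueError("expected 6 heatmap and 10 offset channels")
        if not (np.all(np.isfinite(self.heatmaps)) and np.all(np.isfinite(self.offsets))):
            raise ValueError("prediction tensors must be finite")


@dataclass
class TargetTensors:
    """Prediction-shaped targets plus supervision weights/masks.

    ``offset_norm`` holds the per-cell pod-scale normalizer (1/Z) applied to
    offset residuals inside the loss; ``offset_mask`` is binary and zero on
    sealed slots and away from pod centres.
    """

    heatmaps: np.ndarray
    offsets: np.ndarray
    heat_weights: np.ndarray
    offset_mask: np.ndarray
    offset_norm: np.ndarray
    stride: int = 2


def render_targets(
    ann: ImageAnnotation,
    stride: int = 2,
    gaussian_sd: float = 2.0,
    offset_radius: float = 4.0,
    pos_weight: float = 10.0,
) -> TargetTensors:
    """Render ground-truth tensors for one image.

    Each seed splats a Gaussian peak (sd in output cells, max-combine) on
    its type channel; background = 1 - max over type channels.  Offset
    targets are written at cells within ``offset_radius`` of each pod's
    centre (the centroid of its present seeds) and point to every unsealed
    seed; the mask covers exactly those entries.  Heatmap weights are
    1 + pos_weight * target so sparse peaks are not drowned by background.
    """
    Ho = (ann.height + stride - 1) // stride
    Wo = (ann.width + stride - 1) // stride
    heat = np.zeros((Ho, Wo, N_HEAT), dtype=DTYPE)
    offs = np.zeros((Ho, Wo, 2 * K), dtype=DTYPE)
    mask = np.zeros((Ho, Wo, 2 * K), dtype=DTYPE)
    norm = np.ones((Ho, Wo, 1), dtype=DTYPE)

    r = int(np.ceil(3.0 * gaussian_sd))
    pod_pts = []
    for pod in ann.pods:
        pts = np.asarray(pod.seeds, dtype=float) / stride  # (x, y) in cells
        pod_pts.append(pts)
        for (cx, cy), k in zip(pts, pod.ordinals):
            x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
            y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
            x0c, x1c = max(x0, 0), min(x1, Wo)
            y0c, y1c = max(y0, 0), min(y1, Ho)
            if x0c >= x1c or y0c >= y1c:
                continue
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * gaussian_sd ** 2))
            ch = heat[y0c:y1c, x0c:x1c, k - 1]
            np.maximum(ch, g.astype(DTYPE), out=ch)

    # Offset supervision around each pod centre.  The radius is widened per
    # pod so it always reaches the seed nearest the centroid (spacing jitter
    # can push every seed cell outside a fixed radius); cells claimed by
    # several pods go to the pod with the nearest centre, so touching pods
    # keep disjoint supervision instead of overwriting each other.
    centres = [pts.mean(axis=0) for pts in pod_pts]
    radii = [
        max(offset_radius, float(np.min(np.linalg.norm(pts - c, axis=1))) + 1.5)
        for pts, c in zip(pod_pts, centres)
    ]
    claim = np.full((Ho, Wo), -1, dtype=int)
    claim_d2 = np.full((Ho, Wo), np.inf)
    for p_idx, (centre, rad) in enumerate(zip(centres, radii)):
        rr = int(np.ceil(rad))
        cx0 = max(int(np.floor(centre[0])) - rr, 0)
        cx1 = min(int(np.floor(centre[0])) + rr + 1, Wo)
        cy0 = max(int(np.floor(centre[1])) - rr, 0)
        cy1 = min(int(np.floor(centre[1])) + rr + 1, Ho)
        if cx0 >= cx1 or cy0 >= cy1:
            continue
        yy, xx = np.mgrid[cy0:cy1, cx0:cx1]
        d2 = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2
        near = (d2 <= rad * rad) & (d2 < claim_d2[cy0:cy1, cx0:cx1])
        claim[cy0:cy1, cx0:cx1][near] = p_idx
        claim_d2[cy0:cy1, cx0:cx1][near] = d2[near]

    for p_idx, (pod, pts) in enumerate(zip(ann.pods, pod_pts)):
        cy_idx, cx_idx = np.where(claim == p_idx)
        if cy_idx.size == 0:
            continue
        ext = pts.max(axis=0) - pts.min(axis=0)
        z = max(1.0, float(np.sqrt((ext[0] + 1.0) * (ext[1] + 1.0))))
        for (sx, sy), k in zip(pts, pod.ordinals):
            offs[cy_idx, cx_idx, 2 * (k - 1)] = (sx - cx_idx).astype(DTYPE)
            offs[cy_idx, cx_idx, 2 * (k - 1) + 1] = (sy - cy_idx).astype(DTYPE)
            mask[cy_idx, cx_idx, 2 * (k - 1)] = 1.0
            mask[cy_idx, cx_idx, 2 * (k - 1) + 1] = 1.0
        norm[cy_idx, cx_idx, 0] = 1.0 / z

    heat[:, :, K] = 1.0 - heat[:, :, :K].max(axis=2)
    # emphasize salient cells: peaks on type channels, seed areas on the
    # background channel (whose informative regions are where it DROPS)
    saliency = heat.copy()
    saliency[:, :, K] = 1.0 - heat[:, :, K]
    weights = (1.0 + pos_weight * saliency).astype(DTYPE)
    return TargetTensors(
        heatmaps=heat, offsets=offs, heat_weights=weights,
        offset_mask=mask, offset_norm=norm, stride=stride,
    )


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _bilinear(ch: np.ndarray, x: float, y: float) -> float:
    H, W = ch.shape
    x = min(max(x, 0.0), W - 1.0)
    y = min(max(y, 0.0), H - 1.0)
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, W - 1), min(y0 + 1, H - 1)
    fx, fy = x - x0, y - y0
    return float(
        ch[y0, x0] * (1 - fx) * (1 - fy)
        + ch[y0, x1] * fx * (1 - fy)
        + ch[y1, x0] * (1 - fx) * fy
        + ch[y1, x1] * fx * fy
    )


def _refine_peak(ch: np.ndarray, x: float, y: float, radius: int = 2) -> tuple[float, float]:
    """Snap to the local argmax of a type channel, then sub-cell quadratic fit."""
    H, W = ch.shape
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, W)
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, H)
    patch = ch[y0:y1, x0:x1]
    iy, ix = np.unravel_index(np.argmax(patch), patch.shape)
    px, py = x0 + ix, y0 + iy

    def sub(f0: float, f1: float, f2: float) -> float:
        den = f0 - 2.0 * f1 + f2
        if abs(den) < 1e-9:
            return 0.0
        return float(np.clip(0.5 * (f0 - f2) / den, -0.5, 0.5))

    dx = sub(ch[py, px - 1], ch[py, px], ch[py, px + 1]) if 0 < px < W - 1 else 0.0
    dy = sub(ch[py - 1, px], ch[py, px], ch[py + 1, px]) if 0 < py < H - 1 else 0.0
    return px + dx, py + dy


def decode(
    pred: PredictionTensors,
    heatmap_thresh: float = 0.3,
    nms_thresh: float = 0.05,
    nms_radius_per_unit: float = 200.0,
    min_chain_step: float = 3.0,
    refine: bool = True,
    image_id: str = "",
) -> DetectionSet:
    """Decode prediction tensors into scored pods (input-pixel coordinates).

    Candidate centres are local maxima of the foreground (1 - background)
    above ``heatmap_thresh``.  Each candidate regresses K = 5 seeds through
    its offset vector; a regressed seed survives if its own type channel at
    the regressed position reaches ``heatmap_thresh``, and the pod keeps the
    surviving prefix chain from seed 1 (ordinals count from the pod base, so
    an interior gap ends the chain).  Surviving seeds are optionally snapped
    to the nearby type-channel peak with sub-cell refinement.  Because two
    seeds of one pod cannot physically coincide, the chain also stops when a
    regressed seed lands within ``min_chain_step`` input pixels of the
    previous seed (this rejects sealed slots whose unsupervised offsets
    point back at the candidate itself).  Pose-level
    NMS then removes near-duplicate pods: candidates are visited by
    descending (chain length, score) and a pod is suppressed when its mean
    prefix-aligned seed distance to a kept pod falls below the radius
    ``nms_thresh * nms_radius_per_unit`` input pixels (10 px at the 0.05
    default).
    """
    heat, offs, stride = pred.heatmaps, pred.offsets, pred.stride
    fg = 1.0 - heat[:, :, K]
    local_max = maximum_filter(fg, size=3, mode="nearest") <= fg
    cand_y, cand_x = np.where(local_max & (fg >= heatmap_thresh))

    pods: list[DetectedPod] = []
    for cy, cx in zip(cand_y, cand_x):
        seeds: list[tuple[float, float]] = []
        confs: list[float] = []
        for k in range(K):
            ox, oy = float(offs[cy, cx, 2 * k]), float(offs[cy, cx, 2 * k + 1])
            if k > 0 and abs(ox) + abs(oy) < 1e-9:
                break  # sealed slot: an exactly-zero offset regresses nowhere
            sx, sy = cx + ox, cy + oy
            conf = _bilinear(heat[:, :, k], sx, sy)
            if conf < heatmap_thresh:
                break  # chain ends at the first missing ordinal
            if seeds and np.hypot(
                sx * stride - seeds[-1][0], sy * stride - seeds[-1][1]
            ) < min_chain_step:
                break  # a pod's seeds cannot coincide: sealed slot
            if refine:
                sx, sy = _refine_peak(heat[:, :, k], sx, sy)
                conf = _bilinear(heat[:, :, k], sx, sy)
                if seeds and np.hypot(
                    sx * stride - seeds[-1][0], sy * stride - seeds[-1][1]
                ) < min_chain_step:
                    break  # refinement collapsed onto the previous seed
            seeds.append((sx * stride, sy * stride))
            confs.append(conf)
        if seeds:
            pods.append(
                DetectedPod(
                    seeds=seeds,
                    seed_scores=confs,
                    pod_score=float(np.mean(confs)),
                )
            )

    radius = nms_thresh * nms_radius_per_unit
    kept: list[DetectedPod] = []
    for pod in sorted(pods, key=lambda p: (-p.n, -p.pod_score)):
        dup = False
        for other in kept:
            m = min(pod.n, other.n)
            d = np.linalg.norm(
                np.asarray(pod.seeds[:m]) - np.asarray(other.seeds[:m]), axis=1
            ).mean()
            if d < radius:
                dup = True
                break
        if not dup:
            kept.append(pod)
    kept.sort(key=lambda p: -p.pod_score)
    return DetectionSet(image_id, kept)


# ---------------------------------------------------------------------------
# Toy model and trainer
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Desk-scale training configuration."""

    rho: float = 0.2
    gamma: float = 0.3  # see docs/methods.md: balances a per-entry-mean heat loss
    epochs: int = 60
    lr: float = 5e-3
    lr_decay_at: float = 1.0  # fraction of epochs after which lr drops 5x; 1 = off
    batch_size: int = 8
    stride: int = 2
    channels: int = 24
    rng_seed: int = 0
    flip_augment: bool = True
    gaussian_sd: float = 2.0
    offset_radius: float = 4.0
    normalize_sprior: bool = True  # per-entry mean keeps rho comparable across N
    sprior_tap: str = "mid"  # where the prior branch reads the trunk


class ToyPodNet:
    """Small plain conv encoder with heatmap / offset heads and SPrior tap.

    Trunk: stride-2 5x5 conv then three 3x3 convs (dilations 1, 2, 4) at the
    output resolution, ReLU throughout; receptive field ~49 input px.  The
    SPrior branch reads the trunk feature map directly.
    """

    def __init__(self, channels: int = 24, stride: int = 2, rng_seed: int = 0,
                 sprior_tap: str = "mid"):
        if stride != 2:
            raise ValueError("the toy architecture is built for output stride 2")
        if sprior_tap not in ("mid", "final"):
            raise ValueError("sprior_tap must be 'mid' or 'final'")
        rng = np.random.default_rng(rng_seed)
        c = channels
        self.stride = stride
        self.channels = c
        self.sprior_tap = sprior_tap
        self.trunk = [
            Conv2d(5, 1, c // 2, stride=2, pad=2, rng=rng), ReLU(),
            Conv2d(3, c // 2, c, pad=1, rng=rng), ReLU(),
            Conv2d(3, c, c, pad=2, dilation=2, rng=rng), ReLU(),
            Conv2d(3, c, c, pad=4, dilation=4, rng=rng), ReLU(),
        ]
        # index into the trunk after which the prior branch taps: mid-trunk
        # identity features leave the late dilated convs free for the
        # spatially-distinct offset regression the prior would otherwise fight
        self.tap_index = 4 if sprior_tap == "mid" else len(self.trunk)
        self.head_heat = Conv2d(1, c, N_HEAT, rng=rng)
        # the offset map (cell -> each seed of its pod) needs more depth
        # than a linear readout of the shared features
        self.off_branch = [
            Conv2d(3, c, c, pad=1, rng=rng), ReLU(),
            Conv2d(3, c, 2 * K, pad=1, rng=rng),
        ]
        # the structural-prior branch has its own convolutions: the affinity
        # loss shapes these structural features and reaches the trunk only
        # through them, instead of yanking the shared features directly
        self.sprior_branch = [
            Conv2d(3, c, c, pad=1, rng=rng), ReLU(),
            Conv2d(1, c, c, rng=rng),
        ]
        self.layers = (self.trunk + [self.head_heat] + self.off_branch
                       + self.sprior_branch)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def features(self, images: np.ndarray) -> np.ndarray:
        """Trunk feature maps for a (B, H, W) batch; caches the tap activation."""
        x = images[..., None].astype(DTYPE)
        for i, layer in enumerate(self.trunk):
            x = layer.forward(x)
            if i + 1 == self.tap_index:
                self._tap_act = x
        return x

    def sprior_forward(self) -> np.ndarray:
        """Structural feature maps: the prior branch applied at the tap."""
        x = self._tap_act
        for layer in self.sprior_branch:
            x = layer.forward(x)
        return x

    def sprior_backward(self, dS: np.ndarray) -> np.ndarray:
        """Gradient of the prior w.r.t. the tap activation, via the branch."""
        dx = dS.astype(DTYPE)
        for layer in reversed(self.sprior_branch):
            dx = layer.backward(dx)
        return dx

    def sprior_features(self, image: np.ndarray) -> np.ndarray:
        """Structural feature map of one image (H', W', C)."""
        self.features(image[None])
        return self.sprior_forward()[0]

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (features, heatmaps after sigmoid, offsets)."""
        F = self.features(images)
        self._heat_logits = self.head_heat.forward(F)
        heat = sigmoid(self._heat_logits)
        x = F
        for layer in self.off_branch:
            x = layer.forward(x)
        offs = x
        self._heat = heat
        return F, heat, offs

    def backward(
        self,
        dtap_extra: np.ndarray | None,
        dheat: np.ndarray,
        doffs: np.ndarray,
    ) -> None:
        """Backprop: dheat is w.r.t. post-sigmoid heatmaps; ``dtap_extra``
        is the prior's gradient, injected at the tap index."""
        dlogits = dheat * self._heat * (1.0 - self._heat)
        dF = self.head_heat.backward(dlogits.astype(DTYPE))
        dx = doffs.astype(DTYPE)
        for layer in reversed(self.off_branch):
            dx = layer.backward(dx)
        dF += dx
        if dtap_extra is not None and self.tap_index == len(self.trunk):
            dF += dtap_extra.astype(DTYPE)
        for i in reversed(range(len(self.trunk))):
            if dtap_extra is not None and i + 1 == self.tap_index != len(self.trunk):
                dF += dtap_extra.astype(DTYPE)
            dF = self.trunk[i].backward(dF)

    def predict(self, image: np.ndarray, image_id: str = "", **decode_kw) -> DetectionSet:
        _, heat, offs = self.forward(image[None])
        pred = PredictionTensors(
            heatmaps=np.asarray(heat[0], float),
            offsets=np.asarray(offs[0], float),
            stride=self.stride,
        )
        return decode(pred, image_id=image_id, **decode_kw)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p[...] = state[f"p{i}"]

    def save(self, path) -> None:
        np.savez(path, channels=self.channels, stride=self.stride,
                 tap=self.tap_index, **self.state_dict())

    @classmethod
    def load(cls, path) -> "ToyPodNet":
        data = np.load(path)
        tap = "final" if int(data.get("tap", 4)) == 8 else "mid"
        net = cls(channels=int(data["channels"]), stride=int(data["stride"]),
                  sprior_tap=tap)
        net.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
        return net


def _sprior_forward_backward(
    F: np.ndarray,
    seed_cells: list[tuple[int, int]],
    membership: list[int],
) -> tuple[float, float, np.ndarray]:
    """(raw loss, normalized loss, dF) of the SPrior term for one image."""
    dF = np.zeros_like(F)
    if len(seed_cells) < 2:
        return 0.0, 0.0, dF
    idx_y = np.array([c[0] for c in seed_cells])
    idx_x = np.array([c[1] for c in seed_cells])
    V = F[idx_y, idx_x].astype(float)  # N x C
    norms = np.linalg.norm(V, axis=1) + 1e-8
    U = V / norms[:, None]
    A = U @ U.T
    T = sprior_target(membership)
    D = A - T
    raw = float(np.sum(D * D))
    n = len(seed_cells)

    dU = 2.0 * (D + D.T) @ U  # dL/dA is D*2 but A symmetric in U U^T
    dV = (dU - (np.sum(dU * U, axis=1, keepdims=True)) * U) / norms[:, None]
    np.add.at(dF, (idx_y, idx_x), dV.astype(DTYPE))
    return raw, raw / (n * n), dF


def _seed_cells(ann: ImageAnnotation, stride: int, Ho: int, Wo: int):
    cells, members = [], []
    for pod in ann.pods:
        for x, y in pod.seeds:
            cy = min(int(round(y / stride)), Ho - 1)
            cx = min(int(round(x / stride)), Wo - 1)
            cells.append((cy, cx))
            members.append(pod.pod_id)
    return cells, members


def _flip_annotation(ann: ImageAnnotation) -> ImageAnnotation:
    pods = [
        replace(p, seeds=[(ann.width - 1 - x, y) for x, y in p.seeds])
        for p in ann.pods
    ]
    return replace(ann, pods=pods)


@dataclass
class StepLosses:
    l_heat: float
    l_p: float
    l_sprior: float
    total: float


class DivergenceError(RuntimeError):
    pass


def train_step(
    net: ToyPodNet,
    images: np.ndarray,
    targets: list[TargetTensors],
    anns: list[ImageAnnotation],
    config: TrainConfig,
) -> StepLosses:
    """One forward/backward pass over a batch; gradients left on the net.

    The heatmap term is the weighted squared error averaged per entry (the
    per-image entrywise sum, scaled by the constant tensor size, which keeps
    the learning rate geometry-independent); the offset term is smooth-L1 of
    pod-scale-normalized residuals averaged over active entries; the prior
    term defaults to its per-entry-normalized variant.
    """
    B = images.shape[0]
    F, heat, offs = net.forward(images)
    Ht = np.stack([t.heatmaps for t in targets])
    Wt = np.stack([t.heat_weights for t in targets])
    Ot = np.stack([t.offsets for t in targets])
    Mt = np.stack([t.offset_mask for t in targets])
    Zt = np.stack([t.offset_norm for t in targets])

    n_entries = float(np.prod(Ht.shape))
    dh = (heat - Ht).astype(float)
    l_heat = float(np.sum(Wt * dh * dh) / n_entries)
    dheat = (2.0 * Wt * dh) / n_entries

    active = float(Mt.sum())
    if active > 0:
        # residuals stay in cell units; the pod-scale factor weights the
        # loss (not the residual) so large pods are not doubly down-scaled
        resid = (offs - Ot) * Mt
        l_p = float(np.sum(smooth_l1(resid) * Zt) / active)
        dres = np.clip(resid, -1.0, 1.0)
        doffs = config.gamma * dres * Zt * Mt / active
    else:
        l_p, doffs = 0.0, np.zeros_like(offs)

    l_sprior = 0.0
    dtap = None
    if config.rho > 0:
        S = net.sprior_forward()
        dS = np.zeros_like(S)
        Ho, Wo = S.shape[1], S.shape[2]
        for b in range(B):
            cells, members = _seed_cells(anns[b], net.stride, Ho, Wo)
            raw, normed, dSb = _sprior_forward_backward(S[b], cells, members)
            n = max(len(cells), 1)
            if config.normalize_sprior:
                l_sprior += normed / B
                dSb /= n * n
            else:
                l_sprior += raw / B
            dS[b] = dSb * (config.rho / B)
        dtap = net.sprior_backward(dS)

    total = l_heat + config.gamma * l_p + config.rho * l_sprior
    if not np.isfinite(total):
        raise DivergenceError(f"non-finite loss: heat={l_heat} p={l_p} sprior={l_sprior}")
    net.backward(dtap, dheat, doffs)
    return StepLosses(l_heat, l_p, l_sprior, total)


def train_toy(
    dataset: list[tuple[np.ndarray, ImageAnnotation]],
    config: TrainConfig | None = None,
    log_path=None,
) -> tuple[ToyPodNet, list[dict]]:
    """Train the toy detector on (image, annotation) crops.

    Deterministic given ``config.rng_seed`` (up to floating-point reduction
    order).  Returns the trained network and a per-step loss log; the log is
    also written as CSV when ``log_path`` is given.
    """
    config = config or TrainConfig()
    if not dataset:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(config.rng_seed)
    net = ToyPodNet(channels=config.channels, stride=config.stride,
                    rng_seed=config.rng_seed, sprior_tap=config.sprior_tap)
    opt = Adam(net.params, lr=config.lr)
    log: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        if epoch == int(config.lr_decay_at * config.epochs):
            opt.lr = config.lr / 5.0
        order = rng.permutation(len(dataset))
        for start in range(0, len(order), config.batch_size):
            idx = order[start: start + config.batch_size]
            images, targets, anns = [], [], []
            for i in idx:
                img, ann = dataset[i]
                if config.flip_augment and rng.uniform() < 0.5:
                    img = img[:, ::-1].copy()
                    ann = _flip_annotation(ann)
                images.append(img)
                anns.append(ann)
                targets.append(
                    render_targets(
                        ann, stride=config.stride,
                        gaussian_sd=config.gaussian_sd,
                        offset_radius=config.offset_radius,
                    )
                )
            losses = train_step(net, np.stack(images), targets, anns, config)
            opt.step(net.grads)
            step += 1
            log.append(
                {
                    "step": step, "epoch": epoch,
                    "l_heatmaps": losses.l_heat, "l_p": losses.l_p,
                    "l_sprior": losses.l_sprior, "total": losses.total,
                }
            )
    if log_path is not None:
        import pandas as pd

        pd.DataFrame(log).to_csv(log_path, index=False)
    return net, log


def heldout_sprior_loss(
    net: ToyPodNet,
    dataset: list[tuple[np.ndarray, ImageAnnotation]],
) -> float:
    """Mean per-entry-normalized SPrior loss of a model on held-out crops."""
    vals = []
    for img, ann in dataset:
        F = net.sprior_features(img)
        cells, members = _seed_cells(ann, net.stride, F.shape[0], F.shape[1])
        if len(cells) < 2:
            continue
        pvs = PointVectorSet(
            np.asarray([F[cy, cx] for cy, cx in cells], float), np.asarray(members)
        )
        A = cosine_affinity(pvs)
        vals.append(sprior_loss_normalized(A, sprior_target(members)))
    return float(np.mean(vals)) if vals else 0.0
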