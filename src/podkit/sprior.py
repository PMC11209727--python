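"""Structural-prior (SPrior) mathematics.

The structural prior is an auxiliary *training-time* branch: sample the
C-channel feature vector v_i at every annotated seed position, form the
N x N cosine-affinity matrix A, and pull it towards the binary same-pod
matrix A' with an L2 loss.  Seeds of one pod should carry near-identical
channel features; seeds of different pods should not.  Inference never
evaluates any of this.

Also here: the base detector's losses (weighted heatmap MSE, masked and
normalized smooth-L1 offset regression) and their combination
``l_heatmaps + gamma * l_p + rho * l_sprior``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-8  # guards zero-vector norms; cosine of a zero vector is defined as 0


@dataclass
class FeatureMap:
    """H x W x C feature grid with its image-pixels-per-cell stride."""

    values: np.ndarray
    stride: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("FeatureMap values must be H x W x C")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap values must be finite")
        if self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class PointVectorSet:
    """Per-seed channel vectors v_i with their pod memberships."""

    vectors: np.ndarray  # N x C
    membership: np.ndarray  # N pod ids

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.membership = np.asarray(self.membership)
        if self.vectors.shape[0] != self.membership.shape[0]:
            raise ValueError("one membership id per vector required")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


@dataclass
class LossWeights:
    """Trade-off weights: gamma for offset regression, rho for the prior."""

    gamma: float = 0.03
    rho: float = 0.2

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.rho < 0:
            raise ValueError("loss weights must be non-negative")


def extract_point_vectors(
    fmap: FeatureMap,
    seeds: list[tuple[float, float]],
    membership: list[int],
    bilinear: bool = False,
) -> PointVectorSet:
    """Sample the full channel vector at each seed position.

    Image coordinates are divided by the stride; the default is a
    nearest-cell lookup (v_i is the feature *at* the seed's position), with
    bilinear interpolation as an opt-in.  Positions falling outside the grid
    are clamped to the nearest cell.
    """
    H, W, C = fmap.shape
    if len(seeds) == 0:
        return PointVectorSet(np.zeros((0, C)), np.asarray(membership))
    pts = np.asarray(seeds, dtype=float) / fmap.stride
    xs, ys = pts[:, 0], pts[:, 1]
    if bilinear:
        x0 = np.clip(np.floor(xs).astype(int), 0, W - 1)
        y0 = np.clip(np.floor(ys).astype(int), 0, H - 1)
        x1, y1 = np.minimum(x0 + 1, W - 1), np.minimum(y0 + 1, H - 1)
        fx = np.clip(xs - x0, 0.0, 1.0)[:, None]
        fy = np.clip(ys - y0, 0.0, 1.0)[:, None]
        v = (
            fmap.values[y0, x0] * (1 - fx) * (1 - fy)
            + fmap.values[y0, x1] * fx * (1 - fy)
            + fmap.values[y1, x0] * (1 - fx) * fy
            + fmap.values[y1, x1] * fx * fy
        )
    else:
        cx = np.clip(np.rint(xs).astype(int), 0, W - 1)
        cy = np.clip(np.rint(ys).astype(int), 0, H - 1)
        v = fmap.values[cy, cx]
    return PointVectorSet(v, np.asarray(membership))


def cosine_affinity(pvs: PointVectorSet | np.ndarray) -> np.ndarray:
    """N x N matrix of pairwise cosine similarities A_ij = v_i.v_j / |v_i||v_j|.

    Symmetric by construction; a small epsilon in the norm product makes
    zero vectors well-defined (their cosine is 0).
    """
    V = pvs.vectors if isinstance(pvs, PointVectorSet) else np.atleast_2d(np.asarray(pvs, float))
    norms = np.linalg.norm(V, axis=1)
    G = V @ V.T
    A = G / (np.outer(norms, norms) + EPS)
    return (A + A.T) / 2.0


def sprior_target(membership: np.ndarray | list[int]) -> np.ndarray:
    """Binary same-pod matrix A': A'_ij = 1 iff seeds i and j share a pod id."""
    m = np.asarray(membership)
    if m.size == 0:
        return np.zeros((0, 0))
    return (m[:, None] == m[None, :]).astype(float)


def sprior_loss(A: np.ndarray, target: np.ndarray) -> float:
    """Squared Frobenius distance ||A - A'||_2^2, summed without normalization.

    A normalized (per-entry mean) variant is available through
    ``sprior_loss_normalized`` for scale-stable training on variable N.
    """
    A = np.asarray(A, float)
    target = np.asarray(target, float)
    if A.shape != target.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {target.shape}")
    d = A - target
    return float(np.sum(d * d))


def sprior_loss_normalized(A: np.ndarray, target: np.ndarray) -> float:
    n = max(A.shape[0], 1)
    return sprior_loss(A, target) / float(n * n)


def smooth_l1(x: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """Huber-style smooth-L1: quadratic below ``beta``, linear above."""
    ax = np.abs(x)
    return np.where(ax < beta, 0.5 * ax * ax / beta, ax - 0.5 * beta)


def dekr_loss(
    heatmap_pred: np.ndarray,
    heatmap_true: np.ndarray,
    heat_weights: np.ndarray,
    offsets_pred: np.ndarray,
    offsets_true: np.ndarray,
    offset_mask: np.ndarray,
    gamma: float = 0.03,
    offset_beta: float = 1.0,
) -> tuple[float, float, float]:
    """Base keypoint-regression loss: (l_heatmaps, l_p, combined).

    l_heatmaps is the weighted entrywise squared error over all heatmap
    channels; l_p is smooth-L1 over masked offset entries, normalized by the
    number of active entries (offset targets are expected already expressed
    in pod-scale-normalized units); combined = l_heatmaps + gamma * l_p.
    An all-zero mask gives l_p = 0.
    """
    hd = (np.asarray(heatmap_pred, float) - np.asarray(heatmap_true, float))
    l_heat = float(np.sum(np.asarray(heat_weights, float) * hd * hd))

    mask = np.asarray(offset_mask, float)
    active = float(mask.sum())
    if active > 0:
        od = (np.asarray(offsets_pred, float) - np.asarray(offsets_true, float)) * mask
        l_p = float(np.sum(smooth_l1(od, beta=offset_beta) * mask) / active)
    else:
        l_p = 0.0
    return l_heat, l_p, l_heat + gamma * l_p


def total_loss(combined_dekr: float, l_sprior: float, rho: float = 0.2) -> float:
    """Full training objective: base loss plus rho times the structural prior."""
    if rho < 0:
        raise ValueError("rho must be non-negative")
    return float(combined_dekr + rho * l_sprior)
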