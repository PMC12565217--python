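"""Training objectives and segmentation quality metrics.

Objectives
    * restoration loss  L = w_s * (1 - SSIM(Ie, Igt)) + w_1 * mean|Ie - Igt|
    * soft Dice loss over the lesion classes (core, penumbra), background
      excluded, smoothing eps = 1 in numerator and denominator.

Metrics
    * slice-wise Dice and Jaccard; volumetric Dice / IoU obtained by
      summing per-slice intersections and sizes across the stack;
    * Hausdorff distance over boundary voxels (max, 95th-percentile and
      average-symmetric variants), in millimetres via the voxel spacing;
    * trimap F-measure restricted to a band around the true boundary.

Conventions: overlap metrics are 1.0 when both masks are empty (an empty
prediction of an empty truth is correct); distance metrics raise on empty
surfaces and callers skip those slices, reporting the count. SSIM uses the
standard 11x11 Gaussian window (sigma 1.5) with stabilizers C1 = 0.01^2,
C2 = 0.03^2 on the [0, 1] intensity range; the local map is cropped by the
window radius before averaging, so the result is border-mode independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .autodiff import Tensor, as_tensor, conv2d

__all__ = [
    "MaskVolume", "MetricReport", "ssim", "ssim_t", "loss_preproc",
    "loss_preproc_t", "dice_loss", "dice_loss_t", "dice2d", "jaccard2d",
    "dice3d", "iou3d", "hausdorff", "boundary_points", "trimap_f",
    "metric_report",
]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5          # radius 5 -> 11x11 window
_C1 = 0.01 ** 2
_C2 = 0.03 ** 2
DEFAULT_SPACING_3D = (5.0, 0.5, 0.5)  # (z, y, x) mm


@dataclass
class MaskVolume:
    """Stack of per-slice binary masks for core and penumbra (one-hot with
    the implicit background class)."""

    core: np.ndarray
    penumbra: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING_3D

    def __post_init__(self):
        self.core = np.asarray(self.core).astype(bool)
        self.penumbra = np.asarray(self.penumbra).astype(bool)
        if self.core.ndim == 2:
            self.core = self.core[None]
        if self.penumbra.ndim == 2:
            self.penumbra = self.penumbra[None]
        if self.core.shape != self.penumbra.shape:
            raise ValueError("core and penumbra stacks must share shape")
        if (self.core & self.penumbra).any():
            raise ValueError("core and penumbra masks must be disjoint")

    @property
    def n_slices(self) -> int:
        return self.core.shape[0]

    def labels(self) -> np.ndarray:
        """Integer label volume: 0 background, 1 core, 2 penumbra."""
        return self.core.astype(np.int64) + 2 * self.penumbra.astype(np.int64)


@dataclass
class MetricReport:
    dice2d: dict[str, list[float]] = field(default_factory=dict)
    jaccard2d: dict[str, list[float]] = field(default_factory=dict)
    dice3d: dict[str, float] = field(default_factory=dict)
    iou3d: dict[str, float] = field(default_factory=dict)
    hd3d: dict[str, float | None] = field(default_factory=dict)
    hd95: dict[str, float | None] = field(default_factory=dict)
    assd: dict[str, float | None] = field(default_factory=dict)
    trimap_f: dict[str, float | None] = field(default_factory=dict)
    skipped_empty: dict[str, int] = field(default_factory=dict)
    z_interpolated: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "dice2d", "jaccard2d", "dice3d", "iou3d", "hd3d", "hd95",
            "assd", "trimap_f", "skipped_empty", "z_interpolated")}


# --------------------------------------------------------------------------
# SSIM and restoration loss
# --------------------------------------------------------------------------

def _ssim_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    blur = lambda im: ndimage.gaussian_filter(im, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)
    ua, ub = blur(a), blur(b)
    uaa, ubb, uab = blur(a * a), blur(b * b), blur(a * b)
    va, vb = uaa - ua * ua, ubb - ub * ub
    cov = uab - ua * ub
    return (((2 * ua * ub + _C1) * (2 * cov + _C2))
            / ((ua ** 2 + ub ** 2 + _C1) * (va + vb + _C2)))


def ssim(a, b) -> float:
    """Mean structural similarity of two images in [0, 1] (scalar in [-1, 1])."""
    a = np.asarray(a.values if hasattr(a, "values") else a, dtype=np.float64)
    b = np.asarray(b.values if hasattr(b, "values") else b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim == 2:
        a, b = a[None], b[None]
    radius = int(round(_SSIM_SIGMA * _SSIM_TRUNCATE))
    vals = []
    for c in range(a.shape[0]):
        m = _ssim_map(a[c], b[c])
        core = m[radius:-radius, radius:-radius] if min(m.shape) > 2 * radius else m
        vals.append(core.mean())
    return float(np.mean(vals))


def _gauss_window() -> np.ndarray:
    radius = int(round(_SSIM_SIGMA * _SSIM_TRUNCATE))
    x = np.arange(-radius, radius + 1)
    g = np.exp(-(x ** 2) / (2 * _SSIM_SIGMA ** 2))
    g /= g.sum()
    return np.outer(g, g)


def ssim_t(a: Tensor, b: Tensor) -> Tensor:
    """Differentiable SSIM of (N, C, H, W) batches, averaged over all maps.

    The local statistics use valid-mode separable Gaussian convolutions, so
    the averaged map is exactly the border-cropped map of :func:`ssim` and
    no padding convention enters the gradient.
    """
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    radius = int(round(_SSIM_SIGMA * _SSIM_TRUNCATE))
    g1 = np.exp(-(np.arange(-radius, radius + 1) ** 2) / (2 * _SSIM_SIGMA ** 2))
    g1 /= g1.sum()
    n, c, h, w = a.shape
    wv = Tensor(g1.reshape(1, 1, -1, 1))
    wh = Tensor(g1.reshape(1, 1, 1, -1))

    def blur(x):
        x = x.reshape(n * c, 1, h, w)
        x = conv2d(x, wv)      # valid along H
        x = conv2d(x, wh)      # valid along W
        return x

    ua, ub = blur(a), blur(b)
    uaa, ubb, uab = blur(a * a), blur(b * b), blur(a * b)
    va, vb = uaa - ua * ua, ubb - ub * ub
    cov = uab - ua * ub
    m = ((ua * ub * 2.0 + _C1) * (cov * 2.0 + _C2)) \
        / ((ua * ua + ub * ub + _C1) * (va + vb + _C2))
    return m.mean()


def loss_preproc_t(ie: Tensor, igt: Tensor, weight_ssim: float = 1.0,
                   weight_l1: float = 1.0) -> Tensor:
    if weight_ssim < 0 or weight_l1 < 0:
        raise ValueError("loss weights must be non-negative")
    return (1.0 - ssim_t(ie, igt)) * weight_ssim \
        + (ie - igt).abs().mean() * weight_l1


def loss_preproc(ie, igt, weight_ssim: float = 1.0, weight_l1: float = 1.0) -> float:
    """Restoration objective: weighted (1 - SSIM) plus mean absolute error."""
    if weight_ssim < 0 or weight_l1 < 0:
        raise ValueError("loss weights must be non-negative")
    a = np.asarray(ie.values if hasattr(ie, "values") else ie, dtype=np.float64)
    b = np.asarray(igt.values if hasattr(igt, "values") else igt, dtype=np.float64)
    return weight_ssim * (1.0 - ssim(a, b)) + weight_l1 * float(np.abs(a - b).mean())


# --------------------------------------------------------------------------
# Dice loss
# --------------------------------------------------------------------------

def dice_loss_t(pred_soft: Tensor, target: Tensor, eps: float = 1.0) -> Tensor:
    """1 - mean soft Dice over {core, penumbra}; channels (core, pen, bg)."""
    pred_soft, target = as_tensor(pred_soft), as_tensor(target)
    if pred_soft.shape != target.shape or pred_soft.shape[1] < 2:
        raise ValueError("prediction and target must share shape with core "
                         "and penumbra channels first")
    dices = []
    for ch in (0, 1):
        p = pred_soft[:, ch]
        t = target[:, ch]
        inter = (p * t).sum()
        dices.append((inter * 2.0 + eps) / (p.sum() + t.sum() + eps))
    return 1.0 - (dices[0] + dices[1]) * 0.5


def dice_loss(pred_soft: np.ndarray, target: "MaskVolume | np.ndarray",
              eps: float = 1.0) -> float:
    if isinstance(target, MaskVolume):
        tgt = np.stack([target.core, target.penumbra,
                        ~(target.core | target.penumbra)], axis=1).astype(np.float64)
    else:
        tgt = np.asarray(target, dtype=np.float64)
    p = np.asarray(pred_soft, dtype=np.float64)
    if p.ndim == 3:
        p, tgt = p[None], tgt[None] if tgt.ndim == 3 else tgt
    return float(dice_loss_t(Tensor(p), Tensor(tgt), eps=eps).data)


# --------------------------------------------------------------------------
# overlap metrics
# --------------------------------------------------------------------------

def _check_binary(*masks):
    out = []
    for m in masks:
        m = np.asarray(m)
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary")
        out.append(m.astype(bool))
    return out


def dice2d(pred, true) -> float:
    pred, true = _check_binary(pred, true)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    p, t = pred.sum(), true.sum()
    if p == 0 and t == 0:
        return 1.0
    return 2.0 * (pred & true).sum() / (p + t)


def jaccard2d(pred, true) -> float:
    pred, true = _check_binary(pred, true)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    union = (pred | true).sum()
    if union == 0:
        return 1.0
    return (pred & true).sum() / union


def _vol(x) -> np.ndarray:
    if isinstance(x, MaskVolume):
        raise TypeError("pass a per-class binary stack, e.g. vol.core")
    x = np.asarray(x)
    return x[None] if x.ndim == 2 else x


def dice3d(pred, true) -> float:
    """Volumetric Dice: per-slice intersections and sizes summed over the
    stack, then one ratio (equals the voxel-wise 3-D Dice)."""
    pred, true = _check_binary(_vol(pred), _vol(true))
    if pred.shape != true.shape:
        raise ValueError("slice count or shape mismatch")
    p, t = pred.sum(), true.sum()
    if p == 0 and t == 0:
        return 1.0
    return 2.0 * (pred & true).sum() / (p + t)


def iou3d(pred, true) -> float:
    pred, true = _check_binary(_vol(pred), _vol(true))
    if pred.shape != true.shape:
        raise ValueError("slice count or shape mismatch")
    union = (pred | true).sum()
    if union == 0:
        return 1.0
    return (pred & true).sum() / union


# --------------------------------------------------------------------------
# distance metrics
# --------------------------------------------------------------------------

def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Indices of boundary voxels (mask minus its erosion)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros((0, mask.ndim), dtype=np.int64)
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(pred, true, mode: str = "max",
              spacing: tuple[float, ...] | None = None) -> float:
    """Distance between two surfaces in mm.

    ``pred`` / ``true`` are either (n, d) coordinate arrays or binary masks
    (boundary voxels are extracted). Modes: ``max`` (classic Hausdorff),
    ``hd95`` (95th percentile of directed surface distances, symmetrized by
    max), ``assd`` (average symmetric surface distance).
    """
    if mode not in ("max", "hd95", "assd"):
        raise ValueError(f"unknown mode {mode!r}")
    pts_a = _as_points(pred)
    pts_b = _as_points(true)
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise ValueError("undefined distance: empty point set")
    d = pts_a.shape[1]
    sp = np.ones(d) if spacing is None else np.asarray(spacing, dtype=np.float64)
    if sp.shape != (d,):
        raise ValueError(f"spacing must have {d} components")
    a = pts_a * sp
    b = pts_b * sp
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    if mode == "max":
        return float(max(d_ab.max(), d_ba.max()))
    if mode == "hd95":
        return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


def _as_points(x) -> np.ndarray:
    """Boolean arrays are masks (boundary voxels are used); (n, 2) or (n, 3)
    numeric arrays are coordinate lists."""
    x = np.asarray(x)
    if x.dtype == bool:
        return boundary_points(x)
    if x.ndim == 2 and x.shape[1] in (2, 3):
        return x.astype(np.float64)
    return boundary_points(x)


def trimap_f(pred, true, band: int = 5) -> float:
    """F-measure of pred vs true restricted to pixels within ``band`` of the
    true boundary (Euclidean pixel distance)."""
    pred, true = _check_binary(pred, true)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    if not true.any():
        raise ValueError("undefined trimap F: empty true mask")
    bpts = true & ~ndimage.binary_erosion(true, border_value=0)
    dist = ndimage.distance_transform_edt(~bpts)
    region = dist <= band
    p = pred & region
    t = true & region
    tp = (p & t).sum()
    if p.sum() == 0 and t.sum() == 0:
        return 1.0
    if tp == 0:
        return 0.0
    precision = tp / p.sum()
    recall = tp / t.sum()
    return float(2 * precision * recall / (precision + recall))


# --------------------------------------------------------------------------
# full report
# --------------------------------------------------------------------------

def _maybe_interp_z(stack_: np.ndarray, spacing) -> tuple[np.ndarray, tuple]:
    """Nearest-neighbour z-interpolation onto an isotropic-ish grid."""
    factor = spacing[0] / spacing[1]
    reps = max(1, int(round(factor)))
    return np.repeat(stack_, reps, axis=0), (spacing[0] / reps, spacing[1], spacing[2])


def metric_report(pred: MaskVolume, true: MaskVolume, band: int = 5,
                  interpolate_z: bool = False) -> MetricReport:
    """Per-class segmentation report for a predicted vs reference volume."""
    if pred.core.shape != true.core.shape:
        raise ValueError("prediction and truth volumes must share shape")
    rep = MetricReport(z_interpolated=interpolate_z)
    for cls in ("core", "penumbra"):
        p3 = getattr(pred, cls)
        t3 = getattr(true, cls)
        rep.dice2d[cls] = [dice2d(p3[i], t3[i]) for i in range(p3.shape[0])]
        rep.jaccard2d[cls] = [jaccard2d(p3[i], t3[i]) for i in range(p3.shape[0])]
        rep.dice3d[cls] = dice3d(p3, t3)
        rep.iou3d[cls] = iou3d(p3, t3)
        sp = true.spacing
        pp, tt = p3, t3
        if interpolate_z:
            pp, sp2 = _maybe_interp_z(p3, sp)
            tt, sp = _maybe_interp_z(t3, sp)[0], sp2
        try:
            rep.hd3d[cls] = hausdorff(pp, tt, "max", sp)
            rep.hd95[cls] = hausdorff(pp, tt, "hd95", sp)
            rep.assd[cls] = hausdorff(pp, tt, "assd", sp)
            rep.skipped_empty[cls] = 0
        except ValueError:
            rep.hd3d[cls] = rep.hd95[cls] = rep.assd[cls] = None
            rep.skipped_empty[cls] = 1
        try:
            fs = [trimap_f(p3[i], t3[i], band) for i in range(p3.shape[0])
                  if t3[i].any()]
            rep.trimap_f[cls] = float(np.mean(fs)) if fs else None
        except ValueError:
            rep.trimap_f[cls] = None
    return rep
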