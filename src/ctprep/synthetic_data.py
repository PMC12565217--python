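"""Procedural brain-CT-like phantoms and the paired soft-degradation dataset.

Every other module is testable without downloads through three generators:

* ``generate_phantom`` - a 512x512 windowed slice with an elliptical
  high-intensity skull ring, a smooth textured brain interior, and (with
  configurable probability) a subtle hypodense lesion: a penumbra blob
  containing a darker core blob, with consistent disjoint masks. The
  phantom is procedural and claims no anatomical realism; it carries the
  statistical structure the method assumes (smooth tissue, bright ring,
  graded low-contrast lesion).
* ``generate_uniform_phantom`` - constant-intensity negative controls for
  the artifact-safety protocol.
* ``soft_augment`` - the mild paired degradations used to manufacture
  supervised restoration data from clean slices: Gaussian blur with
  sigma in [0, 0.20] px, additive Gaussian noise with variance drawn from
  [10, 50] on the 8-bit scale (sd/255 in intensity units), center crop to
  [400, 512] followed by resize back to 512, rotation in [-10, 10] degrees,
  and brightness/contrast scaling in [-20%, +20%]. Each transform fires
  independently with its configured probability; every draw is recorded.

All randomness is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .io_windowing import WindowedImage
from .losses_metrics import MaskVolume

__all__ = ["DegradationSpec", "PhantomSample", "generate_phantom",
           "generate_edge_slice", "generate_uniform_phantom", "soft_augment",
           "build_paired_dataset"]


@dataclass
class DegradationSpec:
    blur_sigma_range: tuple[float, float] = (0.0, 0.20)
    noise_var_range: tuple[float, float] = (10.0, 50.0)   # 8-bit scale
    crop_range: tuple[int, int] = (400, 512)
    rotation_deg_range: tuple[float, float] = (-10.0, 10.0)
    bc_range: tuple[float, float] = (-0.20, 0.20)
    p_blur: float = 0.5
    p_noise: float = 0.5
    p_crop: float = 0.5
    p_rotation: float = 0.5
    p_brightness: float = 0.5
    p_contrast: float = 0.5

    def __post_init__(self):
        for p in (self.p_blur, self.p_noise, self.p_crop, self.p_rotation,
                  self.p_brightness, self.p_contrast):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PhantomSample:
    clean: WindowedImage
    masks: MaskVolume
    degraded: WindowedImage | None = None
    seed: int = 0
    params_applied: dict = field(default_factory=dict)


def _ellipse(h, w, cy, cx, ry, rx, angle_deg=0.0):
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    y, x = yy - cy, xx - cx
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_phantom(seed: int, size: int = 512,
                     lesion_probability: float = 1.0) -> PhantomSample:
    """One clean windowed phantom slice with core/penumbra/background masks."""
    if size < 128:
        raise ValueError("size must be at least 128")
    rng = np.random.default_rng(seed)
    h = w = size
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    ry = rng.uniform(0.38, 0.42) * h
    rx = rng.uniform(0.33, 0.38) * w
    outer = _ellipse(h, w, cy, cx, ry, rx)
    inner = _ellipse(h, w, cy, cx, ry - 0.035 * h, rx - 0.035 * w)
    skull = outer & ~inner

    img = np.zeros((h, w))
    # brain parenchyma: mid-gray with large-scale smooth texture
    base = rng.uniform(0.42, 0.5)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 0.06 * size)
    texture *= 0.05 / max(texture.std(), 1e-9)
    # faint ventricle-like darker region near the center
    vent = _ellipse(h, w, cy, cx, 0.10 * h, 0.05 * w, rng.uniform(-25, 25))
    img[inner] = np.clip(base + texture, 0.2, 0.8)[inner]
    img[vent & inner] -= 0.12
    img[skull] = 1.0

    core = np.zeros((h, w), bool)
    pen = np.zeros((h, w), bool)
    if rng.uniform() < lesion_probability:
        # hypodense lesion: penumbra blob containing a darker core blob
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.35, 0.6)
        ly = cy + rad * (ry - 0.08 * h) * np.sin(ang)
        lx = cx + rad * (rx - 0.08 * w) * np.cos(ang)
        pry = rng.uniform(0.07, 0.12) * h
        prx = rng.uniform(0.07, 0.12) * w
        pen_full = _ellipse(h, w, ly, lx, pry, prx, rng.uniform(0, 180)) & inner
        cry, crx = pry * rng.uniform(0.35, 0.55), prx * rng.uniform(0.35, 0.55)
        core = _ellipse(h, w, ly, lx, cry, crx, rng.uniform(0, 180)) & pen_full
        pen = pen_full & ~core
        # graded hypodensity: penumbra slightly dark, core darker
        img[pen_full] -= 0.04
        img[core] -= 0.05
    img = np.clip(img, 0.0, 1.0)
    # stored single-channel; consumers triplicate when a CNN needs 3 planes
    clean = WindowedImage(img)
    masks = MaskVolume(core[None], pen[None])
    return PhantomSample(clean=clean, masks=masks, seed=int(seed),
                         params_applied={})


def generate_edge_slice(seed: int, size: int = 512) -> PhantomSample:
    """A near-empty apex/base slice: air background, a faint partial skull
    cap and mild noise, no lesion. Real CT volumes contain many such
    low-content slices and a preprocessor must learn to leave them alone."""
    rng = np.random.default_rng(seed)
    h = w = size
    img = np.abs(rng.normal(0.0, 0.01, (h, w)))
    if rng.uniform() < 0.7:
        cy = h * rng.uniform(0.45, 0.55)
        cx = w * rng.uniform(0.45, 0.55)
        r = rng.uniform(0.08, 0.22)
        cap_outer = _ellipse(h, w, cy, cx, r * h, r * w)
        cap_inner = _ellipse(h, w, cy, cx, (r - 0.03) * h, (r - 0.03) * w)
        img[cap_outer & ~cap_inner] = 1.0
        img[cap_inner] = np.clip(rng.uniform(0.35, 0.45)
                                 + rng.normal(0, 0.02, cap_inner.sum()), 0, 1)
    img = np.clip(img, 0.0, 1.0)
    empty = np.zeros((1, h, w), bool)
    return PhantomSample(clean=WindowedImage(img),
                         masks=MaskVolume(empty, empty.copy()),
                         seed=int(seed), params_applied={})


def generate_uniform_phantom(value: float, size: int = 512) -> WindowedImage:
    if not 0.0 <= value <= 1.0:
        raise ValueError("value must lie in [0, 1]")
    return WindowedImage(np.full((3, size, size), float(value)))


def _resize_plane(plane: np.ndarray, out: int) -> np.ndarray:
    return Tensor(plane).resize_bilinear(out, out).data


def soft_augment(clean: WindowedImage, spec: DegradationSpec, seed: int,
                 masks: MaskVolume | None = None):
    """Degrade a clean slice; returns (degraded, params, transformed_masks).

    Masks, when given, follow the geometric part of the draw with
    nearest-neighbour resampling so the one-hot structure survives. The
    returned ``degraded`` always has the input's size.
    """
    rng = np.random.default_rng(seed)
    img = clean.plane().copy()
    size = img.shape[0]
    params: dict = {}

    core = masks.core[0].copy() if masks is not None else None
    pen = masks.penumbra[0].copy() if masks is not None else None

    # -- geometric degradations (masks follow with nearest-neighbour) -----
    if rng.uniform() < spec.p_rotation:
        ang = rng.uniform(*spec.rotation_deg_range)
        params["rotation_deg"] = float(ang)
        img = ndimage.rotate(img, ang, reshape=False, order=1, mode="nearest")
        if core is not None:
            core = ndimage.rotate(core.astype(np.uint8), ang, reshape=False,
                                  order=0, mode="constant") > 0
            pen = ndimage.rotate(pen.astype(np.uint8), ang, reshape=False,
                                 order=0, mode="constant") > 0
    if rng.uniform() < spec.p_crop:
        lo, hi = spec.crop_range
        lo = min(lo, size)
        s = int(rng.integers(lo, min(hi, size) + 1))
        params["crop_size"] = s
        off = (size - s) // 2
        sl = slice(off, off + s)
        img = _resize_plane(img[sl, sl], size)
        if core is not None:
            core = _nearest_resize(core[sl, sl], size)
            pen = _nearest_resize(pen[sl, sl], size)

    # -- photometric degradations -----------------------------------------
    if rng.uniform() < spec.p_blur:
        sx = rng.uniform(*spec.blur_sigma_range)
        sy = rng.uniform(*spec.blur_sigma_range)
        params["blur_sigma"] = (float(sx), float(sy))
        img = ndimage.gaussian_filter(img, (sy, sx), mode="nearest")
    if rng.uniform() < spec.p_noise:
        var = rng.uniform(*spec.noise_var_range)
        params["noise_var_8bit"] = float(var)
        img = img + rng.normal(0.0, np.sqrt(var) / 255.0, img.shape)
    if rng.uniform() < spec.p_brightness:
        b = rng.uniform(*spec.bc_range)
        params["brightness"] = float(b)
        img = img + b
    if rng.uniform() < spec.p_contrast:
        c = rng.uniform(*spec.bc_range)
        params["contrast"] = float(c)
        img = 0.5 + (img - 0.5) * (1.0 + c)

    img = np.clip(img, 0.0, 1.0)
    degraded = WindowedImage(img, spacing=clean.spacing)
    out_masks = None
    if masks is not None:
        pen = pen & ~core  # resampling can graze the shared boundary
        out_masks = MaskVolume(core[None], pen[None], spacing=masks.spacing)
    return degraded, params, out_masks


def _nearest_resize(mask: np.ndarray, out: int) -> np.ndarray:
    idx = np.clip(np.round((np.arange(out) + 0.5) * mask.shape[0] / out - 0.5),
                  0, mask.shape[0] - 1).astype(int)
    return mask[np.ix_(idx, idx)]


def build_paired_dataset(n: int, seed: int, spec: DegradationSpec | None = None,
                         size: int = 512, lesion_probability: float = 1.0,
                         geometric_on_target: bool = True,
                         max_redraws: int = 5,
                         store_size: int | None = None,
                         edge_slice_fraction: float = 0.15) -> list[PhantomSample]:
    """n degraded/clean phantom pairs, fully reproducible from the seed.

    Geometric transforms move the lesion, so the masks follow the degraded
    geometry; with ``geometric_on_target`` the clean (target) image is
    replayed through the same geometry so the restoration pair stays
    spatially aligned and only photometric degradation separates source
    from target. Draws that destroy more than 25% of the core are redrawn
    (count recorded per sample).

    ``store_size`` optionally downscales each finished pair (bilinear for
    images, nearest for masks) before it is kept, so a large dataset
    generated at full acquisition resolution can be held at its training
    resolution.

    A fraction of the samples (default 15%) are near-empty apex/base
    slices, mirroring the low-content slices every real CT volume
    contributes to training.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if spec is None:
        spec = DegradationSpec()
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(2 * n + 8) % (2 ** 31)
    samples = []
    for i in range(n):
        kind_draw = (child_seeds[2 * i] % 10_000) / 10_000.0
        if kind_draw < edge_slice_fraction:
            sample = generate_edge_slice(int(child_seeds[2 * i]), size=size)
        else:
            sample = generate_phantom(int(child_seeds[2 * i]), size=size,
                                      lesion_probability=lesion_probability)
        aug_seed = int(child_seeds[2 * i + 1])
        core_area = sample.masks.core.sum()
        for attempt in range(max_redraws + 1):
            degraded, params, moved = soft_augment(
                sample.clean, spec, aug_seed + attempt, masks=sample.masks)
            if core_area == 0 or moved.core.sum() >= 0.75 * core_area:
                break
        params["redraws"] = attempt
        if geometric_on_target:
            target = _replay_geometry(sample.clean, params)
            sample = PhantomSample(clean=target, masks=moved, degraded=degraded,
                                   seed=sample.seed, params_applied=params)
        else:
            sample = PhantomSample(clean=sample.clean, masks=sample.masks,
                                   degraded=degraded, seed=sample.seed,
                                   params_applied=params)
        if store_size is not None and store_size != size:
            sample = _shrink_sample(sample, store_size)
        samples.append(sample)
    return samples


def _shrink_sample(sample: PhantomSample, out: int) -> PhantomSample:
    clean = WindowedImage(np.clip(_resize_plane(sample.clean.plane(), out), 0, 1),
                          spacing=sample.clean.spacing)
    degraded = None
    if sample.degraded is not None:
        degraded = WindowedImage(
            np.clip(_resize_plane(sample.degraded.plane(), out), 0, 1),
            spacing=sample.degraded.spacing)
    masks = MaskVolume(_nearest_resize(sample.masks.core[0], out)[None],
                       _nearest_resize(sample.masks.penumbra[0], out)[None],
                       spacing=sample.masks.spacing)
    return PhantomSample(clean=clean, masks=masks, degraded=degraded,
                         seed=sample.seed, params_applied=sample.params_applied)


def _replay_geometry(clean: WindowedImage, params: dict) -> WindowedImage:
    img = clean.plane().copy()
    size = img.shape[0]
    if "rotation_deg" in params:
        img = ndimage.rotate(img, params["rotation_deg"], reshape=False,
                             order=1, mode="nearest")
    if "crop_size" in params:
        s = params["crop_size"]
        off = (size - s) // 2
        img = _resize_plane(img[off:off + s, off:off + s], size)
    img = np.clip(img, 0.0, 1.0)
    return WindowedImage(img, spacing=clean.spacing)
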