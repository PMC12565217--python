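"""Differentiable image filters driven by predicted scalar parameters.

Each filter is a pure transform ``F(I, params)`` on a 3-channel [0, 1]
image. The enhancement pipeline composes them through their *residual* form
``delta = F(I, p) - I`` summed onto the original image, so that neutral
parameters leave the input untouched and no filter ever synthesizes pixels
on its own.

The bank contains:

* ``brightness`` - additive global offset b in [-1, 1].
* ``contrast``   - piecewise-linear stretch about mid-gray with factor
  s(r) = 1/(1-r) for r > 0 and (1-r) otherwise, r in [-1, 1). The default
  mode restores the 0.5 pivot (identity at r = 0); ``literal`` mode applies
  the raw ``(I - 0.5) * s(r)`` map without the restore.
* ``sharpen``    - convolution with (K + M q) / nu(q), where K is a fixed
  5x5 high-pass matrix (binomial surround, -476 center), M a fixed ring
  map (0.8 outer / 0.9 middle / 1 center) and nu(q) = sum(K + M q)
  = -256 + 21 q; one intensity q per channel.
* ``gaussian_blur`` - (2k+1)^2 samples of the centered 2-D Gaussian,
  renormalized to unit sum; sigma predicted per image.
* ``median``     - exact 3x3 median (non-trainable; order statistic).
* ``kernel_combo`` - softmax-weighted sum of frozen multi-scale kernels
  (5x5, 7x7, 11x11) extracted from a pretrained skip-convolution U-Net;
  only the combination logits train.

All convolutions use reflect padding. Filters accept either numpy arrays
or autodiff tensors; gradients flow through every trainable path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, as_tensor, stack

__all__ = [
    "SHARPNESS_K", "SHARPNESS_M", "sharpness_nu",
    "GaussianSpec", "ContrastParam", "KernelBank",
    "gaussian_kernel", "gaussian_blur", "sharpness_apply", "contrast_apply",
    "brightness_apply", "median_apply", "kernel_combo_apply",
    "FILTERS", "get_filter", "residual", "SIGMA_MAX",
]

# Fixed 5x5 sharpening matrices. K is the outer product of [1,4,6,4,1] with
# itself, with the center replaced by -476 (sum = 256 - 36 - 476 = -256).
SHARPNESS_K = np.array([
    [1, 4, 6, 4, 1],
    [4, 16, 24, 16, 4],
    [6, 24, -476, 24, 6],
    [4, 16, 24, 16, 4],
    [1, 4, 6, 4, 1],
], dtype=np.float64)

# Ring map: 0.8 on the outer ring, 0.9 on the middle ring, 1 at center
# (sum = 16*0.8 + 8*0.9 + 1 = 21).
SHARPNESS_M = np.array([
    [0.8, 0.8, 0.8, 0.8, 0.8],
    [0.8, 0.9, 0.9, 0.9, 0.8],
    [0.8, 0.9, 1.0, 0.9, 0.8],
    [0.8, 0.9, 0.9, 0.9, 0.8],
    [0.8, 0.8, 0.8, 0.8, 0.8],
], dtype=np.float64)

#: upper bound of the trainable blur radius (pixels); sigma -> 0 is identity
SIGMA_MAX = 2.0


def sharpness_nu(q: float) -> float:
    """Normalizer nu(q) = sum(K + M q) = -256 + 21 q."""
    return -256.0 + 21.0 * q


@dataclass
class GaussianSpec:
    """Sampled centered 2-D Gaussian kernel specification."""

    sigma: float
    k: int = 2
    separable: bool = True

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k < 1:
            raise ValueError("k must be at least 1")


@dataclass
class ContrastParam:
    r: float

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        if self.r >= 1.0:
            raise ValueError("r = 1 gives an infinite contrast scale")


@dataclass
class KernelBank:
    """Frozen convolution kernels with softmax-combined weights."""

    kernels: list[np.ndarray]
    alpha_logits: np.ndarray = None  # type: ignore[assignment]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.kernels:
            raise ValueError("kernel bank must contain at least one kernel")
        self.kernels = [np.asarray(k, dtype=np.float64) for k in self.kernels]
        for k in self.kernels:
            if not np.isfinite(k).all():
                raise ValueError("bank kernels must be finite")
            if k.ndim != 2 or k.shape[0] != k.shape[1] or k.shape[0] % 2 == 0:
                raise ValueError("bank kernels must be odd square matrices")
        if self.alpha_logits is None:
            self.alpha_logits = np.zeros(len(self.kernels))
        self.alpha_logits = np.asarray(self.alpha_logits, dtype=np.float64)
        if self.alpha_logits.shape != (len(self.kernels),):
            raise ValueError("one logit per kernel required")

    @property
    def alphas(self) -> np.ndarray:
        z = self.alpha_logits - self.alpha_logits.max()
        e = np.exp(z)
        return e / e.sum()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"),
                 alpha_logits=self.alpha_logits,
                 **{f"kernel_{i}": k for i, k in enumerate(self.kernels)})
        meta = dict(self.manifest)
        meta["sizes"] = [int(k.shape[0]) for k in self.kernels]
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "KernelBank":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            n = sum(1 for k in data.files if k.startswith("kernel_"))
            kernels = [data[f"kernel_{i}"] for i in range(n)]
            logits = data["alpha_logits"]
        mpath = path.with_suffix(".json")
        manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
        return cls(kernels, logits, manifest)


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def _to_nchw(img) -> tuple[Tensor, tuple[int, ...], bool]:
    """Accept (H,W), (C,H,W) or (N,C,H,W); return 4-D tensor + restore info."""
    t = as_tensor(img)
    shape = t.shape
    if t.ndim == 2:
        t = t.reshape(1, 1, *shape)
    elif t.ndim == 3:
        t = t.reshape(1, *shape)
    elif t.ndim != 4:
        raise ValueError("image must be 2-D, 3-D or 4-D")
    return t, shape, isinstance(img, Tensor)


def _restore(t: Tensor, shape, was_tensor: bool):
    out = t.reshape(shape)
    return out if was_tensor else out.data


def gaussian_kernel(spec: GaussianSpec) -> np.ndarray:
    """(2k+1)x(2k+1) samples of G_sigma, renormalized to sum exactly 1."""
    return _gaussian_kernel_t(as_tensor(float(spec.sigma)), spec.k).data


def _gaussian_kernel_t(sigma: Tensor, k: int) -> Tensor:
    coords = np.arange(-k, k + 1, dtype=np.float64)
    r2 = Tensor(coords[:, None] ** 2 + coords[None, :] ** 2)
    two_s2 = sigma * sigma * 2.0
    g = (-(r2 / two_s2)).exp() / (np.pi * two_s2)
    return g / g.sum()


def _depthwise(x: Tensor, kernel: Tensor) -> Tensor:
    """Convolve each channel of NCHW ``x`` with one 2-D kernel (or a stack
    of per-channel kernels shaped (C, kh, kw)); reflect padding."""
    from .autodiff import depthwise_conv2d

    return depthwise_conv2d(x, kernel, pad_mode="reflect")


# --------------------------------------------------------------------------
# filter transforms
# --------------------------------------------------------------------------

def gaussian_blur(img, spec: GaussianSpec | None = None, *, sigma=None, k: int = 2):
    """Blur with the sampled Gaussian kernel. ``sigma`` may be a Tensor so
    the blur radius itself can be trained."""
    if spec is not None:
        sigma, k = spec.sigma, spec.k
    if sigma is None:
        raise ValueError("provide a GaussianSpec or sigma")
    sig = as_tensor(sigma)
    if np.any(sig.data <= 0):
        raise ValueError("sigma must be positive")
    x, shape, wrap = _to_nchw(img)
    kern = _gaussian_kernel_t(sig, k)
    return _restore(_depthwise(x, kern), shape, wrap)


def sharpness_apply(img, q):
    """Convolve each channel with (K + M q_c)/nu(q_c)."""
    x, shape, wrap = _to_nchw(img)
    c = x.shape[1]
    q = as_tensor(q)
    qv = np.atleast_1d(q.data)
    if np.any(np.abs(qv) > 1 + 1e-9):
        raise ValueError("sharpness intensity q must lie in [-1, 1]")
    if q.ndim == 0:
        q = q.reshape(1)
        qs = [q[0]] * c
    elif q.shape[0] == c:
        qs = [q[i] for i in range(c)]
    else:
        raise ValueError(f"need one q per channel ({c}), got {q.shape}")
    kernels = []
    K, M = Tensor(SHARPNESS_K), Tensor(SHARPNESS_M)
    for qc in qs:
        nu = qc * 21.0 + (-256.0)
        if abs(float(nu.data)) < 1e-6:
            raise ValueError("sharpness normalizer vanished")
        kernels.append((K + M * qc) / nu)
    return _restore(_depthwise(x, stack(kernels, axis=0)), shape, wrap)


def contrast_apply(img, r, literal: bool = False):
    """Piecewise-linear contrast stretch, factor 1/(1-r) for r>0 else (1-r).

    Default mode re-adds the 0.5 pivot so that r = 0 is the identity;
    ``literal`` mode returns (I - 0.5) * s(r) exactly.
    """
    r = as_tensor(r)
    rv = float(np.asarray(r.data).reshape(-1)[0]) if r.size == 1 else None
    if rv is not None and not -1.0 <= rv < 1.0:
        raise ValueError("contrast parameter r must lie in [-1, 1)")
    x, shape, wrap = _to_nchw(img)
    pos = (np.asarray(r.data) > 0)
    # s(r): both branches evaluated, blended by the (constant) sign mask
    s = as_tensor(1.0 * pos) / (as_tensor(1.0) - r) \
        + as_tensor(1.0 - 1.0 * pos) * (as_tensor(1.0) - r)
    s = s.reshape(*([1] * x.ndim)) if s.ndim == 0 else s.reshape(1, -1, 1, 1)
    out = (x - 0.5) * s
    if not literal:
        out = out + 0.5
    return _restore(out, shape, wrap)


def brightness_apply(img, b):
    """Additive global brightness offset; clipping is the pipeline's job."""
    b = as_tensor(b)
    if np.any(np.abs(b.data) > 1 + 1e-9):
        raise ValueError("brightness offset b must lie in [-1, 1]")
    x, shape, wrap = _to_nchw(img)
    off = b if b.ndim == 0 else b.reshape(1, -1, 1, 1)
    return _restore(x + off, shape, wrap)


def median_apply(img, window: int = 3):
    """Exact median filter (order statistic), reflect boundary.

    Declared non-trainable: gradients do not flow through it, matching its
    exclusion from the learned part of the bank.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("median window must be odd and >= 3")
    t = as_tensor(img)
    arr = t.data
    if arr.ndim == 2:
        out = ndimage.median_filter(arr, size=window, mode="mirror")
    else:
        out = np.stack([
            ndimage.median_filter(arr[..., c, :, :], size=window, mode="mirror")
            for c in range(arr.shape[-3])
        ], axis=-3)
    return Tensor(out) if isinstance(img, Tensor) else out


def kernel_combo_apply(img, bank: KernelBank, alpha_logits=None):
    """Softmax-weighted sum of the bank's per-kernel convolutions.

    ``alpha_logits`` may be passed as a Tensor to train the combination
    weights while the kernels stay frozen.
    """
    if bank is None or not bank.kernels:
        raise ValueError("kernel bank is empty or missing")
    logits = as_tensor(bank.alpha_logits if alpha_logits is None else alpha_logits)
    alphas = logits.softmax(axis=0)
    x, shape, wrap = _to_nchw(img)
    out = None
    for i, kern in enumerate(bank.kernels):
        yi = _depthwise(x, Tensor(kern)) * alphas[i]
        out = yi if out is None else out + yi
    return _restore(out, shape, wrap)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterInfo:
    """Registry entry: how many scalar parameters a filter consumes, their
    activation range, and the transform itself."""

    name: str
    n_params: int
    range_tag: str              # "unit", "signed" or "free"
    fn: object
    neutral: tuple | None       # residual-vanishing parameters, or None
    trainable: bool = True


def _blur_from_unit(img, u):
    # predicted unit-range parameter scaled into (0, SIGMA_MAX]
    sig = as_tensor(u) * SIGMA_MAX + 1e-4
    return gaussian_blur(img, sigma=sig if sig.ndim == 0 else sig[0], k=2)


# The pipeline's predicted brightness/contrast corrections are scaled from
# the tanh range into +-CORRECTIVE_RANGE: the preprocessor exists to undo
# +-20% photometric degradations, so its global corrections are bounded to
# that order of magnitude. This is part of the artifact-safety design (a
# bounded filter cannot blow a slice out to the clip rails) and also keeps
# the contrast stretch finite when the activation saturates. The library
# functions brightness_apply/contrast_apply accept the full [-1, 1] range.
CORRECTIVE_RANGE = 0.25


def _scalar(p):
    p = as_tensor(p)
    return p if p.ndim == 0 else p[0]


FILTERS: dict[str, FilterInfo] = {
    "brightness": FilterInfo("brightness", 1, "signed",
                             lambda img, p: brightness_apply(
                                 img, _scalar(p) * CORRECTIVE_RANGE),
                             neutral=(0.0,)),
    "contrast": FilterInfo("contrast", 1, "signed",
                           lambda img, p: contrast_apply(
                               img, _scalar(p) * CORRECTIVE_RANGE),
                           neutral=(0.0,)),
    "sharpen": FilterInfo("sharpen", 3, "signed", sharpness_apply, neutral=None),
    "gaussian blur": FilterInfo("gaussian blur", 1, "unit", _blur_from_unit,
                                neutral=None),
    "median filter": FilterInfo("median filter", 0, "free",
                                lambda img, p=None: median_apply(img, 3),
                                neutral=None, trainable=False),
}

#: registry name of the pretrained multi-scale combination block
CB_NAME = "CB 5×5+7×7+11×11"


def get_filter(name: str) -> FilterInfo:
    if name == CB_NAME or name.lower().startswith("cb"):
        return FilterInfo(CB_NAME, 3, "free",
                          lambda img, p, bank=None: kernel_combo_apply(img, bank, p),
                          neutral=None)
    try:
        return FILTERS[name]
    except KeyError:
        raise KeyError(f"unknown filter {name!r}; known: "
                       f"{sorted(FILTERS) + [CB_NAME]}") from None


def residual(name: str, img, params, bank: KernelBank | None = None):
    """delta = F(img, params) - img for the named filter."""
    info = get_filter(name)
    x = as_tensor(img)
    if info.name == CB_NAME:
        y = kernel_combo_apply(x, bank, params)
    elif info.n_params == 0:
        y = info.fn(x)
    else:
        y = info.fn(x, params)
    out = y - x
    return out if isinstance(img, Tensor) else out.data
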