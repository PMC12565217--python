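"""CT input handling: Hounsfield-unit windowing, channel triplication,
downscaling, and reading/writing of DICOM, NIfTI and PNG data.

A non-contrast brain CT slice arrives as a rectangular grid of Hounsfield
units (HU; water = 0, air ~ -1000). The clinical brain window (width 80 HU
centred at level 40 HU) maps the diagnostically relevant interval
[WL - WW/2, WL + WW/2] = [0, 80] HU linearly onto display intensities
[0, 1], clipping outside. The single windowed channel is then copied to
three identical planes purely as a tensor-shape convention for CNN
backbones; no chromatic information is introduced.

Coordinates are row-major, origin top-left, 0-based. Slices of a volume are
ordered by ascending ``slice_index`` with filename as tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .autodiff import Tensor

__all__ = [
    "RawCTSlice", "WindowedImage", "hu_window", "triplicate_channels",
    "downscale", "read_volume", "write_png", "read_png",
    "read_mask_png", "write_mask_png",
]

DEFAULT_SPACING = (0.5, 0.5)  # mm in-plane
DEFAULT_THICKNESS = 5.0       # mm between slices


@dataclass
class RawCTSlice:
    """One CT slice in calibrated Hounsfield units."""

    hu: np.ndarray
    pixel_spacing: tuple[float, float] = DEFAULT_SPACING
    slice_thickness: float = DEFAULT_THICKNESS
    slice_index: int = 0

    def __post_init__(self):
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 2:
            raise ValueError("hu grid must be 2-D")
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing and thickness must be positive")


@dataclass
class WindowedImage:
    """Display-normalized slice with values in [0, 1].

    ``values`` is (H, W) for one channel or (3, H, W) for the triplicated
    form, in which case all three planes are identical copies.
    """

    values: np.ndarray
    spacing: tuple[float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be (H, W) or (C, H, W)")
        if self.values.ndim == 3 and self.values.shape[0] not in (1, 3):
            raise ValueError("channel axis must be 1 or 3")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("windowed intensities must lie in [0, 1]")

    @property
    def channels(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[-2]

    @property
    def width(self) -> int:
        return self.values.shape[-1]

    def plane(self) -> np.ndarray:
        """First (or only) channel as a 2-D array."""
        return self.values if self.values.ndim == 2 else self.values[0]


def hu_window(ct: RawCTSlice, window_width: float = 80.0,
              window_level: float = 40.0) -> WindowedImage:
    """Linear window map clip((hu - (WL - WW/2)) / WW, 0, 1)."""
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    lo = window_level - window_width / 2.0
    vals = np.clip((np.asarray(ct.hu, dtype=np.float64) - lo) / window_width, 0.0, 1.0)
    return WindowedImage(vals, spacing=ct.pixel_spacing)


def triplicate_channels(img: WindowedImage) -> WindowedImage:
    if img.channels == 3:
        warnings.warn("image already has 3 channels; returning unchanged")
        return img
    return WindowedImage(np.broadcast_to(img.plane(), (3,) + img.plane().shape).copy(),
                         spacing=img.spacing)


def downscale(img: WindowedImage, target: int = 128) -> WindowedImage:
    """Bilinear resize (half-pixel centered) to target x target."""
    if target < 8:
        raise ValueError("target must be at least 8 pixels")
    resized = Tensor(img.values).resize_bilinear(target, target).data
    return WindowedImage(np.clip(resized, 0.0, 1.0), spacing=img.spacing)


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def read_volume(path: str | Path) -> list[RawCTSlice]:
    """Read a DICOM series directory or a NIfTI file into ordered HU slices."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return _read_nifti(path)
    if path.suffix == ".dcm":
        return _read_dicom_files([path])
    raise IOError(f"cannot read CT volume from {path}: "
                  "expected a DICOM directory or a NIfTI file")


def _read_dicom_dir(path: Path) -> list[RawCTSlice]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        warnings.warn(f"no DICOM files found under {path}")
        return []
    return _read_dicom_files(files)


def _read_dicom_files(files) -> list[RawCTSlice]:
    import pydicom

    slices = []
    for f in sorted(files, key=lambda p: p.name):
        try:
            ds = pydicom.dcmread(str(f), force=True)
            arr = ds.pixel_array.astype(np.float64)
        except Exception as exc:  # noqa: BLE001 - rewrap with filename
            raise IOError(f"unreadable DICOM file {f}: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        spacing = tuple(float(s) for s in getattr(ds, "PixelSpacing", DEFAULT_SPACING))
        thickness = float(getattr(ds, "SliceThickness", DEFAULT_THICKNESS))
        index = int(getattr(ds, "InstanceNumber", len(slices)))
        slices.append(RawCTSlice(arr * slope + intercept, spacing[:2],
                                 thickness, index))
    slices.sort(key=lambda s: s.slice_index)
    return slices


def _read_nifti(path: Path) -> list[RawCTSlice]:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 2:
        data = data[..., None]
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else DEFAULT_SPACING
    thickness = float(zooms[2]) if len(zooms) >= 3 else DEFAULT_THICKNESS
    return [RawCTSlice(data[:, :, k].T, spacing, thickness, k)
            for k in range(data.shape[2])]


def write_png(img: WindowedImage, path: str | Path) -> None:
    """8-bit grayscale PNG; intensities quantized as round(v * 255)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    arr = np.round(img.plane() * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def read_png(path: str | Path) -> WindowedImage:
    path = Path(path)
    try:
        arr = np.asarray(Image.open(str(path)).convert("L"), dtype=np.float64)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"unreadable PNG {path}: {exc}") from exc
    return WindowedImage(arr / 255.0)


# label codes for mask images: 0 = background, 1 = ischemic core, 2 = penumbra
_PALETTE = [0, 0, 0, 255, 0, 0, 255, 255, 0] + [0] * (256 * 3 - 9)


def write_mask_png(labels: np.ndarray, path: str | Path) -> None:
    """Paletted PNG with integer codes {0: background, 1: core, 2: penumbra}."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("mask labels must be 0, 1 or 2")
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    im.putpalette(_PALETTE)
    im.save(str(Path(path)))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(str(Path(path))), dtype=np.int64)
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError(f"mask {path} contains labels outside {{0,1,2}}")
    return arr
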