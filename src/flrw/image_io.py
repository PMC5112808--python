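"""Image grids, masks, and file I/O.

Grids are plain NumPy arrays with spacing metadata.  Axis order is fixed as
(H, W) in 2-D and (D, H, W) in 3-D with index 0 the slice axis; spacing is
stored in the same order, in millimetres.  MetaImage and NIfTI files are read
and written through SimpleITK (which stores spacing in (x, y, z) order, i.e.
reversed); PNG through imageio (2-D, unit spacing, raw gray values).
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ConfigError, FormatError, IOError_

__all__ = [
    "ImageGrid",
    "LabelMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "denoise",
    "rescale_intensity",
]


@dataclass
class ImageGrid:
    """A 2-D or 3-D scalar intensity field with physical spacing.

    Parameters
    ----------
    values : ndarray
        Intensities, shape (H, W) or (D, H, W); stored as float64.
    spacing : tuple of float
        Physical voxel size per axis in mm, same order as ``values.shape``.
    intensity_unit : str
        ``"raw-gray"`` or ``"HU"``; informational only.
    """

    values: np.ndarray
    spacing: tuple = None
    intensity_unit: str = "raw-gray"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise FormatError(f"ImageGrid must be 2-D or 3-D, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise FormatError(f"degenerate shape {self.values.shape}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.values.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.values.ndim:
            raise FormatError("spacing length must match dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("image contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    @property
    def ndim(self):
        return self.values.ndim


@dataclass
class LabelMask:
    """Binary {0,1} mask on the same grid as its image."""

    labels: np.ndarray
    spacing: tuple = None

    def __post_init__(self):
        lab = np.asarray(self.labels)
        uniq = np.unique(lab)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask values must be exactly {{0,1}}, got {uniq[:10]}")
        self.labels = lab.astype(np.uint8)
        if self.labels.ndim not in (2, 3):
            raise FormatError("LabelMask must be 2-D or 3-D")
        if self.spacing is None:
            self.spacing = (1.0,) * self.labels.ndim
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.labels.shape

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


def _infer_format(path: str) -> str:
    p = path.lower()
    if p.endswith(".mhd") or p.endswith(".mha"):
        return "metaimage"
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        return "nifti"
    if p.endswith(".png"):
        return "png"
    if os.path.isdir(path):
        return "png-stack"
    raise FormatError(f"cannot infer image format from path {path!r}")


def _read_png_2d(path: str) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.all(arr[..., :3] == arr[..., :1]):
            arr = arr[..., 0]
        else:
            raise FormatError(f"PNG {path!r} is not grayscale")
    return np.asarray(arr, dtype=np.float64)


def read_image(path: str, format: str | None = None) -> ImageGrid:
    """Read a grid from MetaImage, NIfTI, a single PNG, or a PNG stack directory.

    Spacing is taken from the header when the format carries one, else unit.
    """
    fmt = format or _infer_format(path)
    if fmt in ("metaimage", "nifti"):
        if not os.path.exists(path):
            raise IOError_(f"no such file: {path!r}")
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:
            raise IOError_(f"unreadable image file {path!r}: {exc}") from exc
        values = sitk.GetArrayFromImage(img)  # (z, y, x) or (y, x)
        spacing = tuple(reversed(img.GetSpacing()))
        if values.ndim == 3 and values.shape[0] == 1:
            # SimpleITK promotes some 2-D files to a one-slice volume
            values = values[0]
            spacing = spacing[1:]
        return ImageGrid(values=values, spacing=spacing)
    if fmt == "png":
        if not os.path.exists(path):
            raise IOError_(f"no such file: {path!r}")
        return ImageGrid(values=_read_png_2d(path), spacing=(1.0, 1.0))
    if fmt == "png-stack":
        files = sorted(glob.glob(os.path.join(path, "*.png")))
        if not files:
            raise IOError_(f"no PNG slices found in {path!r}")
        slices = [_read_png_2d(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent slice sizes in PNG stack {path!r}: {shapes}")
        return ImageGrid(values=np.stack(slices), spacing=(1.0, 1.0, 1.0))
    raise FormatError(f"unknown image format {fmt!r}")


def write_image(grid, path: str, format: str | None = None) -> None:
    """Write a grid (or mask) losslessly; PNG only accepts 8-bit data."""
    fmt = format or _infer_format(path)
    if isinstance(grid, LabelMask):
        values, spacing = grid.labels, grid.spacing
    else:
        values, spacing = grid.values, grid.spacing
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise IOError_(f"directory not writable: {parent!r}")
    if fmt in ("metaimage", "nifti"):
        if values.dtype == np.uint8:
            arr = values
        else:
            arr = values.astype(np.float32)
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(tuple(reversed(spacing)))
        sitk.WriteImage(img, path)
        return
    if fmt == "png":
        if values.ndim != 2:
            raise FormatError("PNG output requires a 2-D grid")
        rounded = np.round(values)
        if not (np.all(rounded == values) and values.min() >= 0 and values.max() <= 255):
            raise FormatError("PNG output requires integer values in [0, 255]")
        iio.imwrite(path, values.astype(np.uint8))
        return
    raise FormatError(f"unknown image format {fmt!r}")


def read_mask(path: str, format: str | None = None) -> LabelMask:
    grid = read_image(path, format)
    values = np.round(grid.values)
    return LabelMask(labels=values, spacing=grid.spacing)


def write_mask(mask: LabelMask, path: str, format: str | None = None) -> None:
    write_image(mask, path, format)


def denoise(grid: ImageGrid, method: str = "median", radius: int = 1) -> ImageGrid:
    """Denoise a grid slice-by-slice (the pipeline is per-slice throughout).

    ``method`` is one of ``none``, ``median`` (window 2*radius+1) or
    ``gaussian`` (sigma = radius).  Radius 0 or method ``none`` returns an
    identical copy.
    """
    if method not in ("none", "median", "gaussian"):
        raise ConfigError(f"unknown denoise method {method!r}")
    if radius < 0:
        raise ConfigError("denoise radius must be >= 0")
    if method == "none" or radius == 0:
        return ImageGrid(grid.values.copy(), grid.spacing, grid.intensity_unit)

    def _filter2d(sl):
        if method == "median":
            return ndimage.median_filter(sl, size=2 * radius + 1, mode="nearest")
        return ndimage.gaussian_filter(sl, sigma=radius, mode="nearest")

    if grid.ndim == 2:
        out = _filter2d(grid.values)
    else:
        out = np.stack([_filter2d(sl) for sl in grid.values])
    return ImageGrid(out, grid.spacing, grid.intensity_unit)


def rescale_intensity(grid: ImageGrid, out_range=(0.0, 1.0)) -> ImageGrid:
    """Affinely map [min, max] of the grid onto ``out_range``.

    A constant grid maps to the midpoint of the range.
    """
    lo, hi = float(out_range[0]), float(out_range[1])
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    if vmax == vmin:
        out = np.full_like(grid.values, (lo + hi) / 2.0)
    else:
        out = lo + (grid.values - vmin) * ((hi - lo) / (vmax - vmin))
        out = np.clip(out, min(lo, hi), max(lo, hi))
    return ImageGrid(out, grid.spacing, grid.intensity_unit)
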