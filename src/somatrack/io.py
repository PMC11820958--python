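"""Reading and writing image stacks (multi-page TIFF) and the 4D container.

Axis convention
---------------
Internally everything is ``(x, y, z, t)`` with 0-based indices. TIFF files
store planes as ``(y, x)`` pages; a z-stack is ``(z, y, x)`` and an
ImageJ-style hyperstack ``(t, z, y, x)``. ``axes_spec`` declares the on-disk
order (a string over the letters ``x y z t``, case-insensitive, e.g.
``"zyx"`` or ``"tzyx"``); when omitted, the reader uses TIFF series metadata
if it unambiguously names the axes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

_LABEL_TAG = "somatrack-labels"


@dataclass
class ImageStack4D:
    """A registered 4D grayscale volume with intensities in [0, 255].

    Parameters
    ----------
    data
        Array of shape ``(I, J, K, T)`` in ``(x, y, z, t)`` order.
    voxel_size
        Physical voxel extent in micrometres per axis ``(x, y, z)``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x, y, z, t) data, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all axes must have extent >= 1, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        if self.data.size:
            lo = float(self.data.min())
            hi = float(self.data.max())
            if lo < 0 or hi > 255:
                raise ValueError(f"intensities must lie in [0, 255], got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


def _normalize_axes_spec(axes_spec: str, ndim: int) -> str:
    spec = axes_spec.lower().replace(" ", "")
    if len(spec) != ndim or len(set(spec)) != len(spec) or not set(spec) <= set("xyzt"):
        raise ValueError(f"invalid axes_spec {axes_spec!r} for {ndim}-dimensional data")
    return spec


def _to_xyzt(arr: np.ndarray, spec: str) -> np.ndarray:
    """Permute ``arr`` whose axes are named by ``spec`` into (x, y, z, t)."""
    for missing in set("xyzt") - set(spec):
        arr = arr[..., np.newaxis]
        spec = spec + missing
    order = [spec.index(ax) for ax in "xyzt"]
    return np.transpose(arr, order)


def _axes_from_metadata(tif: tifffile.TiffFile, ndim: int) -> str | None:
    try:
        axes = tif.series[0].axes.lower()
    except (IndexError, AttributeError):
        return None
    # tifffile uses S for samples (colour) and Q/I for unknown axes
    axes = axes.replace("i", "q")
    if "s" in axes or "c" in axes:
        raise ValueError("non-grayscale (multi-sample/channel) TIFF is not supported")
    if set(axes) <= set("xyzt") and len(axes) == ndim:
        return axes
    return None


def _coerce_intensity(arr: np.ndarray, path) -> np.ndarray:
    """Map input dtypes onto the [0, 255] intensity convention."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        scale = 255.0 / 65535.0
        logger.info("16-bit input %s linearly rescaled to [0,255] (factor %.8f)", path, scale)
        return (arr.astype(np.float32) * scale).astype(np.float32)
    if np.issubdtype(arr.dtype, np.floating):
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError(f"float TIFF {path} has intensities outside [0, 255]")
        return arr.astype(np.float32)
    raise ValueError(f"unsupported TIFF dtype {arr.dtype} in {path}")


def read_stack(
    paths: str | Path | Sequence[str | Path],
    axes_spec: str | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ImageStack4D:
    """Read one hyperstack or an ordered list of per-timepoint TIFF volumes.

    Parameters
    ----------
    paths
        A single multi-page TIFF (optionally containing the time axis) or an
        ordered sequence of per-timepoint files sharing one volume shape.
    axes_spec
        On-disk axis order (e.g. ``"zyx"``, ``"tzyx"``). Required when the
        file metadata does not name its axes.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input paths given")

    volumes = []
    first_shape = None
    for path in paths:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or ""
            if _LABEL_TAG in desc:
                # label stacks round-trip without intensity coercion
                meta = json.loads(desc)
                arr = _to_xyzt(arr, meta["axes"].lower())
                stack = ImageStack4D.__new__(ImageStack4D)
                stack.data = arr
                stack.voxel_size = tuple(float(v) for v in voxel_size)
                return stack
            spec = axes_spec or _axes_from_metadata(tif, arr.ndim)
        if spec is None:
            raise ValueError(f"{path}: axis order not in metadata; pass axes_spec")
        spec = _normalize_axes_spec(spec, arr.ndim)
        if len(paths) > 1 and "t" in spec:
            raise ValueError(f"{path}: per-timepoint files must not contain a t axis")
        arr = _coerce_intensity(arr, path)
        vol = _to_xyzt(arr, spec)
        if first_shape is None:
            first_shape = vol.shape[:3]
        elif vol.shape[:3] != first_shape:
            raise ValueError(
                f"dimension mismatch: {path} has (I,J,K)={vol.shape[:3]}, expected {first_shape}"
            )
        volumes.append(vol)

    data = volumes[0] if len(volumes) == 1 else np.concatenate(volumes, axis=3)
    return ImageStack4D(data=data, voxel_size=voxel_size)


def write_stack(stack: ImageStack4D, path: str | Path) -> Path:
    """Write an intensity stack as a TZYX multi-page TIFF."""
    path = Path(path)
    arr = np.transpose(stack.data, (3, 2, 1, 0))  # (t, z, y, x)
    tifffile.imwrite(path, arr, photometric="minisblack", metadata={"axes": "TZYX"})
    return path


def _label_dtype(max_label: int) -> np.dtype:
    if max_label <= np.iinfo(np.uint8).max:
        return np.dtype(np.uint8)
    if max_label <= np.iinfo(np.uint16).max:
        return np.dtype(np.uint16)
    return np.dtype(np.uint32)


def write_label_stack(labels: np.ndarray, path: str | Path) -> Path:
    """Write a 4D nonnegative integer label grid (0 = background) as TIFF.

    The bit depth is chosen to hold the largest label exactly, and a JSON
    description tags the file so :func:`read_stack` and
    :func:`read_label_stack` return the values unmodified.
    """
    labels = np.asarray(labels)
    if labels.ndim != 4:
        raise ValueError(f"labels must be 4D (x, y, z, t), got ndim={labels.ndim}")
    if not np.issubdtype(labels.dtype, np.integer) or (labels.size and labels.min() < 0):
        raise ValueError("labels must be nonnegative integers")
    path = Path(path)
    max_label = int(labels.max()) if labels.size else 0
    arr = np.transpose(labels.astype(_label_dtype(max_label)), (3, 2, 1, 0))
    tifffile.imwrite(
        path, arr, photometric="minisblack",
        description=json.dumps({_LABEL_TAG: True, "axes": "TZYX"}),
    )
    return path


def read_label_stack(path: str | Path) -> np.ndarray:
    """Read a label stack written by :func:`write_label_stack` back to (x,y,z,t)."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    axes = "tzyx"
    if _LABEL_TAG in desc:
        axes = json.loads(desc)["axes"].lower()
    return _to_xyzt(arr, axes)
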