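"""Reading, writing and normalizing mammogram images.

Everything downstream of this module assumes a single intensity convention:
*white is dense* — larger pixel values mean radiodenser tissue — with the
image background anchored at exactly zero. Sources stored in the opposite
convention (e.g. DICOM ``MONOCHROME1``, where dense tissue is stored dark)
are inverted on load and re-anchored so that the background is exact zero,
because the background-segmentation rule used by the density pipeline is
defined on zero-valued pixels.

Supported inputs are single-frame grayscale DICOM files and 8/16-bit
grayscale PNG/TIFF rasters. Coordinates are 0-based and row-major
throughout; ranges are half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image as PILImage


class View(str, enum.Enum):
    """Mammographic projection."""

    MLO = "MLO"  # mediolateral oblique: includes the pectoralis major
    CC = "CC"  # craniocaudal: density is measured here

    @classmethod
    def coerce(cls, value: "View | str") -> "View":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


class Laterality(str, enum.Enum):
    L = "L"
    R = "R"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: "Laterality | str | None") -> "Laterality":
        if value is None:
            return cls.UNKNOWN
        if isinstance(value, cls):
            return value
        v = str(value).upper()
        return {"L": cls.L, "R": cls.R}.get(v, cls.UNKNOWN)


class Photometric(str, enum.Enum):
    """Stored intensity convention of the *source* file."""

    WHITE_IS_DENSE = "white-is-dense"  # DICOM MONOCHROME2-like
    WHITE_IS_LUCENT = "white-is-lucent"  # DICOM MONOCHROME1-like
    UNKNOWN = "unknown"


@dataclass
class MammogramImage:
    """A 2D mammogram held in the normalized white-is-dense convention.

    Parameters
    ----------
    pixels
        Non-negative float array, shape ``(rows, cols)``.
    view
        Projection (:class:`View`).
    laterality
        Breast side, if known.
    bit_depth
        Native stored bit depth of the source (8 or 16 for rasters,
        DICOM ``BitsStored`` otherwise).
    source_photometric
        Convention of the source file *before* normalization; pixels held
        here are always white-is-dense regardless.
    """

    pixels: np.ndarray
    view: View
    laterality: Laterality = Laterality.UNKNOWN
    bit_depth: int = 8
    source_photometric: Photometric = Photometric.UNKNOWN

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixel grid must be a non-empty 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        self.view = View.coerce(self.view)
        self.laterality = Laterality.coerce(self.laterality)
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _invert_and_anchor(arr: np.ndarray, max_value: float) -> np.ndarray:
    """Invert a white-is-lucent grid and re-anchor the background to zero."""
    inv = max_value - arr
    return inv - inv.min()


def _load_dicom(path: Path, view, laterality):
    ds = pydicom.dcmread(str(path))
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file has no pixel data")
    arr = ds.pixel_array
    if arr.ndim == 3 and arr.shape[0] == 1:  # trivially single-frame
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: only single-frame grayscale DICOM is supported")
    arr = arr.astype(np.float64)
    bits = int(getattr(ds, "BitsStored", 0) or 0) or int(arr.max()).bit_length() or 8
    pi = str(getattr(ds, "PhotometricInterpretation", "")).upper()
    if pi == "MONOCHROME1":
        photometric = Photometric.WHITE_IS_LUCENT
        arr = _invert_and_anchor(arr, float(2**bits - 1))
    elif pi == "MONOCHROME2":
        photometric = Photometric.WHITE_IS_DENSE
    else:
        raise ValueError(f"{path}: unsupported photometric interpretation {pi!r}")
    meta_view = getattr(ds, "ViewPosition", None)
    if meta_view in ("MLO", "CC"):
        view = meta_view
    elif view is None:
        raise ValueError(f"{path}: view not in metadata and not supplied")
    meta_lat = getattr(ds, "ImageLaterality", None) or getattr(ds, "Laterality", None)
    if meta_lat in ("L", "R"):
        laterality = meta_lat
    return arr, view, laterality, bits, photometric


def _load_raster(path: Path, photometric: Photometric):
    with PILImage.open(path) as im:
        if im.mode in ("L",):
            bits = 8
        elif im.mode in ("I;16", "I;16B", "I;16L", "I"):
            bits = 16
        else:
            raise ValueError(
                f"{path}: unsupported image mode {im.mode!r}; "
                "only 8/16-bit single-channel grayscale is accepted"
            )
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{path}: color/multi-channel images are not supported")
    if photometric is Photometric.WHITE_IS_LUCENT:
        arr = _invert_and_anchor(arr, float(2**bits - 1))
    return arr, bits


def load_image(
    path: str | Path,
    view: View | str | None = None,
    laterality: Laterality | str | None = None,
    photometric: Photometric | str = Photometric.WHITE_IS_DENSE,
) -> MammogramImage:
    """Load a mammogram from DICOM, PNG or TIFF into the normalized convention.

    For DICOM, the photometric interpretation, view position and laterality
    are taken from the file's metadata where present (arguments act as
    fallbacks). For plain rasters the caller states the convention via
    ``photometric``; white-is-lucent sources are inverted as
    ``v' = (2**bit_depth - 1) - v`` and then shifted so their minimum is
    exactly zero. Loading a white-is-dense source never changes values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    photometric = Photometric(photometric)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom") or _looks_like_dicom(path):
        arr, view, laterality, bits, photometric = _load_dicom(path, view, laterality)
    else:
        if view is None:
            raise ValueError("view must be supplied for raster images")
        arr, bits = _load_raster(path, photometric)
    return MammogramImage(
        pixels=arr,
        view=View.coerce(view),
        laterality=Laterality.coerce(laterality),
        bit_depth=bits,
        source_photometric=photometric,
    )


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def write_image(
    image: MammogramImage | np.ndarray,
    path: str | Path,
    bit_depth: int | None = None,
) -> None:
    """Write an image or overlay grid to PNG/TIFF, losslessly for integers.

    2D integer-valued grids round-trip exactly through :func:`load_image`.
    ``bit_depth`` forces the container depth (8 or 16); values exceeding the
    requested depth raise. 3D ``(rows, cols, 3)`` uint8 grids are written as
    RGB overlays.
    """
    path = Path(path)
    arr = image.pixels if isinstance(image, MammogramImage) else np.asarray(image)
    if arr.size == 0:
        raise ValueError("cannot write an empty grid")
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise ValueError("overlay grids must have exactly 3 channels")
        PILImage.fromarray(arr.astype(np.uint8), mode="RGB").save(path)
        return
    if arr.ndim != 2:
        raise ValueError("expected a 2D grid or a rows×cols×3 overlay")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("only integer-valued grids can be written losslessly")
    arr = np.round(arr).astype(np.int64)
    if arr.min() < 0:
        raise ValueError("negative values cannot be stored")
    vmax = int(arr.max())
    if bit_depth is None:
        bit_depth = 8 if vmax <= 255 else 16
    if vmax > 2**bit_depth - 1:
        raise ValueError(
            f"values up to {vmax} do not fit the requested {bit_depth}-bit depth"
        )
    if bit_depth == 8:
        PILImage.fromarray(arr.astype(np.uint8), mode="L").save(path)
    elif bit_depth == 16:
        PILImage.fromarray(arr.astype(np.uint16)).save(path)
    else:
        raise ValueError("bit_depth must be 8 or 16")
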