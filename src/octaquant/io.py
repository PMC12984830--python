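"""Image containers and file I/O for en-face angiograms.

An en-face OCTA angiogram is a single-channel 2-D projection of a motion
-contrast volume.  Images carry physical scan metadata (field extent in mm)
so that downstream metrics can be reported in physical units; the standard
macular protocol is a 3 mm x 3 mm field sampled at 512 x 512 px.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("octaquant")

#: default macular scan geometry: 3 mm x 3 mm at 512 x 512 px
DEFAULT_WIDTH_PX = 512
DEFAULT_EXTENT_MM = 3.0


@dataclass(frozen=True)
class ImageSpec:
    """Physical geometry of a square en-face scan."""

    width_px: int = DEFAULT_WIDTH_PX
    height_px: int | None = None
    extent_mm: float = DEFAULT_EXTENT_MM
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.height_px is None:
            object.__setattr__(self, "height_px", self.width_px)
        if self.width_px != self.height_px or self.width_px <= 0:
            raise ValueError("scan must be square with positive size")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def pixel_size_mm(self) -> float:
        return self.extent_mm / self.width_px

    @property
    def pixel_size_um(self) -> float:
        return 1000.0 * self.pixel_size_mm

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm ** 2

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass
class EnFaceImage:
    """A single-channel en-face angiogram plus acquisition metadata.

    ``pixels`` is row-major with origin at the top-left corner; the centre
    of pixel ``(i, j)`` sits at physical coordinates
    ``((j + 0.5) * px, (i + 0.5) * px)`` mm with x along columns.
    """

    pixels: np.ndarray
    spec: ImageSpec = field(default_factory=ImageSpec)
    plexus: str = "SCP"
    device: str = ""
    participant_id: str = ""
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.shape != self.spec.shape:
            raise ValueError(
                f"image shape {self.pixels.shape} does not match spec {self.spec.shape}"
            )
        if self.pixels.min() < 0 or self.pixels.max() > self.spec.max_intensity:
            raise ValueError("pixel values outside bit-depth range")


def read_enface(path: str | Path, spec: ImageSpec | None = None, **metadata) -> EnFaceImage:
    """Read a PNG or TIFF en-face image.

    Multi-channel input is coerced to its first channel with a warning.
    If ``spec`` is given, image dimensions must match it.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel image, using first channel")
        logger.warning("%s: multi-channel image, using first channel", path.name)
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D single-channel image")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    if spec is None:
        if arr.shape[0] != arr.shape[1]:
            raise ValueError(f"{path}: non-square image requires an explicit spec")
        spec = ImageSpec(width_px=arr.shape[1], height_px=arr.shape[0], bit_depth=bit_depth)
    elif arr.shape != spec.shape:
        raise ValueError(f"{path}: image shape {arr.shape} does not match spec {spec.shape}")
    return EnFaceImage(pixels=arr, spec=spec, **metadata)


def write_enface(image: EnFaceImage, path: str | Path) -> None:
    """Write an image as 8/16-bit grayscale PNG or TIFF."""
    path = Path(path)
    arr = np.asarray(image.pixels, dtype=image.spec.dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))
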