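"""Noise and contrast quality metrics with FAZ-anchored ROIs.

Three per-image quality measures, all computed from intensities inside
regions anchored on the avascular zone:

* noise-floor SD — the sample standard deviation (n-1 denominator) of
  pixel intensities inside an eroded FAZ ROI; an avascular region should
  be dark, so its residual intensity variation is a direct background
  noise measure;
* FAZ-noise rate R_FAZ — the percentage of FAZ ROI pixels whose intensity
  strictly exceeds a noise threshold T_FAZ, where T_FAZ is the 97.5th
  percentile of the FAZ intensity distribution pooled over all images in
  the analysis set;
* contrast-to-noise ratio CNR = (I_ring - I_FAZ) / SD_FAZ, where the ring
  is an annulus (default 0.5-1.5 mm radii) over perfused retina.

The FAZ ROI is eroded by 2 px to avoid contamination from parafoveal
capillaries; an inscribed-ellipse ROI mode is available for parity with
manual ellipsoid delineation.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .io import EnFaceImage, ImageSpec
from .metrics import FazRegion

DEFAULT_EROSION_PX = 2
DEFAULT_INNER_MM = 0.5
DEFAULT_OUTER_MM = 1.5
DEFAULT_PERCENTILE = 97.5
MIN_POOL_SAMPLES = 40


@dataclass
class RoiMask:
    """A quality-metric region of interest."""

    mask: np.ndarray
    kind: str  # 'eroded_faz' | 'annulus'
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass
class QualityReport:
    """Per-image quality triplet plus the pooled threshold used."""

    faz_noise_rate_pct: float
    cnr: float
    noise_floor_sd: float
    t_faz_used: float
    roi_provenance: dict = field(default_factory=dict)


def _pixels(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)
    return np.asarray(arr, dtype=float)


def eroded_faz_roi(
    faz: FazRegion,
    erosion_px: int = DEFAULT_EROSION_PX,
    use_inscribed_ellipse: bool = False,
) -> RoiMask:
    """FAZ quality ROI: the FAZ mask eroded by a disk of ``erosion_px``.

    With ``use_inscribed_ellipse`` the ROI is instead the largest ellipse
    inscribed in the FAZ (centre at the distance-transform maximum,
    orientation and axis ratio from second moments, axes shrunk until the
    ellipse fits), then eroded — mirroring a manually delineated ellipsoid.
    """
    from scipy import ndimage
    from skimage.morphology import erosion, disk

    if not faz.mask.any():
        raise ValueError("FAZ region is empty")
    base = faz.mask
    geometry: dict = {"erosion_px": erosion_px}
    if use_inscribed_ellipse:
        base = _inscribed_ellipse_mask(faz.mask)
        geometry["mode"] = "inscribed_ellipse"
    roi = erosion(base, disk(erosion_px)) if erosion_px > 0 else base.copy()
    if not roi.any():
        edt = ndimage.distance_transform_edt(base)
        raise ValueError(
            f"erosion by {erosion_px} px empties the ROI; the FAZ must admit "
            f"an inscribed disk of radius > {erosion_px} px (largest found: "
            f"{edt.max():.1f} px)"
        )
    return RoiMask(roi, "eroded_faz", geometry)


def _inscribed_ellipse_mask(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    from skimage.measure import regionprops

    edt = ndimage.distance_transform_edt(mask)
    r0, c0 = np.unravel_index(np.argmax(edt), edt.shape)
    props = regionprops(mask.astype(np.uint8))[0]
    theta = props.orientation  # major axis angle vs row axis
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    dr, dc = rr - r0, cc - c0
    # regionprops orientation: angle between row axis and major axis
    u = dr * np.cos(theta) - dc * np.sin(theta)
    v = dr * np.sin(theta) + dc * np.cos(theta)
    for scale in np.linspace(1.0, 0.05, 96):
        ell = (v / (a * scale)) ** 2 + (u / (b * scale)) ** 2 <= 1.0
        if not (ell & ~mask).any():
            return ell
    return edt >= edt.max()  # degenerate: fall back to the deepest pixel(s)


def annulus_roi(
    centre_mm: tuple[float, float],
    spec: ImageSpec,
    inner_mm: float = DEFAULT_INNER_MM,
    outer_mm: float = DEFAULT_OUTER_MM,
) -> RoiMask:
    """Annulus ROI about a physical centre (x, y) in mm, clipped to field."""
    if not (0 < inner_mm < outer_mm):
        raise ValueError("require 0 < inner_mm < outer_mm")
    px = spec.pixel_size_mm
    rr, cc = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    x = (cc + 0.5) * px
    y = (rr + 0.5) * px
    r = np.hypot(x - centre_mm[0], y - centre_mm[1])
    mask = (r >= inner_mm) & (r <= outer_mm)
    if not mask.any():
        raise ValueError("annulus lies entirely outside the field")
    return RoiMask(mask, "annulus",
                   {"centre_mm": tuple(centre_mm), "inner_mm": inner_mm,
                    "outer_mm": outer_mm})


def pooled_noise_threshold(faz_samples, q: float = DEFAULT_PERCENTILE) -> float:
    """Noise threshold T_FAZ: the q-th percentile of pooled FAZ intensities.

    Linear interpolation between closest ranks, i.e. rank
    ``r = (q/100) * (n - 1)`` on the sorted pool.  Pools smaller than 40
    samples trigger a stability warning.
    """
    samples = np.asarray(faz_samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty intensity pool")
    if samples.size < MIN_POOL_SAMPLES:
        _warnings.warn(
            f"pooled threshold from only {samples.size} samples; the "
            f"{q}th percentile may be unstable"
        )
    return float(np.percentile(samples, q, method="linear"))


def faz_noise_rate(image, roi: RoiMask, t_faz: float) -> float:
    """Percentage of ROI pixels with intensity strictly above ``t_faz``."""
    if roi.size == 0:
        raise ValueError("empty ROI")
    vals = _pixels(image)[roi.mask]
    return 100.0 * float((vals > t_faz).sum()) / vals.size


def noise_floor_sd(image, faz_roi: RoiMask) -> float:
    """Sample standard deviation (n-1) of ROI intensities."""
    if faz_roi.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    return float(np.std(_pixels(image)[faz_roi.mask], ddof=1))


def contrast_to_noise(image, ring: RoiMask, faz_roi: RoiMask) -> float:
    """CNR = (ring mean - FAZ mean) / FAZ sample SD."""
    if ring.size == 0 or faz_roi.size == 0:
        raise ValueError("both ROIs must be nonempty")
    if (ring.mask & faz_roi.mask).any():
        raise ValueError("ring and FAZ ROIs must be disjoint")
    pix = _pixels(image)
    sd = float(np.std(pix[faz_roi.mask], ddof=1)) if faz_roi.size >= 2 else 0.0
    if sd == 0:
        raise ValueError("CNR undefined: constant FAZ intensities (SD = 0)")
    return (float(pix[ring.mask].mean()) - float(pix[faz_roi.mask].mean())) / sd


def quality_report(
    image,
    faz_roi: RoiMask,
    ring: RoiMask,
    t_faz: float,
) -> QualityReport:
    """Assemble the per-image quality triplet."""
    return QualityReport(
        faz_noise_rate_pct=faz_noise_rate(image, faz_roi, t_faz),
        cnr=contrast_to_noise(image, ring, faz_roi),
        noise_floor_sd=noise_floor_sd(image, faz_roi),
        t_faz_used=t_faz,
        roi_provenance={"faz_roi": faz_roi.geometry, "ring": ring.geometry},
    )
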