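"""Vessel enhancement and binarization.

The segmentation front-end mirrors the common OCTA quantification recipe:
a multi-scale 2-D Frangi vesselness filter enhances bright tubular
structures, and a locally adaptive two-class fuzzy-c-means threshold turns
the vesselness map into a binary vessel mask.

Frangi vesselness (bright-ridge convention): with Hessian eigenvalues
``|l1| <= |l2|`` at scale ``s`` (derivatives scale-normalized by ``s^2``),

    V = 0                                          if l2 >= 0
    V = exp(-Rb^2 / 2 beta^2) * (1 - exp(-S^2 / 2 gamma^2))   otherwise

where ``Rb = l1/l2`` penalizes blobs and ``S = sqrt(l1^2 + l2^2)`` measures
second-order structure.  ``gamma`` follows Frangi's heuristic of half the
maximum ``S`` per scale.  The response is maximized over scales and
normalized to [0, 1].

The adaptive threshold estimates two fuzzy-c-means class centres in a
sliding window (implemented tile-wise with bilinear interpolation of the
centres for tractability); a pixel is a vessel when its membership to the
brighter class exceeds 0.5, which for scalar two-class FCM with fuzzifier
m=2 is equivalent to exceeding the midpoint of the two local centres.
Windows with no meaningful local contrast fall back to the global class
centres so that locally uniform regions are classified by their absolute
level rather than split on noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import EnFaceImage

#: default Frangi scales (px): capillaries span roughly 1-4 px at ~5.9 um/px
DEFAULT_SCALES = (1.0, 2.0, 3.0)
DEFAULT_BETA = 0.5
DEFAULT_KERNEL_PX = 70

# a tile's own FCM centres are used only if their separation exceeds this
# fraction of the global centre separation; below it the window is treated
# as locally uniform
_LOCAL_CONTRAST_FRACTION = 0.25


@dataclass
class VesselnessMap:
    """Multi-scale vesselness response in [0, 1]."""

    values: np.ndarray
    scales_used: tuple[float, ...]


@dataclass
class VesselMask:
    """Binary vessel/non-vessel classification with provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)


def _hessian_eigvals(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Scale-normalized Hessian eigenvalues, sorted by absolute value."""
    norm = sigma ** 2
    hrr = norm * ndimage.gaussian_filter(img, sigma, order=(2, 0))
    hcc = norm * ndimage.gaussian_filter(img, sigma, order=(0, 2))
    hrc = norm * ndimage.gaussian_filter(img, sigma, order=(1, 1))
    tr_half = (hrr + hcc) / 2.0
    disc = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc ** 2)
    e1, e2 = tr_half - disc, tr_half + disc
    swap = np.abs(e1) > np.abs(e2)
    small = np.where(swap, e2, e1)
    large = np.where(swap, e1, e2)
    return small, large


def frangi_enhance(
    image,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    beta: float = DEFAULT_BETA,
    gamma_mode: str = "half-max",
) -> VesselnessMap:
    """Multi-scale 2-D Frangi vesselness for bright vessels on dark ground.

    ``gamma_mode='half-max'`` sets gamma per scale to half the maximum
    Frobenius Hessian norm; a float value fixes gamma explicitly.
    A constant image yields an all-zero map.
    """
    scales = tuple(scales)
    if not scales or min(scales) < 0.5:
        raise ValueError("scales must be nonempty with each >= 0.5 px")
    img = np.asarray(_pixels(image), dtype=float)
    # remove the DC level: the truncated derivative kernels do not sum
    # exactly to zero, and this also makes the response exactly invariant
    # to additive intensity offsets
    img = img - img.mean()
    best = np.zeros_like(img)
    # structureness floor: kills float noise on flat images; depends only on
    # the intensity range, so it is invariant to additive offsets
    s2_floor = (1e-8 * float(np.ptp(img)) + 1e-12) ** 2
    for sigma in scales:
        l1, l2 = _hessian_eigvals(img, sigma)
        s2 = l1 ** 2 + l2 ** 2
        if gamma_mode == "half-max":
            smax = np.sqrt(s2.max())
            gamma = smax / 2.0 if smax > 0 else 1.0
        else:
            gamma = float(gamma_mode)
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2 != 0, (l1 / np.where(l2 != 0, l2, 1.0)) ** 2, 0.0)
        v = np.exp(-rb2 / (2 * beta ** 2)) * (1.0 - np.exp(-s2 / (2 * gamma ** 2)))
        v = np.where((l2 < 0) & (s2 > s2_floor), v, 0.0)  # bright-ridge sign test
        np.maximum(best, v, out=best)
    vmax = best.max()
    if vmax > 0:
        best /= vmax
    return VesselnessMap(values=best, scales_used=scales)


def _fcm_two_class(x: np.ndarray, c_lo: float, c_hi: float,
                   tol: float = 1e-5, max_iter: int = 100) -> tuple[float, float]:
    """Two-class fuzzy c-means (m=2) on scalar data; returns sorted centres."""
    if c_hi <= c_lo:
        return c_lo, c_hi
    eps = 1e-12
    for _ in range(max_iter):
        d_lo = np.abs(x - c_lo) + eps
        d_hi = np.abs(x - c_hi) + eps
        u_lo = 1.0 / (1.0 + (d_lo / d_hi) ** 2)
        u_hi = 1.0 - u_lo
        w_lo, w_hi = u_lo ** 2, u_hi ** 2
        new_lo = float((w_lo * x).sum() / w_lo.sum())
        new_hi = float((w_hi * x).sum() / w_hi.sum())
        shift = max(abs(new_lo - c_lo), abs(new_hi - c_hi))
        c_lo, c_hi = new_lo, new_hi
        if shift < tol:
            break
    return (c_lo, c_hi) if c_lo <= c_hi else (c_hi, c_lo)


def fuzzy_threshold(vmap: VesselnessMap | np.ndarray, kernel_px: int = DEFAULT_KERNEL_PX) -> VesselMask:
    """Adaptive two-class fuzzy-c-means binarization.

    Class centres are estimated in ``kernel_px``-sized windows on a tile
    grid (reflective padding at the borders) and bilinearly interpolated to
    every pixel; a pixel is vessel when it exceeds the midpoint of the two
    interpolated centres.  Tiles whose own centres are nearly coincident
    (under 25% of the global centre separation) reuse the global centres.
    An all-constant map yields an empty mask.
    """
    if kernel_px < 3:
        raise ValueError("kernel_px must be >= 3")
    if kernel_px % 2 == 0:
        kernel_px += 1  # symmetric window
    values = vmap.values if isinstance(vmap, VesselnessMap) else np.asarray(vmap, float)
    h, w = values.shape

    g_lo, g_hi = float(values.min()), float(values.max())
    if g_hi <= g_lo:  # globally constant: brighter class undefined
        return VesselMask(np.zeros_like(values, bool), {"kernel_px": kernel_px, "constant": True})
    g_lo, g_hi = _fcm_two_class(values.ravel(), g_lo, g_hi)
    g_sep = g_hi - g_lo

    half = kernel_px // 2
    padded = np.pad(values, half, mode="reflect")
    n_tr = max(1, int(np.ceil(h / kernel_px)))
    n_tc = max(1, int(np.ceil(w / kernel_px)))
    tr_centers = (np.arange(n_tr) + 0.5) * h / n_tr - 0.5
    tc_centers = (np.arange(n_tc) + 0.5) * w / n_tc - 0.5
    c_lo_grid = np.empty((n_tr, n_tc))
    c_hi_grid = np.empty((n_tr, n_tc))
    for i, rc in enumerate(tr_centers):
        r0 = int(round(rc))
        for j, cc in enumerate(tc_centers):
            c0 = int(round(cc))
            win = padded[r0:r0 + kernel_px, c0:c0 + kernel_px].ravel()
            lo, hi = float(win.min()), float(win.max())
            if hi > lo:
                lo, hi = _fcm_two_class(win, lo, hi)
            if hi - lo < _LOCAL_CONTRAST_FRACTION * g_sep:
                lo, hi = g_lo, g_hi  # locally uniform window
            c_lo_grid[i, j] = lo
            c_hi_grid[i, j] = hi

    # bilinear interpolation of centres to the full pixel grid
    rr = np.clip(np.arange(h), tr_centers[0], tr_centers[-1])
    cc = np.clip(np.arange(w), tc_centers[0], tc_centers[-1])
    ri = np.clip(np.searchsorted(tr_centers, rr) - 1, 0, max(n_tr - 2, 0))
    ci = np.clip(np.searchsorted(tc_centers, cc) - 1, 0, max(n_tc - 2, 0))
    if n_tr > 1:
        fr = (rr - tr_centers[ri]) / (tr_centers[ri + 1] - tr_centers[ri])
    else:
        ri, fr = np.zeros(h, int), np.zeros(h)
    if n_tc > 1:
        fc = (cc - tc_centers[ci]) / (tc_centers[ci + 1] - tc_centers[ci])
    else:
        ci, fc = np.zeros(w, int), np.zeros(w)
    fr = fr[:, None]
    fc = fc[None, :]

    def interp(grid):
        ri1 = np.minimum(ri + 1, n_tr - 1)
        ci1 = np.minimum(ci + 1, n_tc - 1)
        g00 = grid[np.ix_(ri, ci)]
        g01 = grid[np.ix_(ri, ci1)]
        g10 = grid[np.ix_(ri1, ci)]
        g11 = grid[np.ix_(ri1, ci1)]
        return (g00 * (1 - fr) * (1 - fc) + g01 * (1 - fr) * fc
                + g10 * fr * (1 - fc) + g11 * fr * fc)

    midpoint = (interp(c_lo_grid) + interp(c_hi_grid)) / 2.0
    mask = values > midpoint
    return VesselMask(mask, {"kernel_px": kernel_px, "global_centres": (g_lo, g_hi)})


def binarize_pipeline(
    image,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    beta: float = DEFAULT_BETA,
    kernel_px: int = DEFAULT_KERNEL_PX,
) -> VesselMask:
    """Frangi enhancement followed by adaptive fuzzy thresholding."""
    vmap = frangi_enhance(image, scales=scales, beta=beta)
    mask = fuzzy_threshold(vmap, kernel_px=kernel_px)
    mask.provenance.update({"frangi_scales": tuple(scales), "frangi_beta": beta})
    return mask
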