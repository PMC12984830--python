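"""Synthetic en-face angiogram phantoms with ground truth.

Real paired OCTA cohorts are rarely shareable, so this module builds
fully ground-truthed phantoms: a capillary-like planar mesh surrounding an
avascular elliptical FAZ, rasterized at scan resolution, then degraded with
a device-specific noise model.  Two presets emulate the qualitative regimes
seen when comparing OCTA platforms: a low-noise/high-contrast device and a
high-noise/low-contrast device imaging the same eyes.

The vessel network is a Poisson-Delaunay mesh: node positions are sampled
uniformly outside the FAZ ellipse, an explicit ring of nodes traces the
FAZ rim (emulating the terminal capillary ring that bounds the real FAZ),
and Delaunay edges within a plausible capillary length range become vessel
segments with log-normally distributed calibres.  This produces a loopy,
space-filling topology with controllable density; it makes no attempt at
hemodynamic realism.

Background noise is folded normal, ``|N(0, sigma)|`` — nonnegative like a
decorrelation background — so the measured noise-floor SD maps
monotonically to ``background_sigma`` (folded-normal SD is
``sigma * sqrt(1 - 2/pi)``).  Perfused pixels additionally receive
multiplicative speckle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

from .io import EnFaceImage, ImageSpec, write_enface, write_mask_png

# physiological capillary calibre bounds (mm); keeps strokes clear of the FAZ rim
_MIN_DIAMETER_MM = 0.006
_MAX_DIAMETER_MM = 0.022

# clearance between the FAZ ellipse and the surrounding capillary ring (mm)
_RING_MARGIN_MM = 0.015


@dataclass(frozen=True)
class FazEllipse:
    """Avascular-zone ellipse: centre (mm), semi-axes (mm), rotation (rad)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def contains(self, points: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Strict containment test for an (n, 2) array of mm points."""
        pts = np.atleast_2d(points) - np.asarray(self.center)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        u = pts[:, 0] * c + pts[:, 1] * s
        v = -pts[:, 0] * s + pts[:, 1] * c
        a, b = self.semi_axes
        return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 < 1.0

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass
class VesselNetworkTruth:
    """Ground-truth vessel centerlines in mm coordinates.

    ``centerlines`` is a list of (2, 2) arrays (straight segments,
    endpoint rows), ``radii`` the per-segment stroke radius in mm.
    """

    centerlines: list[np.ndarray]
    radii: np.ndarray
    faz_ellipse: FazEllipse
    extent_mm: float
    empty_warning: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.centerlines)


@dataclass(frozen=True)
class NoiseModel:
    """Device-style degradation of a clean phantom.

    background_sigma
        Scale of the additive folded-normal background (intensity units).
    vessel_mean
        Mean intensity of perfused pixels before noise.
    speckle_cv
        Coefficient of variation of multiplicative speckle on vessel pixels.
    """

    background_sigma: float
    vessel_mean: float
    speckle_cv: float = 0.0
    grain_px: float | tuple[float, float] = 2.0
    streak_weight: float = 0.0
    streak_grain_px: tuple[float, float] = (0.8, 2.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.background_sigma < 0:
            raise ValueError("background_sigma must be >= 0")
        if self.vessel_mean <= 0:
            raise ValueError("vessel_mean must be positive")
        if self.speckle_cv < 0:
            raise ValueError("speckle_cv must be >= 0")
        if np.any(np.asarray(self.grain_px) < 0):
            raise ValueError("grain_px must be >= 0")
        if not 0.0 <= self.streak_weight <= 1.0:
            raise ValueError("streak_weight must be in [0, 1]")

    @property
    def grain_sigmas(self) -> tuple[float, float]:
        """(row, column) speckle correlation lengths in px."""
        g = self.grain_px
        return (float(g), float(g)) if np.isscalar(g) else (float(g[0]), float(g[1]))


#: shipped device presets: a low-noise/high-CNR device ("clean") and a
#: high-noise/low-CNR device ("noisy"), on the 8-bit intensity scale.
#: The "clean" preset emulates a low-noise device (isotropic speckle at the
#: transverse PSF scale, high vessel contrast, CNR >~ 10); "noisy" emulates
#: a high-speed device whose elevated noise floor appears as anisotropic
#: decorrelation streaks along the fast-scan (column) axis with low vessel
#: contrast (CNR < 1.5).
DEVICE_PRESETS: dict[str, NoiseModel] = {
    "clean": NoiseModel(background_sigma=5.0, vessel_mean=180.0,
                        speckle_cv=0.10, grain_px=2.0),
    "noisy": NoiseModel(background_sigma=60.0, vessel_mean=120.0,
                        speckle_cv=0.30, grain_px=1.2,
                        streak_weight=1.0, streak_grain_px=(0.9, 2.0)),
}


@dataclass
class SyntheticEye:
    """One phantom eye imaged by every configured device."""

    participant_id: str
    eye_id: str
    truth: VesselNetworkTruth
    image_by_device: dict[str, EnFaceImage]
    truth_mask: np.ndarray
    truth_skeleton: np.ndarray
    truth_faz_mask: np.ndarray

    @property
    def truth_vad_pct(self) -> float:
        return 100.0 * self.truth_mask.sum() / self.truth_mask.size


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def _segment_intersects_ellipse(p0: np.ndarray, p1: np.ndarray, faz: FazEllipse) -> bool:
    # work in the ellipse's unit-circle frame
    c, s = np.cos(faz.rotation), np.sin(faz.rotation)
    a, b = faz.semi_axes

    def to_unit(p):
        d = p - np.asarray(faz.center)
        return np.array([(d[0] * c + d[1] * s) / a, (-d[0] * s + d[1] * c) / b])

    u0, u1 = to_unit(p0), to_unit(p1)
    d = u1 - u0
    dd = d @ d
    t = 0.0 if dd == 0 else np.clip(-(u0 @ d) / dd, 0.0, 1.0)
    nearest = u0 + t * d
    return bool(nearest @ nearest < 1.0)


def generate_vessel_network(
    spec: ImageSpec,
    density: float = 20.0,
    faz_semi_axes: tuple[float, float] = (0.3, 0.25),
    edge_len_range: tuple[float, float] = (0.01, 0.3),
    diameter_lognorm: tuple[float, float] = (np.log(0.012), 0.25),
    seed: int | np.random.SeedSequence | None = 0,
    faz_center: tuple[float, float] | None = None,
    faz_rotation: float = 0.0,
) -> VesselNetworkTruth:
    """Build a capillary-mesh ground truth.

    Parameters
    ----------
    density : float
        Poisson node intensity in points per mm^2.
    faz_semi_axes : (float, float)
        FAZ ellipse semi-axes in mm; each must fit inside half the field.
    edge_len_range : (float, float)
        Delaunay edges are kept only if their length (mm) falls in this range.
    diameter_lognorm : (float, float)
        (mu, sigma) of log vessel diameter in mm; samples are clipped to a
        physiological 6-22 um calibre band.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    half = spec.extent_mm / 2.0
    if max(faz_semi_axes) >= half:
        raise ValueError("faz semi-axes must each be smaller than half the field")
    if faz_center is None:
        faz_center = (half, half)
    faz = FazEllipse(center=faz_center, semi_axes=tuple(faz_semi_axes), rotation=faz_rotation)
    rng = np.random.default_rng(seed)

    n_poisson = rng.poisson(density * spec.extent_mm ** 2)
    pts = rng.uniform(0.0, spec.extent_mm, size=(n_poisson, 2))
    # reject nodes inside (or hugging) the FAZ so strokes stay outside it
    a, b = faz.semi_axes
    keep_scale_a = (a + _RING_MARGIN_MM) / a
    outside = ~faz.contains(pts, scale=keep_scale_a)
    pts = pts[outside]

    # terminal capillary ring: nodes tracing the FAZ rim with clearance so
    # the chords between them also stay outside the true ellipse
    perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    n_ring = max(12, int(np.ceil(perimeter / 0.04)))
    theta = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
    theta += rng.uniform(0, 2 * np.pi / n_ring)
    cr, sr = np.cos(faz.rotation), np.sin(faz.rotation)
    ru = (a + _RING_MARGIN_MM) * np.cos(theta)
    rv = (b + _RING_MARGIN_MM) * np.sin(theta)
    ring = np.column_stack(
        [faz.center[0] + ru * cr - rv * sr, faz.center[1] + ru * sr + rv * cr]
    )
    in_field = np.all((ring >= 0) & (ring <= spec.extent_mm), axis=1)
    nodes = np.vstack([pts, ring[in_field]]) if density > 0 else np.empty((0, 2))

    centerlines: list[np.ndarray] = []
    if len(nodes) >= 3:
        tri = Delaunay(nodes)
        edges = set()
        for simplex in tri.simplices:
            for i in range(3):
                e = (simplex[i], simplex[(i + 1) % 3])
                edges.add((min(e), max(e)))
        lo, hi = edge_len_range
        for i, j in sorted(edges):
            p0, p1 = nodes[i], nodes[j]
            length = float(np.linalg.norm(p1 - p0))
            if not (lo <= length <= hi):
                continue
            if _segment_intersects_ellipse(p0, p1, faz):
                continue
            centerlines.append(np.vstack([p0, p1]))

    mu, sigma = diameter_lognorm
    diam = np.exp(rng.normal(mu, sigma, size=len(centerlines)))
    diam = np.clip(diam, _MIN_DIAMETER_MM, _MAX_DIAMETER_MM)
    return VesselNetworkTruth(
        centerlines=centerlines,
        radii=diam / 2.0,
        faz_ellipse=faz,
        extent_mm=spec.extent_mm,
        empty_warning=(len(centerlines) == 0),
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _mm_to_px(points_mm: np.ndarray, spec: ImageSpec) -> np.ndarray:
    """mm point -> (row, col) pixel index (pixel centres at (i+0.5)*px)."""
    px = spec.pixel_size_mm
    col = np.clip(np.floor(points_mm[..., 0] / px).astype(int), 0, spec.width_px - 1)
    row = np.clip(np.floor(points_mm[..., 1] / px).astype(int), 0, spec.height_px - 1)
    return np.stack([row, col], axis=-1)


def rasterize(
    network: VesselNetworkTruth, spec: ImageSpec, vessel_mean: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize a network into truth masks and a clean intensity image.

    Returns ``(truth_mask, truth_skeleton, truth_faz_mask, clean_image)``:
    disc-capped strokes of the per-segment radius, a Bresenham raster of the
    centerlines, the FAZ ellipse mask, and ``vessel_mean`` on the vessel
    mask (0 elsewhere).  The vessel mask never overlaps the FAZ mask.
    """
    if network.extent_mm != spec.extent_mm:
        raise ValueError("network extent does not match image spec")
    from skimage.draw import line as draw_line

    h, w = spec.shape
    px = spec.pixel_size_mm
    mask = np.zeros((h, w), dtype=bool)
    skel = np.zeros((h, w), dtype=bool)

    for seg, radius in zip(network.centerlines, network.radii):
        p0, p1 = seg[0], seg[1]
        r_px = radius / px
        lo = np.floor((np.minimum(p0, p1) - radius) / px).astype(int)
        hi = np.ceil((np.maximum(p0, p1) + radius) / px).astype(int)
        r0, r1 = max(lo[1], 0), min(hi[1] + 1, h)
        c0, c1 = max(lo[0], 0), min(hi[0] + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        # pixel centres in mm
        cx = (cols + 0.5) * px
        cy = (rows + 0.5) * px
        dx, dy = p1 - p0
        dd = dx * dx + dy * dy
        if dd == 0:
            dist = np.hypot(cx - p0[0], cy - p0[1])
        else:
            t = np.clip(((cx - p0[0]) * dx + (cy - p0[1]) * dy) / dd, 0.0, 1.0)
            dist = np.hypot(cx - (p0[0] + t * dx), cy - (p0[1] + t * dy))
        mask[r0:r1, c0:c1] |= dist <= radius + 1e-12

        (rr0, cc0), (rr1, cc1) = _mm_to_px(np.vstack([p0, p1]), spec)
        rr, cc = draw_line(rr0, cc0, rr1, cc1)
        skel[rr, cc] = True

    rows, cols = np.mgrid[0:h, 0:w]
    centers = np.stack([(cols + 0.5) * px, (rows + 0.5) * px], axis=-1)
    faz_mask = network.faz_ellipse.contains(centers.reshape(-1, 2)).reshape(h, w)

    # enforce FAZ avascularity at pixel resolution
    mask &= ~faz_mask
    skel &= ~faz_mask
    clean = np.where(mask, float(vessel_mean), 0.0)
    return mask, skel, faz_mask, clean


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def _correlated_standard_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    grain: tuple[float, float],
) -> np.ndarray:
    """Standard-normal noise field with per-axis speckle grain (row, col).

    White noise is Gaussian-smoothed to the grain scale — emulating the
    transverse point-spread function and, when anisotropic, the fast-scan
    decorrelation streaks of high-speed OCTA — and renormalized by the
    exact kernel l2 norm per axis, so each pixel's marginal distribution
    remains exactly N(0, 1) and folded-normal closed forms stay valid.
    """
    from scipy import ndimage as _ndi

    white = rng.standard_normal(shape)
    if max(grain) <= 0:
        return white
    std_factor = 1.0
    for g in grain:
        if g <= 0:
            continue
        radius = int(4.0 * g + 0.5) + 1
        impulse = np.zeros(2 * radius + 1)
        impulse[radius] = 1.0
        kernel = _ndi.gaussian_filter1d(impulse, g)
        std_factor *= float((kernel ** 2).sum()) ** 0.5
    return _ndi.gaussian_filter(white, grain) / std_factor


def apply_device_noise(
    clean_image: np.ndarray,
    model: NoiseModel,
    spec: ImageSpec,
    seed: int | np.random.SeedSequence | None = None,
    **metadata,
) -> EnFaceImage:
    """Degrade a clean phantom with a device noise model.

    Output is ``clip(clean + |N(0, sigma_bg)| + vessel * N(0, cv * mu_v))``
    quantized to the scan geometry's bit depth; with zero noise parameters the output
    equals the clean image exactly.
    """
    clean = np.asarray(clean_image, dtype=float)
    if clean.shape != spec.shape:
        raise ValueError("clean image shape does not match spec")
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)
    out = clean.copy()
    if model.background_sigma > 0:
        # variance-preserving mixture of isotropic speckle and fast-scan
        # streaks: both components are exact N(0, 1) fields, so the sum
        # with weights (sqrt(1-w), sqrt(w)) is too
        field_iso = _correlated_standard_noise(rng, clean.shape, model.grain_sigmas)
        w = model.streak_weight
        if w > 0:
            field_streak = _correlated_standard_noise(
                rng, clean.shape, model.streak_grain_px
            )
            field_iso = np.sqrt(1.0 - w) * field_iso + np.sqrt(w) * field_streak
        out += model.background_sigma * np.abs(field_iso)
    if model.speckle_cv > 0:
        vessel = clean > 0
        out[vessel] += rng.normal(
            0.0, model.speckle_cv * model.vessel_mean, size=int(vessel.sum())
        )
    out = np.clip(np.rint(out), 0, spec.max_intensity).astype(spec.dtype)
    return EnFaceImage(pixels=out, spec=spec, **metadata)


# ---------------------------------------------------------------------------
# paired cohorts
# ---------------------------------------------------------------------------

def _eye_seedseq(cohort_seed: int, participant: int, eye: int) -> np.random.SeedSequence:
    """Per-eye sub-seed: SeedSequence spawn keyed on (participant, eye)."""
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(participant, eye))


def generate_paired_cohort(
    n_participants: int = 25,
    eyes_per_participant: int = 2,
    model_A: NoiseModel = DEVICE_PRESETS["clean"],
    model_B: NoiseModel = DEVICE_PRESETS["noisy"],
    spec: ImageSpec | None = None,
    network_params: dict | None = None,
    seed: int = 0,
    device_names: tuple[str, str] = ("A", "B"),
    plexus: str = "SCP",
) -> list[SyntheticEye]:
    """Generate a paired two-device phantom cohort.

    Every eye has one ground-truth network; both devices image that same
    truth (within-subject paired design), differing only in noise model and
    noise realization.  The cohort seed deterministically derives per-eye
    sub-seeds, so regeneration with the same seed is bit-identical.

    Per-eye anatomical variation: FAZ semi-axes drawn uniformly from
    0.25-0.35 mm by 0.20-0.30 mm with random orientation, giving FAZ areas
    around the 0.2-0.3 mm^2 typical of healthy maculae.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    spec = spec or ImageSpec()
    network_params = dict(network_params or {})
    eyes: list[SyntheticEye] = []
    for p in range(n_participants):
        for e in range(eyes_per_participant):
            ss = _eye_seedseq(seed, p, e)
            s_net, s_anat, s_a, s_b = ss.spawn(4)
            anat_rng = np.random.default_rng(s_anat)
            params = dict(network_params)
            params.setdefault(
                "faz_semi_axes",
                (anat_rng.uniform(0.25, 0.35), anat_rng.uniform(0.20, 0.30)),
            )
            params.setdefault("faz_rotation", anat_rng.uniform(0.0, np.pi))
            net = generate_vessel_network(spec, seed=s_net, **params)
            mask, skel, faz_mask, _ = rasterize(net, spec)
            pid, eid = f"P{p:03d}", f"P{p:03d}_E{e}"
            images = {}
            for dev, model, s_dev in (
                (device_names[0], model_A, s_a),
                (device_names[1], model_B, s_b),
            ):
                clean = np.where(mask, model.vessel_mean, 0.0)
                # an explicit per-model seed overrides the derived sub-seed
                # (e.g. to force identical acquisitions for null cohorts)
                images[dev] = apply_device_noise(
                    clean, model, spec,
                    seed=model.seed if model.seed is not None else s_dev,
                    plexus=plexus, device=dev, participant_id=pid, eye_id=eid,
                )
            eyes.append(
                SyntheticEye(
                    participant_id=pid, eye_id=eid, truth=net,
                    image_by_device=images, truth_mask=mask,
                    truth_skeleton=skel, truth_faz_mask=faz_mask,
                )
            )
    return eyes


def write_phantom(eye: SyntheticEye, out_dir: str | Path) -> None:
    """Write one phantom eye: device PNGs, truth-mask PNGs, JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = eye.eye_id
    for dev, img in eye.image_by_device.items():
        write_enface(img, out / f"{stem}_{dev}.png")
    write_mask_png(eye.truth_mask, out / f"{stem}_truth_mask.png")
    write_mask_png(eye.truth_skeleton, out / f"{stem}_truth_skeleton.png")
    write_mask_png(eye.truth_faz_mask, out / f"{stem}_truth_faz.png")
    faz = eye.truth.faz_ellipse
    spec = next(iter(eye.image_by_device.values())).spec
    sidecar = {
        "participant_id": eye.participant_id,
        "eye_id": eye.eye_id,
        "spec": dataclasses.asdict(spec),
        "faz_ellipse": {
            "center_mm": list(faz.center),
            "semi_axes_mm": list(faz.semi_axes),
            "rotation_rad": faz.rotation,
            "area_mm2": faz.area_mm2,
        },
        "truth_vad_pct": eye.truth_vad_pct,
        "n_segments": eye.truth.n_segments,
    }
    (out / f"{stem}_truth.json").write_text(json.dumps(sidecar, indent=2))
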