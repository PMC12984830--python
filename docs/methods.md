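# Methods

`octaquant` quantifies 2-D en-face OCT-angiography (OCTA) images and compares
two devices that imaged the same eyes. This note documents the models and
procedures, the defaults and why they were chosen, what the synthetic phantom
does and does not emulate, and the numerical conventions.

## Pipeline overview

For each en-face angiogram (single-channel, square, with physical extent
metadata; the standard macular protocol is 3 mm × 3 mm at 512 × 512 px,
5.859375 µm/px):

1. **Vessel enhancement** — multi-scale 2-D Frangi vesselness.
2. **Binarization** — windowed two-class fuzzy-c-means thresholding.
3. **Skeleton / graph** — thinning, distance-transform diameters, branch
   point/endpoint graph, twig pruning.
4. **Vascular metrics** — VAD, TVL, node count, MVL/mean segment length,
   MVD, box-counting fractal dimension, FAZ segmentation and area.
5. **Quality metrics** — noise-floor SD, FAZ-noise rate against a pooled
   97.5th-percentile threshold, contrast-to-noise ratio.
6. **Paired statistics** — Shapiro–Wilk display gate, Wilcoxon signed-rank,
   paired Cliff's delta; one comparison row per metric.

Identical settings are applied to both devices in a run; all parameters live
in one serializable `RunConfig` and all randomness derives from its single
seed.

## Vessel enhancement

Frangi vesselness (bright-ridge convention) at scales σ ∈ {1, 2, 3} px with
scale-normalized Hessians (factor σ²). With eigenvalues |λ₁| ≤ |λ₂|:

    V = 0                                            if λ₂ ≥ 0
    V = exp(−R_B²/2β²) · (1 − exp(−S²/2γ²))          otherwise

where R_B = λ₁/λ₂ (blob penalty), S = √(λ₁²+λ₂²) (structureness), β = 0.5,
and γ is half the maximum S per scale (Frangi's heuristic). The response is
maximized over scales and normalized to [0, 1] by its maximum. The scale set
{1, 2, 3} px targets capillary calibres of roughly 1–4 px at the macular
sampling density. The image mean is subtracted before filtering: the
truncated discrete derivative kernels do not sum exactly to zero, and the
subtraction also makes the response invariant to additive intensity offsets.
A structureness floor proportional to the intensity range suppresses float
noise on flat images.

## Binarization

Two-class fuzzy c-means (fuzzifier m = 2, tolerance 1e−5, ≤100 iterations,
centres initialized at window min/max) estimates a dark and a bright class
centre in windows of 70 px (adjusted to 71 for symmetry) on a tile grid,
with reflective padding at the borders; centres are bilinearly interpolated
to every pixel. A pixel is classified vessel when its membership to the
brighter class exceeds 0.5 — for scalar two-class FCM with m = 2 this is
exactly the midpoint of the two interpolated centres.

Design choice for near-uniform windows: when a tile's own centre separation
is below 25% of the global separation, the window carries no usable local
contrast (splitting it would binarize noise), and the tile falls back to the
global two-class centres. A globally constant map yields an empty mask.
This makes locally uniform regions classify by absolute level — a uniformly
bright plateau is vessel, a uniformly dark one background — while regions
containing both vessels and background are thresholded locally.

## Skeleton, diameters, graph, pruning

* Thinning: homotopic 2-D skeletonization to 1-px centerlines.
* Diameters: `2 × EDT` of the mask sampled at skeleton pixels (the
  `2×EDT − 1` convention would read one pixel smaller; the ±1 px ambiguity
  is inherent and documented rather than hidden).
* Graph: branch pixels are skeleton pixels with ≥3 8-neighbours, merged into
  one node per 8-connected cluster (node coordinate = rounded centroid);
  endpoints have exactly one neighbour; segments are the degree-2 chains
  between nodes, with length = Σ steps (1 orthogonal, √2 diagonal) ×
  pixel size. Node-less closed loops become cycle segments.
* Pruning (twig threshold 2 px, in pixel units before µm conversion):
  endpoint-terminated segments with path length < 2 px and connected
  components with total length < 2 px are removed; branch nodes left with
  exactly two incident segments are dissolved by merging them (the joint
  across a multi-pixel node cluster contributes the Euclidean step between
  the two chain ends; merged mean diameter is the unweighted mean of the
  parts). Pruning is a single pass by default; `iterate=True` repeats to a
  fixpoint.

## Vascular metrics

VAD = 100 × vessel pixels / total pixels. TVL = Σ segment lengths (mm).
Node count = branch nodes only (endpoints are not counted; whether published
node counts include endpoints is generally not stated, so the stricter
definition is used and documented). MVL = median per-segment length (µm);
the mean is also reported. MVD = mean per-skeleton-pixel diameter (µm).
Metrics undefined on empty structures propagate as NaN, never 0.

Fractal dimension: Minkowski–Bouligand box counting on the binarized mask
(not the skeleton), box sizes {2, 4, …, 128} px aligned at the origin (no
random offsets, so the value is deterministic), least-squares slope of
log N(s) vs log(1/s). A full mask gives exactly 2; an empty mask reports 0
by convention.

## FAZ segmentation

The vessel mask is morphologically closed (disk radius 2 px) to seal small
capillary gaps; background components are labelled with 4-connectivity; the
FAZ is the component containing the field centre, holes filled, area =
pixel count × pixel area. When the centre pixel is occluded by (spurious)
vasculature, segmentation can be *seeded*: the component containing a given
seed point is used instead, with everything else identical — so seeding is
initialization only, and a seed inside the automatically found region
reproduces it exactly. The pipeline falls back to an automatically placed
seed (the avascular pixel maximizing vessel distance, biased toward the
field centre) and flags the record `faz_seeded`, emulating
operator-assisted initialization on noisy scans.

## Quality metrics

All three are computed on intensities in FAZ-anchored ROIs:

* ROI: the FAZ mask eroded by a 2-px disk (avoiding parafoveal capillary
  contamination). An inscribed-ellipse mode mirrors manual ellipsoid
  delineation and is available for parity; the eroded mask is the
  automation-friendly default.
* Noise-floor SD: sample standard deviation (n−1) of ROI intensities.
* T_FAZ: 97.5th percentile of ROI intensities pooled over all images of the
  analysis set — pooled per plexus across both devices by default
  (`pooling_scope='plexus'`; a joint scope is available, since published
  descriptions of the pooling are often ambiguous). Percentile convention:
  linear interpolation at rank r = q(n−1).
* FAZ-noise rate R_FAZ: percentage of ROI pixels strictly above T_FAZ. By
  construction, when every image shares one noise law the cohort-mean
  R_FAZ calibrates to ≈2.5%.
* CNR = (ring mean − FAZ mean) / FAZ SD, with the ring an annulus of radii
  0.5–1.5 mm about the FAZ centroid (a manually marked fovea can override
  the centre). CNR is invariant to intensity scaling and offsets and is
  undefined (explicit error) when the FAZ is constant.

## Paired statistics

The Shapiro–Wilk test (p ≥ 0.05) chooses only the summary display —
median (IQR) vs mean (SD); the paired test is always the Wilcoxon
signed-rank test. Fractal dimension is summarized as mean (SD) regardless,
because its between-eye variability is tiny. Wilcoxon conventions: zero
differences dropped, mid-ranks for ties; for n ≤ 25 effective pairs the
null distribution is enumerated exactly by dynamic programming over doubled
mid-ranks (integers even under ties), two-sided p = min(1, 2·min(P(W≤w),
P(W≥w))); above that, a normal approximation with tie-corrected variance
and 0.5 continuity correction. Cliff's delta for paired data is
(n⁺ − n⁻)/n with ties in the denominator only; δ = ±1 iff one device
dominates every pair. P-values are reported unadjusted (the intended use is
effect-size-driven method comparison across correlated endpoints); a Holm
adjustment is available but off by default. IQRs use the same linear
percentile interpolation as T_FAZ.

Two eyes per participant are treated as independent pairs, mirroring common
practice in device-comparison studies; no mixed-effects correction for
inter-eye correlation is attempted (known limitation).

## Synthetic phantom

The generator produces paired, ground-truthed angiograms so that every
stage is testable without clinical data.

**Geometry.** Vessel centerlines form a Poisson–Delaunay mesh: nodes are
sampled uniformly at `density` points/mm² outside the FAZ ellipse, an
explicit ring of nodes traces the FAZ rim at a 15 µm clearance (emulating
the terminal capillary ring that bounds the real FAZ — and necessary for
the closing-radius-2 FAZ segmentation to recover the ellipse area), and
Delaunay edges with lengths in 0.01–0.3 mm that do not intersect the
ellipse become straight segments with log-normal diameters (median 12 µm,
σ_log = 0.25) clipped to the 6–22 µm capillary band (the clip also keeps
strokes out of the rim clearance). Edges touching the FAZ are dropped
entirely, not clipped. Per-eye anatomy varies FAZ semi-axes uniformly in
0.25–0.35 × 0.20–0.30 mm with random orientation (areas ≈ 0.16–0.33 mm²,
the healthy macular range).

The default density is 20 points/mm², giving a sparse mesh (true VAD
≈ 8–12%). This is deliberately sparser than a real superficial plexus: the
study conditions are chosen so that the *noise-inflation mechanism* —
spurious vessel detections outweighing true-vessel loss — dominates the
paired density comparison in every eye, which is the regime the degenerate
effect sizes (δ = ±1) describe. Absolute metric levels (VAD, TVL, node
counts) are therefore not calibrated to clinical values, and passing tests
say nothing about absolute accuracy on real angiograms — only about the
pipeline's formulas, invariances, and its response to noise.

**Noise.** Background noise is folded normal: out = clip(clean +
σ·|G| + speckle), where G is a unit-variance correlated Gaussian field.
Correlation is produced by Gaussian-smoothing white noise to a grain scale
and renormalizing by the exact kernel ℓ2 norm, so the per-pixel marginal
stays exactly N(0, 1) and folded-normal closed forms (mean σ√(2/π), SD
σ√(1−2/π)) remain valid. G may mix an isotropic component (speckle at the
transverse-PSF scale, ≈2 px) with an anisotropic component elongated along
the fast-scan axis (decorrelation streaks), again variance-preserving.
Perfused pixels additionally receive N(0, cv·vessel_mean) speckle.

**Device presets** (8-bit scale):

| preset | σ_bg | vessel mean | speckle cv | grain | emulates |
|---|---|---|---|---|---|
| `clean` | 5 | 180 | 0.10 | isotropic 2 px | low-noise device: noise-floor SD ≈ 3, CNR ≈ 5–8 |
| `noisy` | 60 | 120 | 0.30 | streaks (0.9, 2.0) px | high-speed device: noise-floor SD ≈ 36, CNR < 0.5 |

The noisy preset's streak structure is what makes background noise
*vessel-shaped*: isotropic iid noise is suppressed by the Frangi blob
penalty and cannot inflate density readouts, whereas elongated decorrelation
streaks are enhanced, binarized, skeletonized and counted — inflating VAD,
TVL and node counts while fragmentation shortens the median segment. The
clean preset's CNR of ≈5–8 (rather than >10) is a consequence of the sparse
ring perfusion at density 20; the clean/noisy CNR ratio exceeds 10×.

**Pairing and seeds.** Every eye has one ground truth; both devices image
that truth with their own noise model and an independently derived noise
realization. Sub-seeds derive from the cohort seed via
`numpy.random.SeedSequence(entropy=seed, spawn_key=(participant, eye))`
spawns, so regeneration is bit-identical and device images are paired by
construction. An explicit `NoiseModel.seed` overrides the derived sub-seed
(used for null cohorts where both devices must produce identical images).

**Not emulated:** hemodynamics, 3-D volumes and projection artifacts,
motion artifacts, pathology, vessel curvature (segments are straight), and
realistic absolute metric levels (see above).

## Numerical conventions and degenerate inputs

* Coordinates: row-major, origin top-left, pixel centre of (i, j) at
  ((j+0.5)·p, (i+0.5)·p) mm; areas are pixel counts × pixel area.
* Percentiles: linear interpolation at r = q(n−1) everywhere.
* R_FAZ uses strict `>`; ties at T_FAZ are excluded.
* Empty networks, masks, graphs and skeletons propagate as warnings/NaN,
  not errors; a FAZ that fills the whole field is returned but flagged
  degenerate; erosion that empties a quality ROI raises with the minimum
  viable FAZ size; constant-intensity FAZ makes CNR an explicit error.
* FCM ties (locally constant windows) resolve to background.
* The acceptance driver quantifies 25 participants × 2 eyes × 2 devices at
  512², skipping the FAZ/quality stages it does not need; this keeps the
  full recomputation within a few minutes on one core. Tests reuse one
  session-scoped 50-eye study for the cohort-level properties.

## Known limitations

* The windowed-FCM threshold is self-normalizing: it always cuts a
  comparable upper fraction of the local vesselness distribution, so
  *absolute* density readouts depend on the noise regime in a way no single
  calibration removes — which is, in fact, the cross-device comparability
  problem this package is built to study.
* Single-pass pruning can leave twigs created by an earlier removal;
  iterated pruning is exposed as an option.
* FAZ segmentation assumes a fovea-centred scan; badly decentred scans need
  an explicit seed.
* The Wilcoxon exact path enumerates the conditional-on-ties distribution;
  mid-rank ties make the test slightly conservative, as is standard.
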