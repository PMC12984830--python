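# octaquant

Quantification of en-face OCT-angiography (OCTA) images and paired
comparison of two OCTA devices that imaged the same eyes.

Quantitative OCTA biomarkers — vessel area density, total vessel length,
branch-node counts, fractal dimension, segment lengths and diameters, and
the foveal avascular zone (FAZ) area — are widely used for retinal ischemia
assessment, but they are notoriously device-dependent: acquisition speed and
noise behaviour shift density- and topology-related readouts even on the
same healthy eye. `octaquant` implements a unified, non-proprietary
analysis pipeline plus the statistics needed to characterize such
cross-device shifts, and ships a ground-truthed synthetic angiogram
generator so the whole chain is testable without clinical data. It is
aimed at researchers doing OCTA method-comparison or quality-control work.

## What it computes

For each single-channel en-face angiogram (default geometry 3 mm × 3 mm at
512 × 512 px):

* **Segmentation** — multi-scale 2-D Frangi vesselness
  (V = exp(−R_B²/2β²)(1 − exp(−S²/2γ²)) on bright ridges, scales 1–3 px)
  followed by windowed two-class fuzzy-c-means thresholding (kernel 70 px).
* **Topology** — skeletonization, diameters from 2×EDT, a branch-point /
  endpoint graph with twig pruning (2 px threshold); VAD (%), TVL (mm),
  node count, MVL and mean segment length (µm), MVD (µm), box-counting
  fractal dimension.
* **FAZ** — automatic segmentation (morphological closing + centre
  background component), with optional seeding when noise blocks automatic
  initialization; area in mm².
* **Image quality** — noise-floor SD (sample SD of eroded-FAZ intensities),
  FAZ-noise rate R_FAZ against a pooled 97.5th-percentile threshold T_FAZ,
  and CNR = (I_ring − I_FAZ)/SD_FAZ with a 0.5–1.5 mm annulus.
* **Paired statistics** — Wilcoxon signed-rank (exact for n ≤ 25), paired
  Cliff's δ = (n⁺ − n⁻)/n, median (IQR) / mean (SD) summaries gated by
  Shapiro–Wilk, assembled into a per-metric device-comparison table.

See `docs/methods.md` for the full model description and numerical
conventions.

## Worked example

Simulate a small paired cohort (3 participants, 6 eyes; device A = the
low-noise preset, device B = the high-noise preset imaging the same ground
truth) and quantify it end to end:

```python
from octaquant import RunConfig, run_simulate_and_quantify

out = run_simulate_and_quantify(RunConfig(n_participants=3, seed=7))
cols = ["metric", "n", "median_a", "median_b", "p_value", "delta"]
print(out["comparison"][cols].round(4).to_string(index=False))
```

```
            metric  n  median_a  median_b  p_value  delta
           vad_pct  6    8.8568   13.3354   0.0312   -1.0
      faz_area_mm2  6    0.2588    0.2600   0.8438    0.0
            tvl_mm  6   54.3010   85.1738   0.0312   -1.0
           n_nodes  6  267.5000  344.5000   0.0312   -1.0
                fd  6    1.4904    1.6709   0.0312   -1.0
            mvl_um  6   81.9881   25.8645   0.0312    1.0
            mvd_um  6   16.6230   14.7288   0.0312    1.0
faz_noise_rate_pct  6    0.0000    2.5710   0.0312   -1.0
               cnr  6    5.1806    0.3442   0.0312    1.0
    noise_floor_sd  6    3.0074   34.6026   0.0312   -1.0
```

Reading the table: the high-noise device B "sees" denser, more branched
vasculature (VAD 13.3% vs 8.9%, more nodes, longer TVL; δ = −1 means B was
higher in *every* eye) even though both devices imaged identical ground
truth — background noise is being misclassified as vasculature — while
noise fragmentation cuts the median vessel segment from 82 µm to 26 µm
(δ = +1). The quality metrics explain the mechanism: device B's noise-floor
SD is ~35 vs ~3 and its contrast-to-noise ratio collapses to 0.34 vs 5.2.
FAZ area is the one robust biomarker (δ = 0, p = 0.84). Against the
generator's ground truth, the clean device recovers VAD to 0.25 percentage
points (mean absolute error) and FAZ area to ~6%.

A command-line interface wraps the same entry points:

```sh
octaquant synth --participants 25 --preset-a clean --preset-b noisy --seed 1 --out phantoms/
octaquant quantify --manifest phantoms/manifest.csv --config config.yaml --out results/
octaquant synth-run --seed 1 --out results/
```

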