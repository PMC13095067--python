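# cardionuc

Quantitative phenotyping of laminopathy cardiomyocyte models: radial
positioning of painted chromosome territories in nuclei, nuclear
morphometrics, contraction and calcium-transient trace metrics, and
per-chromosome summaries of differentially expressed genes — with seeded
synthetic-data generators so the whole pipeline is testable against known
ground truth.

## Who this is for

Labs studying *LMNA*-mutant (or other nuclear-envelope) cardiomyocyte models
routinely combine three kinds of measurement:

1. **Chromosome painting / FISH images.** Whole-chromosome probes label a
   chromosome's territory; the question is whether the territory sits nearer
   the nuclear center or the lamina. `cardionuc` divides each binarized
   nucleus mask into 10 concentric bins ordered center → periphery via the
   Euclidean distance transform, measures mean probe fluorescence per bin,
   min–max normalizes per probe pooling both groups, and compares groups
   with a two-way (group × bin) ANOVA plus Šídák-adjusted per-bin contrasts.
   Bins 1–5 are the nuclear center, bins 6–10 the periphery; the
   *peripherality index* `Σ(bins 6–10) / Σ(bins 1–10)` summarizes a profile
   in one number. Nuclear shape is described by area, perimeter,
   circularity `4πA/P²`, solidity, and maximal Feret diameter.

2. **Paced contraction / calcium traces.** Displacement traces from
   video-edge tracking (e.g. 63 frames/s, 25 s, 1 Hz pacing) are segmented
   into beats by prominence-based peak detection; onset is a threshold
   crossing at 10% of beat amplitude above the local diastolic baseline,
   refined to the point of departure from baseline; the beat end is the
   subsequent displacement minimum. Contraction time = onset → peak,
   relaxation time = peak → end; per-trace means plus the beat-to-beat SD
   (the *heterogeneity index*, an arrhythmia proxy) are reported.
   Ratiometric calcium traces reuse the segmentation: the diastolic ratio
   is the resting baseline and the *diastolic time* runs from the transient
   peak to the 90% return toward baseline (sub-sample interpolated).
   Force responses to stepwise external calcium (0.3 → 3.0 mmol/L) are fit
   with the Hill model `F = Fmax·c^h/(EC50^h + c^h)` by bounded least
   squares to estimate EC50.

3. **Differential-expression tables.** DESeq2-style tables are filtered at
   `padj < 0.05` and `|log2FC| > 0.5`, tallied per chromosome (DEG percent
   of the chromosome's genes, share of all DEGs, ECM-related DEG counts),
   and tested for per-chromosome enrichment with an exact binomial test
   against the genome-wide DEG fraction (BH-adjusted).

The `synthetic` module generates all three data types with controlled
ground truth (territory radial position, per-beat onset/peak/amplitude,
true-DEG flags), which is how the test suite validates every stage.

## Worked example

```python
from cardionuc import (SceneParams, make_nucleus_mask, render_territory_scene,
                       compute_distance_bins, profile_intensity, peripherality_index,
                       shape_descriptors, TraceParams, simulate_beat_trace,
                       detect_beats, summarize_trace)

# a peripheral territory (mu = 0.7 on the 0=center..1=boundary axis)
sp = SceneParams(territory_radial_mu=0.7, seed=42)
mask = make_nucleus_mask(sp)
scene = render_territory_scene(mask, sp)
bins = compute_distance_bins(mask, n_bins=10, mode="equal_width")
prof = profile_intensity(scene.image[1], bins)
print(f"ground-truth mean radius: {scene.gt_mean_radius:.3f}")
print(f"peripherality index:      {peripherality_index(prof):.3f}")
sd = shape_descriptors(mask)
print(f"nuclear area: {sd.area:.2f} um^2, circularity: {sd.circularity:.3f}")

trace, gt = simulate_beat_trace(TraceParams(amplitude_cv=0.1, noise_sd=0.02, seed=42))
summary = summarize_trace(detect_beats(trace))
print(f"beats: {summary.n_beats}, contraction {summary.mean_contraction_time:.3f} s, "
      f"amplitude heterogeneity {summary.heterogeneity_amplitude:.3f}")
```

prints

```
ground-truth mean radius: 0.720
peripherality index:      0.550
nuclear area: 6.37 um^2, circularity: 0.956
beats: 25, contraction 0.209 s, amplitude heterogeneity 0.118
```

The territory placed at normalized radius 0.72 yields a peripherality index
of 0.55 on the *noisy* rendered image (the camera background dilutes the
index toward 0.5 — group contrasts, not absolute values, carry the signal).
The noisy 1 Hz / 25 s trace still segments into exactly 25 beats; the
~0.21 s contraction time recovers the simulated 0.20 s linear rise, and the
heterogeneity reflects the injected 10% amplitude variability.

## Command line

The full synthetic end-to-end analysis runs from one command:

```sh
cardionuc run --out run1 --seed 7        # simulate + all analysis stages
cardionuc report --out run1              # regenerate run1/report.md
```

Stages (`simulate`, `profile`, `beats`, `calcium`, `degs`, `compare`,
`report`) can also run individually against a JSON config; every run
directory contains a `manifest.json` tracing each output file to the config
and seed by SHA-256 digest.

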