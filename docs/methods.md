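# Methods

This note documents the models, conventions and numerical choices behind
`cardionuc`, and what the synthetic-data generators do and do not emulate.

## Radial binning of nuclear masks

For each foreground pixel of a binarized nucleus mask, let `D` be its exact
Euclidean distance to the nearest background pixel (computed with the exact
distance transform; the boundary is the 4-connected background
neighborhood) and `D_max` the deepest value in the mask. The normalized
boundary distance is `r = 1 − D/D_max`, so the deepest pixel has `r = 0`
and boundary-adjacent pixels approach 1. Ten bins are indexed center (1) to
periphery (10); bins 1–5 are reported as the nuclear center and 6–10 as the
periphery.

Two binning modes are provided because erosion-ring practice varies:

* **equal_width** (default): `bin = min(⌊r·10⌋ + 1, 10)` — ten equal
  intervals of `r`. This is closest to iterative-erosion ring analysis.
* **equal_area**: thresholds are the empirical deciles of `r` over the
  foreground, so bins hold equal pixel counts up to *tie blocks*: all
  pixels sharing one `r` value (e.g. the entire boundary ring at `D = 1`)
  are assigned one bin. A tie block larger than a tenth of the mask can
  legally absorb a bin; occupied bins always form a contiguous range
  starting at 1. Deviations of per-bin counts from `area/10` are bounded by
  the tie block straddling each decile.

Both modes are verified exactly against an independent brute-force
implementation (direct nearest-background search, direct decile split) on
random masks.

## Intensity profiles and normalization

Per nucleus, the profile is the mean probe intensity over each bin's
pixels. Profiles of one probe are min–max normalized with extrema pooled
over *all* profiles of both groups (default `global` scope: one scalar min
and max over all bins and nuclei; a `per_bin` scope computing bin-wise
extrema is available behind a switch, since published descriptions of this
normalization admit both readings). Group rows of the heatmap matrix are
means of the normalized per-nucleus profiles; all values lie in [0, 1], and
the matrix is invariant under positive affine rescaling of the raw
intensities. If all pooled values coincide the normalization is degenerate:
an all-zero matrix is returned with an explicit flag rather than dividing
by zero.

The peripherality index of a 10-bin profile is
`Σ(bins 6–10) / Σ(bins 1–10)`; it is undefined (error) for an all-zero
profile.

## Group comparison

Normalized per-nucleus profiles enter a two-way ANOVA (OLS,
`value ~ C(group) * C(bin)`, type-2 sums of squares) with nucleus as
replicate. Per-bin group contrasts use Welch t-tests with Šídák adjustment
over the 10 bins (`p_adj = 1 − (1 − p)^10`); per-bin group means ± SEM are
reported alongside. Calibration (per-bin adjusted false-positive rate under
the null) and power (interaction detection for a 0.4-vs-0.7 radial shift at
n = 30 nuclei/group) are exercised in the acceptance tests at 200 and 100
seeded repetitions respectively.

## Shape descriptors

Area, perimeter, circularity `4πA/P²`, solidity (area / convex-hull area)
and maximal Feret diameter, all in physical units via the mask's pixel
size (default 0.0658 µm/px, a typical value for 100× super-resolution
painting acquisitions; morphometric examples use 0.11 µm/px). The perimeter
uses the Crofton estimator (4 directions) so rasterized disks stay within a
few percent of circularity 1; raw edge-pixel counting would bias
circularity well below 1.

## Beat segmentation and contractile metrics

Peaks are detected with `scipy.signal.find_peaks` using a prominence floor
of 0.3 × the 5th–95th percentile excursion and a refractory interval of
half the pacing period — both fractional, so segmentation is invariant to
positive rescaling of the units. Per beat:

* **local baseline** — median of the inter-beat window preceding the rise
  (robust to slow drift);
* **onset** — the upward crossing of `baseline + 0.10 × amplitude`
  (onset fraction configurable, echoed in outputs), then walked back while
  the signal is strictly decreasing backwards, i.e. to the point of
  departure from baseline. The walk-back keeps the measured contraction
  time equal to the full rise time within one frame on clean traces, where
  a bare threshold crossing would systematically clip ~10% of the rise;
* **end** — the subsequent displacement minimum before the next onset;
* contraction time = onset → peak; relaxation time = peak → end, both on
  the sample grid (the acquisition is frame-indexed).

Per-trace summaries report means across beats and the beat-to-beat sample
SD (n − 1) of each metric — the heterogeneity index. With a single beat the
SD is 0 by convention.

## Calcium analytics

The diastolic (resting) ratio is the mean of the quiescent pre-onset
windows across transients. Per transient, the diastolic time runs from the
ratio peak to the first crossing of `baseline + 0.10 × (peak − baseline)` —
i.e. the signal has decayed back by 90% of its amplitude — with the
crossing linearly interpolated between samples (the only sub-sample
quantity in the package). For an exponential decay with time constant τ the
analytic value is τ·ln 10, which the implementation reproduces within one
frame period. Transients that never return within 10% of baseline before
the next onset are excluded and counted in a warning. Adding a constant
offset shifts the diastolic ratio by that constant and leaves the diastolic
time unchanged.

## EC50 estimation

The Hill model `F = Fmax·c^h/(EC50^h + c^h)` is fit by bounded
least squares (`scipy.optimize.curve_fit`), with EC50 constrained to
`[0.1·min c, 10·max c]`, `h ∈ (0, 8]` and `Fmax ∈ (0, 2·max F]`; the
initial guess is `(max F, median c, 1.5)`. A flat response or
non-convergence yields a `failed` status with the residual recorded, and a
fitted EC50 outside the measured range is flagged. On the stepwise
0.3–3.0 mmol/L protocol grid the estimator recovers a noiseless EC50 to
better than 1% and keeps the median absolute error under 10% at 5%
multiplicative-scale noise.

## DEG filtering and chromosome summaries

DEGs are rows with `padj < 0.05` and `|log2FC| > 0.5` (strict inequalities,
two-sided in fold change; thresholds are echoed in the output metadata, and
rows missing either value are dropped with a count). Per chromosome the
summary reports the gene count, DEG count, DEG percent of the chromosome's
genes (the default normalization), the share of all DEGs (the alternative
normalization, also emitted), and the ECM-related DEG tally. Chromosomes
absent from the table are omitted, not zero-divided. Enrichment per
chromosome uses an exact two-sided binomial test of the chromosome's DEG
count against the genome-wide DEG fraction with Benjamini–Hochberg
adjustment across chromosomes; a chromosome exactly at the genome-wide rate
gets p = 1 under this convention.

## Synthetic data: what it emulates, and what it does not

**Territory scenes.** Nuclei are rasterized ellipses (default semiaxes
26 × 18 px in a 64 × 64 image) with optional low-order harmonic boundary
wobble; masks are single 4-connected components. A territory of a fixed
area fraction (default 0.08 of the nucleus) is grown from a seed placed at
a controlled normalized radius along a random direction, by lowest-cost
flood fill with cost `|r − target| + 0.25·d_seed/√area` — the blob hugs the
target radial shell, elongating along it the way painted territories do.
The ground-truth mean normalized radius is computed from the pre-noise
territory pixels and is invariant to every noise parameter; it tracks the
control strictly monotonically over the 0.1–0.9 grid. The camera model is
`background + Poisson(photon_scale · Gaussian-blurred indicator) +
N(0, read_noise)`; the background is a fixed offset outside the Poisson so
that zeroing the signal and read noise yields an exactly constant channel
for oracle tests. Not emulated: 3-D nuclei and Z-stacks, chromatin texture,
optical PSFs beyond the small Gaussian blur, segmentation errors (masks are
inputs by design). Passing tests therefore validate the *measurement*
pipeline, not robustness to segmentation or depth artifacts.

**Beat traces.** Default acquisition 63 frames/s × 25 s at 1 Hz pacing
(the first onset at 0.2 s gives exactly 25 beats). Each beat is a linear
rise (0.20 s) followed by an exponential decay (τ = 0.15 s), so onset, peak
and 90%-return are available in closed form; amplitude CV, onset timing
jitter and additive Gaussian noise are all independently controlled and
zero by default. Overlapping beats (`rise + 5τ` exceeding the pacing
period) set a warning flag rather than failing. Not emulated: motion
artifacts, drift, ectopic beats, alternans.

**DE tables.** Gene counts per chromosome approximate the human
protein-coding complement (~19.7k genes over chr1–22 and X). Each gene is a
true DEG with probability `base_deg_prob` (default 0.02) times a
per-chromosome enrichment multiplier; true DEGs draw `padj ~ Beta(0.5, 40)`
and `|log2FC| ~ LogNormal(ln 1.2, 0.4)` with random sign, null genes draw
`padj ~ U(0, 1)` and `log2FC ~ N(0, 0.15)`. ECM flags are drawn at 0.15
among DEGs (×2 on enriched chromosomes in the pipeline defaults) and 0.02
elsewhere. These distributions are a plausible, explicitly stated
stand-in — adjusted-p distributions of real DESeq2 runs depend on the
dataset, so recall/precision results transfer only qualitatively.

## Randomness and determinism

Every generator takes one integer seed and derives a named independent
stream per output (`PCG64` seeded with `[seed, crc32(stream)]`); identical
seeds and parameters give bit-identical outputs, including TIFF/CSV/JSON
files written by the pipeline (verified byte-for-byte by SHA-256 in the
manifest). Ground truth never consumes from the noise streams, so it is
unchanged when noise parameters change. The pipeline derives per-nucleus
and per-trace sub-seeds from the run seed with a CRC-based mix kept below
2³¹.

## Pipeline scales

The library defaults are 30 nuclei/group, 6 traces/group and two ~19.7k
gene tables; a full run takes on the order of a minute on one CPU. The
end-to-end determinism check and the worked examples use a reduced
configuration (12 nuclei/group, 64 × 64 images, 4 traces/group, two
~4.4k-gene tables) — the determinism and recovery properties being
scale-free, the smaller sizes were chosen to keep the examples quick to
rerun. Simulation-study sizes are stated with each result (200 repetitions
for calibration-type checks, 100 for power).

## Known limitations

* The ANOVA treats the 10 bins of one nucleus as independent observations
  (as is common in per-bin painting analyses); a mixed model with a
  per-nucleus random effect would be more conservative.
* The equal-area mode cannot split tie blocks, so very thin masks can leave
  the outermost bin empty (documented above; the equal-width default does
  not have this behavior for masks at least 10 px deep).
* Onset detection on noisy traces stops the walk-back at the first local
  wiggle, biasing onsets slightly late at high noise; the onset fraction
  and prominence are configurable and recorded in outputs.
* The binomial enrichment test treats the genome-wide DEG fraction as a
  fixed reference rate; a hypergeometric (Fisher) variant conditioning on
  the total DEG count would differ slightly for small chromosomes.
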