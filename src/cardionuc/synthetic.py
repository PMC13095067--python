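"""Seeded synthetic data with known ground truth for every pipeline stage.

Three generators emulate the raw inputs of the phenotyping pipeline:

* elliptical nuclei containing a painted chromosome-territory blob whose
  radial position is a controlled parameter, imaged with a
  Poisson-photon / Gaussian-read camera model;
* paced quasi-periodic displacement (or calcium-ratio) traces with
  controlled rise/decay times, amplitude, beat-to-beat jitter and noise;
* differential-expression tables with per-chromosome DEG enrichment and an
  ECM-related gene subset.

Ground truth (territory pixels and mean normalized radius, per-beat onset/
peak/amplitude, true-DEG flags) is computed *before* noise is applied and is
therefore invariant to the noise parameters.  A single integer seed feeds a
named stream per output, so identical parameters give bit-identical data.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .radial import NuclearMask, normalized_boundary_distance
from .traces import BeatTrace, hill

__all__ = [
    "SceneParams",
    "TraceParams",
    "DEGSimParams",
    "TerritoryScene",
    "make_nucleus_mask",
    "render_territory_scene",
    "simulate_beat_trace",
    "simulate_calcium_response",
    "simulate_deg_table",
    "DEFAULT_GENES_PER_CHROMOSOME",
    "DEFAULT_CALCIUM_GRID_MM",
]

#: approximate protein-coding gene counts per human chromosome (autosomes + X)
DEFAULT_GENES_PER_CHROMOSOME: dict[str, int] = {
    "1": 2000, "2": 1200, "3": 1050, "4": 750, "5": 900, "6": 1000, "7": 950,
    "8": 700, "9": 780, "10": 730, "11": 1300, "12": 1030, "13": 320,
    "14": 600, "15": 600, "16": 850, "17": 1200, "18": 270, "19": 1450,
    "20": 550, "21": 230, "22": 450, "X": 820,
}

#: stepwise external-calcium protocol, mmol/L (0.3 up to 3.0)
DEFAULT_CALCIUM_GRID_MM = (0.3, 0.6, 0.9, 1.2, 1.5, 1.8, 2.4, 3.0)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent named stream derived from one global integer seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stream.encode())])


# --------------------------------------------------------------------------
# parameter containers

@dataclass
class SceneParams:
    """Parameters of one synthetic nucleus + territory scene.

    ``territory_radial_mu`` positions the territory on the normalized
    center(0)→boundary(1) axis; ``territory_radial_sigma`` jitters the target
    radius between nuclei.  ``photon_scale`` is the expected photon count of
    the probe signal; ``read_noise_sd`` the Gaussian camera read noise;
    ``background`` a fixed camera offset (counts).
    """

    nucleus_semiaxes: tuple[float, float] = (26.0, 18.0)
    image_size: tuple[int, int] = (64, 64)
    territory_radial_mu: float = 0.5
    territory_radial_sigma: float = 0.05
    territory_area_fraction: float = 0.08
    photon_scale: float = 200.0
    read_noise_sd: float = 3.0
    background: float = 100.0
    boundary_wobble: float = 0.0
    pixel_size: float = 0.0658
    blur_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        a, b = self.nucleus_semiaxes
        h, w = self.image_size
        # the wobble modulates the boundary radius multiplicatively
        margin = 1.0 + self.boundary_wobble
        if a <= 0 or b <= 0:
            raise ValueError("semiaxes must be positive")
        if a * margin > w / 2 - 2 or b * margin > h / 2 - 2:
            raise ValueError("semiaxes must fit inside the image with a 2 px margin")
        if not (0.0 <= self.territory_radial_mu <= 1.0):
            raise ValueError("territory_radial_mu must lie in [0, 1]")
        if not (0.0 < self.territory_area_fraction <= 0.5):
            raise ValueError("territory_area_fraction must lie in (0, 0.5]")
        for name in ("territory_radial_sigma", "photon_scale", "read_noise_sd",
                     "background", "boundary_wobble"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TraceParams:
    """Parameters of a paced quasi-periodic beat trace.

    Defaults follow the video-edge acquisition protocol: 63 frames/s for
    25 s per position under 1 Hz field pacing.  Each beat is a pulse with a
    linear rise over ``rise_time`` and an exponential decay with time
    constant ``decay_time``; beat amplitudes vary with coefficient of
    variation ``amplitude_cv`` and onsets are jittered by
    ``timing_jitter_sd``.
    """

    frame_rate: float = 63.0
    duration: float = 25.0
    pacing_rate: float = 1.0
    amplitude_mu: float = 1.0
    amplitude_cv: float = 0.0
    rise_time: float = 0.20
    decay_time: float = 0.15
    baseline: float = 0.0
    timing_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    start_offset: float = 0.2
    modality: str = "displacement"
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0 or self.pacing_rate <= 0:
            raise ValueError("frame_rate, duration and pacing_rate must be positive")
        if self.frame_rate / self.pacing_rate < 2:
            raise ValueError("need at least 2 samples per beat")
        if self.pacing_rate * self.duration < 3:
            raise ValueError("need at least 3 beats in the trace")
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise ValueError("rise_time and decay_time must be positive")
        for name in ("amplitude_cv", "timing_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DEGSimParams:
    """Parameters of a synthetic differential-expression table.

    Each gene is a DEG with chromosome-specific probability
    ``base_deg_prob * multiplier`` (multiplier from ``enriched_chromosomes``,
    default 1).  DEGs draw ``padj`` from the alternative distribution and
    |log2FC| from a log-normal centered on ``effect_size_mu``; non-DEGs draw
    ``padj`` uniform on (0,1) and log2FC from a tight normal around 0.
    Distribution specs are (name, args) pairs resolved through scipy.stats.
    """

    n_genes_per_chromosome: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CHROMOSOME)
    )
    base_deg_prob: float = 0.02
    enriched_chromosomes: dict[str, float] = field(default_factory=dict)
    effect_size_mu: float = 1.2
    effect_size_sigma: float = 0.4
    null_lfc_sd: float = 0.15
    null_padj_dist: tuple = ("uniform", (0.0, 1.0))
    alt_padj_dist: tuple = ("beta", (0.5, 40.0))
    ecm_fraction: float = 0.15
    ecm_background: float = 0.02
    ecm_enriched_multiplier: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.n_genes_per_chromosome:
            raise ValueError("need at least one chromosome")
        for chrom, n in self.n_genes_per_chromosome.items():
            if n <= 0:
                raise ValueError(f"gene count for chr{chrom} must be > 0")
        for p in (self.base_deg_prob, self.ecm_fraction, self.ecm_background):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for chrom, m in self.enriched_chromosomes.items():
            if m < 1.0:
                raise ValueError(f"enrichment multiplier for chr{chrom} must be >= 1")


def params_to_json(params) -> str:
    """Serialize any params dataclass to JSON (round-trips losslessly)."""
    return json.dumps(dataclasses.asdict(params), sort_keys=True)


def params_from_json(cls, text: str):
    """Rebuild a params dataclass from :func:`params_to_json` output."""
    data = json.loads(text)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    def _deep_tuple(v):
        return tuple(_deep_tuple(x) for x in v) if isinstance(v, list) else v

    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = _deep_tuple(data[f.name])
    return cls(**data)


# --------------------------------------------------------------------------
# nuclei and territories

def make_nucleus_mask(params: SceneParams) -> NuclearMask:
    """Rasterize an elliptical nucleus with optional smooth boundary wobble.

    The boundary radius is modulated by low-order harmonics of random phase
    scaled by ``boundary_wobble`` (0 disables it, leaving an exact ellipse).
    The result is a single 4-connected component.
    """
    params.validate()
    rng = _rng(params.seed, "mask")
    h, w = params.image_size
    a, b = params.nucleus_semiaxes
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    if params.boundary_wobble > 0:
        theta = np.arctan2(dy, dx)
        mod = np.ones_like(theta)
        for k in (2, 3, 4):
            amp = params.boundary_wobble * rng.uniform(0.2, 1.0) / 3.0
            mod += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    else:
        mod = 1.0
    raster = rho <= mod
    lbl, n = ndimage.label(raster, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:  # keep the central component; tiny satellites can arise at high wobble
        raster = lbl == lbl[int(round(cy)), int(round(cx))]
    return NuclearMask(raster=raster, pixel_size=params.pixel_size)


@dataclass
class TerritoryScene:
    """Rendered two-channel image plus pre-noise ground truth."""

    image: np.ndarray  # (2, H, W): channel 0 counterstain, channel 1 probe
    mask: NuclearMask
    territory: np.ndarray  # boolean territory indicator (pre-noise)
    gt_mean_radius: float  # mean normalized boundary distance of territory pixels
    expected: np.ndarray | None = None  # (2, H, W) noiseless expected image


def _grow_territory(
    mask: np.ndarray,
    r: np.ndarray,
    target_r: float,
    angle: float,
    area: int,
    compactness: float = 0.25,
) -> np.ndarray:
    """Grow a connected blob of ``area`` pixels centered on a radial shell.

    The seed pixel sits at normalized radius ``target_r`` along direction
    ``angle`` from the mask centroid.  Growth is a lowest-cost-first flood
    fill (4-connected) with cost ``|r - target_r| + compactness * d_seed /
    sqrt(mask area)``: the blob hugs the target shell, elongating along it
    the way painted territories do, while the compactness term keeps it
    local.  Fully deterministic (row/column tie-break).
    """
    import heapq

    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dr = np.abs(r[ys, xs] - target_r)
    near = dr <= dr.min() + 0.02
    cand_y, cand_x = ys[near], xs[near]
    ang = np.arctan2(cand_y - cy, cand_x - cx)
    d_ang = np.angle(np.exp(1j * (ang - angle)))
    k = int(np.argmin(np.abs(d_ang)))
    seed_y, seed_x = int(cand_y[k]), int(cand_x[k])

    scale = compactness / np.sqrt(mask.sum())
    blob = np.zeros_like(mask)
    visited = np.zeros_like(mask)
    heap: list[tuple[float, int, int]] = [(0.0, seed_y, seed_x)]
    visited[seed_y, seed_x] = True
    n_added = 0
    h, w = mask.shape
    while heap and n_added < area:
        _, y, x = heapq.heappop(heap)
        blob[y, x] = True
        n_added += 1
        for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not visited[ny, nx]:
                visited[ny, nx] = True
                d_seed = np.hypot(ny - seed_y, nx - seed_x)
                cost = abs(r[ny, nx] - target_r) + scale * d_seed
                heapq.heappush(heap, (cost, ny, nx))
    return blob


def render_territory_scene(mask: NuclearMask, params: SceneParams) -> TerritoryScene:
    """Render counterstain + probe channels for a territory inside a nucleus.

    The probe channel is ``background + Poisson(photon_scale * blurred
    territory indicator) + N(0, read_noise_sd)``; the counterstain channel
    covers the whole mask with the same camera model.  Ground truth (the
    territory pixel set and its mean normalized radius) is taken before blur
    and noise.
    """
    params.validate()
    raster = mask.raster
    area = int(round(params.territory_area_fraction * raster.sum()))
    if area < 1 or area > raster.sum():
        raise ValueError("territory_area_fraction infeasible for this mask")
    rng = _rng(params.seed, "territory")
    r = normalized_boundary_distance(raster)
    target = float(np.clip(
        rng.normal(params.territory_radial_mu, params.territory_radial_sigma), 0.0, 1.0
    )) if params.territory_radial_sigma > 0 else params.territory_radial_mu
    angle = rng.uniform(0.0, 2.0 * np.pi)
    territory = _grow_territory(raster, r, target, angle, area)
    gt_mean_radius = float(np.mean(r[territory]))

    cam = _rng(params.seed, "camera")
    h, w = raster.shape
    image = np.zeros((2, h, w), dtype=float)
    expected = np.zeros((2, h, w), dtype=float)
    for ch, indicator in ((0, raster.astype(float)), (1, territory.astype(float))):
        blurred = ndimage.gaussian_filter(indicator, params.blur_sigma)
        expected[ch] = params.background + params.photon_scale * blurred
        photons = cam.poisson(params.photon_scale * np.clip(blurred, 0, None))
        read = cam.normal(0.0, params.read_noise_sd, size=(h, w)) if params.read_noise_sd > 0 else 0.0
        image[ch] = params.background + photons + read
    return TerritoryScene(image=image, mask=mask, territory=territory,
                          gt_mean_radius=gt_mean_radius, expected=expected)


# --------------------------------------------------------------------------
# beat traces and calcium

def _pulse(t: np.ndarray, amplitude: float, rise: float, decay: float) -> np.ndarray:
    """Linear rise over ``rise`` then exponential decay with constant ``decay``."""
    out = np.zeros_like(t)
    up = (t >= 0) & (t < rise)
    out[up] = amplitude * t[up] / rise
    dn = t >= rise
    out[dn] = amplitude * np.exp(-(t[dn] - rise) / decay)
    return out


def simulate_beat_trace(params: TraceParams) -> tuple[BeatTrace, pd.DataFrame]:
    """Simulate a paced trace and its per-beat ground-truth table.

    Returns the trace and a DataFrame with columns ``onset_s``, ``peak_s``,
    ``amplitude``, ``end_s`` (next onset, or trace end for the last beat) and
    an ``overlap_warning`` flag set when ``rise_time + 5*decay_time`` exceeds
    the pacing period, i.e. beats overlap appreciably.
    """
    params.validate()
    rng = _rng(params.seed, "trace")
    period = 1.0 / params.pacing_rate
    n_samples = int(round(params.frame_rate * params.duration))
    t = np.arange(n_samples) / params.frame_rate

    onsets, amps = [], []
    k = 0
    while True:
        onset = params.start_offset + k * period
        if params.timing_jitter_sd > 0:
            onset += rng.normal(0.0, params.timing_jitter_sd)
        elif params.timing_jitter_sd == 0:
            rng.normal(0.0, 1.0)  # keep the stream aligned across jitter settings
        if onset + params.rise_time >= params.duration:
            break
        amp = params.amplitude_mu * max(0.0, rng.normal(1.0, params.amplitude_cv)) \
            if params.amplitude_cv > 0 else params.amplitude_mu
        onsets.append(max(onset, 0.0))
        amps.append(amp)
        k += 1

    x = np.full(n_samples, params.baseline, dtype=float)
    for onset, amp in zip(onsets, amps):
        x += _pulse(t - onset, amp, params.rise_time, params.decay_time)
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, size=n_samples)

    overlap = params.rise_time + 5.0 * params.decay_time > period
    gt = pd.DataFrame({
        "onset_s": onsets,
        "peak_s": [o + params.rise_time for o in onsets],
        "amplitude": amps,
        "end_s": [onsets[i + 1] if i + 1 < len(onsets) else params.duration
                  for i in range(len(onsets))],
    })
    gt["overlap_warning"] = overlap
    trace = BeatTrace(samples=x, frame_rate=params.frame_rate,
                      pacing_rate=params.pacing_rate, modality=params.modality)
    return trace, gt


def simulate_calcium_response(
    ec50: float,
    hill_coef: float,
    fmax: float,
    concentrations=DEFAULT_CALCIUM_GRID_MM,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hill-model force response over a stepwise external-calcium protocol.

    ``force_i = fmax * c_i**h / (ec50**h + c_i**h) + N(0, noise_sd)``.
    Returns (concentrations, forces).
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    f = hill(c, fmax, ec50, hill_coef)
    if noise_sd > 0:
        f = f + _rng(seed, "calcium").normal(0.0, noise_sd, size=c.size)
    return c, f


# --------------------------------------------------------------------------
# differential-expression tables

def _sample_dist(spec: tuple, rng: np.random.Generator, size: int) -> np.ndarray:
    from scipy import stats

    name, args = spec
    if name == "uniform":
        lo, hi = args
        return rng.uniform(lo, hi, size=size)
    dist = getattr(stats, name)(*args)
    return np.asarray(dist.rvs(size=size, random_state=rng))


def simulate_deg_table(params: DEGSimParams) -> pd.DataFrame:
    """Simulate a DESeq2-style gene table with ground-truth DEG flags.

    Columns: ``gene_id``, ``chromosome``, ``log2fc``, ``padj``, ``is_ecm``,
    ``is_deg_true``.  DEG status is drawn per chromosome with probability
    ``base_deg_prob`` times the chromosome's enrichment multiplier (capped at
    1); ECM flags are drawn with ``ecm_fraction`` among DEGs (times
    ``ecm_enriched_multiplier`` on enriched chromosomes) and
    ``ecm_background`` among non-DEGs.
    """
    params.validate()
    rng = _rng(params.seed, "degs")
    rows = []
    for chrom, n in params.n_genes_per_chromosome.items():
        mult = params.enriched_chromosomes.get(chrom, 1.0)
        p_deg = min(params.base_deg_prob * mult, 1.0)
        is_deg = rng.random(n) < p_deg
        lfc = rng.normal(0.0, params.null_lfc_sd, size=n)
        padj = _sample_dist(params.null_padj_dist, rng, n)
        n_alt = int(is_deg.sum())
        if n_alt:
            mag = rng.lognormal(np.log(params.effect_size_mu), params.effect_size_sigma, n_alt)
            sign = rng.choice([-1.0, 1.0], size=n_alt)
            lfc[is_deg] = sign * mag
            padj[is_deg] = _sample_dist(params.alt_padj_dist, rng, n_alt)
        p_ecm = np.where(
            is_deg,
            min(params.ecm_fraction * (params.ecm_enriched_multiplier if mult > 1 else 1.0), 1.0),
            params.ecm_background,
        )
        is_ecm = rng.random(n) < p_ecm
        rows.append(pd.DataFrame({
            "gene_id": [f"chr{chrom}_g{i:05d}" for i in range(n)],
            "chromosome": chrom,
            "log2fc": lfc,
            "padj": np.clip(padj, 0.0, 1.0),
            "is_ecm": is_ecm,
            "is_deg_true": is_deg,
        }))
    return pd.concat(rows, ignore_index=True)
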