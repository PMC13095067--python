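"""Beat segmentation and contractile / calcium-transient metrics.

Displacement traces from video-edge tracking of paced cardiomyocytes are
segmented into beats by prominence-based peak detection.  Per beat, the
contraction onset is found by a threshold on the fractional rise above the
local diastolic baseline ("threshold-based rise onset") refined back to the
point of departure from baseline; the end of relaxation is the subsequent
displacement minimum.  Per-trace summaries average each metric across beats
and report the beat-to-beat standard deviation as the heterogeneity index, a
proxy for arrhythmic irregularity.

Ratiometric calcium traces (405/480 nm emission ratio) reuse the same
segmentation; the diastolic ratio is the mean of the pre-onset windows and
the diastolic time is the interval from the transient peak to the return to
90% of the resting baseline, with sub-sample linear interpolation of the
crossing.

External-calcium force-response curves are fit with the Hill model
``F(c) = Fmax * c**h / (EC50**h + c**h)`` by bounded least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "BeatTrace",
    "Beat",
    "BeatSummary",
    "CalciumMetrics",
    "CalciumResponseCurve",
    "detect_beats",
    "beat_timings",
    "summarize_trace",
    "calcium_metrics",
    "fit_calcium_response",
    "hill",
]

#: fraction of beat amplitude above baseline defining the rise-onset threshold
DEFAULT_ONSET_FRACTION = 0.10

#: default peak prominence, as a fraction of the 5th-95th percentile excursion
DEFAULT_MIN_PROMINENCE = 0.30


@dataclass
class BeatTrace:
    """Uniformly sampled displacement or calcium-ratio series."""

    samples: np.ndarray
    frame_rate: float
    pacing_rate: float = 1.0
    modality: str = "displacement"  # or "calcium_ratio"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace must be 1-D")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.samples.size < 3 * self.frame_rate:
            raise ValueError("trace shorter than 3 s of samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.frame_rate


@dataclass
class Beat:
    """One segmented beat: sample indices and derived timings."""

    onset_index: int
    peak_index: int
    end_index: int
    amplitude: float
    baseline: float
    contraction_time: float
    relaxation_time: float

    def __post_init__(self) -> None:
        if not (self.onset_index < self.peak_index <= self.end_index):
            raise ValueError("beat requires onset < peak <= end")


@dataclass
class BeatSummary:
    """Per-trace means and beat-to-beat heterogeneity (SD across beats)."""

    n_beats: int
    mean_amplitude: float = np.nan
    mean_contraction_time: float = np.nan
    mean_relaxation_time: float = np.nan
    heterogeneity_amplitude: float = np.nan
    heterogeneity_contraction_time: float = np.nan
    heterogeneity_relaxation_time: float = np.nan


@dataclass
class CalciumMetrics:
    """Averaged calcium-transient metrics for one ratiometric trace."""

    diastolic_ratio: float
    diastolic_time: float
    transient_amplitude: float
    n_transients: int
    n_excluded: int = 0


@dataclass
class CalciumResponseCurve:
    """Hill fit of contractile force vs external calcium concentration."""

    concentrations: np.ndarray
    force: np.ndarray
    ec50: float = np.nan
    hill: float = np.nan
    fmax: float = np.nan
    residual: float = np.nan
    status: str = "ok"
    ec50_in_range: bool = True


def _local_baseline(x: np.ndarray, window_start: int, trough: int, half_width: int) -> float:
    """Median of the inter-beat window that precedes the rise."""
    lo = max(window_start, trough - max(half_width, 1))
    return float(np.median(x[lo : trough + 1]))


def detect_beats(
    trace: BeatTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_interval: float | None = None,
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
) -> list[Beat]:
    """Segment a trace into beats.

    Peaks are detected with a prominence floor of ``min_prominence`` times the
    5th-95th percentile excursion and a refractory period ``min_interval``
    (default half the pacing period).  For each peak the onset is the
    departure from the local baseline: the threshold crossing at
    ``baseline + onset_fraction * amplitude`` is walked back monotonically to
    the preceding trough.  The beat end is the subsequent displacement
    minimum before the next onset.  Both thresholds are fractional, so the
    segmentation is invariant to positive rescaling of the units.

    Returns an empty list when no peaks clear the prominence floor.
    """
    x = trace.samples
    if min_interval is None:
        min_interval = 0.5 / trace.pacing_rate
    excursion = float(np.percentile(x, 95) - np.percentile(x, 5))
    if excursion <= 0:
        return []
    distance = max(1, int(round(min_interval * trace.frame_rate)))
    peaks, _ = find_peaks(x, prominence=min_prominence * excursion, distance=distance)
    if peaks.size == 0:
        return []

    beats: list[Beat] = []
    boundaries = np.concatenate([[0], peaks])
    onsets: list[int] = []
    for i, p in enumerate(peaks):
        b = int(boundaries[i])
        seg = x[b : p + 1]
        trough = b + int(np.argmin(seg))
        baseline = _local_baseline(x, b, trough, distance // 2)
        amp = float(x[p] - baseline)
        if amp <= 0:
            onsets.append(-1)
            continue
        threshold = baseline + onset_fraction * amp
        # last index below threshold scanning back from the peak
        j = int(p)
        while j > trough and x[j - 1] >= threshold:
            j -= 1
        # walk back down the rise to the point of departure from baseline
        # (strictly decreasing backwards, so flat baseline stops the walk)
        while j > trough and x[j - 1] < x[j]:
            j -= 1
        onsets.append(j)

    for i, p in enumerate(peaks):
        onset = onsets[i]
        if onset < 0 or onset >= p:
            continue  # degenerate beat discarded
        next_onset = None
        for k in range(i + 1, len(peaks)):
            if onsets[k] >= 0:
                next_onset = onsets[k]
                break
        stop = next_onset if next_onset is not None else x.size - 1
        if stop <= p:
            stop = x.size - 1
        end = p + int(np.argmin(x[p : stop + 1]))
        if end <= p:
            end = min(p + 1, x.size - 1)
        b = int(boundaries[i])
        seg = x[b : p + 1]
        trough = b + int(np.argmin(seg))
        baseline = _local_baseline(x, b, trough, distance // 2)
        amp = float(x[p] - baseline)
        if amp <= 0:
            continue
        beats.append(
            Beat(
                onset_index=int(onset),
                peak_index=int(p),
                end_index=int(end),
                amplitude=amp,
                baseline=baseline,
                contraction_time=(p - onset) / trace.frame_rate,
                relaxation_time=(end - p) / trace.frame_rate,
            )
        )
    return beats


def beat_timings(trace: BeatTrace, beat: Beat) -> tuple[float, float]:
    """Contraction time (onset→peak) and relaxation time (peak→end), seconds."""
    if beat.peak_index <= beat.onset_index:
        raise ValueError("degenerate beat: peak at or before onset")
    contraction = (beat.peak_index - beat.onset_index) / trace.frame_rate
    relaxation = (beat.end_index - beat.peak_index) / trace.frame_rate
    return contraction, relaxation


def summarize_trace(beats: list[Beat]) -> BeatSummary:
    """Average beat metrics and their beat-to-beat SD (heterogeneity index).

    The heterogeneity index is the sample standard deviation (n-1 denominator)
    of each metric across the beats of one recording; for a single beat it is
    0 by convention.  Zero beats yields an explicit empty summary.
    """
    if not beats:
        return BeatSummary(n_beats=0)

    def _sd(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    amp = np.array([b.amplitude for b in beats])
    ct = np.array([b.contraction_time for b in beats])
    rt = np.array([b.relaxation_time for b in beats])
    return BeatSummary(
        n_beats=len(beats),
        mean_amplitude=float(amp.mean()),
        mean_contraction_time=float(ct.mean()),
        mean_relaxation_time=float(rt.mean()),
        heterogeneity_amplitude=_sd(amp),
        heterogeneity_contraction_time=_sd(ct),
        heterogeneity_relaxation_time=_sd(rt),
    )


def calcium_metrics(
    trace: BeatTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
    return_fraction: float = 0.10,
) -> CalciumMetrics:
    """Diastolic ratio, 90%-return diastolic time and transient amplitude.

    The diastolic (resting) ratio is the mean of the pre-onset windows across
    transients.  Per transient, the diastolic time runs from the ratio peak to
    the first crossing of ``baseline + return_fraction*(peak - baseline)``
    (i.e. the signal has decayed back by 90% of its amplitude), with the
    crossing linearly interpolated between samples.  Transients that never
    return within 10% of baseline before the next onset are excluded.
    Metrics are averaged over the remaining transients.

    Adding a constant offset to the whole trace shifts ``diastolic_ratio`` by
    that constant and leaves ``diastolic_time`` unchanged.
    """
    if trace.modality != "calcium_ratio":
        raise ValueError("calcium_metrics requires a calcium_ratio trace")
    beats = detect_beats(trace, min_prominence=min_prominence, onset_fraction=onset_fraction)
    if len(beats) < 3:
        return CalciumMetrics(
            diastolic_ratio=np.nan,
            diastolic_time=np.nan,
            transient_amplitude=np.nan,
            n_transients=0,
        )
    x = trace.samples
    # resting ratio: mean over the quiescent windows preceding each onset
    pre = []
    prev_end = 0
    for b in beats:
        lo = max(prev_end, b.onset_index - int(0.25 * trace.frame_rate / trace.pacing_rate))
        if b.onset_index > lo:
            pre.append(x[lo : b.onset_index])
        prev_end = b.end_index
    baseline = float(np.mean(np.concatenate(pre))) if pre else float(np.median(x))

    times, amps = [], []
    n_excluded = 0
    for i, b in enumerate(beats):
        peak_val = x[b.peak_index]
        amp = peak_val - baseline
        if amp <= 0:
            n_excluded += 1
            continue
        level = baseline + return_fraction * amp
        stop = beats[i + 1].onset_index if i + 1 < len(beats) else x.size - 1
        seg = x[b.peak_index : stop + 1]
        below = np.nonzero(seg <= level)[0]
        if below.size == 0:
            n_excluded += 1
            continue
        k = int(below[0])
        if k == 0:
            t_cross = 0.0
        else:
            y0, y1 = seg[k - 1], seg[k]
            frac = (y0 - level) / (y0 - y1) if y0 != y1 else 1.0
            t_cross = (k - 1 + frac) / trace.frame_rate
        times.append(t_cross)
        amps.append(amp)
    if not times:
        return CalciumMetrics(
            diastolic_ratio=baseline,
            diastolic_time=np.nan,
            transient_amplitude=np.nan,
            n_transients=0,
            n_excluded=n_excluded,
        )
    return CalciumMetrics(
        diastolic_ratio=baseline,
        diastolic_time=float(np.mean(times)),
        transient_amplitude=float(np.mean(amps)),
        n_transients=len(times),
        n_excluded=n_excluded,
    )


def hill(c: np.ndarray, fmax: float, ec50: float, h: float) -> np.ndarray:
    """Hill model: ``F = Fmax * c**h / (EC50**h + c**h)``."""
    c = np.asarray(c, dtype=float)
    return fmax * c**h / (ec50**h + c**h)


def fit_calcium_response(
    concentrations: np.ndarray, forces: np.ndarray
) -> CalciumResponseCurve:
    """Bounded least-squares Hill fit of a force vs [Ca2+]o response curve.

    EC50 is searched in ``[0.1*min(c), 10*max(c)]`` and the Hill coefficient
    in ``(0, 8]``.  The result carries the residual sum of squares, a status
    flag (``ok`` / ``failed``) and whether the fitted EC50 lies inside the
    measured concentration range.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(forces, dtype=float)
    if c.size != f.size:
        raise ValueError("concentrations and forces must have equal length")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    curve = CalciumResponseCurve(concentrations=c, force=f)
    if np.ptp(f) == 0:
        curve.status = "failed"
        curve.residual = 0.0
        return curve
    lo = [1e-12, 0.1 * c.min(), 1e-6]
    hi = [max(2.0 * f.max(), 1e-9), 10.0 * c.max(), 8.0]
    p0 = [max(f.max(), 1e-9), float(np.median(c)), 1.5]
    try:
        popt, _ = curve_fit(hill, c, f, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        curve.status = "failed"
        curve.residual = float(np.sum((f - f.mean()) ** 2))
        return curve
    curve.fmax, curve.ec50, curve.hill = (float(v) for v in popt)
    curve.residual = float(np.sum((f - hill(c, *popt)) ** 2))
    curve.ec50_in_range = bool(c.min() <= curve.ec50 <= c.max())
    return curve
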