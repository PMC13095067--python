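"""Beat segmentation exactness, heterogeneity, calcium analytics, Hill fits."""

import numpy as np
import pytest

from cardionuc.synthetic import TraceParams, simulate_beat_trace, simulate_calcium_response
from cardionuc.traces import (
    Beat,
    BeatTrace,
    beat_timings,
    calcium_metrics,
    detect_beats,
    fit_calcium_response,
    summarize_trace,
)

FRAME = 1.0 / 63.0


@pytest.fixture(scope="module")
def noiseless():
    trace, gt = simulate_beat_trace(TraceParams(seed=1))
    return trace, gt, detect_beats(trace)


def test_noiseless_beat_count_and_peak_alignment(noiseless):
    trace, gt, beats = noiseless
    assert len(beats) == len(gt) == 25
    peak_err = np.abs(np.array([b.peak_index for b in beats]) / 63.0 - gt["peak_s"])
    assert peak_err.max() <= FRAME


def test_noiseless_timings_within_one_frame(noiseless):
    trace, gt, beats = noiseless
    ct = np.array([b.contraction_time for b in beats])
    rt = np.array([b.relaxation_time for b in beats])
    assert np.abs(ct - (gt["peak_s"] - gt["onset_s"])).max() <= FRAME
    assert np.abs(rt - (gt["end_s"] - gt["peak_s"])).max() <= 2 * FRAME


def test_constant_trace_has_no_beats():
    trace = BeatTrace(samples=np.full(300, 1.0), frame_rate=63.0)
    assert detect_beats(trace) == []


def test_segmentation_scale_invariant(noiseless):
    trace, _, beats = noiseless
    doubled = BeatTrace(samples=2.0 * trace.samples, frame_rate=trace.frame_rate,
                        pacing_rate=trace.pacing_rate)
    beats2 = detect_beats(doubled)
    assert [(b.onset_index, b.peak_index, b.end_index) for b in beats] == \
        [(b.onset_index, b.peak_index, b.end_index) for b in beats2]


def test_symmetric_triangle_has_equal_rise_and_fall():
    fr = 63.0
    t = np.arange(int(10 * fr)) / fr
    x = np.zeros_like(t)
    for onset in np.arange(0.5, 9.0, 1.0):
        rel = t - onset
        up = (rel >= 0) & (rel < 0.3)
        dn = (rel >= 0.3) & (rel < 0.6)
        x[up] += rel[up] / 0.3
        x[dn] += (0.6 - rel[dn]) / 0.3
    trace = BeatTrace(samples=x, frame_rate=fr)
    beats = detect_beats(trace)
    assert len(beats) >= 8
    for b in beats:
        ct, rt = beat_timings(trace, b)
        assert abs(ct - rt) <= FRAME


def test_beat_timings_reject_degenerate():
    trace = BeatTrace(samples=np.zeros(300), frame_rate=63.0)
    beat = Beat(onset_index=5, peak_index=10, end_index=20, amplitude=1.0,
                baseline=0.0, contraction_time=0.1, relaxation_time=0.2)
    beat.peak_index = 5  # bypass constructor check to probe the guard
    with pytest.raises(ValueError, match="degenerate"):
        beat_timings(trace, beat)


# --------------------------------------------------------------------------
# summaries / heterogeneity


def _beat(amp, ct=0.2, rt=0.5):
    return Beat(onset_index=0, peak_index=10, end_index=30, amplitude=amp,
                baseline=0.0, contraction_time=ct, relaxation_time=rt)


def test_identical_beats_zero_heterogeneity():
    s = summarize_trace([_beat(1.0)] * 5)
    assert s.heterogeneity_amplitude == 0.0
    assert s.heterogeneity_contraction_time == 0.0
    assert s.heterogeneity_relaxation_time == 0.0


def test_summary_hand_computed_mean_and_sd():
    s = summarize_trace([_beat(1.0), _beat(2.0), _beat(3.0)])
    assert s.mean_amplitude == pytest.approx(2.0)
    assert s.heterogeneity_amplitude == pytest.approx(1.0)


def test_empty_summary_explicit():
    s = summarize_trace([])
    assert s.n_beats == 0 and np.isnan(s.mean_amplitude)


def test_amplitude_cv_recovered_from_heterogeneity():
    """Simulated 20% amplitude CV is recovered from the heterogeneity index."""
    cvs = []
    for seed in range(30):
        tp = TraceParams(amplitude_cv=0.2, seed=seed)
        trace, _ = simulate_beat_trace(tp)
        s = summarize_trace(detect_beats(trace))
        cvs.append(s.heterogeneity_amplitude / s.mean_amplitude)
    assert abs(np.mean(cvs) - 0.2) / 0.2 < 0.2


def test_heterogeneity_shrinks_with_variability_ladder():
    levels = [(0.2, 0.02, 0.05), (0.1, 0.01, 0.02), (0.0, 0.0, 0.0)]
    het = []
    for cv, jit, noise in levels:
        vals = []
        for seed in range(5):
            tp = TraceParams(amplitude_cv=cv, timing_jitter_sd=jit,
                             noise_sd=noise, seed=seed)
            trace, _ = simulate_beat_trace(tp)
            vals.append(summarize_trace(detect_beats(trace)).heterogeneity_amplitude)
        het.append(np.mean(vals))
    assert het[0] > het[1] > het[2]
    # residual at zero variability only reflects first-beat baseline edge effects
    assert het[2] < 0.01


# --------------------------------------------------------------------------
# calcium


def test_diastolic_time_matches_exponential_analytic():
    fr, tau = 200.0, 0.15
    tp = TraceParams(frame_rate=fr, decay_time=tau, baseline=1.0,
                     modality="calcium_ratio", seed=2)
    trace, _ = simulate_beat_trace(tp)
    m = calcium_metrics(trace)
    assert abs(m.diastolic_time - tau * np.log(10)) <= 1.0 / fr
    assert m.diastolic_ratio == pytest.approx(1.0, abs=1e-3)


def test_calcium_offset_translation():
    tp = TraceParams(frame_rate=100.0, baseline=1.0, modality="calcium_ratio", seed=3)
    trace, _ = simulate_beat_trace(tp)
    m0 = calcium_metrics(trace)
    shifted = BeatTrace(samples=trace.samples + 0.7, frame_rate=trace.frame_rate,
                        pacing_rate=trace.pacing_rate, modality="calcium_ratio")
    m1 = calcium_metrics(shifted)
    assert m1.diastolic_time == pytest.approx(m0.diastolic_time, abs=1e-12)
    assert m1.diastolic_ratio - m0.diastolic_ratio == pytest.approx(0.7)


def test_baseline_only_trace_gives_empty_calcium_result():
    trace = BeatTrace(samples=np.full(500, 1.2), frame_rate=100.0,
                      modality="calcium_ratio")
    m = calcium_metrics(trace)
    assert m.n_transients == 0 and np.isnan(m.diastolic_time)


def test_calcium_metrics_requires_ratio_modality():
    trace = BeatTrace(samples=np.zeros(300), frame_rate=63.0)
    with pytest.raises(ValueError, match="calcium_ratio"):
        calcium_metrics(trace)


# --------------------------------------------------------------------------
# EC50 fits


def test_noiseless_hill_fit_recovers_ec50_exactly():
    c, f = simulate_calcium_response(0.9, 2.0, 1.0, noise_sd=0.0)
    fit = fit_calcium_response(c, f)
    assert fit.status == "ok"
    assert abs(fit.ec50 - 0.9) / 0.9 < 0.01
    assert fit.hill == pytest.approx(2.0, rel=0.01)


def test_noisy_ec50_recovery_median_error():
    errors = []
    for seed in range(50):
        c, f = simulate_calcium_response(0.9, 2.0, 1.0, noise_sd=0.05, seed=seed)
        fit = fit_calcium_response(c, f)
        if fit.status == "ok":
            errors.append(abs(fit.ec50 - 0.9) / 0.9)
    assert np.median(errors) < 0.10


def test_flat_response_fails_gracefully():
    fit = fit_calcium_response([0.3, 0.6, 1.2, 3.0], [1.0, 1.0, 1.0, 1.0])
    assert fit.status == "failed"


def test_fit_input_validation():
    with pytest.raises(ValueError, match="distinct"):
        fit_calcium_response([0.3, 0.3, 0.3, 0.3], [0, 1, 2, 3])
    with pytest.raises(ValueError, match="positive"):
        fit_calcium_response([-1, 0.5, 1.0, 2.0], [0, 1, 2, 3])
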