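"""Front-end: filter responses, block averaging, thresholds, detection, windows."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from tactile_reject.preprocess import (
    FilterConfig,
    DetectionEvent,
    ThresholdSet,
    apply_digital_filters,
    detect_onsets,
    downsample,
    estimate_thresholds,
    extract_feature,
    extract_trial_features,
    highpass_coefficients,
    notch_coefficients,
)
from tactile_reject.synthetic_data import SessionSpec, generate_session

FS = 1000.0


def _chain_gain(freq_hz: float) -> float:
    """Oracle: |H(f)| of high-pass + notch, from the designed coefficients."""
    cfg = FilterConfig()
    gain = 1.0
    for b, a in (highpass_coefficients(cfg, FS), notch_coefficients(cfg, FS)):
        _, h = sps.freqz(b, a, worN=[2 * np.pi * freq_hz / FS])
        gain *= abs(h[0])
    return gain


def _steady_state_amplitude(freq_hz: float, seconds: float = 10.0) -> float:
    t = np.arange(int(seconds * FS)) / FS
    out = apply_digital_filters(np.sin(2 * np.pi * freq_hz * t), FS)
    return np.abs(out[0, -int(2 * FS):]).max()


def test_highpass_removes_dc():
    """A constant input decays below 1% well within the settling time."""
    out = apply_digital_filters(np.ones(int(5 * FS)), FS)
    assert np.abs(out[0, int(2 * FS):]).max() < 0.01


def test_notch_attenuation_matches_transfer_function():
    """Steady-state 50 Hz output amplitude equals the designed |H(50 Hz)|."""
    oracle = _chain_gain(50.0)
    assert oracle < 0.01  # the notch zero sits on 50 Hz
    assert _steady_state_amplitude(50.0) == pytest.approx(oracle, abs=0.02)


def test_passband_5hz_within_5_percent():
    oracle = _chain_gain(5.0)
    assert oracle > 0.95
    assert _steady_state_amplitude(5.0) == pytest.approx(oracle, rel=0.02)


def test_filters_preserve_length_and_reject_nonfinite():
    x = np.random.default_rng(0).normal(size=(2, 1234))
    assert apply_digital_filters(x, FS).shape == x.shape
    x[0, 5] = np.nan
    with pytest.raises(ValueError):
        apply_digital_filters(x, FS)


def test_downsample_examples():
    assert np.allclose(downsample(np.full(100, 3.3)), 3.3)
    assert downsample(np.arange(1.0, 11.0)).item() == pytest.approx(5.5)
    assert downsample(np.zeros(1000)).shape[-1] == 100
    assert downsample(np.zeros((2, 1005))).shape == (2, 100)  # truncation
    with pytest.raises(ValueError):
        downsample(np.zeros(10), block=0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(1, 20), st.integers(0, 9), st.integers(0, 2**31 - 1))
def test_downsample_matches_loop_oracle(blocks, extra, seed):
    """Block means agree with an explicit per-block loop at machine precision."""
    block = 10
    x = np.random.default_rng(seed).normal(size=blocks * block + extra)
    got = downsample(x, block)[0]
    expected = [x[i * block:(i + 1) * block].mean() for i in range(blocks)]
    assert np.allclose(got, expected, rtol=0, atol=1e-12)


def test_threshold_formula_against_direct_evaluation():
    rng = np.random.default_rng(7)
    rest = rng.normal(0.0, 0.05, size=(2, 500))
    ts = estimate_thresholds(rest, k=5.0)
    for ch in range(2):
        a = np.abs(rest[ch])
        direct = a.mean() + 5.0 * a.std()
        assert ts.theta[ch] == pytest.approx(direct, rel=1e-12)
    # per-channel independence: each theta depends only on its own channel
    rest2 = rest.copy()
    rest2[1] *= 3.0
    ts2 = estimate_thresholds(rest2, k=5.0)
    assert ts2.theta[0] == ts.theta[0]
    assert ts2.theta[1] != ts.theta[1]


def test_threshold_degenerate_and_short_segment():
    ts = estimate_thresholds(np.zeros((2, 300)))
    assert np.all(ts.theta == 1e-6)  # positive floor on an all-zero channel
    with pytest.raises(ValueError):
        estimate_thresholds(np.zeros((2, 150)))  # < 2 s at 100 Hz


def _thresholds(theta):
    theta = np.asarray(theta, dtype=float)
    return ThresholdSet(theta=theta, rest_mean_abs=theta * 0, rest_sd_abs=theta * 0)


def test_detection_examples():
    # all-zero signal: no crossing
    assert detect_onsets(np.zeros((2, 200)), _thresholds([0.1, 0.1])) == []
    # channel 2 (index 1) steps to 2*theta at index 57; the series ends
    # before the refractory window does, so exactly one event fires
    x = np.zeros((2, 160))
    x[1, 57:] = 0.2
    events = detect_onsets(x, _thresholds([0.1, 0.1]))
    assert [(e.nd, e.triggering_channel) for e in events] == [(57, 1)]
    # both channels cross 5 samples apart; 1 s refractory keeps the first only
    x = np.zeros((2, 200))
    x[0, 40:50] = 0.3
    x[1, 45:55] = 0.3
    events = detect_onsets(x, _thresholds([0.1, 0.1]), refractory=1.0)
    assert [(e.nd, e.triggering_channel) for e in events] == [(40, 0)]


def test_detection_matches_linear_scan_oracle():
    """First-crossing + refractory agrees with a sample-by-sample scan."""
    rng = np.random.default_rng(17)
    x = rng.normal(0.0, 1.0, size=(2, 3000))
    theta = np.array([2.5, 2.7])
    refractory_samples = 30

    expected = []
    next_allowed = 0
    for n in range(x.shape[1]):
        if n < next_allowed:
            continue
        if np.any(np.abs(x[:, n]) > theta):
            if n >= 10 and n + 9 < x.shape[1]:
                expected.append(n)
            next_allowed = n + refractory_samples
    got = detect_onsets(x, _thresholds(theta), refractory=0.3, sampling_rate=100.0)
    assert [e.nd for e in got] == expected


def test_edge_events_discarded():
    x = np.zeros((2, 100))
    x[0, 5] = 1.0
    x[0, 95] = 1.0
    assert detect_onsets(x, _thresholds([0.1, 0.1]), refractory=0.1) == []


def test_feature_window_shape_and_layout():
    """Two channels of 20 samples concatenate to the 40-dimensional vector."""
    series = np.vstack([np.ones(100), -np.ones(100)])
    z = extract_feature(series, DetectionEvent(nd=50, triggering_channel=0))
    assert z.shape == (40,)
    assert np.array_equal(z, np.concatenate([np.ones(20), -np.ones(20)]))
    # window is [nd-10, nd+9] inclusive
    ramp = np.vstack([np.arange(100.0), np.zeros(100)])
    z = extract_feature(ramp, DetectionEvent(nd=50, triggering_channel=0))
    assert np.array_equal(z[:20], np.arange(40.0, 60.0))
    with pytest.raises(IndexError):
        extract_feature(series, DetectionEvent(nd=5, triggering_channel=0))


def test_detection_recall_on_synthetic_session():
    """>= 95% of 300 annotated trials give exactly one detection within 100 ms."""
    spec = SessionSpec(unknown_motions=(), nontarget_motions=(), seed=77)
    rec = generate_session(spec)
    cfg = FilterConfig()
    from tactile_reject.preprocess import apply_digital_filters, downsample

    series = downsample(apply_digital_filters(rec.signal, rec.sampling_rate, cfg))
    rest = series[:, : rec.rest_segment[1] // cfg.downsample_block]
    ts = estimate_thresholds(rest)
    events = detect_onsets(series, ts)
    times = np.array([e.nd / 100.0 for e in events])
    hits = [
        np.sum(np.abs(times - a.true_onset) <= 0.1) == 1
        for a in rec.annotations
    ]
    assert len(hits) == 300
    assert np.mean(hits) >= 0.95


def test_pipeline_determinism_and_shared_code_path(tiny_recording):
    feats_a = extract_trial_features(tiny_recording)
    feats_b = extract_trial_features(tiny_recording)
    assert len(feats_a) == len(feats_b)
    for a, b in zip(feats_a, feats_b):
        assert np.array_equal(a.z, b.z) and a.trial_id == b.trial_id

    # same detection rule for every category: relabeling categories must not
    # change any extracted vector (detection never branches on category)
    relabeled = dataclasses.replace(
        tiny_recording,
        annotations=[
            dataclasses.replace(a, category="target")
            for a in tiny_recording.annotations
        ],
    )
    feats_c = extract_trial_features(relabeled)
    assert [f.trial_id for f in feats_c] == [f.trial_id for f in feats_a]
    for a, c in zip(feats_a, feats_c):
        assert np.array_equal(a.z, c.z)
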