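"""Digital conditioning, event-driven detection, and feature construction.

The pipeline mirrors an online prosthetic controller: each channel is passed
causally through a first-order 0.5 Hz high-pass and a second-order 50 Hz
notch (Q = 25) at the native 1000 Hz rate, then downsampled to 100 Hz by
averaging blocks of 10 samples.  A per-channel detection threshold theta_i is
calibrated from the motion-free resting baseline; a motion is detected at
the first 100 Hz index n_d where |x_i[n]| > theta_i on any channel.  The
feature vector of a trial is the raw 200 ms window around the detection,
20 samples per channel, concatenated channel-wise (40 dimensions for the
two-sensor configuration).  The same detection rule and code path serve
target, unknown, and non-target trials alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic_data import Recording

log = logging.getLogger(__name__)

#: Samples before / after the detection index in the 100 Hz feature window.
PRE_SAMPLES = 10
POST_SAMPLES = 10  # window is [nd - 10, nd + 9] inclusive


@dataclass(frozen=True)
class FilterConfig:
    """Digital front-end: high-pass cutoff, notch centre/Q, downsample block."""

    highpass_cutoff: float = 0.5
    notch_center: float = 50.0
    notch_q: float = 25.0
    downsample_block: int = 10

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not 0 < self.highpass_cutoff < nyq:
            raise ValueError("highpass_cutoff must lie in (0, fs/2)")
        if not 0 < self.notch_center < nyq:
            raise ValueError("notch_center must lie in (0, fs/2)")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be > 0")
        if self.downsample_block < 1:
            raise ValueError("downsample_block must be >= 1")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel detection thresholds with their calibration statistics."""

    theta: np.ndarray  # (n_channels,), volts, all > 0
    rest_mean_abs: np.ndarray
    rest_sd_abs: np.ndarray


@dataclass(frozen=True)
class DetectionEvent:
    """One detected motion onset at the 100 Hz rate."""

    nd: int  # detection index (100 Hz)
    triggering_channel: int


@dataclass
class TrialFeature:
    """40-dimensional feature vector of one detected trial plus ground truth."""

    z: np.ndarray
    motion_id: str
    category: str
    ambiguous: bool
    session_id: str
    trial_id: int


def highpass_coefficients(cfg: FilterConfig, sampling_rate: float):
    return sps.butter(1, cfg.highpass_cutoff, btype="highpass", fs=sampling_rate)


def notch_coefficients(cfg: FilterConfig, sampling_rate: float):
    return sps.iirnotch(cfg.notch_center, cfg.notch_q, fs=sampling_rate)


def apply_digital_filters(
    signal: np.ndarray, sampling_rate: float, cfg: FilterConfig | None = None
) -> np.ndarray:
    """Causal high-pass then notch on every channel; length preserved."""
    cfg = cfg or FilterConfig()
    cfg.validate(sampling_rate)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if not np.isfinite(signal).all():
        raise ValueError("signal contains non-finite samples")
    b_hp, a_hp = highpass_coefficients(cfg, sampling_rate)
    b_n, a_n = notch_coefficients(cfg, sampling_rate)
    out = sps.lfilter(b_hp, a_hp, signal, axis=-1)
    out = sps.lfilter(b_n, a_n, out, axis=-1)
    return out


def downsample(signal: np.ndarray, block: int = 10) -> np.ndarray:
    """Block-average downsampling; trailing partial blocks are truncated."""
    if block < 1:
        raise ValueError("block must be >= 1")
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n = (signal.shape[-1] // block) * block
    return signal[..., :n].reshape(signal.shape[0], -1, block).mean(axis=-1)


#: Floor for degenerate (all-zero) resting channels, volts.
THRESHOLD_FLOOR = 1e-6


def estimate_thresholds(
    rest: np.ndarray, k: float = 5.0, sampling_rate: float = 100.0
) -> ThresholdSet:
    """theta_i = mean(|x_i|) + k * sd(|x_i|) over the resting segment.

    The resting segment must cover at least 2 s.  A channel that is
    identically zero gets the floor value ``THRESHOLD_FLOOR`` so theta_i > 0
    always holds.
    """
    rest = np.atleast_2d(np.asarray(rest, dtype=float))
    if rest.shape[-1] < 2 * sampling_rate:
        raise ValueError(
            f"resting segment too short: {rest.shape[-1]} samples "
            f"(need >= {int(2 * sampling_rate)})"
        )
    a = np.abs(rest)
    mean_abs = a.mean(axis=-1)
    sd_abs = a.std(axis=-1)
    theta = np.maximum(mean_abs + k * sd_abs, THRESHOLD_FLOOR)
    return ThresholdSet(theta=theta, rest_mean_abs=mean_abs, rest_sd_abs=sd_abs)


def detect_onsets(
    series: np.ndarray,
    thresholds: ThresholdSet,
    refractory: float = 1.0,
    sampling_rate: float = 100.0,
) -> list[DetectionEvent]:
    """First-crossing detection with a refractory window.

    An event fires at the earliest index where any channel's absolute value
    strictly exceeds its threshold; further crossings within ``refractory``
    seconds are suppressed.  Events too close to the series edges for a full
    feature window are discarded.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    theta = np.asarray(thresholds.theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("thresholds must be positive")
    exceed = np.abs(series) > theta[:, None]
    any_exceed = exceed.any(axis=0)
    crossing_idx = np.flatnonzero(any_exceed)
    refractory_samples = int(round(refractory * sampling_rate))
    n = series.shape[-1]

    events: list[DetectionEvent] = []
    next_allowed = 0
    for nd in crossing_idx:
        if nd < next_allowed:
            continue
        next_allowed = nd + refractory_samples
        if nd - PRE_SAMPLES < 0 or nd + POST_SAMPLES > n:
            continue
        ratios = np.where(exceed[:, nd], np.abs(series[:, nd]) / theta, -np.inf)
        events.append(DetectionEvent(nd=int(nd), triggering_channel=int(np.argmax(ratios))))
    return events


def extract_feature(series: np.ndarray, event: DetectionEvent) -> np.ndarray:
    """Concatenate each channel's 20-sample window around the detection.

    The window is [nd - 10, nd + 9] inclusive; channel 1 first, so the
    vector has dimension 20 * n_channels (40 for two sensors).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    lo, hi = event.nd - PRE_SAMPLES, event.nd + POST_SAMPLES
    if lo < 0 or hi > series.shape[-1]:
        raise IndexError(
            f"feature window [{lo}, {hi}) out of bounds for length {series.shape[-1]}"
        )
    return series[:, lo:hi].reshape(-1).copy()


def extract_trial_features(
    recording: Recording,
    cfg: FilterConfig | None = None,
    threshold_k: float = 5.0,
    refractory: float = 1.0,
) -> list[TrialFeature]:
    """Full front-end: filter, downsample, detect, window, label.

    Every detection is matched to the annotation whose cue window
    [cue, cue + cue_interval) contains it; the first detection in a window
    wins, extras and detections during rest are dropped, and annotated
    trials that produce no detection are logged and skipped.  One code path
    serves all motion categories.
    """
    cfg = cfg or FilterConfig()
    filtered = apply_digital_filters(recording.signal, recording.sampling_rate, cfg)
    series = downsample(filtered, cfg.downsample_block)
    fs_out = recording.sampling_rate / cfg.downsample_block

    r0, r1 = recording.rest_segment
    rest = series[:, r0 // cfg.downsample_block : r1 // cfg.downsample_block]
    thresholds = estimate_thresholds(rest, k=threshold_k, sampling_rate=fs_out)
    events = detect_onsets(series, thresholds, refractory=refractory, sampling_rate=fs_out)

    features: list[TrialFeature] = []
    matched: set[int] = set()
    anns = sorted(recording.annotations, key=lambda a: a.cue_time)
    for ev in events:
        t_ev = ev.nd / fs_out
        for ann in anns:
            if ann.cue_time <= t_ev < ann.cue_time + recording.cue_interval:
                if ann.trial_id in matched:
                    break
                matched.add(ann.trial_id)
                features.append(
                    TrialFeature(
                        z=extract_feature(series, ev),
                        motion_id=ann.motion_id,
                        category=ann.category,
                        ambiguous=ann.ambiguous,
                        session_id=recording.session_id,
                        trial_id=ann.trial_id,
                    )
                )
                break
    missed = len(anns) - len(matched)
    if missed:
        log.info(
            "session %s: %d/%d annotated trials produced no detection",
            recording.session_id, missed, len(anns),
        )
    return features
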