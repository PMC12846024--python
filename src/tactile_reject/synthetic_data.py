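"""Seeded simulator for two-channel piezoelectric forearm recordings.

Human PVDF tactile recordings of the wrist/hand-motion protocol are not
publicly deposited, so this module generates surrogate sessions with the
same structure: two channels (FCR and ECRL sensor sites) sampled at
1000 Hz, a motion-free resting baseline followed by cued trials every 2 s,
six trained target motions plus optional untrained (unknown) wrist
deviations and a non-target elbow flexion, 50 trials per motion.

Each motion is modelled as a biphasic damped sinusoid per channel with a
class-specific amplitude/polarity/latency signature, superimposed on
Gaussian sensor noise, slow baseline drift (< 0.3 Hz) and 50 Hz power-line
interference.  A configurable fraction of target trials is made ambiguous,
either by blending two target templates (convex mix) or by attenuating the
template, emulating hesitant or weak executions.

Everything is driven by a single integer seed, so recordings are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

N_CHANNELS = 2
CHANNEL_NAMES = ("FCR", "ECRL")

TARGET = "target"
UNKNOWN = "unknown"
NONTARGET = "nontarget"

#: The six wrist-hand motions the classifier is trained on.
TARGET_MOTIONS = (
    "Grasp",
    "Open",
    "Pronation",
    "Supination",
    "PalmarFlexion",
    "Dorsiflexion",
)
#: Untrained wrist deviations, used only at test time.
UNKNOWN_MOTIONS = ("RadialFlexion", "UlnarFlexion")
#: Unrelated upper-limb movement (non-target category).
NONTARGET_MOTIONS = ("ElbowFlexion",)

#: Session naming of the twelve-session study design: every session runs the
#: target protocol, seven additionally run the unknown-motion protocol and
#: four the non-target body-movement protocol.
SESSION_NAMES = ("A1", "A2", "B1", "B2", "C1", "C2", "D1", "E1", "F1", "G1", "H1", "I1")
UNKNOWN_SESSIONS = frozenset({"A2", "B2", "C2", "F1", "G1", "H1", "I1"})
NONTARGET_SESSIONS = frozenset({"F1", "G1", "H1", "I1"})


class InvalidSpecError(ValueError):
    """Raised when a SessionSpec violates its invariants."""


@dataclass(frozen=True)
class MotionTemplate:
    """Deterministic two-channel waveform signature of one motion.

    Per channel the waveform is ``A * exp(-damping * t) * sin(2*pi*f*t)``
    delayed by the channel's onset latency and truncated at ``duration``.
    Amplitudes are volts at the charge-amplifier output.
    """

    motion_id: str
    amplitude: tuple[float, float]
    polarity: tuple[int, int]
    onset_latency: tuple[float, float]
    damping: float = 5.0
    oscillation_frequency: float = 6.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidSpecError(f"{self.motion_id}: duration must be > 0")
        if any(a < 0 for a in self.amplitude) or max(self.amplitude) <= 0:
            raise InvalidSpecError(
                f"{self.motion_id}: amplitudes must be >= 0 with at least one > 0"
            )
        if any(p not in (-1, 1) for p in self.polarity):
            raise InvalidSpecError(f"{self.motion_id}: polarity entries must be +-1")

    def waveform(self, sampling_rate: float) -> np.ndarray:
        """Render the template at ``sampling_rate``; shape (2, n_samples)."""
        n = int(round(self.duration * sampling_rate))
        t = np.arange(n) / sampling_rate
        out = np.zeros((N_CHANNELS, n))
        for ch in range(N_CHANNELS):
            tl = t - self.onset_latency[ch]
            m = tl >= 0
            out[ch, m] = (
                self.polarity[ch]
                * self.amplitude[ch]
                * np.exp(-self.damping * tl[m])
                * np.sin(2 * np.pi * self.oscillation_frequency * tl[m])
            )
        return out


def _default_templates() -> dict[str, MotionTemplate]:
    # Flexion-dominant motions load the FCR channel, extension-dominant the
    # ECRL channel; pro/supination give opposite-polarity biphasic pairs;
    # unknown wrist deviations sit between the trained signatures; elbow
    # flexion is a slower, longer, both-channel deflection.
    t = MotionTemplate
    return {
        m.motion_id: m
        for m in (
            t("Grasp", (2.5, 0.6), (1, 1), (0.05, 0.08), 5.0, 6.0, 1.0),
            t("Open", (0.6, 2.5), (1, 1), (0.08, 0.05), 5.0, 6.0, 1.0),
            t("Pronation", (1.8, 1.6), (1, -1), (0.06, 0.06), 5.0, 5.0, 1.0),
            t("Supination", (1.6, 1.8), (-1, 1), (0.06, 0.06), 5.0, 5.0, 1.0),
            t("PalmarFlexion", (2.2, 1.0), (-1, -1), (0.05, 0.10), 5.0, 7.0, 1.0),
            t("Dorsiflexion", (1.0, 2.2), (-1, -1), (0.10, 0.05), 5.0, 7.0, 1.0),
            t("RadialFlexion", (1.7, 1.1), (1, -1), (0.07, 0.07), 5.0, 6.0, 1.0),
            t("UlnarFlexion", (1.1, 1.7), (-1, 1), (0.07, 0.07), 5.0, 6.0, 1.0),
            t("ElbowFlexion", (1.4, 1.4), (1, 1), (0.10, 0.10), 2.0, 2.0, 1.5),
        )
    }


DEFAULT_TEMPLATES: dict[str, MotionTemplate] = _default_templates()


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one simulated recording session.

    Defaults state the experimental protocol: cues every 2 s, 50 trials per
    motion, six target motions, two unknown wrist deviations, elbow flexion
    as the non-target movement, 1000 Hz sampling, and a >= 10 s resting
    baseline recorded before the first cue for threshold calibration.
    """

    trials_per_motion: int = 50
    target_motions: tuple[str, ...] = TARGET_MOTIONS
    unknown_motions: tuple[str, ...] = UNKNOWN_MOTIONS
    nontarget_motions: tuple[str, ...] = NONTARGET_MOTIONS
    cue_interval: float = 2.0
    sampling_rate: float = 1000.0
    noise_sd: float = 0.1
    drift_amplitude: float = 0.1
    powerline_amplitude: float = 0.05
    ambiguous_fraction: float = 0.15
    ambiguity_mode: str = "blend"
    rest_duration: float = 10.0
    seed: int = 0

    def motions(self) -> list[tuple[str, str]]:
        """(motion_id, category) pairs covered by this session."""
        out = [(m, TARGET) for m in self.target_motions]
        out += [(m, UNKNOWN) for m in self.unknown_motions]
        out += [(m, NONTARGET) for m in self.nontarget_motions]
        return out

    def validate(self, templates: dict[str, MotionTemplate]) -> None:
        if self.trials_per_motion < 1:
            raise InvalidSpecError("trials_per_motion must be >= 1")
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise InvalidSpecError("ambiguous_fraction must lie in [0, 1]")
        if self.ambiguity_mode not in ("blend", "attenuate"):
            raise InvalidSpecError(f"unknown ambiguity_mode {self.ambiguity_mode!r}")
        if not self.target_motions:
            raise InvalidSpecError("at least one target motion required")
        for motion, _ in self.motions():
            if motion not in templates:
                raise InvalidSpecError(f"no template for motion {motion!r}")
            if self.cue_interval < templates[motion].duration:
                raise InvalidSpecError(
                    f"cue_interval {self.cue_interval}s shorter than template "
                    f"duration of {motion} ({templates[motion].duration}s)"
                )


@dataclass(frozen=True)
class Annotation:
    """Ground truth for one cued trial."""

    trial_id: int
    cue_time: float
    true_onset: float
    motion_id: str
    category: str
    ambiguous: bool


@dataclass
class Recording:
    """A raw two-channel voltage recording with ground-truth annotations."""

    signal: np.ndarray  # (2, n_samples), volts
    sampling_rate: float
    annotations: list[Annotation]
    rest_segment: tuple[int, int]  # sample index range known motion-free
    session_id: str = "S1"
    cue_interval: float = 2.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES


# Voltage range of the acquisition chain; the charge-amplifier gain is set so
# recordings stay inside it, and the ADC clips anything beyond.
VOLTAGE_LIMIT = 5.0


def generate_session(
    spec: SessionSpec,
    templates: dict[str, MotionTemplate] | None = None,
    session_id: str = "S1",
) -> Recording:
    """Simulate one recording session.

    The session starts with ``rest_duration`` seconds of motion-free
    baseline, followed by ``trials_per_motion`` cued trials of every listed
    motion in seeded randomized interleaved order, one cue every
    ``cue_interval`` seconds.  ``ambiguous_fraction`` of the target trials
    are modified per ``ambiguity_mode`` ("blend": convex mix with a second
    target template, weight in [0.35, 0.65]; "attenuate": amplitude scaled
    by a factor in [0.2, 0.5]).  The ground-truth onset of a trial is its
    cue time plus the smaller of the template's two channel latencies.
    """
    templates = DEFAULT_TEMPLATES if templates is None else templates
    spec.validate(templates)
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate

    motion_list = spec.motions()
    per_trial = [mc for mc in motion_list for _ in range(spec.trials_per_motion)]
    order = [per_trial[i] for i in rng.permutation(len(per_trial))]
    n_trials = len(order)

    total = spec.rest_duration + n_trials * spec.cue_interval + 1.0
    n = int(round(total * fs))
    signal = np.zeros((N_CHANNELS, n))

    target_idx = [i for i, (_, cat) in enumerate(order) if cat == TARGET]
    n_amb = int(round(spec.ambiguous_fraction * len(target_idx)))
    ambiguous_set = set(
        rng.choice(target_idx, size=n_amb, replace=False)) if n_amb else set()

    annotations: list[Annotation] = []
    for i, (motion, category) in enumerate(order):
        cue = spec.rest_duration + i * spec.cue_interval
        tmpl = templates[motion]
        wave = tmpl.waveform(fs)
        ambiguous = i in ambiguous_set
        if ambiguous:
            if spec.ambiguity_mode == "blend":
                others = [m for m in spec.target_motions if m != motion]
                partner = templates[others[rng.integers(len(others))]]
                w = rng.uniform(0.35, 0.65)
                pw = partner.waveform(fs)
                m = min(wave.shape[1], pw.shape[1])
                wave = w * wave[:, :m] + (1.0 - w) * pw[:, :m]
            else:  # attenuate
                wave = wave * rng.uniform(0.2, 0.5)
        start = int(round(cue * fs))
        signal[:, start : start + wave.shape[1]] += wave
        annotations.append(
            Annotation(
                trial_id=i,
                cue_time=cue,
                true_onset=cue + min(tmpl.onset_latency),
                motion_id=motion,
                category=category,
                ambiguous=ambiguous,
            )
        )

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, signal.shape)
    t = np.arange(n) / fs
    if spec.drift_amplitude > 0:
        for ch in range(N_CHANNELS):
            f_d = rng.uniform(0.05, 0.3)
            phase = rng.uniform(0, 2 * np.pi)
            signal[ch] += spec.drift_amplitude * np.sin(2 * np.pi * f_d * t + phase)
    if spec.powerline_amplitude > 0:
        for ch in range(N_CHANNELS):
            phase = rng.uniform(0, 2 * np.pi)
            signal[ch] += spec.powerline_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)

    np.clip(signal, -VOLTAGE_LIMIT, VOLTAGE_LIMIT, out=signal)
    return Recording(
        signal=signal,
        sampling_rate=fs,
        annotations=annotations,
        rest_segment=(0, int(round(spec.rest_duration * fs))),
        session_id=session_id,
        cue_interval=spec.cue_interval,
    )


def default_study_overrides(
    session_names: tuple[str, ...] = SESSION_NAMES,
    unknown_sessions: frozenset[str] = UNKNOWN_SESSIONS,
    nontarget_sessions: frozenset[str] = NONTARGET_SESSIONS,
) -> dict[int, dict]:
    """Per-session overrides reproducing the twelve-session study design."""
    overrides: dict[int, dict] = {}
    for i, name in enumerate(session_names):
        ov: dict = {}
        if name not in unknown_sessions:
            ov["unknown_motions"] = ()
        if name not in nontarget_sessions:
            ov["nontarget_motions"] = ()
        overrides[i] = ov
    return overrides


def generate_study(
    n_sessions: int,
    base_spec: SessionSpec,
    per_session_overrides: dict[int, dict] | None = None,
    templates: dict[str, MotionTemplate] | None = None,
    session_names: tuple[str, ...] | None = None,
) -> list[Recording]:
    """Simulate ``n_sessions`` recordings with derived sub-seeds.

    Session i uses a seed deterministically derived from ``base_spec.seed``
    and any field overrides from ``per_session_overrides[i]`` (e.g. dropping
    the unknown/non-target protocols for sessions that did not run them).
    """
    if n_sessions < 1:
        raise InvalidSpecError("n_sessions must be >= 1")
    names = session_names or (
        SESSION_NAMES if n_sessions == len(SESSION_NAMES)
        else tuple(f"S{i + 1}" for i in range(n_sessions))
    )
    sub_seeds = session_seeds(base_spec.seed, n_sessions)
    recordings = []
    for i in range(n_sessions):
        overrides = dict((per_session_overrides or {}).get(i, {}))
        spec_i = dataclasses.replace(base_spec, seed=int(sub_seeds[i]), **overrides)
        recordings.append(generate_session(spec_i, templates, session_id=names[i]))
    return recordings


def session_seeds(base_seed: int, n_sessions: int) -> np.ndarray:
    """Derive per-session seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n_sessions, dtype=np.uint32) % (2**31)
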