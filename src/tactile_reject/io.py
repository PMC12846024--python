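"""Plain-text interchange formats, config hashing, and (de)serialisation.

All tabular outputs are comma-separated text with a ``# config_hash:``
header comment so every file is traceable to the exact settings that
produced it.  Raw signals additionally get a single-container ``.npz``
format for speed; the columnar text writer exists for diff-able fixtures.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import TrialFeature
from .synthetic_data import Annotation, Recording


class SchemaError(ValueError):
    """A file does not match the expected column layout."""


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, cfg_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- recordings ---------------------------------------------------------------

def write_recording_text(recording: Recording, signal_path, annotation_path,
                         cfg_hash: str = "") -> None:
    """Columnar text: (time_s, ch1_V, ch2_V) plus a sidecar annotation table."""
    t = np.arange(recording.signal.shape[1]) / recording.sampling_rate
    df = pd.DataFrame(
        {"time_s": t, "ch1_V": recording.signal[0], "ch2_V": recording.signal[1]}
    )
    write_table(df, signal_path, cfg_hash)
    write_annotations(recording, annotation_path, cfg_hash)


def write_annotations(recording: Recording, path, cfg_hash: str = "") -> None:
    df = pd.DataFrame(
        [
            {
                "trial_id": a.trial_id,
                "cue_s": a.cue_time,
                "onset_s": a.true_onset,
                "motion": a.motion_id,
                "category": a.category,
                "ambiguous": a.ambiguous,
            }
            for a in recording.annotations
        ]
    )
    write_table(df, path, cfg_hash)


def write_recording_npz(recording: Recording, path) -> None:
    """Single-container binary format for speed (runtime scratch, not fixtures)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann = recording.annotations
    np.savez_compressed(
        path,
        signal=recording.signal,
        sampling_rate=recording.sampling_rate,
        rest_segment=np.array(recording.rest_segment),
        session_id=np.array(recording.session_id),
        cue_interval=recording.cue_interval,
        ann_trial_id=np.array([a.trial_id for a in ann]),
        ann_cue=np.array([a.cue_time for a in ann]),
        ann_onset=np.array([a.true_onset for a in ann]),
        ann_motion=np.array([a.motion_id for a in ann]),
        ann_category=np.array([a.category for a in ann]),
        ann_ambiguous=np.array([a.ambiguous for a in ann]),
    )


def read_recording_npz(path) -> Recording:
    d = np.load(path, allow_pickle=False)
    annotations = [
        Annotation(
            trial_id=int(tid), cue_time=float(cue), true_onset=float(onset),
            motion_id=str(motion), category=str(cat), ambiguous=bool(amb),
        )
        for tid, cue, onset, motion, cat, amb in zip(
            d["ann_trial_id"], d["ann_cue"], d["ann_onset"],
            d["ann_motion"], d["ann_category"], d["ann_ambiguous"],
        )
    ]
    return Recording(
        signal=d["signal"],
        sampling_rate=float(d["sampling_rate"]),
        annotations=annotations,
        rest_segment=tuple(int(x) for x in d["rest_segment"]),
        session_id=str(d["session_id"]),
        cue_interval=float(d["cue_interval"]),
    )


def read_recording_text(signal_path, annotation_path,
                        rest_duration: float, cue_interval: float,
                        session_id: str = "S1") -> Recording:
    sig = read_table(signal_path)
    for col in ("time_s", "ch1_V", "ch2_V"):
        if col not in sig.columns:
            raise SchemaError(f"{signal_path}: missing column {col!r}")
    t = sig["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    ann_df = read_table(annotation_path)
    annotations = [
        Annotation(
            trial_id=int(r.trial_id), cue_time=float(r.cue_s),
            true_onset=float(r.onset_s), motion_id=str(r.motion),
            category=str(r.category), ambiguous=bool(r.ambiguous),
        )
        for r in ann_df.itertuples()
    ]
    return Recording(
        signal=np.vstack([sig["ch1_V"].to_numpy(), sig["ch2_V"].to_numpy()]),
        sampling_rate=float(round(fs)),
        annotations=annotations,
        rest_segment=(0, int(round(rest_duration * fs))),
        session_id=session_id,
        cue_interval=cue_interval,
    )


# -- feature tables -----------------------------------------------------------

_FEATURE_META = ["session_id", "trial_id", "motion", "category", "ambiguous"]


def write_features(features: list[TrialFeature], path, cfg_hash: str = "") -> None:
    """One row per trial: metadata plus z1..z40."""
    dim = len(features[0].z) if features else 40
    zcols = [f"z{i + 1}" for i in range(dim)]
    rows = []
    for f in features:
        row = {
            "session_id": f.session_id,
            "trial_id": f.trial_id,
            "motion": f.motion_id,
            "category": f.category,
            "ambiguous": f.ambiguous,
        }
        row.update(dict(zip(zcols, f.z.tolist())))
        rows.append(row)
    write_table(pd.DataFrame(rows, columns=_FEATURE_META + zcols), path, cfg_hash)


def read_features(path) -> list[TrialFeature]:
    df = read_table(path)
    missing = [c for c in _FEATURE_META if c not in df.columns]
    zcols = [c for c in df.columns if c.startswith("z") and c[1:].isdigit()]
    if missing or not zcols:
        raise SchemaError(
            f"{path}: not a feature table (missing {missing or 'z-columns'})"
        )
    expected = [f"z{i + 1}" for i in range(len(zcols))]
    if zcols != expected:
        raise SchemaError(f"{path}: feature columns must be z1..z{len(zcols)}")
    return [
        TrialFeature(
            z=np.array([r[c] for c in zcols], dtype=float),
            motion_id=str(r["motion"]),
            category=str(r["category"]),
            ambiguous=bool(r["ambiguous"]),
            session_id=str(r["session_id"]),
            trial_id=int(r["trial_id"]),
        )
        for _, r in df.iterrows()
    ]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(data: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
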