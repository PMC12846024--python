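"""Accept/REJECT decision rules layered on the classifier outputs.

Each mechanism is a pure function of classifier outputs, so it composes
with any backbone without retraining:

* ``baseline`` — argmax of the one-vs-rest decision values; never rejects.
* ``ocsvm`` — accept the baseline prediction iff the one-class score
  Delta(z) > 0; reject otherwise (Delta = 0 rejects, strict inequality).
* ``bpnn_entropy`` — reject iff the Shannon entropy of the softmax output
  exceeds the threshold tau (default 0.7, natural log).
* ``ovr_ro`` — the parameter-free sign-consistency rule: accept iff exactly
  one decision value is strictly positive, in which case that class wins;
  zero or multiple positive signs reject.  Its signature takes the decision
  values and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelBundle
from .preprocess import TrialFeature

#: Sentinel output for withheld decisions.
REJECT = "REJECT"

MECHANISMS = ("baseline", "ocsvm", "bpnn_entropy", "ovr_ro")


@dataclass(frozen=True)
class RejectConfig:
    """Entropy-rejection threshold; log_base None means natural log."""

    tau: float = 0.7
    log_base: float | None = None

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class Decision:
    """Per-trial outcome of one mechanism, with its numeric evidence."""

    trial_id: int
    mechanism: str
    output: str  # class label or REJECT
    evidence: dict


def shannon_entropy(p: np.ndarray, base: float | None = None) -> float:
    """H(p) = -sum_k p_k log p_k, with 0 log 0 = 0.

    ``p`` must be a probability vector (components >= 0, sum 1 within 1e-6).
    Natural log by default; pass ``base`` for another unit.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probability components must be >= 0")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum()})")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def decide_baseline(f: np.ndarray) -> int:
    """Index of the maximum decision value; ties go to the lowest index."""
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("non-finite decision values")
    return int(np.argmax(f))


def decide_ovr_ro(f: np.ndarray) -> int | str:
    """Sign-consistency rule: accept iff exactly one f_k is strictly > 0.

    Parameter-free by construction: the decision values are the only input.
    """
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("non-finite decision values")
    positive = f > 0
    if positive.sum() == 1:
        return int(np.argmax(positive))
    return REJECT


def count_positive(f: np.ndarray) -> int:
    return int((np.asarray(f, dtype=float) > 0).sum())


def decide_ocsvm(delta: float, predicted: int) -> int | str:
    """Gate the baseline prediction on the one-class score: accept iff Delta > 0."""
    if not np.isfinite(delta):
        raise ValueError("non-finite one-class score")
    return predicted if delta > 0 else REJECT


def decide_bpnn_entropy(p: np.ndarray, cfg: RejectConfig | None = None) -> int | str:
    """Reject iff H(p) > tau; otherwise the argmax class (ties to lowest index)."""
    cfg = cfg or RejectConfig()
    h = shannon_entropy(p, base=cfg.log_base)
    if h > cfg.tau:
        return REJECT
    return int(np.argmax(p))


_F_COLUMNS = [f"f{k}" for k in range(1, 7)]


def decide_trials(
    bundle: ModelBundle,
    features: list[TrialFeature],
    mechanisms: tuple[str, ...] = MECHANISMS,
    cfg: RejectConfig | None = None,
) -> pd.DataFrame:
    """Run every requested mechanism over a feature set.

    Returns one row per (trial, mechanism) with the output (class label or
    REJECT), the underlying classifier's no-reject prediction
    (``pred_noreject``: the baseline SVM's for SVM-based mechanisms, the
    network's own for entropy rejection), and the numeric evidence (decision
    values, entropy, one-class score, positive-sign count).
    """
    cfg = cfg or RejectConfig()
    unknown = set(mechanisms) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanisms: {sorted(unknown)}")
    Z = np.stack([f.z for f in features])
    classes = bundle.classes
    fvals = bundle.ovr.decision_values(Z)
    deltas = bundle.ocsvm.score(Z) if "ocsvm" in mechanisms else None
    probs = bundle.bpnn.probs(Z) if "bpnn_entropy" in mechanisms else None

    rows = []
    for i, feat in enumerate(features):
        f = fvals[i]
        svm_pred = decide_baseline(f)
        base = {
            "session_id": feat.session_id,
            "trial_id": feat.trial_id,
            "true_motion": feat.motion_id,
            "category": feat.category,
            "ambiguous_gen": feat.ambiguous,
        }
        fcols = dict(zip(_F_COLUMNS, f.tolist()))
        for mech in mechanisms:
            row = dict(base)
            row["mechanism"] = mech
            row.update(fcols)
            row["n_positive"] = count_positive(f)
            row["entropy"] = np.nan
            row["delta"] = np.nan
            if mech == "baseline":
                out = svm_pred
                row["pred_noreject"] = classes[svm_pred]
            elif mech == "ovr_ro":
                out = decide_ovr_ro(f)
                row["pred_noreject"] = classes[svm_pred]
            elif mech == "ocsvm":
                row["delta"] = float(deltas[i])
                out = decide_ocsvm(deltas[i], svm_pred)
                row["pred_noreject"] = classes[svm_pred]
            else:  # bpnn_entropy
                p = probs[i]
                row["entropy"] = shannon_entropy(p, base=cfg.log_base)
                out = decide_bpnn_entropy(p, cfg)
                row["pred_noreject"] = classes[int(np.argmax(p))]
            row["output"] = REJECT if out == REJECT else classes[out]
            rows.append(row)
    cols = (
        ["session_id", "trial_id", "mechanism", "output", "pred_noreject",
         "true_motion", "category", "ambiguous_gen", "entropy", "delta",
         "n_positive"] + _F_COLUMNS
    )
    return pd.DataFrame(rows, columns=cols)
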