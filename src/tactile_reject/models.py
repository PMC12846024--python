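"""Classifier backbones with fixed, study-wide hyperparameters.

Three models share one stratified training partition of the target trials:

* an RBF one-vs-rest SVM (C = 16, gamma = 0.0625) built from six explicit
  binary class-vs-rest machines so genuine per-class decision values
  f_k(z) are available,
* a one-class SVM (nu = 0.1, gamma = 1 / (d * Var(z)) with d = 40) trained
  on the pooled target features as a novelty envelope, and
* a small fully connected network (40-25-6, tanh hidden layer, softmax
  output) trained full-batch with Adam for 1000 epochs.

Hyperparameters are global constants: one configuration serves every
session and class with no per-session or per-class tuning.  Unknown and
non-target trials are never eligible for training; they are routed to the
test partition unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC, OneClassSVM

from .preprocess import TrialFeature
from .synthetic_data import TARGET


@dataclass(frozen=True)
class SvmConfig:
    C: float = 16.0
    gamma: float = 0.0625

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")


@dataclass(frozen=True)
class OcsvmConfig:
    nu: float = 0.1

    def __post_init__(self):
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")


@dataclass(frozen=True)
class BpnnConfig:
    n_hidden: int = 25
    epochs: int = 1000
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    init: str = "uniform01"  # literal U[0, 1) init; "symmetric" for +-scaled
    seed: int = 0

    def __post_init__(self):
        if self.n_hidden < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid BPNN configuration")
        if self.init not in ("uniform01", "symmetric"):
            raise ValueError(f"unknown init {self.init!r}")


def split_trials(
    features: list[TrialFeature], fraction: float = 0.5, seed: int = 0
) -> tuple[list[TrialFeature], list[TrialFeature]]:
    """Stratified train/test split; only target trials may enter training.

    Target trials are split per motion class at ``fraction`` (train share);
    unknown and non-target trials go to the test side unconditionally.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[TrialFeature]] = {}
    test: list[TrialFeature] = []
    for f in features:
        if f.category == TARGET:
            by_class.setdefault(f.motion_id, []).append(f)
        else:
            test.append(f)
    train: list[TrialFeature] = []
    for motion in sorted(by_class):
        group = by_class[motion]
        if len(group) < 2:
            raise ValueError(f"class {motion!r} has fewer than 2 trials")
        idx = rng.permutation(len(group))
        n_train = int(round(fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        train.extend(group[i] for i in idx[:n_train])
        test.extend(group[i] for i in idx[n_train:])
    return train, test


def stack_features(features: list[TrialFeature]) -> tuple[np.ndarray, np.ndarray]:
    """(n, d) design matrix and label array from a feature list."""
    Z = np.stack([f.z for f in features])
    y = np.array([f.motion_id for f in features])
    return Z, y


class OvrSvm:
    """One-vs-rest RBF SVM exposing the six raw decision values f_k(z).

    Classes are ordered alphabetically (``classes_``); ``predict`` returns
    the class of the maximum decision value, ties resolved toward the
    lowest class index.
    """

    def __init__(self, cfg: SvmConfig | None = None):
        self.cfg = cfg or SvmConfig()
        self.classes_: list[str] = []
        self._machines: list[SVC] = []

    def fit(self, Z: np.ndarray, y: np.ndarray) -> "OvrSvm":
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y)
        self.classes_ = sorted(set(y.tolist()))
        if len(self.classes_) < 2:
            raise ValueError("OvR SVM needs at least 2 classes")
        self._machines = []
        for c in self.classes_:
            m = SVC(kernel="rbf", C=self.cfg.C, gamma=self.cfg.gamma)
            m.fit(Z, (y == c).astype(int))
            self._machines.append(m)
        return self

    def decision_values(self, Z: np.ndarray) -> np.ndarray:
        """(n, k) matrix of per-class decision values; f_k > 0 supports class k."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return np.column_stack([m.decision_function(Z) for m in self._machines])

    def predict(self, Z: np.ndarray) -> np.ndarray:
        f = self.decision_values(Z)
        return np.array([self.classes_[i] for i in np.argmax(f, axis=1)])


def train_ovr_svm(train: list[TrialFeature], cfg: SvmConfig | None = None) -> OvrSvm:
    Z, y = stack_features(train)
    return OvrSvm(cfg).fit(Z, y)


class Ocsvm:
    """One-class novelty envelope over the pooled target training features."""

    def __init__(self, cfg: OcsvmConfig | None = None):
        self.cfg = cfg or OcsvmConfig()
        self.gamma_: float | None = None
        self._model: OneClassSVM | None = None

    def fit(self, Z: np.ndarray) -> "Ocsvm":
        Z = np.asarray(Z, dtype=float)
        if Z.size == 0:
            raise ValueError("empty training set")
        # scale heuristic gamma = 1 / (d * Var(z)), variance of the flattened
        # training matrix, d = feature dimension
        self.gamma_ = 1.0 / (Z.shape[1] * Z.var())
        self._model = OneClassSVM(kernel="rbf", nu=self.cfg.nu, gamma=self.gamma_)
        self._model.fit(Z)
        return self

    def score(self, Z: np.ndarray) -> np.ndarray:
        """Signed score Delta(z); positive inside the learned region."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self._model.decision_function(Z)


def train_ocsvm(train: list[TrialFeature], cfg: OcsvmConfig | None = None) -> Ocsvm:
    Z, _ = stack_features(train)
    return Ocsvm(cfg).fit(Z)


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class Bpnn:
    """40-25-6 multilayer perceptron with softmax output.

    Trained full-batch with Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-8,
    alpha = 1e-3) for a fixed number of epochs on the multiclass
    cross-entropy loss; no early stopping.  Weights (and biases) are
    initialised from U[0, 1) by default, exactly as specified for the
    reference configuration; a conventional symmetric initialisation is
    available via ``BpnnConfig.init = "symmetric"``.
    """

    def __init__(self, cfg: BpnnConfig | None = None):
        self.cfg = cfg or BpnnConfig()
        self.classes_: list[str] = []
        self.params_: dict[str, np.ndarray] = {}
        self.loss_history_: list[float] = []

    def _init_params(self, d: int, h: int, k: int, rng: np.random.Generator):
        if self.cfg.init == "uniform01":
            p = {
                "W1": rng.uniform(0.0, 1.0, (d, h)),
                "b1": rng.uniform(0.0, 1.0, h),
                "W2": rng.uniform(0.0, 1.0, (h, k)),
                "b2": rng.uniform(0.0, 1.0, k),
            }
        else:
            s1, s2 = 1.0 / np.sqrt(d), 1.0 / np.sqrt(h)
            p = {
                "W1": rng.uniform(-s1, s1, (d, h)),
                "b1": np.zeros(h),
                "W2": rng.uniform(-s2, s2, (h, k)),
                "b2": np.zeros(k),
            }
        return p

    def fit(self, Z: np.ndarray, y: np.ndarray) -> "Bpnn":
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y)
        self.classes_ = sorted(set(y.tolist()))
        k = len(self.classes_)
        n, d = Z.shape
        labels = np.array([self.classes_.index(c) for c in y])
        Y = np.eye(k)[labels]

        rng = np.random.default_rng(self.cfg.seed)
        p = self._init_params(d, self.cfg.n_hidden, k, rng)
        m = {key: np.zeros_like(v) for key, v in p.items()}
        v = {key: np.zeros_like(val) for key, val in p.items()}
        b1, b2, eps, lr = self.cfg.beta1, self.cfg.beta2, self.cfg.eps, self.cfg.learning_rate

        self.loss_history_ = []
        for t in range(1, self.cfg.epochs + 1):
            H = np.tanh(Z @ p["W1"] + p["b1"])
            P = _softmax(H @ p["W2"] + p["b2"])
            loss = -np.mean(np.log(np.clip(P[np.arange(n), labels], 1e-300, None)))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {t}")
            self.loss_history_.append(float(loss))

            dlogits = (P - Y) / n
            grads = {
                "W2": H.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            dH = dlogits @ p["W2"].T
            dpre = (1.0 - H**2) * dH
            grads["W1"] = Z.T @ dpre
            grads["b1"] = dpre.sum(axis=0)

            for key in p:
                g = grads[key]
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g**2
                m_hat = m[key] / (1 - b1**t)
                v_hat = v[key] / (1 - b2**t)
                p[key] = p[key] - lr * m_hat / (np.sqrt(v_hat) + eps)

        self.params_ = p
        return self

    def probs(self, Z: np.ndarray) -> np.ndarray:
        """(n, k) class-probability matrix p_k(z); rows sum to 1."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        p = self.params_
        H = np.tanh(Z @ p["W1"] + p["b1"])
        return _softmax(H @ p["W2"] + p["b2"])

    def predict(self, Z: np.ndarray) -> np.ndarray:
        pr = self.probs(Z)
        return np.array([self.classes_[i] for i in np.argmax(pr, axis=1)])


def train_bpnn(train: list[TrialFeature], cfg: BpnnConfig | None = None) -> Bpnn:
    Z, y = stack_features(train)
    return Bpnn(cfg).fit(Z, y)


@dataclass
class ModelBundle:
    """The three trained backbones plus their shared training partition."""

    ovr: OvrSvm
    ocsvm: Ocsvm
    bpnn: Bpnn
    classes: list[str]
    train_ids: list[int]
    test_ids: list[int]

    def save(self, path) -> None:
        import joblib
        from pathlib import Path

        Path(path).parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        import joblib

        return joblib.load(path)


def train_bundle(
    train: list[TrialFeature],
    test: list[TrialFeature],
    svm_cfg: SvmConfig | None = None,
    ocsvm_cfg: OcsvmConfig | None = None,
    bpnn_cfg: BpnnConfig | None = None,
) -> ModelBundle:
    """Train all three backbones on one identical training partition."""
    ovr = train_ovr_svm(train, svm_cfg)
    ocsvm = train_ocsvm(train, ocsvm_cfg)
    bpnn = train_bpnn(train, bpnn_cfg)
    return ModelBundle(
        ovr=ovr,
        ocsvm=ocsvm,
        bpnn=bpnn,
        classes=ovr.classes_,
        train_ids=[f.trial_id for f in train],
        test_ids=[f.trial_id for f in test],
    )
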