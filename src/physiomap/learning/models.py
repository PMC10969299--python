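"""The five IDH-status classifiers and their common training interface.

Classical models (one-hidden-layer MLP with width = n_features + n_classes,
adaptive boosting over entropy-split pruned decision trees, random forest)
are scikit-learn estimators; the 1D-CNN and the LSTM are the package's own
numpy implementations (no deep-learning framework dependency).  Every model
trains on a SMOTE-balanced matrix and predicts the probability of the
IDH-mutant class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .nn import (Adam, Conv1D, Dense, Dropout, Flatten, LSTMLayer, MaxPool1D,
                 Sequential, sigmoid)

__all__ = ["POSITIVE_CLASS", "ModelSpec", "TrainedModel", "train_classical",
           "train_cnn1d", "train_lstm", "predict", "make_classical_estimator"]

POSITIVE_CLASS = "IDHmut"
CLASSICAL_KINDS = ("MLP", "ABoost", "RF")
DEEP_KINDS = ("CNN1D", "LSTM")


@dataclass
class ModelSpec:
    """Classifier kind, hyperparameters and seed."""

    kind: str
    seed: int = 0
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSICAL_KINDS + DEEP_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus its input feature manifest and history."""

    spec: ModelSpec
    backend: object
    feature_names: tuple | None
    history: dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        """Probability of the IDH-mutant class for each row."""
        X = np.asarray(X, dtype=float)
        if self.spec.kind in CLASSICAL_KINDS:
            proba = self.backend.predict_proba(X)
            col = list(self.backend.classes_).index(POSITIVE_CLASS)
            return proba[:, col]
        mu, sd = self.history["scaler"]
        Xs = (X - mu) / sd
        return self.backend.predict(Xs)


def make_classical_estimator(kind: str, n_features: int, seed: int, hyper: dict):
    """Instantiate one of the three traditional learners."""
    if kind == "MLP":
        width = hyper.get("hidden_width", n_features + 2)
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(width,), solver="sgd",
                          learning_rate_init=hyper.get("learning_rate", 0.3),
                          momentum=hyper.get("momentum", 0.2),
                          max_iter=hyper.get("max_iter", 500),
                          random_state=seed))
    if kind == "ABoost":
        tree = DecisionTreeClassifier(criterion="entropy",
                                      min_samples_leaf=hyper.get("min_samples_leaf", 2),
                                      random_state=seed)
        return AdaBoostClassifier(estimator=tree,
                                  n_estimators=hyper.get("n_estimators", 10),
                                  random_state=seed)
    if kind == "RF":
        return RandomForestClassifier(n_estimators=hyper.get("n_estimators", 100),
                                      random_state=seed)
    raise ValueError(f"not a classical kind: {kind!r}")


def train_classical(X, y, spec: ModelSpec, feature_names=None,
                    cv_folds: int = 10) -> TrainedModel:
    """Fit MLP / ABoost / RF and report the k-fold cross-validated accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    est = make_classical_estimator(spec.kind, X.shape[1], spec.seed, spec.hyper)
    cv = StratifiedKFold(n_splits=min(cv_folds, np.bincount(
        np.unique(y, return_inverse=True)[1]).min()), shuffle=True, random_state=spec.seed)
    cv_acc = float(cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean())
    est.fit(X, y)
    return TrainedModel(spec, est, tuple(feature_names) if feature_names is not None else None,
                        history={"cv_accuracy": cv_acc})


# ---------------------------------------------------------------------------
# deep models

class _Cnn1dNet:
    """conv-pool-conv-pool-conv-pool-flatten-dense-dense with 3 dropout sites."""

    def __init__(self, n_features: int, hyper: dict, rng):
        f1, f2, f3 = hyper.get("filters", (32, 64, 64))
        k1, k2, k3 = hyper.get("kernels", (7, 5, 3))
        pool = hyper.get("pool", 2)
        dense1 = hyper.get("dense_width", 64)
        drop = hyper.get("dropout", 0.2)
        L = n_features
        layers = [Conv1D(1, f1, k1, rng), MaxPool1D(pool),
                  Conv1D(f1, f2, k2, rng), Dropout(drop, rng), MaxPool1D(pool),
                  Conv1D(f2, f3, k3, rng), Dropout(drop, rng), MaxPool1D(pool)]
        Lo = L
        for k in (k1, k2, k3):
            Lo = (Lo - k + 1) // pool
        layers += [Flatten(), Dense(Lo * f3, dense1, "relu", rng),
                   Dropout(drop, rng), Dense(dense1, 1, None, rng)]
        self.net = Sequential(layers)

    @property
    def architecture(self):
        names = {Conv1D: "conv", MaxPool1D: "pool", Flatten: "flatten", Dense: "dense"}
        seq = [names[type(l)] for l in self.net.layers if not isinstance(l, Dropout)]
        n_drop = sum(isinstance(l, Dropout) for l in self.net.layers)
        return seq, n_drop

    def forward(self, X, train):
        return sigmoid(self.net.forward(X[:, :, None], train)[:, 0])

    def backward(self, dlogit):
        self.net.backward(dlogit[:, None])

    @property
    def params(self):
        return self.net.params

    @property
    def grads(self):
        return self.net.grads

    def predict(self, X):
        return self.forward(np.asarray(X, dtype=float), train=False)


class _LstmNet:
    """One LSTM layer per biomarker map (107-step sequences) plus two dense layers."""

    def __init__(self, n_features: int, hyper: dict, rng):
        if n_features % 107 != 0:
            raise ValueError("LSTM input length must be a multiple of 107")
        self.n_maps = n_features // 107
        hidden = hyper.get("hidden_width", 64)
        dense1 = hyper.get("dense_width", 32)
        drop = hyper.get("dropout", 0.2)
        self.branches = [LSTMLayer(1, hidden, rng, dropout=drop, recurrent_dropout=drop)
                         for _ in range(self.n_maps)]
        self.head = Sequential([Dense(self.n_maps * hidden, dense1, "sigmoid", rng),
                                Dropout(drop, rng), Dense(dense1, 1, None, rng)])
        self.hidden = hidden

    @property
    def architecture(self):
        return ["lstm"] * self.n_maps + ["dense", "dense"], self.n_maps

    def forward(self, X, train):
        n = X.shape[0]
        seqs = X.reshape(n, self.n_maps, 107, 1)
        hs = [br.forward(seqs[:, m], train) for m, br in enumerate(self.branches)]
        return sigmoid(self.head.forward(np.concatenate(hs, axis=1), train)[:, 0])

    def backward(self, dlogit):
        dh = self.head.backward(dlogit[:, None])
        for m, br in enumerate(self.branches):
            br.backward(dh[:, m * self.hidden:(m + 1) * self.hidden])

    @property
    def params(self):
        return [p for br in self.branches for p in br.params] + self.head.params

    @property
    def grads(self):
        return [g for br in self.branches for g in br.grads] + self.head.grads

    def predict(self, X):
        return self.forward(np.asarray(X, dtype=float), train=False)


def _stratified_split(y_bin, val_fraction, rng):
    train_idx, val_idx = [], []
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y_bin == cls)
        idx = idx[rng.permutation(idx.size)]
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(train_idx), np.array(val_idx)


def _train_deep(net, X, y, spec: ModelSpec, feature_names) -> TrainedModel:
    hyper = spec.hyper
    epochs = hyper.get("epochs", 300)
    batch = hyper.get("batch_size", 28)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))

    X = np.asarray(X, dtype=float)
    y_bin = (np.asarray(y) == POSITIVE_CLASS).astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    tr, va = _stratified_split(y_bin, hyper.get("val_fraction", 0.2), rng)
    opt = Adam(net.params, lr=hyper.get("learning_rate", 0.001),
               beta1=hyper.get("beta1", 0.9), beta2=hyper.get("beta2", 0.999),
               eps=hyper.get("epsilon", 1e-8))

    best_acc, best_params, best_epoch = -1.0, [p.copy() for p in net.params], 0
    losses, val_accs = [], []
    for epoch in range(epochs):
        order = rng.permutation(tr.size)  # reshuffle every epoch
        ep_loss = 0.0
        for s in range(0, tr.size, batch):
            bidx = tr[order[s:s + batch]]
            p = net.forward(Xs[bidx], train=True)
            yb = y_bin[bidx]
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            ep_loss += float(-np.sum(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
            net.backward((p - yb) / len(yb))
            opt.step(net.grads)
        losses.append(ep_loss / tr.size)
        val_p = net.forward(Xs[va], train=False)
        acc = float(((val_p >= 0.5) == (y_bin[va] == 1)).mean())
        val_accs.append(acc)
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_params = [p.copy() for p in net.params]
    for p, bp in zip(net.params, best_params):
        p[...] = bp

    seq, n_drop = net.architecture
    history = {"loss": losses, "val_accuracy": val_accs, "best_epoch": best_epoch,
               "best_val_accuracy": best_acc, "scaler": (mu, sd),
               "architecture": seq, "dropout_sites": n_drop}
    return TrainedModel(spec, net, tuple(feature_names) if feature_names is not None else None,
                        history=history)


def train_cnn1d(X, y, spec: ModelSpec, feature_names=None) -> TrainedModel:
    """Train the 1-D CNN on a 428- or 856-long radiomic feature vector."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] not in (428, 856):
        raise ValueError(f"CNN1D expects a 428- or 856-feature vector, got {X.shape[1]}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 29]))
    net = _Cnn1dNet(X.shape[1], spec.hyper, rng)
    return _train_deep(net, X, y, spec, feature_names)


def train_lstm(X, y, spec: ModelSpec, feature_names=None) -> TrainedModel:
    """Train the LSTM: one 107-step sequence per biomarker map (4 or 8 maps)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] % 107 != 0:
        raise ValueError(f"LSTM input length must divide into 107-step sequences, "
                         f"got {X.shape[1]}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 31]))
    net = _LstmNet(X.shape[1], spec.hyper, rng)
    return _train_deep(net, X, y, spec, feature_names)


def predict(model: TrainedModel, X, feature_names=None) -> np.ndarray:
    """Probability of the IDH-mutant class; validates the feature manifest."""
    X = np.asarray(X, dtype=float)
    if feature_names is not None and model.feature_names is not None:
        if tuple(feature_names) != model.feature_names:
            got, want = set(feature_names), set(model.feature_names)
            extra = sorted(got - want)[:3]
            missing = sorted(want - got)[:3]
            raise ValueError(f"feature manifest mismatch; unexpected={extra}, missing={missing}"
                             if extra or missing else "feature manifest order differs")
    if model.feature_names is not None and X.shape[1] != len(model.feature_names):
        raise ValueError(f"expected {len(model.feature_names)} features, got {X.shape[1]}")
    return model.predict_proba(X)
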