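"""Single-hidden-layer softmax classifiers and the mode-specific bank.

Each classifier is a small feed-forward network: one hidden layer of 20
rectified-linear units and a softmax output, trained with Adam (step size
0.001, minibatch 32) for at most 100 epochs with early stopping on a 10%
random validation split (stop after 3 epochs without improvement, restore
the best epoch's weights).  Features are z-scored with statistics fitted on
the training pool at every (re)training.

The forward predictor is mode-specific: one classifier per current mode,
each over only the successor activities observed from that mode in the
initial training data.  A mode with a single observed successor gets a
constant predictor (posterior 1 on that successor, entropy 0).  The backward
predictor is a single classifier over all activity classes, fed by
mechanical stride features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .activities import Activity
from .dataset import EventSample
from .errors import TrainingError, ValidationError


@dataclass(frozen=True)
class NetConfig:
    """Training regimen of the softmax network."""

    hidden: int = 20
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 3
    validation_fraction: float = 0.10
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden < 1:
            raise ValidationError("hidden nodes must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValidationError("validation fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.max_epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValidationError("invalid training hyperparameter")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class Classifier:
    """A trained softmax network with its class list and z-score parameters."""

    classes: list[Activity]
    mu: np.ndarray
    sigma: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    config: NetConfig
    n_epochs: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = np.maximum((x - self.mu) / self.sigma @ self.w1 + self.b1, 0.0)
        return _softmax(h @ self.w2 + self.b2)

    def predict_posterior(self, x: np.ndarray) -> np.ndarray:
        """Posterior probabilities over ``self.classes`` (sum to 1)."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.n_features:
            raise ValidationError(
                f"feature dimension {x.shape[1]} != training dimension {self.n_features}"
            )
        p = self._forward(x)
        return p[0] if squeeze else p

    def predict(self, x: np.ndarray) -> Activity | list[Activity]:
        p = self.predict_posterior(x)
        if p.ndim == 1:
            return self.classes[int(np.argmax(p))]
        return [self.classes[i] for i in np.argmax(p, axis=1)]


@dataclass
class ConstantClassifier:
    """Degenerate predictor for a mode with a single observed successor."""

    classes: list[Activity]

    def __post_init__(self) -> None:
        if len(self.classes) != 1:
            raise ValidationError("ConstantClassifier takes exactly one class")

    @property
    def n_classes(self) -> int:
        return 1

    def predict_posterior(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return np.ones(1)
        return np.ones((x.shape[0], 1))

    def predict(self, x: np.ndarray) -> Activity | list[Activity]:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return self.classes[0]
        return [self.classes[0]] * x.shape[0]


AnyClassifier = Classifier | ConstantClassifier


def train(
    features: np.ndarray,
    labels: Sequence[Activity],
    config: NetConfig = NetConfig(),
) -> Classifier:
    """Train one softmax network; deterministic given ``config.seed``."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValidationError("features must be 2-D (samples x features)")
    labels = list(labels)
    if len(labels) != x.shape[0]:
        raise ValidationError("features and labels disagree in length")
    if x.shape[0] < 10:
        raise TrainingError("need at least 10 samples to train")
    classes = sorted(set(labels), key=lambda a: a.value)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class; nothing to learn")
    return _fit(x, labels, classes, config)


def _fit(
    x: np.ndarray,
    labels: Sequence[Activity],
    classes: list[Activity],
    config: NetConfig,
) -> Classifier:
    rng = np.random.default_rng(config.seed)
    idx = {c: i for i, c in enumerate(classes)}
    y = np.array([idx[l] for l in labels])
    n, d = x.shape
    k, h = len(classes), config.hidden

    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    xs = (x - mu) / sigma

    # stratified random validation split: every class contributes, so the
    # early-stopping criterion never judges epochs on a single-class split
    val_parts, tr_parts = [], []
    for c in range(k):
        c_idx = rng.permutation(np.where(y == c)[0])
        n_c_val = max(1, int(round(config.validation_fraction * len(c_idx)))) if len(c_idx) >= 2 else 0
        val_parts.append(c_idx[:n_c_val])
        tr_parts.append(c_idx[n_c_val:])
    val_idx = np.concatenate(val_parts)
    tr_idx = np.concatenate(tr_parts)
    if len(tr_idx) == 0:  # tiny pools: fall back to training = validation
        tr_idx = val_idx
    xv, yv = xs[val_idx], y[val_idx]
    xt, yt = xs[tr_idx], y[tr_idx]

    # seeded small-variance (He-style) initialization
    w1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h, k))
    b2 = np.zeros(k)
    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    step = 0

    # an epoch counts as improving if validation error OR validation loss
    # reaches a new best; on small validation splits the error rate is
    # quantized and fluctuates, so loss progress must also hold off the
    # patience counter.  Restored weights are the (error, loss)-best epoch.
    best_key = (np.inf, np.inf)
    best_err = np.inf
    best_loss = np.inf
    best = [p.copy() for p in params]
    best_epoch = 0
    since_best = 0
    n_tr = len(xt)
    onehot = np.eye(k)

    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n_tr)
        for s in range(0, n_tr, config.batch_size):
            b_idx = order[s : s + config.batch_size]
            xb, yb = xt[b_idx], yt[b_idx]
            z1 = xb @ params[0] + params[1]
            a1 = np.maximum(z1, 0.0)
            p = _softmax(a1 @ params[2] + params[3])
            g2 = (p - onehot[yb]) / len(b_idx)
            grads = [None] * 4
            grads[2] = a1.T @ g2
            grads[3] = g2.sum(axis=0)
            g1 = (g2 @ params[2].T) * (z1 > 0)
            grads[0] = xb.T @ g1
            grads[1] = g1.sum(axis=0)
            step += 1
            for i in range(4):
                m[i] = beta1 * m[i] + (1 - beta1) * grads[i]
                v[i] = beta2 * v[i] + (1 - beta2) * grads[i] ** 2
                mhat = m[i] / (1 - beta1**step)
                vhat = v[i] / (1 - beta2**step)
                params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
        a1 = np.maximum(xv @ params[0] + params[1], 0.0)
        pv = _softmax(a1 @ params[2] + params[3])
        val_err = float(np.mean(np.argmax(pv, axis=1) != yv))
        val_loss = float(-np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12)))
        improved = val_err < best_err or val_loss < best_loss
        best_err = min(best_err, val_err)
        best_loss = min(best_loss, val_loss)
        if (val_err, val_loss) < best_key:
            best_key = (val_err, val_loss)
            best = [p.copy() for p in params]
            best_epoch = epoch
        if improved:
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    return Classifier(
        classes=classes,
        mu=mu,
        sigma=sigma,
        w1=best[0],
        b1=best[1],
        w2=best[2],
        b2=best[3],
        config=config,
        n_epochs=epoch,
    )


def predict_posterior(clf: AnyClassifier, x: np.ndarray) -> np.ndarray:
    """Posterior over ``clf.classes``; module-level convenience wrapper."""
    return clf.predict_posterior(x)


@dataclass
class ModeSpecificPredictor:
    """One classifier per current mode, over that mode's successor set."""

    classifiers: dict[Activity, AnyClassifier]

    def class_count(self, mode: Activity) -> int:
        return self.classifiers[mode].n_classes

    def posterior(self, mode: Activity, x: np.ndarray) -> tuple[np.ndarray, list[Activity]]:
        if mode not in self.classifiers:
            raise ValidationError(f"no classifier for mode {mode}")
        clf = self.classifiers[mode]
        return clf.predict_posterior(x), list(clf.classes)

    def predict(self, mode: Activity, x: np.ndarray) -> Activity:
        p, classes = self.posterior(mode, x)
        return classes[int(np.argmax(p))]


def _mode_seed(base: int, tag: int) -> int:
    # stable per-classifier fan-out of the training seed, kept below 2^31
    return int(np.random.SeedSequence([base, tag]).generate_state(1)[0] % (2**31))


def train_mode_specific(
    samples: Sequence[EventSample],
    config: NetConfig = NetConfig(),
    class_lists: dict[Activity, list[Activity]] | None = None,
) -> ModeSpecificPredictor:
    """Group samples by current mode and train one classifier per mode.

    ``class_lists`` freezes each mode's class list (used at retraining so the
    successor sets stay those of the initial training data); samples whose
    label falls outside their mode's list are dropped.  Without it, class
    lists are the successor sets observed in ``samples``.
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("empty sample list")
    by_mode: dict[Activity, list[EventSample]] = {}
    for s in samples:
        by_mode.setdefault(s.mode, []).append(s)
    if class_lists is None:
        class_lists = {
            m: sorted({s.label for s in evs}, key=lambda a: a.value)
            for m, evs in by_mode.items()
        }
    classifiers: dict[Activity, AnyClassifier] = {}
    for i, (mode, classes) in enumerate(sorted(class_lists.items(), key=lambda kv: kv[0].value)):
        evs = [s for s in by_mode.get(mode, []) if s.label in classes]
        if len(classes) == 1:
            classifiers[mode] = ConstantClassifier(classes=list(classes))
            continue
        x = np.array([s.forward for s in evs])
        y = [s.label for s in evs]
        cfg = replace(config, seed=_mode_seed(config.seed, i))
        classifiers[mode] = _fit(x, y, list(classes), cfg)
    return ModeSpecificPredictor(classifiers=classifiers)


def train_backward(
    stride_features: np.ndarray,
    labels: Sequence[Activity],
    config: NetConfig = NetConfig(),
    classes: list[Activity] | None = None,
) -> Classifier:
    """Train the backward predictor: one classifier over all activity classes
    on stride (mechanical-only) feature vectors."""
    x = np.asarray(stride_features, dtype=float)
    labels = list(labels)
    if classes is None:
        classes = sorted(set(labels), key=lambda a: a.value)
    if len(classes) < 2:
        raise TrainingError("backward training needs >= 2 classes")
    if x.shape[0] < 10:
        raise TrainingError("need at least 10 samples to train")
    keep = [i for i, l in enumerate(labels) if l in classes]
    return _fit(x[keep], [labels[i] for i in keep], list(classes), config)


# ---------------------------------------------------------------------------
# serialization


def _clf_to_dict(clf: AnyClassifier) -> dict:
    if isinstance(clf, ConstantClassifier):
        return {"kind": "constant", "classes": [c.value for c in clf.classes]}
    return {
        "kind": "net",
        "classes": [c.value for c in clf.classes],
        "mu": clf.mu.tolist(),
        "sigma": clf.sigma.tolist(),
        "w1": clf.w1.tolist(),
        "b1": clf.b1.tolist(),
        "w2": clf.w2.tolist(),
        "b2": clf.b2.tolist(),
        "config": clf.config.__dict__,
        "n_epochs": clf.n_epochs,
    }


def _clf_from_dict(d: dict) -> AnyClassifier:
    classes = [Activity(c) for c in d["classes"]]
    if d["kind"] == "constant":
        return ConstantClassifier(classes=classes)
    return Classifier(
        classes=classes,
        mu=np.array(d["mu"]),
        sigma=np.array(d["sigma"]),
        w1=np.array(d["w1"]),
        b1=np.array(d["b1"]),
        w2=np.array(d["w2"]),
        b2=np.array(d["b2"]),
        config=NetConfig(**d["config"]),
        n_epochs=d["n_epochs"],
    )


def save_bundle(
    path: str | Path,
    forward: ModeSpecificPredictor,
    backward: Classifier | None = None,
    meta: dict | None = None,
) -> None:
    """Serialize a predictor bundle (weights, class lists, z-score parameters,
    training config and seed) as a single JSON archive."""
    bundle = {
        "descriptor": {"format": "driftadapt-bundle", "version": 1, **(meta or {})},
        "forward": {m.value: _clf_to_dict(c) for m, c in forward.classifiers.items()},
        "backward": _clf_to_dict(backward) if backward is not None else None,
    }
    Path(path).write_text(json.dumps(bundle))


def load_bundle(path: str | Path) -> tuple[ModeSpecificPredictor, Classifier | None, dict]:
    bundle = json.loads(Path(path).read_text())
    forward = ModeSpecificPredictor(
        classifiers={Activity(m): _clf_from_dict(d) for m, d in bundle["forward"].items()}
    )
    backward = _clf_from_dict(bundle["backward"]) if bundle["backward"] else None
    return forward, backward, bundle["descriptor"]
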