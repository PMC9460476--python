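"""Adaptation strategies against concept drift.

Five strategies are compared:

* ``baseline`` — never update.
* ``perfect`` — add every streamed sample with its ground-truth label
  (upper reference; real deployments lack these labels).
* ``entropy`` — self-training gated on confidence: a sample joins the
  forward pool with its *predicted* label iff the posterior entropy falls
  below a class-count-scaled threshold Thr(N) = 0.6/ln(5) * ln(N).
* ``backward`` — relabeling: after each stride, a backward predictor
  classifies the completed stride from mechanical features and its label is
  attached to the forward features unconditionally.
* ``backward_entropy`` — as ``backward``, and additionally the backward
  predictor's own pool grows with entropy-gated (stride features, backward
  label) pairs, so the backward predictor adapts too.

Predictors retrain from scratch on the grown pools after every two trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .activities import Activity
from .dataset import EventSample
from .errors import ConfigurationError, ValidationError
from .models import AnyClassifier

STRATEGIES = ("baseline", "perfect", "entropy", "backward", "backward_entropy")

#: entropy-threshold coefficient: 0.6 at the reference class count of 5
ENTROPY_BASE = 0.6
ENTROPY_REF_CLASSES = 5


def entropy(p: np.ndarray) -> float:
    """Shannon entropy E = -sum p_k ln p_k, with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("posterior must be 1-D")
    if np.any(p < 0):
        raise ValidationError("posterior has negative entries")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"posterior sums to {p.sum():.8f}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def threshold(n_classes: int) -> float:
    """Entropy threshold Thr(N) = 0.6/ln(5) * ln(N); exactly 0.6 at N = 5."""
    if n_classes < 1:
        raise ValidationError("class count must be >= 1")
    return ENTROPY_BASE * (math.log(n_classes) / math.log(ENTROPY_REF_CLASSES))


@dataclass(frozen=True)
class EntropyGate:
    """Confidence gate for one classifier: admit iff E < Thr(N)."""

    n_classes: int

    @property
    def thr(self) -> float:
        return threshold(self.n_classes)

    def admits(self, posterior: np.ndarray) -> tuple[bool, float]:
        e = entropy(posterior)
        return e < self.thr, e


@dataclass
class PoolSample:
    """One pooled training sample with its provenance."""

    uid: tuple[int, int, int]
    mode: Activity
    label: Activity
    features: np.ndarray
    origin: str  # "initial" | strategy name
    added_at: int  # stream trial position; -1 for initial training data


@dataclass
class AdaptationState:
    """Growing pools, retrain scheduler and audit log for one strategy run."""

    strategy: str
    retrain_interval: int = 2
    pool_cap: int | None = None
    forward_pool: list[PoolSample] = field(default_factory=list)
    backward_pool: list[PoolSample] = field(default_factory=list)
    trials_since_retrain: int = 0
    selection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(
                f"unknown strategy '{self.strategy}'; choose from {STRATEGIES}"
            )
        if self.retrain_interval < 1:
            raise ConfigurationError("retrain interval must be >= 1")

    def _cap(self, pool: list[PoolSample]) -> None:
        if self.pool_cap is not None:
            while len(pool) > self.pool_cap:
                pool.pop(0)  # FIFO

    def add_forward(self, sample: PoolSample) -> None:
        self.forward_pool.append(sample)
        self._cap(self.forward_pool)

    def add_backward(self, sample: PoolSample) -> None:
        self.backward_pool.append(sample)
        self._cap(self.backward_pool)


def _log(state: AdaptationState, sample: EventSample, **kw) -> None:
    state.selection_log.append(
        {
            "uid": sample.uid,
            "strategy": state.strategy,
            "mode": sample.mode.value,
            "true_label": sample.label.value,
            **kw,
        }
    )


def entropy_select(
    sample: EventSample,
    posterior: np.ndarray,
    classes: Sequence[Activity],
    gate: EntropyGate,
    state: AdaptationState,
    stream_pos: int,
) -> AdaptationState:
    """Admit (forward features, predicted label) iff E(posterior) < Thr(N).

    Ties reject (strict inequality), so a constant single-class mode
    (E = 0, Thr = 0) never contributes.
    """
    if len(posterior) != gate.n_classes or len(classes) != gate.n_classes:
        raise ValidationError("gate class count must match the posterior length")
    selected, e = gate.admits(posterior)
    predicted = classes[int(np.argmax(posterior))]
    if selected:
        state.add_forward(
            PoolSample(sample.uid, sample.mode, predicted, sample.forward,
                       "entropy", stream_pos)
        )
    _log(state, sample, entropy=e, thr=gate.thr, decision=selected,
         assigned_label=predicted.value, pool="forward", stream_pos=stream_pos)
    return state


def backward_relabel(
    sample: EventSample,
    backward_clf: AnyClassifier,
    state: AdaptationState,
    stream_pos: int,
) -> AdaptationState:
    """Attach the backward predictor's stride label to the forward features
    and pool the pair unconditionally; skip samples without a stride."""
    if sample.backward is None:
        _log(state, sample, decision=False, skipped="missing_stride",
             pool="forward", stream_pos=stream_pos)
        return state
    post = backward_clf.predict_posterior(sample.backward)
    blabel = backward_clf.classes[int(np.argmax(post))]
    state.add_forward(
        PoolSample(sample.uid, sample.mode, blabel, sample.forward,
                   "backward", stream_pos)
    )
    _log(state, sample, decision=True, assigned_label=blabel.value,
         pool="forward", stream_pos=stream_pos)
    return state


def backward_entropy_update(
    sample: EventSample,
    backward_clf: AnyClassifier,
    gate: EntropyGate,
    state: AdaptationState,
    stream_pos: int,
) -> AdaptationState:
    """Forward pool exactly as :func:`backward_relabel`; additionally the
    (stride features, backward label) pair joins the backward pool iff the
    backward posterior's entropy is below Thr(N_backward)."""
    if sample.backward is None:
        _log(state, sample, decision=False, skipped="missing_stride",
             pool="forward", stream_pos=stream_pos)
        return state
    post = backward_clf.predict_posterior(sample.backward)
    blabel = backward_clf.classes[int(np.argmax(post))]
    state.add_forward(
        PoolSample(sample.uid, sample.mode, blabel, sample.forward,
                   "backward_entropy", stream_pos)
    )
    admitted, e = gate.admits(post)
    if admitted:
        state.add_backward(
            PoolSample(sample.uid, sample.mode, blabel, sample.backward,
                       "backward_entropy", stream_pos)
        )
    _log(state, sample, entropy=e, thr=gate.thr, decision=admitted,
         assigned_label=blabel.value, pool="backward", stream_pos=stream_pos)
    return state


def perfect_update(
    sample: EventSample, state: AdaptationState, stream_pos: int
) -> AdaptationState:
    """Pool (forward features, TRUE label) unconditionally."""
    state.add_forward(
        PoolSample(sample.uid, sample.mode, sample.label, sample.forward,
                   "perfect", stream_pos)
    )
    _log(state, sample, decision=True, assigned_label=sample.label.value,
         pool="forward", stream_pos=stream_pos)
    return state


@dataclass
class RetrainDecision:
    due: bool
    retrain_forward: bool
    retrain_backward: bool


def maybe_retrain(state: AdaptationState) -> RetrainDecision:
    """Advance the per-trial counter; report whether a retrain is due.

    Called once per completed trial.  When the counter reaches the interval
    it resets and, for any strategy but baseline, the forward predictor is
    due for retraining on the current pools; ``backward_entropy``
    additionally retrains the backward predictor.  The caller performs the
    actual (from-scratch, freshly seeded) fits.
    """
    state.trials_since_retrain += 1
    due = state.trials_since_retrain >= state.retrain_interval
    if due:
        state.trials_since_retrain = 0
    if state.strategy == "baseline":
        return RetrainDecision(False, False, False)
    return RetrainDecision(
        due=due,
        retrain_forward=due,
        retrain_backward=due and state.strategy == "backward_entropy",
    )
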