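"""Time-domain feature extraction.

Forward vectors combine, per channel of the 300 ms pre-event window, the
classic EMG feature set (mean absolute value, zero crossings, slope-sign
changes, waveform length, 4th-order autoregressive coefficients) with six
summary statistics of each mechanical channel (mean, SD, max, min, start,
end).  Backward vectors use the six summaries on mechanical channels only,
computed over the preceding stride.  Summary features are length-invariant,
so variable stride durations still yield a fixed dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import burg

from .activities import Activity, CircuitSpec
from .dataset import EventSample
from .errors import ValidationError
from .signals import EMG, MECHANICAL, SignalBlock, WindowSpec, cut_forward_window, cut_stride_window

EMG_FEATURE_NAMES = ("mav", "zc", "ssc", "wl", "ar1", "ar2", "ar3", "ar4")
MECH_FEATURE_NAMES = ("mean", "sd", "max", "min", "start", "end")


@dataclass(frozen=True)
class FeatureSpec:
    """AR model order and the zero-crossing / slope-sign-change deadband."""

    ar_order: int = 4
    deadband: float = 0.0

    def __post_init__(self) -> None:
        if self.ar_order < 1:
            raise ValidationError("AR order must be >= 1")
        if self.deadband < 0:
            raise ValidationError("deadband must be >= 0")


def emg_features(window: np.ndarray, spec: FeatureSpec = FeatureSpec()) -> np.ndarray:
    """MAV, ZC, SSC, WL and AR coefficients of one EMG channel window.

    ZC counts sign changes between consecutive samples whose amplitude step
    exceeds the deadband; SSC counts slope-sign changes with the same
    deadband on both adjacent steps.  AR coefficients come from a Burg fit
    of the prediction form x_t = sum_i a_i x_{t-i} + e_t.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValidationError("emg_features expects a single-channel series")
    if len(x) < max(5, spec.ar_order + 1):
        raise ValidationError(f"window of {len(x)} samples is too short")
    if not np.isfinite(x).all():
        raise ValidationError("window contains non-finite values")

    mav = float(np.mean(np.abs(x)))
    dx = np.diff(x)
    wl = float(np.sum(np.abs(dx)))

    step_ok = np.abs(dx) > spec.deadband
    zc = int(np.sum((x[:-1] * x[1:] < 0) & step_ok))

    slope_change = dx[:-1] * dx[1:] < 0
    ssc = int(np.sum(slope_change & step_ok[:-1] & step_ok[1:]))

    centered = x - x.mean()
    if np.allclose(centered, 0.0):
        ar = np.zeros(spec.ar_order)
    else:
        ar, _ = burg(centered, order=spec.ar_order, demean=False)
    return np.concatenate([[mav, zc, ssc, wl], ar])


def mechanical_features(window: np.ndarray) -> np.ndarray:
    """(mean, SD, max, min, start, end) of one mechanical channel window.

    SD uses the population convention (divisor n).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValidationError("mechanical_features expects a non-empty 1-D series")
    if not np.isfinite(x).all():
        raise ValidationError("window contains non-finite values")
    return np.array(
        [x.mean(), x.std(ddof=0), x.max(), x.min(), x[0], x[-1]], dtype=float
    )


def _feature_block(window: SignalBlock, spec: FeatureSpec, roles: set[str]) -> tuple[list[str], list[float]]:
    names: list[str] = []
    values: list[float] = []
    for col, (name, role) in enumerate(zip(window.channels, window.roles)):
        if role not in roles:
            continue
        series = window.data[:, col]
        if role == EMG:
            feats = emg_features(series, spec)
            fnames = EMG_FEATURE_NAMES
        else:
            feats = mechanical_features(series)
            fnames = MECH_FEATURE_NAMES
        names.extend(f"{name}_{f}" for f in fnames)
        values.extend(feats)
    return names, values


def build_forward_vector(
    window: SignalBlock, spec: FeatureSpec = FeatureSpec()
) -> tuple[np.ndarray, list[str]]:
    """Concatenate per-channel features of the forward window in channel
    order: 8 per EMG channel, 6 per mechanical channel."""
    if window.n_samples == 0:
        raise ValidationError("empty window")
    names, values = _feature_block(window, spec, {EMG, MECHANICAL})
    return np.asarray(values, dtype=float), names


def build_backward_vector(window: SignalBlock) -> tuple[np.ndarray, list[str]]:
    """Six summary features per mechanical channel of the stride window.

    EMG channels must not be present: the backward predictor consumes
    mechanical information only.
    """
    if any(r == EMG for r in window.roles):
        raise ValidationError("backward vector is mechanical-only; remove EMG channels")
    if window.n_samples == 0:
        raise ValidationError("empty window")
    names, values = _feature_block(window, FeatureSpec(), {MECHANICAL})
    return np.asarray(values, dtype=float), names


def extract_trial_events(
    block: SignalBlock,
    event_times: list[float],
    labels: list[Activity],
    day: int,
    trial: int,
    window_spec: WindowSpec = WindowSpec(),
    feature_spec: FeatureSpec = FeatureSpec(),
) -> list[EventSample]:
    """Cut windows around each gait event and build its feature vectors.

    The first event of the trial has no preceding stride, hence no backward
    vector.  The current mode of event i is the label of event i-1 (SIT for
    the first event: trials start from the stool).
    """
    if len(event_times) != len(labels):
        raise ValidationError("event_times and labels must have equal length")
    mech = block.select(np.array([r == MECHANICAL for r in block.roles]))
    modes = CircuitSpec.modes_for(labels)
    samples: list[EventSample] = []
    for i, (t_ev, lab, mode) in enumerate(zip(event_times, labels, modes)):
        fwd_win = cut_forward_window(block, t_ev, window_spec)
        fwd, _ = build_forward_vector(fwd_win, feature_spec)
        if i == 0:
            bwd = None
        else:
            stride = cut_stride_window(mech, event_times[i - 1], t_ev, window_spec)
            bwd, _ = build_backward_vector(stride)
        samples.append(
            EventSample(day=day, trial=trial, event=i, mode=mode, label=lab,
                        forward=fwd, backward=bwd)
        )
    return samples
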