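"""Signal conditioning and event-anchored windowing.

The conditioning contract: resample all channels to a common rate (1000 Hz),
high-pass EMG with a zero-lag 2nd-order Butterworth at 20 Hz, then divide
each EMG channel by its maximal-voluntary-contraction (MVC) reference.
Forward prediction consumes a 300 ms window ending one sample before each
gait event; backward prediction consumes the preceding stride, capped at its
most recent 1500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError, WindowingError

EMG = "emg"
MECHANICAL = "mechanical"


@dataclass
class SignalBlock:
    """A time x channels sample matrix with rate, roles and time origin (ms)."""

    data: np.ndarray
    rate: float
    channels: list[str]
    roles: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("signal data must be 2-D (time x channels)")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be > 0")
        if len(self.channels) != self.data.shape[1] or len(self.roles) != self.data.shape[1]:
            raise ValidationError("channel names/roles must cover every column")
        bad = set(self.roles) - {EMG, MECHANICAL}
        if bad:
            raise ValidationError(f"unknown channel roles: {sorted(bad)}")
        if not np.isfinite(self.data).all():
            raise ValidationError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def emg_columns(self) -> np.ndarray:
        return np.array([r == EMG for r in self.roles])

    def replace(self, data: np.ndarray, rate: float | None = None, t0: float | None = None):
        return SignalBlock(
            data=data,
            rate=self.rate if rate is None else rate,
            channels=list(self.channels),
            roles=list(self.roles),
            t0=self.t0 if t0 is None else t0,
        )

    def select(self, mask: np.ndarray) -> "SignalBlock":
        idx = np.where(mask)[0]
        return SignalBlock(
            data=self.data[:, idx],
            rate=self.rate,
            channels=[self.channels[i] for i in idx],
            roles=[self.roles[i] for i in idx],
            t0=self.t0,
        )


@dataclass(frozen=True)
class WindowSpec:
    """Forward window length and backward (stride) window cap, in ms."""

    forward_ms: float = 300.0
    backward_max_ms: float = 1500.0

    def __post_init__(self) -> None:
        if self.forward_ms <= 0 or self.backward_max_ms <= 0:
            raise ConfigurationError("window lengths must be > 0")
        if self.forward_ms > self.backward_max_ms:
            raise ConfigurationError("forward window must not exceed the backward cap")


def highpass_emg(block: SignalBlock, cutoff: float = 20.0, order: int = 2) -> SignalBlock:
    """Zero-lag Butterworth high-pass of the EMG channels only.

    The filter is applied forward and backward (``filtfilt``), so the net
    phase is zero and the magnitude response is squared.
    """
    nyquist = block.rate / 2.0
    if cutoff >= nyquist:
        raise ConfigurationError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    emg = block.emg_columns()
    if not emg.any():
        raise ValidationError("block has no EMG channels")
    sos = sps.butter(order, cutoff, btype="highpass", fs=block.rate, output="sos")
    out = block.data.copy()
    out[:, emg] = sps.sosfiltfilt(sos, block.data[:, emg], axis=0)
    return block.replace(out)


def normalize_mvc(block: SignalBlock, mvc_reference: np.ndarray | dict[str, float]) -> SignalBlock:
    """Divide each EMG channel by its MVC reference; mechanical untouched."""
    emg = block.emg_columns()
    emg_names = [c for c, m in zip(block.channels, emg) if m]
    if isinstance(mvc_reference, dict):
        missing = [c for c in emg_names if c not in mvc_reference]
        if missing:
            raise ValidationError(f"MVC reference missing channels: {missing}")
        ref = np.array([mvc_reference[c] for c in emg_names], dtype=float)
    else:
        ref = np.asarray(mvc_reference, dtype=float)
        if ref.shape != (int(emg.sum()),):
            raise ValidationError("MVC reference length must equal the EMG channel count")
    if np.any(ref <= 0):
        raise ValidationError("MVC reference values must be > 0")
    out = block.data.copy()
    out[:, emg] = out[:, emg] / ref
    return block.replace(out)


def mvc_reference(recording: np.ndarray, rate: float, smooth_hz: float = 2.0) -> float:
    """MVC reference of one channel: peak of the rectified, low-pass-smoothed
    contraction recording."""
    x = np.abs(np.asarray(recording, dtype=float))
    sos = sps.butter(2, smooth_hz, btype="lowpass", fs=rate, output="sos")
    return float(np.max(sps.sosfiltfilt(sos, x)))


def resample(block: SignalBlock, target_rate: float = 1000.0) -> SignalBlock:
    """Polyphase resampling of all channels to ``target_rate``."""
    if target_rate <= 0:
        raise ConfigurationError("target rate must be > 0")
    if block.n_samples == 0:
        raise ValidationError("cannot resample an empty block")
    frac = Fraction(target_rate / block.rate).limit_denominator(1000)
    if frac == 1:
        return block.replace(block.data.copy())
    out = sps.resample_poly(block.data, frac.numerator, frac.denominator, axis=0, padtype="line")
    return block.replace(out, rate=target_rate)


def _index(block: SignalBlock, time_ms: float) -> int:
    return int(round((time_ms - block.t0) * block.rate / 1000.0))


def cut_forward_window(block: SignalBlock, event_time: float, spec: WindowSpec) -> SignalBlock:
    """The forward window: ``forward_ms`` of signal ending just before the
    event (the event sample itself is excluded — causal prediction)."""
    n_win = int(round(spec.forward_ms * block.rate / 1000.0))
    end = _index(block, event_time)
    start = end - n_win
    if start < 0 or end > block.n_samples:
        raise WindowingError(
            f"event at {event_time} ms lacks {spec.forward_ms} ms of preceding signal"
        )
    return block.replace(block.data[start:end].copy(), t0=block.t0 + start * 1000.0 / block.rate)


def cut_stride_window(
    block: SignalBlock, previous_event: float, current_event: float, spec: WindowSpec
) -> SignalBlock:
    """The stride interval [previous_event, current_event), truncated to its
    most recent ``backward_max_ms`` when the stride is longer."""
    if previous_event >= current_event:
        raise ValidationError("previous_event must precede current_event")
    end = _index(block, current_event)
    start = _index(block, previous_event)
    if start < 0 or end > block.n_samples:
        raise WindowingError("stride window falls outside the block")
    cap = int(round(spec.backward_max_ms * block.rate / 1000.0))
    if end - start > cap:
        start = end - cap
    return block.replace(block.data[start:end].copy(), t0=block.t0 + start * 1000.0 / block.rate)
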