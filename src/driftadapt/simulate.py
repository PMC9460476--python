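"""Synthetic multi-day gait sessions.

Two generators are provided:

* :func:`simulate_feature_session` emits feature-level event streams with
  configurable day-to-day concept drift (class-conditional Gaussians whose
  means shift and whose covariances rescale per day).  This is the input of
  the adaptation study.
* :func:`simulate_raw_trial` emits continuous multichannel signals (EMG-like
  band-limited bursts plus smooth class-dependent mechanical waveforms) with
  gait-event timestamps, to exercise the conditioning and feature-extraction
  stages.

The drift model is deliberately simple: an additive per-day mean shift and a
multiplicative per-day covariance scale, with defaults that put the largest
mean jump between day 1 and day 2 and the largest variance on day 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .activities import Activity, CircuitSpec, default_circuit
from .dataset import EventSample, SessionDataset
from .errors import ConfigurationError
from .signals import SignalBlock

DEFAULT_DAYS: tuple[int, ...] = (1, 2, 3, 7)


def _check_cov(cov: np.ndarray, name: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ConfigurationError(f"{name}: covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ConfigurationError(f"{name}: covariance must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        raise ConfigurationError(f"{name}: covariance is not positive semi-definite")
    return cov


@dataclass
class ClassCloudSpec:
    """Class-conditional Gaussians for one feature space, with daily drift.

    ``means`` maps each activity to its base mean vector; ``cov`` is the
    shared base covariance (or a per-class mapping).  ``day_shifts`` maps a
    day id to the additive mean shift applied to every class that day
    (optionally per-class); ``day_scales`` maps a day id to the covariance
    scale.  The first measurement day must use shift 0 and scale 1.
    """

    means: dict[Activity, np.ndarray]
    cov: np.ndarray | dict[Activity, np.ndarray]
    day_shifts: dict[int, np.ndarray | dict[Activity, np.ndarray]]
    day_scales: dict[int, float]
    feature_prefix: str = "f"

    def __post_init__(self) -> None:
        dims = {len(np.asarray(m)) for m in self.means.values()}
        if len(dims) != 1:
            raise ConfigurationError("all class means must share one dimension")
        (self.dim,) = dims
        self.means = {c: np.asarray(m, dtype=float) for c, m in self.means.items()}
        if isinstance(self.cov, dict):
            self.cov = {c: _check_cov(v, f"cov[{c}]") for c, v in self.cov.items()}
        else:
            self.cov = _check_cov(self.cov, "cov")
        for day, s in self.day_scales.items():
            if s <= 0:
                raise ConfigurationError(f"day {day}: covariance scale must be > 0")
        first = min(self.day_scales)
        shift0 = self._shift(first, next(iter(self.means)))
        if self.day_scales[first] != 1.0 or np.any(shift0 != 0.0):
            raise ConfigurationError("the first day must use shift 0 and scale 1")

    def _shift(self, day: int, cls: Activity) -> np.ndarray:
        raw = self.day_shifts[day]
        vec = raw[cls] if isinstance(raw, dict) else raw
        return np.asarray(vec, dtype=float)

    def _chol(self, cls: Activity) -> np.ndarray:
        cov = self.cov[cls] if isinstance(self.cov, dict) else self.cov
        # tiny jitter keeps semi-definite inputs factorable
        return np.linalg.cholesky(cov + 1e-12 * np.eye(self.dim))

    def sample(self, cls: Activity, day: int, rng: np.random.Generator) -> np.ndarray:
        mean = self.means[cls] + self._shift(day, cls)
        z = rng.standard_normal(self.dim)
        return mean + np.sqrt(self.day_scales[day]) * (self._chol(cls) @ z)

    def feature_names(self) -> list[str]:
        return [f"{self.feature_prefix}{i}" for i in range(self.dim)]


@dataclass
class DriftConfig:
    """Drift model for a feature-level session: forward and backward spaces."""

    forward: ClassCloudSpec
    backward: ClassCloudSpec
    seed: int = 0


def _one_hot_means(classes: list[Activity], dim: int, sep: float) -> dict[Activity, np.ndarray]:
    means = {}
    for i, c in enumerate(classes):
        v = np.zeros(dim)
        v[i % dim] = sep
        means[c] = v
    return means


def default_drift_config(
    seed: int = 0,
    days: tuple[int, ...] = DEFAULT_DAYS,
    separation: float = 3.2,
    shift_magnitudes: tuple[float, ...] = (0.0, 2.5, 2.8, 3.0),
    cov_scales: tuple[float, ...] = (1.0, 0.9, 0.85, 0.85),
    backward_shift_factor: float = 0.6,
) -> DriftConfig:
    """Default drift: 7 one-hot class means separated ``separation`` noise-SD,
    a global mean shift per day along a fixed direction (largest jump day
    1 -> 2) and shrinking covariance (largest variance on day 1).

    The stride (backward) feature space drifts along its own direction at
    ``backward_shift_factor`` of the forward magnitude: full-stride mechanics
    degrade more gently than the pre-event window, mirroring the reported
    relative error growth of backward versus forward predictors.
    """
    classes = list(Activity)
    dim = len(classes)
    if len(shift_magnitudes) != len(days) or len(cov_scales) != len(days):
        raise ConfigurationError("need one shift magnitude and one scale per day")
    u_f = np.array([1.0, -1.0] * (dim // 2) + [1.0] * (dim % 2))
    u_f /= np.linalg.norm(u_f)
    u_b = -u_f
    spaces = []
    for prefix, u, factor in (("f", u_f, 1.0), ("b", u_b, backward_shift_factor)):
        spaces.append(
            ClassCloudSpec(
                means=_one_hot_means(classes, dim, separation),
                cov=np.eye(dim),
                day_shifts={d: factor * m * u for d, m in zip(days, shift_magnitudes)},
                day_scales=dict(zip(days, cov_scales)),
                feature_prefix=prefix,
            )
        )
    return DriftConfig(forward=spaces[0], backward=spaces[1], seed=seed)


def simulate_feature_session(
    circuit: CircuitSpec | None = None,
    drift: DriftConfig | None = None,
    n_days: int = 4,
    trials_per_day: int = 40,
    days: tuple[int, ...] | None = None,
    subject: str = "synthetic",
) -> SessionDataset:
    """Generate a feature-level multi-day session.

    Trials follow the circuit's transition sequence; each event's forward and
    backward feature vectors are drawn from the class-conditional Gaussian of
    its true label, shifted and scaled for its day.  The first event of every
    trial has no preceding stride and therefore no backward vector.
    Deterministic given ``drift.seed``.
    """
    if n_days < 1 or trials_per_day < 1:
        raise ConfigurationError("n_days and trials_per_day must be >= 1")
    circuit = circuit or default_circuit()
    drift = drift or default_drift_config()
    if days is None:
        days = DEFAULT_DAYS[:n_days]
    if len(days) != n_days:
        raise ConfigurationError("days must have length n_days")
    for d in days:
        if d not in drift.forward.day_shifts or d not in drift.backward.day_shifts:
            raise ConfigurationError(f"drift config has no entry for day {d}")

    rng = np.random.default_rng(np.random.SeedSequence([drift.seed, 0x5E5]))
    trials: dict[int, list[list[EventSample]]] = {}
    for day in days:
        day_trials: list[list[EventSample]] = []
        for t_idx in range(trials_per_day):
            labels = circuit.sample_labels(rng)
            modes = CircuitSpec.modes_for(labels)
            trial: list[EventSample] = []
            for e_idx, (mode, lab) in enumerate(zip(modes, labels)):
                fwd = drift.forward.sample(lab, day, rng)
                bwd = None if e_idx == 0 else drift.backward.sample(lab, day, rng)
                trial.append(
                    EventSample(
                        day=day, trial=t_idx, event=e_idx,
                        mode=mode, label=lab, forward=fwd, backward=bwd,
                    )
                )
            day_trials.append(trial)
        trials[day] = day_trials
    return SessionDataset(
        subject=subject,
        days=list(days),
        trials=trials,
        forward_names=drift.forward.feature_names(),
        backward_names=drift.backward.feature_names(),
        classes=list(Activity),
    )


# ---------------------------------------------------------------------------
# raw-signal simulation


@dataclass
class RawSignalConfig:
    """Parameters of the raw multichannel trial generator.

    EMG channels are 20-450 Hz band-limited noise amplitude-modulated by a
    stride-locked envelope; mechanical channels are class-dependent smooth
    stride waveforms plus white noise.
    """

    sampling_rate: float = 1000.0
    n_emg: int = 8
    n_mechanical: int = 20
    stride_ms: tuple[float, float] = (900.0, 1300.0)
    emg_band: tuple[float, float] = (20.0, 450.0)
    emg_amplitude: float = 1.0
    mech_amplitude: float = 1.0
    noise_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling rate must be > 0")
        if self.n_emg < 1 or self.n_mechanical < 1:
            raise ConfigurationError("channel counts must be >= 1")
        lo, hi = self.stride_ms
        if lo <= 0 or hi < lo:
            raise ConfigurationError("stride duration range is inverted or non-positive")

    def channel_names(self) -> list[str]:
        return [f"emg{i}" for i in range(self.n_emg)] + [
            f"mech{i}" for i in range(self.n_mechanical)
        ]

    def channel_roles(self) -> list[str]:
        return ["emg"] * self.n_emg + ["mechanical"] * self.n_mechanical


def _class_params(cls: Activity, channel: int, kind: str) -> tuple[float, float, float]:
    """Deterministic per-class, per-channel waveform parameters."""
    idx = list(Activity).index(cls)
    h = (idx * 131 + channel * 17 + (0 if kind == "emg" else 7919)) % 1000 / 1000.0
    amp = 0.5 + h            # 0.5 .. 1.5
    phase = 2 * np.pi * h
    harmonics = 1 + (idx + channel) % 3
    return amp, phase, harmonics


def simulate_raw_trial(
    config: RawSignalConfig,
    circuit: CircuitSpec | None = None,
    seed: int | None = None,
) -> tuple[SignalBlock, list[float], list[Activity]]:
    """Generate one raw trial: a signal block, event times (ms) and labels.

    Gait events mark simulated initial contacts; the first event is placed
    so that at least 300 ms of signal precede it.  EMG channels contain
    stride-synchronized band-limited bursts; mechanical channels contain
    class-dependent periodic waveforms.  Deterministic given ``seed``.
    """
    circuit = circuit or default_circuit()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate
    labels = circuit.sample_labels(rng)

    # stride boundaries: lead-in before the first event, one stride per event
    lead_ms = 400.0
    stride_ms = rng.uniform(config.stride_ms[0], config.stride_ms[1], size=len(labels))
    event_times = lead_ms + np.cumsum(stride_ms)  # each event ends its stride
    n = int(np.ceil((event_times[-1] + 100.0) * fs / 1000.0))
    t = np.arange(n) / fs * 1000.0  # ms

    n_ch = config.n_emg + config.n_mechanical
    data = np.zeros((n, n_ch))

    # per-sample class track: stride i (ending at event i) belongs to label i
    bounds_ms = np.concatenate([[0.0], event_times])
    sos = sps.butter(
        4,
        [config.emg_band[0], min(config.emg_band[1], 0.45 * fs)],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    carrier = sps.sosfiltfilt(sos, rng.standard_normal((n, config.n_emg)), axis=0)
    carrier /= max(1e-12, carrier.std())

    for i, lab in enumerate(labels):
        s = int(bounds_ms[i] * fs / 1000.0)
        e = int(bounds_ms[i + 1] * fs / 1000.0)
        seg = e - s
        if seg <= 0:
            continue
        phase01 = np.linspace(0.0, 1.0, seg, endpoint=False)
        for ch in range(config.n_emg):
            amp, phase, _ = _class_params(lab, ch, "emg")
            envelope = amp * (0.2 + np.sin(np.pi * phase01 + phase * 0.1) ** 2)
            data[s:e, ch] += config.emg_amplitude * envelope * carrier[s:e, ch]
        for ch in range(config.n_mechanical):
            amp, phase, harm = _class_params(lab, ch, "mech")
            wave = amp * np.sin(2 * np.pi * harm * phase01 + phase)
            data[s:e, config.n_emg + ch] += config.mech_amplitude * wave
    if config.noise_level > 0:
        data[:, config.n_emg:] += config.noise_level * rng.standard_normal(
            (n, config.n_mechanical)
        )
    block = SignalBlock(
        data=data,
        rate=fs,
        channels=config.channel_names(),
        roles=config.channel_roles(),
        t0=0.0,
    )
    return block, [float(x) for x in event_times], labels
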