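"""Session containers and their on-disk form.

A session is one subject's multi-day recording: days -> ordered trials ->
ordered gait-event samples.  Each event carries a forward feature vector
(window ending just before the event), a backward feature vector computed
over the preceding stride (absent for the first event of a trial), the
current mode and the true upcoming activity.

On disk a session is a JSON manifest plus one CSV per trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .activities import Activity
from .errors import ManifestError, ValidationError

_MANIFEST_NAME = "manifest.json"
_META_COLUMNS = ["event", "day", "trial", "current_mode", "true_label"]


@dataclass
class EventSample:
    """One gait event: features, current mode and true upcoming activity."""

    day: int
    trial: int
    event: int
    mode: Activity
    label: Activity
    forward: np.ndarray
    backward: np.ndarray | None = None

    @property
    def uid(self) -> tuple[int, int, int]:
        return (self.day, self.trial, self.event)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventSample):
            return NotImplemented
        if (self.day, self.trial, self.event, self.mode, self.label) != (
            other.day,
            other.trial,
            other.event,
            other.mode,
            other.label,
        ):
            return False
        if not np.array_equal(self.forward, other.forward):
            return False
        if (self.backward is None) != (other.backward is None):
            return False
        return self.backward is None or np.array_equal(self.backward, other.backward)


@dataclass
class SessionDataset:
    """A subject's multi-day session of gait-event samples.

    ``trials[day]`` is the ordered list of trials for that day; each trial is
    an ordered list of :class:`EventSample`.
    """

    subject: str
    days: list[int]
    trials: dict[int, list[list[EventSample]]]
    forward_names: list[str]
    backward_names: list[str]
    classes: list[Activity] = field(default_factory=lambda: list(Activity))

    def iter_events(self, day: int | None = None) -> Iterator[EventSample]:
        days = [day] if day is not None else self.days
        for d in days:
            for trial in self.trials[d]:
                yield from trial

    def n_events(self, day: int | None = None) -> int:
        return sum(1 for _ in self.iter_events(day))

    def forward_matrix(self, day: int | None = None) -> np.ndarray:
        return np.array([ev.forward for ev in self.iter_events(day)])

    def labels(self, day: int | None = None) -> list[Activity]:
        return [ev.label for ev in self.iter_events(day)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionDataset):
            return NotImplemented
        if (
            self.subject != other.subject
            or self.days != other.days
            or self.forward_names != other.forward_names
            or self.backward_names != other.backward_names
            or self.classes != other.classes
        ):
            return False
        for d in self.days:
            if len(self.trials[d]) != len(other.trials[d]):
                return False
            for t1, t2 in zip(self.trials[d], other.trials[d]):
                if t1 != t2:
                    return False
        return True


def _trial_frame(trial: list[EventSample], fwd: list[str], bwd: list[str]) -> pd.DataFrame:
    rows = []
    for ev in trial:
        row: dict[str, object] = {
            "event": ev.event,
            "day": ev.day,
            "trial": ev.trial,
            "current_mode": ev.mode.value,
            "true_label": ev.label.value,
        }
        row.update(dict(zip(fwd, ev.forward)))
        back = ev.backward if ev.backward is not None else [np.nan] * len(bwd)
        row.update(dict(zip(bwd, back)))
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLUMNS + fwd + bwd)


def write_session(dataset: SessionDataset, path: str | Path) -> None:
    """Write a session as ``manifest.json`` plus one CSV per trial."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    trial_files: dict[str, list[str]] = {}
    for day in dataset.days:
        names = []
        for t_idx, trial in enumerate(dataset.trials[day]):
            name = f"day{day}_trial{t_idx:03d}.csv"
            frame = _trial_frame(trial, dataset.forward_names, dataset.backward_names)
            # 17 significant digits round-trips float64 exactly
            frame.to_csv(root / name, index=False, float_format="%.17g")
            names.append(name)
        trial_files[str(day)] = names
    manifest = {
        "subject": dataset.subject,
        "mode": "features",
        "days": dataset.days,
        "trial_files": trial_files,
        "classes": [c.value for c in dataset.classes],
        "forward_features": dataset.forward_names,
        "backward_features": dataset.backward_names,
    }
    (root / _MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))


def _require(manifest: dict, key: str) -> object:
    if key not in manifest:
        raise ManifestError(f"manifest is missing required field '{key}'")
    return manifest[key]


def read_session(path: str | Path) -> SessionDataset:
    """Read a session written by :func:`write_session`.

    Raises :class:`ManifestError` on a malformed manifest and
    :class:`ValidationError` on labels outside the session's class list.
    """
    root = Path(path)
    mpath = root / _MANIFEST_NAME
    if not mpath.exists():
        raise ManifestError(f"no {_MANIFEST_NAME} in {root}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - rare
        raise ManifestError(f"manifest is not valid JSON: {exc}") from exc
    days = [int(d) for d in _require(manifest, "days")]
    trial_files = _require(manifest, "trial_files")
    fwd = list(_require(manifest, "forward_features"))
    bwd = list(_require(manifest, "backward_features"))
    class_names = list(_require(manifest, "classes"))
    valid = {a.value for a in Activity}
    bad = [c for c in class_names if c not in valid]
    if bad:
        raise ValidationError(f"unknown activity classes in manifest: {bad}")
    classes = [Activity(c) for c in class_names]

    trials: dict[int, list[list[EventSample]]] = {}
    for day in days:
        day_trials: list[list[EventSample]] = []
        for name in trial_files[str(day)]:
            frame = pd.read_csv(root / name, float_precision="round_trip")
            missing = [c for c in _META_COLUMNS + fwd + bwd if c not in frame.columns]
            if missing:
                raise ManifestError(f"{name}: missing columns {missing}")
            trial: list[EventSample] = []
            for _, row in frame.iterrows():
                for col in ("current_mode", "true_label"):
                    if row[col] not in valid:
                        raise ValidationError(
                            f"{name}: '{row[col]}' in column {col} is not a known activity"
                        )
                back = row[bwd].to_numpy(dtype=float) if bwd else np.empty(0)
                trial.append(
                    EventSample(
                        day=int(row["day"]),
                        trial=int(row["trial"]),
                        event=int(row["event"]),
                        mode=Activity(row["current_mode"]),
                        label=Activity(row["true_label"]),
                        forward=row[fwd].to_numpy(dtype=float),
                        backward=None if bwd and np.isnan(back).all() else back,
                    )
                )
            day_trials.append(trial)
        trials[day] = day_trials
    return SessionDataset(
        subject=str(_require(manifest, "subject")),
        days=days,
        trials=trials,
        forward_names=fwd,
        backward_names=bwd,
        classes=classes,
    )
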