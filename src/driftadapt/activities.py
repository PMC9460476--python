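"""Gait activity labels and the measurement circuit.

A trial walks a fixed circuit of gait-related activities (stand up from a
stool, walk, stairs up, ramp down, walk back, ramp up, stairs down, sit
down).  Every gait event (initial contact) carries the *upcoming* activity
as its label; the activity currently being performed is the event's *mode*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError


class Activity(str, Enum):
    """Closed set of gait-related activity classes."""

    SIT = "SIT"
    STAND = "STAND"
    WALK = "WALK"
    STAIR_ASCENT = "STAIR_ASCENT"
    STAIR_DESCENT = "STAIR_DESCENT"
    RAMP_ASCENT = "RAMP_ASCENT"
    RAMP_DESCENT = "RAMP_DESCENT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_ACTIVITIES: tuple[Activity, ...] = tuple(Activity)


@dataclass(frozen=True)
class CircuitSpec:
    """Ordered activity circuit plus per-activity gait-event counts.

    ``sequence`` is the order in which activities are performed; it must
    begin and end with :attr:`Activity.SIT` (the subject starts and finishes
    seated) and consecutive entries must differ.  ``steps`` maps each
    activity to an inclusive ``(lo, hi)`` range of gait events spent in that
    activity each time it occurs.  The leading SIT is the start *state* and
    contributes no event; the trailing SIT is the sit-down event.
    """

    sequence: tuple[Activity, ...]
    steps: Mapping[Activity, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ConfigurationError("circuit sequence must contain at least two entries")
        if self.sequence[0] is not Activity.SIT or self.sequence[-1] is not Activity.SIT:
            raise ConfigurationError("circuit must begin and end with SIT")
        for a, b in zip(self.sequence, self.sequence[1:]):
            if a is b:
                raise ConfigurationError(f"consecutive circuit entries must differ (got {a} twice)")
        missing = set(ALL_ACTIVITIES) - set(self.sequence)
        if missing:
            raise ConfigurationError(f"circuit never reaches: {sorted(m.value for m in missing)}")
        for act in set(self.sequence[1:]):
            lo, hi = self.steps[act]
            if not (1 <= lo <= hi):
                raise ConfigurationError(f"invalid step range for {act}: ({lo}, {hi})")

    def sample_labels(self, rng: np.random.Generator) -> list[Activity]:
        """Draw the per-event true-label track for one trial.

        Each activity after the initial seated state contributes a number of
        events drawn uniformly from its step range.
        """
        labels: list[Activity] = []
        for act in self.sequence[1:]:
            lo, hi = self.steps[act]
            n = int(rng.integers(lo, hi + 1))
            labels.extend([act] * n)
        return labels

    @staticmethod
    def modes_for(labels: Sequence[Activity]) -> list[Activity]:
        """Current mode per event: the previous event's label, SIT at start."""
        return [Activity.SIT, *labels[:-1]]

    def mean_events_per_trial(self) -> float:
        return float(
            sum((self.steps[a][0] + self.steps[a][1]) / 2.0 for a in self.sequence[1:])
        )


def default_circuit() -> CircuitSpec:
    """The stool-stairs-ramp circuit with 24 gait events per trial."""
    seq = (
        Activity.SIT,
        Activity.STAND,
        Activity.WALK,
        Activity.STAIR_ASCENT,
        Activity.WALK,
        Activity.RAMP_DESCENT,
        Activity.WALK,
        Activity.RAMP_ASCENT,
        Activity.WALK,
        Activity.STAIR_DESCENT,
        Activity.WALK,
        Activity.SIT,
    )
    steps = {
        Activity.SIT: (1, 1),
        Activity.STAND: (1, 1),
        Activity.WALK: (2, 2),
        Activity.STAIR_ASCENT: (3, 3),
        Activity.STAIR_DESCENT: (3, 3),
        Activity.RAMP_ASCENT: (3, 3),
        Activity.RAMP_DESCENT: (3, 3),
    }
    return CircuitSpec(sequence=seq, steps=steps)


def successor_sets(circuit: CircuitSpec) -> dict[Activity, set[Activity]]:
    """Possible event labels per mode under the circuit (transition oracle)."""
    out: dict[Activity, set[Activity]] = {}
    # enumerate one deterministic trial at minimum step counts and one at
    # maximum; the reachable transition structure is identical for any counts
    for pick in (0, 1):
        labels: list[Activity] = []
        for act in circuit.sequence[1:]:
            labels.extend([act] * circuit.steps[act][pick])
        for mode, lab in zip(CircuitSpec.modes_for(labels), labels):
            out.setdefault(mode, set()).add(lab)
    return out
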