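"""Session timeline: the labelled phase structure of a recording.

A recording is divided into contiguous phases — an acclimation baseline,
alternating exercise sets and inter-set rests, and a final recovery. All
analysis windows (the 10-s windows for the pre/post temperature change and
the 5-min windows for spectral analysis) are anchored to this timeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

PHASE_LABELS = ("baseline", "set", "rest", "recovery")


@dataclass(frozen=True)
class Phase:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"phase {self.label!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SessionTimeline:
    """Ordered, contiguous, non-overlapping phases covering [0, end_s]."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("timeline needs at least one phase")
        if self.phases[0].start_s != 0.0:
            raise ValueError("first phase must start at t = 0 s")
        for prev, cur in zip(self.phases, self.phases[1:]):
            if cur.start_s != prev.end_s:
                raise ValueError(
                    f"phases must be contiguous: {prev.label!r} ends at "
                    f"{prev.end_s} s but {cur.label!r} starts at {cur.start_s} s"
                )
        if not any(p.label == "set" for p in self.phases):
            raise ValueError("timeline contains no exercise set")

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s

    @property
    def first_rep_s(self) -> float:
        """Start of the first exercise set (time of the first repetition)."""
        return next(p.start_s for p in self.phases if p.label == "set")

    @property
    def baseline(self) -> Phase:
        return next(p for p in self.phases if p.label == "baseline")

    @property
    def recovery(self) -> Phase:
        return next(p for p in self.phases if p.label == "recovery")

    def phases_labelled(self, label: str) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.label == label)

    def phase_at(self, t_s: float) -> Phase:
        for p in self.phases:
            if p.start_s <= t_s < p.end_s:
                return p
        if t_s == self.end_s:
            return self.phases[-1]
        raise ValueError(f"t = {t_s} s outside timeline [0, {self.end_s}]")

    def to_dict(self) -> dict:
        return {
            "phases": [
                {"label": p.label, "start_s": p.start_s, "end_s": p.end_s}
                for p in self.phases
            ],
            "first_rep_s": self.first_rep_s,
            "end_s": self.end_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionTimeline":
        return cls(
            tuple(Phase(p["label"], p["start_s"], p["end_s"]) for p in d["phases"])
        )


def make_default_timeline(
    set_durations_s: Sequence[float],
    baseline_s: float = 300.0,
    rest_s: float = 180.0,
    recovery_s: float = 300.0,
) -> SessionTimeline:
    """Build the standard protocol timeline.

    The protocol is a seated acclimation baseline, three (or more) exercise
    sets separated by fixed rests, and a seated recovery:
    baseline, set1, rest, set2, rest, ..., setN, recovery.

    Parameters
    ----------
    set_durations_s
        Duration of each exercise set in seconds. Sets are performed to
        exhaustion, so durations typically differ between sets.
    baseline_s, rest_s, recovery_s
        Durations of the acclimation baseline, the inter-set rest, and the
        final recovery. Defaults: 5 min baseline, 3 min rests, 5 min recovery.
    """
    durations: list[tuple[str, float]] = [("baseline", float(baseline_s))]
    for i, d in enumerate(set_durations_s):
        durations.append(("set", float(d)))
        if i < len(set_durations_s) - 1:
            durations.append(("rest", float(rest_s)))
    durations.append(("recovery", float(recovery_s)))

    for label, d in durations:
        if not d > 0:
            raise ValueError(f"non-positive duration for phase {label!r}: {d}")

    phases = []
    t = 0.0
    for label, d in durations:
        phases.append(Phase(label, t, t + d))
        t += d
    return SessionTimeline(tuple(phases))
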