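"""Experiment timeline for the sentence-completion paradigm.

The recording session starts with a 40-s device baseline (a 5-s count,
15 s eyes open, a 5-s countdown, 15 s eyes closed) and is followed by a
4-minute task in which blocks of four 5-s stimulus sentences alternate
with blocks of four 5-s control (nonsense) sentences.  This module encodes
that timeline as an explicit, queryable schedule used both to synthesize
recordings and to label analysis windows.

Event onsets and durations are kept as exact rationals (:class:`~fractions.Fraction`
of seconds) so that block boundaries never drift under float arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Sequence

__all__ = [
    "ParadigmEvent",
    "ParadigmSchedule",
    "BASELINE_KINDS",
    "TASK_KINDS",
    "DEFAULT_BASELINE_SEGMENTS",
    "build_schedule",
    "default_schedule",
    "label_interval",
]

BASELINE_KINDS = ("count", "eyes_open", "countdown", "eyes_closed")
TASK_KINDS = ("stimulus_sentence", "control_sentence")

#: Device baseline protocol: 5-s count, 15 s eyes open, 5-s countdown,
#: 15 s eyes closed — 40 s in total.
DEFAULT_BASELINE_SEGMENTS: tuple[tuple[str, int], ...] = (
    ("count", 5),
    ("eyes_open", 15),
    ("countdown", 5),
    ("eyes_closed", 15),
)


def _as_seconds(value) -> Fraction:
    """Coerce a time value to an exact Fraction of seconds.

    Integers and Fractions are taken verbatim; floats are snapped to the
    nearest rational with a modest denominator so that e.g. ``0.1`` means
    one tenth of a second, not its binary approximation.
    """
    if isinstance(value, Rational):
        return Fraction(value)
    return Fraction(float(value)).limit_denominator(1_000_000)


@dataclass(frozen=True)
class ParadigmEvent:
    """A single timeline event (baseline segment or sentence presentation)."""

    kind: str
    onset: Fraction
    duration: Fraction
    block_index: int
    sentence_index: int | None = None

    def __post_init__(self):
        if self.kind not in BASELINE_KINDS + TASK_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.onset < 0:
            raise ValueError("event onset must be non-negative")
        if self.block_index < 0:
            raise ValueError("block_index must be >= 0")

    @property
    def end(self) -> Fraction:
        return self.onset + self.duration

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "onset": float(self.onset),
            "duration": float(self.duration),
            "block_index": self.block_index,
            "sentence_index": self.sentence_index,
        }


@dataclass(frozen=True)
class ParadigmSchedule:
    """Ordered, non-overlapping timeline of baseline and task events."""

    events: tuple[ParadigmEvent, ...]
    baseline_duration: Fraction
    task_duration: Fraction

    def __post_init__(self):
        prev_end = Fraction(0)
        for ev in self.events:
            if ev.onset < prev_end:
                raise ValueError("events must be ordered and non-overlapping")
            prev_end = ev.end
        if self.events and self.events[-1].end != self.end:
            raise ValueError("last event must end at baseline + task duration")

    @property
    def task_onset(self) -> Fraction:
        """Seconds from recording start to the first task event (= baseline end)."""
        return self.baseline_duration

    @property
    def end(self) -> Fraction:
        return self.baseline_duration + self.task_duration

    @property
    def task_events(self) -> tuple[ParadigmEvent, ...]:
        return tuple(ev for ev in self.events if ev.kind in TASK_KINDS)

    def count(self, kind: str) -> int:
        return sum(1 for ev in self.events if ev.kind == kind)

    # -- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps([ev.to_dict() for ev in self.events], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParadigmSchedule":
        events = tuple(
            ParadigmEvent(
                kind=d["kind"],
                onset=_as_seconds(d["onset"]),
                duration=_as_seconds(d["duration"]),
                block_index=int(d["block_index"]),
                sentence_index=d.get("sentence_index"),
            )
            for d in json.loads(text)
        )
        baseline = sum(
            (ev.duration for ev in events if ev.kind in BASELINE_KINDS), Fraction(0)
        )
        task = sum(
            (ev.duration for ev in events if ev.kind in TASK_KINDS), Fraction(0)
        )
        return cls(events=events, baseline_duration=baseline, task_duration=task)


def build_schedule(
    sentence_duration_s=5,
    sentences_per_block: int = 4,
    task_duration_s=240,
    baseline_segments: Sequence[tuple[str, float]] = DEFAULT_BASELINE_SEGMENTS,
) -> ParadigmSchedule:
    """Build the alternating stimulus/control schedule.

    The task section consists of alternating blocks — stimulus first — each
    holding ``sentences_per_block`` consecutive events of
    ``sentence_duration_s`` seconds, until ``task_duration_s`` is filled.
    ``task_duration_s`` must therefore be an exact multiple of one
    stimulus+control cycle (2 × sentences_per_block × sentence_duration_s).

    With the defaults (5-s sentences, 4 per block, 240-s task) the schedule
    holds 24 stimulus and 24 control sentences after a 40-s baseline.
    """
    sentence_duration = _as_seconds(sentence_duration_s)
    task_duration = _as_seconds(task_duration_s)
    if sentence_duration <= 0:
        raise ValueError("sentence_duration_s must be positive")
    if sentences_per_block < 1:
        raise ValueError("sentences_per_block must be >= 1")
    cycle = 2 * sentences_per_block * sentence_duration
    residual = task_duration % cycle
    if residual != 0:
        raise ValueError(
            f"task_duration_s={task_duration_s} is not an exact multiple of a "
            f"stimulus+control cycle ({cycle} s); residual {float(residual)} s"
        )

    events: list[ParadigmEvent] = []
    t = Fraction(0)
    for kind, dur in baseline_segments:
        dur = _as_seconds(dur)
        events.append(ParadigmEvent(kind=kind, onset=t, duration=dur, block_index=0))
        t += dur
    baseline_duration = t

    n_blocks = int(task_duration / (sentences_per_block * sentence_duration))
    counters = {"stimulus_sentence": 0, "control_sentence": 0}
    for block in range(n_blocks):
        kind = TASK_KINDS[block % 2]
        for _ in range(sentences_per_block):
            events.append(
                ParadigmEvent(
                    kind=kind,
                    onset=t,
                    duration=sentence_duration,
                    block_index=block,
                    sentence_index=counters[kind],
                )
            )
            counters[kind] += 1
            t += sentence_duration

    return ParadigmSchedule(
        events=tuple(events),
        baseline_duration=baseline_duration,
        task_duration=task_duration,
    )


def default_schedule() -> ParadigmSchedule:
    """The published paradigm: 40-s baseline, 240-s task, 5-s sentences, 4/block."""
    return build_schedule()


def label_interval(schedule: ParadigmSchedule, start_s, end_s) -> str:
    """Label a half-open time interval ``[start_s, end_s)`` on the schedule.

    Returns the kind of the unique event that fully covers the interval,
    ``"pre_task"`` if the interval ends at or before the first task event,
    or ``"mixed"`` if it spans an event boundary.  Times are seconds from
    recording start (baseline included).
    """
    start = _as_seconds(start_s)
    end = _as_seconds(end_s)
    if start >= end:
        raise ValueError("interval start must precede its end")
    if end > schedule.end:
        raise ValueError(
            f"interval [{float(start)}, {float(end)}) extends beyond the "
            f"schedule end at {float(schedule.end)} s"
        )
    if end <= schedule.task_onset:
        return "pre_task"
    for ev in schedule.events:
        if ev.onset <= start and end <= ev.end:
            return ev.kind
    return "mixed"
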