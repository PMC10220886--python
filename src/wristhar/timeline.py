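"""Self-reported activity label timelines and overlap correction.

Free-living activity labels are entered by the participants themselves and
are therefore noisy: two intervals may claim the same stretch of time with
different activities.  Because the activities in the vocabulary (sitting at
a computer, standing still, walking, running, cycling) are mutually
exclusive, such overlaps are labeling mistakes, not multi-labeling, and the
overlapping time cannot be trusted for either label.  The correction
implemented here excises every overlap:

* partial overlap — the earlier interval's end is pulled back to the later
  interval's original start, and the later interval's start is pushed
  forward to the earlier interval's original end, so the contested span is
  removed from both;
* full containment — the enclosing interval is truncated at the nested
  interval's start and the nested interval is removed entirely;
* identical spans with different labels — both are removed (the
  longer/shorter rule is undefined there).

Intervals are half-open ``[start, end)`` so touching intervals never count
as overlapping.  Chains of more than two mutually overlapping intervals are
resolved by a left-to-right sweep in start order, re-checking every newly
edited pair until no overlap remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LabelInterval:
    """One labeled activity span, half-open ``[start, end)`` in seconds."""

    start: float
    end: float
    activity: str

    def __post_init__(self) -> None:
        if not self.activity:
            raise ValueError(f"interval [{self.start}, {self.end}) has an empty activity name")
        if not (self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) '{self.activity}': start must be < end"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "LabelInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Timeline:
    """A subject's ordered label intervals plus the class vocabulary."""

    subject_id: str
    intervals: list[LabelInterval]
    activity_vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)
        if not self.activity_vocabulary:
            self.activity_vocabulary = tuple(sorted({iv.activity for iv in self.intervals}))

    def sorted(self) -> "Timeline":
        ivs = sorted(self.intervals, key=lambda iv: (iv.start, -iv.duration))
        return replace(self, intervals=ivs)

    def total_duration(self) -> float:
        return float(sum(iv.duration for iv in self.intervals))

    def has_overlaps(self) -> bool:
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        return any(a.end > b.start for a, b in zip(ivs, ivs[1:]))


@dataclass
class CorrectionEdit:
    rule: str  # "partial" | "nested" | "tie"
    before: list[LabelInterval]
    after: list[LabelInterval]

    def to_dict(self) -> dict:
        as_t = lambda iv: [iv.start, iv.end, iv.activity]
        return {
            "rule": self.rule,
            "before": [as_t(iv) for iv in self.before],
            "after": [as_t(iv) for iv in self.after],
        }


@dataclass
class CorrectionLog:
    edits: list[CorrectionEdit] = field(default_factory=list)
    discarded_s: float = 0.0

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(e.to_dict()) for e in self.edits)


def _first_overlapping_pair(ivs: list[LabelInterval]) -> tuple[int, int] | None:
    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            if ivs[j].start >= ivs[i].end:
                break  # sorted by start: nothing later can overlap i
            return i, j
    return None


def correct_overlaps(timeline: Timeline) -> tuple[Timeline, CorrectionLog]:
    """Remove every pairwise overlap from a timeline.

    Returns the corrected timeline (sorted by start) and a log with one
    entry per applied edit plus the total labeled duration discarded.
    """
    work = sorted(timeline.intervals, key=lambda iv: (iv.start, -iv.duration))
    before_total = float(sum(iv.duration for iv in work))
    log = CorrectionLog()

    while True:
        work.sort(key=lambda iv: (iv.start, -iv.duration))
        pair = _first_overlapping_pair(work)
        if pair is None:
            break
        i, j = pair
        a, b = work[i], work[j]  # a starts first (or is longer on a start tie)

        if a.start == b.start and a.end == b.end:
            edit = CorrectionEdit("tie", [a, b], [])
            del work[j], work[i]
        elif b.end <= a.end:
            # b fully inside a: truncate the enclosing interval, drop the nested one
            after: list[LabelInterval] = []
            if a.start < b.start:
                after.append(LabelInterval(a.start, b.start, a.activity))
            edit = CorrectionEdit("nested", [a, b], after)
            del work[j], work[i]
            work.extend(after)
        else:
            # partial overlap: excise [b.start, a.end) from both
            after = []
            if a.start < b.start:
                after.append(LabelInterval(a.start, b.start, a.activity))
            if a.end < b.end:
                after.append(LabelInterval(a.end, b.end, b.activity))
            edit = CorrectionEdit("partial", [a, b], after)
            del work[j], work[i]
            work.extend(after)
        log.edits.append(edit)

    work.sort(key=lambda iv: iv.start)
    log.discarded_s = before_total - float(sum(iv.duration for iv in work))
    cleaned = Timeline(timeline.subject_id, work, timeline.activity_vocabulary)
    return cleaned, log


def durations_by_activity(timeline: Timeline) -> dict[str, float]:
    """Total labeled seconds per activity; vocabulary activities report 0."""
    out = {a: 0.0 for a in timeline.activity_vocabulary}
    for iv in timeline.intervals:
        out[iv.activity] = out.get(iv.activity, 0.0) + iv.duration
    return out


def usable_sensor_duration(timeline: Timeline, stream, bin_s: float = 1.0) -> dict[str, float]:
    """Labeled time actually covered by sensor samples, per activity.

    Each label interval is cut into one-second bins (from the interval
    start); a bin counts as covered when it contains at least the number of
    samples the nominal rate predicts, minus one sample of slack for edge
    alignment.  Sensor gaps therefore subtract whole seconds from the
    labeled totals, which is what distinguishes labeled duration from
    usable sensor duration.
    """
    out = {a: 0.0 for a in timeline.activity_vocabulary}
    ts = np.asarray(stream.timestamps, dtype=float)
    rate = float(stream.nominal_rate)
    for iv in timeline.intervals:
        edges = np.arange(iv.start, iv.end, bin_s)
        edges = np.append(edges, iv.end)
        counts = np.diff(np.searchsorted(ts, edges))
        widths = np.diff(edges)
        expected = widths * rate
        covered = counts >= np.maximum(expected - 1.0, 1.0)
        out[iv.activity] = out.get(iv.activity, 0.0) + float(widths[covered].sum())
    return out


# ---------------------------------------------------------------------------
# Label CSV schema: start_s,end_s,activity (half-open intervals)

def write_labels(timeline: Timeline, path) -> None:
    df = pd.DataFrame(
        [(iv.start, iv.end, iv.activity) for iv in timeline.intervals],
        columns=["start_s", "end_s", "activity"],
    )
    df.to_csv(path, index=False)


def read_labels(path, subject_id: str, vocabulary: Iterable[str] = ()) -> Timeline:
    df = pd.read_csv(path)
    ivs = [LabelInterval(r.start_s, r.end_s, r.activity) for r in df.itertuples()]
    return Timeline(subject_id, ivs, tuple(vocabulary))


def timeline_summary(timelines: Mapping[str, Timeline]) -> pd.DataFrame:
    """Per-subject labeled duration table (one column per activity)."""
    rows = {}
    for sid, tl in timelines.items():
        rows[sid] = durations_by_activity(tl)
    return pd.DataFrame(rows).T.fillna(0.0)
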