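"""Personalization/hold-out splits, time chunks and cumulative datasets.

Every subject's windows are split, per activity, into a small fixed-size
personalization set (the earliest windows totaling a per-activity labeled
time budget), a 2-minute leakage gap that is discarded, and a hold-out set
used to evaluate every model for that subject.  An activity is excluded
for a subject when the labeled time cannot cover the budget, the gap and
at least half the budget again for testing.

Independently, all windows are assigned to one of 8 chunks by absolute
time (the same boundaries for every subject, so late-starting subjects
have empty early chunks), and cumulative datasets CDS(k) = chunks 1..k
provide nested, growing training pools.  Leave-one-participant-out
training sets are CDS(k) minus the held-out subject's windows; subjects
absent from a CDS share one reusable general model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .signal import WINDOW_S, WindowDataset
from .timeline import Timeline

DEFAULT_BUDGET_MIN = {
    "computer_table": 120.0,
    "cycling": 10.0,
    "running": 10.0,
    "standing_still": 5.0,
    "walking": 10.0,
}
FRACTION_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)
N_CHUNKS = 8


@dataclass
class PersonalizationBudget:
    """Per-activity personalization budgets (minutes) and split rules."""

    minutes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BUDGET_MIN))
    gap_min: float = 2.0
    min_test_fraction: float = 0.5

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.minutes.values()) or self.gap_min <= 0 or self.min_test_fraction <= 0:
            raise ValueError("budgets, gap and test fraction must be positive")

    def seconds(self, activity: str) -> float:
        return self.minutes[activity] * 60.0

    @classmethod
    def demo(cls) -> "PersonalizationBudget":
        """Scaled-down budgets for the shipped demo cohort."""
        return cls(
            minutes={
                "computer_table": 12.0,
                "cycling": 3.0,
                "running": 3.0,
                "standing_still": 3.0,
                "walking": 3.0,
            },
            gap_min=0.5,
        )


@dataclass
class PartitionPlan:
    """Role (personalization / holdout / gap / excluded) and chunk index
    for every window.  ``table`` has one row per window with columns
    ``window_id, subject, activity, start_s, role, chunk``."""

    table: pd.DataFrame
    budget: PersonalizationBudget | None = None
    chunk_boundaries: np.ndarray | None = None

    def ids(self, **filters) -> set[int]:
        mask = np.ones(len(self.table), dtype=bool)
        for col, val in filters.items():
            mask &= (self.table[col] == val).to_numpy()
        return set(self.table.loc[mask, "window_id"])

    def personalization_ids(self, subject: str) -> set[int]:
        return self.ids(subject=subject, role="personalization")

    def holdout_ids(self, subject: str) -> set[int]:
        return self.ids(subject=subject, role="holdout")

    def subjects(self) -> list[str]:
        return sorted(self.table["subject"].unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cumtime_to_timestamp(intervals, target_s: float) -> float:
    """Timestamp at which cumulative labeled time reaches ``target_s``."""
    cum = 0.0
    for iv in intervals:
        if cum + iv.duration >= target_s:
            return iv.start + (target_s - cum)
        cum += iv.duration
    return intervals[-1].end if intervals else 0.0


def split_personalization(
    dataset: WindowDataset,
    timelines: Mapping[str, Timeline],
    budget: PersonalizationBudget | None = None,
) -> PartitionPlan:
    """Assign every window a personalization / gap / holdout / excluded role.

    ``timelines`` must be the *cleaned* timelines (one per subject) the
    windows were cut from; labeled time, not window count, drives the
    split, so overlapping windows at the budget boundary are handled
    consistently.
    """
    budget = budget or PersonalizationBudget()
    known = set(dataset.vocabulary)
    unknown = set(budget.minutes) - known if known else set()
    if unknown:
        raise ValueError(f"budget names activities missing from the vocabulary: {sorted(unknown)}")

    table = dataset.index.copy()
    table["role"] = "excluded"
    table["chunk"] = pd.NA

    for (subject, activity), grp in table.groupby(["subject", "activity"]):
        if activity not in budget.minutes:
            continue
        tl = timelines[subject]
        intervals = sorted(
            (iv for iv in tl.intervals if iv.activity == activity), key=lambda iv: iv.start
        )
        total = sum(iv.duration for iv in intervals)
        b = budget.seconds(activity)
        gap = budget.gap_min * 60.0
        if total < b + gap + budget.min_test_fraction * b:
            continue  # excluded: not enough data for budget + gap + minimum test
        t_split = _cumtime_to_timestamp(intervals, b)
        t_gap_end = _cumtime_to_timestamp(intervals, b + gap)
        starts = grp["start_s"].to_numpy()
        ends = starts + WINDOW_S
        role = np.where(
            ends <= t_split + 1e-9,
            "personalization",
            np.where(starts >= t_gap_end - 1e-9, "holdout", "gap"),
        )
        table.loc[grp.index, "role"] = role
    return PartitionPlan(table=table, budget=budget)


def assign_chunks(
    plan: PartitionPlan | WindowDataset,
    n_chunks: int = N_CHUNKS,
    boundaries: np.ndarray | None = None,
) -> PartitionPlan:
    """Assign each window a chunk index 1..n by absolute start time.

    Default boundaries are equal-duration bins over the pooled [min, max]
    window start times — the same split for all subjects, so a subject who
    started collecting late has empty early chunks.
    """
    if isinstance(plan, WindowDataset):
        table = plan.index.copy()
        table["role"] = "holdout"
        plan = PartitionPlan(table=table)
    table = plan.table.copy()
    starts = table["start_s"].to_numpy(dtype=float)
    if boundaries is None:
        if len(starts) == 0:
            raise ValueError("cannot derive chunk boundaries from an empty dataset")
        boundaries = np.linspace(starts.min(), starts.max(), n_chunks + 1)
    boundaries = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("chunk boundaries must be strictly increasing")
    chunk = np.searchsorted(boundaries, starts, side="right")
    chunk = np.clip(chunk, 1, len(boundaries) - 1)  # last boundary inclusive
    table["chunk"] = chunk
    return PartitionPlan(table=table, budget=plan.budget, chunk_boundaries=boundaries)


def make_cds(plan: PartitionPlan, k: int) -> set[int]:
    """Cumulative dataset k: all windows in chunks 1..k (nested in k)."""
    n = int(plan.table["chunk"].max()) if len(plan.table) else N_CHUNKS
    if not 1 <= k <= max(n, N_CHUNKS):
        raise ValueError(f"k must be in 1..{max(n, N_CHUNKS)}, got {k}")
    mask = plan.table["chunk"].notna() & (plan.table["chunk"] <= k)
    return set(plan.table.loc[mask, "window_id"])


def lopo_training_set(
    plan: PartitionPlan, cds_k: int, held_out_subject: str
) -> tuple[set[int], tuple]:
    """CDS(k) minus the held-out subject's windows, plus a reuse key.

    Subjects with no windows of their own in CDS(k) all receive the same
    reuse key, so one general model trained on the full CDS serves them.
    """
    if held_out_subject not in set(plan.table["subject"]):
        raise ValueError(f"unknown subject {held_out_subject!r}")
    cds = make_cds(plan, cds_k)
    own = plan.ids(subject=held_out_subject) & cds
    training = cds - own
    if not own:
        reuse_key = ("full_cds", cds_k)
    else:
        reuse_key = ("lopo", cds_k, held_out_subject)
    if not training:
        warnings.warn(
            f"LOPO training set for {held_out_subject} at CDS {cds_k} is empty", stacklevel=2
        )
    return training, reuse_key


def personalization_fraction(
    plan: PartitionPlan,
    subject: str,
    fraction: float,
    allow_any_fraction: bool = False,
) -> set[int]:
    """Time-ordered prefix of the personalization set: floor(fraction*n)
    windows per activity.  Prefixes nest across the fraction grid."""
    if not allow_any_fraction and not any(np.isclose(fraction, f) for f in FRACTION_GRID):
        raise ValueError(f"fraction {fraction} not in the grid {FRACTION_GRID}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    sub = plan.table[
        (plan.table["subject"] == subject) & (plan.table["role"] == "personalization")
    ]
    out: set[int] = set()
    for _, grp in sub.groupby("activity"):
        grp = grp.sort_values("start_s")
        n_take = int(np.floor(fraction * len(grp) + 1e-9))
        out.update(grp["window_id"].iloc[:n_take])
    return out
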