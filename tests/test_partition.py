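"""Personalization/hold-out splits, chunking, CDS and LOPO sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wristhar.partition import (
    FRACTION_GRID,
    PartitionPlan,
    PersonalizationBudget,
    assign_chunks,
    lopo_training_set,
    make_cds,
    personalization_fraction,
    split_personalization,
)
from wristhar.signal import WindowDataset, segment_windows
from wristhar.timeline import LabelInterval, Timeline

from conftest import gapless_stream


def windows_for(subject: str, activity: str, duration_s: float, start_s: float = 0.0):
    """Windows plus cleaned timeline for one gapless labeled interval."""
    stream = gapless_stream(subject, duration_s + 1, start_s=start_s)
    tl = Timeline(subject, [LabelInterval(start_s, start_s + duration_s, activity)],
                  activity_vocabulary=("computer_table", "cycling", "walking"))
    return segment_windows(stream, tl), tl


BUDGET = PersonalizationBudget(minutes={"computer_table": 120.0, "cycling": 10.0, "walking": 10.0})


class TestSplitPersonalization:
    def test_120min_budget_yields_1199_personalization_windows(self):
        # 120 min budget + 2 min gap + 60 min of hold-out, one gapless interval
        ds, tl = windows_for("p14", "computer_table", (120 + 2 + 60) * 60.0)
        plan = split_personalization(ds, {"p14": tl}, BUDGET)
        assert len(plan.personalization_ids("p14")) == 1199
        # hold-out windows begin after the 2-minute leakage gap
        holdout_starts = plan.table.loc[plan.table["role"] == "holdout", "start_s"]
        assert holdout_starts.min() >= (120 + 2) * 60.0 - 1e-9

    def test_subject_with_no_data_for_an_activity_is_excluded(self):
        ds, tl = windows_for("p9", "cycling", 20 * 60.0)
        plan = split_personalization(ds, {"p9": tl}, BUDGET)
        # no computer-table data at all: that activity contributes 0/0 windows
        assert len(plan.ids(subject="p9", activity="computer_table")) == 0
        # while the activity with data is retained
        assert len(plan.personalization_ids("p9")) > 0

    def test_exactly_budget_duration_fails_min_test_rule(self):
        ds, tl = windows_for("s", "cycling", 10 * 60.0)
        plan = split_personalization(ds, {"s": tl}, BUDGET)
        assert (plan.table["role"] == "excluded").all()

    def test_retained_activity_has_at_least_half_budget_of_holdout_time(self):
        for minutes in (16, 18, 25):
            ds, tl = windows_for("s", "cycling", minutes * 60.0)
            plan = split_personalization(ds, {"s": tl}, BUDGET)
            roles = set(plan.table["role"])
            if minutes * 60 < (10 + 2 + 5) * 60:
                assert roles == {"excluded"}
            else:
                holdout = plan.table[plan.table["role"] == "holdout"]
                holdout_span = (
                    holdout["start_s"].max() + 12.0 - holdout["start_s"].min()
                )
                assert holdout_span >= 0.5 * 10 * 60 - 12.0

    def test_personalization_and_holdout_never_intersect(self):
        ds, tl = windows_for("s", "cycling", 30 * 60.0)
        plan = split_personalization(ds, {"s": tl}, BUDGET)
        assert not (plan.personalization_ids("s") & plan.holdout_ids("s"))

    def test_unknown_budget_activity_rejected(self):
        ds, tl = windows_for("s", "cycling", 5 * 60.0)
        bad = PersonalizationBudget(minutes={"swimming": 5.0})
        with pytest.raises(ValueError, match="missing from the vocabulary"):
            split_personalization(ds, {"s": tl}, bad)


class TestChunksAndCDS:
    @pytest.fixture()
    def pooled_plan(self):
        dss = []
        tls = {}
        for i, start in enumerate([0.0, 0.0, 5000.0]):
            ds, tl = windows_for(f"s{i}", "cycling", 1200.0, start_s=start)
            dss.append(ds)
            tls[f"s{i}"] = tl
        pooled = WindowDataset.concat(dss)
        return assign_chunks(pooled, n_chunks=8)

    def test_chunk_indices_nondecreasing_in_time_per_subject(self, pooled_plan):
        for _, grp in pooled_plan.table.groupby("subject"):
            ordered = grp.sort_values("start_s")["chunk"].to_numpy(dtype=float)
            assert np.all(np.diff(ordered) >= 0)

    def test_late_starting_subject_has_empty_early_chunks(self, pooled_plan):
        s2 = pooled_plan.table[pooled_plan.table["subject"] == "s2"]
        assert s2["chunk"].min() > 3

    def test_custom_boundaries_equal_to_default_give_identical_assignment(self, pooled_plan):
        again = assign_chunks(
            PartitionPlan(pooled_plan.table.drop(columns="chunk").assign(chunk=pd.NA)),
            boundaries=pooled_plan.chunk_boundaries,
        )
        assert (again.table["chunk"] == pooled_plan.table["chunk"]).all()

    def test_nonincreasing_boundaries_rejected(self, pooled_plan):
        with pytest.raises(ValueError, match="strictly increasing"):
            assign_chunks(PartitionPlan(pooled_plan.table), boundaries=np.array([0.0, 0.0, 1.0]))

    def test_cds_nesting_and_bounds(self, pooled_plan):
        sizes = []
        prev: set[int] = set()
        for k in range(1, 9):
            cds = make_cds(pooled_plan, k)
            assert prev <= cds
            sizes.append(len(cds))
            prev = cds
        assert sizes == sorted(sizes)
        assert make_cds(pooled_plan, 8) == set(pooled_plan.table["window_id"])
        with pytest.raises(ValueError, match="k must be"):
            make_cds(pooled_plan, 0)

    def test_lopo_training_sets(self, pooled_plan):
        full_cds1 = make_cds(pooled_plan, 1)
        # s2 is absent from early chunks: training set is the full CDS
        ids2, key2 = lopo_training_set(pooled_plan, 1, "s2")
        assert ids2 == full_cds1
        # a second absent subject would share the same reuse key
        assert key2 == ("full_cds", 1)
        ids0, key0 = lopo_training_set(pooled_plan, 1, "s0")
        assert key0 != key2
        assert ids0 == full_cds1 - pooled_plan.ids(subject="s0")
        with pytest.raises(ValueError, match="unknown subject"):
            lopo_training_set(pooled_plan, 1, "nobody")

    def test_union_of_lopo_sets_at_full_cds_covers_everything(self, pooled_plan):
        union: set[int] = set()
        for s in pooled_plan.subjects():
            union |= lopo_training_set(pooled_plan, 8, s)[0]
        assert union == make_cds(pooled_plan, 8)

    def test_single_owner_training_set_is_empty_and_flagged(self):
        ds, tl = windows_for("only", "cycling", 600.0)
        plan = assign_chunks(ds, n_chunks=2)
        with pytest.warns(UserWarning, match="empty"):
            ids, _ = lopo_training_set(plan, 2, "only")
        assert ids == set()


class TestPersonalizationFractions:
    @pytest.fixture()
    def plan(self):
        ds, tl = windows_for("s", "cycling", 18 * 60.0)
        return split_personalization(ds, {"s": tl}, BUDGET)

    def test_full_fraction_is_the_whole_personalization_set(self, plan):
        assert personalization_fraction(plan, "s", 1.0) == plan.personalization_ids("s")

    def test_fraction_of_99_windows_takes_floor(self, plan):
        assert len(plan.personalization_ids("s")) == 99  # 10-min budget
        assert len(personalization_fraction(plan, "s", 0.2)) == 19

    def test_fractions_nest(self, plan):
        prev: set[int] = set()
        for f in FRACTION_GRID:
            cur = personalization_fraction(plan, "s", f)
            assert prev <= cur
            prev = cur

    def test_off_grid_fraction_rejected_unless_allowed(self, plan):
        with pytest.raises(ValueError, match="not in the grid"):
            personalization_fraction(plan, "s", 0.5)
        assert personalization_fraction(plan, "s", 0.5, allow_any_fraction=True)
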