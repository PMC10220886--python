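"""Statistical structure and determinism of the synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import periodogram

from wristhar.signal import RATE_HZ
from wristhar.synthetic import (
    ACTIVITIES,
    CONTROLLED_ACTIVITIES,
    GenerationConfig,
    LabelNoiseConfig,
    SubjectProfile,
    draw_profile,
    generate_cohort,
    read_cohort,
    shifted_profile,
    write_cohort,
)
from wristhar.timeline import durations_by_activity


def quiet_profile(subject_id="s00", seed=0, **overrides) -> SubjectProfile:
    """A drawn profile with interruption generation switched off."""
    import dataclasses

    p = draw_profile(subject_id, np.random.default_rng(seed))
    return dataclasses.replace(p, interruption_rate_per_min=0.0, **overrides)


class TestControlledMode:
    def test_exact_durations_and_zero_label_noise(self):
        cfg = GenerationConfig.controlled(n_subjects=10, duration_s=60.0, seed=3)
        streams, reports, truths = generate_cohort(cfg)
        assert len(streams) == 10
        for rep, tru in zip(reports, truths):
            assert sum(durations_by_activity(rep).values()) == pytest.approx(240.0)
            assert not rep.has_overlaps()
            assert [(i.start, i.end, i.activity) for i in rep.intervals] == [
                (i.start, i.end, i.activity) for i in tru.intervals
            ]

    def test_controlled_rate_is_50_hz(self):
        cfg = GenerationConfig.controlled(n_subjects=1, seed=0)
        streams, _, _ = generate_cohort(cfg)
        assert streams[0].nominal_rate == 50.0
        dt = np.diff(streams[0].timestamps[:50])
        assert np.allclose(dt, 1 / 50.0)


class TestDeterminism:
    def test_same_seed_reproduces_streams_and_labels_exactly(self):
        cfg = GenerationConfig(n_subjects=2, seed=42,
                               activity_durations_s={a: 120.0 for a in ACTIVITIES})
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for sa, sb in zip(a[0], b[0]):
            assert np.array_equal(sa.timestamps, sb.timestamps)
            assert np.array_equal(sa.values, sb.values)
        for ta, tb in zip(a[1], b[1]):
            assert [(i.start, i.end, i.activity) for i in ta.intervals] == [
                (i.start, i.end, i.activity) for i in tb.intervals
            ]

    def test_subject_streams_do_not_depend_on_cohort_size(self):
        small = GenerationConfig(n_subjects=1, seed=5,
                                 activity_durations_s={a: 60.0 for a in ACTIVITIES})
        big = GenerationConfig(n_subjects=3, seed=5,
                               activity_durations_s={a: 60.0 for a in ACTIVITIES})
        sa = generate_cohort(small)[0][0]
        sb = generate_cohort(big)[0][0]
        assert np.array_equal(sa.values, sb.values)


class TestSignalStructure:
    def test_walking_periodogram_peaks_at_the_subject_cadence(self):
        profile = quiet_profile(seed=2)
        cfg = GenerationConfig(
            n_subjects=1, seed=2,
            activity_durations_s={"walking": 120.0},
            activities=("walking",),
            label_noise=LabelNoiseConfig(0, 0, 0), gap_rate_per_hour=0.0,
        )
        streams, _, truths = generate_cohort(cfg, [profile])
        iv = truths[0].intervals[0]
        st = streams[0]
        sel = (st.timestamps >= iv.start) & (st.timestamps < iv.end)
        vals = st.values[sel] - st.values[sel].mean(axis=0)
        psd = sum(periodogram(vals[:, i], fs=32.0)[1] for i in range(3))
        freqs = periodogram(vals[:, 0], fs=32.0)[0]
        peak = freqs[np.argmax(psd)]
        assert abs(peak - profile.cadence_hz["walking"]) < 0.1

    def test_static_bout_norm_is_one_g_within_five_percent(self):
        profile = quiet_profile(seed=4)
        cfg = GenerationConfig(
            n_subjects=1, seed=4,
            activity_durations_s={"computer_table": 120.0},
            activities=("computer_table",),
            label_noise=LabelNoiseConfig(0, 0, 0), gap_rate_per_hour=0.0,
        )
        streams, _, _ = generate_cohort(cfg, [profile])
        norms = np.linalg.norm(streams[0].values, axis=1)
        assert abs(norms.mean() - 1.0) < 0.05

    def test_unrotating_a_stream_recovers_the_identity_template(self):
        import dataclasses

        profile = quiet_profile(seed=6)
        template_profile = dataclasses.replace(profile, wrist_rotation=np.eye(3))
        cfg = GenerationConfig(
            n_subjects=1, seed=6,
            activity_durations_s={a: 60.0 for a in ACTIVITIES},
        )
        rotated = generate_cohort(cfg, [profile])[0][0]
        template = generate_cohort(cfg, [template_profile])[0][0]
        unrotated = rotated.values @ profile.wrist_rotation
        assert np.allclose(unrotated, template.values, atol=1e-12)

    def test_shifted_profile_is_a_large_proper_rotation(self):
        p = quiet_profile(seed=1)
        s = shifted_profile(p, np.random.default_rng(0))
        R_rel = s.wrist_rotation @ p.wrist_rotation.T
        angle = np.degrees(np.arccos(np.clip((np.trace(R_rel) - 1) / 2, -1, 1)))
        assert angle > 90.0
        assert np.isclose(np.linalg.det(s.wrist_rotation), 1.0)


class TestLabelNoise:
    def test_noise_free_real_world_report_matches_truth_up_to_jitter(self):
        jitter = 3.0
        cfg = GenerationConfig(
            n_subjects=1, seed=9,
            activity_durations_s={a: 300.0 for a in ACTIVITIES},
            label_noise=LabelNoiseConfig(overlap_prob=0.0, boundary_jitter_sd_s=jitter,
                                         mislabel_prob=0.0),
            gap_rate_per_hour=0.0,
        )
        profile = quiet_profile(seed=9)
        _, reports, truths = generate_cohort(cfg, [profile])
        rep, tru = reports[0], truths[0]
        assert len(rep.intervals) == len(tru.intervals)
        for r, t in zip(sorted(rep.intervals, key=lambda i: i.start),
                        sorted(tru.intervals, key=lambda i: i.start)):
            assert r.activity == t.activity
            assert abs(r.start - t.start) < 8 * jitter
            assert abs(r.end - t.end) < 8 * jitter

    def test_overlap_frequency_matches_configuration(self):
        # ~200 adjacent bout pairs; overlap count must sit in binomial 99% bounds
        p = 0.3
        cfg = GenerationConfig(
            n_subjects=1, seed=13,
            activity_durations_s={"walking": 10_000.0, "running": 10_000.0},
            activities=("walking", "running"),
            max_bout_s={"walking": 100.0, "running": 100.0},
            label_noise=LabelNoiseConfig(overlap_prob=p, boundary_jitter_sd_s=0.0,
                                         mislabel_prob=0.0),
            gap_rate_per_hour=0.0,
        )
        profile = quiet_profile(seed=13)
        _, reports, _ = generate_cohort(cfg, [profile])
        ivs = sorted(reports[0].intervals, key=lambda i: i.start)
        n_pairs = len(ivs) - 1
        n_overlaps = sum(a.end > b.start for a, b in zip(ivs, ivs[1:]))
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], n_pairs, p)
        assert n_pairs >= 190
        assert lo <= n_overlaps <= hi


class TestValidationAndIO:
    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError, match="must be >= 0"):
            GenerationConfig(n_subjects=1, activity_durations_s={"walking": -5.0})
        with pytest.raises(ValueError, match="n_subjects"):
            GenerationConfig(n_subjects=0)

    def test_write_read_round_trip(self, tmp_path):
        cfg = GenerationConfig(n_subjects=2, seed=1,
                               activity_durations_s={a: 30.0 for a in ACTIVITIES})
        streams, reports, _ = generate_cohort(cfg)
        manifest = write_cohort(streams, reports, tmp_path)
        assert len(manifest) == 2
        assert manifest[0]["n_rows"] == len(streams[0])
        back_streams, back_timelines = read_cohort(tmp_path, nominal_rate=32.0)
        for a, b in zip(streams, back_streams):
            assert np.allclose(a.timestamps, b.timestamps)
            assert np.allclose(a.values, b.values)
        for a, b in zip(reports, back_timelines):
            got = [(i.start, i.end, i.activity) for i in b.intervals]
            want = [(pytest.approx(i.start), pytest.approx(i.end), i.activity) for i in a.intervals]
            assert got == want

    def test_empty_cohort_manifest(self, tmp_path):
        assert write_cohort([], [], tmp_path) == []

    def test_ten_seconds_at_32_hz_writes_320_rows(self, tmp_path):
        profile = quiet_profile(seed=3)
        cfg = GenerationConfig(n_subjects=1, seed=3,
                               activity_durations_s={"walking": 10.0},
                               activities=("walking",),
                               label_noise=LabelNoiseConfig(0, 0, 0), gap_rate_per_hour=0.0)
        streams, reports, _ = generate_cohort(cfg, [profile])
        manifest = write_cohort(streams, reports, tmp_path)
        assert manifest[0]["n_rows"] == 320
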