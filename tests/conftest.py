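"""Shared fixtures: small synthetic streams, timelines and cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from wristhar.signal import SensorStream
from wristhar.timeline import LabelInterval, Timeline

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def gapless_stream(subject: str, duration_s: float, rate: float = 32.0,
                   start_s: float = 0.0) -> SensorStream:
    """A constant-zero stream with exact 1/rate spacing."""
    n = int(round(duration_s * rate))
    t = start_s + np.arange(n) / rate
    return SensorStream(subject, t, np.zeros((n, 3)), rate)


def single_interval_timeline(subject: str, duration_s: float, activity: str = "walking",
                             start_s: float = 0.0) -> Timeline:
    return Timeline(subject, [LabelInterval(start_s, start_s + duration_s, activity)])


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 3-subject real-world cohort with all noise sources active."""
    from wristhar.synthetic import ACTIVITIES, GenerationConfig, generate_cohort

    cfg = GenerationConfig(
        n_subjects=3,
        activity_durations_s={a: 240.0 for a in ACTIVITIES},
        seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort):
    """Cleaned and windowed version of the tiny cohort."""
    from wristhar.signal import WindowDataset, segment_windows
    from wristhar.timeline import correct_overlaps

    _, (streams, reports, _) = tiny_cohort
    timelines = {}
    parts = []
    for stream, tl in zip(streams, reports):
        cleaned, _ = correct_overlaps(tl)
        timelines[stream.subject_id] = cleaned
        parts.append(segment_windows(stream, cleaned))
    return WindowDataset.concat(parts), timelines


@pytest.fixture(scope="session")
def two_class_windows():
    """Linearly separable 2-class window set for quick training checks.

    Class 0 carries a 1.2 Hz sinusoid on X, class 1 a 2.6 Hz sinusoid on
    Y, both over small noise — separable by any functioning conv stack.
    """
    rng = np.random.default_rng(11)
    n = 200
    t = np.arange(384) / 32.0
    X = 0.05 * rng.standard_normal((n, 3, 384))
    y = np.arange(n) % 2
    for i in range(n):
        if y[i] == 0:
            X[i, 0] += np.sin(2 * np.pi * 1.2 * t)
        else:
            X[i, 1] += np.sin(2 * np.pi * 2.6 * t)
    return X, y
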