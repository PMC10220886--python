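"""Synthetic multi-participant wrist-accelerometer cohorts.

The generator emulates the structure of free-living activity-recognition
data collected with a wrist-worn accelerometer and self-reported labels,
at two levels of messiness:

* ``real_world`` — 32 Hz streams; bouts of five activities scattered over a
  collection span with unlabeled time in between; activity interruptions
  (a short burst of a different activity inside a bout); self-report label
  noise (boundary jitter, overlapping labels, occasional mislabels,
  interruptions absorbed into the surrounding label); sensor gaps; and a
  subject-specific wrist orientation applied to the whole stream.
* ``controlled`` — 50 Hz streams; uninterrupted exact-duration bouts of
  four activities in a fixed protocol order, zero label noise, no gaps,
  fixed (identity) device orientation.

Per activity bout the signal is a sum of a gravity component (a posture
unit vector scaled to 1 g), a periodic component at the subject's cadence
with three harmonics at fixed relative amplitudes (1, 0.4, 0.15) for
locomotion, and white Gaussian noise; the subject's wrist rotation is
applied last, so un-rotating a stream recovers the same-seed unrotated
template exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .signal import SensorStream
from .timeline import LabelInterval, Timeline

ACTIVITIES = ("computer_table", "standing_still", "walking", "running", "cycling")
LOCOMOTION = ("walking", "running", "cycling")
STATIC = ("computer_table", "standing_still")
CONTROLLED_ACTIVITIES = ("standing_still", "walking", "running", "cycling")
HARMONIC_WEIGHTS = (1.0, 0.4, 0.15)

CADENCE_RANGES = {"walking": (1.6, 2.2), "running": (2.4, 3.2), "cycling": (0.8, 1.5)}
AMPLITUDE_RANGES = {
    "walking": (0.25, 0.6),
    "running": (0.8, 1.6),
    "cycling": (0.15, 0.4),
    "computer_table": (0.01, 0.03),
    "standing_still": (0.01, 0.03),
}
# arm posture while the activity is performed, in the device frame before
# the per-subject wrist rotation (unit vectors)
_POSTURE_BASE = {
    "computer_table": np.array([0.1, -0.7, 0.7]),
    "standing_still": np.array([-0.9, 0.3, 0.2]),
    "walking": np.array([-0.9, 0.2, 0.3]),
    "running": np.array([-0.5, 0.6, 0.6]),
    "cycling": np.array([0.2, -0.8, 0.5]),
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = _unit(np.asarray(axis, dtype=float))
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_wrist_rotation(rng: np.random.Generator, max_angle_deg: float = 45.0) -> np.ndarray:
    """Random placement rotation: uniform axis, uniform angle in [0, max]."""
    axis = _unit(rng.standard_normal(3))
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    return rotation_about_axis(axis, angle)


@dataclass
class SubjectProfile:
    """Per-participant signal characteristics.

    ``wrist_rotation`` models dominant vs non-dominant arm and band
    placement; ``labeling_bias`` is the probability that a short
    interruption is absorbed into the surrounding self-report label.
    """

    subject_id: str
    cadence_hz: dict[str, float]
    amplitude_g: dict[str, float]
    wrist_rotation: np.ndarray
    posture_gravity: dict[str, np.ndarray]
    labeling_bias: float
    interruption_rate_per_min: float
    noise_sd_g: float

    def __post_init__(self) -> None:
        R = np.asarray(self.wrist_rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("wrist_rotation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("wrist_rotation must be proper (determinant +1)")
        self.wrist_rotation = R
        for act, g in self.posture_gravity.items():
            g = np.asarray(g, dtype=float)
            if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-8):
                raise ValueError(f"posture_gravity[{act}] must be a unit vector")
            self.posture_gravity[act] = g
        for act, (lo, hi) in CADENCE_RANGES.items():
            if act in self.cadence_hz and not (0 < self.cadence_hz[act]):
                raise ValueError(f"cadence for {act} must be positive")
        if not 0.0 <= self.labeling_bias <= 1.0:
            raise ValueError("labeling_bias must be in [0, 1]")
        if self.interruption_rate_per_min < 0 or self.noise_sd_g <= 0:
            raise ValueError("rates must be >= 0 and noise_sd_g > 0")


@dataclass
class LabelNoiseConfig:
    overlap_prob: float = 0.1
    boundary_jitter_sd_s: float = 5.0
    mislabel_prob: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.overlap_prob, self.mislabel_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.boundary_jitter_sd_s < 0:
            raise ValueError("boundary_jitter_sd_s must be >= 0")


@dataclass
class GenerationConfig:
    """Cohort-level knobs: mode, sizes, rates, label noise, seed."""

    mode: str = "real_world"
    n_subjects: int = 6
    activity_durations_s: dict[str, float] = field(default_factory=dict)
    sampling_rate_hz: float = 32.0
    collection_start_s: float = 0.0
    label_noise: LabelNoiseConfig = field(default_factory=LabelNoiseConfig)
    gap_rate_per_hour: float = 1.0
    seed: int = 0
    activities: tuple[str, ...] = ACTIVITIES
    max_bout_s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("real_world", "controlled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.gap_rate_per_hour < 0:
            raise ValueError("gap_rate_per_hour must be >= 0")
        if not self.activity_durations_s:
            if self.mode == "controlled":
                self.activity_durations_s = {a: 60.0 for a in self.activities}
            else:
                self.activity_durations_s = {a: 600.0 for a in self.activities}
        for a, d in self.activity_durations_s.items():
            if d < 0:
                raise ValueError(f"duration for {a} must be >= 0")

    @classmethod
    def controlled(cls, n_subjects: int = 10, duration_s: float = 60.0, seed: int = 0, **kw):
        return cls(
            mode="controlled",
            n_subjects=n_subjects,
            activities=CONTROLLED_ACTIVITIES,
            activity_durations_s={a: duration_s for a in CONTROLLED_ACTIVITIES},
            sampling_rate_hz=50.0,
            label_noise=LabelNoiseConfig(0.0, 0.0, 0.0),
            gap_rate_per_hour=0.0,
            seed=seed,
            **kw,
        )


def draw_profile(
    subject_id: str, rng: np.random.Generator, mode: str = "real_world"
) -> SubjectProfile:
    """Draw one subject's characteristics from the population ranges."""
    cadence = {a: rng.uniform(*CADENCE_RANGES[a]) for a in LOCOMOTION}
    amplitude = {a: rng.uniform(*AMPLITUDE_RANGES[a]) for a in ACTIVITIES}
    posture = {}
    for act, base in _POSTURE_BASE.items():
        posture[act] = _unit(_unit(base) + 0.15 * rng.standard_normal(3))
    if mode == "controlled":
        R = np.eye(3)  # fixed protocol placement
    else:
        R = random_wrist_rotation(rng)
    return SubjectProfile(
        subject_id=subject_id,
        cadence_hz=cadence,
        amplitude_g=amplitude,
        wrist_rotation=R,
        posture_gravity=posture,
        labeling_bias=rng.uniform(0.4, 0.9),
        interruption_rate_per_min=rng.uniform(0.1, 0.4),
        noise_sd_g=rng.uniform(0.02, 0.05),
    )


def shifted_profile(profile: SubjectProfile, rng: np.random.Generator,
                    angle_deg: float = 150.0) -> SubjectProfile:
    """A copy of ``profile`` with a wrist orientation far outside the
    population's placement range (e.g. the band worn upside-down on the
    other arm) — the distribution-shifted target personalization exists for."""
    axis = _unit(rng.standard_normal(3))
    return replace(profile, wrist_rotation=rotation_about_axis(axis, np.deg2rad(angle_deg)))


def _bout_signal(
    activity: str,
    n: int,
    rate: float,
    profile: SubjectProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unrotated (N, 3) signal for one bout, in g."""
    t = np.arange(n) / rate
    g_dir = profile.posture_gravity[activity]
    out = np.tile(g_dir, (n, 1)).astype(float)
    amp = profile.amplitude_g[activity]
    if activity in LOCOMOTION:
        f = profile.cadence_hz[activity]
        # two orthonormal axes spanning the plane transverse to gravity
        u1 = _unit(np.cross(g_dir, [0.0, 0.0, 1.0] if abs(g_dir[2]) < 0.9 else [0.0, 1.0, 0.0]))
        u2 = np.cross(g_dir, u1)
        s1 = np.zeros(n)
        s2 = np.zeros(n)
        for h, w in enumerate(HARMONIC_WEIGHTS, start=1):
            phase = rng.uniform(0, 2 * np.pi)
            s1 += w * np.sin(2 * np.pi * h * f * t + phase)
            s2 += 0.5 * w * np.cos(2 * np.pi * h * f * t + phase)
        out += amp * (np.outer(s1, u1) + np.outer(s2, u2))
    else:
        # slow postural sway
        f = 0.25
        phase = rng.uniform(0, 2 * np.pi)
        sway = amp * np.sin(2 * np.pi * f * t + phase)
        out[:, 0] += sway
    out += profile.noise_sd_g * rng.standard_normal((n, 3))
    return out


def _plan_bouts(
    config: GenerationConfig, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """Split per-activity targets into bouts and shuffle their order."""
    default_max = {"computer_table": 900.0}
    bouts: list[tuple[str, float]] = []
    for act in config.activities:
        total = config.activity_durations_s.get(act, 0.0)
        max_bout = config.max_bout_s.get(act, default_max.get(act, 120.0))
        while total > 1e-9:
            d = min(total, max_bout)
            bouts.append((act, d))
            total -= d
    order = rng.permutation(len(bouts))
    return [bouts[i] for i in order]


def _generate_subject(
    profile: SubjectProfile, config: GenerationConfig, rng: np.random.Generator
) -> tuple[SensorStream, Timeline, Timeline]:
    rate = config.sampling_rate_hz
    noise = config.label_noise
    controlled = config.mode == "controlled"

    if controlled:
        bouts = [(a, config.activity_durations_s[a]) for a in config.activities]
        t_cursor = config.collection_start_s
    else:
        bouts = _plan_bouts(config, rng)
        span_offset = rng.uniform(0.0, 0.25) * sum(d for _, d in bouts) * 2.0
        t_cursor = config.collection_start_s + span_offset

    seg_values: list[np.ndarray] = []
    seg_times: list[np.ndarray] = []
    truth: list[LabelInterval] = []
    report_blocks: list[list[LabelInterval]] = []  # one block per bout

    for act, dur in bouts:
        n = int(round(dur * rate))
        t0 = t_cursor
        t = t0 + np.arange(n) / rate

        # interruptions: short segments of a different activity inside the bout
        cuts: list[tuple[float, float, str]] = []
        if not controlled and profile.interruption_rate_per_min > 0 and dur > 60:
            k = rng.poisson(profile.interruption_rate_per_min * dur / 60.0)
            others = [a for a in config.activities if a != act]
            for _ in range(k):
                ilen = rng.uniform(5.0, 30.0)
                istart = rng.uniform(0.0, max(dur - ilen, 0.0))
                span = (t0 + istart, t0 + istart + ilen)
                if all(span[1] <= s or span[0] >= e for s, e, _ in cuts):
                    cuts.append((span[0], span[1], others[rng.integers(len(others))]))
        cuts.sort()

        vals = _bout_signal(act, n, rate, profile, rng)
        for cs, ce, cact in cuts:
            sel = (t >= cs) & (t < ce)
            vals[sel] = _bout_signal(cact, int(sel.sum()), rate, profile, rng)

        seg_values.append(vals)
        seg_times.append(t)

        # ground truth: bout split at interruption boundaries
        edges = [t0] + [x for cs, ce, _ in cuts for x in (cs, ce)] + [t0 + dur]
        acts = []
        for i in range(len(edges) - 1):
            inside = next((c for c in cuts if np.isclose(c[0], edges[i])), None)
            acts.append(inside[2] if inside else act)
        bout_truth = [
            LabelInterval(s, e, a) for s, e, a in zip(edges[:-1], edges[1:], acts) if e - s > 1e-9
        ]
        truth.extend(bout_truth)

        # self report: maybe absorb interruptions, then jitter the bout edges
        block: list[LabelInterval] = []
        if cuts and rng.uniform() < profile.labeling_bias:
            block = [LabelInterval(t0, t0 + dur, act)]
        else:
            block = list(bout_truth)
        report_blocks.append(block)

        t_cursor = t0 + dur + (10.0 if controlled else rng.uniform(10.0, 60.0))

    # --- self-report noise (real-world only) -------------------------------
    report: list[LabelInterval] = []
    if controlled:
        report = [iv for block in report_blocks for iv in block]
    else:
        jittered: list[list[LabelInterval]] = []
        for block in report_blocks:
            if not block:
                continue
            ds = rng.normal(0.0, noise.boundary_jitter_sd_s)
            de = rng.normal(0.0, noise.boundary_jitter_sd_s)
            s0, e0 = block[0].start, block[-1].end
            s1 = min(s0 + ds, e0 - 1.0)
            e1 = max(e0 + de, s1 + 1.0)
            new = []
            for iv in block:
                s = s1 if iv is block[0] else iv.start
                e = e1 if iv is block[-1] else iv.end
                if e - s > 1e-9:
                    new.append(LabelInterval(s, e, iv.activity))
            jittered.append(new)
        # keep blocks from jittering into each other (overlaps are injected
        # separately, below, so their frequency is controlled by overlap_prob)
        for prev, cur in zip(jittered, jittered[1:]):
            if prev and cur and prev[-1].end > cur[0].start:
                mid = 0.5 * (prev[-1].start + cur[0].end)
                prev[-1] = LabelInterval(prev[-1].start, min(prev[-1].end, mid), prev[-1].activity)
                cur[0] = LabelInterval(max(cur[0].start, mid), cur[0].end, cur[0].activity)
        # overlapping labels: extend a block's end past the next block's start
        for prev, cur in zip(jittered, jittered[1:]):
            if prev and cur and rng.uniform() < noise.overlap_prob:
                push = cur[0].start - prev[-1].end + abs(rng.normal(10.0, 5.0)) + 1.0
                prev[-1] = LabelInterval(prev[-1].start, prev[-1].end + push, prev[-1].activity)
        report = [iv for block in jittered for iv in block]
        # occasional outright mislabels
        if noise.mislabel_prob > 0:
            out = []
            for iv in report:
                if rng.uniform() < noise.mislabel_prob:
                    others = [a for a in config.activities if a != iv.activity]
                    out.append(LabelInterval(iv.start, iv.end, others[rng.integers(len(others))]))
                else:
                    out.append(iv)
            report = out

    values = np.concatenate(seg_values) if seg_values else np.empty((0, 3))
    times = np.concatenate(seg_times) if seg_times else np.empty(0)

    # sensor gaps: whole spans removed (real-world only)
    if not controlled and config.gap_rate_per_hour > 0 and len(times):
        total_h = (times[-1] - times[0]) / 3600.0
        k = rng.poisson(config.gap_rate_per_hour * total_h)
        keep = np.ones(len(times), dtype=bool)
        for _ in range(k):
            glen = rng.uniform(10.0, 120.0)
            gstart = rng.uniform(times[0], times[-1])
            keep &= ~((times >= gstart) & (times < gstart + glen))
        values, times = values[keep], times[keep]

    # wrist orientation applied last: stream = R @ template
    values = values @ profile.wrist_rotation.T

    stream = SensorStream(profile.subject_id, times, values, rate)
    vocab = tuple(config.activities)
    return (
        stream,
        Timeline(profile.subject_id, report, vocab),
        Timeline(profile.subject_id, truth, vocab),
    )


def generate_cohort(
    config: GenerationConfig, profiles: list[SubjectProfile] | None = None
) -> tuple[list[SensorStream], list[Timeline], list[Timeline]]:
    """Generate one stream + self-report timeline + ground-truth timeline
    per subject.  With the same config (and seed) the output is identical
    across runs; per-subject substreams are independent of cohort size.
    """
    if profiles is None:
        prof_rngs = [np.random.default_rng([config.seed, 1, i]) for i in range(config.n_subjects)]
        profiles = [draw_profile(f"s{i:02d}", r, config.mode) for i, r in enumerate(prof_rngs)]
    streams, reports, truths = [], [], []
    for i, profile in enumerate(profiles):
        rng = np.random.default_rng([config.seed, 2, i])
        st, rep, tru = _generate_subject(profile, config, rng)
        streams.append(st)
        reports.append(rep)
        truths.append(tru)
    return streams, reports, truths


# ---------------------------------------------------------------------------
# CSV round trip

def write_cohort(streams, timelines, directory) -> list[dict]:
    """Write one stream CSV and one label CSV per subject; return manifest."""
    from .timeline import write_labels

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for stream, tl in zip(streams, timelines):
        sid = stream.subject_id
        stream_path = directory / f"{sid}_stream.csv"
        labels_path = directory / f"{sid}_labels.csv"
        import pandas as pd

        pd.DataFrame(
            {
                "timestamp_s": stream.timestamps,
                "x_g": stream.values[:, 0],
                "y_g": stream.values[:, 1],
                "z_g": stream.values[:, 2],
            }
        ).to_csv(stream_path, index=False)
        write_labels(tl, labels_path)
        manifest.append(
            {
                "subject_id": sid,
                "stream_path": str(stream_path),
                "labels_path": str(labels_path),
                "n_rows": len(stream),
            }
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(directory, nominal_rate: float, vocabulary=()) -> tuple[list[SensorStream], list[Timeline]]:
    """Read back a cohort written by :func:`write_cohort`."""
    from .timeline import read_labels
    import pandas as pd

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    streams, timelines = [], []
    for entry in manifest:
        df = pd.read_csv(entry["stream_path"])
        streams.append(
            SensorStream(
                entry["subject_id"],
                df["timestamp_s"].to_numpy(),
                df[["x_g", "y_g", "z_g"]].to_numpy(),
                nominal_rate,
            )
        )
        timelines.append(read_labels(entry["labels_path"], entry["subject_id"], vocabulary))
    return streams, timelines
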