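"""End-to-end experiment orchestration.

Wires the pipeline together: generate (or load) a cohort, clean the
self-reported labels, window the streams, build the personalization /
hold-out split and the time chunks, train leave-one-participant-out
general models per cumulative dataset (reusing one model for subjects
absent from a CDS), personalize each general model at several fractions
of the personalization data, and evaluate everything on the fixed
per-subject hold-out sets.  Cross-context runs train on the controlled
cohort and evaluate on the real-world one (and vice versa) over the
shared four-activity vocabulary.

All entry points are deterministic given their seed: rerunning a grid
with the same configuration reproduces its result tables bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import zlib

from .metrics import MetricsReport, evaluate_predictions, summarize_reports
from .model import ArchitectureConfig, TrainConfig, TrainedModel, predict, train
from .partition import (
    PartitionPlan,
    PersonalizationBudget,
    assign_chunks,
    lopo_training_set,
    split_personalization,
)
from .personalize import PersonalizeConfig, personalize
from .signal import RATE_HZ, WindowDataset, downsample, segment_windows
from .synthetic import CONTROLLED_ACTIVITIES, GenerationConfig, generate_cohort
from .timeline import Timeline, correct_overlaps

SHARED_VOCABULARY = tuple(sorted(CONTROLLED_ACTIVITIES))


@dataclass
class CohortBundle:
    """A prepared cohort: cleaned timelines, windows and partition plan."""

    streams: list
    timelines: dict[str, Timeline]
    truth: dict[str, Timeline]
    dataset: WindowDataset
    plan: PartitionPlan
    discarded_s: dict[str, float] = field(default_factory=dict)


def prepare_cohort(
    gen_config: GenerationConfig,
    budget: PersonalizationBudget | None = None,
    n_chunks: int = 8,
    label_source: str = "self_report",
) -> CohortBundle:
    """Generate, clean, window and partition a synthetic cohort.

    Streams generated above 32 Hz (the controlled protocol records at
    50 Hz) are mean-downsampled to 32 Hz before windowing.  With
    ``label_source="truth"`` the ground-truth timelines are used instead
    of the noisy self reports (useful to isolate signal effects from
    label effects).
    """
    streams, reports, truths = generate_cohort(gen_config)
    chosen = truths if label_source == "truth" else reports
    timelines: dict[str, Timeline] = {}
    discarded: dict[str, float] = {}
    datasets = []
    for stream, tl in zip(streams, chosen):
        cleaned, log = correct_overlaps(tl)
        timelines[stream.subject_id] = cleaned
        discarded[stream.subject_id] = log.discarded_s
        if stream.nominal_rate > RATE_HZ:
            stream = downsample(stream, RATE_HZ)
        datasets.append(segment_windows(stream, cleaned))
    dataset = WindowDataset.concat(datasets)
    if budget is not None:
        plan = split_personalization(dataset, timelines, budget)
        plan = assign_chunks(plan, n_chunks=n_chunks)
    else:
        plan = assign_chunks(dataset, n_chunks=n_chunks)
    truth_map = {t.subject_id: t for t in truths}
    return CohortBundle(streams, timelines, truth_map, dataset, plan, discarded)


def evaluate_model(
    model: TrainedModel, dataset: WindowDataset, window_ids=None
) -> MetricsReport:
    """Score a model on (a subset of) a dataset with the model's vocabulary."""
    subset = dataset if window_ids is None else dataset.subset(window_ids)
    subset = subset.restrict_vocabulary(model.vocabulary)
    probs = predict(model, subset)
    return evaluate_predictions(subset.labels, probs, model.vocabulary)


def _subsample_ids(ids: set[int], max_train: int | None, rng: np.random.Generator) -> set[int]:
    if max_train is None or len(ids) <= max_train:
        return ids
    arr = np.array(sorted(ids))
    return set(rng.choice(arr, size=max_train, replace=False))


def run_general_grid(
    bundle: CohortBundle,
    arch: ArchitectureConfig | None = None,
    train_config: TrainConfig | None = None,
    cds_keys: tuple[int, ...] | None = None,
    max_train: int | None = None,
    vocabulary: tuple[str, ...] | None = None,
) -> tuple[dict, dict, pd.DataFrame]:
    """LOPO general models per CDS, evaluated on per-subject hold-outs.

    Returns ``(models, reports, summary)`` with models keyed by
    (subject, cds), reports keyed likewise, and a cohort summary table
    (one row per CDS, mean±sd per metric).  Subjects without windows in a
    CDS share one model trained on the full CDS.  ``max_train`` caps the
    training-set size by seeded subsampling, for quick grids.
    """
    arch = arch or ArchitectureConfig()
    train_config = train_config or TrainConfig.free_living()
    plan, dataset = bundle.plan, bundle.dataset
    vocabulary = tuple(vocabulary or dataset.vocabulary)
    if cds_keys is None:
        cds_keys = tuple(range(1, int(plan.table["chunk"].max()) + 1))
    models: dict[tuple, TrainedModel] = {}
    reports: dict[tuple, MetricsReport] = {}
    cache: dict[tuple, TrainedModel] = {}
    for k in cds_keys:
        for subject in plan.subjects():
            ids, reuse_key = lopo_training_set(plan, k, subject)
            if reuse_key in cache:
                model = cache[reuse_key]
            else:
                rng = np.random.default_rng([train_config.seed, k, zlib.crc32(repr(reuse_key).encode()) % 2**31])
                train_ids = _subsample_ids(ids, max_train, rng)
                if not train_ids:
                    continue
                subset = dataset.subset(train_ids).restrict_vocabulary(vocabulary)
                cfg = replace(train_config, seed=int(rng.integers(2**31)))
                model = train(subset, arch=arch, config=cfg, vocabulary=vocabulary)
                model.provenance.update({"cds": k, "reuse_key": str(reuse_key)})
                cache[reuse_key] = model
            models[(subject, k)] = model
            holdout = plan.holdout_ids(subject)
            if holdout:
                reports[(subject, k)] = evaluate_model(model, dataset, holdout)
    summary = summarize_reports(reports, by="cds")
    return models, reports, summary


def run_personalization_grid(
    bundle: CohortBundle,
    general_models: dict,
    config: PersonalizeConfig | None = None,
    base_lr: float | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Personalize every (subject, cds) model at every configured fraction
    and evaluate on the fixed hold-out sets.  Returns the grid log, the
    per-(subject, cds, fraction) reports, and a mean±sd summary keyed by
    fraction."""
    from .personalize import personalization_grid

    config = config or PersonalizeConfig()
    if base_lr is None:
        base_lr = (train_config or TrainConfig.free_living()).lr
    grid, models = personalization_grid(
        general_models, bundle.plan, bundle.dataset, config, base_lr=base_lr
    )
    reports: dict[tuple, MetricsReport] = {}
    for (subject, k, frac), model in models.items():
        holdout = bundle.plan.holdout_ids(subject)
        if holdout:
            reports[(subject, (k, frac))] = evaluate_model(model, bundle.dataset, holdout)
    by_fraction = {(s, kf[1]): r for (s, kf), r in reports.items()}
    summary = summarize_reports(by_fraction, by="fraction")
    return grid, reports, summary


def run_cross_context(
    rw_bundle: CohortBundle,
    controlled_bundle: CohortBundle,
    arch: ArchitectureConfig | None = None,
    rw_train: TrainConfig | None = None,
    controlled_train: TrainConfig | None = None,
    personalize_config: PersonalizeConfig | None = None,
    max_train: int | None = None,
    vocabulary: tuple[str, ...] = SHARED_VOCABULARY,
) -> dict[str, pd.DataFrame]:
    """Cross-context evaluation over the shared four-class vocabulary.

    Trains one model on the full controlled cohort and LOPO models on the
    real-world cohort, evaluates both on the real-world hold-outs, then
    personalizes the controlled model with each real-world subject's
    personalization fractions (a 0.0 "fraction" row repeats the
    unpersonalized model, so that row equals the cross-domain evaluation
    exactly).
    """
    arch = arch or ArchitectureConfig()
    rw_train = rw_train or TrainConfig.free_living()
    controlled_train = controlled_train or TrainConfig.controlled()
    pcfg = personalize_config or PersonalizeConfig()
    vocabulary = tuple(vocabulary)

    ctl_ds = controlled_bundle.dataset.restrict_vocabulary(vocabulary)
    ctl_model = train(ctl_ds, arch=arch, config=controlled_train, vocabulary=vocabulary)

    plan, dataset = rw_bundle.plan, rw_bundle.dataset
    k_max = int(plan.table["chunk"].max())
    rows = []
    cross_reports: dict[tuple, MetricsReport] = {}
    rw_reports: dict[tuple, MetricsReport] = {}
    frac_reports: dict[tuple, MetricsReport] = {}
    cache: dict[tuple, TrainedModel] = {}
    for subject in plan.subjects():
        holdout = plan.holdout_ids(subject)
        if not holdout:
            continue
        ids, reuse_key = lopo_training_set(plan, k_max, subject)
        if reuse_key in cache:
            rw_model = cache[reuse_key]
        else:
            rng = np.random.default_rng([rw_train.seed, zlib.crc32(repr(reuse_key).encode()) % 2**31])
            train_ids = _subsample_ids(ids, max_train, rng)
            subset = dataset.subset(train_ids).restrict_vocabulary(vocabulary)
            rw_model = train(subset, arch=arch, config=replace(rw_train, seed=int(rng.integers(2**31))),
                             vocabulary=vocabulary)
            cache[reuse_key] = rw_model
        rw_reports[(subject, "real_world")] = evaluate_model(rw_model, dataset, holdout)
        cross_reports[(subject, "controlled")] = evaluate_model(ctl_model, dataset, holdout)

        pids = plan.personalization_ids(subject)
        frac_reports[(subject, 0.0)] = cross_reports[(subject, "controlled")]
        if pids:
            for frac in pcfg.fractions:
                from .partition import personalization_fraction

                fids = personalization_fraction(plan, subject, frac, allow_any_fraction=True)
                subset = dataset.subset(fids).restrict_vocabulary(vocabulary)
                if len(subset) == 0:
                    continue
                pmodel = personalize(ctl_model, subset, pcfg, base_lr=controlled_train.lr)
                frac_reports[(subject, frac)] = evaluate_model(pmodel, dataset, holdout)

    on_rw = summarize_reports({**rw_reports, **cross_reports}, by="training_data")
    by_fraction = summarize_reports(frac_reports, by="fraction_personalization")
    raw = pd.DataFrame(
        [
            {"subject": s, "key": str(k), **r.to_dict()}
            for (s, k), r in {**rw_reports, **cross_reports, **frac_reports}.items()
        ]
    )
    return {"on_real_world": on_rw, "cross_personalization": by_fraction, "raw": raw}


# ---------------------------------------------------------------------------
# Trend studies: scaled-down synthetic re-creations of the two headline
# experiment directions — personalization gain under distribution shift,
# and the controlled-vs-free-living domain gap.

def _study_arch() -> ArchitectureConfig:
    return ArchitectureConfig().narrow((8, 8, 8, 8, 8, 16, 16))


def _study_cohort(
    seed: int,
    n_subjects: int,
    duration_s: float,
    budget_min: float,
    activities: tuple[str, ...],
    shift_last: bool,
) -> CohortBundle:
    from .synthetic import draw_profile, shifted_profile

    cfg = GenerationConfig(
        n_subjects=n_subjects,
        activities=activities,
        activity_durations_s={a: duration_s for a in activities},
        seed=seed,
    )
    profiles = [
        draw_profile(f"s{i:02d}", np.random.default_rng([seed, 1, i]))
        for i in range(n_subjects)
    ]
    if shift_last:
        profiles[-1] = shifted_profile(profiles[-1], np.random.default_rng([seed, 9]))
    streams, reports, truths = generate_cohort(cfg, profiles)
    timelines, parts, discarded = {}, [], {}
    for stream, tl in zip(streams, reports):
        cleaned, log = correct_overlaps(tl)
        timelines[stream.subject_id] = cleaned
        discarded[stream.subject_id] = log.discarded_s
        parts.append(segment_windows(stream, cleaned))
    dataset = WindowDataset.concat(parts)
    budget = PersonalizationBudget(
        minutes={a: budget_min for a in activities}, gap_min=0.5
    )
    plan = split_personalization(dataset, timelines, budget)
    plan = assign_chunks(plan, n_chunks=1)
    truth_map = {t.subject_id: t for t in truths}
    return CohortBundle(streams, timelines, truth_map, dataset, plan, discarded)


def personalization_gain_study(
    seed: int,
    n_subjects: int = 5,
    duration_s: float = 360.0,
    budget_min: float = 1.5,
    epochs: int = 14,
    personalize_epochs: int = 10,
    max_train: int = 400,
) -> dict:
    """One seeded cohort with a distribution-shifted target subject.

    The last subject's wrist orientation is rotated far outside the
    population's placement range; a general model is trained on the other
    subjects and then personalized on the target's personalization set.
    Returns the general and personalized hold-out reports, the balanced-
    accuracy gain, and a bit-identity check of the frozen layers.
    """
    from .synthetic import ACTIVITIES

    bundle = _study_cohort(seed, n_subjects, duration_s, budget_min, ACTIVITIES, shift_last=True)
    plan, dataset = bundle.plan, bundle.dataset
    target = plan.subjects()[-1]
    train_ids: set[int] = set()
    for s in plan.subjects():
        if s != target:
            train_ids |= plan.ids(subject=s)
    rng = np.random.default_rng([seed, 3])
    train_ids = _subsample_ids(train_ids, max_train, rng)
    tc = TrainConfig.free_living(epochs=epochs, lr=5e-3, batch_size=32,
                           decay_every=max(2 * epochs // 3, 1), seed=seed)
    general = train(dataset.subset(train_ids), arch=_study_arch(), config=tc,
                    vocabulary=dataset.vocabulary)
    holdout = plan.holdout_ids(target)
    general_report = evaluate_model(general, dataset, holdout)
    pcfg = PersonalizeConfig(epochs=personalize_epochs, batch_size=32, seed=seed)
    personal = personalize(general, dataset.subset(plan.personalization_ids(target)),
                           pcfg, base_lr=tc.lr)
    personal_report = evaluate_model(personal, dataset, holdout)
    frozen_identical = all(
        np.array_equal(general.params[name][k], personal.params[name][k])
        for name in pcfg.freeze_mask()
        for k in general.params[name]
    )
    return {
        "target": target,
        "general": general_report,
        "personalized": personal_report,
        "gain_ba": personal_report.balanced_accuracy - general_report.balanced_accuracy,
        "frozen_identical": frozen_identical,
    }


def domain_gap_study(
    seed: int,
    n_rw_subjects: int = 4,
    n_controlled_subjects: int = 5,
    duration_s: float = 300.0,
    epochs: int = 15,
    max_train: int = 300,
) -> dict:
    """Controlled-trained vs free-living-trained models on one free-living
    hold-out, over the shared four-activity vocabulary.

    The controlled cohort records clean, uninterrupted one-minute bouts at
    a fixed device orientation; the free-living cohort has per-subject
    wrist orientations, interruptions, label noise and gaps.  Returns the
    balanced accuracies of both models on the same hold-out subject.
    """
    rw = _study_cohort(seed, n_rw_subjects, duration_s, 1.5, SHARED_VOCABULARY, shift_last=False)
    ctl = prepare_cohort(GenerationConfig.controlled(n_subjects=n_controlled_subjects, seed=seed + 1))

    plan, dataset = rw.plan, rw.dataset
    target = plan.subjects()[-1]
    holdout = plan.holdout_ids(target)
    train_ids: set[int] = set()
    for s in plan.subjects():
        if s != target:
            train_ids |= plan.ids(subject=s)
    rng = np.random.default_rng([seed, 4])
    train_ids = _subsample_ids(train_ids, max_train, rng)
    arch = _study_arch()
    tc_rw = TrainConfig.free_living(epochs=epochs, lr=5e-3, batch_size=32,
                              decay_every=max(2 * epochs // 3, 1), seed=seed)
    rw_model = train(dataset.subset(train_ids), arch=arch, config=tc_rw,
                     vocabulary=SHARED_VOCABULARY)
    tc_ctl = TrainConfig.controlled(epochs=epochs, lr=5e-3, batch_size=32,
                                    decay_every=max(2 * epochs // 3, 1), seed=seed)
    ctl_model = train(ctl.dataset.restrict_vocabulary(SHARED_VOCABULARY),
                      arch=ArchitectureConfig.controlled().narrow((8, 8, 8, 8, 8, 16, 16)),
                      config=tc_ctl, vocabulary=SHARED_VOCABULARY)
    return {
        "target": target,
        "real_world": evaluate_model(rw_model, dataset, holdout),
        "controlled": evaluate_model(ctl_model, dataset, holdout),
    }


# ---------------------------------------------------------------------------
# Shipped demo: a small cohort that exercises the full grid in minutes.

def demo_generation_config(seed: int = 0) -> GenerationConfig:
    return GenerationConfig(
        mode="real_world",
        n_subjects=6,
        activity_durations_s={
            "computer_table": 1500.0,
            "standing_still": 420.0,
            "walking": 420.0,
            "running": 420.0,
            "cycling": 420.0,
        },
        seed=seed,
    )


def demo_settings(seed: int = 0) -> dict:
    """Scaled-down training settings for the demo grid (narrow channels,
    few epochs, capped training sets) so it runs in minutes on one CPU."""
    return {
        "arch": ArchitectureConfig().narrow((4, 4, 4, 4, 4, 8, 8)),
        "train": TrainConfig.free_living(epochs=5, lr=5e-3, batch_size=32, decay_every=4, seed=seed),
        "personalize": PersonalizeConfig(epochs=3, batch_size=32, fractions=(0.2, 1.0), seed=seed),
        "max_train": 150,
        "n_chunks": 2,
    }


def run_demo_grid(out_dir, seed: int = 0) -> dict[str, Path]:
    """Generate the demo cohort, run the general and personalization grids
    and write the result tables.  Deterministic: same seed, same bytes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = demo_settings(seed)
    bundle = prepare_cohort(
        demo_generation_config(seed),
        budget=PersonalizationBudget.demo(),
        n_chunks=settings["n_chunks"],
    )
    models, reports, summary = run_general_grid(
        bundle,
        arch=settings["arch"],
        train_config=settings["train"],
        max_train=settings["max_train"],
    )
    grid, preports, psummary = run_personalization_grid(
        bundle, models, settings["personalize"], base_lr=settings["train"].lr
    )
    paths = {}
    outputs = {
        "window_counts.csv": bundle.dataset.counts(),
        "partition.csv": bundle.plan.table,
        "table5_general.csv": summary,
        "general_per_subject.csv": pd.DataFrame(
            [{"subject": s, "cds": k, **r.to_dict()} for (s, k), r in reports.items()]
        ),
        "personalization_grid.csv": grid,
        "table_fractions.csv": psummary,
        "personalized_per_subject.csv": pd.DataFrame(
            [{"subject": s, "cds": kf[0], "fraction": kf[1], **r.to_dict()}
             for (s, kf), r in preports.items()]
        ),
    }
    for name, df in outputs.items():
        path = out_dir / name
        df.to_csv(path, float_format="%.10g")
        paths[name] = path
    return paths
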