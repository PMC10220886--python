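"""Transfer-learning personalization of a general activity model.

A general model is adapted to one subject by continuing training on that
subject's small personalization set while freezing the first three
convolutional layers and both dense layers (and, by default, the softmax
head); only convolutional layers 4-7 are updated.  Because the
personalization set is small, the optimizer switches to plain SGD with an
accordingly larger learning rate and regularization is strengthened
(Gaussian noise and dropout multiplied up).  The subject's hold-out set
is never touched during personalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    ALL_LAYER_NAMES,
    TrainConfig,
    TrainedModel,
    train,
)
from .partition import FRACTION_GRID, PartitionPlan, personalization_fraction
from .signal import WindowDataset

DEFAULT_TRAINABLE = ("conv4", "conv5", "conv6", "conv7")


@dataclass(frozen=True)
class PersonalizeConfig:
    """Personalization hyperparameters.

    ``lr_multiplier``, ``noise_multiplier`` and ``dropout_multiplier``
    scale the general regime's base values (x2, x1.5, x1.5 by default —
    the increases are modest because the personalization sets are tiny
    and stronger settings make the continued training diverge); the
    softmax head stays frozen unless ``train_head`` is set.
    """

    trainable: tuple[str, ...] = DEFAULT_TRAINABLE
    train_head: bool = False
    optimizer: str = "sgd"
    lr: float | None = None  # explicit lr; else base_lr * lr_multiplier
    lr_multiplier: float = 2.0
    noise_multiplier: float = 1.5
    dropout_multiplier: float = 1.5
    epochs: int = 60
    batch_size: int = 600
    fractions: tuple[float, ...] = FRACTION_GRID
    seed: int = 0

    def freeze_mask(self) -> tuple[str, ...]:
        trainable = set(self.trainable) | ({"head"} if self.train_head else set())
        return tuple(n for n in ALL_LAYER_NAMES if n not in trainable)


def personalize(
    general: TrainedModel,
    personal_windows,
    config: PersonalizeConfig | None = None,
    base_lr: float = 8e-4,
) -> TrainedModel:
    """Continue training the trainable layers on one subject's data.

    ``personal_windows`` must come from the subject's personalization set
    only.  The returned model's frozen parameters are bit-identical to
    the general model's.
    """
    config = config or PersonalizeConfig()
    if isinstance(personal_windows, WindowDataset) and len(personal_windows) == 0:
        raise ValueError("empty personalization set")
    arch = replace(
        general.architecture,
        input_noise_sd=general.architecture.input_noise_sd * config.noise_multiplier,
        weight_noise_sd=general.architecture.weight_noise_sd * config.noise_multiplier,
        spatial_dropout_rate=min(general.architecture.spatial_dropout_rate * config.dropout_multiplier, 0.9),
        dense_dropout_rate=min(general.architecture.dense_dropout_rate * config.dropout_multiplier, 0.9),
    )
    lr = config.lr if config.lr is not None else base_lr * config.lr_multiplier
    tc = TrainConfig(
        regime="personalize",
        epochs=config.epochs,
        lr=lr,
        optimizer=config.optimizer,
        batch_size=config.batch_size,
        decay_every=max(config.epochs, 1),
        seed=config.seed,
    )
    model = train(
        personal_windows,
        arch=arch,
        config=tc,
        vocabulary=general.vocabulary,
        freeze_mask=config.freeze_mask(),
        initial=general,
    )
    model.provenance.update(
        {
            "personalized_from": general.provenance,
            "trainable": list(config.trainable) + (["head"] if config.train_head else []),
        }
    )
    return model


def personalization_grid(
    general_models: dict,
    plan: PartitionPlan,
    dataset: WindowDataset,
    config: PersonalizeConfig | None = None,
    base_lr: float = 8e-4,
    cds_keys: tuple[int, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Personalize every (subject, CDS) general model at every fraction.

    ``general_models`` maps (subject, cds) -> TrainedModel.  Returns a
    table with one row per produced model (subject, cds, fraction,
    n_train) plus skipped combinations, and the models keyed by
    (subject, cds, fraction).  Subjects with an empty personalization set
    contribute no rows.
    """
    config = config or PersonalizeConfig()
    if cds_keys is None:
        cds_keys = tuple(sorted({k for (_, k) in general_models}))
    rows = []
    models: dict[tuple, TrainedModel] = {}
    for subject in plan.subjects():
        pids = plan.personalization_ids(subject)
        if not pids:
            rows.append({"subject": subject, "cds": None, "fraction": None,
                         "n_train": 0, "status": "no_personalization_data"})
            continue
        for k in cds_keys:
            general = general_models.get((subject, k))
            if general is None:
                rows.append({"subject": subject, "cds": k, "fraction": None,
                             "n_train": 0, "status": "missing_general_model"})
                continue
            for frac in config.fractions:
                ids = personalization_fraction(plan, subject, frac, allow_any_fraction=True)
                subset = dataset.subset(ids)
                if len(subset) == 0:
                    rows.append({"subject": subject, "cds": k, "fraction": frac,
                                 "n_train": 0, "status": "empty_fraction"})
                    continue
                model = personalize(general, subset, config, base_lr=base_lr)
                models[(subject, k, frac)] = model
                rows.append({"subject": subject, "cds": k, "fraction": frac,
                             "n_train": len(subset), "status": "ok"})
    return pd.DataFrame(rows), models
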