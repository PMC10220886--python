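"""The activity classifier: a 7-layer 1D CNN with rotational augmentation.

Architecture: 7 valid 1D convolutions (swish activations, spatial dropout
between them, transient Gaussian weight noise on the first two), global
average pooling, two ReLU dense layers of 32 and 16 units with ordinary
dropout, and a softmax head over the activity vocabulary.  Kernel sizes
default to (16, 17, 17, 17, 17, 17, 17) at stride 1, so the receptive
field is exactly 1 + sum(k_i - 1) = 112 input samples = 3.5 s at 32 Hz —
long enough to span several gait cycles of any of the target activities.

Data augmentation happens before the network: each training window is
left-multiplied by a random proper rotation built by Gram-Schmidt
orthonormalization of B = (1 - s) I + s M, M having i.i.d. standard
normal entries; the strength s in [0, 1] interpolates between the
identity (s = 0) and a fully random rotation.  This mimics the wristband
being placed slightly differently on the wrist between sessions.
Additive Gaussian input noise follows.  At evaluation time augmentation
and all stochastic regularizers are disabled.

Two training regimes are provided: the free-living regime —
Adam, 105 epochs, lr 8e-4 decayed x0.3 every 30 epochs, dropout 0.15,
noise 0.03, rotation strength 0.2, batch 600 — and the "controlled"
regime — 270 epochs, lr 5e-3 decayed x0.3 every 50 epochs, dropout 0.075,
noise 0.015, rotation strength 0.1, batch 600.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .signal import RATE_HZ, WindowDataset

DEFAULT_KERNELS = (16, 17, 17, 17, 17, 17, 17)
DEFAULT_CHANNELS = (32, 32, 64, 64, 64, 128, 128)
CONV_NAMES = tuple(f"conv{i}" for i in range(1, 8))
DENSE_NAMES = ("dense1", "dense2")
HEAD_NAME = "head"
ALL_LAYER_NAMES = CONV_NAMES + DENSE_NAMES + (HEAD_NAME,)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural and regularization hyperparameters of the CNN."""

    kernel_sizes: tuple[int, ...] = DEFAULT_KERNELS
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    strides: tuple[int, ...] = (1,) * 7
    dense_sizes: tuple[int, int] = (32, 16)
    spatial_dropout_rate: float = 0.15
    dense_dropout_rate: float = 0.15
    input_noise_sd: float = 0.03
    weight_noise_sd: float = 0.03
    rotation_strength: float = 0.2

    def __post_init__(self) -> None:
        if not (len(self.kernel_sizes) == len(self.channels) == len(self.strides) == 7):
            raise ValueError("the conv stack has exactly 7 layers")
        if self.dense_sizes != (32, 16):
            raise ValueError("dense sizes are fixed at (32, 16)")
        if not 0.0 <= self.rotation_strength <= 1.0:
            raise ValueError("rotation_strength must be in [0, 1]")

    def receptive_field_samples(self) -> int:
        rf, jump = 1, 1
        for k, s in zip(self.kernel_sizes, self.strides):
            rf += (k - 1) * jump
            jump *= s
        return rf

    def receptive_field_s(self, rate_hz: float = RATE_HZ) -> float:
        return self.receptive_field_samples() / rate_hz

    @classmethod
    def controlled(cls, **kw) -> "ArchitectureConfig":
        defaults = dict(
            spatial_dropout_rate=0.075,
            dense_dropout_rate=0.075,
            input_noise_sd=0.015,
            weight_noise_sd=0.015,
            rotation_strength=0.1,
        )
        defaults.update(kw)
        return cls(**defaults)

    def narrow(self, channels: tuple[int, ...] = (8, 8, 8, 8, 8, 16, 16)) -> "ArchitectureConfig":
        """Same depth, kernels and receptive field, fewer channels —
        for demos and quick experiments on one CPU."""
        return replace(self, channels=channels)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization regime for the general models."""

    regime: str = "free_living"
    epochs: int = 105
    lr: float = 8e-4
    optimizer: str = "adam"
    batch_size: int = 600
    decay_every: int = 30
    decay_factor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.lr <= 0 or self.batch_size <= 0 or self.decay_every <= 0:
            raise ValueError("epochs/lr/batch/decay_every must be positive")
        if not 0 < self.decay_factor < 1:
            raise ValueError("decay factor must be in (0, 1)")

    @classmethod
    def free_living(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(regime="free_living"), **kw})

    @classmethod
    def controlled(cls, **kw) -> "TrainConfig":
        defaults = dict(regime="controlled", epochs=270, lr=5e-3, decay_every=50)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TrainedModel:
    """Parameterized classifier plus vocabulary, freeze mask and provenance."""

    architecture: ArchitectureConfig
    params: dict[str, dict[str, np.ndarray]]
    vocabulary: tuple[str, ...]
    freeze_mask: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)
    train_log: list[dict] = field(default_factory=list)

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            self.architecture,
            {n: {k: v.copy() for k, v in p.items()} for n, p in self.params.items()},
            self.vocabulary,
            self.freeze_mask,
            dict(self.provenance),
            list(self.train_log),
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "architecture": asdict(self.architecture),
            "vocabulary": list(self.vocabulary),
            "freeze_mask": list(self.freeze_mask),
            "provenance": self.provenance,
        }
        (directory / "architecture.json").write_text(json.dumps(meta, indent=1, default=str))
        flat = {f"{n}.{k}": v for n, p in self.params.items() for k, v in p.items()}
        np.savez(directory / "params.npz", **flat)
        if self.train_log:
            import pandas as pd

            pd.DataFrame(self.train_log).to_csv(directory / "train_log.csv", index=False)

    @staticmethod
    def load(directory) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "architecture.json").read_text())
        arch_kw = meta["architecture"]
        for key in ("kernel_sizes", "channels", "strides", "dense_sizes"):
            arch_kw[key] = tuple(arch_kw[key])
        arch = ArchitectureConfig(**arch_kw)
        with np.load(directory / "params.npz") as npz:
            params: dict[str, dict[str, np.ndarray]] = {}
            for key in npz.files:
                name, p = key.rsplit(".", 1)
                params.setdefault(name, {})[p] = npz[key]
        return TrainedModel(
            arch, params, tuple(meta["vocabulary"]), tuple(meta["freeze_mask"]), meta["provenance"]
        )


# ---------------------------------------------------------------------------
# Rotational augmentation

def gram_schmidt(B: np.ndarray) -> np.ndarray:
    """Classical Gram-Schmidt orthonormalization of the columns of B."""
    Q = np.zeros_like(B, dtype=float)
    for j in range(B.shape[1]):
        v = B[:, j].astype(float).copy()
        for i in range(j):
            v -= (Q[:, i] @ B[:, j]) * Q[:, i]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ValueError("degenerate matrix: columns are linearly dependent")
        Q[:, j] = v / norm
    return Q


def sample_rotation(strength: float, rng: np.random.Generator) -> np.ndarray:
    """Random proper rotation with dial-back strength s in [0, 1].

    Draws M with i.i.d. standard normal entries, forms the barycentric
    blend B = (1 - s) I + s M, Gram-Schmidt-orthonormalizes B's columns
    and, if the result is a reflection, negates the last column so the
    determinant is +1.  s = 0 returns the identity exactly.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"rotation strength must be in [0, 1], got {strength}")
    M = rng.standard_normal((3, 3))
    if strength == 0.0:
        return np.eye(3)
    B = (1.0 - strength) * np.eye(3) + strength * M
    R = gram_schmidt(B)
    if np.linalg.det(R) < 0:
        R[:, -1] = -R[:, -1]
    return R


def augment_batch(
    batch: np.ndarray,
    rotation_strength: float,
    input_noise_sd: float,
    training: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rotate each (3, T) window independently, then add Gaussian noise.

    With ``training=False`` the batch is returned unchanged (no rotation,
    no noise), matching evaluation-time behavior.
    """
    batch = np.asarray(batch)
    if batch.ndim != 3 or batch.shape[1] != 3:
        raise ValueError(f"batch must be (N, 3, T), got {batch.shape}")
    if not training:
        return batch
    out = np.empty_like(batch, dtype=float)
    for i in range(len(batch)):
        R = sample_rotation(rotation_strength, rng)
        out[i] = R @ batch[i]
    if input_noise_sd > 0:
        out += rng.normal(0.0, input_noise_sd, out.shape)
    return out.astype(batch.dtype, copy=False)


# ---------------------------------------------------------------------------
# Network assembly and training

def build_network(arch: ArchitectureConfig, n_classes: int, rng: np.random.Generator) -> nn.Network:
    layers: list[nn.Layer] = []
    c_in = 3
    for i, (k, c_out) in enumerate(zip(arch.kernel_sizes, arch.channels), start=1):
        wn = arch.weight_noise_sd if i <= 2 else 0.0
        layers.append(nn.Conv1D(f"conv{i}", c_in, c_out, k, weight_noise_sd=wn, rng=rng))
        layers.append(nn.Swish())
        layers.append(nn.SpatialDropout(arch.spatial_dropout_rate))
        c_in = c_out
    layers.append(nn.GlobalAvgPool())
    n_in = c_in
    for i, n_out in enumerate(arch.dense_sizes, start=1):
        layers.append(nn.Dense(f"dense{i}", n_in, n_out, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(arch.dense_dropout_rate))
        n_in = n_out
    layers.append(nn.Dense(HEAD_NAME, n_in, n_classes, rng=rng))
    return nn.Network(layers)


def _as_xy(data, vocabulary: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, WindowDataset):
        lut = {a: i for i, a in enumerate(vocabulary)}
        unknown = set(data.labels) - set(vocabulary)
        if unknown:
            raise ValueError(f"labels outside the vocabulary: {sorted(unknown)}")
        return data.X.astype(np.float64), np.array([lut[a] for a in data.labels])
    X, y = data
    return np.asarray(X, dtype=np.float64), np.asarray(y)


def train(
    data,
    arch: ArchitectureConfig | None = None,
    config: TrainConfig | None = None,
    vocabulary: tuple[str, ...] | None = None,
    freeze_mask: tuple[str, ...] = (),
    initial: TrainedModel | None = None,
) -> TrainedModel:
    """Train the CNN on labeled windows.

    ``data`` is a :class:`WindowDataset` or an ``(X, y)`` pair with X of
    shape (N, 3, T) and integer labels y.  The softmax always covers the
    full configured vocabulary; classes absent from the training set are
    recorded in the provenance.  With the same seed and data the returned
    parameters are identical across runs.
    """
    arch = arch or ArchitectureConfig()
    config = config or TrainConfig.free_living()
    if isinstance(data, WindowDataset):
        vocabulary = tuple(vocabulary or data.vocabulary)
    elif vocabulary is None:
        raise ValueError("vocabulary is required with raw (X, y) data")
    else:
        vocabulary = tuple(vocabulary)
    X, y = _as_xy(data, vocabulary)
    if len(X) == 0:
        raise ValueError("empty training set")
    missing = sorted(set(range(len(vocabulary))) - set(np.unique(y).tolist()))

    rng = np.random.default_rng(config.seed)
    net = build_network(arch, len(vocabulary), rng)
    if initial is not None:
        if initial.vocabulary != vocabulary:
            raise ValueError("vocabulary mismatch with the initial model")
        net.set_params(initial.params)
    frozen = set(freeze_mask)
    unknown = frozen - set(ALL_LAYER_NAMES)
    if unknown:
        raise ValueError(f"freeze mask names unknown layers: {sorted(unknown)}")

    if config.optimizer == "adam":
        opt: nn.Adam | nn.SGD = nn.Adam(config.lr)
    elif config.optimizer == "sgd":
        opt = nn.SGD(config.lr)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    schedule = nn.StepDecay(config.lr, config.decay_every, config.decay_factor)

    log: list[dict] = []
    n = len(X)
    for epoch in range(config.epochs):
        opt.lr = schedule.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = augment_batch(X[idx], arch.rotation_strength, arch.input_noise_sd, True, rng)
            logits = net.forward(xb, training=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step(net, frozen)
            losses.append(loss)
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": opt.lr})

    return TrainedModel(
        architecture=arch,
        params=net.get_params(),
        vocabulary=vocabulary,
        freeze_mask=tuple(sorted(frozen)),
        provenance={
            "regime": config.regime,
            "seed": config.seed,
            "n_train": n,
            "missing_classes": [vocabulary[i] for i in missing],
        },
        train_log=log,
    )


def predict(model: TrainedModel, windows) -> np.ndarray:
    """Per-window class probabilities (rows sum to 1); no augmentation."""
    if isinstance(windows, WindowDataset):
        X = windows.X.astype(np.float64)
    else:
        X = np.asarray(windows, dtype=np.float64)
    if X.ndim != 3 or X.shape[1] != 3:
        raise ValueError(f"windows must be (N, 3, T), got {X.shape}")
    rng = np.random.default_rng(0)  # never consumed in eval mode
    net = build_network(model.architecture, len(model.vocabulary), rng)
    net.set_params(model.params)
    logits = net.forward(X, training=False, rng=rng)
    return nn.softmax(logits)
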