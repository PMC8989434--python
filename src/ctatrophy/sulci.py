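"""Parietal sulci enlargement identification (pipeline module 3).

The clinical rule defining "enlarged" is: at least two parietal sulci wider
than 5 mm on the supraventricular slice (key slice 4).  The rule itself is
exposed as :func:`sulci_rule_oracle` (it supplies training labels on
phantoms); the image classifier learns the binary decision from the
three-channel fused image at key slice 4, trained with cross-entropy loss
and SGD-momentum (batch size 8, warm-up + piecewise decay), with 5-fold
best-validation-accuracy model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import MEASURE_SIZE, SubjectData, fused_channels, slice_stacks
from .nn import MLP
from .phantom import SULCUS_MIN_COUNT, SULCUS_WIDTH_MM, CTVolume

__all__ = [
    "SulciResult",
    "SulciConfig",
    "SulciModel",
    "sulci_rule_oracle",
    "train_sulci_classifier",
    "predict_sulci",
]


@dataclass(frozen=True)
class SulciResult:
    enlarged: bool
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.enlarged != (self.probability >= 0.5):
            raise ValueError("enlarged flag must equal probability >= 0.5")


def sulci_rule_oracle(sulci_widths) -> bool:
    """True iff at least two sulci are strictly wider than 5 mm."""
    widths = list(sulci_widths)
    if not widths:
        raise ValueError("sulci width list must be non-empty")
    if any(w < 0 for w in widths):
        raise ValueError("sulci widths must be non-negative")
    return sum(1 for w in widths if w > SULCUS_WIDTH_MM) >= SULCUS_MIN_COUNT


@dataclass(frozen=True)
class SulciConfig:
    input_size: int = MEASURE_SIZE
    hidden: tuple[int, ...] = (64,)
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 8
    epochs: int = 25
    n_folds: int = 5
    jitter: tuple[int, ...] = (-1, 0, 1)
    seed: int = 0


@dataclass
class SulciModel:
    net: MLP
    config: SulciConfig
    report: dict = field(default_factory=dict)

    def to_arrays(self) -> dict:
        return self.net.to_arrays()

    @classmethod
    def from_arrays(cls, arrays: dict, config: SulciConfig, report: dict) -> "SulciModel":
        return cls(net=MLP.from_arrays(arrays), config=config, report=report)


def train_sulci_classifier(
    subjects: list[SubjectData], config: SulciConfig | None = None
) -> SulciModel:
    """Train the binary sulci-enlargement classifier on key-slice-4 images."""
    cfg = config or SulciConfig()
    missing = [
        s.subject_id for s in subjects if s.sulci_enlarged is None or s.key_slices is None
    ]
    if missing:
        raise ValueError(f"subjects missing sulci labels: {missing}")
    labels = np.array([int(s.sulci_enlarged) for s in subjects])
    if len(np.unique(labels)) < 2:
        raise ValueError("sulci training labels contain a single class: rejected")
    if len(subjects) < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} subjects")

    rng = np.random.default_rng(cfg.seed)
    folds = np.array_split(rng.permutation(len(subjects)), cfg.n_folds)

    def samples(subj_list):
        xs, ys = [], []
        for s in subj_list:
            stack = s.stacks[cfg.input_size]
            for dz in cfg.jitter:
                z = int(np.clip(s.key_slices.key4 + dz, 0, stack.shape[0] - 1))
                xs.append(fused_channels(stack, z).ravel())
                ys.append(int(s.sulci_enlarged))
        return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=np.int64)

    best_net, best_acc, fold_accs = None, -1.0, []
    for fi, val_ids in enumerate(folds):
        val_set = set(int(i) for i in val_ids)
        x, y = samples([s for i, s in enumerate(subjects) if i not in val_set])
        if len(np.unique(y)) < 2:
            raise ValueError("a training fold contains a single sulci class")
        net = MLP(
            [x.shape[1], *cfg.hidden, 2],
            task="softmax",
            seed=int(np.random.default_rng([cfg.seed, 13, fi]).integers(2**31)),
        )
        net.fit(
            x,
            y,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            optimizer="momentum",
            momentum=cfg.momentum,
            shuffle_seed=int(np.random.default_rng([cfg.seed, 17, fi]).integers(2**31)),
        )
        val_subj = [s for i, s in enumerate(subjects) if i in val_set]
        hits = 0
        for s in val_subj:
            stack = s.stacks[cfg.input_size]
            p = net.predict(fused_channels(stack, s.key_slices.key4).ravel())[0, 1]
            hits += int((p >= 0.5) == bool(s.sulci_enlarged))
        acc = hits / max(1, len(val_subj))
        fold_accs.append(acc)
        if acc > best_acc:
            best_net, best_acc = net, acc
    return SulciModel(net=best_net, config=cfg, report={"fold_accuracies": fold_accs})


def predict_sulci(
    volume_or_subject: CTVolume | SubjectData, key4_index: int, model: SulciModel
) -> SulciResult:
    """Probability of sulci enlargement at key slice 4; enlarged iff p >= 0.5."""
    if isinstance(volume_or_subject, SubjectData):
        stack = volume_or_subject.stacks[model.config.input_size]
    else:
        size = model.config.input_size
        stack = slice_stacks(volume_or_subject, sizes=(size,))[size]
    if not 0 <= key4_index < stack.shape[0]:
        raise IndexError(f"key slice 4 index {key4_index} outside volume")
    p = float(model.net.predict(fused_channels(stack, key4_index).ravel())[0, 1])
    return SulciResult(enlarged=p >= 0.5, probability=p)
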