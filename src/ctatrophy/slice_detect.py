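"""Key-slice detection (pipeline module 1).

Four independent binary scorers — one per anatomically defined key slice —
assign every axial slice a probability of being that key level:

* key slice 1: basal ganglia showing the caudate heads most prominently,
* key slice 2: body of the lateral ventricles,
* key slice 3: clearest Sylvian fissures,
* key slice 4: third slice above the lateral-ventricle top.

Each scorer is trained with cross-entropy loss, SGD with momentum (batch
size 8, warm-up then piecewise learning-rate decay), and model selection
picks the fold with the best validation accuracy out of a 5-fold split of
the training subjects.  Detection takes the per-type argmax over slices
(ties toward the inferior slice) and repairs any ordering violation
(key1 <= key2 < key4) by a constrained argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DETECT_SIZE, SubjectData, slice_stacks
from .nn import MLP
from .phantom import CTVolume, KeySliceSet

__all__ = [
    "SliceDetectConfig",
    "SliceDetectorModel",
    "train_slice_detector",
    "score_slices",
    "detect_key_slices",
]

KEY_NAMES = ("key1", "key2", "key3", "key4")


@dataclass(frozen=True)
class SliceDetectConfig:
    input_size: int = DETECT_SIZE
    hidden: tuple[int, ...] = (64,)
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 8
    epochs: int = 25
    n_folds: int = 5
    neg_per_subject: int = 8  # negatives sampled per subject, class-balanced
    pos_duplication: int = 4
    seed: int = 0


@dataclass
class SliceDetectorModel:
    scorers: dict[str, MLP]
    config: SliceDetectConfig
    report: dict = field(default_factory=dict)  # per-key fold accuracies

    def to_arrays(self) -> dict:
        out = {}
        for name, net in self.scorers.items():
            for k, v in net.to_arrays().items():
                out[f"{name}__{k}"] = v
        return out

    @classmethod
    def from_arrays(cls, arrays: dict, config: SliceDetectConfig, report: dict) -> "SliceDetectorModel":
        scorers = {}
        for name in KEY_NAMES:
            sub = {k.split("__", 1)[1]: v for k, v in arrays.items() if k.startswith(name + "__")}
            scorers[name] = MLP.from_arrays(sub)
        return cls(scorers=scorers, config=config, report=report)


def _subject_samples(
    subj: SubjectData, key_index: int, cfg: SliceDetectConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    stack = subj.stacks[cfg.input_size]
    flat = stack.reshape(stack.shape[0], -1)
    pos = flat[key_index : key_index + 1]
    neg_idx = [z for z in range(stack.shape[0]) if abs(z - key_index) >= 2]
    take = rng.choice(len(neg_idx), size=min(cfg.neg_per_subject, len(neg_idx)), replace=False)
    neg = flat[[neg_idx[i] for i in sorted(take)]]
    x = np.concatenate([np.repeat(pos, cfg.pos_duplication, axis=0), neg])
    y = np.concatenate([np.ones(cfg.pos_duplication, dtype=np.int64), np.zeros(len(neg), dtype=np.int64)])
    return x, y


def train_slice_detector(
    subjects: list[SubjectData], config: SliceDetectConfig | None = None
) -> SliceDetectorModel:
    """Train the four key-slice scorers with 5-fold best-accuracy selection.

    Every subject must carry annotated key slices; validation accuracy is
    the fraction of held-out subjects whose detected slice lies within one
    slice of the annotation.
    """
    cfg = config or SliceDetectConfig()
    missing = [s.subject_id for s in subjects if s.key_slices is None]
    if missing:
        raise ValueError(f"subjects missing key-slice annotations: {missing}")
    if len(subjects) < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} subjects for {cfg.n_folds}-fold selection")
    n_slices = subjects[0].n_slices
    if n_slices < 4:
        raise ValueError("volumes too short to contain negatives: training rejected")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(subjects))
    folds = np.array_split(order, cfg.n_folds)

    scorers: dict[str, MLP] = {}
    report: dict = {"folds": {}}
    for ki, name in enumerate(KEY_NAMES):
        fold_accs = []
        best_net, best_acc = None, -1.0
        for fi, val_ids in enumerate(folds):
            val_set = set(int(i) for i in val_ids)
            train_subj = [s for i, s in enumerate(subjects) if i not in val_set]
            val_subj = [s for i, s in enumerate(subjects) if i in val_set]
            srng = np.random.default_rng([cfg.seed, ki, fi])
            xs, ys = [], []
            for s in train_subj:
                x, y = _subject_samples(s, getattr(s.key_slices, name), cfg, srng)
                xs.append(x)
                ys.append(y)
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            if len(np.unique(y)) < 2:
                raise ValueError("training set contains only key slices (no negatives)")
            net = MLP(
                [x.shape[1], *cfg.hidden, 2],
                task="softmax",
                seed=int(np.random.default_rng([cfg.seed, 7, ki, fi]).integers(2**31)),
            )
            net.fit(
                x,
                y,
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                lr=cfg.learning_rate,
                optimizer="momentum",
                momentum=cfg.momentum,
                shuffle_seed=int(np.random.default_rng([cfg.seed, 11, ki, fi]).integers(2**31)),
            )
            hits = 0
            for s in val_subj:
                stack = s.stacks[cfg.input_size]
                p = net.predict(stack.reshape(stack.shape[0], -1))[:, 1]
                hits += int(abs(int(np.argmax(p)) - getattr(s.key_slices, name)) <= 1)
            acc = hits / max(1, len(val_subj))
            fold_accs.append(acc)
            if acc > best_acc:
                best_net, best_acc = net, acc
        scorers[name] = best_net
        report["folds"][name] = fold_accs
    model = SliceDetectorModel(scorers=scorers, config=cfg, report=report)
    return model


def score_slices(
    volume_or_stack: CTVolume | np.ndarray, model: SliceDetectorModel
) -> dict[str, np.ndarray]:
    """Per-slice key-slice probabilities, one vector per key-slice type.

    Accepts a pre-processed (windowed, tilt-corrected) volume or an already
    downsampled slice stack of shape (n_slices, s, s).
    """
    size = model.config.input_size
    if isinstance(volume_or_stack, CTVolume):
        stack = slice_stacks(volume_or_stack, sizes=(size,))[size]
    else:
        stack = np.asarray(volume_or_stack, dtype=np.float32)
    if stack.ndim != 3 or stack.shape[1] != size or stack.shape[2] != size:
        raise ValueError(
            f"slice stack shape {stack.shape} does not match model input size {size}"
        )
    flat = stack.reshape(stack.shape[0], -1)
    return {name: model.scorers[name].predict(flat)[:, 1] for name in KEY_NAMES}


def detect_key_slices(
    volume_or_stack: CTVolume | np.ndarray, model: SliceDetectorModel
) -> KeySliceSet:
    """Argmax detection with inferior tie-break and ordering repair.

    If the unconstrained argmaxes violate key1 <= key2 < key4, the highest
    joint log-probability triple over admissible orderings is used instead.
    """
    scores = score_slices(volume_or_stack, model)
    if scores["key1"].size == 0:
        raise ValueError("empty volume")
    picks = {name: int(np.argmax(p)) for name, p in scores.items()}  # first max = inferior
    if not (picks["key1"] <= picks["key2"] < picks["key4"]):
        logp = {n: np.log(np.clip(scores[n], 1e-12, None)) for n in ("key1", "key2", "key4")}
        n = scores["key1"].shape[0]
        best, best_val = None, -np.inf
        for k1 in range(n):
            for k2 in range(k1, n):
                rest = logp["key1"][k1] + logp["key2"][k2]
                k4_slice = logp["key4"][k2 + 1 :]
                if k4_slice.size == 0:
                    continue
                k4 = int(np.argmax(k4_slice)) + k2 + 1
                val = rest + logp["key4"][k4]
                if val > best_val:
                    best, best_val = (k1, k2, k4), val
        picks["key1"], picks["key2"], picks["key4"] = best
    return KeySliceSet(
        key1=picks["key1"], key2=picks["key2"], key3=picks["key3"], key4=picks["key4"]
    )
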