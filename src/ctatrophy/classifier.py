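"""Derived ventricular/cortical indices and the atrophy classifier
(pipeline module 4).

Seven classical linear indices are derived from the nine measurements:

====================  =========================================
Huckman number        A + B
ventricle index       D / A
lateral body index    F / E
width of lateral ventricular body index  G / E
ventricle forefoot index                 G / A
third-ventricle width C
Sylvian average       (HL + HR) / 2
====================  =========================================

Together with the binary sulci-enlargement flag (and, in *integrated* mode,
age and gender) they feed an L2-regularized logistic regression — binomial
for atrophy/no-atrophy, multinomial for the no/mild/severe grading — whose
regularization strength is chosen by stratified 5-fold cross-validation.
Binary decisions use the 0.5 probability threshold; three-class prediction
is the probability argmax with ties resolved toward the more severe grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .phantom import CLASSES, MeasurementSet

__all__ = [
    "INDEX_NAMES",
    "ClassifierConfig",
    "AtrophyModel",
    "ClassificationResult",
    "compute_indices",
    "encode_features",
    "fit_classifier",
    "predict",
]

INDEX_NAMES = (
    "huckman_number",
    "ventricle_index",
    "lateral_body_index",
    "width_lateral_body_index",
    "forefoot_index",
    "third_ventricle_width",
    "sylvian_avg",
)
FEATURE_NAMES_BASE = INDEX_NAMES + ("sulci_enlarged",)
FEATURE_NAMES_INTEGRATED = FEATURE_NAMES_BASE + ("age", "gender_code")


def compute_indices(m: MeasurementSet) -> dict[str, float]:
    """The seven derived indices, by exact arithmetic on the measurements."""
    if not m.A > 0:
        raise ValueError("frontal horn width A must be > 0 (denominator)")
    if not m.E > 0:
        raise ValueError("ventricular body width E must be > 0 (denominator)")
    return {
        "huckman_number": m.A + m.B,
        "ventricle_index": m.D / m.A,
        "lateral_body_index": m.F / m.E,
        "width_lateral_body_index": m.G / m.E,
        "forefoot_index": m.G / m.A,
        "third_ventricle_width": m.C,
        "sylvian_avg": (m.HL + m.HR) / 2.0,
    }


def encode_features(
    indices: dict[str, float],
    sulci_enlarged: bool,
    *,
    age: float | None = None,
    gender_code: int | None = None,
    integrated: bool = False,
) -> np.ndarray:
    """Feature vector: 7 indices + sulci flag (+ age, gender if integrated)."""
    vec = [float(indices[name]) for name in INDEX_NAMES]
    vec.append(1.0 if sulci_enlarged else 0.0)
    if integrated:
        if age is None or gender_code is None:
            raise ValueError("integrated mode requires age and gender")
        vec.extend([float(age), float(gender_code)])
    return np.asarray(vec, dtype=float)


@dataclass(frozen=True)
class ClassifierConfig:
    Cs: int = 10  # grid size for the inverse regularization strength
    n_folds: int = 5
    max_iter: int = 5000
    seed: int = 0


@dataclass
class AtrophyModel:
    estimator: LogisticRegressionCV
    task: str  # two_class | three_class
    integrated: bool
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    classes: tuple[str, ...]
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    @property
    def coefficients(self) -> np.ndarray:
        return self.estimator.coef_

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_mean) / self.feature_scale


@dataclass(frozen=True)
class ClassificationResult:
    class_probabilities: np.ndarray
    predicted_class: str
    task: str
    integrated: bool

    def __post_init__(self) -> None:
        p = self.class_probabilities
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class probabilities must be in [0,1] and sum to 1")


def _standardization(x: np.ndarray, integrated: bool) -> tuple[np.ndarray, np.ndarray]:
    # continuous features are z-scored; the binary sulci flag and gender code
    # are passed through unscaled
    names = FEATURE_NAMES_INTEGRATED if integrated else FEATURE_NAMES_BASE
    mean = np.zeros(len(names))
    scale = np.ones(len(names))
    for j, name in enumerate(names):
        if name in ("sulci_enlarged", "gender_code"):
            continue
        mean[j] = x[:, j].mean()
        sd = x[:, j].std()
        scale[j] = sd if sd > 1e-12 else 1.0
    return mean, scale


def fit_classifier(
    features: np.ndarray,
    labels,
    task: str,
    config: ClassifierConfig | None = None,
    *,
    integrated: bool = False,
) -> AtrophyModel:
    """Fit the regularized logistic atrophy classifier.

    ``labels`` are ordinal class names; in two-class mode *mild* and
    *severe* are grouped as "atrophy".  The L2 strength is selected by
    stratified 5-fold cross-validation on the training split only.
    """
    cfg = config or ClassifierConfig()
    if task not in ("two_class", "three_class"):
        raise ValueError("task must be 'two_class' or 'three_class'")
    x = np.asarray(features, dtype=float)
    labels = list(labels)
    for lab in labels:
        if lab not in CLASSES:
            raise ValueError(f"unknown class label {lab!r}; allowed: {CLASSES}")
    expected = len(FEATURE_NAMES_INTEGRATED if integrated else FEATURE_NAMES_BASE)
    if x.shape[1] != expected:
        raise ValueError(f"expected {expected} features, got {x.shape[1]}")

    if task == "two_class":
        classes = ("no_atrophy", "atrophy")
        y = np.array([0 if lab == "no_atrophy" else 1 for lab in labels])
        if len(np.unique(y)) < 2:
            raise ValueError("two-class fit requires both classes present")
    else:
        classes = CLASSES
        y = np.array([CLASSES.index(lab) for lab in labels])
        if len(np.unique(y)) < 3:
            missing = [c for i, c in enumerate(CLASSES) if i not in np.unique(y)]
            raise ValueError(f"three-class fit missing labels: {missing}")

    mean, scale = _standardization(x, integrated)
    xs = (x - mean) / scale
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    est = LogisticRegressionCV(
        Cs=cfg.Cs,
        cv=cv,
        l1_ratios=(0.0,),  # pure L2
        solver="lbfgs",
        scoring="neg_log_loss",
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
        use_legacy_attributes=False,
    )
    est.fit(xs, y)
    return AtrophyModel(
        estimator=est,
        task=task,
        integrated=integrated,
        feature_mean=mean,
        feature_scale=scale,
        classes=classes,
        config=cfg,
    )


def predict(features: np.ndarray, model: AtrophyModel) -> list[ClassificationResult]:
    """Classify one or more feature vectors.

    Two-class: positive ("atrophy") iff its probability >= 0.5.
    Three-class: argmax probability, ties toward the more severe grade.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    expected = len(model.feature_mean)
    if x.shape[1] != expected:
        raise ValueError(f"feature length {x.shape[1]} does not match model ({expected})")
    probs = model.estimator.predict_proba(model.standardize(x))
    out = []
    for p in probs:
        if model.task == "two_class":
            label = model.classes[1] if p[1] >= 0.5 else model.classes[0]
        else:
            rev = p[::-1]  # scan severe -> no_atrophy so ties pick severity
            label = model.classes[len(p) - 1 - int(np.argmax(rev))]
        out.append(
            ClassificationResult(
                class_probabilities=p,
                predicted_class=label,
                task=model.task,
                integrated=model.integrated,
            )
        )
    return out
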