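"""End-to-end orchestration: training suite, model bundle I/O, inference.

Training follows the modular recipe: the subjects are split once into
training and held-out test sets (stratified by atrophy class, 80/20 by
default) before anything is fitted; the key-slice detector, measurement
regressor and sulci classifier are trained on the training subjects only;
the atrophy classifier is then fitted on the *module outputs* for those
same training subjects, so each module consumes what the previous one
produces.  Inference runs the stages strictly in order
detect -> measure / sulci -> indices -> classify.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression

from . import classifier as clf
from .classifier import AtrophyModel, ClassifierConfig, compute_indices, encode_features
from .features import SubjectData, prepare_subject
from .measure import MeasureConfig, MeasurementModel, predict_measurements, train_measurement_model
from .phantom import CLASSES, CTVolume, load_annotation, load_volume
from .preprocess import AugmentConfig, WindowConfig
from .slice_detect import SliceDetectConfig, SliceDetectorModel, detect_key_slices, train_slice_detector
from .sulci import SulciConfig, SulciModel, predict_sulci, train_sulci_classifier

__all__ = [
    "PipelineConfig",
    "ModelBundle",
    "split_subjects",
    "load_subjects_from_manifest",
    "run_training_suite",
    "run_inference",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    task: str = "three_class"
    integrated: bool = False
    test_fraction: float = 0.2  # the 80/20 training/test split ratio
    stratified: bool = True
    detect: SliceDetectConfig = field(default_factory=SliceDetectConfig)
    measure: MeasureConfig = field(default_factory=MeasureConfig)
    sulci: SulciConfig = field(default_factory=SulciConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    preprocess: WindowConfig = field(default_factory=WindowConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub_cls in (
            ("detect", SliceDetectConfig),
            ("measure", MeasureConfig),
            ("sulci", SulciConfig),
            ("classifier", ClassifierConfig),
            ("preprocess", WindowConfig),
            ("augment", AugmentConfig),
        ):
            if key in raw:
                sub = raw.pop(key)
                if "hidden" in sub:
                    sub["hidden"] = tuple(sub["hidden"])
                if "jitter" in sub:
                    sub["jitter"] = tuple(sub["jitter"])
                if "head_epochs" in sub:
                    sub["head_epochs"] = tuple((str(k), int(v)) for k, v in sub["head_epochs"])
                if "zoom_range" in sub:
                    sub["zoom_range"] = tuple(sub["zoom_range"])
                kwargs[key] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        d = asdict(self)
        d["preprocess"] = WindowConfig(**d["preprocess"])
        aug = d["augment"]
        aug["seed"] = seed
        aug["zoom_range"] = tuple(aug["zoom_range"])
        d["augment"] = AugmentConfig(**aug)
        for key, sub_cls in (
            ("detect", SliceDetectConfig),
            ("measure", MeasureConfig),
            ("sulci", SulciConfig),
            ("classifier", ClassifierConfig),
        ):
            sub = d[key]
            sub["seed"] = seed
            if "hidden" in sub:
                sub["hidden"] = tuple(sub["hidden"])
            if "jitter" in sub:
                sub["jitter"] = tuple(sub["jitter"])
            if "head_epochs" in sub:
                sub["head_epochs"] = tuple((str(k), int(v)) for k, v in sub["head_epochs"])
            d[key] = sub_cls(**sub)
        d["seed"] = seed
        return PipelineConfig(**d)


@dataclass
class ModelBundle:
    detector: SliceDetectorModel
    measurement: MeasurementModel
    sulci: SulciModel
    atrophy: AtrophyModel
    config: PipelineConfig
    report: dict = field(default_factory=dict)

    def require_complete(self) -> None:
        for stage, model in (
            ("slice detection", self.detector),
            ("measurement", self.measurement),
            ("sulci identification", self.sulci),
            ("atrophy classification", self.atrophy),
        ):
            if model is None:
                raise ValueError(f"bundle incomplete: missing {stage} model")


# ------------------------------------------------------------------ splitting
def split_subjects(
    labels, test_fraction: float, seed: int, *, stratified: bool = True
) -> tuple[list[int], list[int]]:
    """Deterministic train/test split of subject indices.

    Stratified by class (default) so small synthetic cohorts stay balanced;
    plain random is available for the unstratified variant.
    """
    labels = list(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    test: list[int] = []
    if stratified:
        for cls_name in sorted(set(labels)):
            idx = [i for i, lab in enumerate(labels) if lab == cls_name]
            k = int(round(len(idx) * test_fraction))
            k = min(max(k, 1), len(idx) - 1) if len(idx) > 1 else 0
            test.extend(int(idx[j]) for j in rng.permutation(len(idx))[:k])
    else:
        k = int(round(n * test_fraction))
        test = [int(i) for i in rng.permutation(n)[:k]]
    test_set = set(test)
    train = [i for i in range(n) if i not in test_set]
    return train, sorted(test)


def load_subjects_from_manifest(
    manifest_path: str | Path, config: PipelineConfig | None = None
) -> list[SubjectData]:
    """Load and pre-process every subject listed in a dataset manifest."""
    window = config.preprocess if config is not None else None
    manifest = pd.read_csv(manifest_path)
    subjects = []
    for row in manifest.itertuples():
        volume = load_volume(row.volume_path)
        annotation = load_annotation(row.annotation_path)
        subjects.append(
            prepare_subject(
                str(row.subject_id),
                volume,
                annotation,
                age=float(row.age),
                gender_code=int(row.gender_code),
                window=window,
            )
        )
    return subjects


# ------------------------------------------------------------------- training
def _module_features(subject: SubjectData, bundle_parts: dict, integrated: bool):
    """Run detect -> measure/sulci -> indices on one subject; returns the
    atrophy-classifier feature vector plus the intermediate outputs."""
    detector: SliceDetectorModel = bundle_parts["detector"]
    measurement: MeasurementModel = bundle_parts["measurement"]
    sulci_model: SulciModel = bundle_parts["sulci"]
    stack = subject.stacks[detector.config.input_size]
    key_slices = detect_key_slices(stack, detector)
    measures, flags = predict_measurements(subject, key_slices, measurement)
    sulci_res = predict_sulci(subject, key_slices.key4, sulci_model)
    indices = compute_indices(measures)
    features = encode_features(
        indices,
        sulci_res.enlarged,
        age=subject.age,
        gender_code=subject.gender_code,
        integrated=integrated,
    )
    return features, key_slices, measures, sulci_res, indices, flags


def run_training_suite(
    subjects: list[SubjectData], config: PipelineConfig | None = None
) -> tuple[ModelBundle, dict]:
    """Train all four modules with a leak-free stratified split.

    Returns the fitted bundle and a training report (split membership,
    per-module cross-validation metrics).  The held-out test subjects are
    never seen by any module.
    """
    cfg = config or PipelineConfig()
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in the training manifest")
    labels = [s.atrophy_class for s in subjects]
    if any(lab is None for lab in labels):
        raise ValueError("all subjects need an atrophy class label for training")
    train_idx, test_idx = split_subjects(
        labels, cfg.test_fraction, cfg.seed, stratified=cfg.stratified
    )
    leak = set(train_idx) & set(test_idx)
    if leak:
        raise RuntimeError(f"test-set leakage: subjects in both splits: {sorted(leak)}")
    train = [subjects[i] for i in train_idx]

    detector = train_slice_detector(train, cfg.detect)
    measurement = train_measurement_model(train, cfg.measure)
    sulci_model = train_sulci_classifier(train, cfg.sulci)

    parts = {"detector": detector, "measurement": measurement, "sulci": sulci_model}
    feats = []
    for s in train:
        features, *_ = _module_features(s, parts, cfg.integrated)
        feats.append(features)
    atrophy = clf.fit_classifier(
        np.array(feats),
        [s.atrophy_class for s in train],
        cfg.task,
        cfg.classifier,
        integrated=cfg.integrated,
    )

    report = {
        "seed": cfg.seed,
        "task": cfg.task,
        "integrated": cfg.integrated,
        "train_subjects": [subjects[i].subject_id for i in train_idx],
        "test_subjects": [subjects[i].subject_id for i in test_idx],
        "slice_detector_folds": detector.report["folds"],
        "measurement_final_mse": measurement.report["final_mse"],
        "measurement_fold_mse": measurement.report["fold_mse"],
        "sulci_fold_accuracies": sulci_model.report["fold_accuracies"],
    }
    bundle = ModelBundle(
        detector=detector,
        measurement=measurement,
        sulci=sulci_model,
        atrophy=atrophy,
        config=cfg,
        report=report,
    )
    return bundle, report


# ------------------------------------------------------------------ inference
def run_inference(
    volume_or_subject: CTVolume | SubjectData,
    bundle: ModelBundle,
    *,
    age: float | None = None,
    gender_code: int | None = None,
    subject_id: str = "subject",
) -> dict:
    """Full pipeline on one subject: detect -> measure/sulci -> classify.

    Returns a JSON-serializable report with the detected key slices, the
    nine measurements (mm), the seven indices, the sulci result and the
    class probabilities.
    """
    bundle.require_complete()
    if isinstance(volume_or_subject, SubjectData):
        subject = volume_or_subject
    else:
        subject = prepare_subject(
            subject_id, volume_or_subject, age=age, gender_code=gender_code
        )
    if age is not None:
        subject.age = age
    if gender_code is not None:
        subject.gender_code = gender_code
    if bundle.config.integrated and (subject.age is None or subject.gender_code is None):
        raise ValueError("integrated bundle requires age and gender metadata")

    parts = {
        "detector": bundle.detector,
        "measurement": bundle.measurement,
        "sulci": bundle.sulci,
    }
    features, key_slices, measures, sulci_res, indices, flags = _module_features(
        subject, parts, bundle.config.integrated
    )
    result = clf.predict(features, bundle.atrophy)[0]
    return {
        "subject_id": subject.subject_id,
        "key_slices": asdict(key_slices),
        "estimated_tilt_deg": subject.estimated_tilt_deg,
        "measurements_mm": {k: float(getattr(measures, k)) for k in measures.NAMES},
        "indices": {k: float(v) for k, v in indices.items()},
        "sulci": {"enlarged": bool(sulci_res.enlarged), "probability": sulci_res.probability},
        "classification": {
            "task": result.task,
            "integrated": result.integrated,
            "probabilities": {
                c: float(p) for c, p in zip(bundle.atrophy.classes, result.class_probabilities)
            },
            "predicted_class": result.predicted_class,
        },
        "clamped_measurements": flags,
        "seed": bundle.config.seed,
    }


# ----------------------------------------------------------------- bundle I/O
def save_bundle(bundle: ModelBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "slice_detector.npz", **bundle.detector.to_arrays())
    np.savez(out / "measurement.npz", **bundle.measurement.to_arrays())
    np.savez(out / "sulci.npz", **bundle.sulci.to_arrays())
    est = bundle.atrophy.estimator
    (out / "atrophy_classifier.json").write_text(
        json.dumps(
            {
                "coef": est.coef_.tolist(),
                "intercept": est.intercept_.tolist(),
                "sk_classes": np.asarray(est.classes_).tolist(),
                "task": bundle.atrophy.task,
                "integrated": bundle.atrophy.integrated,
                "feature_mean": bundle.atrophy.feature_mean.tolist(),
                "feature_scale": bundle.atrophy.feature_scale.tolist(),
                "classes": list(bundle.atrophy.classes),
                "config": asdict(bundle.atrophy.config),
            },
            indent=1,
        )
    )
    cfg = asdict(bundle.config)
    (out / "pipeline_config.json").write_text(json.dumps(cfg, indent=1))
    (out / "training_report.json").write_text(json.dumps(bundle.report, indent=1))


def load_bundle(bundle_dir: str | Path) -> ModelBundle:
    d = Path(bundle_dir)
    for fname, stage in (
        ("slice_detector.npz", "slice detection"),
        ("measurement.npz", "measurement"),
        ("sulci.npz", "sulci identification"),
        ("atrophy_classifier.json", "atrophy classification"),
        ("pipeline_config.json", "pipeline configuration"),
    ):
        if not (d / fname).exists():
            raise FileNotFoundError(f"bundle incomplete: missing {stage} ({fname})")
    raw_cfg = json.loads((d / "pipeline_config.json").read_text())
    for key, sub_cls in (
        ("detect", SliceDetectConfig),
        ("measure", MeasureConfig),
        ("sulci", SulciConfig),
        ("classifier", ClassifierConfig),
        ("preprocess", WindowConfig),
        ("augment", AugmentConfig),
    ):
        sub = raw_cfg[key]
        if "hidden" in sub:
            sub["hidden"] = tuple(sub["hidden"])
        if "jitter" in sub:
            sub["jitter"] = tuple(sub["jitter"])
        if "head_epochs" in sub:
            sub["head_epochs"] = tuple((str(k), int(v)) for k, v in sub["head_epochs"])
        if "zoom_range" in sub:
            sub["zoom_range"] = tuple(sub["zoom_range"])
        raw_cfg[key] = sub_cls(**sub)
    cfg = PipelineConfig(**raw_cfg)
    report = json.loads((d / "training_report.json").read_text()) if (d / "training_report.json").exists() else {}

    detector = SliceDetectorModel.from_arrays(
        dict(np.load(d / "slice_detector.npz")), cfg.detect, report
    )
    measurement = MeasurementModel.from_arrays(
        dict(np.load(d / "measurement.npz")), cfg.measure, report
    )
    sulci_model = SulciModel.from_arrays(dict(np.load(d / "sulci.npz")), cfg.sulci, report)

    meta = json.loads((d / "atrophy_classifier.json").read_text())
    est = LogisticRegression(solver="lbfgs")
    est.coef_ = np.array(meta["coef"])
    est.intercept_ = np.array(meta["intercept"])
    est.classes_ = np.array(meta["sk_classes"])
    atrophy = AtrophyModel(
        estimator=est,
        task=meta["task"],
        integrated=meta["integrated"],
        feature_mean=np.array(meta["feature_mean"]),
        feature_scale=np.array(meta["feature_scale"]),
        classes=tuple(meta["classes"]),
        config=ClassifierConfig(**meta["config"]),
    )
    return ModelBundle(
        detector=detector,
        measurement=measurement,
        sulci=sulci_model,
        atrophy=atrophy,
        config=cfg,
        report=report,
    )
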