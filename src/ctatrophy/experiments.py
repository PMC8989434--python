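"""Desk-scale validation experiments on synthetic phantoms.

These functions reproduce the pipeline's evaluation protocol end to end on
the phantom population: ground-truth-feature classification at a 300/100
split, learned-module recovery after CPU-scale training on 200 phantoms,
and tilt-estimation recovery.  They are used both by the test suite and by
the reproducibility script, and return plain dictionaries of the computed
quantities.
"""

from __future__ import annotations

import numpy as np

from . import phantom as ph
from .classifier import ClassifierConfig, compute_indices, encode_features, fit_classifier, predict
from .features import prepare_subject
from .measure import MeasureConfig, oracle_measurements, predict_measurements, train_measurement_model
from .phantom import CLASSES, dataset_specs, render_volume, sample_phantom_spec
from .preprocess import estimate_head_tilt
from .slice_detect import SliceDetectConfig, detect_key_slices, train_slice_detector
from .stats import agreement_stats, binary_metrics, kappa, multiclass_metrics, roc_auc
from .sulci import SulciConfig, predict_sulci, sulci_rule_oracle, train_sulci_classifier

__all__ = [
    "oracle_feature_classification",
    "learned_module_recovery",
    "rotation_recovery",
]


def _class_specs(n_per_class: int, seed: int, offset: int = 0):
    out = []
    i = 0
    for cls in CLASSES:
        for _ in range(n_per_class):
            out.append(sample_phantom_spec(cls, (seed * 2_000_003 + offset + i) % (2**31)))
            i += 1
    return out


def oracle_feature_classification(
    n_train_per_class: int = 100, n_test_per_class: int = 34, seed: int = 0
) -> dict:
    """Atrophy classification from ground-truth measurements and sulci flags.

    Trains the logistic classifier on oracle features of ``3 *
    n_train_per_class`` phantoms and evaluates on an independent test set:
    two-class AUC, three-class weighted kappa, and the base-versus-
    integrated (age + gender) comparison.
    """
    train = _class_specs(n_train_per_class, seed)
    test = _class_specs(n_test_per_class, seed, offset=900_000)

    def feats(specs, integrated):
        x, y = [], []
        for s in specs:
            idx = compute_indices(oracle_measurements(s))
            x.append(
                encode_features(
                    idx,
                    sulci_rule_oracle(s.parietal_sulci_widths),
                    age=s.age,
                    gender_code=s.gender_code,
                    integrated=integrated,
                )
            )
            y.append(s.atrophy_class)
        return np.array(x), y

    out: dict = {"n_train": len(train), "n_test": len(test)}
    for integrated in (False, True):
        xtr, ytr = feats(train, integrated)
        xte, yte = feats(test, integrated)
        cfg = ClassifierConfig(seed=seed)
        m2 = fit_classifier(xtr, ytr, "two_class", cfg, integrated=integrated)
        scores = m2.estimator.predict_proba(m2.standardize(xte))[:, 1]
        truth = np.array([lab != "no_atrophy" for lab in yte])
        auc, ci = roc_auc(scores, truth)
        m3 = fit_classifier(xtr, ytr, "three_class", cfg, integrated=integrated)
        pred3 = [r.predicted_class for r in predict(xte, m3)]
        mm = multiclass_metrics(pred3, yte)
        tag = "integrated" if integrated else "base"
        out[f"two_class_auc_{tag}"] = auc
        out[f"two_class_auc_ci_{tag}"] = ci
        out[f"three_class_weighted_kappa_{tag}"] = mm.weighted_kappa
        out[f"three_class_accuracy_{tag}"] = mm.accuracy
    return out


def learned_module_recovery(
    n_train: int = 200,
    n_test: int = 50,
    seed: int = 0,
    *,
    detect_config: SliceDetectConfig | None = None,
    measure_config: MeasureConfig | None = None,
    sulci_config: SulciConfig | None = None,
) -> dict:
    """Train the three image modules on rendered phantoms and measure their
    held-out recovery of the analytic ground truth.

    Reports per-key-slice exact-or-adjacent detection accuracy, Pearson
    correlation / MAE / paired-t p-value of each predicted measurement
    against the oracle, and sulci classification accuracy and kappa.
    """
    n_total = n_train + n_test
    per_class = int(np.ceil(n_total / 3))
    subjects = []
    for sid, spec in dataset_specs(per_class, seed)[:n_total]:
        vol, ann = render_volume(spec)
        subjects.append(
            prepare_subject(sid, vol, ann, age=spec.age, gender_code=spec.gender_code)
        )
    order = np.random.default_rng(seed).permutation(n_total)
    train = [subjects[i] for i in order[:n_train]]
    test = [subjects[i] for i in order[n_train:]]

    dcfg = detect_config or SliceDetectConfig(epochs=20, seed=seed)
    mcfg = measure_config or MeasureConfig(epochs=150, seed=seed)
    scfg = sulci_config or SulciConfig(epochs=25, seed=seed)

    out: dict = {"n_train": n_train, "n_test": len(test)}

    detector = train_slice_detector(train, dcfg)
    hits = {k: 0 for k in ("key1", "key2", "key3", "key4")}
    for s in test:
        ks = detect_key_slices(s.stacks[dcfg.input_size], detector)
        for k in hits:
            hits[k] += int(abs(getattr(ks, k) - getattr(s.key_slices, k)) <= 1)
    for k, v in hits.items():
        out[f"detect_adjacent_accuracy_{k}"] = v / len(test)

    model = train_measurement_model(train, mcfg)
    pred = np.array([predict_measurements(s, s.key_slices, model)[0].as_array() for s in test])
    truth = np.array([s.measurements.as_array() for s in test])
    for i, name in enumerate(ph.MeasurementSet.NAMES):
        ag = agreement_stats(pred[:, i], truth[:, i])
        out[f"measure_pearson_r_{name}"] = ag.pearson_r
        out[f"measure_mae_mm_{name}"] = float(np.mean(np.abs(pred[:, i] - truth[:, i])))
        out[f"measure_paired_t_p_{name}"] = ag.t_p_value

    sulci_model = train_sulci_classifier(train, scfg)
    s_pred, s_truth = [], []
    for s in test:
        s_pred.append(predict_sulci(s, s.key_slices.key4, sulci_model).enlarged)
        s_truth.append(bool(s.sulci_enlarged))
    bm = binary_metrics(s_pred, s_truth)
    out["sulci_accuracy"] = bm.accuracy
    out["sulci_cohen_kappa"] = kappa(
        [int(p) for p in s_pred], [int(t) for t in s_truth], "none", categories=[0, 1]
    )
    return out


def rotation_recovery(n_phantoms: int = 20, seed: int = 0, max_tilt: float = 8.0) -> dict:
    """Render phantoms with known tilts and measure estimation error."""
    rng = np.random.default_rng(seed)
    errors = []
    import dataclasses

    for i in range(n_phantoms):
        tilt = float(rng.uniform(-max_tilt, max_tilt))
        spec = sample_phantom_spec(CLASSES[i % 3], (seed * 3_000_017 + i) % (2**31))
        spec = dataclasses.replace(spec, head_tilt_deg=tilt)
        vol, _ = render_volume(spec)
        errors.append(abs(estimate_head_tilt(vol) - tilt))
    return {
        "n_phantoms": n_phantoms,
        "max_abs_error_deg": float(np.max(errors)),
        "mean_abs_error_deg": float(np.mean(errors)),
    }
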