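"""Performance and agreement statistics for the atrophy pipeline.

Binary metrics (sensitivity, specificity, accuracy, F1), ROC AUC with a
DeLong 95% CI, the paired DeLong test for comparing correlated ROC curves,
Cohen's and weighted kappa, macro/micro F1 for the three-class grading, and
the paired t-test / Pearson correlation protocol used to judge automatic
linear measurements against a reference.

AUC is the Mann-Whitney statistic (ties counted 1/2), computed from
midranks; the DeLong variance comes from the structural components of that
statistic, which also yield the paired test for two markers scored on the
same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "BinaryMetrics",
    "MulticlassMetrics",
    "AgreementStats",
    "binary_metrics",
    "roc_auc",
    "delong_test",
    "kappa",
    "agreement_stats",
    "multiclass_metrics",
]


@dataclass
class BinaryMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class MulticlassMetrics:
    accuracy: float
    average_f1: float  # macro over the three ordered classes
    micro_f1: float
    weighted_kappa: float  # linear weights (default reporting)
    weighted_kappa_quadratic: float
    notes: list[str] = field(default_factory=list)


@dataclass
class AgreementStats:
    pearson_r: float
    r_p_value: float
    paired_t: float
    t_p_value: float
    notes: list[str] = field(default_factory=list)


# ------------------------------------------------------------ binary metrics
def binary_metrics(predicted, truth) -> BinaryMetrics:
    """Sensitivity, specificity, accuracy and F1 from boolean vectors."""
    pred = np.asarray(predicted, dtype=bool)
    y = np.asarray(truth, dtype=bool)
    if pred.shape != y.shape or pred.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    notes = []

    def ratio(num, den, name):
        if den == 0:
            notes.append(f"{name} undefined (empty denominator)")
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / pred.size
    prec = ratio(tp, tp + fp, "precision")
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        notes.append("f1 undefined")
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return BinaryMetrics(sensitivity=sens, specificity=spec, accuracy=acc, f1=f1, notes=notes)


# ------------------------------------------------------------------ ROC/AUC
def _delong_components(scores: np.ndarray, truth: np.ndarray):
    """AUC and its structural components V10 (positives), V01 (negatives)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute AUC")
    all_scores = np.concatenate([pos, neg])
    tz = sps.rankdata(all_scores)  # midranks over the pooled sample
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return auc, v10, v01


def roc_auc(scores, truth, *, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a DeLong-variance normal-approximation CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if scores.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    auc, v10, v01 = _delong_components(scores, y)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(var)
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return float(auc), (float(lo), float(hi))


def delong_test(scores_a, scores_b, truth) -> tuple[float, float, float]:
    """Paired DeLong test comparing two correlated ROC AUCs.

    Returns (auc_a, auc_b, two-sided p).  Scores must be paired on the same
    subjects; identical score vectors give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and truth must be paired (equal length)")
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    m, n = len(v10a), len(v01a)
    var = 0.0
    if m > 1:
        s10 = np.cov(v10a, v10b, ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(v01a, v01b, ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(p)


# -------------------------------------------------------------------- kappa
def kappa(rater_a, rater_b, weighting: str = "none", categories=None) -> float:
    """Cohen's kappa, optionally with linear or quadratic ordinal weights.

    Disagreement weights are |i - j| / (k - 1) (linear) or its square
    (quadratic) over the shared ordered category set.
    """
    if weighting not in ("none", "linear", "quadratic"):
        raise ValueError("weighting must be 'none', 'linear' or 'quadratic'")
    a = list(rater_a)
    b = list(rater_b)
    if len(a) != len(b) or not a:
        raise ValueError("rater vectors must be equal-length and non-empty")
    cats = list(categories) if categories is not None else sorted(set(a) | set(b))
    k = len(cats)
    index = {c: i for i, c in enumerate(cats)}
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[index[x], index[y]] += 1
    obs /= obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weighting == "none":
        w = (ii != jj).astype(float)
    else:
        w = np.abs(ii - jj) / max(k - 1, 1)
        if weighting == "quadratic":
            w = w**2
    denom = float((w * expected).sum())
    if denom == 0:  # a rater used a single category: agreement is degenerate
        return 1.0 if float((w * obs).sum()) == 0 else 0.0
    return float(1.0 - (w * obs).sum() / denom)


# ------------------------------------------------------- measurement agreement
def agreement_stats(x, y) -> AgreementStats:
    """Pearson correlation and paired t-test between two paired samples.

    Used to compare automatic measurements with their reference: good
    agreement = high r and a non-significant paired difference.  When all
    differences are zero the t statistic is 0 and p is reported as 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be paired with length >= 3")
    notes = []
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        notes.append("correlation undefined (zero variance)")
        r, r_p = float("nan"), float("nan")
    else:
        r, r_p = sps.pearsonr(x, y)
    diffs = x - y
    if np.ptp(diffs) == 0:
        if diffs[0] == 0:
            t, t_p = 0.0, 1.0  # identical pairs: no difference by convention
        else:
            t, t_p = float(np.sign(diffs[0]) * np.inf), 0.0
            notes.append("constant non-zero difference")
    else:
        t, t_p = sps.ttest_rel(x, y)
    return AgreementStats(
        pearson_r=float(r),
        r_p_value=float(r_p),
        paired_t=float(t),
        t_p_value=float(t_p),
        notes=notes,
    )


# ----------------------------------------------------------- multiclass
def multiclass_metrics(predicted, truth, classes=None) -> MulticlassMetrics:
    """Accuracy, macro ("average") F1 and weighted kappa for ordinal grades."""
    from .phantom import CLASSES

    classes = tuple(classes) if classes is not None else CLASSES
    pred = list(predicted)
    y = list(truth)
    if len(pred) != len(y) or not y:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    bad = [lab for lab in set(pred) | set(y) if lab not in classes]
    if bad:
        raise ValueError(f"labels outside the class set: {bad}")
    pred_arr = np.array([classes.index(p) for p in pred])
    y_arr = np.array([classes.index(t) for t in y])
    acc = float(np.mean(pred_arr == y_arr))
    notes = []
    f1s = []
    tp_total = 0
    for ci, cname in enumerate(classes):
        if not np.any(y_arr == ci) and not np.any(pred_arr == ci):
            notes.append(f"class {cname} absent; F1 contribution 0")
            f1s.append(0.0)
            continue
        bm = binary_metrics(pred_arr == ci, y_arr == ci)
        f1s.append(0.0 if np.isnan(bm.f1) else bm.f1)
        tp_total += int(np.sum((pred_arr == ci) & (y_arr == ci)))
    micro = tp_total / len(y)  # single-label multiclass: micro-F1 == accuracy
    return MulticlassMetrics(
        accuracy=acc,
        average_f1=float(np.mean(f1s)),
        micro_f1=float(micro),
        weighted_kappa=kappa(pred, y, "linear", categories=classes),
        weighted_kappa_quadratic=kappa(pred, y, "quadratic", categories=classes),
        notes=notes,
    )
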