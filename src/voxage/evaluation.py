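"""Threshold-swept FAR/FRR, equal error rate and verification accuracy.

For each threshold t in {0.00, 0.01, ..., 1.00} a test item is accepted
as the target iff its target-class probability strictly exceeds t. The
false acceptance rate FAR = FP / (FP + TN) and false rejection rate
FRR = FN / (FN + TP) are computed per threshold; the EER is read off at
the threshold where |FAR - FRR| is smallest (ties toward the smaller
threshold) as (FAR + FRR) / 2, and verification accuracy is 1 - EER.
Ensemble results are the mean of per-model accuracies, not a pooled
score set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

THRESHOLDS = np.round(np.arange(0, 101) * 0.01, 2)


class UndefinedRateError(ValueError):
    """A rate whose denominator is zero (missing class)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ThresholdCurve:
    thresholds: np.ndarray
    far_values: np.ndarray
    frr_values: np.ndarray


@dataclass(frozen=True)
class EerResult:
    eer: float
    threshold_at_eer: float
    accuracy: float


def confusion_at_threshold(p_target, is_target,
                           threshold: float) -> ConfusionCounts:
    """Counts with strict acceptance: predicted target iff p > threshold."""
    p = np.asarray(p_target, dtype=np.float64)
    y = np.asarray(is_target, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("p_target and is_target lengths differ")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present in the truth")
    pred = p > threshold
    return ConfusionCounts(tp=int(np.sum(pred & y)),
                           fp=int(np.sum(pred & ~y)),
                           tn=int(np.sum(~pred & ~y)),
                           fn=int(np.sum(~pred & y)))


def far(c: ConfusionCounts) -> float:
    """False acceptance rate FP / (FP + TN)."""
    if c.fp + c.tn == 0:
        raise UndefinedRateError("FAR undefined: no non-target samples")
    return c.fp / (c.fp + c.tn)


def frr(c: ConfusionCounts) -> float:
    """False rejection rate FN / (FN + TP)."""
    if c.fn + c.tp == 0:
        raise UndefinedRateError("FRR undefined: no target samples")
    return c.fn / (c.fn + c.tp)


def threshold_curve(p_target, is_target) -> ThresholdCurve:
    """FAR and FRR over the 101-point threshold grid (vectorized)."""
    p = np.asarray(p_target, dtype=np.float64)
    y = np.asarray(is_target, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("p_target and is_target lengths differ")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present in the truth")
    accept = p[None, :] > THRESHOLDS[:, None]  # (101, n)
    n_target = int(y.sum())
    n_non = y.size - n_target
    fp = np.sum(accept & ~y[None, :], axis=1)
    tp = np.sum(accept & y[None, :], axis=1)
    return ThresholdCurve(thresholds=THRESHOLDS.copy(),
                          far_values=fp / n_non,
                          frr_values=(n_target - tp) / n_target)


def eer(curve: ThresholdCurve) -> EerResult:
    """EER at the grid threshold where FAR and FRR are closest."""
    if curve.thresholds.size == 0:
        raise ValueError("empty threshold curve")
    gap = np.abs(curve.far_values - curve.frr_values)
    i = int(np.argmin(gap))  # argmin takes the first (lowest) threshold
    value = (curve.far_values[i] + curve.frr_values[i]) / 2.0
    return EerResult(eer=float(value),
                     threshold_at_eer=float(curve.thresholds[i]),
                     accuracy=1.0 - float(value))


def accuracy_from_scores(p_target, is_target) -> float:
    """EER-based verification accuracy of one score set."""
    return eer(threshold_curve(p_target, is_target)).accuracy


def evaluate_cross_period(models, test_features: np.ndarray,
                          test_is_target) -> dict:
    """Score an ensemble on held-out (other-period) samples.

    Returns per-model EER results and their mean accuracy — the ensemble
    average is the final verification accuracy.
    """
    from . import verifier  # local import to avoid a cycle at import time

    if not models:
        raise ValueError("ensemble must contain at least one model")
    per_model = []
    for model in models:
        p = verifier.predict_proba(model, test_features)[:, 0]
        per_model.append(eer(threshold_curve(p, test_is_target)))
    return {
        "per_model": per_model,
        "accuracies": [r.accuracy for r in per_model],
        "mean_accuracy": float(np.mean([r.accuracy for r in per_model])),
    }
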