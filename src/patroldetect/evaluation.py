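"""Posterior-predictive classification and its scores.

The model's point prediction for a record is the posterior mean of the
marginal detection probability v*p.  Classifying at a fixed threshold gives a
confusion matrix (rows = model prediction, columns = dataset outcome) and the
usual precision/recall/F1; on heavily imbalanced data the F1-optimal
threshold is found by a grid sweep and typically sits well below 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .records import Design
from .sampling import PosteriorDraws


@dataclass
class ConfusionMatrix:
    """2x2 counts, prediction (rows) against dataset outcome (columns)."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            [[self.tn, self.fn], [self.fp, self.tp]],
            index=["predicted not detected", "predicted detected"],
            columns=["not detected", "detected"],
        )


@dataclass
class Scores:
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    accuracy: float


@dataclass
class ThresholdSweepResult:
    thresholds: np.ndarray
    f1: np.ndarray            # NaN where undefined
    best_threshold: float | None
    best_f1: float | None
    no_positives: bool = False


# ---------------------------------------------------------------------------

def _posterior_mean_probs(draws: PosteriorDraws, design: Design, batch: int = 250):
    """Posterior means of p, v and v*p per record, averaged over all draws."""
    B = draws.flat()
    k_det = len(design.det_names)
    S = B.shape[0]
    n = design.n_records
    p_sum = np.zeros(n)
    v_sum = np.zeros(n)
    vp_sum = np.zeros(n)
    for start in range(0, S, batch):
        chunk = B[start : start + batch]
        eta_det = chunk[:, 0][None, :] + design.X_det @ chunk[:, 1 : 1 + k_det].T
        eta_viol = chunk[:, 1 + k_det][None, :] + design.X_viol @ chunk[:, 2 + k_det :].T
        p = expit(eta_det)
        v = expit(eta_viol)
        p_sum += p.sum(axis=1)
        v_sum += v.sum(axis=1)
        vp_sum += (v * p).sum(axis=1)
    return p_sum / S, v_sum / S, vp_sum / S


def posterior_mean_probabilities(draws: PosteriorDraws, design: Design):
    """Per-record posterior means of detectability p, violation probability v,
    and the marginal detection probability v*p."""
    return _posterior_mean_probs(draws, design)


def posterior_predict(draws: PosteriorDraws, design: Design) -> np.ndarray:
    """Per-record posterior mean of the marginal probability P(y=1) = v*p."""
    return _posterior_mean_probs(draws, design)[2]


def classify(probabilities, threshold: float) -> np.ndarray:
    """Threshold the predicted probabilities; a value exactly at the
    threshold classifies as detected (1)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return (np.asarray(probabilities, dtype=float) >= threshold).astype(int)


def confusion_and_scores(predictions, outcomes):
    """Confusion matrix plus precision, recall, specificity, F1 and accuracy.

    Undefined ratios (zero denominators) are reported as None with a warning,
    never silently as 0.
    """
    pred = np.asarray(predictions, dtype=int)
    obs = np.asarray(outcomes, dtype=int)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {obs.shape} outcomes")
    cm = ConfusionMatrix(
        tn=int(((pred == 0) & (obs == 0)).sum()),
        fp=int(((pred == 1) & (obs == 0)).sum()),
        fn=int(((pred == 0) & (obs == 1)).sum()),
        tp=int(((pred == 1) & (obs == 1)).sum()),
    )

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as missing")
            return None
        return num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        if precision is not None and recall is not None:
            warnings.warn("F1 undefined (precision + recall = 0); reported as missing")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (cm.tp + cm.tn) / cm.n
    return cm, Scores(precision=precision, recall=recall, specificity=specificity,
                      f1=f1, accuracy=accuracy)


def threshold_sweep(probabilities, outcomes, step: float = 0.01) -> ThresholdSweepResult:
    """Evaluate F1 on the grid {step, 2*step, ..., 1-step} and return the best
    threshold (smallest argmax on ties)."""
    if not 0 < step <= 0.5:
        raise ValueError("grid step must lie in (0, 0.5]")
    probs = np.asarray(probabilities, dtype=float)
    obs = np.asarray(outcomes, dtype=int)
    n_steps = int(round(1.0 / step))
    thresholds = np.round(np.arange(1, n_steps) * step, 12)
    thresholds = thresholds[thresholds < 1.0]

    no_positives = obs.sum() == 0
    f1s = np.full(len(thresholds), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, t in enumerate(thresholds):
            _, scores = confusion_and_scores(classify(probs, t), obs)
            if scores.f1 is not None:
                f1s[i] = scores.f1
    if no_positives:
        warnings.warn("no positive outcomes: F1 undefined at every threshold")
        return ThresholdSweepResult(thresholds, f1s, None, None, no_positives=True)
    if np.isnan(f1s).all():
        return ThresholdSweepResult(thresholds, f1s, None, None)
    best = int(np.nanargmax(f1s))
    return ThresholdSweepResult(
        thresholds, f1s, best_threshold=float(thresholds[best]), best_f1=float(f1s[best])
    )
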