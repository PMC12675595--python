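"""Classification metrics with Youden-index thresholding."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["Metrics", "youden_threshold", "evaluate_scores", "aggregate_runs"]


@dataclass
class Metrics:
    auroc: float
    auprc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    seed: int = 0


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cut-point maximizing Youden's J = sensitivity + specificity − 1.

    Candidates are the observed scores; a sample is called positive
    when its score is at or above the threshold. Ties in J are broken
    toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):  # ascending, so first strict max is the lowest
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    calibration_scores: np.ndarray,
    calibration_labels: np.ndarray,
    seed: int = 0,
) -> Metrics:
    """AUROC/AUPRC from raw scores; thresholded metrics at the Youden cut.

    The threshold is fit on the calibration split (the validation set
    in-domain), then applied to the evaluation scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    threshold = youden_threshold(
        np.asarray(calibration_scores, dtype=float), np.asarray(calibration_labels, dtype=int)
    )
    pred = scores >= threshold
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    return Metrics(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        accuracy=float((pred == labels).mean()),
        sensitivity=float((pred & (labels == 1)).sum() / n_pos),
        specificity=float((~pred & (labels == 0)).sum() / n_neg),
        threshold=float(threshold),
        seed=seed,
    )


def aggregate_runs(values: list[float]) -> dict:
    """Per-seed values with mean ± sd; every individual value is kept."""
    arr = np.asarray(values, dtype=float)
    return {
        "values": arr.tolist(),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n": int(arr.size),
    }
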