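"""Mahalanobis-probability class assignment with no-call statuses.

A spectrum projected into LD space is scored against every class cluster by
its squared Mahalanobis distance; Gaussian kernels (per-class covariance
determinants included) convert distances to posterior probabilities in log
space, so distant points never underflow to an all-zero posterior. A point
is an *outlier* when it is implausibly far from every cluster (chi-square
quantile on the minimum distance), *unclassifiable* when its best posterior
falls below the acceptance threshold, and *classified* otherwise. No-calls
are excluded from accuracy but counted in the duty cycle, mirroring
clinical practice where no decision is made on unclassifiable data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import logsumexp
from scipy.stats import chi2

__all__ = [
    "ClassPrediction",
    "ClassificationStats",
    "mahalanobis_sq",
    "class_log_posteriors",
    "class_posteriors",
    "predict_events",
    "classification_statistics",
]

CLASSIFIED = "classified"
UNCLASSIFIABLE = "unclassifiable"
OUTLIER = "outlier"


@dataclass
class ClassPrediction:
    """Outcome of classifying one spectrum."""

    event_id: str | None
    status: str                      # classified | unclassifiable | outlier
    predicted_class: str | None
    posteriors: dict[str, float]     # per-class, sums to 1
    distances: dict[str, float]      # per-class squared Mahalanobis distance
    threshold_used: float


def mahalanobis_sq(x, centroid, covariance) -> float:
    """Squared Mahalanobis distance (x-c)' Sigma^-1 (x-c)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    diff = x - np.atleast_1d(np.asarray(centroid, dtype=float))
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance must be positive-definite") from err
    sol = scipy.linalg.solve_triangular(L, diff, lower=True)
    return float(sol @ sol)


def class_log_posteriors(d2, log_dets=None, priors=None) -> np.ndarray:
    """Log posterior class probabilities from squared distances.

    posterior_k is proportional to prior_k * exp(-d2_k / 2) / sqrt(det
    Sigma_k); normalization happens entirely in log space.
    """
    d2 = np.asarray(d2, dtype=float)
    squeeze = d2.ndim == 1
    d2 = np.atleast_2d(d2)
    k = d2.shape[1]
    if k < 2:
        raise ValueError("need at least 2 classes")
    if log_dets is None:
        log_dets = np.zeros(k)
    if priors is None:
        priors = np.full(k, 1.0 / k)
    priors = np.asarray(priors, dtype=float)
    log_kernel = np.log(priors)[None, :] - 0.5 * d2 \
        - 0.5 * np.asarray(log_dets, dtype=float)[None, :]
    log_post = log_kernel - logsumexp(log_kernel, axis=1, keepdims=True)
    return log_post[0] if squeeze else log_post


def class_posteriors(d2, log_dets=None, priors=None) -> np.ndarray:
    """Posterior class probabilities (rows sum to 1)."""
    return np.exp(class_log_posteriors(d2, log_dets=log_dets, priors=priors))


def predict_events(model, X, event_ids=None, threshold=None,
                   outlier_quantile=None) -> list[ClassPrediction]:
    """Classify spectra against a fitted PCA-LDA model.

    status is *outlier* if the smallest squared Mahalanobis distance exceeds
    the chi-square quantile (dof = n_ld) for every class, *classified* if
    the top posterior reaches the threshold, else *unclassifiable*. Ties
    break toward ascending class-label order (argmax convention).
    """
    threshold = model.threshold if threshold is None else float(threshold)
    outlier_quantile = (model.outlier_quantile if outlier_quantile is None
                        else float(outlier_quantile))
    d2 = model.mahalanobis_sq(X)
    post = class_posteriors(d2, log_dets=model.log_dets_, priors=model.priors_)
    cutoff = chi2.ppf(outlier_quantile, df=model.n_ld_)
    labels = [str(c) for c in model.classes_]
    if event_ids is None:
        event_ids = [None] * d2.shape[0]
    out: list[ClassPrediction] = []
    for i in range(d2.shape[0]):
        posteriors = {lab: float(p) for lab, p in zip(labels, post[i])}
        distances = {lab: float(v) for lab, v in zip(labels, d2[i])}
        best = int(np.argmax(post[i]))
        if float(d2[i].min()) > cutoff:
            status, predicted = OUTLIER, None
        elif post[i, best] >= threshold:
            status, predicted = CLASSIFIED, labels[best]
        else:
            status, predicted = UNCLASSIFIABLE, None
        out.append(ClassPrediction(
            event_id=None if event_ids[i] is None else str(event_ids[i]),
            status=status, predicted_class=predicted,
            posteriors=posteriors, distances=distances,
            threshold_used=threshold))
    return out


@dataclass
class ClassificationStats:
    """Accuracy over classified calls plus duty-cycle accounting."""

    accuracy: float | None      # None when nothing was classified
    duty_cycle: float
    n_total: int
    n_classified: int
    n_correct: int
    counts: dict[str, int]      # events per status


def classification_statistics(predictions, truth) -> ClassificationStats:
    """Accuracy over classified events and duty cycle over all attempts.

    accuracy = correct / classified (absent when nothing is classified);
    duty_cycle = classified / total attempts. No-calls carry no clinical
    decision, so they are excluded from accuracy but not from the duty
    cycle.
    """
    truth = [str(t) for t in truth]
    if len(truth) != len(predictions):
        raise ValueError("predictions and truth differ in length")
    counts = {CLASSIFIED: 0, UNCLASSIFIABLE: 0, OUTLIER: 0}
    correct = 0
    for pred, t in zip(predictions, truth):
        counts[pred.status] = counts.get(pred.status, 0) + 1
        if pred.status == CLASSIFIED and pred.predicted_class == t:
            correct += 1
    n_total = len(predictions)
    n_classified = counts[CLASSIFIED]
    accuracy = correct / n_classified if n_classified else None
    duty = n_classified / n_total if n_total else 0.0
    return ClassificationStats(accuracy=accuracy, duty_cycle=duty,
                               n_total=n_total, n_classified=n_classified,
                               n_correct=correct, counts=counts)
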