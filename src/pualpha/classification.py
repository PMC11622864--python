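"""Alpha-guided relabeling, retraining, and the six-metric report.

With a trustworthy alpha, the top round(alpha |U|) unlabeled examples by
calibrated probability are relabeled as probable positives and a second
classifier is retrained with out-of-fold CV on the updated labels. When
ground truth is available the retrained scores are compared against it
with six metrics: accuracy, AUC-ROC, Brier score, F1, Matthews correlation
coefficient, and average precision.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn import metrics as skm

from .calibration import calibrate, calibrate_clusters
from .config import CV_FOLDS, DECISION_THRESHOLD, CALIBRATION_BINS, child_seeds, get_logger
from .pu_core import PUDataset, ScoredPU, cv_class1_probabilities
from .pulsnar import SnarAlphaEstimate

logger = get_logger(__name__)


@dataclass
class MetricsReport:
    accuracy: float
    auc_roc: float
    brier: float
    f1: float
    mcc: float
    aps: float
    threshold: float = DECISION_THRESHOLD

    def as_dict(self) -> dict:
        return asdict(self)


def relabel_top_alpha(calibrated_unl, alpha: float) -> np.ndarray:
    """Label the round(alpha |U|) highest-probability unlabeled rows 1.

    Ties at the cutoff break by original row order (stable sort).
    """
    probs = np.asarray(calibrated_unl, dtype=float).ravel()
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    k = int(round(alpha * probs.size))
    labels = np.zeros(probs.size, dtype=int)
    if k:
        order = np.argsort(-probs, kind="stable")
        labels[order[:k]] = 1
    return labels


def evaluate_metrics(probs, y_true, threshold: float = DECISION_THRESHOLD) -> MetricsReport:
    """Six standard metrics of probabilities against ground truth.

    Thresholded metrics (accuracy, F1, MCC) use the given cutoff. With a
    single-class truth vector, AUC-ROC and MCC are undefined and reported
    as NaN with a warning.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=int).ravel()
    if probs.shape != y_true.shape:
        raise ValueError("probs and y_true must align")
    pred = (probs >= threshold).astype(int)
    single_class = len(np.unique(y_true)) < 2
    if single_class:
        logger.warning("y_true has a single class; AUC-ROC and MCC are undefined")
    return MetricsReport(
        accuracy=float(skm.accuracy_score(y_true, pred)),
        auc_roc=float("nan") if single_class else float(skm.roc_auc_score(y_true, probs)),
        brier=float(skm.brier_score_loss(y_true, probs)),
        f1=float(skm.f1_score(y_true, pred, zero_division=0)),
        mcc=float("nan") if single_class else float(skm.matthews_corrcoef(y_true, pred)),
        aps=float(skm.average_precision_score(y_true, probs)),
        threshold=threshold,
    )


def baseline_metrics(
    data: PUDataset, folds: int = CV_FOLDS, seed: int = 0,
    threshold: float = DECISION_THRESHOLD,
) -> MetricsReport:
    """Plain cross-validated classifier on the raw assigned labels."""
    if data.y_true is None:
        raise ValueError("ground truth required for evaluation")
    scored = cv_class1_probabilities(data, folds=folds, seed=seed)
    return evaluate_metrics(scored.p, data.y_true, threshold)


def improve_and_evaluate(
    data: PUDataset,
    alpha: float | SnarAlphaEstimate,
    method: str = "isotonic",
    n_bins: int = CALIBRATION_BINS,
    folds: int = CV_FOLDS,
    seed: int = 0,
    threshold: float = DECISION_THRESHOLD,
    scored: ScoredPU | None = None,
) -> MetricsReport:
    """Calibrate (scope U), relabel the top alpha |U|, retrain, evaluate.

    ``alpha`` may be a scalar SCAR estimate, in which case the calibrated
    probabilities come from one scope-U calibration of the supplied (or
    freshly computed) out-of-fold scores, or a SNAR estimate, in which case
    every unlabeled example's c per-cluster calibrated probabilities are
    combined before ranking.
    """
    if data.y_true is None:
        raise ValueError("ground truth required for evaluation")
    # the retraining CV reuses the caller's seed so that alpha = 0 reproduces
    # the plain baseline exactly
    s_cal, s_cv = child_seeds(seed, 2)

    if isinstance(alpha, SnarAlphaEstimate):
        calibrated_unl = calibrate_clusters(
            alpha.cluster_scores, alpha.per_cluster_alpha,
            method=method, n_bins=n_bins, seed=s_cal,
        )
        alpha_value = alpha.alpha_total_clipped
    else:
        if scored is None:
            scored = cv_class1_probabilities(data, folds=folds, seed=s_cv)
        result = calibrate(data, scored, alpha, method=method, scope="U",
                           n_bins=n_bins, seed=s_cal)
        calibrated_unl = result.calibrated
        alpha_value = float(alpha)

    s_hat = data.s.copy()
    s_hat[data.s == 0] = relabel_top_alpha(calibrated_unl, alpha_value)
    updated = PUDataset(
        features=data.features, s=s_hat, feature_names=data.feature_names,
    )
    rescored = cv_class1_probabilities(updated, folds=folds, seed=seed)
    return evaluate_metrics(rescored.p, data.y_true, threshold)
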