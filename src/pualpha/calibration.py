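"""Probability calibration against an estimated hidden-positive fraction.

Raw PU classifier scores are not calibrated: the model was trained calling
every unlabeled example negative, so p(s=1|x) underestimates p(y=1|x).
Once alpha is known, calibration proceeds by probabilistically flipping
round(alpha |U|) unlabeled labels from 0 to 1 so that the flipped examples
match the labeled positives' score histogram (100 equispaced bins by
default), walking bins from the highest-score bin downward and carrying
any shortfall into the next lower bin. An isotonic (or logistic) fit of
the flipped labels on the raw scores then yields calibrated probabilities
whose sum is approximately alpha |U| over the unlabeled set, or
|P| + alpha |U| when positives are included in the fit.

For SNAR data each of the c clusters produces its own calibrated
probability for every unlabeled example; these combine as

    p = 1 - (1 - p_1)(1 - p_2) ... (1 - p_c),

one minus the probability of belonging to none of the subclasses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

from .config import CALIBRATION_BINS, get_logger
from .pu_core import PUDataset, ScoredPU
from .synthetic import largest_remainder

logger = get_logger(__name__)

METHODS = ("isotonic", "sigmoid")
SCOPES = ("PU", "U")


@dataclass
class CalibrationResult:
    """Flipped unlabeled labels and calibrated probabilities.

    ``flipped_labels`` covers the unlabeled rows (1 = flipped to positive);
    ``calibrated`` covers whichever rows ``scope`` includes, in dataset
    order.
    """

    flipped_labels: np.ndarray
    calibrated: np.ndarray
    method: str
    scope: str
    per_bin_flip_counts: np.ndarray
    seed: int


def _bin_index(probs: np.ndarray, n_bins: int) -> np.ndarray:
    # right-open bins, last bin right-closed: an edge value joins the higher bin
    return np.minimum((probs * n_bins).astype(int), n_bins - 1)


def flip_by_positive_histogram(
    pos_probs,
    unl_probs,
    alpha: float,
    n_bins: int = CALIBRATION_BINS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flip round(alpha |U|) unlabeled labels, matching the positive histogram.

    Per-bin targets are the positive score-histogram masses times
    alpha |U| (largest-remainder integerized). Bins are processed from the
    top score bin downward; within a bin the flipped examples are chosen
    uniformly at random (seeded), and demand exceeding a bin's population
    carries to the next lower bin.
    """
    pos_probs = np.asarray(pos_probs, dtype=float).ravel()
    unl_probs = np.asarray(unl_probs, dtype=float).ravel()
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n_unl = unl_probs.size
    total = int(round(alpha * n_unl))
    flipped = np.zeros(n_unl, dtype=int)
    per_bin = np.zeros(n_bins, dtype=int)
    if total == 0:
        return flipped, per_bin
    if total > n_unl:
        raise ValueError("cannot flip more examples than the unlabeled set holds")

    pos_counts, _ = np.histogram(pos_probs, bins=n_bins, range=(0.0, 1.0))
    if pos_counts.sum() == 0:
        raise ValueError("positive scores produced an empty histogram")
    targets = largest_remainder(total, pos_counts / pos_counts.sum())

    bins_u = _bin_index(unl_probs, n_bins)
    rng = np.random.default_rng(seed)
    carry = 0
    for k in range(n_bins - 1, -1, -1):
        n1 = int(targets[k]) + carry
        members = np.flatnonzero(bins_u == k)
        n2 = members.size
        if n1 > n2:
            chosen = members
            carry = n1 - n2
        else:
            chosen = rng.choice(members, size=n1, replace=False) if n1 else []
            carry = 0
        flipped[chosen] = 1
        per_bin[k] = len(chosen)
    if carry > 0:
        # demand left over below the lowest populated bin (possible when the
        # positive histogram has mass where no unlabeled example sits);
        # place it on the highest-score unflipped examples to keep the total
        # exact
        rest = np.flatnonzero(flipped == 0)
        rest = rest[np.argsort(-unl_probs[rest], kind="stable")][:carry]
        flipped[rest] = 1
        np.add.at(per_bin, _bin_index(unl_probs[rest], n_bins), 1)
    assert per_bin.sum() == total
    return flipped, per_bin


def fit_calibrator(probs, labels, method: str = "isotonic") -> np.ndarray:
    """Monotone map from raw scores to calibrated probabilities.

    Returns the calibrated values at the training scores. Single-class
    labels yield a constant map equal to the class rate (with a warning).
    """
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must align")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if len(np.unique(labels)) < 2:
        logger.warning("single-class labels; returning the constant class rate")
        return np.full_like(probs, labels.mean(), dtype=float)
    if method == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        return iso.fit_transform(probs, labels)
    lr = LogisticRegression(C=1e10, solver="lbfgs", max_iter=1000)
    lr.fit(probs.reshape(-1, 1), labels)
    return lr.predict_proba(probs.reshape(-1, 1))[:, 1]


def combine_cluster_probabilities(p_list) -> float:
    """1 - prod(1 - p_j): probability of belonging to at least one subclass."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one cluster probability")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def calibrate(
    data: PUDataset,
    scored: ScoredPU,
    alpha: float,
    method: str = "isotonic",
    scope: str = "U",
    n_bins: int = CALIBRATION_BINS,
    seed: int = 0,
) -> CalibrationResult:
    """Histogram-matched label flipping followed by a monotone fit.

    Scope "PU" fits the calibrator on positives plus unlabeled (flipped)
    labels; scope "U" fits on the unlabeled rows alone.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    pos_mask = data.s == 1
    p_p = scored.p[pos_mask]
    p_u = scored.p[~pos_mask]
    flipped, per_bin = flip_by_positive_histogram(p_p, p_u, alpha, n_bins, seed)
    if scope == "PU":
        probs = np.concatenate([p_p, p_u])
        labels = np.concatenate([np.ones(p_p.size, dtype=int), flipped])
    else:
        probs, labels = p_u, flipped
    calibrated = fit_calibrator(probs, labels, method)
    return CalibrationResult(
        flipped_labels=flipped,
        calibrated=calibrated,
        method=method,
        scope=scope,
        per_bin_flip_counts=per_bin,
        seed=seed,
    )


def calibrate_clusters(
    cluster_scores: list[dict],
    per_cluster_alpha,
    method: str = "isotonic",
    n_bins: int = CALIBRATION_BINS,
    seed: int = 0,
) -> np.ndarray:
    """Combined calibrated probabilities for unlabeled rows under SNAR.

    Each cluster's unlabeled scores are calibrated (scope U) against that
    cluster's alpha; the c per-cluster probabilities of every unlabeled
    example are combined with the none-of-the-subclasses rule.
    """
    per_cluster_alpha = np.asarray(per_cluster_alpha, dtype=float)
    if len(cluster_scores) != per_cluster_alpha.size:
        raise ValueError("one alpha per cluster required")
    stacked = []
    for j, (entry, a_j) in enumerate(zip(cluster_scores, per_cluster_alpha)):
        flipped, _ = flip_by_positive_histogram(
            entry["pos_probs"], entry["unl_probs"], float(np.clip(a_j, 0, 1)),
            n_bins, seed + j,
        )
        stacked.append(fit_calibrator(entry["unl_probs"], flipped, method))
    stacked = np.vstack(stacked)
    return 1.0 - np.prod(1.0 - stacked, axis=0)
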