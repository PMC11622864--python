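"""Mixture-proportion estimation under SCAR labeling (PULSCAR).

The unlabeled score density decomposes as D_u = alpha D_p + (1-alpha) D_n
with D_n >= 0, so alpha D_p <= D_u everywhere and the largest admissible
mixing proportion is

    alpha_max = min_i D_u[i] / D_p[i]   over grid points with D_p[i] != 0.

PULSCAR scans the objective

    f(alpha) = log(|min(D_u - alpha D_p)| + eps),
    eps = |min(D_p)| if min(D_p) != 0 else 1e-10,

over alpha in [0, 1] with step 0.0001. As alpha crosses the admissible
boundary the minimum difference passes through zero and f dips sharply;
the estimate is the grid point where the finite-difference slope of f
changes the most (or, for multi-dip curves, the first sufficiently sharp
change, since any later dip would drive the implied negative density
D_u - alpha D_p below zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ALPHA_STEP, DEFAULT_BIN_RULE, get_logger
from .density import (
    DensityGrid,
    beta_kernel_density,
    estimate_bandwidth,
    histogram_bin_count,
)

logger = get_logger(__name__)

MODES = ("max_slope_change", "first_sharp_change")
# relative prominence a slope-change peak needs to count as "sharp"
SHARP_FRACTION = 0.5
# bins where the positive density falls below this fraction of its peak are
# far-tail kernel extrapolation; the score pipeline drops them from the
# bin-wise minimum
DP_FLOOR_FRACTION = 0.05


@dataclass
class ObjectiveCurve:
    alphas: np.ndarray
    f: np.ndarray
    epsilon: float
    bw: float
    n_bins: int


@dataclass
class AlphaEstimate:
    alpha_hat: float
    curve: ObjectiveCurve
    alpha_max_diagnostic: float
    mode: str
    seed: int


def _alpha_grid() -> np.ndarray:
    n = int(round(1.0 / ALPHA_STEP)) + 1
    return np.linspace(0.0, 1.0, n)


def _epsilon(Dp_vals: np.ndarray) -> float:
    m = float(np.min(Dp_vals))
    return abs(m) if m != 0 else 1e-10


def _resolve_mask(grid: DensityGrid, mask) -> np.ndarray:
    if mask is None:
        return np.ones(grid.n_bins, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.z.shape:
        raise ValueError("mask must align with the density grid")
    if not mask.any():
        return np.ones(grid.n_bins, dtype=bool)
    return mask


def objective(alpha: float, Du: DensityGrid, Dp: DensityGrid) -> float:
    """f(alpha) = log(|min(D_u - alpha D_p)| + eps) on a shared grid."""
    if not Du.same_grid(Dp):
        raise ValueError("Du and Dp must share the same grid")
    eps = _epsilon(Dp.D)
    return float(np.log(np.abs(np.min(Du.D - alpha * Dp.D)) + eps))


def alpha_max_oracle(Du: DensityGrid, Dp: DensityGrid, mask=None) -> float:
    """Largest alpha keeping D_u - alpha D_p nonnegative, clipped to [0, 1]."""
    if not Du.same_grid(Dp):
        raise ValueError("Du and Dp must share the same grid")
    keep = _resolve_mask(Dp, mask)
    pos = keep & (Dp.D > 0)
    if not pos.any():
        raise ValueError("all positive-density bins are zero")
    return float(np.clip(np.min(Du.D[pos] / Dp.D[pos]), 0.0, 1.0))


def _objective_curve(Du: DensityGrid, Dp: DensityGrid, mask=None) -> ObjectiveCurve:
    alphas = _alpha_grid()
    keep = _resolve_mask(Dp, mask)
    eps = _epsilon(Dp.D[keep])
    diffs = Du.D[None, keep] - alphas[:, None] * Dp.D[None, keep]
    f = np.log(np.abs(diffs.min(axis=1)) + eps)
    return ObjectiveCurve(alphas=alphas, f=f, epsilon=eps,
                          bw=Dp.bw if Dp.bw is not None else np.nan,
                          n_bins=Dp.n_bins)


def select_alpha(curve: ObjectiveCurve, mode: str = "max_slope_change") -> float:
    """Pick the grid alpha at the largest (or first sharp) slope change.

    The slope is the forward first difference of f; its change is the
    second difference, attributed to the grid point between the two slope
    segments, so alpha = 0 can never be returned. Ties break toward the
    smallest alpha.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    d = np.diff(curve.f)
    change = np.abs(np.diff(d))  # change at alphas[1 .. n-2]
    if mode == "max_slope_change":
        i = int(np.argmax(change))
    else:
        top = change.max()
        peaks = np.flatnonzero(
            (change >= SHARP_FRACTION * top)
            & (np.r_[True, change[1:] >= change[:-1]])
            & (np.r_[change[:-1] >= change[1:], True])
        )
        i = int(peaks[0]) if peaks.size else int(np.argmax(change))
    return float(curve.alphas[i + 1])


def estimate_alpha_from_densities(
    Du: DensityGrid,
    Dp: DensityGrid,
    mode: str = "max_slope_change",
    seed: int = 0,
    mask=None,
) -> AlphaEstimate:
    """Run the alpha scan on pre-built density grids.

    ``mask`` optionally restricts the bin-wise minimum to a subset of grid
    points (used by the score pipeline to stay inside the unlabeled
    sample's observed support).
    """
    curve = _objective_curve(Du, Dp, mask)
    alpha_hat = select_alpha(curve, mode)
    return AlphaEstimate(
        alpha_hat=alpha_hat,
        curve=curve,
        alpha_max_diagnostic=alpha_max_oracle(Du, Dp, mask),
        mode=mode,
        seed=seed,
    )


def estimate_alpha(
    pos_probs,
    unl_probs,
    n_bins: int | str = "auto",
    mode: str = "max_slope_change",
    seed: int = 0,
    bin_rule: str = DEFAULT_BIN_RULE,
) -> AlphaEstimate:
    """Estimate the hidden-positive fraction from classifier scores.

    The kernel bandwidth is estimated once from the pooled positive and
    unlabeled scores and shared by both densities; ``n_bins="auto"``
    resolves via the configured histogram bin-count rule on the pooled
    scores. The bin-wise minimum skips grid points where the positive
    density lies below a small fraction of its own peak: such bins are
    far-tail kernel extrapolation whose near-zero density ratios would
    collapse both the admissible alpha and the noise floor epsilon.
    Bins with substantial positive density are always kept — including
    ones where the unlabeled density is genuinely near zero, which is
    exactly the evidence that no positives hide there.
    """
    pos_probs = np.asarray(pos_probs, dtype=float).ravel()
    unl_probs = np.asarray(unl_probs, dtype=float).ravel()
    if pos_probs.size == 0 or unl_probs.size == 0:
        raise ValueError("both score vectors must be non-empty")
    pooled = np.concatenate([pos_probs, unl_probs])
    if n_bins == "auto":
        n_bins = histogram_bin_count(pooled, bin_rule)
    n_bins = int(n_bins)

    pos_hist, _ = np.histogram(pos_probs, bins=n_bins, range=(0, 1))
    unl_hist, _ = np.histogram(unl_probs, bins=n_bins, range=(0, 1))
    if (pos_hist > 0).sum() == 1 and (unl_hist > 0).sum() == 1:
        raise ValueError(
            "degenerate score distributions: all positive and all unlabeled "
            "scores fall in a single bin each; the classifier carries no "
            "usable signal"
        )

    bw = estimate_bandwidth(pooled, n_bins, seed=seed)
    Dp = beta_kernel_density(pos_probs, bw, n_bins)
    Du = beta_kernel_density(unl_probs, bw, n_bins)
    mask = Dp.D >= DP_FLOOR_FRACTION * Dp.D.max()
    return estimate_alpha_from_densities(Du, Dp, mode=mode, seed=seed, mask=mask)
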