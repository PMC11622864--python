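"""Density estimation on the unit interval.

Classifier scores live on [0, 1], where Gaussian kernels leak mass past the
boundaries (and fast polynomial approximations can even go negative, which
breaks any method that needs a nonnegative density difference). The
estimator here instead averages Beta-distribution kernels,

    h(x; a, b) = Gamma(a+b) / (Gamma(a) Gamma(b)) * x^(a-1) (1-x)^(b-1),

with a = 1 + z/bw and b = 1 + (1-z)/bw at each evaluation point z, so the
estimate is supported exactly on [0, 1] and is nonnegative by construction.

The bandwidth bw is chosen by minimizing the mean squared error between the
beta-kernel estimate and a histogram-derived density on a shared grid of
n_bins equispaced points spanning [0, 1], using a seeded differential-
evolution search over bw in [0.01, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import jensenshannon

from .config import BW_MAX, BW_MIN, DE_MAXITER, DE_POPSIZE, DE_TOL, get_logger

logger = get_logger(__name__)

BIN_RULES = ("sqrt", "sturges", "rice", "scott", "fd")


@dataclass
class DensityGrid:
    """Density values ``D`` at ``n_bins`` equispaced points ``z`` on [0, 1].

    ``bw`` is the beta-kernel bandwidth used to build ``D``; it is ``None``
    for histogram-derived densities, which have no kernel bandwidth.
    """

    z: np.ndarray
    D: np.ndarray
    bw: float | None
    n_bins: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.z.shape != self.D.shape or self.z.ndim != 1:
            raise ValueError("z and D must be 1-D arrays of equal length")
        if len(self.z) != self.n_bins:
            raise ValueError("grid length must equal n_bins")
        if np.any(self.D < 0):
            raise ValueError("density values must be nonnegative")

    def same_grid(self, other: "DensityGrid") -> bool:
        return self.n_bins == other.n_bins and np.allclose(self.z, other.z)

    def to_csv(self, path) -> None:
        """Write the grid as two-column (z, D) CSV for diagnostics."""
        np.savetxt(path, np.c_[self.z, self.D], delimiter=",",
                   header="z,D", comments="")


def _check_probs(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("values must lie in [0, 1]")
    return values


def beta_kernel_density(values, bw: float, n_bins: int) -> DensityGrid:
    """Beta-kernel density of ``values`` at ``n_bins`` equispaced points.

    D[j] is the mean over data points x of the Beta pdf with parameters
    a = 1 + z_j/bw, b = 1 + (1 - z_j)/bw evaluated at x.
    """
    values = _check_probs(values)
    if not (BW_MIN <= bw <= BW_MAX):
        raise ValueError(f"bandwidth must lie in [{BW_MIN}, {BW_MAX}]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    z = np.linspace(0.0, 1.0, n_bins)
    a = 1.0 + z / bw
    b = 1.0 + (1.0 - z) / bw
    # log normalizing constant; a + b = 2 + 1/bw is the same for every z
    log_c = special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b)
    # xlogy handles the x = 0 / x = 1 boundaries (0 * log 0 -> 0)
    log_k = (
        log_c[:, None]
        + special.xlogy(a[:, None] - 1.0, values[None, :])
        + special.xlogy(b[:, None] - 1.0, 1.0 - values[None, :])
    )
    D = np.exp(log_k).mean(axis=1)
    return DensityGrid(z=z, D=D, bw=float(bw), n_bins=n_bins)


def histogram_bin_count(values, method: str = "sqrt") -> int:
    """Number of histogram bins under one of five standard rules.

    Supported rules: square-root, Sturges, Rice, Scott, Freedman-Diaconis.
    Results are rounded up and floored at 2. Scott/FD fall back to the
    square-root rule (with a warning) when the spread they divide by is 0.
    """
    values = _check_probs(values)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values to pick a bin count")
    if method not in BIN_RULES:
        raise ValueError(f"unknown bin rule {method!r}; choose from {BIN_RULES}")
    if method == "sqrt":
        count = np.sqrt(n)
    elif method == "sturges":
        count = 1 + np.log2(n)
    elif method == "rice":
        count = 2 * n ** (1 / 3)
    else:
        spread = (
            3.5 * values.std() if method == "scott"
            else 2 * (np.percentile(values, 75) - np.percentile(values, 25))
        )
        if spread == 0:
            logger.warning(
                "%s rule degenerate (zero spread); falling back to sqrt", method
            )
            count = np.sqrt(n)
        else:
            h = spread / n ** (1 / 3)
            count = (values.max() - values.min()) / h
    return max(2, int(np.ceil(count)))


def histogram_density(values, n_bins: int) -> DensityGrid:
    """Histogram-derived density evaluated on the shared [0, 1] grid.

    The histogram has n_bins equal-width bins on [0, 1] normalized so that
    density x width sums to 1; each grid point takes the density of the bin
    containing it (bins right-open, the last right-closed).
    """
    values = _check_probs(values)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    hist, _ = np.histogram(values, bins=n_bins, range=(0.0, 1.0), density=True)
    z = np.linspace(0.0, 1.0, n_bins)
    idx = np.minimum((z * n_bins).astype(int), n_bins - 1)
    return DensityGrid(z=z, D=hist[idx], bw=None, n_bins=n_bins)


def _bandwidth_error(bw, values: np.ndarray, ref: DensityGrid,
                     metric: str) -> float:
    est = beta_kernel_density(values, float(np.asarray(bw).ravel()[0]), ref.n_bins)
    if metric == "js":
        return float(jensenshannon(ref.D + 1e-12, est.D + 1e-12))
    return float(np.mean((ref.D - est.D) ** 2))


def estimate_bandwidth(values, n_bins: int, seed: int = 0,
                       metric: str = "mse") -> float:
    """MSE-optimal beta-kernel bandwidth in [0.01, 0.5].

    Minimizes the error between the histogram density and the beta-kernel
    density on the shared grid via seeded differential evolution. The
    Jensen-Shannon distance is available as an alternative error metric
    (``metric="js"``).
    """
    values = _check_probs(values)
    if metric not in ("mse", "js"):
        raise ValueError("metric must be 'mse' or 'js'")
    ref = histogram_density(values, n_bins)
    result = optimize.differential_evolution(
        _bandwidth_error,
        bounds=[(BW_MIN, BW_MAX)],
        args=(values, ref, metric),
        seed=seed,
        maxiter=DE_MAXITER,
        popsize=DE_POPSIZE,
        tol=DE_TOL,
        polish=True,
        workers=1,
    )
    if not result.success:
        logger.warning(
            "bandwidth search did not converge (%s); using best-seen bw=%.4f",
            result.message, float(result.x[0]),
        )
    return float(np.clip(result.x[0], BW_MIN, BW_MAX))
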