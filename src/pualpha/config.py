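"""Package-wide defaults and logging setup.

Every stochastic component takes an explicit seed; the helpers here derive
stable child seeds from a master seed so that a whole pipeline run is
reproducible from a single integer.
"""

from __future__ import annotations

import logging

import numpy as np

LOGGER_NAME = "pualpha"

# Beta-kernel bandwidth search interval.
BW_MIN = 0.01
BW_MAX = 0.5

# Resolution of the alpha grid scanned by the mixture-proportion objective.
ALPHA_STEP = 1e-4

# Budget of the differential-evolution bandwidth search (1-D problem; this
# is ample to locate the MSE minimum to ~1e-3).
DE_MAXITER = 20
DE_POPSIZE = 8
DE_TOL = 0.01

# Histogram bin-count rule applied when callers ask for "auto" bins.
# Scott's rule adapts to the spread of the scores: bimodal PU score
# distributions get a coarse, stable histogram, which keeps the
# MSE-matched kernel bandwidth away from its spiky lower bound.
DEFAULT_BIN_RULE = "scott"

# Calibration histogram resolution.
CALIBRATION_BINS = 100

# Gaussian-mixture settings for clustering labeled positives.
GMM_MAX_ITER = 250
GMM_COVARIANCE = "full"
GMM_N_INIT = 3
DEFAULT_MAX_CLUSTERS = 25
MIN_CLUSTER_SIZE = 20

# Gradient-boosted tree defaults. The positive-class weight |U|/|P| is set
# per dataset at fit time; everything else is a fixed, untuned default.
XGB_PARAMS = {
    "n_estimators": 100,
    "max_depth": 6,
    "learning_rate": 0.1,
    "tree_method": "hist",
    "n_jobs": 1,
    "verbosity": 0,
    "eval_metric": "logloss",
}

CV_FOLDS = 5
DECISION_THRESHOLD = 0.5


def get_logger(name: str = LOGGER_NAME) -> logging.Logger:
    """Return the package logger (handlers configured by the CLI or caller)."""
    return logging.getLogger(name)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
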