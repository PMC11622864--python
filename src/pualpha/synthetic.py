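"""Synthetic SCAR and SNAR positive-unlabeled data.

The generators emulate the hypercube-cluster construction used for
classification benchmarks: each class (the negative class and every
positive subclass) is a Gaussian cluster whose centroid sits on a random
vertex of the hypercube {-class_sep, +class_sep}^n_informative, whose
informative coordinates are randomly linearly mixed by a cluster-specific
transform (so every cluster has its own full covariance), and whose
remaining coordinates are pure noise. Small class_sep (the study setting
is 0.3) gives heavily overlapping, hard-to-classify clusters; class_sep
>= 2 gives nearly separable ones. The cluster-specific covariances are
what make positive subclasses recoverable by model-based clustering even
when their centroids nearly coincide.

SCAR datasets hide k% of the unlabeled set as positives drawn from the
same cluster as the labeled positives. SNAR datasets use several positive
subclasses: labeled positives are split equally across subclasses while
hidden unlabeled positives follow a skewed proportion vector (default
1/31, 2/31, 4/31, 8/31, 16/31 for five subclasses), so the labeled set is
not a random sample of all positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import get_logger
from .pu_core import PUDataset

logger = get_logger(__name__)


def default_subclass_proportions(n_subclasses: int) -> np.ndarray:
    """Doubling proportions 2^j / (2^c - 1); (1, 2, 4, 8, 16)/31 for c = 5."""
    w = 2.0 ** np.arange(n_subclasses)
    return w / w.sum()


def largest_remainder(total: int, proportions) -> np.ndarray:
    """Apportion ``total`` into integer counts matching ``proportions``."""
    proportions = np.asarray(proportions, dtype=float)
    quotas = total * proportions / proportions.sum()
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic PU dataset.

    ``frac_k`` is the percentage of the unlabeled set that is hidden
    positive. ``n_subclasses = 1`` describes a SCAR dataset; larger values
    describe SNAR datasets with ``subclass_props`` governing the hidden
    positives' subclass mix (labeled positives are always split equally).
    """

    n_pos: int = 2000
    n_unl: int = 6000
    frac_k: float = 10.0
    n_features: int = 50
    n_informative: int = 30
    class_sep: float = 0.3
    n_subclasses: int = 1
    subclass_props: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_k < 100:
            raise ValueError("frac_k must lie in [0, 100)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.subclass_props is None:
            self.subclass_props = default_subclass_proportions(self.n_subclasses)
        self.subclass_props = np.asarray(self.subclass_props, dtype=float)
        if len(self.subclass_props) != self.n_subclasses:
            raise ValueError("subclass_props length must equal n_subclasses")
        if not np.isclose(self.subclass_props.sum(), 1.0):
            raise ValueError("subclass_props must sum to 1")

    @property
    def n_hidden(self) -> int:
        return int(round(self.frac_k / 100.0 * self.n_unl))


def _cluster_centroids(rng: np.random.Generator, n_clusters: int,
                       n_informative: int, class_sep: float) -> np.ndarray:
    """Distinct random hypercube vertices scaled by class_sep."""
    seen: set[tuple] = set()
    centroids = []
    while len(centroids) < n_clusters:
        vertex = rng.integers(0, 2, size=n_informative) * 2 - 1
        key = tuple(vertex)
        if key not in seen:
            seen.add(key)
            centroids.append(vertex * class_sep)
    return np.array(centroids, dtype=float)


def _sample_cluster(rng: np.random.Generator, centroid: np.ndarray,
                    mixing: np.ndarray, count: int, n_features: int) -> np.ndarray:
    n_inf = centroid.shape[0]
    x = rng.normal(size=(count, n_features))
    x[:, :n_inf] = x[:, :n_inf] @ mixing + centroid
    return x


def _assemble(spec: SyntheticSpec, labeled_counts: np.ndarray,
              hidden_counts: np.ndarray, n_neg: int) -> PUDataset:
    rng = np.random.default_rng(spec.seed)
    centroids = _cluster_centroids(
        rng, spec.n_subclasses + 1, spec.n_informative, spec.class_sep
    )
    # cluster-specific random linear mixing of the informative subspace
    mixings = rng.uniform(
        -1.0, 1.0,
        size=(spec.n_subclasses + 1, spec.n_informative, spec.n_informative),
    )
    blocks, s, y, sub = [], [], [], []
    for j in range(spec.n_subclasses):  # labeled positives, subclass j+1
        c = int(labeled_counts[j])
        blocks.append(_sample_cluster(
            rng, centroids[j + 1], mixings[j + 1], c, spec.n_features))
        s += [1] * c
        y += [1] * c
        sub += [j + 1] * c
    for j in range(spec.n_subclasses):  # hidden positives, labels flipped to 0
        c = int(hidden_counts[j])
        if c == 0 and spec.n_hidden > 0:
            logger.info("subclass %d received no hidden positives", j + 1)
        blocks.append(_sample_cluster(
            rng, centroids[j + 1], mixings[j + 1], c, spec.n_features))
        s += [0] * c
        y += [1] * c
        sub += [j + 1] * c
    blocks.append(_sample_cluster(rng, centroids[0], mixings[0], n_neg, spec.n_features))
    s += [0] * n_neg
    y += [0] * n_neg
    sub += [0] * n_neg

    features = np.vstack(blocks)
    s = np.asarray(s)
    order = rng.permutation(len(s))
    return PUDataset(
        features=features[order],
        s=s[order],
        y_true=np.asarray(y)[order],
        subclass=np.asarray(sub)[order],
    )


def make_scar(spec: SyntheticSpec) -> PUDataset:
    """SCAR dataset: one positive cluster, k% of it hidden among unlabeled."""
    if spec.n_subclasses != 1:
        raise ValueError("SCAR data has a single positive class; use make_snar")
    n_hidden = spec.n_hidden
    n_neg = spec.n_unl - n_hidden
    if n_neg < 0:
        raise ValueError("infeasible counts: hidden positives exceed unlabeled size")
    return _assemble(spec, np.array([spec.n_pos]), np.array([n_hidden]), n_neg)


def make_snar(spec: SyntheticSpec) -> PUDataset:
    """SNAR dataset: equal labeled subclasses, skew-mixed hidden positives."""
    if spec.n_subclasses < 2:
        raise ValueError("SNAR data needs at least two positive subclasses")
    labeled = largest_remainder(spec.n_pos, np.ones(spec.n_subclasses))
    hidden = largest_remainder(spec.n_hidden, spec.subclass_props)
    n_neg = spec.n_unl - spec.n_hidden
    if n_neg < 0:
        raise ValueError("infeasible counts: hidden positives exceed unlabeled size")
    return _assemble(spec, labeled, hidden, n_neg)


def inject_flipped_positives(
    n_pos_available: int, n_unl: int, k: float, seed: int = 0
) -> tuple[int, np.ndarray]:
    """Benchmark-style injection: flip m positives so k% of the final
    unlabeled set is hidden positive, with m = k |U| / (100 - k).

    Returns m and the (seeded) indices of the positives to flip.
    """
    if not 0 <= k < 100:
        raise ValueError("k must lie in [0, 100)")
    m = int(round(k * n_unl / (100.0 - k)))
    if m > n_pos_available:
        raise ValueError(
            f"need {m} positives to reach {k}% but only {n_pos_available} available"
        )
    rng = np.random.default_rng(seed)
    plan = rng.choice(n_pos_available, size=m, replace=False)
    return m, plan
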