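"""Core positive-unlabeled data model and cross-validated scoring.

A PU dataset is a feature matrix plus an assigned-label vector s, where
s = 1 marks a labeled positive and s = 0 an unlabeled example (a mix of
hidden positives and negatives). All labeled examples are assumed to be
true positives; the fraction alpha of hidden positives among the unlabeled
set is the quantity the rest of the package estimates.

With |P| labeled positives, |U| unlabeled examples and hidden-positive
fraction alpha, the label frequency and class prior satisfy

    p(s=1)       = |P| / (|P| + |U|)
    p(y=1)       = (|P| + alpha |U|) / (|P| + |U|)
    p(s=1 | y=1) = |P| / (|P| + alpha |U|)   (constant under SCAR)

Scoring treats labeled positives as class 1 and unlabeled as class 0 and
produces strictly out-of-fold class-1 probabilities from a gradient-boosted
tree ensemble, optionally weighting the positive class by |U|/|P| to
counter class imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .config import CV_FOLDS, XGB_PARAMS, get_logger

logger = get_logger(__name__)


@dataclass
class PUDataset:
    """Features plus assigned labels, with optional hidden ground truth.

    ``s`` is the assigned label (1 = labeled positive, 0 = unlabeled);
    ``y_true`` the optional true class and ``subclass`` the optional hidden
    positive subtype (0 for negatives).
    """

    features: np.ndarray
    s: np.ndarray
    y_true: np.ndarray | None = None
    subclass: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.s = np.asarray(self.s, dtype=int).ravel()
        n = self.features.shape[0]
        if self.s.shape[0] != n:
            raise ValueError("s must have one entry per row of features")
        if not np.isin(self.s, (0, 1)).all():
            raise ValueError("s must be binary (0/1)")
        if self.n_pos < 1 or self.n_unl < 1:
            raise ValueError("need at least one labeled positive and one unlabeled example")
        if self.y_true is not None:
            self.y_true = np.asarray(self.y_true, dtype=int).ravel()
            if self.y_true.shape[0] != n:
                raise ValueError("y_true length mismatch")
            if np.any((self.s == 1) & (self.y_true != 1)):
                raise ValueError("every labeled example must be a true positive")
        if self.subclass is not None:
            self.subclass = np.asarray(self.subclass, dtype=int).ravel()
            if self.subclass.shape[0] != n:
                raise ValueError("subclass length mismatch")
        if self.feature_names is None:
            self.feature_names = [f"x{i}" for i in range(self.features.shape[1])]
        elif len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n_examples(self) -> int:
        return self.features.shape[0]

    @property
    def n_pos(self) -> int:
        return int((self.s == 1).sum())

    @property
    def n_unl(self) -> int:
        return int((self.s == 0).sum())


@dataclass
class ScoredPU:
    """Out-of-fold class-1 probabilities aligned to a PUDataset's rows."""

    p: np.ndarray
    fold_id: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        self.fold_id = np.asarray(self.fold_id, dtype=int).ravel()
        if self.p.shape != self.fold_id.shape:
            raise ValueError("p and fold_id must align")
        if self.p.min() < 0 or self.p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PriorSummary:
    p_s1: float
    p_y1: float
    label_frequency: float


def default_classifier(seed: int, scale_pos_weight: float = 1.0) -> XGBClassifier:
    """Gradient-boosted tree classifier with the package's fixed defaults."""
    return XGBClassifier(
        random_state=int(seed) % (2**31),
        scale_pos_weight=scale_pos_weight,
        **XGB_PARAMS,
    )


def cv_class1_probabilities(
    data: PUDataset,
    folds: int = CV_FOLDS,
    weight_positives: bool = True,
    seed: int = 0,
    classifier_factory=None,
) -> ScoredPU:
    """Out-of-fold class-1 probabilities, labeled positives as class 1.

    Stratified k-fold CV on the assigned labels; each row is scored exactly
    once, by a model that never saw it during training. With
    ``weight_positives`` the positive-class training weight is |U|/|P|.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if data.n_pos < folds or data.n_unl < folds:
        raise ValueError(
            f"need at least {folds} examples of each assigned label "
            f"(have |P|={data.n_pos}, |U|={data.n_unl})"
        )
    if not np.all(np.isfinite(data.features)):
        raise ValueError("features must be finite")
    if classifier_factory is None:
        classifier_factory = default_classifier
    spw = data.n_unl / data.n_pos if weight_positives else 1.0

    p = np.full(data.n_examples, np.nan)
    fold_id = np.full(data.n_examples, -1, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    for k, (train_idx, test_idx) in enumerate(skf.split(data.features, data.s)):
        clf = classifier_factory(seed=seed + k, scale_pos_weight=spw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(data.features[train_idx], data.s[train_idx])
            p[test_idx] = clf.predict_proba(data.features[test_idx])[:, 1]
        fold_id[test_idx] = k
    assert not np.isnan(p).any(), "every row must be scored exactly once"
    return ScoredPU(p=np.clip(p, 0.0, 1.0), fold_id=fold_id, seed=seed)


def label_frequency_and_prior(n_pos: int, n_unl: int, alpha: float) -> PriorSummary:
    """Label frequency p(s=1|y=1) and class prior p(y=1) implied by alpha."""
    if n_pos < 0 or n_unl < 0 or n_pos + n_unl == 0:
        raise ValueError("need n_pos >= 0, n_unl >= 0 and at least one example")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    total = n_pos + n_unl
    p_s1 = n_pos / total
    p_y1 = (n_pos + alpha * n_unl) / total
    label_frequency = n_pos / (n_pos + alpha * n_unl) if p_y1 > 0 else 0.0
    return PriorSummary(p_s1=p_s1, p_y1=p_y1, label_frequency=label_frequency)


def gain_importances(data: PUDataset, seed: int = 0) -> dict[str, float]:
    """Per-feature gain scores from a boosted-tree model trained on s.

    Features the model never split on get gain 0; constant-feature data
    therefore yields all-zero gains (flagged with a warning, not an error).
    """
    if not np.all(np.isfinite(data.features)):
        raise ValueError("features must be finite")
    spw = data.n_unl / data.n_pos
    clf = default_classifier(seed=seed, scale_pos_weight=spw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(data.features, data.s)
    raw = clf.get_booster().get_score(importance_type="gain")
    gains = {name: 0.0 for name in data.feature_names}
    for key, value in raw.items():
        # booster names features f0, f1, ... when fit on plain arrays
        idx = int(key[1:]) if key.startswith("f") and key[1:].isdigit() else None
        name = data.feature_names[idx] if idx is not None else key
        gains[name] = float(value)
    if all(v == 0.0 for v in gains.values()):
        logger.warning("model found no usable splits; all gain scores are 0")
    return gains


def read_pu_csv(
    path,
    s_col: str = "s",
    y_true_col: str | None = None,
    subclass_col: str | None = None,
    sep: str | None = None,
) -> PUDataset:
    """Load a PU dataset from a delimited file with a header row.

    ``s_col`` names the assigned-label column; optional columns give the
    hidden truth and subclass. All remaining numeric columns are features.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if s_col not in df.columns:
        raise ValueError(f"label column {s_col!r} not found")
    s = df[s_col].to_numpy()
    if not np.isin(s, (0, 1)).all():
        raise ValueError(f"column {s_col!r} must be binary (0/1)")
    special = {s_col}
    kwargs = {}
    if y_true_col is not None:
        kwargs["y_true"] = df[y_true_col].to_numpy()
        special.add(y_true_col)
    if subclass_col is not None:
        kwargs["subclass"] = df[subclass_col].to_numpy()
        special.add(subclass_col)
    feat = df.drop(columns=sorted(special)).select_dtypes(include=[np.number])
    if feat.shape[1] == 0:
        raise ValueError("no numeric feature columns found")
    return PUDataset(
        features=feat.to_numpy(dtype=float),
        s=s,
        feature_names=list(feat.columns),
        **kwargs,
    )
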