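"""Protein-pair similarity: threshold matching and random-forest classification.

Two decision rules share the 60-value propensity descriptor:

* **Features mode** — two proteins are similar when at least ``min_matches``
  (default 25) of the 60 coordinates differ by at most ``tolerance``
  (default 1 unit).
* **ML mode** — a random forest classifies the element-wise absolute
  difference of the two descriptors.  The forest defaults mirror the
  tool's published configuration: 500 trees, depth cap 30, 10 candidate
  features per split, full bootstrap, minimum leaf size 1, trained on a
  3:1 negative:positive table with all negatives preceding positives.

The module also provides the confusion-matrix arithmetic used to report
classifier performance (sensitivity, specificity, F1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ppinet.features import FEATURE_LAYOUT_VERSION, N_FEATURES, FeatureVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatchConfig:
    """Features-mode rule: ``min_matches`` coordinates within ``tolerance``."""

    min_matches: int = 25
    tolerance: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.min_matches <= N_FEATURES:
            raise ValueError(f"min_matches must be in [1, {N_FEATURES}]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Random-forest configuration (defaults = the published custom set)."""

    n_tree: int = 500
    max_depth: int = 30
    n_trial: int = 10
    bagging_ratio: float = 1.0
    min_region_samples: int = 1
    negative_ratio: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tree", "max_depth", "n_trial", "min_region_samples", "negative_ratio"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.bagging_ratio <= 1:
            raise ValueError("bagging_ratio must be in (0, 1]")


@dataclass
class PairTable:
    """Encoded labeled pair rows, all negatives preceding all positives."""

    X: np.ndarray
    y: np.ndarray  # 0 = negative, 1 = positive

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.y.size and not np.all(np.diff(self.y.astype(int)) >= 0):
            raise ValueError("pair table must list all negatives before all positives")

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == 0))

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))


@dataclass
class SimilarityModel:
    """A trained forest plus the configuration and feature layout it expects."""

    forest: RandomForestClassifier
    config: ModelConfig
    feature_layout_version: str = FEATURE_LAYOUT_VERSION

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "SimilarityModel":
        model = joblib.load(path)
        if not isinstance(model, SimilarityModel):
            raise TypeError(f"{path}: not a SimilarityModel file")
        return model


@dataclass(frozen=True)
class EvaluationMetrics:
    """Confusion-matrix counts and the derived rates.

    A degenerate denominator (no positive-condition or negative-condition
    instances) leaves the corresponding rate NaN and sets its flag.
    """

    tn: int
    fn: int
    tp: int
    fp: int
    sensitivity: float
    specificity: float
    f1: float
    sensitivity_undefined: bool = False
    specificity_undefined: bool = False

    def rounded(self, ndigits: int = 4) -> tuple[float, float, float]:
        """Display rounding (the reporting convention is 4 decimals)."""
        return (
            round(self.sensitivity, ndigits),
            round(self.specificity, ndigits),
            round(self.f1, ndigits),
        )


def _as_array(v) -> np.ndarray:
    arr = v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
    if arr.shape != (N_FEATURES,):
        raise ValueError(f"expected a length-{N_FEATURES} feature vector, got shape {arr.shape}")
    return arr


def match_by_features(a, b, cfg: FeatureMatchConfig | None = None) -> bool:
    """Features-mode similarity: count coordinates within tolerance."""
    cfg = cfg or FeatureMatchConfig()
    va, vb = _as_array(a), _as_array(b)
    return int(np.sum(np.abs(va - vb) <= cfg.tolerance)) >= cfg.min_matches


def match_matrix(A: np.ndarray, B: np.ndarray, cfg: FeatureMatchConfig | None = None) -> np.ndarray:
    """Vectorized Features-mode decisions for all rows of A against all rows
    of B; returns a boolean (len(A), len(B)) matrix."""
    cfg = cfg or FeatureMatchConfig()
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    out = np.empty((len(A), len(B)), dtype=bool)
    # chunk over A to bound the broadcast temporary
    step = max(1, int(2e7) // max(1, B.size))
    for i in range(0, len(A), step):
        diff = np.abs(A[i : i + step, None, :] - B[None, :, :]) <= cfg.tolerance
        out[i : i + step] = diff.sum(axis=2) >= cfg.min_matches
    return out


def encode_pair(a, b) -> np.ndarray:
    """Symmetric pair encoding: element-wise absolute difference."""
    return np.abs(_as_array(a) - _as_array(b))


def build_pair_table(labeled_pairs, ratio: int = 3, seed: int = 0) -> PairTable:
    """Encode labeled (vector_a, vector_b, label) pairs into a training table.

    Negatives are downsampled (seeded, without replacement) to
    ``ratio × n_positive`` when more are available; rows are ordered with
    all negatives before all positives.
    """
    if ratio < 1:
        raise ValueError("negative:positive ratio must be >= 1")
    negatives, positives = [], []
    for a, b, label in labeled_pairs:
        row = encode_pair(a, b)
        (positives if label else negatives).append(row)
    if not positives:
        raise ValueError("pair table needs at least one positive pair")
    if not negatives:
        raise ValueError("pair table needs at least one negative pair")
    target = ratio * len(positives)
    if len(negatives) > target:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(negatives), size=target, replace=False)
        negatives = [negatives[i] for i in sorted(idx)]
    elif len(negatives) < target:
        logger.warning(
            "only %d negatives available for requested ratio %d:1 (%d wanted); keeping all",
            len(negatives), ratio, target,
        )
    X = np.vstack(negatives + positives)
    y = np.concatenate([np.zeros(len(negatives), dtype=int), np.ones(len(positives), dtype=int)])
    return PairTable(X=X, y=y)


def train_model(table: PairTable, cfg: ModelConfig | None = None) -> SimilarityModel:
    """Train the seeded random-forest pair classifier."""
    cfg = cfg or ModelConfig()
    if len(table.X) == 0:
        raise ValueError("empty pair table")
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValueError("pair table must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_tree,
        max_depth=cfg.max_depth,
        max_features=min(cfg.n_trial, N_FEATURES),
        min_samples_leaf=cfg.min_region_samples,
        max_samples=None if cfg.bagging_ratio >= 1.0 else cfg.bagging_ratio,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(table.X, table.y)
    return SimilarityModel(forest=forest, config=cfg)


def predict_pair(model: SimilarityModel, a, b) -> tuple[bool, float]:
    """Classify one pair; returns (label, positive-class score).

    The label is ``score >= 0.5`` (majority vote); symmetric in (a, b)
    because the encoding is.
    """
    if model.feature_layout_version != FEATURE_LAYOUT_VERSION:
        raise ValueError(
            f"model feature layout {model.feature_layout_version!r} does not match "
            f"featurizer {FEATURE_LAYOUT_VERSION!r}"
        )
    row = encode_pair(a, b)[None, :]
    score = float(model.forest.predict_proba(row)[0, list(model.forest.classes_).index(1)])
    return score >= 0.5, score


def predict_matrix(model: SimilarityModel, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized ML-mode decisions for all rows of A against all rows of B."""
    if model.feature_layout_version != FEATURE_LAYOUT_VERSION:
        raise ValueError("model/featurizer layout mismatch")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    pos_col = list(model.forest.classes_).index(1)
    rows = np.abs(A[:, None, :] - B[None, :, :]).reshape(-1, A.shape[1])
    scores = model.forest.predict_proba(rows)[:, pos_col]
    return (scores >= 0.5).reshape(len(A), len(B))


def classification_metrics(tn: int, fn: int, tp: int, fp: int) -> EvaluationMetrics:
    """Sensitivity, specificity and F1 from confusion-matrix counts.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    f1 = 2·tp/(2·tp+fp+fn).  Undefined ratios are returned as NaN with the
    matching flag set.
    """
    if min(tn, fn, tp, fp) < 0:
        raise ValueError("confusion-matrix counts must be non-negative")
    sens_undef = (tp + fn) == 0
    spec_undef = (tn + fp) == 0
    sensitivity = float("nan") if sens_undef else tp / (tp + fn)
    specificity = float("nan") if spec_undef else tn / (tn + fp)
    f1 = float("nan") if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return EvaluationMetrics(
        tn=tn, fn=fn, tp=tp, fp=fp,
        sensitivity=sensitivity, specificity=specificity, f1=f1,
        sensitivity_undefined=sens_undef, specificity_undefined=spec_undef,
    )


def write_arff(table: PairTable, path, relation: str = "protein_pairs") -> None:
    """Emit the pair table as ARFF text: numeric attributes f1..f60, the
    binary class attribute last, negatives before positives."""
    lines = [f"@relation {relation}", ""]
    lines += [f"@attribute f{i + 1} numeric" for i in range(table.X.shape[1])]
    lines.append("@attribute class {negative,positive}")
    lines.append("")
    lines.append("@data")
    for row, label in zip(table.X, table.y):
        cells = ",".join(f"{v:.6g}" for v in row)
        lines.append(f"{cells},{'positive' if label else 'negative'}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
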