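"""Class rebalancing, random-forest classification, cross-dataset assembly.

Class imbalance is the norm here ("same" dominates), so minority classes in
the *training* partition are oversampled with SMOTE — synthetic minority
samples interpolated between a real minority sample and one of its k nearest
minority-class neighbours.  Oversampling never touches test rows, and every
synthetic row is flagged so leakage checks can prove it.  The classifier is
a random forest with library-default parameters (see
:data:`RF_PARAMETER_REGISTRY` for the exact values in use).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from fohpred.features import feature_columns

logger = logging.getLogger(__name__)


def smote(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic minority oversampling up to the majority-class count.

    For each minority class, synthetic samples are drawn as
    ``x + u * (neighbour - x)`` with ``u ~ U(0, 1)``, where ``neighbour`` is
    one of the ``k_neighbors`` nearest same-class samples.  For classes
    smaller than ``k_neighbors + 1`` the neighbourhood shrinks; a singleton
    class cannot seed neighbours and is left un-oversampled with a warning.

    Returns ``(X_res, y_res, synthetic)`` where ``synthetic`` flags the
    appended artificial rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling needs at least 2 classes")
    rng = np.random.default_rng(seed)
    target = counts.max()
    parts_X, parts_y = [X], [y]
    flags = [np.zeros(len(y), dtype=bool)]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        if cnt == 1:
            logger.warning("class %r has a single instance; left un-oversampled", cls)
            continue
        rows = X[y == cls]
        k = min(k_neighbors, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(rows)
        neigh = nn.kneighbors(rows, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, cnt, size=need)
        pick = neigh[base, rng.integers(0, k, size=need)]
        u = rng.random((need, 1))
        synth = rows[base] + u * (rows[pick] - rows[base])
        parts_X.append(synth)
        parts_y.append(np.full(need, cls, dtype=y.dtype))
        flags.append(np.ones(need, dtype=bool))
    return (
        np.concatenate(parts_X),
        np.concatenate(parts_y),
        np.concatenate(flags),
    )


def oversample_train(
    train_features: pd.DataFrame,
    train_labels: np.ndarray | pd.Series,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """SMOTE on a training feature frame; returns (X, y, synthetic flags)."""
    cols = feature_columns(train_features)
    Xr, yr, flag = smote(
        train_features[cols].to_numpy(), np.asarray(train_labels), seed, k_neighbors
    )
    return pd.DataFrame(Xr, columns=cols), yr, flag


#: The exact "default" forest parameters this package relies on; recorded
#: explicitly because library defaults drift between versions.
RF_PARAMETER_REGISTRY = {
    "n_estimators": 100,
    "criterion": "gini",
    "max_depth": None,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
    "max_features": "sqrt",
    "bootstrap": True,
}


@dataclass
class TrainedModel:
    """A fitted forest plus the exact feature-column contract it expects."""

    estimator: RandomForestClassifier
    columns: list[str]
    classes: list
    seed: int
    meta: dict = field(default_factory=dict)

    def _check(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"prediction input lacks columns: {missing}")
        return X[self.columns]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._check(X))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(self._check(X))


def fit_classifier(
    features: pd.DataFrame, labels: np.ndarray | pd.Series, seed: int = 0
) -> TrainedModel:
    """Fit a default-parameter random forest; deterministic given the seed."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    cols = feature_columns(features)
    X = features[cols]
    if X.isna().any().any():
        raise ValueError("features must be imputed (complete) before fitting")
    est = RandomForestClassifier(random_state=seed, **RF_PARAMETER_REGISTRY)
    est.fit(X, y)
    return TrainedModel(est, cols, list(est.classes_), seed)


def combine_train_sets(
    primary: pd.DataFrame, auxiliary: pd.DataFrame
) -> pd.DataFrame:
    """Stack two feature matrices on their shared columns (cross-dataset training).

    A ``dataset`` provenance column is retained for audit; it is metadata,
    never a feature.
    """
    from fohpred.features import compatible_feature_set

    if len(auxiliary) == 0:
        common = feature_columns(primary)
    else:
        common = compatible_feature_set(primary, auxiliary)
    meta = [c for c in ("patient_id", "date", "label") if c in primary.columns]
    a = primary[meta + common].copy()
    a["dataset"] = "primary"
    if len(auxiliary) == 0:
        return a.reset_index(drop=True)
    b = auxiliary[[c for c in meta if c in auxiliary.columns] + common].copy()
    b["dataset"] = "auxiliary"
    return pd.concat([a, b], ignore_index=True)


def feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Impurity-based importances, non-negative, summing to 1, descending."""
    scores = model.estimator.feature_importances_
    ranked = sorted(zip(model.columns, scores), key=lambda t: (-t[1], t[0]))
    return [(name, float(s)) for name, s in ranked]
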