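"""Random-forest training with class subsampling and two-stage feature
selection.

The protocol mirrors how shallow forests are trained for time-activity
classification: indoor fixes dominate free-living GPS data, so the indoor
class is subsampled to a cap (30,000 for a study-sized dataset, 5,000 for a
small one) while every fix of the rarer classes is kept.  Feature selection
runs in two stages: (1) rank all features by mean-decrease-in-impurity
importance and greedily keep the top-ranked ones that are not highly
correlated (|r| < 0.75) with anything already kept, up to 20; (2) refit on
the survivors, estimate an importance z-score by repeated refits under
bootstrap resampling, and keep features with one-sided p < 0.001.

The forest itself is deliberately shallow (10 trees, depth 3 by default):
unlimited depth looks better in cross-validation but transfers poorly to
data from a different device or population.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .rulebased import CLASS_ORDER, INDOOR

__all__ = ["ForestConfig", "TrainedForest", "subsample_training",
           "select_features", "train_forest", "predict"]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 10
    max_depth: int | None = 3          # None = unlimited (sensitivity runs)
    indoor_cap: int = 30_000           # 30,000 study-sized; 5,000 small dataset
    correlation_cap: float = 0.75
    shortlist_size: int = 20
    zscore_p_threshold: float = 0.001
    n_refits: int = 25                 # refits behind the importance z-score
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")


@dataclass
class TrainedForest:
    """A fitted ensemble plus everything needed to reproduce it."""

    estimator: RandomForestClassifier
    selected_features: list[str]
    importances: pd.Series
    training_class_counts: dict[str, int]
    training_medians: pd.Series
    config: ForestConfig
    importance_method: str = "mean_decrease_impurity; z from repeated bootstrap refits"


def subsample_training(features: pd.DataFrame, labels: Sequence[str],
                       cap_indoor: int, seed: int,
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Cap the indoor class; keep every point of the other classes.

    Sampling is without replacement and deterministic under ``seed``.
    Returns positional row indices alongside the subsampled frame so
    callers can recover the original points.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(features):
        raise ValueError("labels and features length mismatch")
    rng = np.random.default_rng(seed)
    indoor_idx = np.flatnonzero(labels == INDOOR)
    other_idx = np.flatnonzero(labels != INDOOR)
    for cls in CLASS_ORDER:
        if not np.any(labels == cls):
            import logging
            logging.getLogger(__name__).warning("class %r absent from training data", cls)
    if indoor_idx.size > cap_indoor:
        indoor_idx = np.sort(rng.choice(indoor_idx, size=cap_indoor, replace=False))
    keep = np.sort(np.concatenate([indoor_idx, other_idx]))
    return features.iloc[keep].reset_index(drop=True), keep


def _impute(frame: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    return frame.fillna(medians).fillna(0.0)


def _fit(X: pd.DataFrame, y: np.ndarray, cfg: ForestConfig,
         seed: int) -> RandomForestClassifier:
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees, max_depth=cfg.max_depth,
        random_state=int(seed) % (2**31), n_jobs=1)
    est.fit(X.to_numpy(), y)
    return est


def select_features(features: pd.DataFrame, labels: Sequence[str],
                    cfg: ForestConfig = ForestConfig()) -> list[str]:
    """Two-stage feature selection; returns the kept names in rank order."""
    labels = np.asarray(labels, dtype=object)
    X = features.copy()

    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if constant:
        import logging
        logging.getLogger(__name__).warning(
            "excluding constant features before ranking: %s", constant)
        X = X.drop(columns=constant)
    medians = X.median()
    Xi = _impute(X, medians)

    # stage 1: importance ranking + greedy decorrelation
    est = _fit(Xi, labels, cfg, cfg.seed)
    imp = pd.Series(est.feature_importances_, index=Xi.columns)
    ranked = imp.sort_values(ascending=False, kind="stable").index.tolist()
    corr = Xi.corr().abs()
    kept: list[str] = []
    for name in ranked:
        if len(kept) >= cfg.shortlist_size:
            break
        if all(corr.loc[name, k] < cfg.correlation_cap for k in kept):
            kept.append(name)
    if not kept:
        return []

    # stage 2: z-score of importance under repeated bootstrap refits
    Xk = Xi[kept]
    rng = np.random.default_rng(cfg.seed)
    n = len(Xk)
    imps = np.empty((cfg.n_refits, len(kept)))
    for b in range(cfg.n_refits):
        rows = rng.integers(0, n, size=n)
        est_b = _fit(Xk.iloc[rows], labels[rows], cfg,
                     seed=rng.integers(0, 2**31 - 1))
        imps[b] = est_b.feature_importances_
    mean = imps.mean(axis=0)
    sd = imps.std(axis=0, ddof=1)
    z = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.where(mean > 0, np.inf, 0.0))
    p = sps.norm.sf(z)
    selected = [name for name, pj in zip(kept, p) if pj < cfg.zscore_p_threshold]
    order = np.argsort(-mean)
    return [kept[i] for i in order if kept[i] in selected]


def train_forest(features: pd.DataFrame, labels: Sequence[str],
                 selected: Sequence[str] | None = None,
                 cfg: ForestConfig = ForestConfig()) -> TrainedForest:
    """Fit the shallow forest on the selected features.

    Prediction is by majority vote over trees; probability ties are broken
    by a fixed class-order priority (indoor first) so results are
    deterministic under the seed.
    """
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    cols = list(selected) if selected is not None else list(features.columns)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise KeyError(f"selected features missing from matrix: {missing}")
    X = features[cols]
    medians = X.median()
    est = _fit(_impute(X, medians), labels, cfg, cfg.seed)
    counts = {cls: int((labels == cls).sum()) for cls in CLASS_ORDER
              if (labels == cls).any()}
    return TrainedForest(
        estimator=est, selected_features=cols,
        importances=pd.Series(est.feature_importances_, index=cols),
        training_class_counts=counts, training_medians=medians, config=cfg)


def predict(forest: TrainedForest, features: pd.DataFrame) -> np.ndarray:
    """One activity label per row; missing values imputed by training
    medians; ties broken indoor > outdoor static > walking > in-vehicle."""
    missing = [c for c in forest.selected_features if c not in features.columns]
    if missing:
        raise KeyError(f"feature matrix lacks selected columns: {missing}")
    if len(features) == 0:
        return np.array([], dtype=object)
    X = _impute(features[forest.selected_features], forest.training_medians)
    proba = forest.estimator.predict_proba(X.to_numpy())
    classes = list(forest.estimator.classes_)
    priority = [classes.index(c) for c in CLASS_ORDER if c in classes]
    proba = proba[:, priority]  # argmax takes the first max -> priority order
    winners = np.argmax(proba, axis=1)
    ordered = [classes[i] for i in priority]
    return np.array([ordered[w] for w in winners], dtype=object)
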