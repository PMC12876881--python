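"""Viability classification from radiomics feature vectors.

A gradient-boosted decision-tree ensemble (XGBoost) is trained and
validated with stratified 10-fold cross-validation; performance is
reported as ROC curves and the mean AUC across folds.  The trained model
scores longitudinally tracked organoids day by day, and the overall
viability of a track is the fraction of observed days predicted HIGH
(0 = always low viability, 1 = always high viability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .config import ClassifierParams
from .radiomics import FEATURE_NAMES

__all__ = [
    "CVResult",
    "TrackViability",
    "cross_validate",
    "learning_curve",
    "fit_full",
    "feature_importance",
    "score_tracks",
]


def _as_matrix(features, feature_names=None):
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(X.shape[1])
        ]
    if np.isnan(X).any():
        raise ValueError("missing feature values are rejected, not imputed")
    return X, names


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        mapped = np.where(y == "HIGH", 1, np.where(y == "LOW", 0, -1))
        if (mapped < 0).any():
            raise ValueError("labels must be HIGH/LOW or 0/1")
        return mapped.astype(int)
    return y.astype(int)


def _new_model(params: ClassifierParams, seed: int) -> XGBClassifier:
    # exact splits (midpoints between observed values) generalise better
    # than histogram bin edges on the small feature tables used here
    return XGBClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        tree_method="exact",
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )


@dataclass
class CVResult:
    """Per-fold ROC curves, AUCs, mean AUC and the fold assignment."""

    fold_curves: list[tuple[np.ndarray, np.ndarray]]
    fold_aucs: list[float]
    mean_auc: float
    fold_assignment: np.ndarray  # validation-fold index per sample
    seed: int
    n_folds: int = 10
    fold_scores: list[np.ndarray] = field(default_factory=list)
    fold_labels: list[np.ndarray] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "fold_aucs": list(self.fold_aucs),
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def cross_validate(
    features,
    labels,
    k: int = 10,
    seed: int = 0,
    params: Optional[ClassifierParams] = None,
    feature_names: Optional[Sequence[str]] = None,
    fold_assignment: Optional[np.ndarray] = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the viability classifier.

    Each sample lands in exactly one validation fold; per fold the model
    is fitted on the remaining folds and the validation ROC/AUC recorded.
    ``fold_assignment`` (a per-sample validation-fold index) reuses a
    previous run's folds instead of drawing new ones.
    """
    params = params or ClassifierParams()
    X, names = _as_matrix(features, feature_names)
    y = _as_binary(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes present")
    if counts.min() < k:
        raise ValueError(f"need >= {k} samples per class for {k}-fold CV")
    if fold_assignment is not None:
        fold_assignment = np.asarray(fold_assignment, int)
        splits = [
            (np.nonzero(fold_assignment != f)[0], np.nonzero(fold_assignment == f)[0])
            for f in range(k)
        ]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    curves, aucs, all_scores, all_labels = [], [], [], []
    assignment = np.full(len(y), -1, dtype=int)
    for fold, (tr, va) in enumerate(splits):
        model = _new_model(params, seed)
        model.fit(X[tr], y[tr])
        scores = model.predict_proba(X[va])[:, 1]
        fpr, tpr, _ = roc_curve(y[va], scores)
        curves.append((fpr, tpr))
        aucs.append(float(auc(fpr, tpr)))
        all_scores.append(scores)
        all_labels.append(y[va])
        assignment[va] = fold
    return CVResult(
        fold_curves=curves,
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        fold_assignment=assignment,
        seed=seed,
        n_folds=k,
        fold_scores=all_scores,
        fold_labels=all_labels,
    )


def learning_curve(
    features,
    labels,
    fractions: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    k: int = 10,
    seed: int = 0,
    params: Optional[ClassifierParams] = None,
) -> dict[float, float]:
    """Mean CV AUC as a function of the dataset fraction used.

    For each fraction a stratified subsample is drawn and
    :func:`cross_validate` run on it; the default grid is 10% to 100% in
    steps of 10% (10 entries).
    """
    X, _ = _as_matrix(features)
    y = _as_binary(labels)
    out: dict[float, float] = {}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        if frac >= 1.0:
            Xs, ys = X, y
        else:
            idx = np.arange(len(y))
            sub, _ = train_test_split(
                idx, train_size=frac, stratify=y, random_state=seed
            )
            Xs, ys = X[sub], y[sub]
        counts = np.bincount(ys, minlength=2)
        if counts.min() < k:
            raise ValueError(
                f"fraction {frac} leaves {counts.min()} samples in the smaller "
                f"class; need >= {k}"
            )
        out[float(frac)] = cross_validate(Xs, ys, k=k, seed=seed, params=params).mean_auc
    return out


def fit_full(
    features,
    labels,
    seed: int = 0,
    params: Optional[ClassifierParams] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> XGBClassifier:
    """Fit the classifier on the full dataset (for importances/scoring)."""
    params = params or ClassifierParams()
    X, names = _as_matrix(features, feature_names)
    y = _as_binary(labels)
    model = _new_model(params, seed)
    model.fit(X, y)
    model._ocpam_feature_names = names
    return model


def feature_importance(model: XGBClassifier, feature_names=None) -> list[tuple[str, float]]:
    """Gain-based importances, normalised to sum 1, descending.

    Features never used by any split receive importance 0.
    """
    names = feature_names or getattr(model, "_ocpam_feature_names", None)
    if names is None:
        names = list(FEATURE_NAMES)
    raw = model.get_booster().get_score(importance_type="gain")
    scores = np.zeros(len(names))
    for key, val in raw.items():
        idx = int(key[1:]) if key.startswith("f") and key[1:].isdigit() else names.index(key)
        scores[idx] = val
    total = scores.sum()
    if total > 0:
        scores = scores / total
    ranked = sorted(zip(names, scores), key=lambda kv: (-kv[1], kv[0]))
    return [(n, float(s)) for n, s in ranked]


@dataclass
class TrackViability:
    """Per-day predicted status of one track and its overall viability."""

    track_id: int
    days: tuple[int, ...]
    statuses: tuple[str, ...]  # HIGH | LOW per observed day
    overall_viability: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.days) != len(self.statuses):
            raise ValueError("days and statuses must align")
        if not self.days:
            raise ValueError("track has zero scorable days")
        n_high = sum(s == "HIGH" for s in self.statuses)
        self.overall_viability = n_high / len(self.days)

    def to_flat(self) -> dict:
        return {
            "track_id": self.track_id,
            "days": ";".join(str(d) for d in self.days),
            "statuses": ";".join(self.statuses),
            "overall_viability": self.overall_viability,
        }


def score_tracks(
    model: XGBClassifier,
    features_by_track: Mapping[int, Mapping[int, Sequence[float]]],
    threshold: float = 0.5,
) -> list[TrackViability]:
    """Predict HIGH/LOW per observed day and the overall viability.

    ``features_by_track`` maps track id -> day -> feature vector.  A day
    is HIGH iff the model's positive-class probability is strictly above
    ``threshold``.
    """
    out = []
    for tid in sorted(features_by_track):
        per_day = features_by_track[tid]
        if not per_day:
            raise ValueError(f"track {tid} has zero scorable days")
        days = tuple(sorted(per_day))
        X = np.asarray([per_day[d] for d in days], dtype=float)
        proba = model.predict_proba(X)[:, 1]
        statuses = tuple("HIGH" if p > threshold else "LOW" for p in proba)
        out.append(TrackViability(track_id=tid, days=days, statuses=statuses))
    return out
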