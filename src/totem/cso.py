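"""Seven-class cancer-signal-origin (CSO) stacked ensemble.

Features are logit-MFR values of the CSO markers, z-normalized with the
training mean and standard deviation per marker.  The architecture
mirrors a bagged stacking design: a base layer of four diverse learner
families (gradient-boosted trees, random forest, L2 multinomial
regression, single-hidden-layer network) is trained with repeated
stratified k-fold bagging; two stacker models consume the out-of-fold
base probabilities concatenated with the preprocessed features; the
final output is a convex combination of the stackers, with weights
chosen by greedy forward selection on out-of-fold log-loss.

Out-of-fold bookkeeping guarantees that no sample's stacking input was
produced by a base model trained on that sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .errors import InvalidInputError, SchemaError
from .matrix import MarkerMatrix
from .score import logit_transform, wilson_interval

__all__ = [
    "CSOPreprocessor",
    "CSOEnsemble",
    "train_ensemble",
    "predict_proba",
    "top_k_accuracy",
    "merge_hpca",
]

HPCA_MEMBERS = ("LIHC", "PAAD")
STD_FLOOR = 1e-6


@dataclass
class CSOPreprocessor:
    """Logit + z-normalization of MFR using training statistics."""

    markers: list[str] = field(default_factory=list)
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, matrix: MarkerMatrix, markers: Sequence[str]) -> "CSOPreprocessor":
        sub = matrix.subset_markers(markers)
        x = logit_transform(sub.mfc.to_numpy(), sub.n_informative.to_numpy())
        self.markers = list(markers)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean = np.nanmean(x, axis=0)
            self.std = np.nanstd(x, axis=0, ddof=1)
        # constant or all-missing markers: center only
        self.mean = np.where(np.isfinite(self.mean), self.mean, 0.0)
        self.std = np.where(
            np.isfinite(self.std) & (self.std > STD_FLOOR), self.std, 1.0
        )
        return self

    def transform(self, matrix: MarkerMatrix) -> pd.DataFrame:
        if self.mean is None:
            raise InvalidInputError("preprocessor not fitted")
        sub = matrix.subset_markers(self.markers)
        x = logit_transform(sub.mfc.to_numpy(), sub.n_informative.to_numpy())
        z = (x - self.mean) / self.std
        z = np.where(np.isfinite(z), z, 0.0)  # missing -> training mean
        return pd.DataFrame(z, index=sub.samples, columns=self.markers)

    def to_dict(self) -> dict:
        return {
            "markers": self.markers,
            "mean": [float(v) for v in self.mean],
            "std": [float(v) for v in self.std],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CSOPreprocessor":
        pre = cls(markers=list(d["markers"]))
        pre.mean = np.array(d["mean"], float)
        pre.std = np.array(d["std"], float)
        return pre


def _base_learners(seed: int) -> dict[str, Callable[[], object]]:
    return {
        "gbdt": lambda: HistGradientBoostingClassifier(
            max_iter=120, max_depth=3, learning_rate=0.1, random_state=seed
        ),
        "rf": lambda: RandomForestClassifier(
            n_estimators=200, min_samples_leaf=2, random_state=seed + 1
        ),
        "logreg": lambda: LogisticRegression(C=1.0, max_iter=2000),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(32,), alpha=1e-2, max_iter=800, random_state=seed + 2
        ),
    }


def _stackers(seed: int) -> dict[str, Callable[[], object]]:
    return {
        "stack_logreg": lambda: LogisticRegression(C=0.5, max_iter=2000),
        "stack_gbdt": lambda: HistGradientBoostingClassifier(
            max_iter=80, max_depth=2, learning_rate=0.1, random_state=seed + 3
        ),
    }


@dataclass
class CSOEnsemble:
    classes: list[str]
    preprocessor: CSOPreprocessor
    base_fold_models: dict[str, list]           # name -> fitted fold models
    stacker_models: dict[str, object]           # fitted on full OOF table
    blend_weights: dict[str, float]
    seed: int
    k_folds: int
    n_repeats: int
    fold_assignments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    oof_base: np.ndarray | None = None          # training OOF base probabilities


def _oof_base_probabilities(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    factories: dict[str, Callable[[], object]],
    k_folds: int,
    n_repeats: int,
    seed: int,
):
    """Repeated stratified k-fold bagging of every base learner.

    Returns fold models, the per-sample OOF probability table (averaged
    over repeats), and the fold assignments used (for leak audits).
    """
    splitter = RepeatedStratifiedKFold(
        n_splits=k_folds, n_repeats=n_repeats, random_state=seed
    )
    folds = [(tr, te) for tr, te in splitter.split(X, y)]
    fold_models: dict[str, list] = {name: [] for name in factories}
    oof = {name: np.zeros((X.shape[0], n_classes)) for name in factories}
    hits = np.zeros(X.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in folds:
            hits[te] += 1
            for name, make in factories.items():
                model = make()
                model.fit(X[tr], y[tr])
                fold_models[name].append(model)
                oof[name][te] += _proba_full(model, X[te], n_classes)
    for name in factories:
        oof[name] /= hits[:, None]
    stacked = np.hstack([oof[name] for name in factories])
    return fold_models, stacked, folds


def _proba_full(model, X: np.ndarray, n_classes: int) -> np.ndarray:
    """Probability matrix padded to the full class set (folds can miss classes)."""
    p = model.predict_proba(X)
    if p.shape[1] == n_classes:
        return p
    out = np.zeros((X.shape[0], n_classes))
    for j, cls in enumerate(model.classes_):
        out[:, int(cls)] = p[:, j]
    return out


def _greedy_blend(
    oof_by_stacker: dict[str, np.ndarray], y: np.ndarray, n_iter: int = 20
) -> dict[str, float]:
    """Forward selection with replacement maximizing OOF log-loss improvement."""
    names = sorted(oof_by_stacker)
    counts = {name: 0 for name in names}
    current = None
    for _ in range(n_iter):
        best_name, best_loss = None, np.inf
        for name in names:
            total = sum(counts.values())
            cand = (
                oof_by_stacker[name]
                if current is None
                else (current * total + oof_by_stacker[name]) / (total + 1)
            )
            loss = log_loss(y, cand, labels=np.arange(cand.shape[1]))
            if loss < best_loss - 1e-12:
                best_name, best_loss = name, loss
        prev_loss = (
            np.inf if current is None
            else log_loss(y, current, labels=np.arange(current.shape[1]))
        )
        if best_loss >= prev_loss - 1e-9:
            break
        total = sum(counts.values())
        current = (
            oof_by_stacker[best_name]
            if current is None
            else (current * total + oof_by_stacker[best_name]) / (total + 1)
        )
        counts[best_name] += 1
    total = sum(counts.values())
    if total == 0:
        counts[names[0]] = 1
        total = 1
    return {name: counts[name] / total for name in names}


def train_ensemble(
    features: pd.DataFrame,
    labels: Sequence[str],
    preprocessor: CSOPreprocessor,
    k_folds: int = 5,
    n_repeats: int = 2,
    seed: int = 0,
) -> CSOEnsemble:
    """Train the stacked CSO ensemble on preprocessed features.

    ``features`` rows are training samples (true positives), columns the
    CSO markers; ``labels`` their cancer classes.
    """
    y_labels = np.asarray(labels)
    classes = sorted(set(y_labels))
    if len(classes) < 2:
        raise InvalidInputError("need >= 2 classes")
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[c] for c in y_labels])
    counts = np.bincount(y, minlength=len(classes))
    if counts.min() < k_folds:
        raise InvalidInputError(
            f"every class needs >= k_folds={k_folds} samples (min is {counts.min()})"
        )
    X = features.to_numpy(dtype=float)
    bases = _base_learners(seed)
    fold_models, oof_base, folds = _oof_base_probabilities(
        X, y, len(classes), bases, k_folds, n_repeats, seed
    )
    stack_X = np.hstack([oof_base, X])

    # stacker OOF predictions via an independent repeated k-fold
    stacker_factories = _stackers(seed)
    splitter = RepeatedStratifiedKFold(
        n_splits=k_folds, n_repeats=n_repeats, random_state=seed + 1000
    )
    oof_stack = {name: np.zeros((X.shape[0], len(classes))) for name in stacker_factories}
    hits = np.zeros(X.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in splitter.split(stack_X, y):
            hits[te] += 1
            for name, make in stacker_factories.items():
                model = make()
                model.fit(stack_X[tr], y[tr])
                oof_stack[name][te] += _proba_full(model, stack_X[te], len(classes))
        for name in oof_stack:
            oof_stack[name] /= hits[:, None]

        weights = _greedy_blend(oof_stack, y)
        stacker_models = {
            name: make().fit(stack_X, y) for name, make in stacker_factories.items()
        }
    return CSOEnsemble(
        classes=classes,
        preprocessor=preprocessor,
        base_fold_models=fold_models,
        stacker_models=stacker_models,
        blend_weights=weights,
        seed=seed,
        k_folds=k_folds,
        n_repeats=n_repeats,
        fold_assignments=folds,
        oof_base=oof_base,
    )


def predict_proba(model: CSOEnsemble, features: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class probabilities from the blended stackers.

    Base-layer probabilities for new samples are the average over all
    bagged fold models (no fold saw the new sample, so every fold model
    is usable).
    """
    if list(features.columns) != model.preprocessor.markers:
        raise SchemaError("feature columns do not match the fitted marker set")
    X = features.to_numpy(dtype=float)
    n_classes = len(model.classes)
    # base ordering identical to training (insertion order of factories)
    base_probs = [
        np.mean([_proba_full(m, X, n_classes) for m in model.base_fold_models[name]], axis=0)
        for name in model.base_fold_models
    ]
    stack_X = np.hstack(base_probs + [X])
    out = np.zeros((X.shape[0], n_classes))
    for name, w in model.blend_weights.items():
        if w > 0:
            out += w * _proba_full(model.stacker_models[name], stack_X, n_classes)
    out /= out.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, index=features.index, columns=model.classes)


def rank_classes(proba: pd.DataFrame) -> pd.DataFrame:
    """Classes ranked by probability per sample; ties break alphabetically."""
    cols = sorted(proba.columns)
    vals = proba[cols].to_numpy()
    order = np.argsort(-vals, axis=1, kind="stable")  # stable -> alphabetical ties
    ranked = np.array(cols)[order]
    return pd.DataFrame(
        ranked, index=proba.index, columns=[f"rank{i+1}" for i in range(len(cols))]
    )


def top_k_accuracy(
    proba: pd.DataFrame, true_labels: Sequence[str], k: int
) -> dict:
    """Fraction of samples whose true class is among the top-k predictions."""
    if k < 1 or k > proba.shape[1]:
        raise InvalidInputError("k must be in [1, n_classes]")
    ranked = rank_classes(proba)
    truth = np.asarray(true_labels)
    hits = np.any(ranked.iloc[:, :k].to_numpy() == truth[:, None], axis=1)
    n = len(truth)
    k_hit = int(hits.sum())
    lo, hi = wilson_interval(k_hit, n)
    return {"accuracy": k_hit / n, "n": n, "ci": [lo, hi]}


def merge_hpca(proba: pd.DataFrame) -> pd.DataFrame:
    """Fuse LIHC and PAAD into a hepatopancreatic class (HPCA).

    The HPCA probability is the sum of its members; all other classes
    are untouched, so probabilities still sum to one.
    """
    missing = [c for c in HPCA_MEMBERS if c not in proba.columns]
    if missing:
        raise SchemaError(f"prediction schema missing {missing}")
    out = proba.drop(columns=list(HPCA_MEMBERS)).copy()
    out["HPCA"] = proba[list(HPCA_MEMBERS)].sum(axis=1)
    return out[sorted(out.columns)]


def merge_hpca_labels(labels: Sequence[str]) -> np.ndarray:
    return np.array([
        "HPCA" if lab in HPCA_MEMBERS else lab for lab in np.asarray(labels)
    ])
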