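"""Marker selection: mutual information ranking and bootstrapped elimination.

Diagnostic markers are ranked per cancer class by the plug-in mutual
information between discretized MFC values and the class-vs-healthy
label; the union of the per-class top-X lists forms the multi-cancer
diagnostic set, with X chosen to maximize training AUC of the
methylation-score model.

Cancer-signal-origin (CSO) markers start from the union of top-k MI
lists over all 21 unordered class pairs, then get pruned by backward
elimination under an L2-penalized multinomial logistic model, scored by
AIC (unpenalized log-likelihood at the penalized estimate, k = free
parameter count).  Elimination runs on 10 stratified 80% bootstraps;
markers retained in more than six draws survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import InvalidInputError
from .matrix import CANCER_CLASSES, HEALTHY_LABEL, MarkerMatrix
from . import score as _score

__all__ = [
    "mutual_information",
    "rank_markers_by_mi",
    "DiagnosticSelection",
    "select_diagnostic_markers",
    "optimize_top_x",
    "select_cso_candidates",
    "backward_eliminate",
    "CSOSelection",
    "bootstrap_cso_selection",
]


def _discretize(values: np.ndarray, n_bins: int, scheme: str) -> np.ndarray:
    if scheme == "binarize":
        return (values > 0).astype(int)
    if scheme != "quantile":
        raise InvalidInputError(f"unknown discretization scheme {scheme!r}")
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)  # merge degenerate bins
    return np.searchsorted(edges, values, side="right")


def mutual_information(
    values, labels, n_bins: int = 4, scheme: str = "quantile"
) -> float:
    """Plug-in mutual information (bits) between discretized values and labels.

    Values are quantile-binned into at most ``n_bins`` bins (degenerate
    bins merged); with ``scheme="binarize"`` the statistic uses the
    presence/absence of methylated fragments instead.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise InvalidInputError("values and labels must align")
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise InvalidInputError("labels must contain at least two groups")
    if min(np.bincount(y)) < 2:
        raise InvalidInputError("need >= 2 samples per group")
    x = _discretize(values, n_bins, scheme)
    joint = np.zeros((x.max() + 1, len(classes)))
    np.add.at(joint, (x, y), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def rank_markers_by_mi(
    matrix: MarkerMatrix,
    sample_ids: Sequence[str],
    labels: Sequence,
    n_bins: int = 4,
    scheme: str = "quantile",
) -> pd.DataFrame:
    """MI per marker over the given samples, ranked descending.

    Ties break on the lexicographic marker id so rankings are identical
    across platforms and runs.
    """
    sub = matrix.subset_samples(sample_ids)
    labels = np.asarray(labels)
    mi = np.array(
        [
            mutual_information(sub.mfc[m].to_numpy(), labels, n_bins, scheme)
            for m in sub.markers
        ]
    )
    ranking = pd.DataFrame({"mcb_id": sub.markers, "mi_bits": mi})
    ranking = ranking.sort_values(
        ["mi_bits", "mcb_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


@dataclass
class DiagnosticSelection:
    rankings: dict[str, pd.DataFrame]  # class -> ranked marker table
    top_x: int
    union_markers: list[str]

    def union_at(self, top_x: int) -> list[str]:
        union: set[str] = set()
        for ranking in self.rankings.values():
            union.update(ranking["mcb_id"].head(top_x))
        return sorted(union)


def select_diagnostic_markers(
    matrix: MarkerMatrix,
    sheet: pd.DataFrame,
    top_x: int,
    split: str | None = "train",
    n_bins: int = 4,
    scheme: str = "quantile",
) -> DiagnosticSelection:
    """Per-class MI ranking vs healthy controls; union of top-X lists."""
    sub = sheet if split is None else sheet[sheet["split"] == split]
    healthy_ids = sub.loc[sub["label"] == HEALTHY_LABEL, "sample_id"].tolist()
    rankings: dict[str, pd.DataFrame] = {}
    for cls in CANCER_CLASSES:
        cls_ids = sub.loc[sub["label"] == cls, "sample_id"].tolist()
        if len(cls_ids) < 2 or len(healthy_ids) < 2:
            raise InvalidInputError(f"class {cls} or healthy underrepresented")
        ids = healthy_ids + cls_ids
        labels = np.r_[np.zeros(len(healthy_ids)), np.ones(len(cls_ids))]
        rankings[cls] = rank_markers_by_mi(matrix, ids, labels, n_bins, scheme)
    selection = DiagnosticSelection(rankings=rankings, top_x=top_x, union_markers=[])
    selection.union_markers = selection.union_at(top_x)
    return selection


def optimize_top_x(
    matrix: MarkerMatrix,
    sheet: pd.DataFrame,
    candidate_x: Sequence[int] = range(1, 101),
    specificity: float = 0.98,
    n_bins: int = 4,
    scheme: str = "quantile",
) -> tuple[int, DiagnosticSelection, pd.DataFrame]:
    """Choose X maximizing training AUC of the methylation-score model.

    Returns the optimum (smallest X on ties), the selection at that X,
    and the full AUC-vs-X grid table.
    """
    candidate_x = [x for x in candidate_x if x >= 1]
    if not candidate_x:
        raise InvalidInputError("empty top-X grid")
    train = sheet[sheet["split"] == "train"]
    control_ids = train.loc[train["label"] == HEALTHY_LABEL, "sample_id"].tolist()
    train_ids = train["sample_id"].tolist()
    y = (train["label"] != HEALTHY_LABEL).to_numpy().astype(int)
    selection = select_diagnostic_markers(matrix, sheet, max(candidate_x), "train",
                                          n_bins, scheme)
    rows = []
    best_x, best_auc = None, -np.inf
    for x in sorted(candidate_x):
        union = selection.union_at(x)
        baseline = _score.fit_baseline(matrix, control_ids, markers=union)
        scores = _score.score_samples(matrix, baseline, train_ids)
        auc = _score.roc_auc(scores.to_numpy(), y)
        rows.append((x, len(union), auc))
        if auc > best_auc + 1e-12:
            best_x, best_auc = x, auc
    grid = pd.DataFrame(rows, columns=["top_x", "n_markers", "train_auc"])
    selection.top_x = best_x
    selection.union_markers = selection.union_at(best_x)
    return best_x, selection, grid


def select_cso_candidates(
    matrix: MarkerMatrix,
    sheet: pd.DataFrame,
    sample_ids: Sequence[str],
    pair_top_k: int = 100,
    n_bins: int = 4,
    scheme: str = "quantile",
    classes: Sequence[str] = CANCER_CLASSES,
) -> tuple[list[str], dict[tuple[str, str], pd.DataFrame]]:
    """Top-k MI markers for each unordered cancer-class pair.

    ``sample_ids`` should be the true-positive training cancer samples;
    with the full seven classes this is the 21-pair sweep.  Returns the
    candidate union and the per-pair rankings.
    """
    sub = sheet.set_index("sample_id").loc[list(sample_ids)]
    classes = tuple(classes)
    rankings: dict[tuple[str, str], pd.DataFrame] = {}
    union: set[str] = set()
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            ids_a = sub.index[sub["label"] == a].tolist()
            ids_b = sub.index[sub["label"] == b].tolist()
            if len(ids_a) < 2 or len(ids_b) < 2:
                raise InvalidInputError(f"pair ({a}, {b}) underrepresented")
            ids = ids_a + ids_b
            labels = np.r_[np.zeros(len(ids_a)), np.ones(len(ids_b))]
            ranking = rank_markers_by_mi(matrix, ids, labels, n_bins, scheme)
            rankings[(a, b)] = ranking
            union.update(ranking["mcb_id"].head(pair_top_k))
    return sorted(union), rankings


# ---------------------------------------------------------------------------
# L2 multinomial logistic fit (warm-startable) + AIC backward elimination

def _fit_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    l2: float = 1.0,
    coef0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Fit softmax regression with L2 penalty on weights (not intercepts).

    Returns the coefficient matrix of shape (n_classes, p + 1), intercept
    last, and the *unpenalized* log-likelihood at the estimate.
    """
    n, p = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y] = 1.0
    mask = np.ones((n_classes, p + 1))
    mask[:, -1] = 0.0  # intercepts unpenalized

    def objective(w_flat: np.ndarray):
        W = w_flat.reshape(n_classes, p + 1)
        Z = Xa @ W.T
        Z -= Z.max(axis=1, keepdims=True)
        expZ = np.exp(Z)
        denom = expZ.sum(axis=1, keepdims=True)
        log_p = Z - np.log(denom)
        ll = float((Y * log_p).sum())
        P = expZ / denom
        grad = (P - Y).T @ Xa + l2 * W * mask
        f = -ll + 0.5 * l2 * float(((W * mask) ** 2).sum())
        return f, grad.ravel()

    x0 = (
        np.zeros(n_classes * (p + 1))
        if coef0 is None
        else np.asarray(coef0, dtype=float).ravel()
    )
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-10})
    W = res.x.reshape(n_classes, p + 1)
    Z = Xa @ W.T
    Z -= Z.max(axis=1, keepdims=True)
    log_p = Z - np.log(np.exp(Z).sum(axis=1, keepdims=True))
    ll = float((Y * log_p).sum())
    return W, ll


def _aic(ll: float, n_classes: int, n_features: int) -> float:
    k = (n_classes - 1) * (n_features + 1)
    return 2.0 * k - 2.0 * ll


def backward_eliminate(
    features: pd.DataFrame,
    labels: Sequence,
    l2_strength: float = 1.0,
    screen_top: int | None = 20,
) -> list[str]:
    """AIC-guided backward elimination of marker features.

    At each step the single feature whose removal most improves
    (decreases) the AIC is dropped; the procedure stops when no removal
    improves AIC.  Refits are warm-started from the current coefficient
    matrix.  With ``screen_top`` set, only the ``screen_top`` features
    with the smallest L2 coefficient norm are considered for removal at
    each step (the AIC comparison among them is still exact); pass
    ``None`` to evaluate every remaining feature, which is quadratic in
    the candidate count.
    """
    if features.shape[1] == 0:
        raise InvalidInputError("empty feature set")
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    if len(classes) < 2:
        raise InvalidInputError("need >= 2 classes")
    if features.shape[0] < 2:
        raise InvalidInputError("need more than one sample")
    current = list(features.columns)
    X = features.to_numpy(dtype=float)
    col_of = {m: i for i, m in enumerate(features.columns)}
    W, ll = _fit_multinomial(X, y, len(classes), l2_strength)
    best_aic = _aic(ll, len(classes), len(current))
    while len(current) > 1:
        if screen_top is not None and len(current) > screen_top:
            norms = np.linalg.norm(W[:, :-1], axis=0)
            shortlist = set(np.argsort(norms, kind="stable")[:screen_top])
        else:
            shortlist = set(range(len(current)))
        best_drop, best_drop_aic, best_drop_W = None, best_aic, None
        for j in sorted(shortlist):
            marker = current[j]
            keep = [col_of[m] for m in current if m != marker]
            W0 = np.delete(W, j, axis=1)  # drop feature column, keep intercept
            W_try, ll_try = _fit_multinomial(
                X[:, keep], y, len(classes), l2_strength, coef0=W0
            )
            aic_try = _aic(ll_try, len(classes), len(current) - 1)
            if aic_try < best_drop_aic - 1e-9:
                best_drop, best_drop_aic, best_drop_W = marker, aic_try, W_try
        if best_drop is None:
            break
        current.remove(best_drop)
        W, best_aic = best_drop_W, best_drop_aic
    return current


@dataclass
class CSOSelection:
    candidates: list[str]
    retention: pd.Series  # marker -> retention count over bootstraps
    retention_threshold: int
    final_markers: list[str] = field(default_factory=list)

    def final_at(self, threshold: int) -> list[str]:
        return sorted(self.retention.index[self.retention > threshold])


def bootstrap_cso_selection(
    features: pd.DataFrame,
    labels: Sequence,
    n_bootstraps: int = 10,
    subsample: float = 0.80,
    retention_threshold: int = 6,
    l2_strength: float = 1.0,
    seed: int = 0,
) -> CSOSelection:
    """Backward elimination over stratified 80% bootstraps.

    Markers retained in more than ``retention_threshold`` of the
    ``n_bootstraps`` draws form the final CSO marker set.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    counts = np.bincount(pd.factorize(labels)[0])
    if counts.min() < 3:
        raise InvalidInputError("every class needs >= 3 samples for bootstrapping")
    rng = np.random.default_rng(seed)
    retention = pd.Series(0, index=features.columns, dtype=int)
    for b in range(n_bootstraps):
        draw_seed = rng.integers(0, 2**31 - 1)
        draw_rng = np.random.default_rng(draw_seed)
        rows: list = []
        for cls, group in labels.groupby(labels, sort=True):
            ids = np.array(group.index)
            n_take = max(2, int(round(subsample * len(ids))))
            rows.extend(draw_rng.choice(ids, size=n_take, replace=False))
        kept = backward_eliminate(features.loc[rows], labels.loc[rows], l2_strength)
        retention.loc[kept] += 1
    selection = CSOSelection(
        candidates=list(features.columns),
        retention=retention,
        retention_threshold=retention_threshold,
    )
    selection.final_markers = selection.final_at(retention_threshold)
    return selection
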