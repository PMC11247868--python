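"""End-to-end orchestration: quantified matrix -> diagnosis -> CSO.

``run_pipeline`` executes the two-step design on a marker matrix plus
sample sheet: select diagnostic markers on the training split, fit the
healthy baseline and the score threshold, evaluate detection, gate
cancer samples at the threshold (true positives), select CSO markers,
train the stacked CSO ensemble, and evaluate localization.  Every stage
honors the train/test split and the single run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cso as _cso
from . import score as _score
from . import selection as _selection
from .errors import InvalidInputError
from .matrix import HEALTHY_LABEL, MarkerMatrix

logger = logging.getLogger("totem")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "marker_count_sweep"]


@dataclass
class PipelineConfig:
    """Tunable knobs of a full run (all stages honor ``seed``)."""

    specificity: float = 0.98
    top_x_grid: Sequence[int] = tuple(range(1, 101))
    fixed_top_x: int | None = None       # skip the AUC optimization when set
    mi_bins: int = 4
    mi_scheme: str = "quantile"
    cso_pair_top_k: int = 100
    cso_n_bootstraps: int = 10
    cso_subsample: float = 0.80
    cso_retention_threshold: int = 6
    cso_l2_strength: float = 1.0
    cso_k_folds: int = 5
    cso_n_repeats: int = 2
    fit_cso: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    diagnostic_selection: _selection.DiagnosticSelection
    top_x_grid: pd.DataFrame | None
    baseline: _score.BaselineModel
    threshold: _score.ThresholdModel
    scores: pd.Series
    report: dict
    cso_selection: _selection.CSOSelection | None = None
    cso_model: _cso.CSOEnsemble | None = None
    cso_predictions: pd.DataFrame | None = None

    def save_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report, indent=1, default=float))

    def report_markdown(self) -> str:
        r = self.report
        lines = ["# Pipeline report", ""]
        d = r["diagnostic"]
        lines.append(f"- diagnostic markers: {d['n_markers']} (top-X = {d['top_x']})")
        lines.append(f"- score cutoff: {d['cutoff']:.3f} "
                     f"(target specificity {d['specificity_target']:.2f})")
        for split in ("train", "test"):
            if d.get(split):
                lines.append(f"- {split} AUC: {d[split]['auc']:.3f}")
        if r.get("cso"):
            c = r["cso"]
            lines.append(f"- CSO markers: {c['n_markers']}")
            for split in ("train", "test"):
                if c.get(split):
                    lines.append(
                        f"- CSO {split} top-1/top-2: "
                        f"{c[split]['top1']['accuracy']:.3f} / "
                        f"{c[split]['top2']['accuracy']:.3f}"
                    )
        return "\n".join(lines) + "\n"


def _split_ids(sheet: pd.DataFrame, split: str) -> pd.DataFrame:
    sub = sheet[sheet["split"] == split]
    if sub.empty:
        raise InvalidInputError(f"no samples in split {split!r}")
    return sub


def _evaluate_split(
    matrix: MarkerMatrix,
    sheet_split: pd.DataFrame,
    baseline: _score.BaselineModel,
    threshold: _score.ThresholdModel,
) -> tuple[pd.Series, dict]:
    ids = sheet_split["sample_id"].tolist()
    scores = _score.score_samples(matrix, baseline, ids)
    labels = (sheet_split.set_index("sample_id").loc[ids, "label"] != HEALTHY_LABEL)
    entry = _score.sensitivity_report(scores, sheet_split, threshold)
    if labels.nunique() == 2:
        entry["auc"] = _score.roc_auc(scores.to_numpy(), labels.to_numpy())
    return scores, entry


def run_pipeline(
    matrix: MarkerMatrix, sheet: pd.DataFrame, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run diagnosis + CSO on a split cohort; return models and report."""
    config = config or PipelineConfig()
    train = _split_ids(sheet, "train")
    control_ids = train.loc[train["label"] == HEALTHY_LABEL, "sample_id"].tolist()
    logger.info("train: %d samples (%d controls)", len(train), len(control_ids))

    # 1. diagnostic marker selection
    if config.fixed_top_x is not None:
        selection = _selection.select_diagnostic_markers(
            matrix, sheet, config.fixed_top_x, "train",
            config.mi_bins, config.mi_scheme,
        )
        grid = None
    else:
        _, selection, grid = _selection.optimize_top_x(
            matrix, sheet, config.top_x_grid, config.specificity,
            config.mi_bins, config.mi_scheme,
        )
    markers = selection.union_markers
    logger.info("diagnostic markers: %d (top-X=%d)", len(markers), selection.top_x)

    # 2. baseline + threshold
    baseline = _score.fit_baseline(matrix, control_ids, markers=markers)
    train_scores = _score.score_samples(matrix, baseline, train["sample_id"].tolist())
    threshold = _score.calibrate_threshold(
        train_scores.loc[control_ids].to_numpy(), config.specificity
    )
    logger.info("score cutoff: %.4f", threshold.cutoff)

    # 3. detection evaluation
    report: dict = {
        "seed": config.seed,
        "diagnostic": {
            "top_x": selection.top_x,
            "n_markers": len(markers),
            "markers": markers,
            "cutoff": threshold.cutoff,
            "specificity_target": config.specificity,
        },
    }
    scores_all = [train_scores]
    _, report["diagnostic"]["train"] = _evaluate_split(matrix, train, baseline, threshold)
    has_test = (sheet["split"] == "test").any()
    if has_test:
        test = _split_ids(sheet, "test")
        test_scores, entry = _evaluate_split(matrix, test, baseline, threshold)
        report["diagnostic"]["test"] = entry
        scores_all.append(test_scores)
    scores = pd.concat(scores_all)

    result = PipelineResult(
        diagnostic_selection=selection,
        top_x_grid=grid,
        baseline=baseline,
        threshold=threshold,
        scores=scores,
        report=report,
    )
    if not config.fit_cso:
        return result

    # 4. true-positive gating on the training split
    train_cancer = train[train["label"] != HEALTHY_LABEL]
    tp_train = train_cancer[
        threshold.call(scores.loc[train_cancer["sample_id"]].to_numpy())
    ]
    logger.info("training true positives: %d", len(tp_train))
    # classes with too few detected samples cannot be learned or
    # bootstrap-stratified; they are excluded from CSO training (and
    # will count as CSO errors at evaluation time)
    tp_counts = tp_train["label"].value_counts()
    usable_classes = tp_counts.index[tp_counts >= 3]
    dropped = sorted(set(tp_counts.index) - set(usable_classes))
    if dropped:
        logger.warning("CSO training drops classes with <3 true positives: %s", dropped)
    tp_train = tp_train[tp_train["label"].isin(usable_classes)]
    if len(usable_classes) < 2:
        logger.warning("fewer than two CSO-trainable classes; skipping CSO stage")
        report["cso"] = None
        return result

    # 5. CSO marker selection
    candidates, _ = _selection.select_cso_candidates(
        matrix, sheet, tp_train["sample_id"].tolist(),
        config.cso_pair_top_k, config.mi_bins, config.mi_scheme,
        classes=sorted(usable_classes),
    )
    pre_all = _cso.CSOPreprocessor().fit(
        matrix.subset_samples(tp_train["sample_id"].tolist()), candidates
    )
    feats_all = pre_all.transform(matrix.subset_samples(tp_train["sample_id"].tolist()))
    cso_selection = _selection.bootstrap_cso_selection(
        feats_all,
        tp_train.set_index("sample_id").loc[feats_all.index, "label"],
        n_bootstraps=config.cso_n_bootstraps,
        subsample=config.cso_subsample,
        retention_threshold=config.cso_retention_threshold,
        l2_strength=config.cso_l2_strength,
        seed=config.seed + 11,
    )
    cso_markers = cso_selection.final_markers
    if not cso_markers:  # degenerate pruning: fall back to the candidate set
        cso_markers = cso_selection.candidates
    logger.info("CSO markers: %d of %d candidates", len(cso_markers), len(candidates))

    # 6. CSO ensemble
    tp_ids = tp_train["sample_id"].tolist()
    preprocessor = _cso.CSOPreprocessor().fit(
        matrix.subset_samples(tp_ids), cso_markers
    )
    train_feats = preprocessor.transform(matrix.subset_samples(tp_ids))
    train_labels = tp_train.set_index("sample_id").loc[tp_ids, "label"]
    k_folds = min(config.cso_k_folds, int(tp_train["label"].value_counts().min()))
    k_folds = max(k_folds, 2)
    if k_folds < config.cso_k_folds:
        logger.warning("reducing CSO folds to %d for the smallest class", k_folds)
    model = _cso.train_ensemble(
        train_feats, train_labels,
        preprocessor,
        k_folds=k_folds,
        n_repeats=config.cso_n_repeats,
        seed=config.seed + 17,
    )
    report["cso"] = {
        "n_candidates": len(candidates),
        "n_markers": len(cso_markers),
        "markers": cso_markers,
        "n_train_true_positives": len(tp_ids),
    }

    def cso_eval(ids: list[str], labels: pd.Series) -> tuple[pd.DataFrame, dict]:
        feats = preprocessor.transform(matrix.subset_samples(ids))
        proba = _cso.predict_proba(model, feats)
        entry = {
            "top1": _cso.top_k_accuracy(proba, labels, 1),
            "top2": _cso.top_k_accuracy(proba, labels, 2),
        }
        if set(_cso.HPCA_MEMBERS) <= set(model.classes):
            merged = _cso.merge_hpca(proba)
            merged_labels = _cso.merge_hpca_labels(labels)
            entry["hpca_top1"] = _cso.top_k_accuracy(merged, merged_labels, 1)
            entry["hpca_top2"] = _cso.top_k_accuracy(merged, merged_labels, 2)
        else:  # a hepatopancreatic class was dropped at TP gating
            entry["hpca_top1"] = entry["hpca_top2"] = None
        return proba, entry

    train_proba, report["cso"]["train"] = cso_eval(tp_ids, train_labels)
    predictions = [train_proba.assign(split="train")]
    if has_test:
        test_cancer = test[test["label"] != HEALTHY_LABEL]
        tp_test = test_cancer[
            threshold.call(scores.loc[test_cancer["sample_id"]].to_numpy())
        ]
        report["cso"]["n_test_true_positives"] = len(tp_test)
        if len(tp_test):
            test_labels = tp_test.set_index("sample_id")["label"]
            test_proba, report["cso"]["test"] = cso_eval(
                tp_test["sample_id"].tolist(), test_labels
            )
            predictions.append(test_proba.assign(split="test"))
    result.cso_selection = cso_selection
    result.cso_model = model
    result.cso_predictions = pd.concat(predictions)
    result.report = report
    return result


def marker_count_sweep(
    matrix: MarkerMatrix,
    sheet: pd.DataFrame,
    result: PipelineResult,
    top_x_grid: Sequence[int] = tuple(range(1, 101)),
    retention_grid: Sequence[int] = tuple(range(0, 10)),
    config: PipelineConfig | None = None,
    fit_cso: bool = False,
) -> dict[str, pd.DataFrame]:
    """Performance versus marker-set size.

    The diagnostic sweep refits baseline + threshold for every top-X and
    reports train (and test) AUC.  The CSO sweep reports the marker count
    surviving each retention threshold; with ``fit_cso=True`` it also
    retrains the ensemble per threshold and reports top-1/top-2.
    """
    config = config or PipelineConfig()
    train = _split_ids(sheet, "train")
    control_ids = train.loc[train["label"] == HEALTHY_LABEL, "sample_id"].tolist()
    has_test = (sheet["split"] == "test").any()
    max_rank = len(matrix.markers)
    top_x_grid = [x for x in top_x_grid if 1 <= x]
    if any(x > max_rank for x in top_x_grid):
        logger.warning("top-X grid truncated to the %d available markers", max_rank)
        top_x_grid = [x for x in top_x_grid if x <= max_rank]
    rows = []
    for x in sorted(top_x_grid):
        union = result.diagnostic_selection.union_at(x)
        baseline = _score.fit_baseline(matrix, control_ids, markers=union)
        train_scores = _score.score_samples(matrix, baseline, train["sample_id"].tolist())
        threshold = _score.calibrate_threshold(
            train_scores.loc[control_ids].to_numpy(), config.specificity
        )
        y_train = (train.set_index("sample_id").loc[train_scores.index, "label"]
                   != HEALTHY_LABEL).to_numpy()
        row = {
            "top_x": x,
            "n_markers": len(union),
            "train_auc": _score.roc_auc(train_scores.to_numpy(), y_train),
        }
        if has_test:
            test = _split_ids(sheet, "test")
            test_scores = _score.score_samples(matrix, baseline, test["sample_id"].tolist())
            y_test = (test.set_index("sample_id").loc[test_scores.index, "label"]
                      != HEALTHY_LABEL).to_numpy()
            row["test_auc"] = _score.roc_auc(test_scores.to_numpy(), y_test)
        rows.append(row)
    sweep: dict[str, pd.DataFrame] = {"diagnostic": pd.DataFrame(rows)}

    if result.cso_selection is not None:
        retention = result.cso_selection.retention
        cso_rows = []
        for t in sorted(retention_grid):
            markers = result.cso_selection.final_at(t)
            row: dict = {"retention_threshold": t, "n_markers": len(markers)}
            if fit_cso and markers:
                sub_cfg = PipelineConfig(**{**config.__dict__})
                tp_ids = result.cso_predictions.index[
                    result.cso_predictions["split"] == "train"
                ].tolist()
                labels = sheet.set_index("sample_id").loc[tp_ids, "label"]
                pre = _cso.CSOPreprocessor().fit(matrix.subset_samples(tp_ids), markers)
                feats = pre.transform(matrix.subset_samples(tp_ids))
                model = _cso.train_ensemble(
                    feats, labels, pre,
                    k_folds=config.cso_k_folds, n_repeats=config.cso_n_repeats,
                    seed=config.seed + 17,
                )
                test_ids = result.cso_predictions.index[
                    result.cso_predictions["split"] == "test"
                ].tolist()
                if test_ids:
                    t_labels = sheet.set_index("sample_id").loc[test_ids, "label"]
                    proba = _cso.predict_proba(
                        model, pre.transform(matrix.subset_samples(test_ids))
                    )
                    row["test_top1"] = _cso.top_k_accuracy(proba, t_labels, 1)["accuracy"]
                    row["test_top2"] = _cso.top_k_accuracy(proba, t_labels, 2)["accuracy"]
            cso_rows.append(row)
        sweep["cso"] = pd.DataFrame(cso_rows)
    return sweep
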