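"""Diagnostic methylation score: healthy baseline + Fisher combination.

Per marker *i* the logit-transformed methylated fragment ratio
``x_i = logit((mfc + 0.5) / (n_informative + 1))`` of a test sample is
standardized against the training-control baseline,

    Z_i = (x_i - mu_i) / sigma_i,

converted to a one-sided upper-tail normal p-value (the panel targets
hypermethylation, so only positive deviations count as signal), and the
per-marker p-values are combined with a coverage-weighted Fisher method:

    score = -2 * sum_i w_i ln p_i / sum_i w_i,

with ``w_i`` the sample's fragment coverage of marker *i*.  Under the
null every ``-2 ln p_i`` is chi-square with 2 df, so healthy samples
score about 2 regardless of how many markers the panel uses; tumor
signal pushes individual p-values down and the score up.  A sample is
called cancer-positive when its score exceeds the empirical
98th-quantile cutoff of the training controls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, InvalidStateError
from .matrix import MarkerMatrix

__all__ = [
    "BaselineModel",
    "ThresholdModel",
    "logit_transform",
    "fit_baseline",
    "marker_z",
    "z_to_p",
    "methylation_score",
    "score_samples",
    "calibrate_threshold",
    "roc_auc",
    "wilson_interval",
    "sensitivity_report",
]

SIGMA_FLOOR = 1e-6
P_FLOOR = 1e-300


def logit_transform(mfc, n_informative):
    """Continuity-corrected logit of the MFR: logit((m + 0.5)/(n + 1)).

    Finite for every ``0 <= mfc <= n_informative`` with at least one
    informative fragment; cells with ``n_informative == 0`` come back NaN
    (no evidence, excluded downstream).
    """
    mfc = np.asarray(mfc, dtype=float)
    n = np.asarray(n_informative, dtype=float)
    if (mfc < 0).any() or (n < 0).any():
        raise InvalidInputError("negative fragment counts")
    if (mfc > n).any():
        raise InvalidInputError("mfc exceeds n_informative")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (mfc + 0.5) / (n + 1.0)
        x = np.log(p / (1.0 - p))
    return np.where(n > 0, x, np.nan)


@dataclass
class BaselineModel:
    """Per-marker healthy-control distribution of logit-MFR."""

    markers: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    usable: np.ndarray  # markers with >=2 non-missing control values
    sigma_floor: float = SIGMA_FLOOR

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "mu": [None if not np.isfinite(v) else float(v) for v in self.mu],
            "sigma": [None if not np.isfinite(v) else float(v) for v in self.sigma],
            "usable": [bool(u) for u in self.usable],
            "sigma_floor": self.sigma_floor,
            "logit_correction": {"numerator": 0.5, "denominator": 1.0},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineModel":
        to_arr = lambda xs: np.array([np.nan if v is None else v for v in xs], float)
        return cls(
            markers=list(d["markers"]),
            mu=to_arr(d["mu"]),
            sigma=to_arr(d["sigma"]),
            usable=np.array(d["usable"], dtype=bool),
            sigma_floor=float(d.get("sigma_floor", SIGMA_FLOOR)),
        )


def fit_baseline(
    matrix: MarkerMatrix,
    control_ids: Sequence[str],
    markers: Sequence[str] | None = None,
    sigma_floor: float = SIGMA_FLOOR,
) -> BaselineModel:
    """Fit per-marker (mu, sigma) of logit-MFR over training healthy controls.

    Sigma uses the n-1 denominator and is floored at ``sigma_floor``;
    markers with fewer than two non-missing control values are flagged
    unusable and never contribute to scores.
    """
    if len(control_ids) == 0:
        raise InvalidInputError("no healthy training controls")
    sub = matrix.subset_samples(control_ids)
    if markers is not None:
        sub = sub.subset_markers(markers)
    x = logit_transform(sub.mfc.to_numpy(), sub.n_informative.to_numpy())
    n_obs = np.isfinite(x).sum(axis=0)
    usable = n_obs >= 2
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=0)
        sigma = np.nanstd(np.where(np.isfinite(x), x, np.nan), axis=0, ddof=1)
    sigma = np.maximum(sigma, sigma_floor)
    mu[~usable] = np.nan
    sigma[~usable] = np.nan
    return BaselineModel(
        markers=list(sub.markers), mu=mu, sigma=sigma, usable=usable,
        sigma_floor=sigma_floor,
    )


def marker_z(x, mu, sigma):
    """Z_i = (x_i - mu_i) / sigma_i."""
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise InvalidStateError("baseline sigma must be positive")
    return (np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)) / sigma


def z_to_p(z):
    """One-sided upper-tail standard-normal p-value, clipped away from 0."""
    return np.clip(stats.norm.sf(np.asarray(z, dtype=float)), P_FLOOR, 1.0)


def methylation_score(p_values, weights):
    """Coverage-weighted Fisher combination: -2 sum(w ln p) / sum(w).

    Missing p-values (NaN) and their weights are excluded from both sums.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise InvalidInputError("negative weights")
    keep = np.isfinite(p) & (w > 0)
    if not keep.any() or w[keep].sum() == 0:
        raise InvalidInputError("no marker with positive weight and a p-value")
    p, w = p[keep], w[keep]
    return float(-2.0 * np.sum(w * np.log(p)) / np.sum(w))


def score_samples(
    matrix: MarkerMatrix, baseline: BaselineModel, sample_ids: Sequence[str] | None = None
) -> pd.Series:
    """Methylation score per sample over the baseline's usable markers."""
    sub = matrix if sample_ids is None else matrix.subset_samples(sample_ids)
    sub = sub.subset_markers(baseline.markers)
    x = logit_transform(sub.mfc.to_numpy(), sub.n_informative.to_numpy())
    usable = baseline.usable
    z = marker_z(
        x[:, usable], baseline.mu[usable], baseline.sigma[usable]
    )
    p = z_to_p(z)
    p[~np.isfinite(x[:, usable])] = np.nan
    w = sub.coverage.to_numpy()[:, usable].astype(float)
    scores = [methylation_score(p[i], w[i]) for i in range(p.shape[0])]
    return pd.Series(scores, index=sub.samples, name="methylation_score")


@dataclass
class ThresholdModel:
    """Empirical-quantile score cutoff; positive iff score > cutoff."""

    cutoff: float
    specificity: float = 0.98
    convention: str = "empirical-lower-quantile"

    def call(self, scores) -> np.ndarray:
        return np.asarray(scores, dtype=float) > self.cutoff


def calibrate_threshold(
    control_scores, specificity: float = 0.98, min_controls: int = 10
) -> ThresholdModel:
    """Set the cutoff at the empirical ``specificity``-quantile of controls.

    The cutoff is the smallest control score s with
    ``mean(controls <= s) >= specificity``, i.e. order statistic
    ``ceil(specificity * n)``; training specificity is then at least the
    target by construction.
    """
    scores = np.sort(np.asarray(control_scores, dtype=float))
    if scores.size < min_controls:
        raise InvalidInputError(f"need >= {min_controls} control scores")
    if not 0 < specificity <= 1:
        raise InvalidInputError("specificity must be in (0, 1]")
    k = int(math.ceil(specificity * scores.size))
    cutoff = float(scores[k - 1])
    return ThresholdModel(cutoff=cutoff, specificity=specificity)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


_STAGE_ORDER = {"": 0, "healthy": 0, "I": 1, "II": 2, "III": 3, "IV": 4}


def sensitivity_report(
    scores: pd.Series,
    sheet: pd.DataFrame,
    threshold: ThresholdModel,
) -> dict:
    """Per-class / per-stage sensitivity, specificity and stage correlation.

    Empty strata are reported as missing rather than raising.  The
    Spearman statistic correlates the score with the ordinal stage
    (healthy < I < II < III < IV), one-sided for positive association.
    """
    sheet = sheet.set_index("sample_id").loc[scores.index]
    calls = threshold.call(scores.to_numpy())
    is_cancer = (sheet["label"] != "healthy").to_numpy()

    def stratum(mask: np.ndarray) -> dict:
        n = int(mask.sum())
        if n == 0:
            return {"n": 0, "value": None, "ci": None}
        k = int(calls[mask].sum())
        lo, hi = wilson_interval(k, n)
        return {"n": n, "value": k / n, "ci": [lo, hi]}

    report: dict = {
        "threshold": threshold.cutoff,
        "specificity_target": threshold.specificity,
        "specificity": {},
        "sensitivity": {"overall": stratum(is_cancer)},
        "by_class": {},
        "by_stage": {},
    }
    ctrl = ~is_cancer
    n_ctrl = int(ctrl.sum())
    if n_ctrl:
        k = int((~calls[ctrl]).sum())
        lo, hi = wilson_interval(k, n_ctrl)
        report["specificity"] = {"n": n_ctrl, "value": k / n_ctrl, "ci": [lo, hi]}
    for label in sorted(sheet.loc[is_cancer, "label"].unique()):
        report["by_class"][label] = stratum((sheet["label"] == label).to_numpy())
    stages = sheet.get("stage", pd.Series("", index=sheet.index)).fillna("")
    for stage in ("I", "II", "III", "IV"):
        report["by_stage"][stage] = stratum(
            (is_cancer & (stages == stage)).to_numpy()
        )
    early = is_cancer & stages.isin(["I", "II"]).to_numpy()
    report["sensitivity"]["early_stage"] = stratum(early)
    ordinal = stages.map(_STAGE_ORDER).fillna(0).to_numpy()
    if len(np.unique(ordinal)) > 1:
        rho, pval = stats.spearmanr(scores.to_numpy(), ordinal, alternative="greater")
        report["spearman_score_vs_stage"] = {"rho": float(rho), "p_one_sided": float(pval)}
    else:
        report["spearman_score_vs_stage"] = None
    return report


# ---------------------------------------------------------------------------
# model (de)serialization

def save_score_model(
    baseline: BaselineModel, threshold: ThresholdModel | None, path: str | Path
) -> None:
    blob = {"baseline": baseline.to_dict()}
    if threshold is not None:
        blob["threshold"] = {
            "cutoff": threshold.cutoff,
            "specificity": threshold.specificity,
            "convention": threshold.convention,
        }
    Path(path).write_text(json.dumps(blob, indent=1))


def load_score_model(path: str | Path) -> tuple[BaselineModel, ThresholdModel | None]:
    blob = json.loads(Path(path).read_text())
    baseline = BaselineModel.from_dict(blob["baseline"])
    threshold = None
    if "threshold" in blob:
        t = blob["threshold"]
        threshold = ThresholdModel(
            cutoff=float(t["cutoff"]),
            specificity=float(t["specificity"]),
            convention=str(t.get("convention", "empirical-lower-quantile")),
        )
    return baseline, threshold
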