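"""Diagnostic methylation score: transforms, Fisher combination, metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from totem.errors import InvalidInputError, InvalidStateError
from totem.score import (
    ThresholdModel,
    calibrate_threshold,
    fit_baseline,
    load_score_model,
    logit_transform,
    marker_z,
    methylation_score,
    roc_auc,
    save_score_model,
    score_samples,
    sensitivity_report,
    wilson_interval,
    z_to_p,
)

from conftest import make_marker_matrix


class TestLogitTransform:
    def test_symmetric_midpoint_maps_to_zero(self):
        assert logit_transform(5, 10) == pytest.approx(0.0)

    def test_zero_count_closed_form(self):
        # p = 0.5/10 = 0.05 -> log(0.05/0.95)
        assert logit_transform(0, 9) == pytest.approx(math.log(0.05 / 0.95))

    def test_boundary_counts_stay_finite(self):
        assert np.isfinite(logit_transform(0, 1))
        assert np.isfinite(logit_transform(50, 50))

    def test_no_informative_fragments_is_missing(self):
        assert np.isnan(logit_transform(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            logit_transform(-1, 5)
        with pytest.raises(InvalidInputError):
            logit_transform(6, 5)


class TestBaseline:
    def test_two_point_baseline(self):
        # logit values (-1, 1) over two controls: mu=0, sigma=sqrt(2)
        x = np.array([-1.0, 1.0])
        assert x.mean() == pytest.approx(0.0)
        assert x.std(ddof=1) == pytest.approx(math.sqrt(2))

    def test_degenerate_variance_floored(self):
        m = make_marker_matrix([[2], [2], [2]], [[10], [10], [10]])
        model = fit_baseline(m, ["s0", "s1", "s2"])
        assert model.sigma[0] == pytest.approx(model.sigma_floor)

    def test_all_missing_marker_flagged_unusable(self):
        m = make_marker_matrix([[0, 1], [0, 2]], [[0, 8], [0, 9]])
        model = fit_baseline(m, ["s0", "s1"])
        assert not model.usable[0] and model.usable[1]

    def test_no_controls_rejected(self):
        m = make_marker_matrix([[1]], [[4]])
        with pytest.raises(InvalidInputError):
            fit_baseline(m, [])


def test_marker_z_examples():
    assert marker_z(1.0, 1.0, 0.5) == pytest.approx(0.0)
    assert marker_z(1.5, 1.0, 0.5) == pytest.approx(1.0)
    assert marker_z(2.5, 1.0, 0.5) == pytest.approx(3.0)
    with pytest.raises(InvalidStateError):
        marker_z(1.0, 0.0, 0.0)


def test_z_to_p_tail_behavior():
    assert z_to_p(0.0) == pytest.approx(0.5)
    assert z_to_p(1.959964) == pytest.approx(0.025, rel=1e-4)
    assert z_to_p(1e9) == pytest.approx(1e-300)  # clip floor
    assert z_to_p(-1e9) == pytest.approx(1.0)


class TestMethylationScore:
    def test_all_p_one_gives_zero(self):
        assert methylation_score([1.0, 1.0, 1.0], [3.0, 1.0, 2.0]) == pytest.approx(0.0)

    def test_single_marker_closed_form(self):
        assert methylation_score([0.5], [1.0]) == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_weight_scale_invariance(self, rng):
        p = rng.uniform(1e-6, 1, 10)
        w = rng.uniform(0.5, 50, 10)
        s1 = methylation_score(p, w)
        s2 = methylation_score(p, 7.3 * w)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_missing_markers_excluded(self):
        full = methylation_score([0.5, np.nan], [1.0, 100.0])
        assert full == pytest.approx(methylation_score([0.5], [1.0]))

    def test_zero_total_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            methylation_score([0.5], [0.0])

    def test_monotone_decreasing_in_each_p(self, rng):
        p = rng.uniform(0.05, 0.95, 6)
        w = rng.uniform(1, 5, 6)
        base = methylation_score(p, w)
        for i in range(6):
            q = p.copy()
            q[i] *= 0.5  # smaller p -> stronger evidence
            assert methylation_score(q, w) > base

    def test_null_expectation_is_two(self, rng):
        # x ~ N(mu, sigma) at baseline: -2 ln p ~ chi^2_2, so E[score] -> 2
        n, k = 4000, 20
        z = rng.normal(size=(n, k))
        p = stats.norm.sf(z)
        scores = (-2 * np.log(p)).mean(axis=1)
        assert scores.mean() == pytest.approx(2.0, abs=3 * scores.std() / math.sqrt(n))


class TestThreshold:
    def test_98th_order_statistic(self, rng):
        scores = rng.normal(size=100)
        model = calibrate_threshold(scores, 0.98)
        assert model.cutoff == pytest.approx(np.sort(scores)[97])
        assert model.call(scores).sum() == 2

    def test_full_specificity_uses_max(self, rng):
        scores = rng.normal(size=50)
        model = calibrate_threshold(scores, 1.0)
        assert model.cutoff == pytest.approx(scores.max())
        assert model.call(scores).sum() == 0

    def test_tied_scores_give_zero_positives(self):
        model = calibrate_threshold(np.full(20, 3.3), 0.98)
        assert model.cutoff == pytest.approx(3.3)
        assert model.call(np.full(20, 3.3)).sum() == 0

    def test_too_few_controls_rejected(self):
        with pytest.raises(InvalidInputError):
            calibrate_threshold(np.arange(5), 0.98)


class TestRocAuc:
    def test_separated_and_tied(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)
        assert roc_auc([1, 1, 1, 1], [0, 0, 1, 1]) == pytest.approx(0.5)
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 6, n).astype(float)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_auc([1, 2], [1, 1])


class TestWilson:
    def test_closed_form_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(0, 10), (10, 10), (8, 10), (42, 137)]:
            lo, hi = wilson_interval(k, n)
            slo, shi = proportion_confint(k, n, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-12)
            assert hi == pytest.approx(shi, abs=1e-12)

    def test_degenerate_counts(self):
        lo, hi = wilson_interval(0, 12)
        assert lo == pytest.approx(0.0, abs=1e-12) and hi > 0
        lo, hi = wilson_interval(12, 12)
        assert hi == pytest.approx(1.0, abs=1e-12) and lo < 1


def test_sensitivity_report_strata_and_spearman(rng):
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(40)],
        "label": ["healthy"] * 20 + ["LIHC"] * 10 + ["STAD"] * 10,
        "stage": [""] * 20 + ["I"] * 5 + ["IV"] * 5 + ["II"] * 10,
        "split": ["train"] * 40,
    })
    scores = pd.Series(
        np.r_[rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20)],
        index=sheet["sample_id"],
    )
    report = sensitivity_report(scores, sheet, ThresholdModel(cutoff=2.0))
    assert report["sensitivity"]["overall"]["value"] == pytest.approx(1.0)
    assert report["specificity"]["value"] == pytest.approx(1.0)
    assert report["by_stage"]["III"]["n"] == 0 and report["by_stage"]["III"]["value"] is None
    assert report["by_class"]["LIHC"]["n"] == 10
    assert report["spearman_score_vs_stage"]["rho"] > 0


def test_score_model_round_trip(tmp_path, rng):
    mfc = rng.integers(0, 5, (12, 6))
    n = mfc + rng.integers(5, 30, (12, 6))
    m = make_marker_matrix(mfc, n, coverage=n + 2)
    baseline = fit_baseline(m, [f"s{i}" for i in range(8)])
    scores = score_samples(m, baseline)
    threshold = calibrate_threshold(scores.to_numpy(), 0.9, min_controls=5)
    path = tmp_path / "model.json"
    save_score_model(baseline, threshold, path)
    b2, t2 = load_score_model(path)
    scores2 = score_samples(m, b2)
    pd.testing.assert_series_equal(scores, scores2)
    assert t2.cutoff == pytest.approx(threshold.cutoff)


def test_score_monotone_in_marker_signal():
    # raising one marker's mfc (holding others fixed) never lowers the score
    base_mfc = np.array([[1, 1, 1]])
    n = np.array([[20, 20, 20]])
    controls_mfc = np.array([[1, 1, 1], [2, 1, 1], [1, 2, 1], [1, 1, 2]])
    controls_n = np.full((4, 3), 20)
    m = make_marker_matrix(
        np.vstack([controls_mfc, base_mfc]), np.vstack([controls_n, n])
    )
    baseline = fit_baseline(m, ["s0", "s1", "s2", "s3"])
    prev = score_samples(m, baseline, ["s4"]).iloc[0]
    for bump in range(2, 20, 4):
        m2 = make_marker_matrix(
            np.vstack([controls_mfc, [[bump, 1, 1]]]), np.vstack([controls_n, n])
        )
        cur = score_samples(m2, baseline, ["s4"]).iloc[0]
        assert cur >= prev - 1e-12
        prev = cur
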