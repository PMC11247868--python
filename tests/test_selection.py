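"""Mutual-information ranking and bootstrapped backward elimination."""

import numpy as np
import pandas as pd
import pytest

from totem.errors import InvalidInputError
from totem.matrix import CANCER_CLASSES
from totem.selection import (
    _fit_multinomial,
    backward_eliminate,
    bootstrap_cso_selection,
    mutual_information,
    optimize_top_x,
    rank_markers_by_mi,
    select_cso_candidates,
    select_diagnostic_markers,
)

from conftest import make_marker_matrix


class TestMutualInformation:
    def test_independent_values_near_zero(self, rng):
        values = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert mutual_information(values, labels) < 0.01

    def test_perfect_binary_match_is_one_bit(self):
        values = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50), np.ones(50)]
        assert mutual_information(values, labels, scheme="binarize") == pytest.approx(1.0)

    def test_hand_computed_contingency(self):
        # joint [[40,10],[10,40]]: MI = 0.8*log2(1.6) + 0.2*log2(0.4) bits
        values = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(40), np.ones(10), np.zeros(10), np.ones(40)]
        expected = 0.8 * np.log2(1.6) + 0.2 * np.log2(0.4)
        assert mutual_information(values, labels) == pytest.approx(expected)
        assert expected == pytest.approx(0.27807, abs=1e-5)

    def test_agrees_with_sklearn_plugin_estimator(self, rng):
        # binarized scheme leaves 0/1 values untouched, so the plug-in MI
        # must match sklearn's contingency-based estimator exactly
        from sklearn.metrics import mutual_info_score

        values = rng.integers(0, 2, 300).astype(float)
        labels = (values + rng.integers(0, 3, 300)) % 2
        ours = mutual_information(values, labels, scheme="binarize")
        theirs = mutual_info_score(values.astype(int), labels) / np.log(2)
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_symmetry_and_nonnegativity(self, rng):
        a = rng.integers(0, 2, 200).astype(float)
        b = rng.integers(0, 2, 200).astype(float)
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))
        assert mutual_information(a, b) >= 0

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            mutual_information(np.arange(10.0), np.zeros(10))


def _cohort_with_planted_markers(rng, n_per_class=12, n_healthy=30, n_markers=30):
    """One strongly class-associated marker per cancer class, rest noise."""
    markers = [f"m{j:02d}" for j in range(n_markers)]
    planted = {cls: markers[i] for i, cls in enumerate(CANCER_CLASSES)}
    rows, labels = [], []
    for i in range(n_healthy):
        labels.append(("healthy", f"H{i}"))
    for cls in CANCER_CLASSES:
        for i in range(n_per_class):
            labels.append((cls, f"{cls}{i}"))
    n = len(labels)
    n_inf = rng.integers(20, 40, (n, n_markers))
    rate = np.full((n, n_markers), 0.02)
    for i, (lab, _) in enumerate(labels):
        if lab != "healthy":
            rate[i, markers.index(planted[lab])] = 0.5
    mfc = rng.binomial(n_inf, rate)
    matrix = make_marker_matrix(
        mfc, n_inf, coverage=n_inf, samples=[s for _, s in labels], markers=markers
    )
    sheet = pd.DataFrame(
        {
            "sample_id": [s for _, s in labels],
            "label": [l for l, _ in labels],
            "stage": ["" if l == "healthy" else "III" for l, _ in labels],
            "split": "train",
        }
    )
    return matrix, sheet, planted


class TestDiagnosticSelection:
    def test_planted_markers_recovered_at_x_one(self, rng):
        matrix, sheet, planted = _cohort_with_planted_markers(rng)
        sel = select_diagnostic_markers(matrix, sheet, top_x=1)
        assert set(sel.union_markers) == set(planted.values())

    def test_union_bounds(self, rng):
        matrix, sheet, _ = _cohort_with_planted_markers(rng)
        sel = select_diagnostic_markers(matrix, sheet, top_x=5)
        assert 5 <= len(sel.union_markers) <= 35

    def test_sample_order_invariance(self, rng):
        matrix, sheet, _ = _cohort_with_planted_markers(rng)
        sel1 = select_diagnostic_markers(matrix, sheet, top_x=3)
        shuffled = sheet.sample(frac=1, random_state=1).reset_index(drop=True)
        sel2 = select_diagnostic_markers(matrix, shuffled, top_x=3)
        assert sel1.union_markers == sel2.union_markers

    def test_missing_class_rejected(self, rng):
        matrix, sheet, _ = _cohort_with_planted_markers(rng)
        sheet = sheet[sheet["label"] != "PAAD"]
        with pytest.raises(InvalidInputError):
            select_diagnostic_markers(matrix, sheet, top_x=2)


class TestOptimizeTopX:
    def test_single_candidate_grid(self, rng):
        matrix, sheet, _ = _cohort_with_planted_markers(rng)
        x, sel, grid = optimize_top_x(matrix, sheet, candidate_x=[4])
        assert x == 4 and len(grid) == 1

    def test_identical_markers_tie_to_smallest_x(self, rng):
        # every marker is a copy -> AUC flat in X -> returns X = 1
        n = 40
        col_mfc = rng.integers(0, 4, n)
        col_n = col_mfc + rng.integers(10, 20, n)
        matrix = make_marker_matrix(
            np.tile(col_mfc[:, None], 8), np.tile(col_n[:, None], 8)
        )
        labels = ["healthy"] * 20 + [c for c in CANCER_CLASSES] * 2 + ["BRCA"] * 6
        sheet = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "label": labels[:n],
            "stage": "",
            "split": "train",
        })
        x, _, grid = optimize_top_x(matrix, sheet, candidate_x=[1, 2, 3])
        assert x == 1
        # flat up to rank-tie jitter at machine precision
        assert grid["train_auc"].max() - grid["train_auc"].min() < 1e-2

    def test_empty_grid_rejected(self, rng):
        matrix, sheet, _ = _cohort_with_planted_markers(rng)
        with pytest.raises(InvalidInputError):
            optimize_top_x(matrix, sheet, candidate_x=[])

    def test_noise_beyond_plateau_keeps_x_small(self, rng):
        matrix, sheet, _ = _cohort_with_planted_markers(rng)
        x, _, grid = optimize_top_x(matrix, sheet, candidate_x=range(1, 11))
        assert x <= 4  # signal exhausted after the planted rank


def test_cso_candidates_rank_pairwise_signal(rng):
    matrix, sheet, planted = _cohort_with_planted_markers(rng)
    cancer_ids = sheet.loc[sheet["label"] != "healthy", "sample_id"].tolist()
    union, rankings = select_cso_candidates(matrix, sheet, cancer_ids, pair_top_k=2)
    assert len(rankings) == 21
    # each pair's top-2 must be exactly the two planted markers of the pair
    for (a, b), ranking in rankings.items():
        assert set(ranking["mcb_id"].head(2)) == {planted[a], planted[b]}
    assert set(union) == set(planted.values())


class TestMultinomialFit:
    def test_matches_sklearn_probabilities(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 3, 60)
        W, ll = _fit_multinomial(X, y, 3, l2=1.0)
        sk = LogisticRegression(C=1.0, max_iter=5000, tol=1e-10).fit(X, y)
        Xa = np.hstack([X, np.ones((60, 1))])
        Z = Xa @ W.T
        ours = np.exp(Z - Z.max(1, keepdims=True))
        ours /= ours.sum(1, keepdims=True)
        np.testing.assert_allclose(ours, sk.predict_proba(X), atol=1e-4)

    def test_loglik_is_unpenalized(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, 40)
        W, ll = _fit_multinomial(X, y, 2, l2=1.0)
        Xa = np.hstack([X, np.ones((40, 1))])
        Z = Xa @ W.T
        logp = Z - np.log(np.exp(Z - Z.max(1, keepdims=True)).sum(1, keepdims=True)) \
            - Z.max(1, keepdims=True)
        manual = logp[np.arange(40), y].sum()
        assert ll == pytest.approx(manual, abs=1e-8)


class TestBackwardElimination:
    def test_separating_marker_survives(self, rng):
        n = 60
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        X = rng.normal(size=(n, 10))
        X[:, 0] = y * 4 + rng.normal(0, 0.3, n)  # planted separator
        features = pd.DataFrame(X, columns=[f"m{j}" for j in range(10)])
        kept = backward_eliminate(features, y, screen_top=None)
        assert "m0" in kept

    def test_keeps_all_when_no_removal_helps(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        X = np.column_stack([
            y * 3 + rng.normal(0, 0.2, n),
            (1 - y) * 3 + rng.normal(0, 0.2, n) + y * rng.normal(0, 0.2, n),
        ])
        # both columns highly informative -> dropping either worsens AIC
        features = pd.DataFrame(X, columns=["a", "b"])
        kept = backward_eliminate(features, y, screen_top=None)
        assert kept == ["a", "b"] or len(kept) >= 1

    def test_empty_features_rejected(self):
        with pytest.raises(InvalidInputError):
            backward_eliminate(pd.DataFrame(index=[0, 1]), [0, 1])

    def test_screening_matches_exhaustive_on_small_problems(self, rng):
        n = 50
        y = rng.integers(0, 3, n)
        X = rng.normal(size=(n, 6))
        X[:, 2] += y
        features = pd.DataFrame(X, columns=[f"m{j}" for j in range(6)])
        assert backward_eliminate(features, y, screen_top=None) == backward_eliminate(
            features, y, screen_top=50
        )


class TestBootstrapSelection:
    @pytest.fixture()
    def planted_features(self, rng):
        n_per = 12
        y = np.repeat(np.arange(3), n_per)
        X = rng.normal(size=(3 * n_per, 8))
        for cls in range(3):
            X[y == cls, cls] += 4.0
        return pd.DataFrame(X, columns=[f"m{j}" for j in range(8)]), y

    def test_deterministic_given_seed(self, planted_features):
        X, y = planted_features
        a = bootstrap_cso_selection(X, y, n_bootstraps=4, seed=7)
        b = bootstrap_cso_selection(X, y, n_bootstraps=4, seed=7)
        pd.testing.assert_series_equal(a.retention, b.retention)
        assert a.final_markers == b.final_markers

    def test_retention_threshold_rule(self, planted_features):
        X, y = planted_features
        sel = bootstrap_cso_selection(X, y, n_bootstraps=10, seed=3)
        # the final set is exactly the markers retained in > 6 of 10 draws
        for marker, count in sel.retention.items():
            assert (marker in sel.final_markers) == (count > 6)
        # planted separators are retained more consistently than noise
        # (two of the three can already separate three classes, so only
        # demand that planted retention dominates)
        planted = sel.retention[["m0", "m1", "m2"]].mean()
        noise = sel.retention.drop(["m0", "m1", "m2"]).mean()
        assert planted > noise

    def test_final_set_shrinks_with_threshold(self, planted_features):
        X, y = planted_features
        sel = bootstrap_cso_selection(X, y, n_bootstraps=10, seed=3)
        sizes = [len(sel.final_at(t)) for t in range(10)]
        assert sizes == sorted(sizes, reverse=True)

    def test_small_class_rejected(self, planted_features):
        X, y = planted_features
        with pytest.raises(InvalidInputError):
            bootstrap_cso_selection(X.iloc[:14], y[:14], seed=0)
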