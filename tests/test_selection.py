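import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macnet.selection import (
    FeatureSelectionResult,
    LogisticGD,
    auc,
    deg_top,
    intersect_signature,
    mic,
    mic_top,
    mrmr_select,
    pca_scores,
    permutation_importance,
    plsda_scores,
    stratified_cv_evaluate,
)
from oracles import auc_pair_count, mic_exhaustive


class TestMRMR:
    def test_first_pick_maximizes_label_mi(self, rng):
        labels = np.array([0] * 20 + [1] * 20)
        informative = labels + rng.normal(scale=0.1, size=40)
        noise = rng.normal(size=(4, 40))
        x = pd.DataFrame(
            np.vstack([noise[:2], informative, noise[2:]]),
            index=["n1", "n2", "sig", "n3", "n4"],
        )
        assert mrmr_select(x, labels, 1) == ["sig"]

    def test_redundant_copy_deferred(self, rng):
        labels = np.array([0] * 20 + [1] * 20)
        f1 = labels + rng.normal(scale=0.05, size=40)
        f2 = f1.copy()  # exact duplicate of the top pick
        f3 = labels + rng.normal(scale=0.8, size=40)  # weaker but independent noise
        x = pd.DataFrame([f1, f2, f3], index=["f1", "f2", "f3"])
        order = mrmr_select(x, labels, 3)
        assert order[0] == "f1"  # tie with f2 broken by id
        assert order[1] == "f3"
        assert order[2] == "f2"

    def test_single_class_labels_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 30)), index=list("abc"))
        with pytest.raises(ValueError):
            mrmr_select(x, np.zeros(30), 2)


class TestMIC:
    def test_noiseless_linear_relationship_is_one(self):
        x = np.linspace(0, 1, 100)
        assert mic(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constant_variable_is_zero(self, rng):
        assert mic(np.ones(50), rng.normal(size=50)) == 0.0

    def test_bounded_by_one(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 60))
            assert 0.0 <= mic(x, y) <= 1.0

    def test_independent_pairs_have_modest_mic(self, rng):
        vals = [mic(rng.normal(size=200), rng.normal(size=200)) for _ in range(20)]
        assert np.mean(vals) < 0.3

    def test_matches_exhaustive_small_grid_oracle(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=(2, 30))
            got = mic(x, y, max_cells_cap=12, max_axis=3)
            ref = mic_exhaustive(x, y, cap=12, max_axis=3)
            assert got == pytest.approx(ref, abs=1e-12)

    def test_matches_oracle_four_by_four(self, rng):
        x, y = rng.normal(size=(2, 25))
        got = mic(x, y, max_cells_cap=16, max_axis=4)
        ref = mic_exhaustive(x, y, cap=16, max_axis=4)
        assert got == pytest.approx(ref, abs=1e-12)


class TestMicTop:
    def test_label_copy_ranks_first(self, rng):
        labels = np.array([0] * 25 + [1] * 25)
        x = pd.DataFrame(
            np.vstack([rng.normal(size=(5, 50)), labels.astype(float)]),
            index=["a", "b", "c", "d", "e", "copy"],
        )
        assert mic_top(x, labels, 3)[0] == "copy"

    def test_k_equals_n_genes_returns_all(self, rng):
        labels = np.array([0] * 15 + [1] * 15)
        x = pd.DataFrame(rng.normal(size=(4, 30)), index=list("abcd"))
        assert sorted(mic_top(x, labels, 4)) == list("abcd")


class TestIntersection:
    def test_identical_lists(self):
        fs = FeatureSelectionResult(["a", "b"], ["a", "b"], ["a", "b"])
        table = intersect_signature(fs)
        assert set(table["gene"]) == {"a", "b"}

    def test_disjoint_lists_warn_empty(self):
        fs = FeatureSelectionResult(["a"], ["b"], ["c"])
        with pytest.warns(UserWarning):
            table = intersect_signature(fs)
        assert table.empty


class TestAUC:
    def test_perfect_and_inverted_and_ties(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.9, 0.1], [0, 1]) == 0.0
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_pair_concordance_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 25))
        scores = r.choice([0.1, 0.25, 0.5, 0.8], size=n)
        labels = np.concatenate([[0, 1], r.integers(0, 2, size=n - 2)])
        assert auc(scores, labels) == pytest.approx(auc_pair_count(scores, labels))


class TestCV:
    def test_separable_data_perfect_auc(self, rng):
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        x = np.column_stack([y * 6 + rng.normal(size=n), rng.normal(size=n)])
        report = stratified_cv_evaluate(x, y, n_folds=5, n_repeats=2)
        assert (report.table["auc"] == 1.0).all()

    def test_fold_class_counts_stratified(self, rng):
        y = np.array([0] * 23 + [1] * 44)
        x = rng.normal(size=(67, 3))
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test in skf.split(x, y):
            frac = y[test].mean()
            assert abs(frac * len(test) - y.mean() * len(test)) <= 1.0

    def test_small_class_rejected(self, rng):
        y = np.array([0] * 3 + [1] * 30)
        with pytest.raises(ValueError):
            stratified_cv_evaluate(rng.normal(size=(33, 2)), y)

    def test_null_labels_auc_near_half(self, rng):
        y = rng.permutation([0] * 30 + [1] * 30)
        x = rng.normal(size=(60, 5))
        report = stratified_cv_evaluate(x, y, n_repeats=10, base_seed=1)
        assert abs(report.summary()["auc_mean"] - 0.5) <= 0.06


class TestImportance:
    def test_sole_informative_feature_dominates(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        x = np.column_stack(
            [rng.normal(size=60), y * 3 + rng.normal(size=60), rng.normal(size=60)]
        )
        for seed in range(5):
            imp = permutation_importance(x, y, seed=seed, feature_names=["a", "sig", "b"])
            assert imp.idxmax() == "sig"

    def test_label_independent_feature_near_zero(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        x = np.column_stack([y * 3 + rng.normal(size=60), rng.normal(size=60)])
        imp = permutation_importance(x, y, seed=0, feature_names=["sig", "noise"])
        assert abs(imp["noise"]) <= 0.05


class TestOrdination:
    def test_pca_line_captures_all_variance(self, rng):
        t = rng.normal(size=30)
        x = np.column_stack([t, 2 * t, -t])
        scores = pca_scores(x)
        total = ((x - x.mean(0)) ** 2).sum()
        assert (scores[:, 0] ** 2).sum() == pytest.approx(total)
        assert abs(scores[:, 1]).max() < 1e-9

    def test_pca_scores_orthogonal_and_match_svd(self, rng):
        x = rng.normal(size=(25, 6))
        scores = pca_scores(x)
        assert abs(np.dot(scores[:, 0], scores[:, 1])) < 1e-9
        z = x - x.mean(0)
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        ref = u[:, :2] * s[:2]
        for k in range(2):
            assert abs(np.corrcoef(scores[:, k], ref[:, k])[0, 1]) == pytest.approx(1.0)

    def test_plsda_weight_collinear_with_informative_axis(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        yc = y - y.mean()
        noise = rng.normal(size=(40, 2))
        # make the uninformative axes exactly orthogonal to the response
        noise -= yc[:, None] * (yc @ noise)[None, :] / (yc @ yc)
        x = np.column_stack([y * 4.0, noise])
        _, weights = plsda_scores(x, y)
        w = weights[:, 0]
        cosine = abs(w[0]) / np.linalg.norm(w)
        assert cosine >= 0.99

    def test_plsda_null_separation_not_significant(self, rng):
        y = rng.permutation([0] * 20 + [1] * 20)
        x = rng.normal(size=(40, 6))
        scores, _ = plsda_scores(x, y)
        observed = abs(scores[y == 1, 0].mean() - scores[y == 0, 0].mean())
        null = []
        for _ in range(100):
            yp = rng.permutation(y)
            sp, _ = plsda_scores(x, yp)
            null.append(abs(sp[yp == 1, 0].mean() - sp[yp == 0, 0].mean()))
        p = np.mean([v >= observed for v in null])
        assert p > 0.05


class TestLogisticGD:
    def test_learns_separable_boundary(self, rng):
        y = np.array([0] * 40 + [1] * 40)
        x = np.column_stack([y * 4 + rng.normal(size=80), rng.normal(size=80)])
        clf = LogisticGD().fit(x, y)
        scores = clf.score_samples(x)
        assert auc(scores, y) == 1.0

    def test_deterministic(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        x = rng.normal(size=(40, 3))
        c1 = LogisticGD().fit(x, y).coef_
        c2 = LogisticGD().fit(x, y).coef_
        assert np.array_equal(c1, c2)
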