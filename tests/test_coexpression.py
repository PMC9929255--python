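import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macnet.coexpression import (
    UNASSIGNED,
    adjacency,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit_index,
    topological_overlap,
)
from oracles import tom_triple_loop


class TestScaleFreeFit:
    def test_power_law_degrees_fit_high(self):
        ks = np.arange(1, 51)
        mult = np.maximum(1, np.round(1000 * ks**-2.0)).astype(int)
        degrees = np.repeat(ks, mult).astype(float)
        assert scale_free_fit_index(degrees) >= 0.9

    def test_exact_line_gives_r2_one(self):
        # two distinct degree values -> two occupied bins -> perfect regression
        degrees = np.array([1.0] * 50 + [10.0] * 5)
        assert scale_free_fit_index(degrees) == pytest.approx(1.0, abs=1e-9)

    def test_all_equal_degrees_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit_index(np.full(20, 3.0))


class TestAdjacency:
    def test_definition_and_bounds(self, rng):
        f = rng.normal(size=40)
        x = pd.DataFrame([f, -0.5 * f + rng.normal(size=40) * 1e-9], index=["a", "b"])
        a = adjacency(x, 2)
        r = np.corrcoef(x.to_numpy())[0, 1]
        assert a[0, 1] == pytest.approx(r**2)
        assert a[0, 0] == 0

    def test_perfect_correlation_any_power(self, rng):
        f = rng.normal(size=25)
        x = pd.DataFrame([f, 2 * f + 1], index=["a", "b"])
        for power in (1, 3, 7):
            assert adjacency(x, power)[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 20)), index=[f"g{i}" for i in range(30)])
        a = adjacency(x, 6)
        vals = x.to_numpy()
        for i in range(30):
            for j in range(i + 1, 30):
                ref = abs(np.corrcoef(vals[i], vals[j])[0, 1]) ** 6
                assert a[i, j] == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_gene_is_named(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 15)), index=["a", "flat", "c"])
        x.loc["flat"] = 2.0
        with pytest.raises(ValueError, match="flat"):
            adjacency(x, 2)


class TestTOM:
    def test_isolated_pair(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert topological_overlap(a)[0, 1] == pytest.approx(1.0)

    def test_full_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(1.0)  # (1+1)/(2+1-1)

    def test_empty_adjacency(self):
        tom = topological_overlap(np.zeros((4, 4)))
        off = tom[~np.eye(4, dtype=bool)]
        assert np.all(off == 0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(3):
            raw = rng.uniform(0, 1, size=(40, 40))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 0)
            assert np.max(np.abs(topological_overlap(a) - tom_triple_loop(a))) < 1e-10


class TestEigengene:
    def test_identical_profiles(self, rng):
        f = rng.normal(size=30)
        x = pd.DataFrame([f, f, f], index=list("abc"), columns=[f"s{i}" for i in range(30)])
        eig = module_eigengene(x, ["a", "b", "c"])
        z = (f - f.mean()) / f.std(ddof=1)
        ref = z / np.linalg.norm(z)
        assert np.allclose(eig.to_numpy(), ref, atol=1e-9)

    def test_single_gene_module(self, rng):
        f = rng.normal(size=20)
        x = pd.DataFrame([f], index=["a"])
        eig = module_eigengene(x, ["a"])
        assert np.linalg.norm(eig) == pytest.approx(1.0)
        assert abs(np.corrcoef(eig, f)[0, 1]) == pytest.approx(1.0)

    def test_matches_svd_oracle(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 25)), index=[f"g{i}" for i in range(10)])
        eig = module_eigengene(x, list(x.index))
        z = stats.zscore(x.to_numpy(), axis=1, ddof=1)
        _, _, vt = np.linalg.svd(z)
        assert abs(np.corrcoef(eig, vt[0])[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_first_pc_beats_single_gene_surrogates(self, rng):
        for _ in range(10):
            f = rng.normal(size=40)
            x = pd.DataFrame(
                [lam * f + rng.normal(scale=0.7, size=40) for lam in rng.uniform(0.3, 1, 8)],
                index=[f"g{i}" for i in range(8)],
            )
            z = stats.zscore(x.to_numpy(), axis=1, ddof=1)
            eig = module_eigengene(x, list(x.index)).to_numpy()
            var_eig = np.sum((z @ eig) ** 2)
            for row in z:
                surrogate = row / np.linalg.norm(row)
                assert var_eig >= np.sum((z @ surrogate) ** 2) - 1e-9


class TestDetectModules:
    def test_two_noiseless_blocks_recovered_exactly(self, rng):
        f1, f2 = rng.normal(size=(2, 50))
        lam = rng.uniform(0.4, 1, size=80)
        rows = [lam[i] * (f1 if i < 40 else f2) for i in range(80)]
        x = pd.DataFrame(rows, index=[f"g{i}" for i in range(80)])
        ms = detect_modules(x, 6)
        labels = ms.assignment
        assert labels.nunique() == 2
        assert labels.iloc[:40].nunique() == 1 and labels.iloc[40:].nunique() == 1

    def test_pure_noise_goes_unassigned(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = pd.DataFrame(r.normal(size=(100, 60)), index=[f"g{i}" for i in range(100)])
            ms = detect_modules(x, 6)
            aris.append(adjusted_rand_score(["bg"] * 100, ms.assignment))
        assert np.mean(aris) >= 0.9

    def test_assignment_invariant_under_gene_permutation(self, small_cohort):
        x = small_cohort.expression
        ms1 = detect_modules(x, 8)
        perm = np.random.default_rng(3).permutation(len(x))
        ms2 = detect_modules(x.iloc[perm], 8)
        from sklearn.metrics import adjusted_rand_score

        common = list(x.index)
        assert adjusted_rand_score(ms1.assignment[common], ms2.assignment[common]) == pytest.approx(1.0)

    def test_too_few_genes_warns_all_unassigned(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 20)), index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning):
            ms = detect_modules(x, 6, min_size=30)
        assert (ms.assignment == UNASSIGNED).all()


class TestSoftThreshold:
    def test_report_is_internally_consistent(self, small_cohort):
        report = pick_soft_threshold(small_cohort.expression)
        assert report.chosen_power in set(report.table["power"])
        fits = report.table["fit_index"].dropna()
        assert ((fits >= 0) & (fits <= 1)).all()

    def test_noise_matrix_uses_argmax_fallback(self, rng):
        x = pd.DataFrame(rng.normal(size=(120, 30)), index=[f"g{i}" for i in range(120)])
        report = pick_soft_threshold(x, target_fit=0.999)
        best = report.table.loc[report.table["fit_index"].idxmax(), "power"]
        assert report.chosen_power == int(best)


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, small_cohort):
        ms = detect_modules(small_cohort.expression, 8)
        lab = ms.eigengenes.index[0]
        traits = pd.DataFrame({"t": ms.eigengenes.loc[lab]})
        res = module_trait_correlation(ms, traits)
        row = res[(res.module == lab) & (res.trait == "t")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p < 1e-30

    def test_student_asymptotic_formula(self):
        # r = 0.5 at n = 47 -> t = 3.873, p = 3.44e-4
        from macnet.coexpression import _pearson_p

        assert _pearson_p(0.5, 47) == pytest.approx(3.44e-4, rel=0.01)

    def test_constant_trait_is_error(self, small_cohort):
        ms = detect_modules(small_cohort.expression, 8)
        traits = pd.DataFrame({"flat": 1.0}, index=ms.eigengenes.columns)
        with pytest.raises(ValueError, match="flat"):
            module_trait_correlation(ms, traits)

    def test_planted_trait_coupling_recovered(self, default_cohort):
        ami = default_cohort.meta.index[default_cohort.meta.group == "AMI"]
        x = default_cohort.expression[list(ami)]
        report = pick_soft_threshold(x)
        ms = detect_modules(x, report.chosen_power)
        res = module_trait_correlation(ms, default_cohort.traits)
        sub = res[res.trait == "infarct_size"].sort_values("p")
        best = sub.iloc[0]
        truth_members = set(default_cohort.truth.module_members("P4"))
        detected = set(ms.members(best.module))
        jacc = len(truth_members & detected) / len(truth_members | detected)
        assert jacc > 0.5
        assert abs(best.r - 0.6) <= 0.15
        assert best.p_adj < 0.05
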