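import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bulkdecon.markers as mk


def _frame(rows, columns=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(rows.shape[0])],
        columns=columns or [f"T{j}" for j in range(rows.shape[1])],
    )


class TestSpecificityRaw:
    @pytest.mark.parametrize("k", range(2, 17))
    def test_closed_forms(self, k):
        X = _frame([[5.0] * k, [8.0] + [0.0] * (k - 1)])
        s = mk.specificity_raw(X)
        assert s.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert s.iloc[1] == pytest.approx(np.log2(k), rel=1e-12)

    def test_single_positive_entry_k4(self):
        assert mk.specificity_raw(_frame([[8, 0, 0, 0]])).iloc[0] == pytest.approx(2.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            mk.specificity_raw(_frame([[0, 0, 0]]))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e4), min_size=2, max_size=12).filter(
            lambda row: sum(row) > 0
        )
    )
    def test_nonnegative_and_bounded_by_log2_k(self, row):
        s = float(mk.specificity_raw(_frame([row])).iloc[0])
        assert s >= -1e-9
        assert s <= np.log2(len(row)) + 1e-9
        if len(set(row)) == 1:
            assert s == pytest.approx(0.0, abs=1e-12)


class TestGeneWeights:
    def test_divide_by_median_of_row_maxima(self):
        X = _frame([[2, 1], [4, 1], [8, 1]])
        assert mk.gene_weights(X).tolist() == [0.5, 1.0, 2.0]

    def test_identical_rows_all_one(self):
        X = _frame([[3, 1, 2]] * 5)
        assert (mk.gene_weights(X) == 1.0).all()

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            mk.gene_weights(_frame([[0, 0]]))


class TestSpecificityFinal:
    def test_zero_weight_kills_score(self):
        s = mk.specificity_final(pd.Series([3.0]), pd.Series([0.0]))
        assert s.iloc[0] == 0.0

    def test_direct_evaluation(self):
        s = mk.specificity_final(pd.Series([2.0]), pd.Series([10.0]), lam=0.1)
        assert s.iloc[0] == pytest.approx(np.tanh(1.0) * 2.0)

    def test_saturates_to_raw_score(self):
        s = mk.specificity_final(pd.Series([2.0]), pd.Series([1.0]), lam=50.0)
        assert s.iloc[0] == pytest.approx(2.0, rel=1e-9)

    def test_monotone_in_weight(self):
        weights = pd.Series(np.linspace(0, 20, 100))
        s = mk.specificity_final(pd.Series([1.5] * 100), weights)
        assert (np.diff(s.to_numpy()) >= 0).all()
        assert (s <= 1.5 + 1e-12).all()

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            mk.specificity_final(pd.Series([1.0]), pd.Series([1.0]), lam=0.0)


class TestBackground:
    def test_constant_matrix_gives_zero_scores(self):
        null = mk.background_scores(_frame([[5, 5], [5, 5]]), n_profiles=3, seed=0)
        assert (null == 0).all()

    def test_score_count_bookkeeping(self):
        X = _frame(np.random.default_rng(0).uniform(1, 10, (50, 3)))
        assert mk.background_scores(X, n_profiles=2, seed=0).size == 100

    def test_fixed_seed_reproducible(self, tiny_reference):
        a = mk.background_scores(tiny_reference, n_profiles=5, seed=7)
        b = mk.background_scores(tiny_reference, n_profiles=5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_fit_recovers_normal_parameters(self):
        scores = np.random.default_rng(0).normal(0.5, 0.1, 100_000)
        mu, sigma = mk.fit_background(scores)
        assert mu == pytest.approx(0.5, abs=0.01)
        assert sigma == pytest.approx(0.1, abs=0.005)

    def test_mode_more_outlier_robust_than_mean(self):
        rng = np.random.default_rng(1)
        clean = rng.normal(0.5, 0.1, 20_000)
        contaminated = np.concatenate([clean, np.full(200, 5.0)])
        mu, _ = mk.fit_background(contaminated)
        assert abs(mu - 0.5) < abs(contaminated.mean() - 0.5)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            mk.fit_background(np.zeros(100))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            mk.fit_background(np.arange(10.0))


class TestCandidateMarkers:
    def test_score_at_null_center_never_candidate(self):
        s = pd.Series([0.5], index=["g"])
        out = mk.candidate_markers(s, mu=0.5, sigma=0.1)
        assert out.loc["g", "p_value"] == pytest.approx(0.5)
        assert not out.loc["g", "candidate"]

    def test_five_sigma_outlier_is_sole_candidate(self):
        s = pd.Series(np.full(100, 0.2), index=[f"g{i}" for i in range(100)])
        s.iloc[7] = 0.2 + 5 * 0.02
        out = mk.candidate_markers(s, mu=0.2, sigma=0.02, alpha=0.01)
        assert out.loc["g7", "p_value"] == pytest.approx(2.8665e-7, rel=1e-3)
        assert out.loc["g7", "p_adjusted"] == pytest.approx(2.8665e-5, rel=1e-3)
        assert out["candidate"].sum() == 1 and out.loc["g7", "candidate"]

    def test_all_at_center_empty(self):
        s = pd.Series(np.full(10, 0.3))
        assert mk.candidate_markers(s, mu=0.3, sigma=0.05)["candidate"].sum() == 0


class TestPiValues:
    def test_max_over_uniform_rest(self):
        for k in (3, 5, 9):
            X = _frame([[100.0] + [1.0] * (k - 1)])
            assert mk.pi_values(X).iloc[0] == pytest.approx(np.log2(100), rel=1e-12)

    def test_uniform_row_is_zero(self):
        assert mk.pi_values(_frame([[4, 4, 4, 4]])).iloc[0] == pytest.approx(0.0)

    def test_strictly_exclusive_uses_pseudo_expression(self):
        X = _frame([[50, 0, 0], [50, 1, 1], [50, 25, 25]])
        pi = mk.pi_values(X, epsilon=1.0)
        assert pi.iloc[0] == pytest.approx(np.log2(50 * 2))
        assert np.isfinite(pi.iloc[0])
        assert pi.iloc[0] == pi.max()

    def test_needs_two_cell_types(self):
        with pytest.raises(ValueError):
            mk.pi_values(_frame([[1.0]]))


class TestSelectSeeds:
    def test_single_candidate_per_type(self, tiny_reference):
        pi = mk.pi_values(tiny_reference)
        seeds = mk.select_seeds(["gA", "gB", "gC"], pi, tiny_reference)
        assert seeds == {"A": "gA", "B": "gB", "C": "gC"}

    def test_highest_pi_wins(self):
        X = _frame([[100, 1, 1], [40, 1, 1], [1, 50, 1], [1, 1, 50]])
        pi = mk.pi_values(X)
        seeds = mk.select_seeds(X.index, pi, X)
        assert seeds["T0"] == "g0"

    def test_pi_tie_breaks_lexicographically(self):
        X = pd.DataFrame(
            [[50.0, 1.0], [50.0, 1.0], [1.0, 50.0]],
            index=["zz", "aa", "b"],
            columns=["T0", "T1"],
        )
        seeds = mk.select_seeds(X.index, mk.pi_values(X), X)
        assert seeds["T0"] == "aa"

    def test_missing_type_named_in_error(self, tiny_reference):
        pi = mk.pi_values(tiny_reference)
        with pytest.raises(ValueError, match="C"):
            mk.select_seeds(["gA", "gB"], pi, tiny_reference)


class TestMutualLinearity:
    def _samples(self):
        rng = np.random.default_rng(3)
        seed_row = rng.uniform(1, 10, 12)
        data = pd.DataFrame(
            {
                "seed": seed_row,
                "clone": seed_row * 2.0,
                "anti": seed_row.max() + 1 - seed_row,
                "flat": np.full(12, 3.0),
                "noise": rng.uniform(1, 10, 12),
            }
        ).T
        data.columns = [f"s{i}" for i in range(12)]
        return data

    def test_matches_pearson_formula(self):
        from scipy.stats import pearsonr

        expr = self._samples()
        pi = pd.Series(0.0, index=expr.index)
        rho = mk.mutual_linearity(expr, expr.index, {"T": "seed"}, pi)
        for gene in ["clone", "anti", "noise"]:
            r = pearsonr(expr.loc[gene], expr.loc["seed"]).statistic
            expected = r**2 * 0.5 * np.sign(r)
            assert rho.loc[gene, "T"] == pytest.approx(expected, rel=1e-9)

    def test_perfect_clone_with_large_pi_approaches_one(self):
        expr = self._samples()
        pi = pd.Series(50.0, index=expr.index)
        rho = mk.mutual_linearity(expr, ["clone"], {"T": "seed"}, pi)
        assert rho.loc["clone", "T"] == pytest.approx(1.0)

    def test_zero_variance_gene_gets_zero(self):
        expr = self._samples()
        pi = pd.Series(1.0, index=expr.index)
        rho = mk.mutual_linearity(expr, ["flat"], {"T": "seed"}, pi)
        assert rho.loc["flat", "T"] == 0.0

    def test_needs_three_samples(self):
        expr = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            mk.mutual_linearity(expr, ["a"], {"T": "b"}, pd.Series(0.0, index=expr.index))


def oracle_empirical_p(background, rho):
    """Independent rank-based oracle: fraction of background co-linearities
    at or above rho, with the +1/+1 small-sample correction."""
    n = len(background)
    count_ge = sum(1 for b in background if b >= rho)
    return max(0.0, (count_ge - 1) / (n + 1))


class TestEmpiricalPvalues:
    BG = pd.DataFrame({"T": [0.1, 0.2, 0.3, 0.4, 0.5]}, index=list("abcde"))

    def _p(self, rho):
        cand = pd.DataFrame({"T": [rho]}, index=["g"])
        return float(mk.empirical_pvalues(cand, self.BG).iloc[0, 0])

    def test_hand_evaluation(self):
        assert self._p(0.25) == pytest.approx(1 / 3)

    def test_below_whole_background_is_maximal(self):
        assert self._p(0.05) == pytest.approx(1 - 2 / 6)

    def test_above_whole_background_is_zero(self):
        assert self._p(0.9) == 0.0

    def test_empty_background_rejected(self):
        cand = pd.DataFrame({"T": [0.1]}, index=["g"])
        with pytest.raises(ValueError):
            mk.empirical_pvalues(cand, self.BG.iloc[:0])

    @pytest.mark.parametrize("n_background", range(1, 21))
    def test_exhaustive_oracle_equivalence(self, n_background):
        rng = np.random.default_rng(n_background)
        bg_values = np.round(rng.uniform(-1, 1, n_background), 2)
        grid = np.concatenate([np.linspace(-1.2, 1.2, 49), bg_values])
        bg = pd.DataFrame({"T": bg_values})
        cand = pd.DataFrame({"T": grid})
        got = mk.empirical_pvalues(cand, bg)["T"].to_numpy()
        expected = [oracle_empirical_p(bg_values, r) for r in grid]
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestAllocate:
    P = pd.DataFrame(
        [[0.01, 0.80], [0.01, 0.03], [0.90, 0.90]],
        index=["one", "both", "none"],
        columns=["T1", "T2"],
    )

    def test_allocation_rules(self):
        alloc = mk.allocate(self.P, threshold=0.05)
        assert alloc["T1"] == ["one", "both"]
        assert alloc["T2"] == ["both"]
        assert all("none" not in genes for genes in alloc.values())


class TestEndToEnd:
    def test_planted_markers_recovered(self, stage1, exclusive_markers):
        hits = sum(
            row.gene in stage1.allocations[row.cell_type]
            for row in exclusive_markers.itertuples()
        )
        assert hits / len(exclusive_markers) >= 0.95

    def test_seed_peaks_in_its_cell_type(self, stage1, reference_profile):
        for cell_type, gene in stage1.seeds.items():
            assert reference_profile.loc[gene].idxmax() == cell_type

    def test_stage1_bit_identical_across_runs(self, simulated, reference_profile, stage1):
        expr, _, _ = simulated
        import bulkdecon as bd

        again = bd.identify_markers(expr, reference_profile, seed=2)
        pd.testing.assert_frame_equal(stage1.specificity, again.specificity)
        pd.testing.assert_frame_equal(stage1.p_empirical, again.p_empirical)
        assert stage1.allocations == again.allocations

    def test_marker_table_schema(self, stage1):
        table = stage1.table()
        assert list(table.columns) == [
            "gene",
            "cell_type",
            "s_raw",
            "weight",
            "s_final",
            "p_adjusted",
            "pi",
            "rho",
            "p_empirical",
        ]
        assert (table["p_empirical"] <= 0.05).all()
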