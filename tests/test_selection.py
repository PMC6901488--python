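import numpy as np
import pytest

from rsca.data_model import MultiBlockData, ValidationError, concatenate, preprocess
from rsca.estimator import fit_rsca, lambda_max
from rsca.selection import (
    TuningGrid,
    align_components,
    bic_score,
    bic_select,
    bolasso,
    cv_one_se,
    index_of_sparseness,
    is_select,
    make_grid,
    mspe_cv,
    q_bound,
    rdcv,
    stability_selection,
    tucker_congruence,
)


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(7)
    return preprocess(
        MultiBlockData([rng.standard_normal((12, 6)), rng.standard_normal((12, 4))])
    )


@pytest.fixture(scope="module")
def grid(data):
    return make_grid(data, 3, 5)


class TestGrid:
    def test_two_points_are_endpoints(self, data):
        g = make_grid(data, 3, 2, floor_value=1e-7)
        assert g.lasso_values[0] == 1e-7
        assert g.lasso_values[-1] == pytest.approx(lambda_max(data, 3, "lasso"), rel=0.02)

    def test_equal_spacing(self, data, grid):
        for values in (grid.lasso_values, grid.group_values):
            np.testing.assert_allclose(np.diff(values), np.diff(values)[0], atol=1e-10)

    def test_largest_value_fully_shrinks(self, data, grid):
        m = fit_rsca(data, 3, float(grid.lasso_values[-1]), float(grid.group_values[-1]))
        assert m.n_nonzero == 0

    def test_too_few_points_rejected(self, data):
        with pytest.raises(ValidationError):
            make_grid(data, 3, 1)

    def test_non_increasing_values_rejected(self):
        with pytest.raises(ValidationError):
            TuningGrid(np.array([0.5, 0.2]), np.array([0.1, 0.2]))


class TestMspeCv:
    def test_deterministic_under_seed(self, data):
        a = mspe_cv(data, 3, 0.1, 0.05, seed=3)
        b = mspe_cv(data, 3, 0.1, 0.05, seed=3)
        assert a == b
        c = mspe_cv(data, 3, 0.1, 0.05, seed=4)
        assert a != c

    def test_zero_predictor_error_at_lambda_max(self, data):
        """At full shrinkage the model predicts 0 for every held-out cell."""
        lam = lambda_max(data, 3, "lasso")
        mspe, _ = mspe_cv(data, 3, lam, lam, n_folds=5, seed=0)
        X = concatenate(data)
        # total held-out error over all folds is then ||X||^2
        assert mspe * 5 == pytest.approx(np.sum(X * X), rel=1e-10)

    def test_low_rank_structure_is_exploited(self, rng):
        """Near-noiseless rank-R data yield far lower MSPE than the zero model."""
        T0, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        P0 = rng.standard_normal((12, 3))
        X = T0 @ P0.T
        nd = MultiBlockData([X[:, :8], X[:, 8:]])
        mspe, _ = mspe_cv(nd, 3, 1e-7, 1e-7, seed=3)
        zero_mspe = np.sum(X * X) / 5
        assert mspe < 0.5 * zero_mspe


class TestCvOneSe:
    def test_single_pair_grid_returned(self, data):
        g = TuningGrid(np.array([0.2]), np.array([0.1]))
        res = cv_one_se(data, 3, g, seed=0)
        assert (res.chosen_lambda_L, res.chosen_lambda_G) == (0.2, 0.1)

    def test_tie_goes_to_sparser_pair(self, data):
        # two values beyond lambda_max: every fit is all-zero, MSPEs tie
        lam = lambda_max(data, 3, "lasso")
        lag = lambda_max(data, 3, "group")
        g = TuningGrid(np.array([lam, 2 * lam]), np.array([lag, 2 * lag]))
        res = cv_one_se(data, 3, g, seed=0)
        assert res.chosen_lambda_L == 2 * lam
        assert res.chosen_lambda_G == 2 * lag

    def test_not_larger_mode_respects_bound(self, data, grid):
        res = cv_one_se(data, 3, grid, seed=1, mode="not_larger")
        surf = res.diagnostics["mspe_surface"]
        chosen = surf[
            (surf.lambda_L == res.chosen_lambda_L)
            & (surf.lambda_G == res.chosen_lambda_G)
        ].iloc[0]
        assert chosen.mspe <= res.diagnostics["bound"] + 1e-12


class TestRdcv:
    def test_single_pair_grid_degenerate(self, data):
        g = TuningGrid(np.array([0.2]), np.array([0.1]))
        res = rdcv(data, 3, g, n_repetitions=3, seed=0)
        assert (res.chosen_lambda_L, res.chosen_lambda_G) == (0.2, 0.1)
        assert res.diagnostics["frequency_lambda_L"].iloc[0] == 6  # reps x segments

    def test_reproducible_and_on_grid(self, data, grid):
        res1 = rdcv(data, 3, grid, n_repetitions=2, seed=5)
        res2 = rdcv(data, 3, grid, n_repetitions=2, seed=5)
        assert res1.chosen_lambda_L == res2.chosen_lambda_L
        assert res1.chosen_lambda_L in grid.lasso_values
        assert res1.chosen_lambda_G in grid.group_values

    def test_segment_too_small_rejected(self, data):
        with pytest.raises(ValidationError):
            rdcv(data, 3, TuningGrid(np.array([0.1]), np.array([0.1])), n_segments=7)


class TestBic:
    def test_hand_recomputation(self, data):
        baseline = fit_rsca(data, 3, 0.0, 0.0)
        model = fit_rsca(data, 3, 0.3, 0.1)
        X = concatenate(data)
        V = np.sum((X - baseline.T @ baseline.P_C.T) ** 2)
        Vt = np.sum((X - model.T @ model.P_C.T) ** 2)
        df = np.count_nonzero(model.P_C)
        expected = Vt / V + df * np.log(12) / 12
        got = bic_score(data, 3, 0.3, 0.1, baseline)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_variants_differ_by_factor_I(self, data, grid):
        baseline = fit_rsca(data, 3, 0.0, 0.0)
        for lam_l, lam_g in grid.pairs():
            croux = bic_score(data, 3, lam_l, lam_g, baseline, variant="croux")
            guo = bic_score(data, 3, lam_l, lam_g, baseline, variant="guo")
            assert guo == pytest.approx(data.I * croux, abs=1e-10)

    def test_near_unpenalized_bic(self, data):
        """A fully dense fit has Vt ~ V and df = all loadings."""
        baseline = fit_rsca(data, 3, 0.0, 0.0)
        got = bic_score(data, 3, 1e-12, 1e-12, baseline)
        assert got == pytest.approx(1 + 30 * np.log(12) / 12, rel=1e-3)

    def test_exact_low_rank_data_rejected(self, rng):
        T0, _ = np.linalg.qr(rng.standard_normal((10, 2)))
        X = T0 @ rng.standard_normal((6, 2)).T
        nd = MultiBlockData([X])
        baseline = fit_rsca(nd, 2, 0.0, 0.0)
        with pytest.raises(ValidationError, match="noise|reduce R"):
            bic_score(nd, 2, 0.1, 0.0, baseline)

    def test_select_minimizes_surface(self, data, grid):
        res = bic_select(data, 3, grid)
        surf = res.diagnostics["bic_surface"]
        assert surf.score.min() == surf[
            (surf.lambda_L == res.chosen_lambda_L)
            & (surf.lambda_G == res.chosen_lambda_G)
        ].score.iloc[0]


class TestIndexOfSparseness:
    def test_dense_solution_scores_zero(self, data):
        baseline = fit_rsca(data, 3, 0.0, 0.0)
        assert index_of_sparseness(data, 3, 1e-12, 1e-12, baseline) == 0.0

    def test_all_zero_solution_scores_zero(self, data):
        baseline = fit_rsca(data, 3, 0.0, 0.0)
        assert index_of_sparseness(data, 3, 100.0, 100.0, baseline) == 0.0

    def test_hand_recomputation(self, data):
        baseline = fit_rsca(data, 3, 0.0, 0.0)
        model = fit_rsca(data, 3, 0.3, 0.1)
        X = concatenate(data)
        V_o = np.sum(X * X)
        V_s = np.sum((baseline.T @ baseline.P_C.T) ** 2)
        V_a = np.sum((model.T @ model.P_C.T) ** 2)
        n_zero = np.sum(model.P_C == 0)
        expected = V_a * V_s / V_o**2 * n_zero / 30
        got = index_of_sparseness(data, 3, 0.3, 0.1, baseline)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_df_bookkeeping_on_surface(self, data, grid):
        res = is_select(data, 3, grid)
        surf = res.diagnostics["is_surface"]
        for _, row in surf.iterrows():
            model = fit_rsca(data, 3, row.lambda_L, row.lambda_G)
            assert row.df == 30 - np.sum(model.P_C == 0)


class TestTuckerAndAlignment:
    def test_self_and_negated_congruence(self, rng):
        T = rng.standard_normal((8, 3))
        assert tucker_congruence(T, T) == pytest.approx(1.0)
        assert tucker_congruence(T, -T) == pytest.approx(-1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert tucker_congruence(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_zero_input_rejected(self):
        with pytest.raises(ValidationError):
            tucker_congruence(np.zeros(3), np.ones(3))

    def test_recovers_planted_permutation_and_sign(self, rng):
        ref = rng.standard_normal((10, 3))
        est = ref[:, [2, 0, 1]].copy()
        est[:, 0] *= -1
        perm, signs, aligned = align_components(ref, est)
        np.testing.assert_allclose(aligned, ref, atol=1e-12)

    def test_identity_alignment(self, rng):
        ref = rng.standard_normal((10, 4))
        perm, signs, aligned = align_components(ref, ref)
        np.testing.assert_array_equal(perm, np.arange(4))
        np.testing.assert_array_equal(signs, np.ones(4))

    def test_alignment_is_idempotent(self, rng):
        ref = rng.standard_normal((12, 3))
        est = ref + 0.1 * rng.standard_normal((12, 3))
        est = est[:, [1, 2, 0]]
        est[:, 2] *= -1
        _, _, aligned = align_components(ref, est)
        perm2, signs2, _ = align_components(ref, aligned)
        np.testing.assert_array_equal(perm2, np.arange(3))
        np.testing.assert_array_equal(signs2, np.ones(3))

    def test_exhaustive_matches_assignment_path(self, rng):
        from scipy.optimize import linear_sum_assignment

        from rsca.selection import _congruence_matrix

        ref = rng.standard_normal((15, 3))
        est = ref[:, [1, 0, 2]] + 0.3 * rng.standard_normal((15, 3))
        perm, signs, _ = align_components(ref, est)
        C = np.abs(_congruence_matrix(ref, est))
        rows, cols = linear_sum_assignment(-C)
        np.testing.assert_array_equal(perm, cols[np.argsort(rows)])


class TestBolasso:
    def test_single_repetition_equals_single_cv_support(self, data, grid):
        res = bolasso(data, 3, grid, n_repetitions=1, seed=42)
        assert res.pattern.mask.sum() == res.diagnostics["bootstrap_supports"][0].sum()

    def test_pattern_is_intersection_of_stored_supports(self, planted):
        data, truth = planted
        grid = make_grid(data, 3, 4)
        res = bolasso(data, 3, grid, n_repetitions=5, seed=1)
        supports = res.diagnostics["bootstrap_supports"]
        np.testing.assert_array_equal(
            res.pattern.mask, np.logical_and.reduce(supports)
        )

    def test_near_empty_on_pure_noise_with_high_penalties(self):
        rng = np.random.default_rng(77)
        nd = preprocess(
            MultiBlockData(
                [rng.standard_normal((20, 10)), rng.standard_normal((20, 6))]
            )
        )
        g = make_grid(nd, 3, 4)
        high = TuningGrid(g.lasso_values[2:], g.group_values[2:])
        res = bolasso(nd, 3, high, n_repetitions=5, seed=0)
        assert res.pattern.n_nonzero <= 0.05 * res.pattern.mask.size


class TestStabilitySelection:
    def test_degenerate_q_selects_everything(self, data):
        lmax = lambda_max(data, 3, "lasso")
        vals = np.linspace(1e-7, lmax, 4)[::-1]
        res = stability_selection(data, 3, vals, Q=30, n_subsamples=10, seed=0)
        assert res.pattern.mask.all()

    def test_deterministic_and_granular(self, data):
        lmax = lambda_max(data, 3, "lasso")
        vals = np.linspace(1e-7, lmax, 4)[::-1]
        kwargs = dict(Q=8, n_subsamples=20, seed=9)
        r1 = stability_selection(data, 3, vals, **kwargs)
        r2 = stability_selection(data, 3, vals, **kwargs)
        np.testing.assert_array_equal(r1.pattern.mask, r2.pattern.mask)
        probs = r1.diagnostics["selection_probabilities"]
        np.testing.assert_allclose(probs * 20, np.round(probs * 20), atol=1e-9)

    def test_probabilities_zero_at_lambda_max(self, data):
        lmax = lambda_max(data, 3, "lasso")
        res = stability_selection(
            data, 3, np.array([lmax * 1.1, lmax]), Q=5, n_subsamples=10, seed=2
        )
        history = res.diagnostics["probability_history"]
        assert float(history[0].max()) == 0.0

    def test_increasing_values_rejected(self, data):
        with pytest.raises(ValidationError):
            stability_selection(data, 3, np.array([0.1, 0.2]), Q=5)

    def test_bad_pi_thr_rejected(self, data):
        with pytest.raises(ValidationError):
            stability_selection(data, 3, np.array([0.2, 0.1]), Q=5, pi_thr=0.5)


class TestQBound:
    @pytest.mark.parametrize(
        "EV, pi, total, expected",
        [(1, 0.9, 450, 19), (1, 0.9, 500, 20), (4, 0.9, 450, 38)],
    )
    def test_closed_form(self, EV, pi, total, expected):
        assert q_bound(EV, pi, total) == expected

    def test_pi_at_half_rejected(self):
        with pytest.raises(ValidationError):
            q_bound(1, 0.5, 100)
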