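import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mdfdr.data import ExpressionMatrix, GroupDesign
from mdfdr.dunnett import (
    DunnettNullModel,
    dunnett_pairwise_pvalue,
    dunnett_statistics,
    max_abs_t_tail,
    screening_pvalue,
    two_sided_t_pvalues,
)


def equicorrelated_model(q, df, r=0.5):
    rho = np.full((q, q), float(r))
    np.fill_diagonal(rho, 1.0)
    return DunnettNullModel(q=q, df=df, rho=rho)


def mc_max_abs_t(q, df, rho_offdiag, n_draws, seed):
    """Monte-Carlo oracle: sample the multivariate t directly."""
    rng = np.random.default_rng(seed)
    rho = np.full((q, q), rho_offdiag)
    np.fill_diagonal(rho, 1.0)
    z = rng.standard_normal((n_draws, q)) @ np.linalg.cholesky(rho).T
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.abs(z).max(axis=1) / s


class TestStatistics:
    def test_hand_computed_oracle(self):
        """T matches an independently coded textbook computation."""
        rng = np.random.default_rng(5)
        values = rng.normal(size=(3, 12))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["r"] * 3
        design = GroupDesign(labels, "r")
        got = dunnett_statistics(
            ExpressionMatrix(values, ["x", "y", "z"]), design
        )
        assert got.df == 8
        for j in range(3):
            groups = [values[j, k * 3 : (k + 1) * 3] for k in range(4)]
            s2 = sum(((g - g.mean()) ** 2).sum() for g in groups) / 8.0
            for i in range(3):
                expect = (groups[i].mean() - groups[3].mean()) / (
                    np.sqrt(s2) * np.sqrt(1 / 3 + 1 / 3)
                )
                assert got.t[j, i] == pytest.approx(expect, rel=1e-12)

    def test_equal_group_means_give_zero(self, balanced_design):
        # identical group means but within-group spread: T = 0 exactly
        block = np.tile([-1.0, 1.0, 0.0, 2.0, -2.0, 0.5, -0.5, 1.5, -1.5, 0.0], 4)
        matrix = ExpressionMatrix(block[None, :], ["f0"])
        t = dunnett_statistics(matrix, balanced_design).t
        np.testing.assert_array_equal(t, np.zeros((1, 3)))

    def test_constant_feature_flagged_undefined(self, balanced_design):
        values = np.vstack([np.zeros(40), np.random.default_rng(0).normal(size=40)])
        stats_ = dunnett_statistics(
            ExpressionMatrix(values, ["flat", "ok"]), balanced_design
        )
        assert np.isnan(stats_.t[0]).all()
        assert np.isfinite(stats_.t[1]).all()
        model = DunnettNullModel.from_design(balanced_design)
        assert screening_pvalue(stats_, model)[0] == 1.0

    def test_balanced_rho_is_half(self, balanced_design):
        model = DunnettNullModel.from_design(balanced_design)
        off = model.rho[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 0.5)

    def test_unbalanced_rho_formula(self):
        labels = ["a"] * 4 + ["b"] * 8 + ["r"] * 6
        model = DunnettNullModel.from_design(GroupDesign(labels, "r"))
        expect = np.sqrt((4 / 10) * (8 / 14))
        assert model.rho[0, 1] == pytest.approx(expect, rel=1e-12)
        np.testing.assert_allclose(model.lambdas, [4 / 10, 8 / 14])


class TestTailProbability:
    def test_at_zero_is_one(self):
        model = equicorrelated_model(3, 36)
        assert max_abs_t_tail(0.0, model) == 1.0

    def test_q1_reduces_to_two_sided_t(self):
        for df in (10, 36):
            model = DunnettNullModel(q=1, df=df, rho=np.array([[1.0]]))
            c = np.array([0.0, 0.5, 1.0, 2.5, 3.5, 6.0])
            np.testing.assert_allclose(
                max_abs_t_tail(c, model), 2 * sps.t.sf(c, df), atol=1e-8
            )

    def test_matches_monte_carlo_oracle(self):
        """Quadrature agrees with 200k-draw sampling of the multivariate t."""
        model = equicorrelated_model(3, 36)
        draws = mc_max_abs_t(3, 36, 0.5, 200_000, seed=42)
        for c in (1.0, 2.5):
            est = (draws >= c).mean()
            se = np.sqrt(est * (1 - est) / draws.size)
            assert abs(max_abs_t_tail(c, model) - est) < 3 * se

    def test_unbalanced_matches_monte_carlo(self):
        labels = ["a"] * 4 + ["b"] * 8 + ["r"] * 6
        model = DunnettNullModel.from_design(GroupDesign(labels, "r"))
        rng = np.random.default_rng(7)
        lam = model.lambdas
        z0 = rng.standard_normal(200_000)
        zi = rng.standard_normal((200_000, 2))
        y = np.sqrt(lam) * z0[:, None] + np.sqrt(1 - lam) * zi
        s = np.sqrt(rng.chisquare(model.df, 200_000) / model.df)
        draws = np.abs(y).max(axis=1) / s
        est = (draws >= 2.0).mean()
        se = np.sqrt(est * (1 - est) / draws.size)
        assert abs(max_abs_t_tail(2.0, model) - est) < 3 * se

    def test_strictly_monotone_on_working_range(self):
        model = equicorrelated_model(3, 36)
        p = max_abs_t_tail(np.arange(0.0, 5.0, 0.05), model)
        assert np.all(np.diff(p) < 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_matches_scipy_dunnett(self):
        """Independent route: scipy's many-to-one test on the same data."""
        rng = np.random.default_rng(3)
        samples = [rng.normal(loc, 1.0, 10) for loc in (0.8, 0.0, -0.5)]
        control = rng.normal(0.0, 1.0, 10)
        ref = sps.dunnett(*samples, control=control, random_state=1)
        design = GroupDesign(
            ["a"] * 10 + ["b"] * 10 + ["c"] * 10 + ["r"] * 10, "r"
        )
        matrix = ExpressionMatrix(
            np.concatenate(samples + [control])[None, :], ["f0"]
        )
        stats_ = dunnett_statistics(matrix, design)
        model = DunnettNullModel.from_design(design)
        np.testing.assert_allclose(stats_.t[0], ref.statistic, rtol=1e-10)
        for i in range(3):
            ours = dunnett_pairwise_pvalue(stats_.t[0, i], model)
            assert ours == pytest.approx(ref.pvalue[i], abs=2e-3)

    def test_generic_product_form_rho_factorized(self):
        """A product-form rho given without group sizes is still exact."""
        rho = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.52], [0.5, 0.52, 1.0]])
        model = DunnettNullModel(q=3, df=36, rho=rho)
        lam = model.lambdas
        fitted = np.sqrt(np.outer(lam, lam))
        np.testing.assert_allclose(fitted[np.triu_indices(3, 1)],
                                   rho[np.triu_indices(3, 1)], atol=1e-10)

    def test_mc_fallback_for_non_product_rho(self):
        """A correlation with no product form falls back to seeded MC."""
        # lambda_2 would need r12*r23/r13 = 0.64/0.6 > 1: no factorization
        rho = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, 0.8], [0.6, 0.8, 1.0]])
        assert np.linalg.eigvalsh(rho).min() > 0
        model = DunnettNullModel(q=3, df=36, rho=rho)
        assert model.lambdas is None
        p, se = max_abs_t_tail(2.5, model, return_se=True)
        assert se > 0
        # bracketed by the single-comparison tail and its Bonferroni bound
        single = 2 * sps.t.sf(2.5, 36)
        assert single - 3 * se <= p <= 3 * single + 3 * se
        # fixed seed: reproducible
        assert max_abs_t_tail(2.5, model) == p


class TestScreening:
    @given(
        st.lists(
            st.floats(min_value=-6, max_value=6, allow_nan=False),
            min_size=3,
            max_size=3,
        )
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bonferroni_domination(self, trow):
        """Adjusted p never exceeds q times the two-sided t p-value."""
        model = equicorrelated_model(3, 36)
        from mdfdr.data import FeatureStats

        stats_ = FeatureStats(t=np.array([trow]), df=36, rho=model.rho)
        p = screening_pvalue(stats_, model)[0]
        raw = two_sided_t_pvalues(stats_)[0]
        assert p <= min(1.0, 3 * raw.min()) + 1e-9

    def test_all_zero_statistics_give_p_one(self):
        from mdfdr.data import FeatureStats

        model = equicorrelated_model(3, 36)
        stats_ = FeatureStats(t=np.zeros((2, 3)), df=36, rho=model.rho)
        np.testing.assert_array_equal(screening_pvalue(stats_, model), 1.0)

    def test_consistent_with_pairwise_at_max(self):
        """Screening p equals the adjusted p evaluated at the feature's max |T|."""
        from mdfdr.data import FeatureStats

        model = equicorrelated_model(3, 36)
        rng = np.random.default_rng(11)
        t = rng.normal(scale=2, size=(20, 3))
        stats_ = FeatureStats(t=t, df=36, rho=model.rho)
        sp = screening_pvalue(stats_, model)
        for j in range(20):
            assert sp[j] == pytest.approx(
                dunnett_pairwise_pvalue(np.abs(t[j]).max(), model), abs=1e-12
            )

    def test_null_screening_pvalues_uniform(self):
        """KS test on 10k simulated null features must not reject at 0.001."""
        rng = np.random.default_rng(2024)
        design = GroupDesign(
            [g for g in "abc" for _ in range(10)] + ["r"] * 10, "r"
        )
        values = rng.standard_normal((10_000, 40))
        stats_ = dunnett_statistics(
            ExpressionMatrix(values, [f"f{j}" for j in range(10_000)]), design
        )
        model = DunnettNullModel.from_design(design)
        p = screening_pvalue(stats_, model)
        assert sps.kstest(p, "uniform").pvalue > 0.001
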