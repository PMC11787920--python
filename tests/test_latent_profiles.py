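"""Gaussian-mixture LPA: EM, BIC, entropy, BLRT and model selection."""

import numpy as np
import pytest
from scipy import stats

from phenotyper import latent_profiles as lp
from phenotyper.latent_profiles import (
    MixtureFitError,
    MixtureSpec,
    bic_score,
    blrt,
    canonical_order,
    fit_mixture,
    n_parameters,
    normalized_entropy,
    posterior_assign,
    reorder_components,
    select_profiles,
    total_entropy,
)


def two_cluster_1d(rng, n=100, gap=10.0, sd=0.5):
    X = np.concatenate([
        rng.normal(0, sd, n // 2), rng.normal(gap, sd, n - n // 2)
    ]).reshape(-1, 1)
    truth = np.repeat([0, 1], [n // 2, n - n // 2])
    return X, truth


class TestFitMixture:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2, 1.3, size=(60, 3))
        fit = fit_mixture(X, MixtureSpec(1, "full-varying", prior_weight=0.0))
        assert fit.means[0] == pytest.approx(X.mean(axis=0))
        mle_cov = np.cov(X.T, bias=True)
        assert fit.covariances[0] == pytest.approx(mle_cov, rel=1e-6)
        expected_ll = stats.multivariate_normal(X.mean(axis=0), mle_cov).logpdf(X).sum()
        assert fit.loglik == pytest.approx(expected_ll, rel=1e-9)

    def test_separated_clusters_recovered_exactly(self):
        rng = np.random.default_rng(1)
        X, truth = two_cluster_1d(rng)
        fit = fit_mixture(X, MixtureSpec(2, "diagonal-varying", seed=0))
        labels = fit.labels
        if labels[0] != truth[0]:
            labels = 1 - labels
        assert np.array_equal(labels, truth)
        assert fit.posteriors.min(axis=1).max() < 1e-6  # crisp assignment

    @pytest.mark.parametrize("family", lp.FAMILIES)
    def test_loglik_trace_is_monotone_for_mle(self, family):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (40, 4)), rng.normal(2, 1.5, (40, 4))])
        fit = fit_mixture(X, MixtureSpec(3, family, prior_weight=0.0, seed=3))
        assert np.all(np.diff(fit.ll_trace) >= -1e-7 * np.abs(fit.ll_trace[:-1]))

    def test_best_of_restarts_is_at_least_single_restart(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (80, 2))
        multi = fit_mixture(X, MixtureSpec(3, "diagonal-varying", restarts=8, seed=5))
        single = fit_mixture(X, MixtureSpec(3, "diagonal-varying", restarts=1, seed=5))
        assert multi.loglik >= single.loglik - 1e-9

    def test_nonfinite_input_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_mixture(X, MixtureSpec(1))

    def test_matches_sklearn_loglik(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        X, _ = two_cluster_1d(rng, n=120, gap=6.0)
        mine = fit_mixture(X, MixtureSpec(2, "full-varying", prior_weight=0.0, seed=0))
        sk = GaussianMixture(2, covariance_type="full", n_init=5,
                             reg_covar=1e-10, random_state=0).fit(X)
        assert mine.loglik == pytest.approx(sk.score(X) * len(X), rel=1e-5)


class TestBic:
    def test_parameter_counts(self):
        assert n_parameters(3, 10, "full-varying") == 2 + 30 + 3 * 55
        assert n_parameters(3, 10, "diagonal-varying") == 2 + 30 + 30
        assert n_parameters(3, 10, "diagonal-equal") == 2 + 30 + 10
        assert n_parameters(1, 1, "spherical-equal") == 2

    def test_three_point_example(self):
        X = np.array([[0.0], [1.0], [2.0]])
        fit = fit_mixture(X, MixtureSpec(1, "full-varying", prior_weight=0.0))
        var = 2.0 / 3.0
        ll = stats.norm(1.0, np.sqrt(var)).logpdf([0, 1, 2]).sum()
        assert fit.loglik == pytest.approx(ll, rel=1e-9)
        assert bic_score(fit) == pytest.approx(2 * ll - 2 * np.log(3), rel=1e-9)

    def test_argmax_convention_on_reported_fit_column(self):
        # selection maximizes BIC: on the published fit column the
        # three-profile row wins
        bic = {1: -2880.00, 2: -2526.03, 3: -2481.03,
               4: -2693.27, 5: -2707.86, 6: -2793.31}
        assert max(bic, key=bic.get) == 3

    def test_more_parameters_raise_loglik_but_can_lower_bic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (60, 3))
        simple = fit_mixture(X, MixtureSpec(1, "spherical-equal", prior_weight=0.0))
        rich = fit_mixture(X, MixtureSpec(1, "full-varying", prior_weight=0.0))
        assert rich.loglik >= simple.loglik
        assert bic_score(rich) < bic_score(simple)


class TestEntropy:
    def test_hard_posteriors(self):
        P = np.eye(3)[np.random.default_rng(0).integers(0, 3, 30)]
        assert normalized_entropy(P) == pytest.approx(1.0)

    def test_uniform_posteriors(self):
        assert normalized_entropy(np.full((10, 2), 0.5)) == pytest.approx(0.0)

    def test_single_row_hand_value(self):
        P = np.array([[0.9, 0.1]])
        shannon = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert total_entropy(P) == pytest.approx(shannon)
        assert normalized_entropy(P) == pytest.approx(1 - shannon / np.log(2))

    def test_single_component_defined_as_one(self):
        assert normalized_entropy(np.ones((7, 1))) == 1.0

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(1)
        P = rng.dirichlet([1, 1, 1], size=40)
        perm = P[:, [2, 0, 1]]
        assert normalized_entropy(perm) == pytest.approx(normalized_entropy(P))

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            normalized_entropy(np.array([[0.7, 0.7]]))


class TestBlrt:
    def test_separated_clusters_give_minimal_p(self):
        rng = np.random.default_rng(2)
        X, _ = two_cluster_1d(rng)
        res = blrt(X, MixtureSpec(1, "diagonal-varying"),
                   MixtureSpec(2, "diagonal-varying"), B=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.statistic > 100
        assert np.all(res.boot_stats < res.statistic)

    def test_family_mismatch_rejected(self):
        with pytest.raises(ValueError, match="family"):
            blrt(np.zeros((10, 1)), MixtureSpec(1, "diagonal-varying"),
                 MixtureSpec(2, "full-varying"), B=9)

    def test_early_stop_reports_nonrejection(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (150, 1))
        res = blrt(X, MixtureSpec(1, "diagonal-varying", prior_weight=0),
                   MixtureSpec(2, "diagonal-varying", prior_weight=0),
                   B=199, seed=1, early_stop_alpha=0.05)
        if res.early_stopped:
            assert res.p_value > 0.05
            assert res.n_boot < 199


class TestSelection:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (50, 2))
        sel = select_profiles(X, g_range=[1], families=("diagonal-varying",), seed=0)
        assert sel.best.n_components == 1
        assert len(sel.table) == 1

    def test_single_gaussian_data_selects_one_component(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (150, 3))
        sel = select_profiles(X, g_range=range(1, 5), seed=0)
        assert sel.best.n_components == 1

    def test_overparameterized_candidates_marked_ineligible(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (30, 10))
        sel = select_profiles(X, g_range=range(1, 4),
                              families=("diagonal-varying",), seed=0)
        big = sel.table[sel.table.k >= 30]
        assert not big.empty and not big.eligible.any()

    def test_relabeling_preserves_fit_statistics(self):
        rng = np.random.default_rng(7)
        X, _ = two_cluster_1d(rng)
        fit = fit_mixture(X, MixtureSpec(2, "diagonal-varying", seed=0))
        flipped = reorder_components(fit, [1, 0])
        assert flipped.loglik == fit.loglik
        assert bic_score(flipped) == pytest.approx(bic_score(fit))
        assert normalized_entropy(flipped.posteriors) == pytest.approx(
            normalized_entropy(fit.posteriors))
        assert np.array_equal(flipped.labels, 1 - fit.labels)

    def test_canonical_order_sorts_by_descending_column_mean(self):
        rng = np.random.default_rng(8)
        X, _ = two_cluster_1d(rng)
        fit = canonical_order(
            fit_mixture(X, MixtureSpec(2, "diagonal-varying", seed=0)), by_column=0
        )
        assert fit.means[0, 0] > fit.means[1, 0]


class TestPosteriorAssign:
    def test_single_component_certainty(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (20, 2))
        fit = fit_mixture(X, MixtureSpec(1))
        labels, maxpost = posterior_assign(fit)
        assert np.all(labels == 0) and np.all(maxpost == 1.0)

    def test_equidistant_point_ties_to_lower_index(self):
        base = fit_mixture(
            np.vstack([np.random.default_rng(0).normal(0, 1, (30, 1)),
                       np.random.default_rng(1).normal(8, 1, (30, 1))]),
            MixtureSpec(2, "diagonal-varying", seed=0),
        )
        # symmetrize the fit by hand, then score the midpoint
        means = np.array([[0.0], [8.0]])
        covs = np.array([np.eye(1), np.eye(1)])
        sym = base.__class__(base.spec, np.array([0.5, 0.5]), means, covs,
                             base.loglik, base.n_obs, base.posteriors,
                             True, base.ll_trace, base.n_iter)
        labels, maxpost = posterior_assign(sym, np.array([[4.0]]))
        assert labels[0] == 0
        assert maxpost[0] == pytest.approx(0.5)

    def test_point_at_component_mean_is_certain(self):
        rng = np.random.default_rng(10)
        X, _ = two_cluster_1d(rng, gap=12.0)
        fit = canonical_order(
            fit_mixture(X, MixtureSpec(2, "diagonal-varying", seed=0)), by_column=0
        )
        labels, maxpost = posterior_assign(fit, fit.means[:1])
        assert labels[0] == 0 and maxpost[0] > 0.999999
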