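"""Uncertainty estimators: closed-form identities and behavioral contracts."""

import numpy as np
import pytest
from scipy import integrate

from moluq.errors import (ConfigurationError, DomainError, InputError)
from moluq.regressors import RegressorSpec, train_regressor
from moluq.uq import (NIGParams, QuantilePrediction, UQEstimate, consensus_uq,
                      ensemble_uq, evidential_uq, gbm_quantile_uq,
                      knn_density_uq, mcdo_uq, mve_nll_loss, mve_uq,
                      nig_log_density, nig_moments, union_uq)


class TestGBMQuantileUQ:
    def test_half_interval(self):
        est = gbm_quantile_uq(QuantilePrediction([1.0], [3.0]), [2.0])
        assert est.sigma[0] == pytest.approx(1.0, abs=1e-12)
        assert est.calibrated

    def test_zero_width(self):
        est = gbm_quantile_uq(QuantilePrediction([2.0], [2.0]), [2.0])
        assert est.sigma[0] == 0.0

    def test_crossed_quantiles_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="crossed"):
            est = gbm_quantile_uq(QuantilePrediction([1.2], [1.0]), [1.1])
        assert est.sigma[0] == 0.0

    def test_misaligned_rejected(self):
        with pytest.raises(InputError):
            gbm_quantile_uq(QuantilePrediction([1.0, 2.0], [3.0, 4.0]), [1.0])


class TestMVE:
    @pytest.mark.parametrize("y,mu,s2,expected", [
        (0.0, 0.0, 1.0, 0.5 * np.log(2 * np.pi)),
        (1.0, 0.0, 1.0, 0.5 * np.log(2 * np.pi) + 0.5),
        (3.0, 3.0, np.e ** 2, 0.5 * np.log(2 * np.pi) + 1.0),
    ])
    def test_nll_closed_form(self, y, mu, s2, expected):
        assert mve_nll_loss(y, mu, s2) == pytest.approx(expected, abs=1e-12)

    def test_nll_rejects_nonpositive_variance(self):
        with pytest.raises(DomainError):
            mve_nll_loss(0.0, 0.0, 0.0)

    def test_wrong_head_rejected(self, small_table):
        tr = small_table.subset(np.arange(300))
        spec = RegressorSpec(hidden_sizes=(8,), max_epochs=3, seed=0)
        model = train_regressor(spec, tr, head="point")
        with pytest.raises(Exception):
            mve_uq(model, tr.X)


class TestNIG:
    def test_density_hand_value(self):
        p = NIGParams(gamma=0.0, upsilon=1.0, alpha=2.0, beta=1.0)
        expected = np.exp(-1.0) / np.sqrt(2 * np.pi)
        assert nig_log_density(0.0, 1.0, p) == pytest.approx(
            np.log(expected), abs=1e-12)

    def test_density_integrates_to_one(self):
        """Numeric quadrature of the joint density over (mu, sigma2)."""
        p = NIGParams(gamma=0.0, upsilon=1.0, alpha=3.0, beta=1.0)

        def dens(s2, mu):
            return np.exp(nig_log_density(mu, s2, p))

        mass, _ = integrate.dblquad(dens, -12, 12, 1e-4, 60.0)
        assert mass == pytest.approx(1.0, abs=0.01)

    def test_density_symmetric_in_mu(self):
        p = NIGParams(gamma=0.7, upsilon=2.0, alpha=2.5, beta=0.8)
        for delta in (0.1, 1.3, 2.2):
            assert nig_log_density(0.7 + delta, 0.9, p) == pytest.approx(
                nig_log_density(0.7 - delta, 0.9, p), abs=1e-12)

    @pytest.mark.parametrize("params,expected", [
        (dict(gamma=2.0, upsilon=1.0, alpha=3.0, beta=4.0), (2.0, 2.0, 2.0)),
        (dict(gamma=-1.0, upsilon=4.0, alpha=2.0, beta=1.0),
         (-1.0, 1.0, 0.25)),
    ])
    def test_moments_closed_form(self, params, expected):
        assert nig_moments(NIGParams(**params)) == pytest.approx(
            expected, abs=1e-12)

    def test_moments_vanishing_epistemic_limit(self):
        small = nig_moments(NIGParams(gamma=0, upsilon=1e12, alpha=3, beta=4))
        assert small[1] == pytest.approx(2.0, abs=1e-12)  # aleatoric unchanged
        assert small[2] < 1e-11

    def test_alpha_at_most_one_rejected(self):
        with pytest.raises(DomainError):
            NIGParams(gamma=0.0, upsilon=1.0, alpha=1.0, beta=1.0)


@pytest.fixture(scope="module")
def trained(small_table):
    tr = small_table.subset(np.arange(600))
    va = small_table.subset(np.arange(600, 700))
    spec = RegressorSpec(hidden_sizes=(16, 8), max_epochs=30, seed=5)
    return tr, va, spec, train_regressor(spec, tr, va, head="point")


@pytest.fixture(scope="module")
def evidential_model(small_table):
    tr = small_table.subset(np.arange(600))
    va = small_table.subset(np.arange(600, 700))
    spec = RegressorSpec(hidden_sizes=(16, 8), max_epochs=40, seed=6)
    return train_regressor(spec, tr, va, head="evidential"), tr


class TestEnsembleAndMCDO:
    def test_single_member_rejected(self, trained):
        tr, va, spec, _ = trained
        with pytest.raises(ConfigurationError):
            ensemble_uq([spec], tr, va, tr.X[:5])

    def test_identical_seeds_give_zero_sigma(self, trained):
        tr, va, spec, _ = trained
        est = ensemble_uq([spec, spec], tr, va, tr.X[:20])
        np.testing.assert_allclose(est.sigma, 0.0, atol=1e-12)

    def test_distinct_seeds_give_positive_sigma(self, trained):
        tr, va, spec, _ = trained
        specs = [spec.with_seed(10 + i) for i in range(5)]
        est = ensemble_uq(specs, tr, va, tr.X[:200])
        assert np.mean(est.sigma > 0) >= 0.99

    def test_mcdo_zero_dropout_gives_zero_sigma(self, trained):
        *_, model = trained
        est = mcdo_uq(model, model.x_mean[None, :] + 0.0, n_passes=10,
                      dropout_rate=0.0, seed=0)
        np.testing.assert_allclose(est.sigma, 0.0, atol=1e-12)

    def test_mcdo_deterministic_given_seed(self, trained):
        tr, *_ , model = trained
        a = mcdo_uq(model, tr.X[:30], n_passes=20, seed=7)
        b = mcdo_uq(model, tr.X[:30], n_passes=20, seed=7)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        np.testing.assert_array_equal(a.mean, b.mean)

    def test_mcdo_monte_carlo_convergence(self, trained):
        """Sigma stabilizes as the number of passes grows."""
        tr, *_, model = trained
        big = mcdo_uq(model, tr.X[:100], n_passes=1000, seed=3).sigma
        half = mcdo_uq(model, tr.X[:100], n_passes=500, seed=3).sigma
        rel = np.abs(big - half) / np.maximum(big, 1e-12)
        assert np.mean(rel < 0.10) >= 0.95

    def test_mcdo_rejects_non_handle(self):
        with pytest.raises(Exception):
            mcdo_uq(object(), np.zeros((2, 3)))


class TestEvidentialUQ:
    def test_total_is_sum_of_components(self, evidential_model):
        m, tr = evidential_model
        X = tr.X[:50]
        e = evidential_uq(m, X, report="epistemic").sigma
        a = evidential_uq(m, X, report="aleatoric").sigma
        t = evidential_uq(m, X, report="total").sigma
        np.testing.assert_allclose(t ** 2, e ** 2 + a ** 2, rtol=1e-10)

    def test_invalid_report_rejected(self, evidential_model):
        m, tr = evidential_model
        with pytest.raises(ConfigurationError):
            evidential_uq(m, tr.X[:5], report="both")


class TestKNNDensity:
    def test_duplicated_query_has_zero_sigma(self):
        train = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        est = knn_density_uq(train, np.array([[1.0, 0.0]]), k=3)
        assert est.sigma[0] == pytest.approx(0.0, abs=1e-9)
        assert not est.calibrated

    def test_mean_of_k_neighbor_distances(self):
        """Three training points at cosine distances 0.1/0.2/0.3 from the
        query give sigma 0.2."""
        def at_distance(d):
            theta = np.arccos(1.0 - d)
            return [np.cos(theta), np.sin(theta)]

        train = np.array([at_distance(0.1), at_distance(0.2),
                          at_distance(0.3)])
        est = knn_density_uq(train, np.array([[1.0, 0.0]]), k=3)
        assert est.sigma[0] == pytest.approx(0.2, abs=1e-9)

    def test_orthogonal_query(self):
        train = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        est = knn_density_uq(train, np.array([[0.0, 1.0]]), k=3)
        assert est.sigma[0] == pytest.approx(1.0, abs=1e-9)

    def test_too_few_training_rows(self):
        with pytest.raises(ConfigurationError):
            knn_density_uq(np.eye(2), np.eye(2), k=3)


class TestUnion:
    def test_union_plumbing_and_error_correlation(self, small_table):
        from scipy.stats import spearmanr
        tr = small_table.subset(np.arange(700))
        va = small_table.subset(np.arange(700, 800))
        te = small_table.subset(np.arange(800, 1000))
        spec = RegressorSpec(hidden_sizes=(32, 16), max_epochs=60, seed=2)
        model = train_regressor(spec, tr, va, head="point")
        est = union_uq(model, tr, te.X, seed=0)
        assert est.calibrated and len(est) == 200
        np.testing.assert_allclose(est.mean, model.predict(te.X))
        rho = spearmanr(est.sigma, np.abs(te.y - est.mean)).statistic
        assert rho > 0

    def test_constant_features_give_constant_sigma(self, small_table):
        tr = small_table.subset(np.arange(400))
        spec = RegressorSpec(hidden_sizes=(8, 4), max_epochs=3, seed=1)
        model = train_regressor(spec, tr, head="point")
        # zero all hidden weights: every input maps to one feature vector
        for W in model.net.W[:-1]:
            W[:] = 0.0
        est = union_uq(model, tr, tr.X[:30], seed=0)
        assert np.allclose(est.sigma, est.sigma[0])


class TestConsensus:
    def _mk(self, sigma, mean, method="m"):
        n = len(sigma)
        return UQEstimate([f"i{k}" for k in range(n)], mean, sigma, True,
                          method)

    def test_elementwise_average(self):
        ests = [self._mk([1.0], [0.0]), self._mk([2.0], [2.0]),
                self._mk([3.0], [1.0])]
        c = consensus_uq(ests)
        assert c.sigma[0] == pytest.approx(2.0, abs=1e-12)
        assert c.mean[0] == pytest.approx(1.0, abs=1e-12)

    def test_idempotence(self):
        e = self._mk([0.5, 1.5], [1.0, 2.0])
        c = consensus_uq([e, e])
        np.testing.assert_allclose(c.sigma, e.sigma)
        np.testing.assert_allclose(c.mean, e.mean)

    def test_misaligned_ids_rejected(self):
        a = self._mk([1.0], [0.0])
        b = UQEstimate(["other"], [0.0], [1.0], True, "m")
        with pytest.raises(InputError):
            consensus_uq([a, b])

    def test_uncalibrated_member_rejected(self):
        a = self._mk([1.0], [0.0])
        b = UQEstimate(a.ids, [0.0], [1.0], False, "knn")
        with pytest.raises(InputError):
            consensus_uq([a, b])


class TestUQEstimateContract:
    def test_negative_sigma_rejected(self):
        with pytest.raises(InputError):
            UQEstimate(["a"], [0.0], [-0.1], True, "m")

    def test_rank_metrics_invariant_to_sd_vs_variance(self):
        """Reporting sigma or sigma^2 leaves Spearman-based metrics
        unchanged (monotone transform)."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(0)
        sigma = rng.random(50) + 0.1
        err = rng.random(50)
        r1 = spearmanr(sigma, err).statistic
        r2 = spearmanr(sigma ** 2, err).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)
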