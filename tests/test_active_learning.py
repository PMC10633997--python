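"""Active-learning sampling, paired statistics, and grid bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moluq.active_learning import (ALConfig, al_grid_summary,
                                   correlate_al_with_uq, fraction_ood_sampled,
                                   improvement_pct, paired_one_sided_t,
                                   run_al_experiment, select_batch,
                                   DEFAULT_BATCH_SIZES, DEFAULT_FRACTIONS)
from moluq.errors import DegenerateError, InputError
from moluq.synthetic import SyntheticConfig, generate_dataset


class TestSelectBatch:
    def test_linear_weighting_frequencies(self):
        """Weights {1,1,2} give single-draw probabilities {1/4,1/4,1/2}."""
        rng = np.random.default_rng(0)
        counts = np.zeros(3)
        n_draws = 100_000
        sigma = np.array([1.0, 1.0, 2.0])
        for _ in range(n_draws):
            counts[select_batch(sigma, {}, 1, "uq_weighted", rng)[0]] += 1
        freqs = counts / n_draws
        np.testing.assert_allclose(freqs, [0.25, 0.25, 0.5], atol=0.01)
        # chi-square goodness of fit against the linear-weight law
        chi2 = stats.chisquare(counts, n_draws * np.array([.25, .25, .5]))
        assert chi2.pvalue > 0.01

    def test_dominant_weight_always_chosen(self):
        rng = np.random.default_rng(1)
        sigma = np.array([1e-9, 1e-9, 1.0, 1e-9])
        hits = sum(select_batch(sigma, {}, 1, "uq_weighted", rng)[0] == 2
                   for _ in range(10_000))
        assert hits / 10_000 > 0.999

    def test_exhaustion_returns_whole_pool(self):
        rng = np.random.default_rng(2)
        for strategy in ("random", "uq_weighted", "diversity"):
            meta = {"embeddings": np.random.default_rng(0).normal(size=(4, 3))}
            idx = select_batch(np.ones(4), meta, 4, strategy, rng)
            assert sorted(idx.tolist()) == [0, 1, 2, 3]

    def test_all_zero_weights_rejected(self):
        with pytest.raises(DegenerateError):
            select_batch(np.zeros(5), {}, 2, "uq_weighted",
                         np.random.default_rng(0))

    def test_ood_only_caps_with_warning(self):
        rng = np.random.default_rng(3)
        meta = {"removed_mask": np.array([True, True, False, False])}
        with pytest.warns(RuntimeWarning, match="capped"):
            idx = select_batch(np.ones(4), meta, 3, "ood_only", rng)
        assert sorted(idx.tolist()) == [0, 1]

    def test_ood_only_samples_only_bin_members(self):
        rng = np.random.default_rng(4)
        mask = np.zeros(50, bool)
        mask[::5] = True
        idx = select_batch(np.ones(50), {"removed_mask": mask}, 5,
                           "ood_only", rng)
        assert all(mask[i] for i in idx)

    def test_without_replacement(self):
        rng = np.random.default_rng(5)
        idx = select_batch(np.arange(1.0, 21.0), {}, 15, "uq_weighted", rng)
        assert len(set(idx.tolist())) == 15


class TestStatistics:
    def test_improvement_pct_single_rep(self):
        assert improvement_pct([0.99], [1.0]) == pytest.approx(1.0, abs=1e-12)

    def test_improvement_identity_zero(self):
        assert improvement_pct([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_improvement_cancellation(self):
        assert improvement_pct([0.9, 1.1], [1.0, 1.0]) == pytest.approx(
            0.0, abs=1e-12)

    def test_zero_random_rmse_rejected(self):
        with pytest.raises(DegenerateError):
            improvement_pct([0.5], [0.0])

    def test_paired_t_zero_mean_gives_half(self):
        """Differences {0.1, 0.2, -0.3} have mean 0, hence t=0, p=0.5."""
        al = np.array([1.0, 1.0, 1.0])
        rand = al + np.array([0.1, 0.2, -0.3])
        assert paired_one_sided_t(al, rand) == pytest.approx(0.5, abs=1e-12)

    def test_paired_t_zero_variance_flagged(self):
        assert math.isnan(paired_one_sided_t([1.0, 1.0], [1.2, 1.2]))

    def test_paired_t_strong_effect(self):
        rng = np.random.default_rng(0)
        rand = 1.0 + 0.01 * rng.normal(size=30)
        al = rand - 0.5 + 0.01 * rng.normal(size=30)
        p = paired_one_sided_t(al, rand)
        assert p < 0.001
        # closed-form check through the t CDF
        d = rand - al
        t = d.mean() / (d.std(ddof=1) / math.sqrt(30))
        assert p == pytest.approx(stats.t.sf(t, 29), abs=1e-12)

    @pytest.mark.parametrize("batch,removed,expected", [
        ([1, 2, 3], [7, 8], 0.0),
        ([7, 8], [7, 8, 9], 1.0),
        ([1, 2, 7, 8, 3, 4, 5, 6], [7, 8], 0.25),
    ])
    def test_fraction_ood_sampled(self, batch, removed, expected):
        assert fraction_ood_sampled(np.array(batch), np.array(removed)) == \
            pytest.approx(expected, abs=1e-12)

    def test_fraction_empty_batch_rejected(self):
        with pytest.raises(InputError):
            fraction_ood_sampled(np.array([]), np.array([1]))


@pytest.fixture(scope="module")
def al_data():
    return generate_dataset(SyntheticConfig(n_molecules=1500, seed=1))


class TestRunALExperiment:
    def test_random_vs_random_improvement_exactly_zero(self, al_data):
        cfg = ALConfig(initial_fraction=0.1, n_add=40, sampler="random",
                       uq_method="none", scenario="leave_bin_out",
                       pc_index=1, bin_index=3, n_reps=2, seed=0)
        out = run_al_experiment(cfg, al_data, model_family="gbm",
                                model_params={"n_estimators": 30})
        for subset, v in out.improvement_pct.items():
            assert v == 0.0

    def test_ood_only_fraction_is_one(self, al_data):
        cfg = ALConfig(initial_fraction=0.1, n_add=30, sampler="ood_only",
                       uq_method="none", scenario="leave_bin_out",
                       pc_index=1, bin_index=2, n_reps=2, seed=0)
        out = run_al_experiment(cfg, al_data, model_family="gbm",
                                model_params={"n_estimators": 30})
        np.testing.assert_allclose(out.fraction_ood_sampled, 1.0)

    def test_whole_rmse_is_weighted_combination(self, al_data):
        """whole^2 = w*ood^2 + (1-w)*id^2 for each (rep, sampler)."""
        cfg = ALConfig(initial_fraction=0.1, n_add=40, sampler="uq_weighted",
                       uq_method="knn_density", scenario="leave_bin_out",
                       pc_index=1, bin_index=3, n_reps=2, seed=0)
        out = run_al_experiment(cfg, al_data, model_family="gbm",
                                model_params={"n_estimators": 30})
        df = out.results.pivot_table(index=["rep", "sampler"],
                                     columns="subset", values="rmse")
        for _, row in df.iterrows():
            lo = min(row["ood_bin"], row["id_bins"])
            hi = max(row["ood_bin"], row["id_bins"])
            assert lo - 1e-9 <= row["whole"] <= hi + 1e-9

    def test_deterministic_given_seed(self, al_data):
        cfg = ALConfig(initial_fraction=0.1, n_add=30, sampler="uq_weighted",
                       uq_method="knn_density", scenario="standard",
                       n_reps=2, seed=5)
        a = run_al_experiment(cfg, al_data, model_family="gbm",
                              model_params={"n_estimators": 30})
        b = run_al_experiment(cfg, al_data, model_family="gbm",
                              model_params={"n_estimators": 30})
        pd.testing.assert_frame_equal(a.results, b.results)


class TestGridBookkeeping:
    def test_default_grid_counts(self):
        """4 fractions x 6 batch sizes = 24 combinations; x 15 scenarios =
        360 experiments."""
        rows = []
        for f in DEFAULT_FRACTIONS:
            for n in DEFAULT_BATCH_SIZES:
                for pc in (1, 2, 3):
                    for b in range(1, 6):
                        rows.append({"initial_fraction": f, "n_add": n,
                                     "pc_index": pc, "bin_index": b,
                                     "improvement_pct_whole": 0.1})
        summary = al_grid_summary(pd.DataFrame(rows))
        assert summary["n_combinations"] == 24
        assert summary["n_scenarios"] == 15
        assert summary["n_experiments"] == 360

    def test_single_cell_summary_is_identity(self):
        df = pd.DataFrame([{"initial_fraction": 0.1, "n_add": 50,
                            "improvement_pct_whole": 2.5}])
        summary = al_grid_summary(df)
        assert summary["n_experiments"] == 1
        assert summary["by_fraction"].loc[0.1,
                                          "improvement_pct_whole"] == 2.5

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            al_grid_summary(pd.DataFrame())


class TestCorrelateALWithUQ:
    def _tables(self, improvements):
        metric = pd.DataFrame({
            "uq_method": ["a", "b", "c", "d"],
            "ence": [0.1, 0.4, 0.2, 0.9],
            "rho_error": [0.5, 0.1, 0.3, 0.2],
            "rho_ood": [0.9, 0.2, 0.5, 0.1],
            "rho_delta_error": [0.8, 0.1, 0.4, 0.0],
        })
        al = pd.DataFrame({"uq_method": ["a", "b", "c", "d"],
                           "improvement_pct_ood_bin": improvements})
        return metric, al

    def test_identity_column_correlates_to_one(self):
        metric, al = self._tables([0.9, 0.2, 0.5, 0.1])  # = rho_ood
        out = correlate_al_with_uq(metric, al)
        assert out.loc["rho_ood",
                       "improvement_pct_ood_bin"] == pytest.approx(1.0)

    def test_matches_brute_force(self):
        from scipy.stats import spearmanr
        metric, al = self._tables([0.3, 0.9, 0.1, 0.5])
        out = correlate_al_with_uq(metric, al)
        for m in ("ence", "rho_error", "rho_ood", "rho_delta_error"):
            want = spearmanr(metric[m], al["improvement_pct_ood_bin"]).statistic
            assert out.loc[m, "improvement_pct_ood_bin"] == pytest.approx(
                want, abs=1e-12)

    def test_too_few_methods_rejected(self):
        metric, al = self._tables([0.3, 0.9, 0.1, 0.5])
        with pytest.raises(InputError):
            correlate_al_with_uq(metric.iloc[:2], al.iloc[:2])
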