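"""Single-iteration uncertainty-weighted active learning.

The experiment: hold out a test set, optionally excise one PCA bin from the
initial training sample (the "generalization" scenario), train a model,
score the remaining candidate pool with an uncertainty estimator, draw a
batch with selection probability linear in the uncertainty (a molecule with
twice the uncertainty is twice as likely to be drawn), retrain on the
augmented set, and compare test RMSE against a seed-paired random batch.
Baselines: uniform random, diversity-weighted (mean pairwise distance in
embedding space), and an oracle that samples only from the removed bin.

Evaluation is on three test subsets — the removed (OOD) bin, the remaining
(ID) bins, and the whole test set — with percentage RMSE improvement over
the random arm and a paired one-sided t-test across repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from moluq.errors import (ConfigurationError, DegenerateError, InputError)
from moluq.ood import pca_top_bins
from moluq.regressors import RegressorSpec, fit_mean_gbm, train_regressor
from moluq.synthetic import MoleculeTable, similarity_matrix
from moluq.uq import (QuantilePrediction, gbm_quantile_uq, knn_density_uq,
                      mcdo_uq, mve_uq)
from moluq.regressors import fit_quantile_gbm

DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.40)
DEFAULT_BATCH_SIZES = (25, 50, 100, 250, 500, 1000)

SAMPLERS = ("uq_weighted", "random", "diversity", "ood_only")


@dataclass(frozen=True)
class ALConfig:
    """One cell of the active-learning experiment grid."""

    initial_fraction: float = 0.10
    n_add: int = 100
    sampler: str = "uq_weighted"
    uq_method: str = "knn_density"
    scenario: str = "standard"          # or "leave_bin_out"
    pc_index: int = 1
    bin_index: int = 1
    n_reps: int = 30
    seed: int = 0
    test_fraction: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.initial_fraction < 1.0:
            raise ConfigurationError("initial_fraction must be in (0, 1)")
        if self.n_add <= 0:
            raise ConfigurationError("n_add must be positive")
        if self.sampler not in SAMPLERS:
            raise ConfigurationError(f"unknown sampler {self.sampler!r}")
        if self.scenario not in ("standard", "leave_bin_out"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2 for paired t-tests")


@dataclass
class ALOutcome:
    """Per-repetition RMSEs and derived statistics for one grid cell."""

    config: ALConfig
    results: pd.DataFrame          # columns: rep, sampler, subset, rmse
    improvement_pct: dict          # subset -> % improvement of AL over random
    p_value: dict                  # subset -> one-sided paired p
    fraction_ood_sampled: np.ndarray = field(default_factory=lambda:
                                             np.array([]))

    def rmse_matrix(self, sampler: str, subset: str) -> np.ndarray:
        sub = self.results[(self.results["sampler"] == sampler)
                           & (self.results["subset"] == subset)]
        return sub.sort_values("rep")["rmse"].to_numpy()


# -- batch selection --------------------------------------------------------

def _weighted_without_replacement(weights: np.ndarray, n: int,
                                  rng: np.random.Generator) -> np.ndarray:
    """Sequential proportional draws with renormalization after each draw."""
    weights = np.asarray(weights, float)
    pool = np.flatnonzero(weights > 0)
    if len(pool) == 0:
        raise DegenerateError("all selection weights are zero")
    chosen = []
    w = weights[pool].astype(float)
    alive = np.ones(len(pool), bool)
    for _ in range(min(n, len(pool))):
        p = np.where(alive, w, 0.0)
        p = p / p.sum()
        pick = rng.choice(len(pool), p=p)
        alive[pick] = False
        chosen.append(pool[pick])
    if len(chosen) < n:
        # weights exhausted: fill uniformly from zero-weight members
        rest = np.setdiff1d(np.arange(len(weights)), np.asarray(chosen))
        warnings.warn("fewer positive-weight members than requested; "
                      "filling uniformly", RuntimeWarning, stacklevel=3)
        extra = rng.choice(rest, size=n - len(chosen), replace=False)
        chosen.extend(extra.tolist())
    return np.asarray(chosen, int)


def select_batch(pool_sigma: np.ndarray, pool_meta: dict, n: int,
                 strategy: str, rng: np.random.Generator) -> np.ndarray:
    """Draw a without-replacement batch of pool indices.

    ``pool_meta`` may carry ``embeddings`` (diversity strategy) and
    ``removed_mask`` (boolean, True for removed-bin members; ood_only
    strategy).  ``ood_only`` caps at the removed-bin pool size with a
    warning rather than failing.
    """
    pool_sigma = np.asarray(pool_sigma, float)
    m = len(pool_sigma)
    if n > m:
        raise InputError(f"cannot draw {n} from a pool of {m}")
    if n == m:
        return np.arange(m)
    if strategy == "random":
        return rng.choice(m, size=n, replace=False)
    if strategy == "uq_weighted":
        if np.all(pool_sigma == 0):
            raise DegenerateError("all pool uncertainties are zero")
        return _weighted_without_replacement(pool_sigma, n, rng)
    if strategy == "diversity":
        E = np.asarray(pool_meta["embeddings"], float)
        S = similarity_matrix(E, E)
        dist = 2.0 * (1.0 - S)
        np.fill_diagonal(dist, 0.0)
        weights = dist.sum(axis=1) / (m - 1)
        return _weighted_without_replacement(weights, n, rng)
    if strategy == "ood_only":
        mask = np.asarray(pool_meta["removed_mask"], bool)
        members = np.flatnonzero(mask)
        if len(members) == 0:
            raise DegenerateError("no removed-bin members in the pool")
        if n > len(members):
            warnings.warn(
                f"ood_only batch capped at {len(members)} (< {n})",
                RuntimeWarning, stacklevel=2)
            return members
        return rng.choice(members, size=n, replace=False)
    raise ConfigurationError(f"unknown strategy {strategy!r}")


# -- per-repetition machinery ----------------------------------------------

def _fit_predict(model_family: str, train: MoleculeTable, seed: int,
                 model_params: dict | None):
    """Train the evaluation model; returns (handle_or_model, predict_fn)."""
    params = dict(model_params or {})
    if model_family == "gbm":
        model = fit_mean_gbm(train, seed=seed, **params)
        return model, lambda X: model.predict(X)
    if model_family == "mlp":
        spec = params.pop("spec", RegressorSpec(hidden_sizes=(64, 32)))
        spec = spec.with_seed(seed)
        handle = train_regressor(spec, train, head="point")
        return handle, handle.predict
    raise ConfigurationError(f"unknown model_family {model_family!r}")


def _pool_sigma(uq_method: str, train: MoleculeTable, pool: MoleculeTable,
                model, model_family: str, seed: int,
                uq_params: dict | None) -> np.ndarray:
    """Score the candidate pool with the configured uncertainty estimator."""
    params = dict(uq_params or {})
    if uq_method == "knn_density":
        return knn_density_uq(train.X, pool.X, **params).sigma
    if uq_method == "knn_density_eb":
        return knn_density_uq(train.E, pool.E, **params).sigma
    if uq_method == "gbm":
        gbm_params = params.pop("gbm_params", {})
        lo = fit_quantile_gbm(train, 0.1, seed=seed, **gbm_params).predict(pool.X)
        hi = fit_quantile_gbm(train, 0.9, seed=seed, **gbm_params).predict(pool.X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return gbm_quantile_uq(QuantilePrediction(lo, hi),
                                   np.zeros(len(pool))).sigma
    if uq_method == "mcdo":
        if model_family != "mlp":
            raise ConfigurationError("mcdo uncertainty requires model_family='mlp'")
        return mcdo_uq(model, pool.X, seed=seed, **params).sigma
    if uq_method == "mve":
        spec = params.pop("spec", RegressorSpec(hidden_sizes=(64, 32)))
        handle = train_regressor(spec.with_seed(seed), train, head="mve")
        return mve_uq(handle, pool.X).sigma
    if uq_method == "none":
        return np.zeros(len(pool))
    raise ConfigurationError(f"unknown uq_method {uq_method!r}")


def run_al_experiment(config: ALConfig, data: MoleculeTable,
                      model_family: str = "gbm",
                      model_params: dict | None = None,
                      uq_params: dict | None = None) -> ALOutcome:
    """Run one grid cell: paired AL-vs-random over ``config.n_reps`` repetitions.

    Both arms share the initial training indices of each repetition (paired
    design); batch selection randomness is keyed by (seed, rep, strategy) so
    that a random-vs-random comparison is exactly zero.
    """
    n = len(data)
    rng_split = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(101,)))
    order = rng_split.permutation(n)
    n_test = int(round(config.test_fraction * n))
    test_idx = np.sort(order[:n_test])
    trainval_idx = np.sort(order[n_test:])

    if config.scenario == "leave_bin_out":
        assignment = pca_top_bins(data.X)[config.pc_index - 1]
        bin_members = set(assignment.members(config.bin_index).tolist())
    else:
        bin_members = set()

    eligible = np.array([i for i in trainval_idx if i not in bin_members], int)
    n_initial = max(2, int(round(config.initial_fraction * len(trainval_idx))))
    if n_initial > len(eligible):
        raise ConfigurationError("initial_fraction infeasible after bin removal")

    test_table = data.subset(test_idx)
    test_in_bin = np.array([i in bin_members for i in test_idx], bool)
    subsets = {"whole": np.ones(len(test_idx), bool),
               "id_bins": ~test_in_bin, "ood_bin": test_in_bin}

    arms = [config.sampler, "random"]
    rows = []
    frac_ood = []
    for rep in range(config.n_reps):
        rng_init = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(102, rep)))
        initial_idx = np.sort(rng_init.choice(eligible, size=n_initial,
                                              replace=False))
        pool_idx = np.setdiff1d(trainval_idx, initial_idx)
        train_table = data.subset(initial_idx)
        pool_table = data.subset(pool_idx)
        removed_mask = np.array([i in bin_members for i in pool_idx], bool)

        model, _ = _fit_predict(model_family, train_table,
                                config.seed * 1000 + rep, model_params)
        sigma = _pool_sigma(config.uq_method, train_table, pool_table, model,
                            model_family, config.seed * 1000 + rep, uq_params)
        meta = {"embeddings": pool_table.E, "removed_mask": removed_mask}

        seen = {}
        for arm in arms:
            if arm in seen:
                continue
            rng_sel = np.random.default_rng(np.random.SeedSequence(
                entropy=config.seed,
                spawn_key=(103, rep, SAMPLERS.index(arm))))
            batch = select_batch(sigma, meta, config.n_add, arm, rng_sel)
            seen[arm] = batch
            if arm == config.sampler:
                frac_ood.append(
                    fraction_ood_sampled(pool_idx[batch],
                                         np.array(sorted(bin_members), int))
                    if bin_members else 0.0)
            augmented = data.subset(np.sort(np.concatenate(
                [initial_idx, pool_idx[batch]])))
            _, predict = _fit_predict(model_family, augmented,
                                      config.seed * 1000 + rep, model_params)
            pred = predict(test_table.X)
            for name, mask in subsets.items():
                if mask.sum() == 0:
                    continue
                err = float(np.sqrt(np.mean(
                    (test_table.y[mask] - pred[mask]) ** 2)))
                rows.append({"rep": rep, "sampler": arm, "subset": name,
                             "rmse": err})

    results = pd.DataFrame(rows)
    improvement = {}
    pvals = {}
    for name in subsets:
        al = results[(results["sampler"] == config.sampler)
                     & (results["subset"] == name)].sort_values("rep")
        rd = results[(results["sampler"] == "random")
                     & (results["subset"] == name)].sort_values("rep")
        if len(al) == 0 or len(rd) == 0:
            continue
        a, r = al["rmse"].to_numpy(), rd["rmse"].to_numpy()
        improvement[name] = improvement_pct(a, r)
        pvals[name] = paired_one_sided_t(a, r)
    return ALOutcome(config, results, improvement, pvals,
                     np.asarray(frac_ood, float))


# -- statistics -------------------------------------------------------------

def improvement_pct(rmse_al: np.ndarray, rmse_random: np.ndarray) -> float:
    """Mean percentage RMSE decrease of the AL arm relative to random."""
    rmse_al = np.asarray(rmse_al, float)
    rmse_random = np.asarray(rmse_random, float)
    if rmse_al.shape != rmse_random.shape or rmse_al.size == 0:
        raise InputError("paired RMSE vectors must be aligned and nonempty")
    if np.any(rmse_random == 0):
        raise DegenerateError("random-arm RMSE of zero")
    return float(100.0 * np.mean((rmse_random - rmse_al) / rmse_random))


def paired_one_sided_t(rmse_al: np.ndarray, rmse_random: np.ndarray) -> float:
    """One-sided paired t-test p-value for mean(random - al) > 0.

    Returns nan (degenerate) when the differences have zero variance.
    """
    rmse_al = np.asarray(rmse_al, float)
    rmse_random = np.asarray(rmse_random, float)
    if rmse_al.shape != rmse_random.shape or rmse_al.size < 2:
        raise InputError("need >= 2 aligned pairs")
    d = rmse_random - rmse_al
    if np.allclose(d.std(ddof=1), 0.0):
        return float("nan")
    return float(stats.ttest_rel(rmse_random, rmse_al,
                                 alternative="greater").pvalue)


def fraction_ood_sampled(batch: np.ndarray, removed_idx: np.ndarray) -> float:
    """Fraction of the selected batch that belongs to the removed bin."""
    batch = np.asarray(batch)
    if batch.size == 0:
        raise InputError("empty batch")
    removed = set(np.asarray(removed_idx).tolist())
    return sum(1 for b in batch.tolist() if b in removed) / batch.size


def al_grid_summary(outcomes: pd.DataFrame) -> dict:
    """Aggregate a grid of AL outcomes.

    Expects one row per (initial_fraction, n_add, pc_index, bin_index, ...)
    cell with at least ``improvement_pct_*`` columns.  Returns aggregate
    tables by initial fraction and by batch size plus enumeration counts.
    """
    if len(outcomes) == 0:
        raise InputError("empty outcome table")
    imp_cols = [c for c in outcomes.columns if c.startswith("improvement_pct")]
    by_fraction = outcomes.groupby("initial_fraction")[imp_cols].mean()
    by_batch = outcomes.groupby("n_add")[imp_cols].mean()
    n_comb = outcomes[["initial_fraction", "n_add"]].drop_duplicates().shape[0]
    if {"pc_index", "bin_index"}.issubset(outcomes.columns):
        n_scen = outcomes[["pc_index", "bin_index"]].drop_duplicates().shape[0]
    else:
        n_scen = 1
    return {"by_fraction": by_fraction, "by_batch_size": by_batch,
            "n_combinations": n_comb, "n_scenarios": n_scen,
            "n_experiments": n_comb * n_scen, "table": outcomes}


def correlate_al_with_uq(metric_table: pd.DataFrame, al_table: pd.DataFrame,
                         metric_cols=("ence", "rho_error", "rho_ood",
                                      "rho_delta_error")) -> pd.DataFrame:
    """Correlate UQ metrics with AL improvement across estimators.

    Both tables are keyed by ``uq_method``; improvement columns are every
    ``improvement_pct_*`` column in ``al_table``.  Requires >= 3 matched
    methods; returns a metrics-by-subsets table of Spearman correlations.
    """
    from moluq.metrics import spearman  # local import avoids a cycle

    merged = metric_table.merge(al_table, on="uq_method")
    if len(merged) < 3:
        raise InputError("need at least 3 matched uq methods")
    imp_cols = [c for c in merged.columns if c.startswith("improvement_pct")]
    out = pd.DataFrame(index=list(metric_cols), columns=imp_cols, dtype=float)
    for mc in metric_cols:
        for ic in imp_cols:
            sub = merged[[mc, ic]].apply(pd.to_numeric,
                                         errors="coerce").dropna()
            if len(sub) >= 3:
                try:
                    out.loc[mc, ic] = spearman(sub[mc].to_numpy(),
                                               sub[ic].to_numpy())
                except DegenerateError:
                    out.loc[mc, ic] = np.nan
    return out
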