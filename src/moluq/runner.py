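"""End-to-end study orchestration: UQ evaluation and the AL grid.

A :class:`StudyConfig` (constructed directly or loaded from YAML) drives
three entry points:

* :func:`run_uq_evaluation` — train every configured estimator once, score
  the four metrics (ENCE, rho_error, rho_ood, rho_delta_error) and emit a
  benchmark table with one row per estimator.
* :func:`run_al_grid` — execute the (initial fraction x batch size x
  scenario) active-learning grid with paired random baselines.
* :func:`write_report` — persist tables as CSV/JSON with a run manifest.

Per-scenario artifacts are cached as JSON keyed by a config hash so an
interrupted run resumes without recomputing finished cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from moluq import __version__
from moluq.active_learning import ALConfig, run_al_experiment
from moluq.errors import ConfigurationError, InputError
from moluq.metrics import (MetricSuite, ence, rho_delta_error, rho_error,
                           rho_ood, rmse)
from moluq.ood import (OODPool, leave_bin_out, pca_top_bins,
                       similarity_to_training, uniform_similarity_sample)
from moluq.regressors import (RegressorSpec, fit_mean_gbm, fit_quantile_gbm,
                              train_regressor)
from moluq.synthetic import MoleculeTable, SyntheticConfig, generate_dataset, \
    make_ood_pool
from moluq.uq import (QuantilePrediction, UQEstimate, consensus_uq,
                      ensemble_uq, evidential_uq, gbm_quantile_uq,
                      knn_density_uq, mcdo_uq, mve_uq, union_uq)

log = logging.getLogger("moluq")

UQ_METHODS = ("gbm", "ensemble", "mcdo", "mve", "evidential", "union",
              "knn_density", "knn_density_eb", "consensus")


@dataclass
class StudyConfig:
    """Configuration of a full synthetic benchmark study."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    regressor: RegressorSpec = field(
        default_factory=lambda: RegressorSpec(hidden_sizes=(64, 32),
                                              max_epochs=150))
    uq_methods: tuple[str, ...] = ("gbm", "mcdo", "mve", "knn_density")
    ensemble_size: int = 5
    mcdo_passes: int = 30
    ence_bins: int = 10
    n_pool: int = 2000
    pool_sample: int = 500
    delta_components: int = 1      # PCs used for the leave-bin-out sweep
    gbm_params: dict = field(default_factory=lambda: {"n_estimators": 200})
    al_fractions: tuple[float, ...] = (0.10,)
    al_batch_sizes: tuple[int, ...] = (50, 100)
    al_samplers: tuple[str, ...] = ("uq_weighted", "ood_only")
    al_uq_method: str = "knn_density"
    al_scenarios: tuple[tuple[int, int], ...] = ((1, 1), (1, 3), (1, 5))
    al_reps: int = 5
    outdir: Path = Path("moluq_out")
    seed: int = 0

    def __post_init__(self):
        for m in self.uq_methods:
            if m not in UQ_METHODS:
                raise ConfigurationError(
                    f"unknown uq method {m!r}; valid: {sorted(UQ_METHODS)}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "regressor" in raw and isinstance(raw["regressor"], dict):
            spec = raw["regressor"]
            if "hidden_sizes" in spec:
                spec["hidden_sizes"] = tuple(spec["hidden_sizes"])
            raw["regressor"] = RegressorSpec(**spec)
        for key in ("uq_methods", "al_fractions", "al_batch_sizes",
                    "al_samplers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "al_scenarios" in raw:
            raw["al_scenarios"] = tuple(tuple(s) for s in raw["al_scenarios"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _split_indices(n: int, seed: int):
    """Deterministic 70/10/20 train/val/test split."""
    order = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(201,))).permutation(n)
    n_test = int(round(0.2 * n))
    n_val = int(round(0.1 * n))
    return (np.sort(order[n_test + n_val:]),
            np.sort(order[n_test:n_test + n_val]),
            np.sort(order[:n_test]))


class _EstimatorBank:
    """Builds per-method UQ estimates for an arbitrary (train, val) pair.

    One bank instance per training partition; neural models are trained
    lazily and shared between the methods that need them.
    """

    def __init__(self, study: StudyConfig, train: MoleculeTable,
                 val: MoleculeTable, seed: int):
        self.study = study
        self.train = train
        self.val = val
        self.seed = seed
        self._models = {}

    def _model(self, head: str):
        if head not in self._models:
            spec = self.study.regressor.with_seed(self.seed)
            self._models[head] = train_regressor(spec, self.train, self.val,
                                                 head=head)
        return self._models[head]

    def estimate(self, method: str, query_X: np.ndarray,
                 query_E: np.ndarray | None = None) -> UQEstimate:
        s = self.study
        if method == "gbm":
            mean = fit_mean_gbm(self.train, seed=self.seed,
                                **s.gbm_params).predict(query_X)
            lo = fit_quantile_gbm(self.train, 0.1,
                                  seed=self.seed).predict(query_X)
            hi = fit_quantile_gbm(self.train, 0.9,
                                  seed=self.seed).predict(query_X)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return gbm_quantile_uq(QuantilePrediction(lo, hi), mean)
        if method == "ensemble":
            specs = [s.regressor.with_seed(self.seed + 1 + m)
                     for m in range(s.ensemble_size)]
            return ensemble_uq(specs, self.train, self.val, query_X)
        if method == "mcdo":
            return mcdo_uq(self._model("point"), query_X,
                           n_passes=s.mcdo_passes, seed=self.seed)
        if method == "mve":
            return mve_uq(self._model("mve"), query_X)
        if method == "evidential":
            return evidential_uq(self._model("evidential"), query_X)
        if method == "union":
            return union_uq(self._model("point"), self.train, query_X,
                            seed=self.seed)
        if method == "knn_density":
            return knn_density_uq(self.train.X, query_X,
                                  mean=self._model("point").predict(query_X))
        if method == "knn_density_eb":
            if query_E is None:
                raise InputError("embedding representation required")
            return knn_density_uq(self.train.E, query_E,
                                  mean=self._model("point").predict(query_X),
                                  method="knn_density_eb")
        if method == "consensus":
            members = [self.estimate(m, query_X) for m in
                       ("gbm", "mcdo", "mve")]
            return consensus_uq(members)
        raise ConfigurationError(
            f"unknown uq method {method!r}; valid: {sorted(UQ_METHODS)}")


def run_uq_evaluation(study: StudyConfig) -> pd.DataFrame:
    """Score every configured estimator on the four benchmark metrics.

    Returns a table shaped like the benchmark report: one row per method
    with columns (method, model, ence, rho_error, rho_ood,
    rho_delta_error); density methods carry ``NA`` in the ENCE column.
    """
    cache_dir = study.outdir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(study.synthetic)
    train_idx, val_idx, test_idx = _split_indices(len(data), study.seed)
    train, val, test = (data.subset(i) for i in
                        (train_idx, val_idx, test_idx))

    raw_pool = make_ood_pool(study.synthetic, train, study.n_pool)
    sim = similarity_to_training(raw_pool.X, train, seed=study.seed)
    pool = uniform_similarity_sample(OODPool(raw_pool, sim),
                                     study.pool_sample, seed=study.seed)

    assignments = pca_top_bins(data.X)[: study.delta_components]
    full_split = (train_idx, val_idx, test_idx)
    full_bank = _EstimatorBank(study, train, val, study.seed)

    # bin-removed banks are shared across methods (cache by scenario)
    removed_banks = {}
    scen_splits = {}
    for assignment in assignments:
        for b in range(1, assignment.n_bins + 1):
            key = (assignment.pc_index, b)
            scen_splits[key] = leave_bin_out(full_split, assignment, b)

    suites = []
    for method in study.uq_methods:
        cache_file = cache_dir / f"uq_{method}_{study.config_hash()}.json"
        if cache_file.exists():
            suites.append(MetricSuite(**json.loads(cache_file.read_text())))
            log.info("loaded cached metrics for %s", method)
            continue
        log.info("evaluating %s", method)
        est_test = full_bank.estimate(method, test.X, test.E)
        est_pool = full_bank.estimate(method, pool.pool.X, pool.pool.E)
        suite = MetricSuite(method=method, model="ff" if method != "gbm"
                            else "gbm")
        cal = ence(est_test, test.y, n_bins=study.ence_bins)
        suite.ence = cal.ence if cal.applicable else math.nan
        suite.rho_error = rho_error(est_test, test.y)
        suite.rho_ood = rho_ood(est_pool, pool)

        records = []
        for (pc, b), split in scen_splits.items():
            if (pc, b) not in removed_banks:
                removed_banks[(pc, b)] = _EstimatorBank(
                    study, data.subset(split.train_idx),
                    data.subset(split.val_idx), study.seed)
            bank_r = removed_banks[(pc, b)]
            assignment = assignments[pc - 1]
            in_bin = np.isin(test_idx, assignment.members(b))
            sub = test.subset(np.flatnonzero(in_bin))
            e_full = full_bank.estimate(method, sub.X, sub.E)
            e_rem = bank_r.estimate(method, sub.X, sub.E)
            records.append({
                "pc_index": pc, "bin_index": b,
                "rmse_full": rmse(sub.y, e_full.mean),
                "rmse_removed": rmse(sub.y, e_rem.mean),
                "uq_full": float(e_full.sigma.mean()),
                "uq_removed": float(e_rem.sigma.mean()),
            })
        suite.rho_delta_error, _ = rho_delta_error(records)
        cache_file.write_text(json.dumps(dataclasses.asdict(suite)))
        suites.append(suite)

    return pd.DataFrame([s.to_row() for s in suites])


def run_al_grid(study: StudyConfig, model_params: dict | None = None
                ) -> pd.DataFrame:
    """Execute the configured active-learning grid.

    One row per (fraction, batch size, scenario, sampler) with improvement
    percentages, one-sided p-values and the mean OOD fraction sampled.
    Failed cells are recorded and the run continues.
    """
    cache_dir = study.outdir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(study.synthetic)
    model_params = model_params or {"n_estimators": 100}
    rows = []
    for frac in study.al_fractions:
        for n_add in study.al_batch_sizes:
            for pc, b in study.al_scenarios:
                for sampler in study.al_samplers:
                    tag = f"al_{frac}_{n_add}_{pc}_{b}_{sampler}"
                    cache_file = cache_dir / (
                        f"{tag}_{study.config_hash()}.json")
                    if cache_file.exists():
                        rows.append(json.loads(cache_file.read_text()))
                        continue
                    cfg = ALConfig(initial_fraction=frac, n_add=n_add,
                                   sampler=sampler,
                                   uq_method=study.al_uq_method,
                                   scenario="leave_bin_out", pc_index=pc,
                                   bin_index=b, n_reps=study.al_reps,
                                   seed=study.seed)
                    try:
                        out = run_al_experiment(cfg, data,
                                                model_family="gbm",
                                                model_params=model_params)
                    except Exception as exc:  # record and continue
                        log.warning("cell %s failed: %s", tag, exc)
                        rows.append({"initial_fraction": frac, "n_add": n_add,
                                     "pc_index": pc, "bin_index": b,
                                     "sampler": sampler, "failed": str(exc)})
                        continue
                    row = {"initial_fraction": frac, "n_add": n_add,
                           "pc_index": pc, "bin_index": b, "sampler": sampler,
                           "uq_method": study.al_uq_method, "failed": ""}
                    for subset, v in out.improvement_pct.items():
                        row[f"improvement_pct_{subset}"] = v
                    for subset, v in out.p_value.items():
                        row[f"p_{subset}"] = v
                    row["mean_fraction_ood"] = (
                        float(out.fraction_ood_sampled.mean())
                        if out.fraction_ood_sampled.size else math.nan)
                    cache_file.write_text(json.dumps(_jsonable(row)))
                    rows.append(row)
    return pd.DataFrame(rows)


def write_report(tables: dict[str, pd.DataFrame], outdir: str | Path,
                 manifest_extra: dict | None = None) -> list[Path]:
    """Write each table as CSV plus a JSON run manifest; returns the paths."""
    if not tables:
        raise InputError("no tables to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        if table is None or len(table) == 0:
            raise InputError(f"table {name!r} is empty")
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=isinstance(table.index, pd.MultiIndex)
                     or table.index.name is not None)
        written.append(path)
    manifest = {"moluq_version": __version__,
                "numpy_version": np.__version__,
                "tables": [p.name for p in written]}
    manifest.update(manifest_extra or {})
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(_jsonable(manifest), indent=2))
    written.append(mpath)
    return written
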