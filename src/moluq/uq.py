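"""The uncertainty estimators and their common per-molecule contract.

Every estimator returns a :class:`UQEstimate`: a predicted mean, a
nonnegative per-molecule uncertainty ``sigma``, and a ``calibrated`` flag.
Calibrated estimators report sigma on the error scale (a standard
deviation in target units) so that calibration metrics apply; the kNN
density scores are relative only and carry ``calibrated=False``.

Estimators
----------
- quantile-GBM half-interval: sigma = (P90 - P10) / 2
- ensemble: population sd of point predictions across seeds
- Monte Carlo dropout: population sd across stochastic forward passes
- mean-variance estimation (MVE): sqrt of the predicted variance
- deep evidential regression: sqrt of a Normal-Inverse-Gamma variance
  component (aleatoric E[sigma^2] = beta/(alpha-1), epistemic
  Var[mu] = beta/(upsilon (alpha-1)), or their sum)
- union: quantile GBMs fit on the network's last-layer features
- kNN density: mean cosine distance to the 3 nearest training rows
- consensus: elementwise average of several calibrated estimates
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.neighbors import NearestNeighbors

from moluq.errors import (ConfigurationError, DomainError, InputError,
                          UnsupportedModelError)
from moluq.regressors import (RegressorHandle, RegressorSpec, train_regressor,
                              extract_last_layer, fit_quantile_gbm)
from moluq.synthetic import MoleculeTable


@dataclass
class UQEstimate:
    """Per-molecule prediction and uncertainty under a common contract."""

    ids: list[str]
    mean: np.ndarray
    sigma: np.ndarray
    calibrated: bool
    method: str

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.sigma = np.asarray(self.sigma, float)
        if not (len(self.ids) == len(self.mean) == len(self.sigma)):
            raise InputError("ids, mean and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise InputError("sigma must be nonnegative")

    def __len__(self):
        return len(self.ids)


@dataclass
class QuantilePrediction:
    """Lower/upper quantile predictions (default 10% and 90%)."""

    pred_lo: np.ndarray
    pred_hi: np.ndarray

    def __post_init__(self):
        self.pred_lo = np.asarray(self.pred_lo, float)
        self.pred_hi = np.asarray(self.pred_hi, float)
        if self.pred_lo.shape != self.pred_hi.shape:
            raise InputError("quantile vectors must be aligned")


@dataclass(frozen=True)
class NIGParams:
    """Normal-Inverse-Gamma parameters for one molecule."""

    gamma: float
    upsilon: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.upsilon <= 0 or self.beta <= 0:
            raise DomainError("upsilon and beta must be positive")
        if self.alpha <= 1:
            raise DomainError("alpha must exceed 1 for finite moments")


def _default_ids(n: int) -> list[str]:
    return [f"q_{i:06d}" for i in range(n)]


# -- quantile interval -----------------------------------------------------

def gbm_quantile_uq(q: QuantilePrediction, mean_pred: np.ndarray,
                    ids: list[str] | None = None,
                    method: str = "gbm") -> UQEstimate:
    """Half the 10-90% interquantile range as the uncertainty.

    Crossed quantiles (upper below lower) are clipped to zero with a warning.
    """
    mean_pred = np.asarray(mean_pred, float)
    if mean_pred.shape != q.pred_lo.shape:
        raise InputError("mean_pred not aligned with quantile predictions")
    width = (q.pred_hi - q.pred_lo) / 2.0
    n_crossed = int(np.sum(width < 0))
    if n_crossed:
        warnings.warn(f"{n_crossed} crossed quantile pairs clipped to sigma=0",
                      RuntimeWarning, stacklevel=2)
    sigma = np.maximum(width, 0.0)
    return UQEstimate(ids or _default_ids(len(sigma)), mean_pred, sigma,
                      calibrated=True, method=method)


# -- ensembles and dropout --------------------------------------------------

def ensemble_uq(specs: list[RegressorSpec], train: MoleculeTable,
                val: MoleculeTable | None, X_query: np.ndarray,
                head: str = "point",
                ids: list[str] | None = None) -> UQEstimate:
    """Mean and population sd of point predictions over an ensemble of seeds."""
    if len(specs) < 2:
        raise ConfigurationError("an ensemble needs at least 2 members")
    preds = np.stack([
        train_regressor(s, train, val, head=head).predict(X_query)
        for s in specs])
    return UQEstimate(ids or _default_ids(preds.shape[1]),
                      preds.mean(axis=0), preds.std(axis=0, ddof=0),
                      calibrated=True, method="ensemble")


def mcdo_uq(model: RegressorHandle, X_query: np.ndarray, n_passes: int = 30,
            dropout_rate: float | None = None, seed: int = 0,
            ids: list[str] | None = None) -> UQEstimate:
    """Monte Carlo dropout: sd over stochastic forward passes.

    Deterministic given ``seed``.  A dropout rate of zero yields zero
    uncertainty everywhere (no stochasticity to sample).
    """
    if not isinstance(model, RegressorHandle):
        raise UnsupportedModelError("mcdo requires a feedforward model handle")
    if n_passes < 2:
        raise ConfigurationError("mcdo needs at least 2 passes")
    preds = model.predict_stochastic(X_query, n_passes, seed=seed,
                                     dropout_rate=dropout_rate)
    return UQEstimate(ids or _default_ids(preds.shape[1]),
                      preds.mean(axis=0), preds.std(axis=0, ddof=0),
                      calibrated=True, method="mcdo")


# -- mean-variance estimation ----------------------------------------------

def mve_nll_loss(y: float, mu: float, sigma2: float) -> float:
    """Gaussian negative log-likelihood of one observation."""
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    return float(0.5 * np.log(2 * np.pi) + 0.5 * np.log(sigma2)
                 + (y - mu) ** 2 / (2 * sigma2))


def mve_uq(model: RegressorHandle, X_query: np.ndarray,
           ids: list[str] | None = None) -> UQEstimate:
    """Predicted mean and sd from a mean-variance head."""
    mu, var = model.predict_mve(X_query)
    return UQEstimate(ids or _default_ids(len(mu)), mu, np.sqrt(var),
                      calibrated=True, method="mve")


# -- evidential regression --------------------------------------------------

def nig_log_density(mu: float, sigma2: float, p: NIGParams) -> float:
    """Log Normal-Inverse-Gamma density at (mu, sigma2).

    ``p(mu, sigma2) = beta^alpha sqrt(upsilon) / (Gamma(alpha)
    sqrt(2 pi sigma2)) * (1/sigma2)^(alpha+1)
    * exp(-(2 beta + upsilon (gamma - mu)^2) / (2 sigma2))``
    """
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    return float(
        p.alpha * np.log(p.beta) + 0.5 * np.log(p.upsilon)
        - gammaln(p.alpha) - 0.5 * np.log(2 * np.pi * sigma2)
        - (p.alpha + 1) * np.log(sigma2)
        - (2 * p.beta + p.upsilon * (p.gamma - mu) ** 2) / (2 * sigma2))


def nig_moments(p: NIGParams):
    """(predicted mean, aleatoric variance, epistemic variance).

    E[mu] = gamma; E[sigma^2] = beta / (alpha - 1);
    Var[mu] = beta / (upsilon (alpha - 1)).
    """
    if p.alpha <= 1:
        raise DomainError("alpha must exceed 1 for finite moments")
    aleatoric = p.beta / (p.alpha - 1.0)
    return p.gamma, aleatoric, aleatoric / p.upsilon


def evidential_uq(model: RegressorHandle, X_query: np.ndarray,
                  report: str = "epistemic",
                  ids: list[str] | None = None) -> UQEstimate:
    """Evidential uncertainty: sqrt of the chosen NIG variance component."""
    if report not in ("epistemic", "aleatoric", "total"):
        raise ConfigurationError(f"unknown report kind {report!r}")
    d = model.predict_evidential(X_query)
    aleatoric = d["beta"] / (d["alpha"] - 1.0)
    epistemic = aleatoric / d["upsilon"]
    var = {"epistemic": epistemic, "aleatoric": aleatoric,
           "total": aleatoric + epistemic}[report]
    return UQEstimate(ids or _default_ids(len(var)), d["gamma"], np.sqrt(var),
                      calibrated=True, method=f"evidential_{report}")


# -- union (last-layer features into quantile GBMs) -------------------------

def union_uq(model: RegressorHandle, train: MoleculeTable,
             X_query: np.ndarray, quantiles: tuple[float, float] = (0.1, 0.9),
             seed: int = 0, ids: list[str] | None = None,
             **gbm_overrides) -> UQEstimate:
    """Quantile GBMs on the network's last-layer features.

    The neural model's own prediction is the reported mean; the GBMs,
    trained on (last-layer features, y), provide the interval width.
    """
    H_train = extract_last_layer(model, train.X)
    H_query = extract_last_layer(model, X_query)
    lo = fit_quantile_gbm((H_train, train.y), quantiles[0], seed=seed,
                          **gbm_overrides).predict(H_query)
    hi = fit_quantile_gbm((H_train, train.y), quantiles[1], seed=seed,
                          **gbm_overrides).predict(H_query)
    est = gbm_quantile_uq(QuantilePrediction(lo, hi), model.predict(X_query),
                          ids=ids, method="union")
    return est


# -- density / applicability domain -----------------------------------------

def knn_density_uq(train_reps: np.ndarray, query_reps: np.ndarray, k: int = 3,
                   mean: np.ndarray | None = None,
                   ids: list[str] | None = None,
                   method: str = "knn_density") -> UQEstimate:
    """Mean cosine distance to the k nearest training representations.

    A relative applicability-domain score in [0, 2]; ``calibrated=False``
    because it carries no error-scale information.
    """
    train_reps = np.asarray(train_reps, float)
    query_reps = np.asarray(query_reps, float)
    if train_reps.shape[0] < k:
        raise ConfigurationError(
            f"need at least k={k} training rows, got {train_reps.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k, metric="cosine").fit(train_reps)
    dist, _ = nn.kneighbors(query_reps)
    sigma = np.maximum(dist.mean(axis=1), 0.0)  # guards tiny negative fp error
    n = query_reps.shape[0]
    if mean is None:
        mean = np.zeros(n)
    return UQEstimate(ids or _default_ids(n), mean, sigma,
                      calibrated=False, method=method)


# -- consensus ---------------------------------------------------------------

def consensus_uq(estimates: list[UQEstimate]) -> UQEstimate:
    """Elementwise average of aligned calibrated estimates."""
    if len(estimates) < 2:
        raise ConfigurationError("consensus needs at least 2 estimates")
    ids = estimates[0].ids
    for e in estimates[1:]:
        if e.ids != ids:
            raise InputError("consensus inputs must share aligned ids")
    if not all(e.calibrated for e in estimates):
        raise InputError("consensus requires calibrated estimates")
    mean = np.mean([e.mean for e in estimates], axis=0)
    sigma = np.mean([e.sigma for e in estimates], axis=0)
    tag = "consensus(" + ",".join(e.method for e in estimates) + ")"
    return UQEstimate(list(ids), mean, sigma, calibrated=True, method=tag)
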