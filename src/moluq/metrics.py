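"""Evaluation metrics for per-molecule uncertainty estimates.

Four metrics, as used throughout the benchmark:

ENCE
    Expected Normalized Calibration Error.  Samples are sorted by predicted
    uncertainty into N equal-count bins; per bin the root mean variance
    ``RMV(j) = sqrt(mean(sigma_t^2))`` is compared with the empirical
    ``RMSE(j)``, and ``ENCE = mean_j |RMV(j) - RMSE(j)| / RMV(j)``.
    Only defined for calibrated (error-scale) estimates.
rho_error
    Spearman rank correlation between per-sample absolute error and sigma.
rho_ood
    Spearman rank correlation between sigma and (1 - similarity to the
    training set) on a similarity-uniform candidate pool; positive values
    mean dissimilar molecules receive higher uncertainty.
rho_delta_error
    Across leave-bin-out scenarios, the Spearman correlation between the
    change in removed-bin RMSE and the change in removed-bin mean
    uncertainty when the bin is excised from training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from moluq.errors import DegenerateError, InputError
from moluq.ood import OODPool, _rank_bins
from moluq.uq import UQEstimate


@dataclass
class CalibrationBins:
    """Per-bin calibration summary plus the scalar ENCE."""

    n_bins: int
    sigma_lo: np.ndarray
    sigma_hi: np.ndarray
    counts: np.ndarray
    rmv: np.ndarray
    rmse: np.ndarray
    ence: float
    applicable: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sigma_lo": self.sigma_lo, "sigma_hi": self.sigma_hi,
            "count": self.counts, "rmv": self.rmv, "rmse": self.rmse,
        })


@dataclass
class MetricSuite:
    """One row of the benchmark report: the four metrics for one estimator."""

    method: str
    model: str = ""
    ence: float = math.nan         # nan encodes "not applicable"
    rho_error: float = math.nan
    rho_ood: float = math.nan
    rho_delta_error: float = math.nan

    def to_row(self) -> dict:
        def fmt(v):
            return "NA" if (v is None or (isinstance(v, float)
                                          and math.isnan(v))) else v
        return {"method": self.method, "model": self.model,
                "ence": fmt(self.ence), "rho_error": fmt(self.rho_error),
                "rho_ood": fmt(self.rho_ood),
                "rho_delta_error": fmt(self.rho_delta_error)}


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared residual."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred must be aligned")
    if y_true.size == 0:
        raise InputError("rmse of an empty vector is undefined")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def ence(estimate: UQEstimate, y_true: np.ndarray,
         n_bins: int = 10) -> CalibrationBins:
    """Expected Normalized Calibration Error over equal-count sigma bins.

    Uncalibrated estimates (relative scores such as kNN density) yield a
    not-applicable result with ``ence = nan``.
    """
    y_true = np.asarray(y_true, float)
    if len(estimate) != len(y_true):
        raise InputError("estimate and y_true must be aligned")
    if not estimate.calibrated:
        empty = np.full(n_bins, np.nan)
        return CalibrationBins(n_bins, empty, empty,
                               np.zeros(n_bins, int), empty, empty,
                               ence=math.nan, applicable=False)
    if len(estimate) < n_bins:
        raise InputError("need at least n_bins samples")
    labels = _rank_bins(estimate.sigma, n_bins)
    err2 = (y_true - estimate.mean) ** 2
    lo = np.empty(n_bins)
    hi = np.empty(n_bins)
    counts = np.empty(n_bins, int)
    rmv = np.empty(n_bins)
    rmse_j = np.empty(n_bins)
    for b in range(1, n_bins + 1):
        members = labels == b
        s = estimate.sigma[members]
        lo[b - 1], hi[b - 1] = s.min(), s.max()
        counts[b - 1] = members.sum()
        rmv[b - 1] = math.sqrt(float(np.mean(s ** 2)))
        rmse_j[b - 1] = math.sqrt(float(np.mean(err2[members])))
    if np.any(rmv == 0.0):
        raise DegenerateError("a calibration bin has RMV = 0")
    val = float(np.mean(np.abs(rmv - rmse_j) / rmv))
    return CalibrationBins(n_bins, lo, hi, counts, rmv, rmse_j, ence=val)


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (Pearson on average ranks, ties averaged)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise InputError("need two aligned vectors of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise DegenerateError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(a, b).statistic)


def rho_error(estimate: UQEstimate, y_true: np.ndarray) -> float:
    """Rank correlation between per-sample |error| and sigma."""
    y_true = np.asarray(y_true, float)
    if len(estimate) != len(y_true):
        raise InputError("estimate and y_true must be aligned")
    return spearman(np.abs(y_true - estimate.mean), estimate.sigma)


def rho_ood(estimate_on_pool: UQEstimate, pool: OODPool) -> float:
    """Rank correlation between sigma and dissimilarity to the training set.

    Computed as Spearman(sigma, 1 - similarity) on a similarity-uniform
    pool, so that positive values mean molecules far from the training data
    are assigned higher uncertainty.
    """
    if len(estimate_on_pool) != len(pool):
        raise InputError("estimate and pool must be aligned")
    return spearman(estimate_on_pool.sigma, 1.0 - pool.similarity)


def rho_delta_error(scenarios) -> tuple[float, pd.DataFrame]:
    """Correlation of Delta-RMSE with Delta-UQ across leave-bin-out scenarios.

    Each scenario record holds, for one (component, bin) pair and evaluated
    on the removed bin's test molecules: RMSE and mean sigma under the full
    model and under the bin-removed model.  Returns the Spearman correlation
    over the scenario points plus the per-scenario table.
    """
    rows = []
    for rec in scenarios:
        missing = [k for k in ("pc_index", "bin_index", "rmse_full",
                               "rmse_removed", "uq_full", "uq_removed")
                   if k not in rec]
        if missing:
            raise InputError(f"scenario record missing fields {missing}")
        rows.append({
            "pc_index": rec["pc_index"], "bin_index": rec["bin_index"],
            "delta_rmse": rec["rmse_removed"] - rec["rmse_full"],
            "delta_uq": rec["uq_removed"] - rec["uq_full"],
        })
    if not rows:
        raise InputError("no scenarios supplied")
    table = pd.DataFrame(rows)
    rho = spearman(table["delta_rmse"].to_numpy(),
                   table["delta_uq"].to_numpy())
    return rho, table


_METRIC_COLS = ("ence", "rho_error", "rho_ood", "rho_delta_error")


def metric_cross_correlation(suites, columns=_METRIC_COLS) -> pd.DataFrame:
    """Pairwise rank correlation between metric columns across estimators.

    ``suites`` is an iterable of :class:`MetricSuite` or a DataFrame with
    the metric columns.  Pairs are computed over rows where both metrics are
    present; a constant or insufficient column yields nan in its cells.
    """
    if isinstance(suites, pd.DataFrame):
        df = suites
    else:
        df = pd.DataFrame([{c: getattr(s, c) for c in columns}
                           for s in suites])
    if len(df) < 3:
        raise InputError("need at least 3 rows")
    for c in columns:
        if c not in df.columns or df[c].isna().all():
            raise InputError(f"metric column {c!r} is missing or all-NA")
    out = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    for i, ci in enumerate(columns):
        for j, cj in enumerate(columns):
            if i >= j:
                continue
            sub = df[[ci, cj]].dropna()
            try:
                r = spearman(sub[ci].to_numpy(), sub[cj].to_numpy())
            except (DegenerateError, InputError):
                r = math.nan
            out.loc[ci, cj] = out.loc[cj, ci] = r
    return out
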