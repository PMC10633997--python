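"""Property-prediction models: descriptor feedforward nets and quantile GBMs.

The feedforward regressor (the analogue of a descriptor-based "MDM") is a
ReLU network trained on z-scored descriptors with one of three heads: a
plain point-prediction head, a mean-variance head, or an evidential
(Normal-Inverse-Gamma) head.  The gradient-boosting models are LightGBM
trees fit to the pinball loss at a chosen quantile, or to squared error for
a mean model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import lightgbm as lgb

# lightgbm's sklearn wrapper registers auto-generated feature names even for
# ndarray input, making sklearn warn on every ndarray predict; pure noise here
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names",
    category=UserWarning)

from moluq.errors import ConfigurationError, InputError, UnsupportedModelError
from moluq.nnet import FeedForward
from moluq.synthetic import MoleculeTable


@dataclass(frozen=True)
class RegressorSpec:
    """Hyper-parameters of the feedforward regressor."""

    hidden_sizes: tuple[int, ...] = (128, 64)
    dropout_rate: float = 0.2
    max_epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 128
    early_stop_patience: int = 20
    evid_lambda: float = 0.05   # evidence-regularizer weight (evidential head)
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_sizes) < 1 or any(h <= 0 for h in self.hidden_sizes):
            raise ConfigurationError("hidden_sizes must be positive integers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        for name in ("max_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.early_stop_patience < 0:
            raise ConfigurationError("early_stop_patience must be >= 0")

    def with_seed(self, seed: int) -> "RegressorSpec":
        return RegressorSpec(**{**asdict(self), "seed": seed})


@dataclass
class PredictionSet:
    """Aligned true/predicted target vectors for a set of molecules."""

    ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self):
        if not (len(self.ids) == len(self.y_true) == len(self.y_pred)):
            raise InputError("ids, y_true and y_pred must have equal length")
        if not (np.all(np.isfinite(self.y_true))
                and np.all(np.isfinite(self.y_pred))):
            raise InputError("predictions must be finite")


class RegressorHandle:
    """A trained feedforward model plus its feature/target scalers.

    Predictions are returned in original target units; the network itself is
    trained in z-scored space for both features and target.
    """

    def __init__(self, net: FeedForward, spec: RegressorSpec, head: str,
                 x_mean, x_sd, y_mean, y_sd, fit_info=None):
        self.net = net
        self.spec = spec
        self.head = head
        self.x_mean = np.asarray(x_mean, float)
        self.x_sd = np.asarray(x_sd, float)
        self.y_mean = float(y_mean)
        self.y_sd = float(y_sd)
        self.fit_info = fit_info or {}

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.x_mean.shape[0]:
            raise InputError(
                f"expected {self.x_mean.shape[0]} features, got {X.shape[1]}")
        return (X - self.x_mean) / self.x_sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Point prediction in original units (gamma for evidential heads)."""
        out = self.net.predict_raw(self._scale(X))
        mu = self.net.decode(out)["mu" if self.head != "evidential" else "gamma"]
        return mu * self.y_sd + self.y_mean

    def predict_mve(self, X: np.ndarray):
        """(mean, variance) in original units; requires an mve head."""
        if self.head != "mve":
            raise UnsupportedModelError("model was not trained with an mve head")
        d = self.net.decode(self.net.predict_raw(self._scale(X)))
        return d["mu"] * self.y_sd + self.y_mean, d["var"] * self.y_sd ** 2

    def predict_evidential(self, X: np.ndarray) -> dict:
        """NIG parameters with gamma/beta rescaled to original target units."""
        if self.head != "evidential":
            raise UnsupportedModelError(
                "model was not trained with an evidential head")
        d = self.net.decode(self.net.predict_raw(self._scale(X)))
        return {
            "gamma": d["gamma"] * self.y_sd + self.y_mean,
            "upsilon": d["upsilon"],
            "alpha": d["alpha"],
            "beta": d["beta"] * self.y_sd ** 2,
        }

    def predict_stochastic(self, X: np.ndarray, n_passes: int, seed: int = 0,
                           dropout_rate: float | None = None) -> np.ndarray:
        """(n_passes, n) point predictions with dropout active at inference."""
        Xs = self._scale(X)
        rng = np.random.default_rng(seed)
        rate = self.spec.dropout_rate if dropout_rate is None else dropout_rate
        key = "mu" if self.head != "evidential" else "gamma"
        preds = np.empty((n_passes, Xs.shape[0]))
        for t in range(n_passes):
            out, _, _ = self.net.forward(Xs, dropout_rng=rng, dropout_rate=rate)
            preds[t] = self.net.decode(out)[key] * self.y_sd + self.y_mean
        return preds

    def last_layer(self, X: np.ndarray) -> np.ndarray:
        return self.net.last_hidden(self._scale(X))

    # -- serialization (JSON weights + metadata sidecar) ------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "W": [w.tolist() for w in self.net.W],
            "b": [b.tolist() for b in self.net.b],
        }
        path.write_text(json.dumps(payload))
        meta = {
            "spec": asdict(self.spec), "head": self.head,
            "x_mean": self.x_mean.tolist(), "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean, "y_sd": self.y_sd,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RegressorHandle":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        spec_d = meta["spec"]
        spec_d["hidden_sizes"] = tuple(spec_d["hidden_sizes"])
        spec = RegressorSpec(**spec_d)
        payload = json.loads(path.read_text())
        net = FeedForward(len(meta["x_mean"]), spec.hidden_sizes, meta["head"],
                          spec.dropout_rate, spec.seed)
        net.W = [np.asarray(w) for w in payload["W"]]
        net.b = [np.asarray(b) for b in payload["b"]]
        return cls(net, spec, meta["head"], meta["x_mean"], meta["x_sd"],
                   meta["y_mean"], meta["y_sd"])


def _split_val(train: MoleculeTable, seed: int, frac: float = 0.1):
    rng = np.random.default_rng(seed)
    n = len(train)
    order = rng.permutation(n)
    n_val = max(1, int(round(frac * n)))
    return train.subset(order[n_val:]), train.subset(order[:n_val])


def train_regressor(spec: RegressorSpec, train: MoleculeTable,
                    val: MoleculeTable | None = None,
                    head: str = "point") -> RegressorHandle:
    """Fit the feedforward regressor on z-scored descriptors.

    Features and target are standardized with training-set statistics only;
    early stopping monitors the head loss on the validation table (10% of
    the training partition when no explicit validation set is given).
    Deterministic given ``spec.seed``.
    """
    if val is None:
        train, val = _split_val(train, spec.seed)
    if train.X.shape[1] != val.X.shape[1]:
        raise InputError("train and val feature dimensions differ")

    x_mean = train.X.mean(axis=0)
    x_sd = np.where(train.X.std(axis=0) > 0, train.X.std(axis=0), 1.0)
    y_mean = float(train.y.mean())
    y_sd = float(train.y.std()) or 1.0

    Xtr = (train.X - x_mean) / x_sd
    ytr = (train.y - y_mean) / y_sd
    Xva = (val.X - x_mean) / x_sd
    yva = (val.y - y_mean) / y_sd

    net = FeedForward(Xtr.shape[1], spec.hidden_sizes, head,
                      spec.dropout_rate, spec.seed,
                      evid_lambda=spec.evid_lambda)
    info = net.fit(Xtr, ytr, Xva, yva, max_epochs=spec.max_epochs,
                   learning_rate=spec.learning_rate,
                   batch_size=spec.batch_size,
                   patience=spec.early_stop_patience)
    return RegressorHandle(net, spec, head, x_mean, x_sd, y_mean, y_sd, info)


def extract_last_layer(model: RegressorHandle, X: np.ndarray) -> np.ndarray:
    """Final hidden-layer representation of each row; dropout disabled."""
    if not isinstance(model, RegressorHandle):
        raise UnsupportedModelError(
            "last-layer extraction requires a feedforward model handle")
    return model.last_layer(X)


# -- gradient-boosted trees -----------------------------------------------

_GBM_DEFAULTS = dict(n_estimators=500, max_depth=6, learning_rate=0.05,
                     num_leaves=63)
# Quantile fits need far stronger regularization than squared-error fits:
# boosted pinball models are prone to overfitting the conditional quantiles,
# which narrows the P10-P90 interval and destroys held-out coverage.
_QUANTILE_DEFAULTS = dict(n_estimators=30, max_depth=6, learning_rate=0.05,
                          num_leaves=15, min_child_samples=100)


def _gbm(objective: str, seed: int, alpha: float | None = None, **overrides):
    params = dict(_QUANTILE_DEFAULTS if objective == "quantile"
                  else _GBM_DEFAULTS)
    params.update(overrides)
    return lgb.LGBMRegressor(
        objective=objective, alpha=alpha, random_state=int(seed),
        n_jobs=1, deterministic=True, force_row_wise=True, verbose=-1,
        **params)


def fit_quantile_gbm(train: MoleculeTable | tuple, quantile: float,
                     seed: int = 0, **overrides):
    """Gradient-boosted trees minimizing pinball loss at ``quantile``.

    ``train`` may be a :class:`MoleculeTable` or an ``(X, y)`` pair (the
    latter is what the union approach uses with last-layer features).
    Returns the fitted LightGBM regressor.
    """
    if not 0.0 < quantile < 1.0:
        raise ConfigurationError("quantile must lie strictly inside (0, 1)")
    X, y = (train.X, train.y) if isinstance(train, MoleculeTable) else train
    model = _gbm("quantile", seed, alpha=float(quantile), **overrides)
    model.fit(np.asarray(X, float), np.asarray(y, float))
    return model


def fit_mean_gbm(train: MoleculeTable | tuple, seed: int = 0, **overrides):
    """Squared-error gradient-boosted trees (the GBM mean predictor)."""
    X, y = (train.X, train.y) if isinstance(train, MoleculeTable) else train
    model = _gbm("regression", seed, **overrides)
    model.fit(np.asarray(X, float), np.asarray(y, float))
    return model
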