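"""Compact numpy feedforward regression engine.

A fully-connected ReLU network with inverted dropout, Adam, minibatching and
early stopping, supporting three output heads:

``point``
    one output, squared-error loss.
``mve``
    two outputs (mean, raw variance); the variance passes through a softplus
    with a small floor and the loss is the Gaussian negative log-likelihood
    ``0.5 log(2*pi) + 0.5 log(sigma^2) + (y - mu)^2 / (2 sigma^2)``.
``evidential``
    four outputs mapped to Normal-Inverse-Gamma parameters
    (gamma, upsilon, alpha, beta) with upsilon, beta > 0 via softplus and
    alpha = 1 + softplus(.) > 1; trained with the marginal Student-t negative
    log-likelihood plus an evidence regularizer ``lambda * |y - gamma| *
    (2 upsilon + alpha)``.

All gradients are written out analytically (see ``_head_grad``) and are
verified against numerical differentiation in the test suite.  Everything is
deterministic given the construction seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, digamma

from moluq.errors import ConfigurationError, TrainingDivergenceError

_VAR_FLOOR = 1e-6

_HEAD_WIDTH = {"point": 1, "mve": 2, "evidential": 4}


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _head_loss_grad(head: str, out: np.ndarray, y: np.ndarray,
                    evid_lambda: float = 0.01, mean_only: bool = False):
    """Per-sample loss and gradient w.r.t. the raw network outputs.

    Returns (loss_vector, dL/dout of shape (n, head_width)).
    ``mean_only`` restricts the mve head to its mean output (warm-up phase).
    """
    n = out.shape[0]
    grad = np.zeros_like(out)
    if head == "point":
        r = out[:, 0] - y
        loss = 0.5 * r * r
        grad[:, 0] = r
        return loss, grad

    if head == "mve":
        mu, s = out[:, 0], out[:, 1]
        if mean_only:
            r = mu - y
            grad[:, 0] = r
            return 0.5 * r * r, grad
        var = softplus(s) + _VAR_FLOOR
        r = y - mu
        loss = 0.5 * np.log(2 * np.pi) + 0.5 * np.log(var) + r * r / (2 * var)
        grad[:, 0] = -r / var
        grad[:, 1] = (0.5 / var - r * r / (2 * var * var)) * expit(s)
        return loss, grad

    if head == "evidential":
        gam = out[:, 0]
        ups = softplus(out[:, 1]) + _VAR_FLOOR
        alp = 1.0 + softplus(out[:, 2]) + _VAR_FLOOR
        bet = softplus(out[:, 3]) + _VAR_FLOOR
        e = y - gam
        omega = 2.0 * bet * (1.0 + ups)
        D = ups * e * e + omega
        loss = (0.5 * np.log(np.pi / ups) - alp * np.log(omega)
                + (alp + 0.5) * np.log(D) + gammaln(alp) - gammaln(alp + 0.5))
        loss = loss + evid_lambda * np.abs(e) * (2.0 * ups + alp)

        sgn = np.sign(e)
        d_gam = (alp + 0.5) * (-2.0 * ups * e) / D - evid_lambda * sgn * (
            2.0 * ups + alp)
        d_ups = (-0.5 / ups - alp * 2.0 * bet / omega
                 + (alp + 0.5) * (e * e + 2.0 * bet) / D
                 + evid_lambda * 2.0 * np.abs(e))
        d_alp = (-np.log(omega) + np.log(D) + digamma(alp)
                 - digamma(alp + 0.5) + evid_lambda * np.abs(e))
        d_bet = (-alp * 2.0 * (1.0 + ups) / omega
                 + (alp + 0.5) * 2.0 * (1.0 + ups) / D)

        grad[:, 0] = d_gam
        grad[:, 1] = d_ups * expit(out[:, 1])
        grad[:, 2] = d_alp * expit(out[:, 2])
        grad[:, 3] = d_bet * expit(out[:, 3])
        return loss, grad

    raise ConfigurationError(f"unknown head {head!r}")


class FeedForward:
    """ReLU multilayer perceptron with a configurable uncertainty head."""

    def __init__(self, n_in: int, hidden_sizes: tuple[int, ...], head: str,
                 dropout_rate: float = 0.0, seed: int = 0,
                 evid_lambda: float = 0.01):
        if head not in _HEAD_WIDTH:
            raise ConfigurationError(f"unknown head {head!r}")
        if not hidden_sizes:
            raise ConfigurationError("at least one hidden layer required")
        if not 0.0 <= dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        self.n_in = int(n_in)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.head = head
        self.dropout_rate = float(dropout_rate)
        self.evid_lambda = float(evid_lambda)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        dims = [self.n_in, *self.hidden_sizes, _HEAD_WIDTH[head]]
        self.W = [rng.normal(size=(a, b)) * np.sqrt(2.0 / a)
                  for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(b) for b in dims[1:]]
        # evidential: bias alpha/beta raw outputs positive for a sane start
        if head == "evidential":
            self.b[-1][1:] = 1.0

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None
                = None, dropout_rate: float | None = None):
        """Forward pass; returns (raw output, cached activations, masks)."""
        rate = self.dropout_rate if dropout_rate is None else dropout_rate
        acts = [np.asarray(X, float)]
        masks = []
        h = acts[0]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if dropout_rng is not None and rate > 0.0:
                    m = (dropout_rng.random(h.shape) >= rate) / (1.0 - rate)
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                h = z
        return h, acts, masks

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout disabled)."""
        out, _, _ = self.forward(X)
        return out

    def last_hidden(self, X: np.ndarray) -> np.ndarray:
        """Final hidden-layer activations, dropout disabled."""
        _, acts, _ = self.forward(X)
        return acts[-1]

    # -- gradients --------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       dropout_rng=None, mean_only: bool = False):
        """Mean loss and parameter gradients on a batch."""
        out, acts, masks = self.forward(X, dropout_rng=dropout_rng)
        loss, dout = _head_loss_grad(self.head, out, np.asarray(y, float),
                                     self.evid_lambda, mean_only)
        n = X.shape[0]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout / n
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                delta = delta * (acts[i] > 0.0)
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
        return float(loss.mean()), gW, gb

    def mean_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        out = self.predict_raw(X)
        loss, _ = _head_loss_grad(self.head, out, np.asarray(y, float),
                                  self.evid_lambda)
        return float(loss.mean())

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, X_val: np.ndarray,
            y_val: np.ndarray, max_epochs: int = 300, learning_rate: float
            = 1e-3, batch_size: int = 128, patience: int = 20,
            mve_warmup: int = 50) -> dict:
        """Adam with early stopping on validation loss; restores best weights."""
        rng = np.random.default_rng(self.seed + 1)
        drop_rng = np.random.default_rng(self.seed + 2)
        params = self.W + self.b
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps, t = 0.9, 0.999, 1e-8, 0
        n = X.shape[0]
        best_loss = np.inf
        best = [p.copy() for p in params]
        best_epoch, bad = 0, 0
        history = []
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            warm = self.head == "mve" and epoch < mve_warmup
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, gW, gb = self.loss_and_grads(
                    X[idx], y[idx],
                    dropout_rng=drop_rng if self.dropout_rate > 0 else None,
                    mean_only=warm)
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(
                        f"non-finite loss at epoch {epoch}")
                grads = gW + gb
                t += 1
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = b1 * m[j] + (1 - b1) * g
                    v[j] = b2 * v[j] + (1 - b2) * g * g
                    mhat = m[j] / (1 - b1 ** t)
                    vhat = v[j] / (1 - b2 ** t)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            if warm:
                continue  # warm-up epochs do not drive early stopping
            vloss = self.mean_loss(X_val, y_val)
            history.append(vloss)
            if vloss < best_loss - 1e-9:
                best_loss = vloss
                best = [p.copy() for p in params]
                best_epoch, bad = epoch, 0
            else:
                bad += 1
                if bad > patience:
                    break
        for p, bp in zip(params, best):
            p[...] = bp
        return {"best_val_loss": best_loss, "best_epoch": best_epoch,
                "val_history": history}

    # -- head decoding ----------------------------------------------------

    def decode(self, out: np.ndarray) -> dict:
        """Map raw outputs to head-specific quantities (standardized units)."""
        if self.head == "point":
            return {"mu": out[:, 0]}
        if self.head == "mve":
            return {"mu": out[:, 0], "var": softplus(out[:, 1]) + _VAR_FLOOR}
        return {
            "gamma": out[:, 0],
            "upsilon": softplus(out[:, 1]) + _VAR_FLOOR,
            "alpha": 1.0 + softplus(out[:, 2]) + _VAR_FLOOR,
            "beta": softplus(out[:, 3]) + _VAR_FLOOR,
        }
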