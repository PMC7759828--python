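"""Neural propensity-score estimation, IPT weights, and balance diagnostics.

The propensity score e(X) = P(Z=1 | X) is estimated with a small fully connected
network: one rectifier hidden layer (width configurable, 0 for a plain logistic
model) and a sigmoid output trained under binary cross-entropy with mini-batch
stochastic gradient descent and Nesterov momentum.  The learning rate is chosen
by grid search against a held-out validation split.

Inverse-probability-of-treatment weights follow the usual rule
w = 1/e for treated and 1/(1-e) for untreated subjects, creating a
pseudo-population in which the measured covariates are balanced across arms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import MLP, SGDNesterov
from .design import DesignMatrix

__all__ = ["PropensityModel", "PropensityResults", "compute_ipt_weights",
           "balance_diagnostics"]

DEFAULT_LR_GRID = tuple(np.round(np.geomspace(0.001, 0.05, 6), 6))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _bce(p, z, eps=1e-12):
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(z * np.log(p) + (1 - z) * np.log(1 - p)))


class PropensityModel:
    """Model for treatment assignment given baseline covariates.

    Parameters
    ----------
    treatment : (n,) array of 0/1 treatment indicators.
    design : DesignMatrix (or plain 2-d array) of encoded covariates.
    hidden_units : width of the single rectifier hidden layer; 0 gives a
        logistic-regression-equivalent linear model.
    """

    def __init__(self, treatment, design, hidden_units: int = 16):
        self.Z = np.asarray(treatment, dtype=float).ravel()
        self.design = design
        self.X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
        if self.X.shape[0] != self.Z.shape[0]:
            raise ValueError("treatment and design row counts differ")
        if not set(np.unique(self.Z)) <= {0.0, 1.0}:
            raise ValueError("treatment must be binary 0/1")
        if len(np.unique(self.Z)) < 2:
            raise ValueError("both treatment arms must be present")
        self.hidden_units = int(hidden_units)

    # ------------------------------------------------------------------ fit
    def fit(self, learning_rate: float | None = None,
            lr_grid=DEFAULT_LR_GRID, epochs: int = 200, batch_size: int = 128,
            momentum: float = 0.9, patience: int = 20, val_fraction: float = 0.2,
            seed: int = 0) -> "PropensityResults":
        """Train the network; grid-search the learning rate unless one is given."""
        rng = np.random.default_rng(seed)
        n = len(self.Z)
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if learning_rate is None else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        if learning_rate is not None:
            grid = [float(learning_rate)]
        else:
            grid = [float(lr) for lr in lr_grid]

        best = None
        for lr in grid:
            net, history = self._train(self.X[train_idx], self.Z[train_idx], lr,
                                       epochs, batch_size, momentum, patience,
                                       self.X[val_idx] if n_val else None,
                                       self.Z[val_idx] if n_val else None,
                                       np.random.default_rng(seed + 1))
            crit = history["val_loss"][-1] if n_val else history["train_loss"][-1]
            if best is None or crit < best[0]:
                best = (crit, lr, net, history)
        _, lr_sel, net, history = best
        if learning_rate is None:
            # refit on the full sample at the selected rate
            net, history = self._train(self.X, self.Z, lr_sel, epochs, batch_size,
                                       momentum, patience, None, None,
                                       np.random.default_rng(seed + 1))
        scores = self._predict_net(net, self.X)
        return PropensityResults(model=self, network=net, learning_rate=lr_sel,
                                 history=history, scores=scores,
                                 final_loss=_bce(scores, self.Z), seed=seed)

    def _train(self, X, Z, lr, epochs, batch_size, momentum, patience,
               X_val, Z_val, rng):
        net = MLP.init(X.shape[1], (self.hidden_units,) if self.hidden_units else (),
                       1, rng)
        opt = SGDNesterov(net.params(), lr, momentum)
        n = len(Z)
        history = {"train_loss": [], "val_loss": []}
        best_val, best_net, wait = np.inf, None, 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                cache = []
                logits = net.forward(X[idx], cache)[:, 0]
                p = _sigmoid(logits)
                # d BCE / d logit, averaged over the batch
                dlogit = ((p - Z[idx]) / len(idx))[:, None]
                dW, db = net.backward(cache, dlogit)
                opt.step(dW + db)
            train_loss = _bce(self._predict_net(net, X), Z)
            if not np.isfinite(train_loss):
                raise FloatingPointError(
                    f"propensity training diverged (loss not finite) at "
                    f"learning rate {lr}")
            history["train_loss"].append(train_loss)
            if X_val is not None:
                val_loss = _bce(self._predict_net(net, X_val), Z_val)
                history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-7:
                    best_val, best_net, wait = val_loss, net.copy(), 0
                else:
                    wait += 1
                    if wait >= patience:
                        break
        if X_val is not None and best_net is not None:
            net = best_net
        return net, history

    @staticmethod
    def _predict_net(net, X):
        return _sigmoid(net.forward(X)[:, 0])


@dataclass
class PropensityResults:
    """Fitted propensity network with its estimated scores."""

    model: PropensityModel
    network: MLP
    learning_rate: float
    history: dict
    scores: np.ndarray
    final_loss: float
    seed: int = 0

    def predict(self, design) -> np.ndarray:
        """Propensity scores in (0,1) for new encoded rows."""
        X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
        if X.shape[1] != self.network.n_inputs:
            raise ValueError(
                f"design has {X.shape[1]} columns; model expects "
                f"{self.network.n_inputs}")
        return PropensityModel._predict_net(self.network, X)

    def ipt_weights(self, clip: float = 0.01) -> np.ndarray:
        return compute_ipt_weights(self.scores, self.model.Z, clip=clip)

    def summary(self) -> str:
        lines = [
            "Propensity score model (neural, single hidden layer)",
            f"  n subjects          : {len(self.model.Z)}",
            f"  treated fraction    : {self.model.Z.mean():.4f}",
            f"  hidden units        : {self.model.hidden_units}",
            f"  learning rate       : {self.learning_rate}",
            f"  final cross-entropy : {self.final_loss:.5f}",
            f"  score range         : [{self.scores.min():.4f}, {self.scores.max():.4f}]",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        design = self.model.design
        meta = {
            "learning_rate": self.learning_rate,
            "final_loss": self.final_loss,
            "hidden_units": self.model.hidden_units,
            "seed": self.seed,
            "activation": {"hidden": "relu", "output": "sigmoid"},
            "network": self.network.to_dict(),
        }
        if isinstance(design, DesignMatrix):
            meta["columns"] = list(design.columns)
            meta["standardization"] = design.standardization
        return json.dumps(meta, indent=1)


def compute_ipt_weights(scores, Z, clip: float = 0.01) -> np.ndarray:
    """IPT weights: 1/e for treated, 1/(1-e) for untreated.

    Scores are clipped to ``[clip, 1-clip]`` first; ``clip=0`` applies the
    unclipped rule.  Every weight is >= 1 by construction.
    """
    if not (0.0 <= clip < 0.5):
        raise ValueError(f"clip must lie in [0, 0.5), got {clip}")
    e = np.asarray(scores, dtype=float)
    if np.any(e <= 0.0) or np.any(e >= 1.0):
        raise ValueError("propensity scores must lie strictly in (0,1)")
    Z = np.asarray(Z, dtype=float)
    e = np.clip(e, clip, 1.0 - clip) if clip > 0 else e
    return np.where(Z == 1, 1.0 / e, 1.0 / (1.0 - e))


def balance_diagnostics(design, Z, weights=None) -> pd.DataFrame:
    """Standardized mean differences per encoded covariate, raw and weighted.

    SMD = (mean difference between arms) / pooled *unweighted* standard
    deviation, so the weighted and unweighted columns share a denominator and
    are directly comparable.  Zero-variance columns get SMD 0 and a degeneracy
    flag rather than a division by zero.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
    cols = design.columns if isinstance(design, DesignMatrix) else \
        [f"x{i}" for i in range(X.shape[1])]
    Z = np.asarray(Z, dtype=float)
    w = np.ones_like(Z) if weights is None else np.asarray(weights, dtype=float)
    t, c = Z == 1, Z == 0
    sd_pool = np.sqrt((X[t].var(axis=0, ddof=1) + X[c].var(axis=0, ddof=1)) / 2.0)
    degenerate = sd_pool == 0.0

    def _smd(wt):
        mu_t = np.average(X[t], axis=0, weights=wt[t])
        mu_c = np.average(X[c], axis=0, weights=wt[c])
        with np.errstate(divide="ignore", invalid="ignore"):
            smd = (mu_t - mu_c) / sd_pool
        return np.where(degenerate, 0.0, smd)

    return pd.DataFrame({
        "covariate": cols,
        "smd_unweighted": _smd(np.ones_like(Z)),
        "smd_weighted": _smd(w),
        "degenerate": degenerate,
    })
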