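"""IPT-weighted deep survival network: loss, fitting, curves, effect weights.

The network g_theta maps (covariates, treatment indicator) to a scalar log
relative risk.  Training minimizes the weighted partial-likelihood-style loss

    l(theta) = -(1/sum_i d_i) * sum_i d_i w_i [ g_i - log sum_{j in R_i} exp(g_j) ]

where R_i = {j : Y_j >= Y_i} is the at-risk set at subject i's observed time
(Breslow tie handling; the literal strict inequality R_i = {j : Y_j > Y_i} is
available behind ``strict_risk=True`` for the loss value, dropping event terms
whose risk set is empty).  The IPT weight w_i multiplies each event's
contribution; the normalizer is the event count.

Optimization is full-batch Adam with a triangular cyclical learning rate; the
base rate is grid-searched against a held-out validation split when not given.

Marginal survival curves are built by counterfactual standardization: a
weighted Breslow baseline cumulative hazard H0 is estimated on the fitted
risks, then every subject's covariates are combined with treatment forced to
each arm, S_i(t) = exp(-H0(t) exp(g(X_i, arm))), and averaged.  "Expected
survival" is the restricted mean survival time (area under the curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, cyclical_lr
from .design import DesignMatrix

__all__ = ["weighted_loss", "risk_sets", "DeepSurvivalModel",
           "DeepSurvivalResults", "BaselineHazard", "SurvivalCurve",
           "breslow_baseline", "expected_survival", "fit_survival_network"]


# --------------------------------------------------------------------- loss

def _check_lengths(g, Y, d, w):
    g = np.asarray(g, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if not (len(g) == len(Y) == len(d) == len(w)):
        raise ValueError("g, Y, d, w must have equal length")
    if d.sum() < 1:
        raise ValueError("zero events: loss undefined (division by sum of d)")
    return g, Y, d, w


def weighted_loss(g, Y, d, w, strict_risk: bool = False) -> float:
    """The IPT-weighted negative log partial-likelihood-style objective.

    With ``strict_risk=True`` the at-risk set uses the strict inequality
    Y_j > Y_i; event terms whose strict risk set is empty are dropped from the
    sum (the normalizer keeps all events).
    """
    g, Y, d, w = _check_lengths(g, Y, d, w)
    order = np.argsort(Y, kind="stable")
    gs, Ys, ds, ws = g[order], Y[order], d[order], w[order]
    m = gs.max()
    rexp = np.exp(gs - m)
    rcum = np.cumsum(rexp[::-1])[::-1]
    if strict_risk:
        # first index strictly past each tie group
        pos = np.searchsorted(Ys, Ys, side="right")
        valid = pos < len(Ys)
        logS0 = np.full(len(Ys), np.nan)
        logS0[valid] = np.log(rcum[pos[valid]]) + m
        terms = ds * ws * (gs - logS0)
        total = np.nansum(np.where(valid, terms, 0.0))
    else:
        first = np.searchsorted(Ys, Ys, side="left")
        logS0 = np.log(rcum[first]) + m
        total = float(np.sum(ds * ws * (gs - logS0)))
    return float(-total / d.sum())


def _loss_and_grad(g, Y, d, w):
    """Loss (Breslow risk sets) and its gradient with respect to g."""
    g, Y, d, w = _check_lengths(g, Y, d, w)
    n = len(g)
    order = np.argsort(Y, kind="stable")
    gs, Ys, ds, ws = g[order], Y[order], d[order], w[order]
    m = gs.max()
    rexp = np.exp(gs - m)
    rcum = np.cumsum(rexp[::-1])[::-1]
    first = np.searchsorted(Ys, Ys, side="left")
    last = np.searchsorted(Ys, Ys, side="right") - 1
    S0 = rcum[first]
    dw = ds * ws
    sum_d = d.sum()
    loss = -float(np.sum(dw * (gs - (np.log(S0) + m)))) / sum_d
    # c_j = sum over events i with Y_i <= Y_j of dw_i / S0(t_i)
    c = np.cumsum(dw / S0)[last]
    grad_sorted = -(dw - rexp * c) / sum_d
    grad = np.empty(n)
    grad[order] = grad_sorted
    return loss, grad


def risk_sets(Y, d, strict: bool = False) -> dict:
    """Map each event subject's index to the indices of its at-risk set.

    Intended for inspection and testing; the fitting path uses cumulative sums
    instead of materialized sets.
    """
    Y = np.asarray(Y, dtype=float)
    d = np.asarray(d)
    out = {}
    for i in np.nonzero(d)[0]:
        if strict:
            out[int(i)] = np.nonzero(Y > Y[i])[0]
        else:
            out[int(i)] = np.nonzero(Y >= Y[i])[0]
    return out


# ---------------------------------------------------------------- baseline

@dataclass
class BaselineHazard:
    """Weighted Breslow cumulative baseline hazard on the distinct event times."""

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if np.any(self.increments < 0):
            raise ValueError("negative hazard increment")

    @property
    def cumhaz(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def cumulative(self, t) -> np.ndarray:
        """H0 evaluated at times t (right-continuous step function)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        ch = np.concatenate([[0.0], self.cumhaz])
        return ch[idx]


def breslow_baseline(g, Y, d, w) -> BaselineHazard:
    """Weighted Breslow estimator of the baseline cumulative hazard.

    Increment at event time t:  (sum of w over events at t) /
    (sum of w * exp(g) over subjects with Y >= t).
    """
    g, Y, d, w = _check_lengths(g, Y, d, w)
    order = np.argsort(Y, kind="stable")
    gs, Ys, ds, ws = g[order], Y[order], d[order], w[order]
    m = gs.max()
    wrexp = ws * np.exp(gs - m)
    rcum = np.cumsum(wrexp[::-1])[::-1]
    first = np.searchsorted(Ys, Ys, side="left")
    denom = rcum[first] * np.exp(m)
    ev = ds > 0
    df = pd.DataFrame({"t": Ys[ev], "num": (ws * ds)[ev], "den": denom[ev]})
    grouped = df.groupby("t", sort=True).agg(num=("num", "sum"), den=("den", "first"))
    return BaselineHazard(grouped.index.to_numpy(), (grouped.num / grouped.den).to_numpy())


# ------------------------------------------------------------------ curves

@dataclass
class SurvivalCurve:
    """Monotone step survival function on a time grid, optionally with a band."""

    times: np.ndarray
    survival: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times[0] != 0.0:
            self.times = np.concatenate([[0.0], self.times])
            self.survival = np.concatenate([[1.0], self.survival])
            if self.lower is not None:
                self.lower = np.concatenate([[1.0], np.asarray(self.lower, float)])
            if self.upper is not None:
                self.upper = np.concatenate([[1.0], np.asarray(self.upper, float)])
        if np.any(self.survival > 1.0 + 1e-12) or np.any(self.survival < -1e-12):
            raise ValueError("survival values outside [0,1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival function must be nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        out = {"time": self.times, "survival": self.survival}
        if self.lower is not None:
            out["lower"] = self.lower
        if self.upper is not None:
            out["upper"] = self.upper
        return pd.DataFrame(out)


def expected_survival(curve: SurvivalCurve, horizon: float | None = None) -> float:
    """Restricted mean survival time: area under the step curve on [0, horizon].

    The curve is integrated exactly as a right-continuous step function.  The
    horizon defaults to the last grid time and may not exceed it.
    """
    t, S = curve.times, curve.survival
    tau = float(t[-1]) if horizon is None else float(horizon)
    if tau <= 0:
        raise ValueError("horizon must be positive")
    if tau > t[-1] + 1e-9:
        raise ValueError(f"horizon {tau} exceeds last grid time {t[-1]}")
    area = 0.0
    for k in range(len(t)):
        left = t[k]
        right = t[k + 1] if k + 1 < len(t) else tau
        right = min(right, tau)
        if right <= left:
            break
        area += S[k] * (right - left)
    return float(area)


# ------------------------------------------------------------------- model

DEFAULT_SURV_LR_GRID = (0.002, 0.004, 0.008, 0.016, 0.032, 0.064)


class DeepSurvivalModel:
    """IPT-weighted survival network (two rectifier hidden layers by default).

    Parameters
    ----------
    durations, events : observed times and event indicators.
    exog : DesignMatrix or array of encoded baseline covariates; may be None
        for a treatment-only model.
    treatment : (n,) 0/1 treatment indicators, appended as the last input.
    weights : IPT weights (default all ones).
    hidden : hidden-layer widths; ``()`` gives a linear model whose optimum is
        the weighted Cox fit.
    """

    def __init__(self, durations, events, exog, treatment, weights=None,
                 hidden: tuple = (32, 16)):
        self.Y = np.asarray(durations, dtype=float).ravel()
        self.d = np.asarray(events, dtype=float).ravel()
        self.Z = np.asarray(treatment, dtype=float).ravel()
        if len(np.unique(self.Z)) < 2:
            raise ValueError("both treatment arms must be present")
        if self.d.sum() < 1:
            raise ValueError("at least one event is required")
        if exog is None:
            X = np.empty((len(self.Y), 0))
            names = []
        elif isinstance(exog, DesignMatrix):
            X, names = exog.X, list(exog.columns)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            names = [f"x{i}" for i in range(X.shape[1])]
        self.Xfull = np.column_stack([X, self.Z])
        self.feature_names = names + ["treatment"]
        self.treatment_index = self.Xfull.shape[1] - 1
        self.w = (np.ones(len(self.Y)) if weights is None
                  else np.asarray(weights, dtype=float).ravel())
        if not (len(self.Y) == len(self.d) == len(self.w) == self.Xfull.shape[0]):
            raise ValueError("input lengths differ")
        self.hidden = tuple(int(h) for h in hidden)

    def loss(self, network: MLP) -> float:
        g = network.forward(self.Xfull)[:, 0]
        return weighted_loss(g, self.Y, self.d, self.w)

    def fit(self, learning_rate: float | None = None,
            lr_grid=DEFAULT_SURV_LR_GRID, epochs: int = 300,
            cycle_period: int = 20, val_fraction: float = 0.2,
            seed: int = 0) -> "DeepSurvivalResults":
        """Full-batch Adam with a triangular cyclical learning rate."""
        rng = np.random.default_rng(seed)
        if learning_rate is not None:
            grid = [float(learning_rate)]
            lr_sel = float(learning_rate)
        else:
            grid = [float(lr) for lr in lr_grid]
            perm = rng.permutation(len(self.Y))
            n_val = max(2, int(round(val_fraction * len(self.Y))))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            best = None
            for lr in grid:
                try:
                    net, hist = self._train(tr_idx, lr, epochs, cycle_period,
                                            np.random.default_rng(seed + 1))
                    gval = net.forward(self.Xfull[val_idx])[:, 0]
                    crit = weighted_loss(gval, self.Y[val_idx], self.d[val_idx],
                                         self.w[val_idx])
                except (FloatingPointError, ValueError):
                    crit = np.inf
                if best is None or crit < best[0]:
                    best = (crit, lr)
            lr_sel = best[1]
        net, history = self._train(np.arange(len(self.Y)), lr_sel, epochs,
                                   cycle_period, np.random.default_rng(seed + 1))
        g = net.forward(self.Xfull)[:, 0]
        baseline = breslow_baseline(g, self.Y, self.d, self.w)
        return DeepSurvivalResults(model=self, network=net, learning_rate=lr_sel,
                                   history=history, final_loss=history[-1],
                                   baseline=baseline, seed=seed)

    def _train(self, idx, lr, epochs, cycle_period, rng):
        X, Y, d, w = self.Xfull[idx], self.Y[idx], self.d[idx], self.w[idx]
        if d.sum() < 1:
            raise ValueError("training split has no events")
        net = MLP.init(X.shape[1], self.hidden, 1, rng)
        opt = Adam(net.params(), lr)
        history = []
        for epoch in range(epochs):
            cache = []
            g = net.forward(X, cache)[:, 0]
            loss, dg = _loss_and_grad(g, Y, d, w)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"survival training diverged (loss not finite) at learning "
                    f"rate {lr}, hidden {self.hidden}, epoch {epoch}")
            dW, db = net.backward(cache, dg[:, None])
            opt.step(dW + db, lr=cyclical_lr(epoch, lr, cycle_period))
            history.append(loss)
        return net, history


@dataclass
class DeepSurvivalResults:
    """Fitted survival network with baseline hazard and effect summaries."""

    model: DeepSurvivalModel
    network: MLP
    learning_rate: float
    history: list
    final_loss: float
    baseline: BaselineHazard
    seed: int = 0
    _curves: dict = field(default_factory=dict, repr=False)

    def predict_risk(self, exog=None, treatment=None) -> np.ndarray:
        """Log relative risk g(X, Z); defaults to the training inputs."""
        if exog is None and treatment is None:
            Xfull = self.model.Xfull
        else:
            X = exog.X if isinstance(exog, DesignMatrix) else np.asarray(exog, float)
            if X.ndim == 1:
                X = X[:, None]
            Z = np.asarray(treatment, dtype=float).ravel()
            Xfull = np.column_stack([X, Z])
        return self.network.forward(Xfull)[:, 0]

    def accumulated_weights(self) -> pd.Series:
        """Layer-accumulated per-input effect weights (product of weight matrices)."""
        return pd.Series(self.network.accumulated_weights(),
                         index=self.model.feature_names, name="accumulated_weight")

    def marginal_survival(self, arm: int, times=None) -> SurvivalCurve:
        """Counterfactual-standardized marginal curve for one treatment arm.

        Every subject's treatment input is forced to ``arm``; individual
        survival functions exp(-H0(t) exp(g)) are averaged.
        """
        if arm not in (0, 1):
            raise ValueError("arm must be 0 or 1")
        Xcf = self.model.Xfull.copy()
        Xcf[:, self.model.treatment_index] = float(arm)
        g = self.network.forward(Xcf)[:, 0]
        grid = self.baseline.times if times is None else np.asarray(times, float)
        H0 = self.baseline.cumulative(grid)
        S = np.exp(-np.outer(H0, np.exp(g))).mean(axis=1)
        return SurvivalCurve(grid, S)

    def expected_survival(self, arm: int, horizon: float | None = None) -> float:
        return expected_survival(self.marginal_survival(arm), horizon)

    def summary(self) -> str:
        acc = self.accumulated_weights()
        lines = [
            "IPT-weighted deep survival network",
            f"  n subjects     : {len(self.model.Y)}",
            f"  events         : {int(self.model.d.sum())}",
            f"  hidden widths  : {self.model.hidden}",
            f"  learning rate  : {self.learning_rate}",
            f"  final loss     : {self.final_loss:.6f}",
            f"  treatment accumulated weight : {acc['treatment']:+.4f}",
        ]
        return "\n".join(lines)


def fit_survival_network(durations, events, exog, treatment, weights=None,
                         hidden=(32, 16), **fit_kwargs) -> DeepSurvivalResults:
    """Convenience wrapper: build and fit a :class:`DeepSurvivalModel`."""
    return DeepSurvivalModel(durations, events, exog, treatment, weights,
                             hidden=hidden).fit(**fit_kwargs)
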