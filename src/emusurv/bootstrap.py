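"""Subsample bootstrap (0.632 n without replacement) over the full pipeline.

Each replicate draws floor(0.632 n) distinct subjects, refits the propensity
network, recomputes IPT weights, refits the survival network, and records the
layer-accumulated effect weights and both arms' marginal survival curves on a
common time grid (the distinct event times of the full cohort, so replicate
curves are comparable).  Summaries are empirical quantiles: median and 25/75%
for the accumulated weights (forest-plot intervals), 5/95% pointwise for the
curves (90% bands).  Sampling without replacement at rate 0.632 matches the
expected distinct-subject count of n-out-of-n resampling while avoiding ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .propensity import PropensityModel, compute_ipt_weights
from .survival import DeepSurvivalModel, SurvivalCurve

__all__ = ["SUBSAMPLE_RATE", "subsample_632", "BootstrapReplicate",
           "BootstrapSummary", "run_bootstrap", "summarize"]

SUBSAMPLE_RATE = 0.632


def subsample_632(n: int, seed) -> np.ndarray:
    """floor(0.632 n) distinct indices drawn uniformly without replacement."""
    if n < 2:
        raise ValueError("need n >= 2 to subsample")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = int(np.floor(SUBSAMPLE_RATE * n))
    return np.sort(rng.choice(n, size=k, replace=False))


@dataclass
class BootstrapReplicate:
    index: int
    subsample: np.ndarray
    accumulated: pd.Series
    curve0: SurvivalCurve
    curve1: SurvivalCurve
    meta: dict = field(default_factory=dict)


@dataclass
class BootstrapSummary:
    """Quantile summaries across replicates."""

    weight_quantiles: pd.DataFrame   # features x (q25, median, q75)
    band0: pd.DataFrame              # time grid x (q05, q95)
    band1: pd.DataFrame
    n_replicates: int
    n_failed: int = 0

    def forest_table(self) -> pd.DataFrame:
        return self.weight_quantiles


def run_bootstrap(design, treatment, durations, events, B: int,
                  base_seed: int = 0, *, ps_hidden: int = 16,
                  ps_learning_rate: float = 0.01, ps_epochs: int = 100,
                  surv_hidden=(32, 16), surv_learning_rate: float = 0.016,
                  surv_epochs: int = 200, clip: float = 0.01,
                  refit_propensity: bool = True,
                  fixed_weights=None,
                  max_failure_fraction: float = 0.10) -> list:
    """Run B subsample replicates of the propensity + survival pipeline.

    Hyperparameters (learning rates, widths) are the full-data tuned values
    and are reused per replicate rather than re-tuned.  ``refit_propensity=
    False`` is a clearly non-default fast mode that reuses ``fixed_weights``
    (subsetted) instead of refitting the propensity step.  Failed replicates
    (degenerate subsamples, divergence) are skipped and counted; more than
    ``max_failure_fraction`` failures aborts.
    """
    from .design import DesignMatrix

    Z = np.asarray(treatment, dtype=float).ravel()
    Y = np.asarray(durations, dtype=float).ravel()
    d = np.asarray(events, dtype=float).ravel()
    n = len(Z)
    grid = np.unique(Y[d > 0])
    seeds = np.random.default_rng(base_seed).integers(0, 2 ** 31 - 1, size=B)
    replicates, failures = [], []
    for b in range(B):
        rng = np.random.default_rng(seeds[b])
        idx = subsample_632(n, rng)
        sub_design = design.with_rows(idx) if isinstance(design, DesignMatrix) \
            else np.asarray(design, float)[idx]
        try:
            if refit_propensity:
                ps = PropensityModel(Z[idx], sub_design, hidden_units=ps_hidden)
                ps_res = ps.fit(learning_rate=ps_learning_rate,
                                epochs=ps_epochs, seed=int(seeds[b] % 2**31))
                w = compute_ipt_weights(ps_res.scores, Z[idx], clip=clip)
            else:
                if fixed_weights is None:
                    raise ValueError("fixed_weights required when "
                                     "refit_propensity=False")
                w = np.asarray(fixed_weights, float)[idx]
            surv = DeepSurvivalModel(Y[idx], d[idx], sub_design, Z[idx],
                                     weights=w, hidden=surv_hidden)
            res = surv.fit(learning_rate=surv_learning_rate,
                           epochs=surv_epochs, seed=int(seeds[b] % 2**31))
            rep = BootstrapReplicate(
                index=b, subsample=idx,
                accumulated=res.accumulated_weights(),
                curve0=res.marginal_survival(0, times=grid),
                curve1=res.marginal_survival(1, times=grid),
                meta={"seed": int(seeds[b]), "final_loss": res.final_loss})
            replicates.append(rep)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            failures.append((b, repr(exc)))
    if len(failures) > max_failure_fraction * B:
        raise RuntimeError(
            f"{len(failures)} of {B} bootstrap replicates failed "
            f"(> {max_failure_fraction:.0%}); first failures: {failures[:3]}")
    for rep in replicates:
        rep.meta["n_failed"] = len(failures)
    return replicates


def summarize(replicates: list) -> BootstrapSummary:
    """Empirical quantile summary (type-7 linear interpolation) of replicates."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 successful replicates to summarize")
    W = pd.DataFrame([r.accumulated for r in replicates])
    wq = pd.DataFrame({
        "q25": W.quantile(0.25),
        "median": W.quantile(0.50),
        "q75": W.quantile(0.75),
    })

    def _band(attr):
        curves = [getattr(r, attr) for r in replicates]
        times = curves[0].times
        S = np.vstack([c.survival for c in curves])
        return pd.DataFrame({
            "time": times,
            "q05": np.quantile(S, 0.05, axis=0),
            "q95": np.quantile(S, 0.95, axis=0),
        })

    return BootstrapSummary(weight_quantiles=wq, band0=_band("curve0"),
                            band1=_band("curve1"),
                            n_replicates=len(replicates),
                            n_failed=replicates[0].meta.get("n_failed", 0))
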