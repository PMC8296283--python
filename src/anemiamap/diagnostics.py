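"""Convergence and model-comparison diagnostics.

Gelman-Rubin potential scale reduction in its classic form (no rank
normalisation), and the Deviance Information Criterion
DIC = Dbar + pD = Dhat + 2 pD, with pD = Dbar - Dhat the effective number of
parameters.  Dhat is the deviance at the posterior means of every quantity
entering the linear predictor (beta, u, v) — the usual plug-in convention.
DIC differences of 3 or less are treated as indistinguishable, between 3 and
7 as weak evidence, above 7 as clear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ChildDataset
from .mcmc import ChainSet
from .model import ModelSpec, bernoulli_deviance, inverse_logit, linear_predictor

__all__ = ["DICResult", "gelman_rubin", "rhat_table", "dic", "compare_models"]


@dataclass(frozen=True)
class DICResult:
    """DIC decomposition for one fitted model."""

    kind: str
    d_bar: float
    d_hat: float

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_hat

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d

    def __post_init__(self):
        # the identity DIC = Dhat + 2 pD is definitional; assert finiteness
        if not (np.isfinite(self.d_bar) and np.isfinite(self.d_hat)):
            raise ValueError("non-finite deviance summaries")


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction R-hat for one scalar parameter.

    ``chains`` is (n_chains, n_iterations).  With W the mean within-chain
    variance and B the between-chain variance (n times the variance of the
    chain means), R-hat = sqrt(((n-1)/n W + B/n) / W).  Returns NaN when
    W = 0 (constant chains), where the diagnostic is undefined.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = chains.shape[1]
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return float("nan")
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def rhat_table(chains: ChainSet) -> pd.DataFrame:
    """R-hat for every sampled scalar (coefficients, effects, variances)."""
    rows = [(name, gelman_rubin(arr)) for name, arr in chains.scalar_chains().items()]
    return pd.DataFrame(rows, columns=["parameter", "rhat"])


def dic(chains: ChainSet, spec: ModelSpec, ds: ChildDataset) -> DICResult:
    """DIC from the kept draws.

    Dbar averages the per-draw deviances recorded during sampling; Dhat
    plugs the posterior means of (beta, u, v) into the linear predictor.
    """
    d_bar = float(chains.pooled("deviance").mean())
    beta_hat = chains.pooled("beta").mean(axis=0)
    u_hat = chains.pooled("u").mean(axis=0) if spec.has_u else None
    v_hat = chains.pooled("v").mean(axis=0) if spec.has_v else None
    eta_hat = linear_predictor(spec, beta_hat, u_hat, v_hat, region=ds.region)
    d_hat = bernoulli_deviance(ds.y, inverse_logit(eta_hat))
    return DICResult(kind=spec.kind, d_bar=d_bar, d_hat=d_hat)


def _delta_label(delta: float) -> str:
    if delta <= 3.0:
        return "indistinguishable"
    if delta <= 7.0:
        return "weak"
    return "clear"


def compare_models(results: list[DICResult]) -> pd.DataFrame:
    """Rank models by DIC and label each against the best.

    Sorted ascending by DIC (ties broken by input order).  ``vs_best`` labels
    the DIC gap to the best model: <= 3 "indistinguishable", (3, 7] "weak",
    > 7 "clear".
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    order = sorted(range(len(results)), key=lambda i: (results[i].dic, i))
    best = results[order[0]].dic
    rows = []
    for rank, i in enumerate(order, start=1):
        r = results[i]
        delta = r.dic - best
        rows.append((rank, r.kind, r.d_bar, r.d_hat, r.p_d, r.dic, delta, _delta_label(delta)))
    return pd.DataFrame(
        rows,
        columns=["rank", "model", "d_bar", "d_hat", "p_d", "dic", "delta_dic", "vs_best"],
    )
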