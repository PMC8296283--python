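"""Probabilistic core: logistic link, nested model structure, priors.

Four nested Bernoulli-logit models for a binary outcome over areal units:

* M1 — fixed effects only:            logit p_ij = x_i' beta
* M2 — + exchangeable region effect:  ... + v_j,  v_j ~ N(0, sigma2)
* M3 — + ICAR spatial effect:         ... + u_j,  u ~ ICAR(tau2)
* M4 — convolution (BYM):             ... + u_j + v_j

Priors: beta_h ~ N(0, 1/beta_precision) for intercept and coefficients alike
(default precision 1e-3, i.e. essentially flat); the precisions 1/sigma2 and
1/tau2 carry Gamma(shape, rate) hyperpriors (default 1e-3, 1e-3 — with both
constants equal the shape/rate vs shape/scale conventions coincide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .datasets import ChildDataset, DesignMatrix
from .spatial import AdjacencyGraph, icar_log_density_unnormalized

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "PriorSpec",
    "inverse_logit",
    "linear_predictor",
    "bernoulli_deviance",
    "log_posterior",
]

MODEL_KINDS = ("M1", "M2", "M3", "M4")


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four nested models, with its design and (M3/M4) graph."""

    kind: str
    design: DesignMatrix
    graph: AdjacencyGraph | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        if self.has_u and self.graph is None:
            raise ValueError(f"{self.kind} requires an adjacency graph")

    @property
    def has_v(self) -> bool:
        """Exchangeable (heterogeneity) region effect present."""
        return self.kind in ("M2", "M4")

    @property
    def has_u(self) -> bool:
        """ICAR (spatially structured) region effect present."""
        return self.kind in ("M3", "M4")


@dataclass(frozen=True)
class PriorSpec:
    """Prior constants: N(0, 1/beta_precision) coefficients, Gamma precisions."""

    beta_precision: float = 1e-3
    gamma_shape: float = 1e-3
    gamma_rate: float = 1e-3

    def __post_init__(self):
        if min(self.beta_precision, self.gamma_shape, self.gamma_rate) <= 0:
            raise ValueError("all prior constants must be positive")


def inverse_logit(eta):
    """Logistic link inverse p = 1/(1+exp(-eta)), stable for large |eta|."""
    return expit(eta)


def linear_predictor(
    spec: ModelSpec,
    beta: np.ndarray,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    *,
    region: np.ndarray,
) -> np.ndarray:
    """Per-child linear predictor eta_ij for the given model kind.

    M1: x'beta;  M2: + v_j;  M3: + u_j;  M4: + u_j + v_j.  Supplying an
    effect vector a model does not use is an error (guards against silently
    fitting the wrong model).
    """
    if u is not None and not spec.has_u:
        raise ValueError(f"{spec.kind} takes no spatial effect u")
    if v is not None and not spec.has_v:
        raise ValueError(f"{spec.kind} takes no exchangeable effect v")
    eta = spec.design.X @ np.asarray(beta, dtype=float)
    if spec.has_u:
        if u is None:
            raise ValueError(f"{spec.kind} requires u")
        eta = eta + np.asarray(u, dtype=float)[region]
    if spec.has_v:
        if v is None:
            raise ValueError(f"{spec.kind} requires v")
        eta = eta + np.asarray(v, dtype=float)[region]
    return eta


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """D = -2 sum[y ln p + (1-y) ln(1-p)]; error on a saturated mismatch."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) & (y == 1)) or np.any((p >= 1) & (y == 0)):
        raise ValueError("infinite deviance: p at 0/1 with mismatched y")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y == 1, np.log(p), np.log1p(-p))
    return float(-2.0 * ll.sum())


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x


def log_posterior(
    spec: ModelSpec,
    priors: PriorSpec,
    beta: np.ndarray,
    u: np.ndarray | None,
    v: np.ndarray | None,
    sigma2: float | None,
    tau2: float | None,
    ds: ChildDataset,
) -> float:
    """Unnormalised log posterior: the product of the model's four factors.

    Bernoulli likelihood; N(0, sigma2 I) for v with a Gamma hyperprior on
    1/sigma2; ICAR(tau2) for u with a Gamma hyperprior on 1/tau2; N(0,
    1/beta_precision) for every coefficient.  Factors a model does not use
    are simply absent.  Only differences of this quantity are meaningful.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite beta")
    eta = linear_predictor(
        spec,
        beta,
        u if spec.has_u else None,
        v if spec.has_v else None,
        region=ds.region,
    )
    y = ds.y.astype(float)
    # log-lik = sum y*eta - log(1+exp(eta)), stable via logaddexp
    lp = float((y * eta).sum() - np.logaddexp(0.0, eta).sum())
    lp += -0.5 * priors.beta_precision * float(beta @ beta)
    if spec.has_v:
        if sigma2 is None or sigma2 <= 0:
            raise ValueError("sigma2 must be positive for models with v")
        v = np.asarray(v, dtype=float)
        lp += -0.5 * len(v) * np.log(sigma2) - 0.5 * float(v @ v) / sigma2
        lp += _gamma_logpdf(1.0 / sigma2, priors.gamma_shape, priors.gamma_rate)
    if spec.has_u:
        if tau2 is None or tau2 <= 0:
            raise ValueError("tau2 must be positive for models with u")
        lp += icar_log_density_unnormalized(np.asarray(u, dtype=float), spec.graph, tau2)
        lp += _gamma_logpdf(1.0 / tau2, priors.gamma_shape, priors.gamma_rate)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior")
    return lp
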