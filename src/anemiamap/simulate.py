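"""Synthetic survey-like data with known truth.

Generates child-level datasets structurally matching the Guinea MICS5
application: ~2609 children over 8 regions, categorical covariates drawn
independently from the published survey margins, exchangeable region effects
v ~ N(0, sigma2), spatially structured effects u from the sum-to-zero ICAR
on the bundled contiguity graph, and Bernoulli outcomes through the logistic
link.  Every latent quantity is returned in a truth record so recovery can
be checked end-to-end.

The default truth places the published adjusted effects on the logit scale —
intercept logit(0.77) (the national prevalence), oldest-age-group ln(0.47),
secondary-education ln(0.67), Kissi-ethnicity ln(0.48) — with all other
coefficients zero and random-effect scales sigma2 = tau2 = 0.01 (sd 0.1,
the magnitude of the published posterior region effects).

Known departure from real survey data: covariate columns are mutually
independent, and there is no household/cluster sampling structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import guinea
from .datasets import ChildDataset, Schema, encode_factors, guinea_schema
from .model import inverse_logit
from .spatial import AdjacencyGraph, guinea_graph, sample_icar

__all__ = ["SyntheticConfig", "default_guinea_config", "generate"]


@dataclass
class SyntheticConfig:
    """Generator settings; probabilities are normalised to sum to one."""

    n: int
    region_probs: np.ndarray
    schema: Schema
    covariate_probs: dict[str, np.ndarray]
    beta_true: dict[str, float]
    sigma2_true: float
    tau2_true: float
    graph: AdjacencyGraph

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.sigma2_true < 0 or self.tau2_true < 0:
            raise ValueError("random-effect scales must be nonnegative")
        self.region_probs = _normalise(self.region_probs, len(self.schema.regions))
        self.covariate_probs = {
            c: _normalise(p, len(self.schema.levels[c])) for c, p in self.covariate_probs.items()
        }
        if set(self.covariate_probs) != set(self.schema.levels):
            raise ValueError("covariate_probs must cover exactly the schema covariates")


def _normalise(p, expected_len: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if len(p) != expected_len:
        raise ValueError(f"probability vector has length {len(p)}, expected {expected_len}")
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("probabilities must be nonnegative with positive sum")
    return p / p.sum()


def default_guinea_config() -> SyntheticConfig:
    """Generator calibrated to the published Guinea survey margins."""
    schema = guinea_schema()
    region_probs = np.array([guinea.REGION_TABLE[r]["n"] for r in guinea.REGIONS], dtype=float)
    cov_probs = {
        c: np.array([counts[lv] for lv in schema.levels[c]], dtype=float)
        for c, counts in guinea.COVARIATE_COUNTS.items()
    }
    p0 = 0.77  # national anemia prevalence
    beta_true = {
        "(Intercept)": float(np.log(p0 / (1 - p0))),
        "child_age=48-59": float(np.log(0.47)),
        "mother_education=Secondary+": float(np.log(0.67)),
        "ethnicity=Kissi": float(np.log(0.48)),
    }
    return SyntheticConfig(
        n=guinea.N_CHILDREN,
        region_probs=region_probs,
        schema=schema,
        covariate_probs=cov_probs,
        beta_true=beta_true,
        sigma2_true=0.01,
        tau2_true=0.01,
        graph=guinea_graph(),
    )


def generate(
    cfg: SyntheticConfig, seed: int | np.random.Generator = 0
) -> tuple[ChildDataset, dict]:
    """Draw one synthetic dataset and its truth record.

    Region and covariates are sampled independently per child from the
    configured margins; y_i ~ Bernoulli(inverse_logit(x_i' beta + u_j + v_j)).
    The truth record holds the full beta vector (aligned with the encoded
    design columns), u, v, the scales, and the per-child linear predictor.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schema = cfg.schema
    J = len(schema.regions)

    region = rng.choice(J, size=cfg.n, p=cfg.region_probs)
    covariates = pd.DataFrame(
        {
            c: np.asarray(schema.levels[c])[rng.choice(len(schema.levels[c]), size=cfg.n, p=p)]
            for c, p in cfg.covariate_probs.items()
        }
    )
    # encode via a throwaway dataset (outcome filled after eta is known)
    ds = ChildDataset(
        y=np.zeros(cfg.n, dtype=np.int8),
        region=region,
        region_labels=tuple(schema.regions),
        covariates=covariates,
        schema=schema,
    )
    design = encode_factors(ds)
    beta = np.zeros(design.k)
    for name, value in cfg.beta_true.items():
        beta[design.column_index(name)] = value

    v = rng.normal(0.0, np.sqrt(cfg.sigma2_true), size=J) if cfg.sigma2_true > 0 else np.zeros(J)
    u = sample_icar(cfg.graph, cfg.tau2_true, rng) if cfg.tau2_true > 0 else np.zeros(J)
    eta = design.X @ beta + u[region] + v[region]
    ds.y = (rng.random(cfg.n) < inverse_logit(eta)).astype(np.int8)

    truth = {
        "beta": beta,
        "beta_names": design.column_names,
        "u": u,
        "v": v,
        "sigma2": cfg.sigma2_true,
        "tau2": cfg.tau2_true,
        "eta": eta,
    }
    return ds, truth
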