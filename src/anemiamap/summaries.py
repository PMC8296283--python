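"""Posterior reporting: odds-ratio tables, predicted prevalence, effect maps.

Conventions (documented because more than one is defensible):

* OR point estimate is exp(posterior mean of the coefficient), with an
  equal-tailed 95% credible interval exp of the (2.5%, 97.5%) quantiles of
  the coefficient draws.
* Predicted region prevalence is the posterior mean of the region-average
  success probability (averaging inverse-logit within each draw), not the
  probability at the posterior-mean parameters.
* Random-effect maps use the category bins low (<= 0), moderate (0, 0.1],
  high (> 0.1) on the effect scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import ChildDataset, decode_column
from .descriptive import round_half_up
from .mcmc import ChainSet
from .model import ModelSpec, inverse_logit

__all__ = [
    "posterior_or_table",
    "predicted_region_prevalence",
    "random_effect_summary",
    "effect_category",
]


def posterior_or_table(
    chains: ChainSet, level: float = 0.95, include_reference: bool = True
) -> pd.DataFrame:
    """Odds ratios with credible intervals, one row per covariate level.

    Reference levels are emitted as OR = 1 with no interval (matching the
    layout of published adjusted-OR tables); set ``include_reference=False``
    for coefficient rows only.  The intercept is reported as a coefficient
    row (its exponential is a baseline odds, not an OR, and is labelled so).
    """
    alpha = (1.0 - level) / 2.0
    draws = chains.pooled("beta")
    rows = []
    seen_cov: set[str] = set()
    for h, name in enumerate(chains.column_names):
        parsed = decode_column(name)
        if parsed is None:
            rows.append(("(baseline odds)", "", float(np.exp(draws[:, h].mean())),
                         float(np.exp(np.quantile(draws[:, h], alpha))),
                         float(np.exp(np.quantile(draws[:, h], 1 - alpha)))))
            continue
        cov, lvl = parsed
        if include_reference and cov not in seen_cov:
            seen_cov.add(cov)
            # reference row: the omitted baseline level, OR fixed at 1
            rows.append((cov, "(reference)", 1.0, np.nan, np.nan))
        b = draws[:, h]
        rows.append((cov, lvl, float(np.exp(b.mean())),
                     float(np.exp(np.quantile(b, alpha))),
                     float(np.exp(np.quantile(b, 1 - alpha)))))
    return pd.DataFrame(rows, columns=["covariate", "level", "or", "lo", "hi"])


def predicted_region_prevalence(
    chains: ChainSet, ds: ChildDataset, spec: ModelSpec, chunk: int = 512
) -> pd.DataFrame:
    """Posterior-mean region prevalence (%) under the fitted model.

    For each kept draw, the region prevalence is the average of
    inverse_logit(eta_ij) over the region's children; the report is the
    posterior mean of that quantity, in percent to two decimals.  Regions
    with no children are omitted.
    """
    beta = chains.pooled("beta")
    T = beta.shape[0]
    u = chains.pooled("u") if spec.has_u else np.zeros((T, ds.n_regions))
    v = chains.pooled("v") if spec.has_v else np.zeros((T, ds.n_regions))
    X = spec.design.X
    totals = np.zeros(ds.n_regions)
    groups = [np.flatnonzero(ds.region == j) for j in range(ds.n_regions)]
    for start in range(0, T, chunk):
        sl = slice(start, min(start + chunk, T))
        eta = X @ beta[sl].T  # (n, t)
        eta += (u[sl] + v[sl]).T[ds.region]
        p = inverse_logit(eta)
        for j, g in enumerate(groups):
            if len(g):
                totals[j] += p[g].mean(axis=0).sum()
    rows = [
        (lab, len(g), round_half_up(100.0 * totals[j] / T))
        for j, (lab, g) in enumerate(zip(ds.region_labels, groups))
        if len(g)
    ]
    return pd.DataFrame(rows, columns=["region", "N", "predicted_prevalence"])


def effect_category(value: float) -> str:
    """Bin a region effect for choropleth-style reporting."""
    if value <= 0.0:
        return "low"
    if value <= 0.1:
        return "moderate"
    return "high"


def random_effect_summary(chains: ChainSet) -> pd.DataFrame:
    """Posterior mean and sd per region for the sampled random effects.

    One row per (effect, region); ``category`` bins the posterior mean for
    mapping (low <= 0 < moderate <= 0.1 < high).
    """
    rows = []
    for name in ("u", "v"):
        arr = getattr(chains, name)
        if arr is None:
            continue
        pooled = chains.pooled(name)
        for j, lab in enumerate(chains.region_labels):
            m = float(pooled[:, j].mean())
            rows.append((name, lab, m, float(pooled[:, j].std(ddof=1)), effect_category(m)))
    if not rows:
        raise ValueError(f"model {chains.kind} has no random effects to summarise")
    return pd.DataFrame(rows, columns=["effect", "region", "mean", "sd", "category"])
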