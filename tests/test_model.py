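"""Logistic link, nested linear predictors, deviance, and the log posterior."""

import numpy as np
import pytest
from scipy import stats

from anemiamap import (
    ModelSpec,
    PriorSpec,
    bernoulli_deviance,
    encode_factors,
    inverse_logit,
    linear_predictor,
    log_posterior,
)
from anemiamap.spatial import AdjacencyGraph, icar_pairwise_ss
from conftest import make_toy_dataset


def test_inverse_logit_values():
    assert inverse_logit(0.0) == pytest.approx(0.5)
    assert inverse_logit(np.log(3)) == pytest.approx(0.75)
    p = inverse_logit(-745.0)
    assert 0.0 <= p < 1e-300 and not np.isnan(p)


def _toy(n_regions=3):
    rng = np.random.default_rng(0)
    n = 10
    levels = ["A", "B", "C"]
    ds = make_toy_dataset(
        y=rng.integers(0, 2, n),
        region=rng.integers(0, n_regions, n),
        levels=levels,
        values=rng.choice(levels, n),
        n_regions=n_regions,
    )
    graph = AdjacencyGraph.from_edges(ds.region_labels, [("R0", "R1"), ("R1", "R2")])
    return ds, encode_factors(ds), graph


def test_linear_predictor_nesting_and_additivity():
    ds, dm, graph = _toy()
    beta = np.zeros(dm.k)
    z = np.zeros(3)
    for kind, kw in [
        ("M1", {}),
        ("M2", {"v": z}),
        ("M3", {"u": z}),
        ("M4", {"u": z, "v": z}),
    ]:
        spec = ModelSpec(kind, dm, graph if kind in ("M3", "M4") else None)
        assert np.all(linear_predictor(spec, beta, region=ds.region, **kw) == 0.0)

    spec4 = ModelSpec("M4", dm, graph)
    beta[0] = 0.3
    u = np.full(3, -0.1)
    v = np.full(3, 0.05)
    eta = linear_predictor(spec4, beta, u, v, region=ds.region)
    assert np.allclose(eta, 0.25)

    spec2 = ModelSpec("M2", dm)
    eta2 = linear_predictor(spec2, beta, v=v, region=ds.region)
    eta4 = linear_predictor(spec4, beta, u=np.zeros(3), v=v, region=ds.region)
    assert np.array_equal(eta2, eta4)


def test_effect_supplied_to_m1_is_an_error():
    ds, dm, _ = _toy()
    spec = ModelSpec("M1", dm)
    with pytest.raises(ValueError):
        linear_predictor(spec, np.zeros(dm.k), u=np.zeros(3), region=ds.region)


def test_m3_requires_graph():
    _, dm, _ = _toy()
    with pytest.raises(ValueError, match="graph"):
        ModelSpec("M3", dm)


def test_deviance_values():
    assert bernoulli_deviance([1], [0.5]) == pytest.approx(-2 * np.log(0.5))
    assert bernoulli_deviance([1, 0], [0.5, 0.5]) == pytest.approx(2.7726, abs=1e-4)


def test_deviance_saturated_limit():
    y = np.array([1, 0, 1])
    for eps in (1e-4, 1e-8, 1e-12):
        p = np.clip(y.astype(float), eps, 1 - eps)
        assert bernoulli_deviance(y, p) < 10 * eps
    with pytest.raises(ValueError):
        bernoulli_deviance([1], [0.0])


def test_deviance_order_invariant():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 50)
    p = rng.uniform(0.1, 0.9, 50)
    perm = rng.permutation(50)
    assert bernoulli_deviance(y, p) == pytest.approx(bernoulli_deviance(y[perm], p[perm]))


def _oracle_log_posterior(spec, priors, beta, u, v, sigma2, tau2, ds, graph):
    """Independent term-by-term evaluation using scipy distributions."""
    eta = spec.design.X @ beta
    if spec.has_u:
        eta = eta + u[ds.region]
    if spec.has_v:
        eta = eta + v[ds.region]
    p = 1 / (1 + np.exp(-eta))
    lp = stats.bernoulli.logpmf(ds.y, p).sum()
    lp += stats.norm.logpdf(beta, 0, 1 / np.sqrt(priors.beta_precision)).sum()
    if spec.has_v:
        lp += stats.norm.logpdf(v, 0, np.sqrt(sigma2)).sum()
        lp += stats.gamma.logpdf(1 / sigma2, priors.gamma_shape, scale=1 / priors.gamma_rate)
    if spec.has_u:
        lp += -icar_pairwise_ss(u, graph) / (2 * tau2) - (graph.J - 1) / 2 * np.log(tau2)
        lp += stats.gamma.logpdf(1 / tau2, priors.gamma_shape, scale=1 / priors.gamma_rate)
    return lp


def test_log_posterior_matches_term_oracle_up_to_constant():
    ds, dm, graph = _toy()
    spec = ModelSpec("M4", dm, graph)
    priors = PriorSpec(beta_precision=0.5, gamma_shape=2.0, gamma_rate=3.0)
    rng = np.random.default_rng(42)

    def point():
        return (
            rng.normal(0, 0.5, dm.k),
            rng.normal(0, 0.3, 3),
            rng.normal(0, 0.3, 3),
            float(rng.uniform(0.2, 2)),
            float(rng.uniform(0.2, 2)),
        )

    p1, p2 = point(), point()
    ours = log_posterior(spec, priors, *p1, ds) - log_posterior(spec, priors, *p2, ds)
    oracle = _oracle_log_posterior(spec, priors, *p1, ds, graph) - _oracle_log_posterior(
        spec, priors, *p2, ds, graph
    )
    assert ours == pytest.approx(oracle, abs=1e-8)


def test_doubling_sigma2_changes_only_the_v_factor():
    ds, dm, graph = _toy()
    spec = ModelSpec("M4", dm, graph)
    priors = PriorSpec()
    rng = np.random.default_rng(9)
    beta = rng.normal(0, 0.3, dm.k)
    u = rng.normal(0, 0.2, 3)
    u -= u.mean()
    v = rng.normal(0, 0.2, 3)
    s2, t2 = 0.5, 0.4
    delta = log_posterior(spec, priors, beta, u, v, 2 * s2, t2, ds) - log_posterior(
        spec, priors, beta, u, v, s2, t2, ds
    )
    expected = (
        stats.norm.logpdf(v, 0, np.sqrt(2 * s2)).sum()
        + stats.gamma.logpdf(1 / (2 * s2), priors.gamma_shape, scale=1 / priors.gamma_rate)
        - stats.norm.logpdf(v, 0, np.sqrt(s2)).sum()
        - stats.gamma.logpdf(1 / s2, priors.gamma_shape, scale=1 / priors.gamma_rate)
    )
    assert delta == pytest.approx(expected, abs=1e-8)
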