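"""Posterior reporting: OR tables, predicted prevalence, effect summaries."""

import numpy as np
import pandas as pd
import pytest

from anemiamap import (
    ChainSet,
    McmcConfig,
    ModelSpec,
    encode_factors,
    inverse_logit,
    posterior_or_table,
    predicted_region_prevalence,
    random_effect_summary,
)
from anemiamap.spatial import AdjacencyGraph
from anemiamap.summaries import effect_category
from conftest import make_toy_dataset


def _chainset(beta_draws, column_names, u=None, v=None, regions=("R0", "R1", "R2")):
    beta_draws = np.asarray(beta_draws, dtype=float)
    T = beta_draws.shape[0] // 2
    cfg = McmcConfig(n_iter=2 * T + 1, burn_in=0, seed=0)
    shape = (2, T)
    return ChainSet(
        kind="M4" if u is not None else ("M2" if v is not None else "M1"),
        column_names=tuple(column_names),
        region_labels=tuple(regions),
        beta=beta_draws.reshape(2, T, -1),
        u=None if u is None else np.asarray(u, float).reshape(2, T, -1),
        v=None if v is None else np.asarray(v, float).reshape(2, T, -1),
        sigma2=None if v is None else np.ones(shape),
        tau2=None if u is None else np.ones(shape),
        deviance=np.zeros(shape),
        accept_rates={},
        config=cfg,
    )


def test_zero_draws_give_unit_odds_ratio():
    cs = _chainset(np.zeros((10, 2)), ("(Intercept)", "x=B"))
    t = posterior_or_table(cs, include_reference=False)
    row = t[t.level == "B"].iloc[0]
    assert (row["or"], row.lo, row.hi) == (1.0, 1.0, 1.0)


def test_reference_levels_emitted_as_one():
    cs = _chainset(np.zeros((10, 2)), ("(Intercept)", "x=B"))
    t = posterior_or_table(cs)
    ref = t[(t.covariate == "x") & (t.level == "(reference)")].iloc[0]
    assert ref["or"] == 1.0 and np.isnan(ref.lo)


def test_or_quantiles_match_sorted_draw_oracle():
    rng = np.random.default_rng(0)
    b = rng.normal(np.log(0.47), 0.2, size=1000)
    draws = np.column_stack([np.zeros(1000), b])
    cs = _chainset(draws, ("(Intercept)", "x=B"))
    t = posterior_or_table(cs, include_reference=False)
    row = t[t.level == "B"].iloc[0]
    s = np.sort(b)
    # equal-tailed interval endpoints from the empirical quantiles
    assert row["or"] == pytest.approx(np.exp(b.mean()), rel=1e-12)
    assert row.lo == pytest.approx(np.exp(np.quantile(s, 0.025)), rel=1e-9)
    assert row.hi == pytest.approx(np.exp(np.quantile(s, 0.975)), rel=1e-9)
    assert row.lo <= row["or"] <= row.hi


def _three_child_setup():
    ds = make_toy_dataset([1, 0, 1], [0, 1, 2], ["A", "B"], ["A", "B", "A"])
    design = encode_factors(ds)
    graph = AdjacencyGraph.from_edges(ds.region_labels, [("R0", "R1"), ("R1", "R2")])
    return ds, ModelSpec("M4", design, graph)


def test_all_zero_draws_predict_fifty_percent():
    ds, spec = _three_child_setup()
    cs = _chainset(
        np.zeros((10, 2)), ("(Intercept)", "x=B"),
        u=np.zeros((10, 3)), v=np.zeros((10, 3)),
    )
    t = predicted_region_prevalence(cs, ds, spec)
    assert t.predicted_prevalence.tolist() == [50.0, 50.0, 50.0]


def test_single_draw_matches_hand_computation():
    ds, spec = _three_child_setup()
    beta = np.array([0.4, -0.3])
    u = np.array([0.1, -0.2, 0.1])
    v = np.array([-0.05, 0.0, 0.05])
    # two chains of one identical draw each
    cs = _chainset(
        np.tile(beta, (2, 1)), ("(Intercept)", "x=B"),
        u=np.tile(u, (2, 1)), v=np.tile(v, (2, 1)),
    )
    t = predicted_region_prevalence(cs, ds, spec).set_index("region")
    etas = [0.4 + 0.1 - 0.05, 0.4 - 0.3 - 0.2 + 0.0, 0.4 + 0.1 + 0.05]
    for region, eta in zip(("R0", "R1", "R2"), etas):
        expected = round(100 * float(inverse_logit(eta)), 2)
        assert t.loc[region, "predicted_prevalence"] == pytest.approx(expected, abs=5e-3)


def test_shifting_v_raises_region_prevalence():
    ds, spec = _three_child_setup()
    rng = np.random.default_rng(1)
    beta = rng.normal(0, 0.3, (20, 2))
    u = rng.normal(0, 0.2, (20, 3))
    v = rng.normal(0, 0.2, (20, 3))
    base = predicted_region_prevalence(_chainset(beta, ("(Intercept)", "x=B"), u=u, v=v), ds, spec)
    v_up = v.copy()
    v_up[:, 1] += 0.5
    bumped = predicted_region_prevalence(
        _chainset(beta, ("(Intercept)", "x=B"), u=u, v=v_up), ds, spec
    )
    assert bumped.set_index("region").loc["R1", "predicted_prevalence"] > base.set_index(
        "region"
    ).loc["R1", "predicted_prevalence"]
    assert bumped.set_index("region").loc["R0", "predicted_prevalence"] == base.set_index(
        "region"
    ).loc["R0", "predicted_prevalence"]


def test_random_effect_summary_oracle_and_centering():
    rng = np.random.default_rng(2)
    u = rng.normal(0, 0.1, (500, 3))
    u -= u.mean(axis=1, keepdims=True)
    v = rng.normal(0, 0.1, (500, 3))
    cs = _chainset(np.zeros((500, 2)), ("(Intercept)", "x=B"), u=u, v=v)
    t = random_effect_summary(cs)
    u_rows = t[t.effect == "u"].set_index("region")
    assert u_rows["mean"].sum() == pytest.approx(0.0, abs=1e-12)
    for j, region in enumerate(("R0", "R1", "R2")):
        assert u_rows.loc[region, "sd"] == pytest.approx(u[:, j].std(ddof=1), rel=1e-9)


@pytest.mark.parametrize(
    "value,category",
    [(-0.02, "low"), (0.0, "low"), (0.05, "moderate"), (0.1, "moderate"), (0.11, "high")],
)
def test_effect_category_bins(value, category):
    assert effect_category(value) == category


def test_models_without_effects_cannot_be_summarised():
    cs = _chainset(np.zeros((10, 2)), ("(Intercept)", "x=B"))
    with pytest.raises(ValueError):
        random_effect_summary(cs)
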