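"""End-to-end workflow: describe -> fit -> diagnose -> report.

The pipeline is driven by a YAML (or dict) configuration validated with
pydantic.  All randomness flows from one root seed, split deterministically
per stage, so re-running with the same configuration reproduces every
numeric output byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .datasets import ChildDataset, guinea_schema, load_dataset, load_schema
from .descriptive import TwoByTwo, crude_odds_ratio, frequency_table, prevalence_by_group
from .diagnostics import compare_models, dic, rhat_table
from .mcmc import McmcConfig, run_chains
from .model import MODEL_KINDS, ModelSpec, PriorSpec
from .datasets import encode_factors
from .simulate import default_guinea_config, generate
from .spatial import guinea_graph, read_adjacency
from .summaries import posterior_or_table, predicted_region_prevalence, random_effect_summary

__all__ = ["PipelineConfig", "run_pipeline"]


class SimulateBlock(BaseModel):
    n: int | None = None
    sigma2_true: float | None = None
    tau2_true: float | None = None


class DataBlock(BaseModel):
    csv: str | None = None
    schema_file: str | None = None
    simulate: SimulateBlock | None = None

    @field_validator("csv")
    @classmethod
    def _one_source(cls, v, info):
        return v


class McmcBlock(BaseModel):
    n_iter: int = 100_000
    burn_in: int = 5_000
    n_chains: int = 2
    thin: int = 1


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    data: DataBlock
    adjacency: str | None = None
    models: list[str] = Field(default_factory=lambda: list(MODEL_KINDS))
    mcmc: McmcBlock = Field(default_factory=McmcBlock)
    seed: int = 0
    output: str = "anemiamap_output"

    @field_validator("models")
    @classmethod
    def _known_models(cls, v):
        bad = [m for m in v if m not in MODEL_KINDS]
        if bad:
            raise ValueError(f"unknown model kind(s) {bad}; expected subset of {MODEL_KINDS}")
        if not v:
            raise ValueError("at least one model must be requested")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.model_validate(yaml.safe_load(Path(path).read_text()))


def _stage_seed(root: int, stage: str) -> int:
    # stable across processes (unlike builtin hash)
    import zlib

    ss = np.random.SeedSequence([root, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def _resolve_data(cfg: PipelineConfig, out: Path) -> tuple[ChildDataset, dict | None]:
    d = cfg.data
    if (d.csv is None) == (d.simulate is None):
        raise ValueError("config must name exactly one data source: data.csv or data.simulate")
    if d.csv is not None:
        schema = load_schema(d.schema_file) if d.schema_file else guinea_schema()
        return load_dataset(d.csv, schema), None
    sim = default_guinea_config()
    if d.simulate.n is not None:
        sim.n = d.simulate.n
    if d.simulate.sigma2_true is not None:
        sim.sigma2_true = d.simulate.sigma2_true
    if d.simulate.tau2_true is not None:
        sim.tau2_true = d.simulate.tau2_true
    ds, truth = generate(sim, seed=_stage_seed(cfg.seed, "simulate"))
    ds.to_csv(out / "synthetic_data.csv")
    (out / "synthetic_truth.json").write_text(
        json.dumps(
            {
                "beta": dict(zip(truth["beta_names"], truth["beta"].tolist())),
                "u": truth["u"].tolist(),
                "v": truth["v"].tolist(),
                "sigma2": truth["sigma2"],
                "tau2": truth["tau2"],
            },
            indent=2,
        )
    )
    return ds, truth


def _resolve_graph(cfg: PipelineConfig):
    if cfg.adjacency is None:
        return None
    if cfg.adjacency == "guinea":
        return guinea_graph()
    return read_adjacency(cfg.adjacency)


def describe_stage(ds: ChildDataset, out: Path) -> None:
    """Frequency, prevalence-by-region, and crude region odds-ratio tables."""
    freq = []
    for var in ["anemia", "region", *ds.schema.levels]:
        t = frequency_table(ds, var)
        t.insert(0, "variable", var)
        freq.append(t)
    pd.concat(freq).to_csv(out / "frequencies.csv", index=False)
    prev = prevalence_by_group(ds, "region")
    prev.to_csv(out / "prevalence_by_region.csv", index=False)

    ref = ds.region_labels[0]
    pos = [(int(ds.y[ds.region == j].sum()), int((ds.region == j).sum())) for j in range(ds.n_regions)]
    c, ref_n = pos[0]
    rows = []
    for j in range(1, ds.n_regions):
        a, n_j = pos[j]
        s = crude_odds_ratio(TwoByTwo(a, n_j - a, c, ref_n - c), label=ds.region_labels[j])
        o, lo, hi = s.rounded()
        rows.append((s.label, ref, o, lo, hi))
    pd.DataFrame(rows, columns=["region", "reference", "or", "lo", "hi"]).to_csv(
        out / "crude_region_or.csv", index=False
    )


def run_pipeline(config: PipelineConfig | str | Path, **overrides) -> Path:
    """Run the full workflow; returns the artifact directory.

    ``overrides`` replace top-level config fields (seed, models, output, ...).
    Stage order: describe, fit (each requested model), diagnose, report.  A
    manifest records the configuration, per-stage seeds, and package version.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    if overrides:
        config = config.model_copy(update=overrides)
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)

    graph = _resolve_graph(config)
    needs_graph = [m for m in config.models if m in ("M3", "M4")]
    if needs_graph and graph is None:
        raise ValueError(
            f"models {needs_graph} need an adjacency graph but the config has no "
            "'adjacency' entry (use a neighbours file path or 'guinea')"
        )

    ds, _truth = _resolve_data(config, out)
    describe_stage(ds, out)

    design = encode_factors(ds)
    priors = PriorSpec()
    dics = []
    for kind in config.models:
        spec = ModelSpec(kind=kind, design=design, graph=graph if kind in ("M3", "M4") else None)
        mcfg = McmcConfig(
            n_iter=config.mcmc.n_iter,
            burn_in=config.mcmc.burn_in,
            n_chains=config.mcmc.n_chains,
            thin=config.mcmc.thin,
            seed=_stage_seed(config.seed, f"fit-{kind}"),
        )
        chains = run_chains(spec, priors, ds, mcfg)
        chains.save(out, stem=f"chains_{kind}")
        rhat_table(chains).to_csv(out / f"rhat_{kind}.csv", index=False)
        dics.append(dic(chains, spec, ds))
        posterior_or_table(chains).to_csv(out / f"or_table_{kind}.csv", index=False)
        if kind != "M1":
            predicted_region_prevalence(chains, ds, spec).to_csv(
                out / f"predicted_prevalence_{kind}.csv", index=False
            )
            random_effect_summary(chains).to_csv(
                out / f"random_effects_{kind}.csv", index=False
            )

    if len(dics) >= 2:
        comparison = compare_models(dics)
        comparison.to_csv(out / "dic_comparison.csv", index=False)
        (out / "dic.json").write_text(
            json.dumps(
                {r.kind: {"d_bar": r.d_bar, "d_hat": r.d_hat, "p_d": r.p_d, "dic": r.dic}
                 for r in dics},
                indent=2,
            )
        )
    elif dics:
        r = dics[0]
        (out / "dic.json").write_text(
            json.dumps({r.kind: {"d_bar": r.d_bar, "d_hat": r.d_hat, "p_d": r.p_d, "dic": r.dic}})
        )

    manifest = {
        "version": __version__,
        "config": config.model_dump(),
        "stage_seeds": {
            "simulate": _stage_seed(config.seed, "simulate"),
            **{m: _stage_seed(config.seed, f"fit-{m}") for m in config.models},
        },
        "n_children": ds.n,
        "dropped_rows": ds.dropped,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
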