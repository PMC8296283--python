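import numpy as np
import pandas as pd
import pytest

from anemiamap import (
    ChildDataset,
    Schema,
    default_guinea_config,
    encode_factors,
    generate,
    guinea_graph,
)
from anemiamap import guinea


@pytest.fixture(scope="session")
def graph():
    return guinea_graph()


@pytest.fixture(scope="session")
def synthetic_small():
    """A small synthetic survey (400 children) with its truth record."""
    cfg = default_guinea_config()
    cfg.n = 400
    return generate(cfg, seed=7)


@pytest.fixture(scope="session")
def synthetic_default():
    """A full-size synthetic survey under the default study conditions."""
    return generate(default_guinea_config(), seed=11)


def make_toy_dataset(y, region, levels, values, n_regions=3, references=None):
    """Hand-built dataset: one covariate named 'x' with the given levels."""
    schema = Schema(
        levels={"x": tuple(levels)},
        references={"x": (references or levels[0])},
        regions=tuple(f"R{j}" for j in range(n_regions)),
    )
    return ChildDataset(
        y=np.asarray(y),
        region=np.asarray(region),
        region_labels=schema.regions,
        covariates=pd.DataFrame({"x": list(values)}),
        schema=schema,
    )


@pytest.fixture(scope="session")
def survey_margins_dataset():
    """Deterministic dataset whose margins equal the published survey tables.

    Region counts and per-region positives reproduce the published
    prevalence table exactly; a 'sex' column carries the published
    male/female margin.  Joint structure is arbitrary (margins only).
    """
    rows_region = []
    rows_y = []
    for j, r in enumerate(guinea.REGIONS):
        n_j = int(guinea.REGION_TABLE[r]["n"])
        pos = guinea.region_positives()[r]
        rows_region += [j] * n_j
        rows_y += [1] * pos + [0] * (n_j - pos)
    n = len(rows_y)
    sex = ["Male"] * 1340 + ["Female"] * (n - 1340)
    schema = Schema(
        levels={"sex": ("Male", "Female")},
        references={"sex": "Male"},
        regions=guinea.REGIONS,
    )
    return ChildDataset(
        y=np.asarray(rows_y),
        region=np.asarray(rows_region),
        region_labels=guinea.REGIONS,
        covariates=pd.DataFrame({"sex": sex}),
        schema=schema,
    )
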