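"""Child-level dataset handling: loading, validation, and dummy encoding.

The unit of analysis is a child; each row carries a binary anemia outcome,
an areal region label, and a set of categorical covariates with declared
level sets.  Analysis is complete-case: rows with a missing or undeclared
covariate level are dropped and counted, mirroring survey analyses restricted
to children with full covariate information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import guinea

__all__ = [
    "Schema",
    "ChildDataset",
    "DesignMatrix",
    "load_dataset",
    "load_schema",
    "guinea_schema",
    "encode_factors",
    "decode_column",
]

#: Accepted encodings of the binary outcome column.
_OUTCOME_MAP = {"0": 0, "1": 1, "Negative": 0, "Positive": 1, "negative": 0, "positive": 1}


@dataclass(frozen=True)
class Schema:
    """Declared covariate level sets, reference levels, and region order.

    Parameters
    ----------
    levels
        Mapping covariate name -> ordered tuple of admissible levels.
    references
        Mapping covariate name -> reference level (must be in ``levels``).
    regions
        Region labels in the fixed (alphabetical) order used for indexing.
    """

    levels: dict[str, tuple[str, ...]]
    references: dict[str, str]
    regions: tuple[str, ...] = guinea.REGIONS

    def __post_init__(self):
        for cov, ref in self.references.items():
            if cov not in self.levels:
                raise ValueError(f"reference declared for unknown covariate {cov!r}")
            if ref not in self.levels[cov]:
                raise ValueError(f"reference level {ref!r} not among levels of {cov!r}")


@dataclass
class ChildDataset:
    """Validated child-level table.

    Attributes
    ----------
    y
        Binary outcome per child (1 = anemia positive), shape (n,).
    region
        0-based region index per child, shape (n,).
    region_labels
        Region names; ``region`` indexes into this tuple.
    covariates
        Categorical covariate columns (object dtype), one row per child.
    schema
        The declared level sets / references the data were validated against.
    dropped
        Number of input rows removed by the complete-case filter.
    """

    y: np.ndarray
    region: np.ndarray
    region_labels: tuple[str, ...]
    covariates: pd.DataFrame
    schema: Schema
    dropped: int = 0

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        self.region = np.asarray(self.region, dtype=np.int64)
        bad = set(np.unique(self.y)) - {0, 1}
        if bad:
            raise ValueError(f"outcome values outside {{0,1}}: {sorted(bad)}")
        if self.region.min(initial=0) < 0 or self.region.max(initial=0) >= len(self.region_labels):
            raise ValueError("region index out of range")
        if len(self.covariates) != len(self.y):
            raise ValueError("covariate table and outcome length differ")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_per_region(self) -> np.ndarray:
        """Children per region (in region-label order)."""
        return np.bincount(self.region, minlength=self.n_regions)

    def to_frame(self) -> pd.DataFrame:
        """Flat table view: outcome, region label, covariates."""
        df = self.covariates.copy()
        df.insert(0, "region", [self.region_labels[j] for j in self.region])
        df.insert(0, "anemia", self.y)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DesignMatrix:
    """Intercept + treatment-coded dummy columns for the declared covariates.

    For a categorical covariate with L declared levels, exactly L-1 columns
    are emitted (the reference level produces none), ordered as declared.
    Column names are ``"covariate=level"``; the intercept is ``"(Intercept)"``.
    """

    X: np.ndarray
    column_names: tuple[str, ...]
    reference_levels: dict[str, str]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def column_index(self, name: str) -> int:
        return self.column_names.index(name)


def load_schema(path: str | Path) -> Schema:
    """Read a YAML/JSON schema file declaring level sets and references.

    Expected structure::

        regions: [Boke, Conakry, ...]        # optional
        covariates:
          residence:
            levels: [Urban, Rural]
            reference: Urban
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    covs = raw["covariates"]
    levels = {c: tuple(d["levels"]) for c, d in covs.items()}
    refs = {c: d.get("reference", d["levels"][0]) for c, d in covs.items()}
    regions = tuple(raw.get("regions", guinea.REGIONS))
    return Schema(levels=levels, references=refs, regions=regions)


def guinea_schema() -> Schema:
    """Default schema matching the Guinea survey covariate set (k = 22)."""
    levels = {c: tuple(d) for c, d in guinea.COVARIATE_COUNTS.items()}
    return Schema(levels=levels, references=dict(guinea.REFERENCE_LEVELS))


def load_dataset(
    path: str | Path,
    schema: Schema | None = None,
    *,
    outcome_col: str = "anemia",
    region_col: str = "region",
) -> ChildDataset:
    """Load a child-level CSV, validate against the schema, drop incomplete rows.

    Region labels are mapped to indices in the schema's fixed region order
    (alphabetical for the bundled Guinea schema).  Rows with a missing value
    or an undeclared covariate level are dropped and counted in
    ``ChildDataset.dropped``.  An unknown region label or an unparseable
    outcome is a hard error, not a droppable condition.
    """
    schema = schema or guinea_schema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = [outcome_col, region_col, *schema.levels]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")

    bad_outcome = ~df[outcome_col].isin(_OUTCOME_MAP)
    if bad_outcome.any():
        val = df.loc[bad_outcome, outcome_col].iloc[0]
        raise ValueError(f"outcome value {val!r} not in {{0,1,Positive,Negative}}")
    region_order = {r: j for j, r in enumerate(schema.regions)}
    bad_region = ~df[region_col].isin(region_order)
    if bad_region.any():
        val = df.loc[bad_region, region_col].iloc[0]
        raise ValueError(f"unknown region label {val!r}")

    keep = pd.Series(True, index=df.index)
    for cov, lv in schema.levels.items():
        keep &= df[cov].isin(lv)
    dropped = int((~keep).sum())
    df = df[keep]

    y = df[outcome_col].map(_OUTCOME_MAP).to_numpy(dtype=np.int8)
    region = df[region_col].map(region_order).to_numpy(dtype=np.int64)
    covariates = df[list(schema.levels)].reset_index(drop=True)
    return ChildDataset(
        y=y,
        region=region,
        region_labels=tuple(schema.regions),
        covariates=covariates,
        schema=schema,
        dropped=dropped,
    )


def encode_factors(ds: ChildDataset, refs: dict[str, str] | None = None) -> DesignMatrix:
    """Build the treatment-coded design matrix (intercept + L-1 dummies each).

    Columns are ordered as (intercept, covariates in declared order, levels in
    declared order minus the reference).  A child at all reference levels
    encodes to the row (1, 0, ..., 0).
    """
    refs = dict(refs or ds.schema.references)
    cols = [np.ones(ds.n)]
    names = ["(Intercept)"]
    for cov, lv in ds.schema.levels.items():
        if len(lv) < 2:
            raise ValueError(f"covariate {cov!r} has a single level; no contrast")
        ref = refs.get(cov, lv[0])
        if ref not in lv:
            raise ValueError(f"reference {ref!r} not a level of {cov!r}")
        refs[cov] = ref
        values = ds.covariates[cov].to_numpy()
        for level in lv:
            if level == ref:
                continue
            cols.append((values == level).astype(float))
            names.append(f"{cov}={level}")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, column_names=tuple(names), reference_levels=refs)


def decode_column(name: str) -> tuple[str, str] | None:
    """Invert a design column name to (covariate, level); None for intercept."""
    if name == "(Intercept)":
        return None
    cov, _, level = name.partition("=")
    if not level:
        raise ValueError(f"not a dummy column name: {name!r}")
    return cov, level
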