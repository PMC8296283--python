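"""Descriptive stage: frequency tables, prevalence by group, crude odds ratios.

Crude (unadjusted) odds ratios come from 2x2 exposure-by-outcome tables with
Woolf (log-normal Wald) 95% confidence intervals:
``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.  Display rounding is
half-up to two decimals; full precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ChildDataset

__all__ = [
    "TwoByTwo",
    "ORSummary",
    "frequency_table",
    "prevalence_by_group",
    "crude_odds_ratio",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed survey tables)."""
    factor = 10.0**ndigits
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x))


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table: exposed (a+, b-) vs reference (c+, d-) counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    def swapped(self) -> "TwoByTwo":
        """Exchange exposure rows (inverts the odds ratio)."""
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class ORSummary:
    """Odds ratio with an interval; ``lo``/``hi`` are NaN when undefined."""

    or_: float
    lo: float
    hi: float
    label: str = ""

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return tuple(round_half_up(v, ndigits) for v in (self.or_, self.lo, self.hi))


def frequency_table(ds: ChildDataset, var: str) -> pd.DataFrame:
    """Counts and percentages per declared level of one variable.

    ``var`` may be a covariate, ``"region"`` or ``"anemia"``.  Levels appear
    in declared order; percents are 100*count/N rounded half-up to 2 decimals.
    """
    if var == "region":
        values = pd.Series([ds.region_labels[j] for j in ds.region])
        order = list(ds.region_labels)
    elif var == "anemia":
        values = pd.Series(np.where(ds.y == 1, "Positive", "Negative"))
        order = ["Negative", "Positive"]
    else:
        if var not in ds.covariates.columns:
            raise KeyError(f"unknown variable {var!r}")
        values = ds.covariates[var]
        order = list(ds.schema.levels[var])
    counts = values.value_counts()
    rows = [
        (lv, int(counts.get(lv, 0)), round_half_up(100.0 * counts.get(lv, 0) / ds.n))
        for lv in order
    ]
    return pd.DataFrame(rows, columns=["level", "count", "percent"])


def prevalence_by_group(ds: ChildDataset, group: str = "region") -> pd.DataFrame:
    """Outcome prevalence (%) per level of a grouping variable.

    Empty levels are omitted.  Prevalence is 100 * positives / N within the
    level, rounded half-up to two decimals for display.
    """
    freq = frequency_table(ds, group)
    if group == "region":
        values = np.asarray([ds.region_labels[j] for j in ds.region])
    else:
        values = ds.covariates[group].to_numpy()
    rows = []
    for lv, n_level, _ in freq.itertuples(index=False):
        if n_level == 0:
            continue
        pos = int(ds.y[values == lv].sum())
        rows.append((lv, n_level, round_half_up(100.0 * pos / n_level)))
    return pd.DataFrame(rows, columns=["level", "N", "prevalence"])


def crude_odds_ratio(t: TwoByTwo, level: float = 0.95, label: str = "") -> ORSummary:
    """Crude odds ratio (a/b)/(c/d) with a Woolf confidence interval.

    The OR needs b, c > 0; the Woolf CI additionally needs a, d > 0 and is
    reported as NaN bounds otherwise (no continuity correction is applied).
    """
    if t.b == 0 or t.c == 0:
        raise ZeroDivisionError("odds ratio undefined: zero b or c cell")
    or_ = (t.a / t.b) / (t.c / t.d)
    if min(t.a, t.b, t.c, t.d) == 0:
        return ORSummary(or_, float("nan"), float("nan"), label)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)
    log_or = np.log(or_)
    return ORSummary(or_, float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)), label)
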