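"""Descriptive stage on the published Guinea survey margins.

The per-region anemia-positive counts are exactly reconstructible from the
published N and prevalence columns, so the whole descriptive stage — outcome
frequencies, prevalence by region, and crude odds ratios with Woolf 95%
CIs — can be recomputed without the restricted microdata.
"""

import numpy as np
import pandas as pd

from anemiamap import ChildDataset, Schema, TwoByTwo, crude_odds_ratio, frequency_table, prevalence_by_group
from anemiamap import guinea

# Rebuild a child-level table whose margins equal the published tables.
rows_region, rows_y = [], []
positives = guinea.region_positives()
for j, region in enumerate(guinea.REGIONS):
    n_j = int(guinea.REGION_TABLE[region]["n"])
    pos = positives[region]
    rows_region += [j] * n_j
    rows_y += [1] * pos + [0] * (n_j - pos)

schema = Schema(levels={"sex": ("Male", "Female")}, references={"sex": "Male"})
ds = ChildDataset(
    y=np.asarray(rows_y),
    region=np.asarray(rows_region),
    region_labels=guinea.REGIONS,
    covariates=pd.DataFrame({"sex": ["Male"] * 1340 + ["Female"] * (len(rows_y) - 1340)}),
    schema=schema,
)

print("Outcome frequencies (count, percent of 2609 children):")
print(frequency_table(ds, "anemia").to_string(index=False))

print("\nAnemia prevalence by region (percent of the region's children):")
print(prevalence_by_group(ds, "region").to_string(index=False))

print("\nCrude odds ratios vs Boke (odds of anemia relative to the reference")
print("region; Woolf 95% CI — an interval excluding 1 marks a region whose")
print("crude risk differs from Boke's):")
ref_pos, ref_n = positives["Boke"], int(guinea.REGION_TABLE["Boke"]["n"])
for region in guinea.REGIONS[1:]:
    n_r = int(guinea.REGION_TABLE[region]["n"])
    t = TwoByTwo(positives[region], n_r - positives[region], ref_pos, ref_n - ref_pos)
    o, lo, hi = crude_odds_ratio(t).rounded()
    print(f"  {region:<10} {o:5.2f} [{lo:4.2f}, {hi:4.2f}]")
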