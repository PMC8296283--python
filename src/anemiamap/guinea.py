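"""Bundled reference data for the Guinea MICS5 (2016) child-anemia application.

The package's motivating application is the 2016 Guinea Multiple Indicator
Cluster Survey round 5 (MICS5): 2609 children under five with complete
covariate information across Guinea's eight administrative regions.  The raw
microdata are distributed by UNICEF (https://mics.unicef.org/surveys) and are
not redistributable here, but the published summary tables — covariate
margins, anemia prevalence by region, and the crude/adjusted odds-ratio
tables — are embedded below.  They serve three purposes:

* calibrating the synthetic-data generator to realistic survey margins,
* reconstructing region-level 2x2 tables for crude odds ratios (the
  per-region counts of anemia-positive children are recoverable exactly from
  N and the printed prevalence), and
* providing reference numbers for the descriptive stage.

Regions are always ordered alphabetically; every region-indexed array in the
package follows :data:`REGIONS`.
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = (
    "Boke",
    "Conakry",
    "Faranah",
    "Kankan",
    "Kindia",
    "Labe",
    "Mamou",
    "Nzerekore",
)

#: Undirected region adjacency (first-order contiguity of Guinea's eight
#: administrative regions, read off the national map).  Conakry is a coastal
#: enclave inside Kindia; Boke borders Kindia and Labe; the forest region
#: Nzerekore touches Faranah and Kankan.
ADJACENCY: tuple[tuple[str, str], ...] = (
    ("Boke", "Kindia"),
    ("Boke", "Labe"),
    ("Conakry", "Kindia"),
    ("Kindia", "Mamou"),
    ("Mamou", "Labe"),
    ("Mamou", "Faranah"),
    ("Labe", "Faranah"),
    ("Faranah", "Kankan"),
    ("Faranah", "Nzerekore"),
    ("Kankan", "Nzerekore"),
)

N_CHILDREN = 2609

#: Children per region and observed anemia prevalence (%) from the survey.
#: ``positives`` = round(N * prevalence / 100); the reconstruction is exact —
#: the positives sum to the published national count of 2009 anemic children.
REGION_TABLE: dict[str, dict[str, float]] = {
    "Boke": {"n": 467, "prevalence": 79.01},
    "Conakry": {"n": 268, "prevalence": 70.52},
    "Faranah": {"n": 369, "prevalence": 77.24},
    "Kankan": {"n": 308, "prevalence": 75.65},
    "Kindia": {"n": 288, "prevalence": 80.56},
    "Labe": {"n": 245, "prevalence": 69.39},
    "Mamou": {"n": 229, "prevalence": 69.87},
    "Nzerekore": {"n": 435, "prevalence": 85.29},
}

#: Model-predicted prevalence (%) per region after adjusting for exchangeable
#: (non-spatial) region effects, as published for the survey analysis.
PREDICTED_PREVALENCE: dict[str, float] = {
    "Boke": 77.98,
    "Conakry": 70.32,
    "Faranah": 77.71,
    "Kankan": 77.30,
    "Kindia": 78.96,
    "Labe": 72.23,
    "Mamou": 71.40,
    "Nzerekore": 83.60,
}

#: Outcome margins: counts of anemia and malaria status among the 2609
#: children (prevalences 77.00% and 15.14%).
OUTCOME_COUNTS: dict[str, dict[str, int]] = {
    "anemia": {"Positive": 2009, "Negative": 600},
    "malaria": {"Positive": 395, "Negative": 2214},
}

#: Covariate margins (level -> count) for the adjusted-model covariate set,
#: in the declared level order with the reference level first.  These are the
#: survey's published frequency distributions.
COVARIATE_COUNTS: dict[str, dict[str, int]] = {
    "residence": {"Urban": 752, "Rural": 1857},
    "child_age": {
        "0-11": 170,
        "12-23": 427,
        "24-35": 523,
        "36-47": 710,
        "48-59": 779,
    },
    "wealth": {
        "Poorest": 644,
        "Second": 671,
        "Middle": 522,
        "Fourth": 458,
        "Richest": 314,
    },
    "mother_education": {"None": 1950, "Primary": 329, "Secondary+": 330},
    "ethnicity": {
        "Soussou": 435,
        "Peul": 960,
        "Malinke": 665,
        "Kissi": 156,
        "Toma": 62,
        "Guerze/Kono/Mano": 187,
        "Other": 144,
    },
    "religion": {"Muslim": 2203, "Christian": 353, "Other": 53},
    "own_tv": {"Yes": 666, "No": 1943},
    "electricity": {"Yes": 706, "No": 1903},
}

#: Reference level per covariate (the "1" rows of the published OR tables).
REFERENCE_LEVELS: dict[str, str] = {
    "residence": "Urban",
    "child_age": "0-11",
    "wealth": "Poorest",
    "mother_education": "None",
    "ethnicity": "Soussou",
    "religion": "Muslim",
    "own_tv": "Yes",
    "electricity": "Yes",
}

#: Published crude (unadjusted) region odds ratios vs Boke, with Woolf 95%
#: CIs, for cross-checking the descriptive stage.
CRUDE_REGION_OR: dict[str, tuple[float, float, float]] = {
    "Conakry": (0.64, 0.45, 0.90),
    "Faranah": (0.90, 0.65, 1.25),
    "Kankan": (0.83, 0.59, 1.16),
    "Kindia": (1.10, 0.76, 1.59),
    "Labe": (0.60, 0.42, 0.86),
    "Mamou": (0.62, 0.43, 0.88),
    "Nzerekore": (1.54, 1.09, 2.18),
}

#: Published DIC values for the four models fitted to the survey data
#: (plain logistic, + exchangeable effects, + ICAR effects, convolution).
PUBLISHED_DIC: dict[str, float] = {"M1": 2724.9, "M2": 2721.9, "M3": 2722.9, "M4": 2721.9}


def region_positives() -> dict[str, int]:
    """Reconstruct anemia-positive counts per region from N and prevalence.

    Uses half-up rounding of ``n * prevalence / 100``; the reconstruction is
    validated by the positives summing to the published national total.
    """
    import math

    out = {}
    for name, row in REGION_TABLE.items():
        out[name] = int(math.floor(row["n"] * row["prevalence"] / 100.0 + 0.5))
    return out


def region_counts_csv_rows() -> list[tuple[str, int, int]]:
    """Per-region (label, positives, negatives) tuples in alphabetical order."""
    pos = region_positives()
    return [(r, pos[r], int(REGION_TABLE[r]["n"]) - pos[r]) for r in REGIONS]
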