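"""Published summary figures from the 2017-2020 CAIGE bread-wheat evaluation.

These are aggregates printed in the program's public reporting; the raw
plot-level and grain-handler data are not redistributable, so the package
carries only these small summaries.  They serve as fixture inputs for the
economics summary (present-value sums) and as reference cohort counts for the
selection-tool checks.
"""

from __future__ import annotations

import pandas as pd

#: Present-value sums (2020 AUD) of the program benefit-cost analysis, with the
#: funder attribution fraction.
BENEFIT_COST_AGGREGATES = {
    "sum_investment": 14_194_045,
    "sum_benefits": 286_444_855,
    "attribution": 0.455,
}

#: Evaluated cohort sizes by year and germplasm source.
COHORT_SIZES = pd.DataFrame(
    {
        "Australian": [12, 14, 12, 15],
        "CIMMYT": [112, 164, 178, 373],
        "ICARDA": [111, 135, 105, 271],
    },
    index=[2017, 2018, 2019, 2020],
)

#: Genotypes per year and source in the top 10% for additive overall performance.
TOP10_ADDITIVE = pd.DataFrame(
    {
        "Australian": [7, 10, 7, 10],
        "CIMMYT": [6, 13, 17, 48],
        "ICARDA": [10, 6, 3, 7],
    },
    index=[2017, 2018, 2019, 2020],
)

#: Genotypes per year and source in the top 10% for total overall performance.
TOP10_TOTAL = pd.DataFrame(
    {
        "Australian": [9, 7, 7, 9],
        "CIMMYT": [6, 17, 16, 46],
        "ICARDA": [8, 5, 4, 10],
    },
    index=[2017, 2018, 2019, 2020],
)

#: Dataset summary ranges by year: environments, entries, percent replication,
#: environment mean yield (t/ha), and trial reliability.
DATASET_SUMMARY = pd.DataFrame(
    [
        (2017, 7, (190, 234), (52, 79), (1.9, 6.6), (0.56, 0.90)),
        (2018, 6, (194, 309), (14, 70), (1.6, 5.7), (0.53, 0.82)),
        (2019, 7, (180, 312), (18, 100), (0.6, 4.0), (0.47, 0.85)),
        (2020, 14, (232, 501), (5, 32), (1.2, 5.6), (0.35, 0.89)),
    ],
    columns=["year", "n_locations", "n_lines", "pct_replication",
             "env_mean_yield", "reliability"],
).set_index("year")
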