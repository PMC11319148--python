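"""Convert raw disease severities to the common ordinal scale and summarize.

Raw scores (1-9 severity here) become the nine-point reaction scale from R
(resistant) to VS (very susceptible); the summary reports the percentage of
scored genotypes rated R to MR per disease — the figure pathologists quote
when describing a cohort's resistance profile.
"""

from pathlib import Path

import pandas as pd

from germeval.scales import pct_resistant, to_ordinal

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    raw = pd.read_csv(OUT / "disease_raw.csv")
    raw["category"] = [to_ordinal(s, sch) for s, sch in zip(raw["raw_score"], raw["scheme"])]
    raw.to_csv(OUT / "disease_categories.csv", index=False)
    summary = pct_resistant(raw)
    summary.round(1).to_csv(OUT / "disease_summary.csv", header=["pct_R_or_MR"])
    print("percentage of genotypes rated R to MR, by disease:")
    print(summary.round(1).to_string())


if __name__ == "__main__":
    main()
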