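"""Factor-analytic selection tools on the fitted MET model.

Computes per-genotype overall performance (additive and total), RMSD
stability and responsiveness from the serialized fit, and counts genotypes
per germplasm source in the top 10% — the summary a breeding program uses to
shortlist parents and release candidates.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from germeval.famm import FAModelFit, METDataset
from germeval.selection import selection_summary, top_fraction

OUT = Path(__file__).resolve().parents[1] / "results"


def load_fit() -> FAModelFit:
    with open(OUT / "famm_fit.json") as fh:
        d = json.load(fh)
    met = METDataset.from_csv(OUT / "met.csv")
    source = met.df.drop_duplicates("genotype").set_index("genotype")["source"] \
        if "source" in met.df.columns else None
    arr = lambda x: None if x is None else np.asarray(x)
    return FAModelFit(
        envs=d["envs"], genotypes=d["genotypes"],
        tau=pd.Series(d["tau"], index=d["envs"]),
        ka=d["ka"], ke=d["ke"],
        Lambda_a=arr(d["Lambda_a"]), psi_a=arr(d["psi_a"]),
        Lambda_i=arr(d["Lambda_i"]), psi_i=arr(d["psi_i"]),
        scores_a=arr(d["scores_a"]), scores_i=arr(d["scores_i"]),
        delta_a=None, delta_i=None, effects_a=None, effects_i=None,
        sigma2=pd.Series(d["sigma2"], index=d["envs"]),
        sigma2_block=d["sigma2_block"],
        loglik=d["loglik"], n_vparams=0, converged=True, boundary=False,
        source=source,
    )


def main() -> None:
    fit = load_fit()
    summ = selection_summary(fit)
    summ.to_csv(OUT / "selection_summary.csv")
    print(summ.describe().round(3).to_string())
    for measure in ("OP_additive", "OP_total"):
        counts, members = top_fraction(summ, measure, 0.10)
        print(f"\ntop 10% by {measure} ({len(members)} genotypes) by source:")
        print(counts.to_string())
    best = summ.sort_values("OP_additive", ascending=False).head(8)
    print("\nbest parents (high additive OP, low RMSD preferred):")
    print(best[["OP_additive", "OP_total", "RMSD", "source"]].round(3).to_string())


if __name__ == "__main__":
    main()
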