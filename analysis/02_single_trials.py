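"""Preliminary single-trial analyses: outlier screening and trial reliabilities.

Each environment is analysed on its own (random genotype, block, row, column
over a fixed mean) to flag outlying plots and compute the trial reliability
(1 - mean PEV / genetic variance), the unbalanced-design generalization of
line-mean heritability.  Writes results/single_trials.csv.
"""

from pathlib import Path

import pandas as pd

from germeval.famm import METDataset, detect_outliers, fit_single_trial, reliability

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    met = METDataset.from_csv(OUT / "met.csv")
    rows = []
    for env in met.envs:
        trial = met.environment(env)
        fit = fit_single_trial(trial)
        flags = detect_outliers(fit, threshold=3.0)
        rows.append({
            "env": env,
            "n_plots": fit.n_plots,
            "mean_yield": trial.df["yield"].mean(),
            "sigma2_g": fit.sigma2_g,
            "sigma2_e": fit.sigma2_e,
            "reliability": reliability(fit),
            "n_outliers": int(flags.sum()),
        })
    table = pd.DataFrame(rows).set_index("env")
    table.to_csv(OUT / "single_trials.csv")
    print(table.round(3).to_string())
    print(f"\nreliability range: {table['reliability'].min():.2f}"
          f"-{table['reliability'].max():.2f}; "
          f"{table['n_outliers'].sum()} plots flagged as outliers")


if __name__ == "__main__":
    main()
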