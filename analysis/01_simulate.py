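"""Simulate the study inputs: pedigree, p-rep MET, disease scores, economics.

Generates a pedigreed genotype cohort evaluated in an unbalanced p-rep MET
whose genetic effects follow a known factor-analytic structure, plus ordinal
disease scores and an economics ledger, and writes everything under
results/ for the later analysis steps.
"""

import sys
from pathlib import Path

from germeval import pedigree as pm
from germeval.synth import EconSimConfig, SimConfig, gen_disease, gen_econ, gen_met, gen_pedigree

OUT = Path(__file__).resolve().parents[1] / "results"

MET_CONFIG = SimConfig(
    n_founders=30, n_crosses=150,
    n_environments=8, n_genotypes=120,
    ka=2, ke=1,
    replication_fraction=(0.05, 1.0),
    seed=20240901,
)
ECON_CONFIG = EconSimConfig(seed=20240901)


def main(seed: int = MET_CONFIG.seed) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(**{**MET_CONFIG.__dict__, "seed": seed})

    ped = gen_pedigree(cfg)
    ped.to_csv(OUT / "pedigree.csv")
    A = pm.nrm(ped)
    A.to_csv(OUT / "nrm.csv")
    met, truth = gen_met(cfg, ped, A=A)
    met.to_csv(OUT / "met.csv")
    truth.to_json(OUT / "met_truth.json")
    print(f"pedigree: {len(ped)} records ({ped.df['purdy'].ne('').sum()} with Purdy strings)")
    print(f"MET: {len(met.df)} plots, {len(met.envs)} environments, "
          f"{len(met.genotypes)} genotypes")
    reps = met.df.groupby(['env', 'genotype']).size().groupby('env').apply(
        lambda s: 100.0 * (s == 2).mean())
    print("percent replication by environment:")
    print(reps.round(1).to_string())

    disease = gen_disease(n_genotypes=cfg.n_genotypes, seed=seed)
    disease.to_csv(OUT / "disease_raw.csv", index=False)

    production, prices, investment, econ_truth = gen_econ(
        EconSimConfig(**{**ECON_CONFIG.__dict__, "seed": seed}))
    production.to_csv(OUT / "production.csv", index=False)
    prices.to_csv(OUT / "prices.csv", index=False)
    investment.to_csv(OUT / "investment.csv", index=False)
    print(f"economics: {production['cultivar'].nunique()} cultivars over "
          f"{production['season'].nunique()} seasons; configured BCR "
          f"{econ_truth['bcr']:.2f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else MET_CONFIG.seed)
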