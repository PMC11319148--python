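"""Design next season's trials: packet allocation and p-rep layouts.

Allocates check and test genotype packets to locations (checks duplicated
everywhere, second test packets hierarchically to the key locations), then
builds a partially replicated row-column layout for the mother site and
reports the A-measure improvement delivered by the swap search.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from germeval.design import a_measure, allocate_locations, layout_prep, percent_replication

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 20240901) -> None:
    genotypes = pd.DataFrame(
        [{"genotype": f"CHK{i}", "role": "check"} for i in range(4)]
        + [{"genotype": f"T{i:03d}", "role": "test"} for i in range(60)]
    )
    locations = {"MotherSite": 100, "South": 80, "West": 72}
    plan = allocate_locations(genotypes, locations, key_locations=["MotherSite"])
    plan.df.to_csv(OUT / "allocation_plan.csv", index=False)
    per_loc = plan.df.groupby("location")["n_packets"].sum()
    print("packets allocated per location:")
    print(per_loc.to_string())

    pk = plan.packets("MotherSite")
    reps = pk.to_numpy()
    names = list(pk.index)
    n_plots = int(reps.sum())
    n_rows, n_cols = n_plots // 10, 10
    start = layout_prep(names, reps, n_rows, n_cols, seed=seed, n_iter=0)
    final = layout_prep(names, reps, n_rows, n_cols, seed=seed, n_iter=400)
    final.to_frame("MotherSite").to_csv(OUT / "layout_mother_site.csv", index=False)
    a0, a1 = a_measure(start), a_measure(final)
    print(f"\nmother-site layout: {n_rows} x {n_cols} plots, "
          f"{percent_replication(final):.1f}% replication")
    print(f"A-measure: {a0:.4f} (random start) -> {a1:.4f} after swap search "
          f"({100 * (a0 - a1) / a0:.1f}% lower)")


if __name__ == "__main__":
    main()
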