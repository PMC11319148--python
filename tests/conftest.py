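import numpy as np
import pandas as pd
import pytest

from germeval.famm import METDataset
from germeval.pedigree import PedigreeTable, build_pedigree


def random_pedigree(rng: np.random.Generator, n_members: int, n_founders: int | None = None,
                    selfing: bool = False) -> PedigreeTable:
    """Random valid pedigree built from explicit parent pairs (test helper)."""
    if n_founders is None:
        n_founders = max(2, n_members // 4)
    n_founders = min(n_founders, n_members)
    entries = [(f"I{i:03d}", (None, None)) for i in range(n_founders)]
    for i in range(n_founders, n_members):
        lo = i  # parents drawn from earlier individuals only
        p1 = int(rng.integers(lo))
        p2 = int(rng.integers(lo))
        if not selfing and p2 == p1 and lo > 1:
            p2 = (p1 + 1 + int(rng.integers(lo - 1))) % lo
        entries.append((f"I{i:03d}", (f"I{p1:03d}", f"I{p2:03d}")))
    return build_pedigree(entries)


def balanced_rcbd(rng: np.random.Generator, m: int = 60, r: int = 2,
                  sigma_g: float = 1.0, sigma_e: float = 1.0, mean: float = 3.0) -> METDataset:
    """Balanced randomized complete block design with known variance components."""
    g = rng.normal(0.0, sigma_g, m)
    rows = []
    for rep in range(r):
        order = rng.permutation(m)
        for pos, i in enumerate(order):
            rows.append({
                "env": "T1", "genotype": f"g{i:03d}", "block": rep + 1,
                "row": pos + 1, "col": rep + 1,
                "yield": mean + g[i] + rng.normal(0.0, sigma_e),
            })
    return METDataset(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
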