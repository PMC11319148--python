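"""Synthetic data generators with known ground truth.

Emulates the kind of data a national germplasm-evaluation network produces —
pedigreed genotype cohorts, unbalanced p-rep multi-environment yield trials
whose genetic effects follow a factor-analytic structure correlated by
pedigree kinship, ordinal disease scores, and an economics ledger — so every
downstream stage (NRM construction, FA-LMM fitting, selection tools, the
benefit-cost chain) can be tested end to end without any external download.

Default calibration follows the published 2017-2020 evaluation summary:
environment mean yields 0.6-6.6 t/ha, per-trial replication 5-100%, trial
reliabilities 0.35-0.90 (implied by the residual-variance range against a
mean total genetic variance near 0.18 (t/ha)^2).

All generators draw from hierarchical streams of one seed: generator k uses
``np.random.default_rng([seed, k])``, so adding a generator never perturbs
the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import pedigree as ped_mod
from .famm import METDataset, _chol_psd
from .pedigree import PedigreeTable, build_pedigree, format_purdy, leaf, cross

__all__ = [
    "SimConfig",
    "TruthRecord",
    "EconSimConfig",
    "gen_pedigree",
    "gen_met",
    "gen_econ",
    "gen_disease",
]

_STREAM_PEDIGREE = 1
_STREAM_MET = 2
_STREAM_ECON = 3
_STREAM_DISEASE = 4


@dataclass
class SimConfig:
    """Configuration of the pedigree + MET generators.

    Variances are (t/ha)^2; ``loadings_scale`` is t/ha per unit factor score.
    ``replication_fraction`` gives the range from which each environment's
    fraction of twice-planted genotypes is drawn (a scalar pins it).
    """

    n_founders: int = 20
    n_crosses: int = 80
    n_environments: int = 6
    n_genotypes: int = 60
    ka: int = 1
    ke: int = 0
    loadings_scale: float = 0.35
    specific_variance: tuple[float, float] = (0.005, 0.05)
    residual_variance: tuple[float, float] = (0.02, 0.3)
    env_mean: tuple[float, float] = (0.6, 6.6)
    replication_fraction: tuple[float, float] | float = (0.05, 1.0)
    block_variance: float = 0.01
    sources: tuple[str, ...] = ("Australian", "CIMMYT", "ICARDA")
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_environments < 1 or self.n_genotypes < 2:
            raise ValueError("need p >= 1 environments and m >= 2 genotypes")
        if self.ka < 0 or self.ke < 0:
            raise ValueError("FA orders must be >= 0")
        for lo, hi in (self.specific_variance, self.residual_variance):
            if lo < 0 or hi < lo:
                raise ValueError("variance ranges must be 0 <= lo <= hi")
        rf = self.replication_fraction
        lo, hi = (rf, rf) if np.isscalar(rf) else rf
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("replication fraction must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated MET."""

    envs: list
    genotypes: list
    Lambda_a: np.ndarray
    psi_a: np.ndarray
    Lambda_i: np.ndarray
    psi_i: np.ndarray
    scores: np.ndarray          # m x (ka + ke) factor scores
    env_means: np.ndarray
    residual_variances: np.ndarray
    block_variance: float
    effects_a: np.ndarray       # m x p additive GE effects
    effects_i: np.ndarray

    def Ga(self) -> np.ndarray:
        return self.Lambda_a @ self.Lambda_a.T + np.diag(self.psi_a)

    def Gi(self) -> np.ndarray:
        return self.Lambda_i @ self.Lambda_i.T + np.diag(self.psi_i)

    def to_json(self, path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def gen_pedigree(config: SimConfig) -> PedigreeTable:
    """Generate a pedigree of founders plus crosses with Purdy strings.

    Founders get unknown parents and cycle through ``config.sources``; each
    cross samples existing genotypes into a shallow cross tree (depth 1-2,
    using only the round-trip-exact ``/``, ``//`` operators), and the Purdy
    string is materialized through :func:`germeval.pedigree.build_pedigree`,
    so parents always precede offspring.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PEDIGREE])
    founders = [f"F{i + 1:03d}" for i in range(config.n_founders)]
    entries: list[tuple[str, str | tuple]] = [(f, (None, None)) for f in founders]
    sources = {f: config.sources[i % len(config.sources)] for i, f in enumerate(founders)}
    pool = list(founders)
    for i in range(config.n_crosses):
        gid = f"G{i + 1:03d}"
        depth2 = len(pool) >= 3 and rng.random() < 0.3
        if depth2:
            a, b, c = rng.choice(len(pool), size=3, replace=False)
            tree = cross(cross(leaf(pool[a]), leaf(pool[b])), leaf(pool[c]))
        else:
            a, b = rng.choice(len(pool), size=2, replace=False)
            tree = cross(leaf(pool[a]), leaf(pool[b]))
        purdy = format_purdy(tree)
        entries.append((gid, purdy))
        parent_pool = tree.leaves()
        sources[gid] = sources[parent_pool[int(rng.integers(len(parent_pool)))]]
        pool.append(gid)
    return build_pedigree(entries, sources=sources, default_source="derived")


def _draw_loadings(rng, p: int, k: int, scale: float) -> np.ndarray:
    """First factor: a common positive response; later factors: contrasts.

    First-factor loadings are log-uniform over roughly [0.35, 2.8] x scale, so
    per-environment genetic variances span nearly two orders of magnitude —
    the spread real trial networks show (published per-trial genetic variances
    run from ~0.014 to ~0.975 (t/ha)^2 across environments).
    """
    Lam = np.zeros((p, k))
    if k >= 1:
        u = np.exp(rng.uniform(np.log(0.35), np.log(2.8), size=p))
        Lam[:, 0] = scale * u
    for c in range(1, k):
        col = rng.normal(0.0, 0.8 * scale, size=p)
        col -= col.mean()  # contrast between environments, roughly orthogonal to f1
        Lam[:, c] = col
    return Lam


def gen_met(
    config: SimConfig,
    pedigree: PedigreeTable | None = None,
    A: pd.DataFrame | None = None,
) -> tuple[METDataset, TruthRecord]:
    """Simulate a p-rep MET with factor-analytic additive + non-additive GE effects.

    Additive effects have between-environment covariance
    ``Ga = Lambda_a Lambda_a' + diag(psi_a)`` and between-genotype covariance
    A (identity when no pedigree is given); non-additive effects use Gi with
    identity between genotypes.  Plot yields add an environment mean, one of
    two resolvable block effects, and an iid residual.  Each environment
    duplicates a fraction of genotypes (its replication fraction), arranged on
    a two-column-block grid.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng([config.seed, _STREAM_MET])
    p, m, ka, ke = config.n_environments, config.n_genotypes, config.ka, config.ke

    if pedigree is not None:
        real = [g for g in pedigree.genotypes if not g.startswith("#")]
        if len(real) < m:
            raise ValueError(f"pedigree has {len(real)} named genotypes; need {m}")
        genotypes = real[-m:]
        if A is None:
            A = ped_mod.nrm(pedigree)
        Am = A.loc[genotypes, genotypes].to_numpy(dtype=float)
        src = {g: pedigree.source(g) for g in genotypes}
    elif A is not None:
        genotypes = list(A.index)[:m]
        Am = A.loc[genotypes, genotypes].to_numpy(dtype=float)
        src = {g: "" for g in genotypes}
    else:
        genotypes = [f"G{i + 1:04d}" for i in range(m)]
        Am = np.eye(m)
        src = {g: "" for g in genotypes}
    L_A = _chol_psd(Am)

    envs = [f"E{j + 1:02d}" for j in range(p)]
    Lam_a = _draw_loadings(rng, p, ka, config.loadings_scale)
    Lam_i = _draw_loadings(rng, p, ke, 0.6 * config.loadings_scale)
    lo, hi = config.specific_variance
    psi_a = rng.uniform(lo, hi, size=p) if ka >= 0 else np.zeros(p)
    psi_i = rng.uniform(lo, hi, size=p)
    if lo == hi:
        psi_a = np.full(p, lo)
        psi_i = np.full(p, lo)
    rlo, rhi = config.residual_variance
    sigma2 = rng.uniform(rlo, rhi, size=p)
    mlo, mhi = config.env_mean
    env_means = np.sort(rng.uniform(mlo, mhi, size=p))
    rf = config.replication_fraction
    if np.isscalar(rf):
        rep_frac = np.full(p, float(rf))
    else:
        rep_frac = rng.uniform(rf[0], rf[1], size=p)

    # additive: u = F Lam' + delta with factor scores correlated by A
    F_a = L_A @ rng.standard_normal((m, ka)) if ka else np.zeros((m, 0))
    delta_a = (L_A @ rng.standard_normal((m, p))) * np.sqrt(psi_a)
    U_a = F_a @ Lam_a.T + delta_a
    F_i = rng.standard_normal((m, ke)) if ke else np.zeros((m, 0))
    delta_i = rng.standard_normal((m, p)) * np.sqrt(psi_i)
    U_i = F_i @ Lam_i.T + delta_i

    rows = []
    for j, env in enumerate(envs):
        n_dbl = int(round(rep_frac[j] * m))
        if (m + n_dbl) % 2:  # two equal column blocks need an even plot count
            n_dbl += -1 if n_dbl > 0 else 1
        n_dbl = int(np.clip(n_dbl, 0, m))
        doubles = rng.choice(m, size=n_dbl, replace=False) if n_dbl else np.array([], dtype=int)
        singles = np.setdiff1d(np.arange(m), doubles)
        n_rows = (m + n_dbl) // 2
        half = rng.permutation(len(singles))
        b0 = list(doubles) + list(singles[half[: len(singles) // 2]])
        b1 = list(doubles) + list(singles[half[len(singles) // 2 :]])
        assert len(b0) == len(b1) == n_rows
        b0 = rng.permutation(b0)
        b1 = rng.permutation(b1)
        blk_eff = rng.normal(0.0, np.sqrt(config.block_variance), size=2)
        for col, (members, beff) in enumerate(((b0, blk_eff[0]), (b1, blk_eff[1]))):
            for r, g in enumerate(members):
                e = rng.normal(0.0, np.sqrt(sigma2[j]))
                y = env_means[j] + U_a[g, j] + U_i[g, j] + beff + e
                rows.append({
                    "env": env, "genotype": genotypes[g], "block": col + 1,
                    "row": r + 1, "col": col + 1, "yield": y,
                    "source": src[genotypes[g]],
                })
    met = METDataset(pd.DataFrame(rows))
    met.validate()
    truth = TruthRecord(
        envs=envs, genotypes=list(genotypes),
        Lambda_a=Lam_a, psi_a=psi_a, Lambda_i=Lam_i, psi_i=psi_i,
        scores=np.hstack([F_a, F_i]),
        env_means=env_means, residual_variances=sigma2,
        block_variance=config.block_variance,
        effects_a=U_a, effects_i=U_i,
    )
    return met, truth


# ---------------------------------------------------------------------------
# economics
# ---------------------------------------------------------------------------

@dataclass
class EconSimConfig:
    """Configuration of the economics-ledger generator.

    Defaults follow the published program accounting: nine production seasons
    (2010/11-2018/19), about fifty cultivars at an average around 2e5 t each,
    a 1.4% yield advantage, and five zero-benefit breeding seasons before the
    first production season.
    """

    years: tuple[int, ...] = tuple(range(2010, 2019))
    n_cultivars: int = 50
    tonnes_scale: float = 2.0e5
    yield_advantage: float = 0.014
    price_level: float = 300.0
    cpi_growth: float = 0.025
    investment_per_year: float = 9.0e5
    breeding_years: int = 5
    program_fraction: float = 0.8   # cultivars carrying >= threshold program ancestry
    noise_sd: float = 0.0           # lognormal sd on tonnes; 0 = noiseless
    seed: int = 0

    def __post_init__(self):
        if len(self.years) == 0:
            raise ValueError("need at least one production year")
        if min(self.tonnes_scale, self.price_level, self.investment_per_year) < 0:
            raise ValueError("monetary and tonnage values must be >= 0")


def gen_econ(config: EconSimConfig):
    """Generate production, price and investment tables plus an arithmetic truth.

    Returns ``(production, prices, investment, truth)``.  ``truth`` contains
    the benefit series and the BCR computed by an independent plain-arithmetic
    loop over the same chain (real prices, flexibility above the mean,
    advantage x share x tonnes x (1 - royalty), linear projection, CPI
    inflation / discounting), so a noiseless run through the econ pipeline
    must reproduce ``truth["bcr"]`` exactly.
    """
    from .econ import EconParams  # deferred: synth must not depend on econ at import

    rng = np.random.default_rng([config.seed, _STREAM_ECON])
    params = EconParams(yield_advantage=config.yield_advantage)
    years = sorted(config.years)
    start_invest = years[0] - config.breeding_years

    cultivars = [f"CV{i + 1:03d}" for i in range(config.n_cultivars)]
    n_prog = int(round(config.program_fraction * config.n_cultivars))
    shares = np.concatenate([
        rng.uniform(0.05, 0.9, size=n_prog),
        rng.uniform(0.0, 0.009, size=config.n_cultivars - n_prog),
    ])
    base_tonnes = config.tonnes_scale * rng.lognormal(0.0, 0.8, size=config.n_cultivars)

    prod_rows = []
    for t, season in enumerate(years):
        growth = 1.0 + 0.03 * t
        for i, cv in enumerate(cultivars):
            tn = base_tonnes[i] * growth
            if config.noise_sd > 0:
                tn *= rng.lognormal(0.0, config.noise_sd)
            prod_rows.append({"season": season, "cultivar": cv,
                              "tonnes": tn, "share": shares[i]})
    production = pd.DataFrame(prod_rows)

    price_seasons = list(range(start_invest, params.base_season + 1))
    prices = pd.DataFrame({
        "season": price_seasons,
        "nominal_price": [config.price_level * (1.0 + 0.01 * (s - years[0]))
                          for s in price_seasons],
        "cpi": [100.0 * (1.0 + config.cpi_growth) ** (s - params.base_season)
                for s in price_seasons],
    })
    investment = pd.DataFrame({
        "season": list(range(start_invest, params.base_season + 1)),
        "amount": config.investment_per_year,
    })

    # ---- independent arithmetic truth (no econ-module calls) ---------------
    cpi = dict(zip(prices["season"], prices["cpi"]))
    nominal = dict(zip(prices["season"], prices["nominal_price"]))
    cpi_base = cpi[params.base_season]
    tot = production.groupby("season")["tonnes"].sum()
    mean_t = float(tot.mean())
    benefits = {}
    for season in years:
        rp = nominal[season] * cpi_base / cpi[season]
        above = max(0.0, 100.0 * (tot[season] - mean_t) / mean_t)
        price_adj = rp * (1.0 + params.flexibility * above / 100.0)
        b = 0.0
        for r in production[production["season"] == season].itertuples():
            if r.share >= params.threshold:
                b += r.tonnes * r.share * params.yield_advantage * price_adj * (1.0 - params.royalty)
        benefits[season] = b
    slope, intercept = np.polyfit(years, [benefits[s] for s in years], 1)
    peak = max(years[0] + params.peak_offset, years[-1])
    peak_val = max(0.0, slope * peak + intercept)
    for s in range(years[-1] + 1, params.end_season + 1):
        if s <= peak:
            benefits[s] = max(0.0, slope * s + intercept)
        else:
            benefits[s] = max(0.0, peak_val * (params.end_season - s) / (params.end_season - peak))
    pv_b = 0.0
    for s, v in benefits.items():
        if s < params.base_season:
            pv_b += v * cpi_base / cpi[s]
        elif s == params.base_season:
            pv_b += v
        else:
            pv_b += v / (1.0 + params.discount) ** (s - params.base_season)
    pv_i = 0.0
    for s in range(start_invest, params.base_season + 1):
        amt = config.investment_per_year
        if s < params.base_season:
            pv_i += amt * cpi_base / cpi[s]
        else:
            pv_i += amt
    truth = {
        "benefit_series": benefits,
        "pv_benefits": pv_b,
        "pv_investment": pv_i,
        "bcr": pv_b / pv_i if pv_i > 0 else np.nan,
        "params": params,
    }
    return production, prices, investment, truth


def gen_disease(
    n_genotypes: int = 200,
    diseases: tuple[str, ...] = ("stem rust", "leaf rust", "stripe rust", "crown rot"),
    resistant_fraction: tuple[float, ...] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate raw 1-9 severity scores with disease-specific resistance prevalence.

    Returns a long table (genotype, disease, raw_score, scheme) ready for
    :mod:`germeval.scales`.
    """
    rng = np.random.default_rng([seed, _STREAM_DISEASE])
    if resistant_fraction is None:
        resistant_fraction = tuple(0.8 - 0.15 * i for i in range(len(diseases)))
    rows = []
    for d, frac in zip(diseases, resistant_fraction):
        res = rng.random(n_genotypes) < frac
        score = np.where(
            res,
            rng.uniform(1.0, 3.5, size=n_genotypes),
            rng.uniform(3.5, 9.0, size=n_genotypes),
        )
        for i in range(n_genotypes):
            rows.append({"genotype": f"G{i + 1:04d}", "disease": d,
                         "raw_score": float(score[i]), "scheme": "1-9"})
    return pd.DataFrame(rows)
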