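"""Benefit-cost accounting for a germplasm-evaluation program.

The benefit chain attributes a share of each cultivar's annual production to
imported-program ancestry (its pedigree share), applies the program's average
yield advantage, values the attributable extra tonnes at CPI-deflated grower
prices adjusted for price flexibility, deducts the end-point royalty, projects
the benefit stream forward (peak at a fixed year, linear decline to zero), and
discounts everything to a base season.  Summaries report NPV, BCR, IRR and
MIRR for the total investment and for the attributed share.

Seasons are integers naming the season's starting year (2010 means the
2010/2011 season); ``parse_season`` accepts either form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

PROGRAM = "CAIGE"
NON_PROGRAM = "Non-CAIGE"

__all__ = [
    "PROGRAM",
    "NON_PROGRAM",
    "EconParams",
    "BenefitLedger",
    "parse_season",
    "classify",
    "real_price",
    "flexibility_adjust",
    "annual_benefit",
    "project_benefits",
    "present_value",
    "irr",
    "mirr",
    "summarize",
    "run_benefit_cost",
]


def parse_season(label) -> int:
    """Season label -> starting year: 2010, "2010", and "2010/2011" all -> 2010."""
    if isinstance(label, (int, np.integer)):
        return int(label)
    return int(str(label).split("/")[0].split("-")[0])


@dataclass(frozen=True)
class EconParams:
    """Benefit-cost parameters (2020 AUD conventions).

    ``flexibility`` — the percent price change per percent extra supply — is
    the reciprocal of the demand elasticity, rounded to 3 decimals.
    """

    yield_advantage: float = 0.014      # fraction: program vs non-program yield gap
    elasticity: float = -39.93          # % tonnes per % price
    royalty: float = 0.03               # end-point royalty on grain value
    discount: float = 0.05              # rate for future flows
    attribution: float = 0.455          # funder share of the investment
    threshold: float = 0.01             # pedigree share classifying a cultivar
    peak_offset: int = 10               # benefits peak this many years after start
    end_season: int = 2034              # benefits decline to zero by this season
    base_season: int = 2020             # present-value base
    mirr_finance: float = 0.03
    mirr_reinvest: float = 0.05

    @property
    def flexibility(self) -> float:
        return round(1.0 / self.elasticity, 3)


def classify(share: float, threshold: float = 0.01) -> str:
    """Label a cultivar by its program pedigree share; the boundary counts as program."""
    if not 0.0 <= share <= 1.0:
        raise ValueError(f"pedigree share {share} outside [0, 1]")
    return PROGRAM if share >= threshold else NON_PROGRAM


def real_price(nominal: float, cpi_obs: float, cpi_base: float) -> float:
    """Inflate a nominal price to base-season dollars: nominal x cpi_base / cpi_obs."""
    if cpi_obs <= 0 or cpi_base <= 0:
        raise ValueError("CPI indices must be positive")
    return nominal * cpi_base / cpi_obs


def flexibility_adjust(
    price: float, tonnes: float, mean_tonnes: float, flexibility: float = -0.025
) -> float:
    """Lower the price by |flexibility| percent per percent supply above the mean.

    No adjustment at or below the period-mean tonnage (set
    ``symmetric=True`` on :func:`run_benefit_cost` to apply it both ways).
    """
    if mean_tonnes <= 0:
        raise ValueError("mean tonnage must be positive")
    pct_above = max(0.0, 100.0 * (tonnes - mean_tonnes) / mean_tonnes)
    return price * (1.0 + flexibility * pct_above / 100.0)


def annual_benefit(
    tonnes: float, share: float, advantage: float, price: float, royalty: float
) -> float:
    """tonnes x pedigree share x yield advantage x price x (1 - royalty)."""
    if min(tonnes, share, advantage, price, royalty) < 0 or max(share, advantage, royalty) > 1:
        raise ValueError("inputs must be non-negative with fractions <= 1")
    return tonnes * share * advantage * price * (1.0 - royalty)


def project_benefits(
    observed: pd.Series, peak_offset: int = 10, end_season: int = 2034
) -> pd.Series:
    """Extend an observed benefit series: linear trend to the peak, then to zero.

    A linear trend fitted to the observed seasons is extrapolated to the peak
    season (first observed season + ``peak_offset``); from the peak the series
    declines linearly to exactly 0 at ``end_season``.  All projected values
    are floored at 0.  Observed values are returned unchanged.
    """
    seasons = sorted(parse_season(s) for s in observed.index)
    if len(seasons) < 2:
        raise ValueError("need at least 2 observed seasons to project")
    end = parse_season(end_season)
    if end <= seasons[-1]:
        raise ValueError(f"end season {end} not after last observation {seasons[-1]}")
    vals = np.array([observed[s] for s in seasons], dtype=float)
    slope, intercept = np.polyfit(seasons, vals, 1)
    peak = seasons[0] + peak_offset
    peak = max(peak, seasons[-1])  # never truncate the observed data
    out = {s: float(v) for s, v in zip(seasons, vals)}
    peak_val = max(0.0, slope * peak + intercept)
    for s in range(seasons[-1] + 1, peak + 1):
        out[s] = max(0.0, slope * s + intercept)
    for s in range(peak + 1, end + 1):
        frac = (end - s) / (end - peak)
        out[s] = max(0.0, peak_val * frac)
    out[end] = 0.0
    return pd.Series(out).sort_index()


def present_value(
    series: pd.Series,
    base_season: int,
    discount: float,
    cpi: pd.Series,
) -> pd.Series:
    """Present value per season: CPI-inflate past flows to base, discount future ones.

    Past seasons use ``value x cpi[base] / cpi[season]``; future seasons use
    ``value / (1 + discount)^(season - base)``; the base season is unchanged.
    """
    base = parse_season(base_season)
    cpi = pd.Series({parse_season(k): v for k, v in cpi.items()})
    if base not in cpi.index:
        raise ValueError(f"CPI series lacks the base season {base}")
    out = {}
    for s, v in series.items():
        s = parse_season(s)
        if s < base:
            if s not in cpi.index:
                raise ValueError(f"CPI missing for past season {s}")
            out[s] = v * cpi[base] / cpi[s]
        elif s == base:
            out[s] = float(v)
        else:
            out[s] = v / (1.0 + discount) ** (s - base)
    return pd.Series(out).sort_index()


def irr(cashflows) -> float:
    """Internal rate of return: smallest root of the NPV polynomial in (-0.99, 10).

    ``cashflows`` is an ordered series (period 0 first).  Bracketed bisection
    (scipy brentq) to 1e-8; raises if the flows never change sign.
    """
    cf = np.asarray(list(cashflows), dtype=float)
    nz = cf[cf != 0]
    if len(nz) == 0 or np.all(nz > 0) or np.all(nz < 0):
        raise ValueError("IRR undefined: cash flows do not change sign")
    t = np.arange(len(cf))

    def npv(r):
        return float(np.sum(cf / (1.0 + r) ** t))

    grid = np.concatenate([np.linspace(-0.99, 1.0, 400), np.linspace(1.0, 10.0, 1801)])
    vals = np.array([npv(r) for r in grid])
    sign = np.sign(vals)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if len(idx) == 0:
        exact = np.flatnonzero(vals == 0)
        if len(exact):
            return float(grid[exact[0]])
        raise ValueError("IRR undefined: no sign change of NPV in (-0.99, 10)")
    i = idx[0]
    return float(optimize.brentq(npv, grid[i], grid[i + 1], xtol=1e-10, rtol=1e-12))


def mirr(cashflows, finance_rate: float = 0.03, reinvest_rate: float = 0.05) -> float:
    """Modified IRR: positive flows compound forward, negative flows discount back.

    ``(FV_positive(reinvest) / |PV_negative(finance)|)^(1/n) - 1`` over the
    ``n`` periods from the first to the last flow.
    """
    cf = np.asarray(list(cashflows), dtype=float)
    if not (np.any(cf > 0) and np.any(cf < 0)):
        raise ValueError("MIRR undefined: need at least one inflow and one outflow")
    n = len(cf) - 1
    if n == 0:
        raise ValueError("MIRR undefined over a single period")
    t = np.arange(len(cf))
    fv_pos = float(np.sum(np.where(cf > 0, cf, 0.0) * (1.0 + reinvest_rate) ** (n - t)))
    pv_neg = float(np.sum(np.where(cf < 0, -cf, 0.0) / (1.0 + finance_rate) ** t))
    return (fv_pos / pv_neg) ** (1.0 / n) - 1.0


@dataclass
class BenefitLedger:
    """Season-indexed cash flows of the benefit-cost analysis.

    ``table`` columns: investment, benefit (both nominal-of-season dollars),
    investment_pv, benefit_pv (base-season dollars).  Attribution and rate
    summaries come from :func:`summarize`.
    """

    table: pd.DataFrame
    params: EconParams

    @property
    def sum_investment(self) -> float:
        return float(self.table["investment_pv"].sum())

    @property
    def sum_benefit(self) -> float:
        return float(self.table["benefit_pv"].sum())

    def net_cashflows(self, attributed: bool = False) -> pd.Series:
        b = self.table["benefit"] * (self.params.attribution if attributed else 1.0)
        return b - self.table["investment"]

    def summary(self) -> pd.DataFrame:
        return summarize(self)


def summarize(
    ledger: "BenefitLedger | None" = None,
    sum_investment: float | None = None,
    sum_benefit: float | None = None,
    attribution: float | None = None,
    irr_total: float | None = None,
    mirr_total: float | None = None,
    irr_attr: float | None = None,
    mirr_attr: float | None = None,
    params: EconParams | None = None,
) -> pd.DataFrame:
    """Two-column benefit-cost summary: total, and the attributed share.

    Dollar rows are rounded to the nearest dollar, ratios to 2 decimals.
    The attributed BCR divides the attributed benefits by the TOTAL
    investment (the attributed column answers "what did the funder's share of
    the program return per program dollar", so the denominator stays whole);
    attributed NPV is attributed benefits minus attributed investment.
    """
    params = params or (ledger.params if ledger is not None else EconParams())
    if attribution is None:
        attribution = params.attribution
    if ledger is not None:
        sum_investment = ledger.sum_investment
        sum_benefit = ledger.sum_benefit
        cf_total = ledger.net_cashflows(attributed=False).to_numpy()
        cf_attr = ledger.net_cashflows(attributed=True).to_numpy()
        try:
            irr_total = irr(cf_total)
            irr_attr = irr(cf_attr)
        except ValueError:
            pass
        try:
            mirr_total = mirr(cf_total, params.mirr_finance, params.mirr_reinvest)
            mirr_attr = mirr(cf_attr, params.mirr_finance, params.mirr_reinvest)
        except ValueError:
            pass
    if sum_investment is None or sum_benefit is None:
        raise ValueError("need a ledger or explicit present-value sums")
    if sum_investment <= 0:
        raise ValueError("BCR undefined: total investment is zero")
    si = round(sum_investment)
    sb = round(sum_benefit)
    si_attr = round(attribution * sum_investment)
    sb_attr = round(attribution * sum_benefit)
    rows = {
        "sum_investment": (si, si_attr),
        "sum_benefits": (sb, sb_attr),
        "net_present_value": (sb - si, sb_attr - si_attr),
        "benefit_cost_ratio": (round(sum_benefit / sum_investment, 2),
                               round(sb_attr / sum_investment, 2)),
        "internal_rate_of_return": (
            None if irr_total is None else round(irr_total, 4),
            None if irr_attr is None else round(irr_attr, 4),
        ),
        "modified_rate_of_return": (
            None if mirr_total is None else round(mirr_total, 4),
            None if mirr_attr is None else round(mirr_attr, 4),
        ),
    }
    return pd.DataFrame(rows, index=["total", "attributed"]).T


def run_benefit_cost(
    production: pd.DataFrame,
    prices: pd.DataFrame,
    investment: pd.DataFrame,
    params: EconParams = EconParams(),
    symmetric: bool = False,
    project: bool = True,
) -> BenefitLedger:
    """Run the full benefit chain from raw tables to a season ledger.

    ``production``: season, cultivar, tonnes, share (program pedigree share).
    ``prices``: season, nominal_price, cpi.  ``investment``: season, amount.
    Benefits accrue only from cultivars classified as program-derived; the
    observed benefit series is then projected (peak + decline) and all flows
    are brought to base-season present value.
    """
    prod = production.copy()
    prod["season"] = prod["season"].map(parse_season)
    prices = prices.copy()
    prices["season"] = prices["season"].map(parse_season)
    prices = prices.set_index("season").sort_index()
    invest = investment.copy()
    invest["season"] = invest["season"].map(parse_season)
    inv_series = invest.groupby("season")["amount"].sum()

    cpi = prices["cpi"]
    cpi_base = float(cpi.loc[params.base_season]) if params.base_season in cpi.index else float(cpi.iloc[-1])

    prod["label"] = prod["share"].map(lambda s: classify(s, params.threshold))
    total_tonnes = prod.groupby("season")["tonnes"].sum()
    mean_tonnes = float(total_tonnes.mean())

    benefits = {}
    for season, sub in prod.groupby("season"):
        rp = real_price(float(prices.loc[season, "nominal_price"]),
                        float(cpi.loc[season]), cpi_base)
        tonnes_season = float(total_tonnes.loc[season])
        if symmetric:
            pct = 100.0 * (tonnes_season - mean_tonnes) / mean_tonnes
            price_adj = rp * (1.0 + params.flexibility * pct / 100.0)
        else:
            price_adj = flexibility_adjust(rp, tonnes_season, mean_tonnes, params.flexibility)
        sub_p = sub[sub["label"] == PROGRAM]
        benefits[season] = float(sum(
            annual_benefit(r.tonnes, r.share, params.yield_advantage, price_adj, params.royalty)
            for r in sub_p.itertuples()
        ))
    benefit_series = pd.Series(benefits).sort_index()
    if project:
        benefit_series = project_benefits(benefit_series, params.peak_offset, params.end_season)

    # zero-benefit breeding seasons at the head of the ledger (program start
    # precedes the first benefit season by the breeding lag)
    seasons = sorted(set(inv_series.index) | set(benefit_series.index))
    idx = range(min(seasons), max(seasons) + 1)
    table = pd.DataFrame(index=pd.Index(idx, name="season"))
    table["investment"] = inv_series.reindex(idx, fill_value=0.0)
    table["benefit"] = benefit_series.reindex(idx, fill_value=0.0)

    cpi_full = cpi.reindex(idx)
    if cpi_full.isna().any():
        # extend CPI flat outside the price table for past seasons without prices
        cpi_full = cpi_full.ffill().bfill()
    table["investment_pv"] = present_value(table["investment"], params.base_season,
                                           params.discount, cpi_full)
    table["benefit_pv"] = present_value(table["benefit"], params.base_season,
                                        params.discount, cpi_full)
    return BenefitLedger(table, params)
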