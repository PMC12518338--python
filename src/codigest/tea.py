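"""Techno-economics: capital/operating costs and the RNG minimum fuel
selling price (MFSP).

The MFSP is the product price at which the project's net present value is
zero at the target internal rate of return, over a fixed plant life with
straight-line depreciation and a constant tax rate. Taxable losses are
offset at the margin (loss carryforward against other income), which keeps
the cash flow linear in price and every cost line, so the $/GJ breakdown
closes against the solved MFSP exactly.

Capital scales with raw biogas throughput by a power law anchored at a
reference flow; feedstocks are priced on wet mass as received.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .plant import PlantBalance, CH4_MOLAR_MASS, CO2_MOLAR_MASS, MOLAR_VOLUME_STP

__all__ = ["CostParameters", "TEAResult", "capital_cost", "operating_cost",
           "biochar_revenue", "npv", "mfsp_solve", "cost_breakdown",
           "evaluate", "cashflow_table"]


@dataclass(frozen=True)
class CostParameters:
    """Prices and financial assumptions.

    Prices in $/tonne as received; ``irr`` is the target internal rate of
    return used as the discount rate. ``biochar_recovery`` is the marketable
    fraction of biochar mass (thermal-treatment losses and off-spec fines).
    """

    price_manure: float = 41.0
    price_biomass: float = 120.0
    price_natural_gas: float = 245.0
    price_mea: float = 1080.0
    price_biochar: float = 150.0
    irr: float = 0.07
    plant_life: int = 20
    capacity_factor: float = 0.9
    tax_rate: float = 0.21
    depreciation_years: int = 10
    base_capital: float = 13.31e6
    ref_biogas_m3_d: float = 5690.0   # raw biogas at STP, anchor flow
    capital_exponent: float = 0.6
    om_fraction: float = 0.06         # fixed O&M as a fraction of capital
    biochar_recovery: float = 0.91

    def __post_init__(self) -> None:
        for name in ("price_manure", "price_biomass", "price_natural_gas",
                     "price_mea", "price_biochar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.irr < 1.0:
            raise ValueError("irr must be in (0, 1)")
        if self.plant_life < 1:
            raise ValueError("plant_life must be >= 1")

    @property
    def annual_hours(self) -> float:
        return 8760.0 * self.capacity_factor


@dataclass
class TEAResult:
    """Solved cash-flow summary for one scenario."""

    capital: float                  # $
    opex: dict[str, float]          # $/y by line item
    biochar_revenue: float          # $/y
    annual_GJ: float                # GJ RNG sold per year
    mfsp: float                     # $/GJ
    breakdown: dict[str, float]     # $/GJ, sums to mfsp (credit negative)
    npv_at_mfsp: float              # $ (independent re-summation)

    @property
    def total_opex(self) -> float:
        return sum(self.opex.values())


def raw_biogas_m3_d(bal: PlantBalance) -> float:
    """Raw digester biogas volumetric flow at STP, m3/d."""
    n = bal.biogas_ch4 / CH4_MOLAR_MASS + bal.biogas_co2 / CO2_MOLAR_MASS
    return n * MOLAR_VOLUME_STP * 24.0


def capital_cost(bal: PlantBalance, params: CostParameters = CostParameters()
                 ) -> float:
    """Installed capital, $: base cost x (biogas flow / reference)^exponent."""
    q = raw_biogas_m3_d(bal)
    if q <= 0:
        raise ValueError("capital cost undefined for zero gas throughput")
    return params.base_capital * (q / params.ref_biogas_m3_d) ** params.capital_exponent


def operating_cost(bal: PlantBalance, capital: float,
                   params: CostParameters = CostParameters()
                   ) -> dict[str, float]:
    """Annual operating cost by line item, $/y.

    Feedstock purchases on wet mass, MEA makeup and natural gas at their
    prices, all scaled by the capacity factor; fixed O&M is a fraction of
    capital, independent of throughput.
    """
    h = params.annual_hours
    return {
        "feedstock_biomass": bal.biomass_wet / 1000.0 * params.price_biomass * h,
        "feedstock_manure": bal.manure_wet / 1000.0 * params.price_manure * h,
        "mea": bal.mea_makeup / 1000.0 * params.price_mea * h,
        "natural_gas": bal.ng_purchase / 1000.0 * params.price_natural_gas * h,
        "fixed_om": params.om_fraction * capital,
    }


def biochar_revenue(bal: PlantBalance,
                    params: CostParameters = CostParameters()) -> float:
    """Annual biochar co-product revenue, $/y."""
    return (bal.biochar / 1000.0 * params.biochar_recovery
            * params.price_biochar * params.annual_hours)


def _discount_factors(params: CostParameters) -> np.ndarray:
    years = np.arange(1, params.plant_life + 1)
    return (1.0 + params.irr) ** -years


def npv(price: float, capital: float, opex_total: float, revenue: float,
        annual_GJ: float, params: CostParameters = CostParameters()) -> float:
    """Project NPV at RNG price ``price`` ($/GJ), by direct cash-flow summation.

    Year 0 carries the investment; years 1..life carry after-tax operating
    cash flow with straight-line depreciation over ``depreciation_years``.
    """
    df = _discount_factors(params)
    dep = np.zeros(params.plant_life)
    n_dep = min(params.depreciation_years, params.plant_life)
    dep[:n_dep] = capital / params.depreciation_years
    ebitda = price * annual_GJ + revenue - opex_total
    taxable = ebitda - dep
    tax = params.tax_rate * taxable
    cash = ebitda - tax
    return float(-capital + np.sum(cash * df))


def mfsp_solve(capital: float, opex_total: float, revenue: float,
               annual_GJ: float, params: CostParameters = CostParameters()
               ) -> float:
    """RNG price ($/GJ) zeroing the NPV, by bracketing root search.

    The bracket is widened geometrically until the NPV changes sign; the
    returned root satisfies |NPV| < $1.
    """
    if annual_GJ <= 0:
        raise ValueError("annual_GJ must be > 0")
    f = lambda p: npv(p, capital, opex_total, revenue, annual_GJ, params)  # noqa: E731
    lo, hi = 0.0, 100.0
    for _ in range(40):
        if f(lo) * f(hi) <= 0:
            break
        lo, hi = (lo - (hi - lo), hi) if f(lo) > 0 else (lo, hi * 2.0)
    else:
        raise RuntimeError("could not bracket the MFSP root")
    p = brentq(f, lo, hi, xtol=1e-10, rtol=1e-14)
    assert abs(f(p)) < 1.0
    return float(p)


def cost_breakdown(capital: float, opex: dict[str, float], revenue: float,
                   annual_GJ: float,
                   params: CostParameters = CostParameters()
                   ) -> dict[str, float]:
    """$/GJ decomposition of the MFSP; components sum to the solved price.

    The return-on-investment term carries the capital recovery grossed up
    for tax, net of the depreciation tax shield; operating items and the
    biochar credit convert at $/GJ of annual sales.
    """
    df = _discount_factors(params)
    dep = np.zeros(params.plant_life)
    n_dep = min(params.depreciation_years, params.plant_life)
    dep[:n_dep] = capital / params.depreciation_years
    dep_pv = float(np.sum(dep * df))
    sum_df = float(np.sum(df))
    tau = params.tax_rate
    roi = (capital - tau * dep_pv) / ((1.0 - tau) * sum_df * annual_GJ)
    out = {
        "feedstock": (opex["feedstock_biomass"] + opex["feedstock_manure"])
        / annual_GJ,
        "mea": opex["mea"] / annual_GJ,
        "natural_gas": opex["natural_gas"] / annual_GJ,
        "fixed_om": opex["fixed_om"] / annual_GJ,
        "roi": roi,
        "biochar_credit": -revenue / annual_GJ,
    }
    return out


def evaluate(bal: PlantBalance,
             params: CostParameters = CostParameters()) -> TEAResult:
    """Full TEA of one plant balance: capital, opex, MFSP and breakdown."""
    capital = capital_cost(bal, params)
    opex = operating_cost(bal, capital, params)
    revenue = biochar_revenue(bal, params)
    annual_GJ = bal.rng_GJ_hr * params.annual_hours
    mfsp = mfsp_solve(capital, sum(opex.values()), revenue, annual_GJ, params)
    breakdown = cost_breakdown(capital, opex, revenue, annual_GJ, params)
    return TEAResult(
        capital=capital, opex=opex, biochar_revenue=revenue,
        annual_GJ=annual_GJ, mfsp=mfsp, breakdown=breakdown,
        npv_at_mfsp=npv(mfsp, capital, sum(opex.values()), revenue,
                        annual_GJ, params),
    )


def cashflow_table(tea: TEAResult,
                   params: CostParameters = CostParameters()) -> pd.DataFrame:
    """Year-by-year cash-flow table at the solved MFSP."""
    rows = [{"year": 0, "revenue": 0.0, "opex": 0.0, "depreciation": 0.0,
             "tax": 0.0, "net": -tea.capital, "discounted_net": -tea.capital}]
    n_dep = min(params.depreciation_years, params.plant_life)
    for t in range(1, params.plant_life + 1):
        revenue = tea.mfsp * tea.annual_GJ + tea.biochar_revenue
        dep = tea.capital / params.depreciation_years if t <= n_dep else 0.0
        taxable = revenue - tea.total_opex - dep
        tax = params.tax_rate * taxable
        net = revenue - tea.total_opex - tax
        rows.append({"year": t, "revenue": revenue, "opex": tea.total_opex,
                     "depreciation": dep, "tax": tax, "net": net,
                     "discounted_net": net / (1.0 + params.irr) ** t})
    return pd.DataFrame(rows)


def write_report(tea: TEAResult, json_path, csv_path=None,
                 params: CostParameters = CostParameters()) -> None:
    """JSON TEA report and optional CSV cash-flow table."""
    payload = {
        "capital_usd": tea.capital,
        "opex_usd_per_y": tea.opex,
        "biochar_revenue_usd_per_y": tea.biochar_revenue,
        "annual_GJ": tea.annual_GJ,
        "mfsp_usd_per_GJ": tea.mfsp,
        "breakdown_usd_per_GJ": tea.breakdown,
        "npv_at_mfsp_usd": tea.npv_at_mfsp,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if csv_path is not None:
        cashflow_table(tea, params).to_csv(csv_path, index=False)
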