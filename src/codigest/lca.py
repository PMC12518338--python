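"""Life-cycle impact assessment per GJ of RNG, nine TRACI categories.

Inventory streams crossing the well-to-gate boundary: prairie biomass and
cattle manure feed (manure carries credit-signed factors as an avoided
waste), MEA makeup, purchased natural gas, the system CH4 leak, and — via
boundary expansion — synthetic nitrogen fertilizer displaced 1:1 by the
nitrogen in the biochar co-product. Impacts are linear in every flow and
reported per GJ of RNG as gains (burdens, > 0), losses (credits, < 0) and
net. A separate attributional view allocates the un-expanded totals between
RNG and biochar on a mass, energy or economic basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .plant import PlantBalance

__all__ = [
    "CATEGORIES", "STREAMS", "LCAParameters", "ImpactResult",
    "load_impact_factors", "inventory_flows", "fertilizer_offset",
    "category_impacts", "allocation_shares", "allocate_impacts",
]

CATEGORIES = [
    "acidification", "ecotoxicity", "eutrophication", "global_warming",
    "ozone_depletion", "photochemical_oxidation", "carcinogenics",
    "non_carcinogenics", "respiratory_effects",
]

STREAMS = [
    "prairie_biomass", "cattle_manure", "avoided_n_fertilizer", "mea",
    "natural_gas", "ch4_leak",
]


@dataclass(frozen=True)
class LCAParameters:
    """Boundary-expansion and allocation settings.

    Biochar nitrogen contents are dry-weight fractions for manure-derived
    and herbaceous-biomass-derived char; a scenario's char N is the VS-share
    weighted mean. Energy contents (MJ/kg) drive the energy allocation
    basis. ``transport_factor_per_kg`` is an optional additional burden per
    kg of purchased chemicals (default 0: the packaged factor table carries
    no separate transport stream)."""

    biochar_n_manure: float = 0.0171
    biochar_n_biomass: float = 0.0178
    biochar_energy_MJ_kg: float = 22.0
    rng_energy_MJ_kg: float = 52.5
    transport_factor_per_kg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("biochar_n_manure", "biochar_n_biomass"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ImpactResult:
    """Per-category gains, losses and nets per GJ RNG, plus stream detail."""

    table: pd.DataFrame            # index: category; columns: gain, loss, net, unit
    by_stream: pd.DataFrame        # index: category; columns: streams (per GJ)
    flows_kg_hr: dict[str, float]
    rng_GJ_hr: float

    def net(self, category: str) -> float:
        return float(self.table.loc[category, "net"])


def load_impact_factors() -> pd.DataFrame:
    """Packaged impact-factor inventory: one row per (stream, category),
    columns ``factor`` (impact per kg of stream) and ``unit``."""
    ref = resources.files("codigest.data") / "impact_factors.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    missing = {(s, c) for s in STREAMS for c in CATEGORIES} - set(
        zip(df["stream"], df["category"]))
    if missing:
        raise ValueError(f"impact-factor table incomplete: {sorted(missing)}")
    return df


def factor_matrix(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Factors pivoted to category x stream."""
    if df is None:
        df = load_impact_factors()
    return df.pivot(index="category", columns="stream", values="factor").loc[
        CATEGORIES, STREAMS]


def fertilizer_offset(biochar_kg_hr: float, vs_ratio_biomass: float,
                      params: LCAParameters = LCAParameters()) -> float:
    """Avoided synthetic N fertilizer, kg/hr: 1:1 with the biochar N mass.

    The char nitrogen content is the VS-share weighted mean of the
    manure-derived and herbaceous-biomass-derived contents.
    """
    if not 0.0 <= vs_ratio_biomass <= 1.0:
        raise ValueError("vs_ratio_biomass must be in [0, 1]")
    if biochar_kg_hr < 0:
        raise ValueError("biochar mass must be >= 0")
    n_content = (vs_ratio_biomass * params.biochar_n_biomass
                 + (1.0 - vs_ratio_biomass) * params.biochar_n_manure)
    return biochar_kg_hr * n_content


def inventory_flows(bal: PlantBalance,
                    params: LCAParameters = LCAParameters()
                    ) -> dict[str, float]:
    """Map the plant balance onto the six inventory streams, kg/hr.

    Feedstocks enter at wet mass (the manure factor row is credit-signed,
    so its positive mass yields negative impacts); the leak stream is the
    CH4 leak mass; the fertilizer stream is the boundary-expansion offset.
    """
    flows = {
        "prairie_biomass": bal.biomass_wet,
        "cattle_manure": bal.manure_wet,
        "avoided_n_fertilizer": fertilizer_offset(
            bal.biochar, bal.vs_ratio_biomass, params),
        "mea": bal.mea_makeup,
        "natural_gas": bal.ng_purchase,
        "ch4_leak": bal.leak_ch4,
    }
    bad = [k for k, v in flows.items() if v < 0]
    if bad:
        raise ValueError(f"negative inventory flows: {bad}")
    return flows


def category_impacts(flows: dict[str, float], rng_GJ_hr: float,
                     factors: pd.DataFrame | None = None,
                     params: LCAParameters = LCAParameters()) -> ImpactResult:
    """Per-category impact intensities: flow x factor / RNG energy rate.

    Gains sum the positive stream terms, losses the negative; net is their
    sum. Linear in every flow; invariant under joint scaling of all flows
    and the RNG rate.
    """
    if rng_GJ_hr <= 0:
        raise ValueError("rng_GJ_hr must be > 0")
    fm = factor_matrix(factors)
    unknown = set(flows) - set(STREAMS)
    if unknown:
        raise ValueError(f"unmapped inventory streams: {sorted(unknown)}")
    units = load_impact_factors().drop_duplicates("category").set_index(
        "category")["unit"]
    per_stream = fm.copy()
    for s in STREAMS:
        extra = (params.transport_factor_per_kg
                 if s in ("mea", "natural_gas") else 0.0)
        per_stream[s] = (fm[s] + extra) * flows.get(s, 0.0) / rng_GJ_hr
    gain = per_stream.clip(lower=0.0).sum(axis=1)
    loss = per_stream.clip(upper=0.0).sum(axis=1)
    table = pd.DataFrame({
        "gain": gain, "loss": loss, "net": gain + loss,
        "unit": [units[c].replace("/kg", "/GJ") for c in per_stream.index],
    })
    return ImpactResult(table=table.loc[CATEGORIES],
                        by_stream=per_stream.loc[CATEGORIES],
                        flows_kg_hr=dict(flows), rng_GJ_hr=rng_GJ_hr)


def allocation_shares(biochar_kg: float, rng_GJ: float, basis: str,
                      biochar_price: float = 150.0,
                      rng_price: float | None = None,
                      params: LCAParameters = LCAParameters()
                      ) -> dict[str, float]:
    """Product split (%) between biochar and RNG on a given basis.

    mass: biochar kg vs RNG kg (GJ / RNG energy content);
    energy: biochar kg x its energy content vs RNG GJ;
    economic: biochar kg x price vs RNG GJ x price (e.g. the MFSP).
    Shares sum to 100. Amounts may be per dry tonne or per hour — the basis
    is scale-free.
    """
    if basis not in ("mass", "energy", "economic"):
        raise ValueError(f"unknown allocation basis {basis!r}")
    if biochar_kg < 0 or rng_GJ < 0 or biochar_kg + rng_GJ <= 0:
        raise ValueError("product amounts must be >= 0 and not all zero")
    if basis == "mass":
        a = biochar_kg
        b = rng_GJ / (params.rng_energy_MJ_kg / 1000.0)
    elif basis == "energy":
        a = biochar_kg * params.biochar_energy_MJ_kg / 1000.0
        b = rng_GJ
    else:
        if rng_price is None:
            raise ValueError("economic basis requires rng_price ($/GJ)")
        a = biochar_kg / 1000.0 * biochar_price
        b = rng_GJ * rng_price
    total = a + b
    return {"biochar": 100.0 * a / total, "rng": 100.0 * b / total}


def allocate_impacts(total_impact: float,
                     shares: dict[str, float]) -> dict[str, float]:
    """Split an un-expanded total impact between the products.

    ``total_impact`` must exclude the boundary-expansion fertilizer credit
    (allocation and system expansion are alternative treatments of the
    co-product). The parts sum to the total.
    """
    if abs(shares["biochar"] + shares["rng"] - 100.0) > 1e-9:
        raise ValueError("allocation shares must sum to 100")
    return {k: total_impact * v / 100.0 for k, v in shares.items()}


def write_results(result: ImpactResult, csv_path, scenario: str = "") -> None:
    """Long-format results CSV: scenario, category, gain, loss, net, unit."""
    df = result.table.reset_index().rename(columns={"index": "category"})
    df.insert(0, "scenario", scenario)
    df.to_csv(csv_path, index=False)
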