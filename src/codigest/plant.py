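"""Steady-state biorefinery balance around the digester.

Feed logistics (wet-mass flows delivering a volatile-solids split plus
dilution water to the reactor solids target), biogas conditioning (5% of raw
biogas combusted on site, amine CO2 scrubbing with MEA makeup, a 2% CH4 leak
on the upgraded product), digestate thermal treatment to biochar with
residual digestate CH4 capture, and the plant utility closure with purchased
natural gas. All mass flows in kg/hr, energies in GJ/hr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import pandas as pd

from .feedstock import FeedstockComposition

__all__ = [
    "PlantParameters", "PlantBalance", "feed_flows", "biogas_conditioning",
    "digestate_products", "utility_balance", "rng_yield", "build_balance",
    "load_production_rates", "default_plant_parameters",
    "CH4_MOLAR_MASS", "CO2_MOLAR_MASS", "MOLAR_VOLUME_STP",
]

CH4_MOLAR_MASS = 16.043   # kg/kmol
CO2_MOLAR_MASS = 44.01
MOLAR_VOLUME_STP = 22.414  # m3/kmol at 0 C, 1 atm


@dataclass(frozen=True)
class PlantParameters:
    """Conditioning, digestate and utility settings.

    ``thermal_yield_*`` are the biochar mass recovered per kg of undegraded
    digestate solids for the two mono-digestion endpoints; they are a
    calibration against observed production rates, interpolated on the VS
    share for blends, not a pyrolysis model. Residual digestate CH4
    (m3/dry tonne at STP) interpolates linearly between the all-biomass and
    all-manure endpoints.
    """

    reactor_ts: float = 0.10
    combust_fraction: float = 0.05      # share of raw biogas burned on site
    co2_removal: float = 0.98           # scrubber CO2 capture efficiency
    mea_makeup_kg_per_t_co2: float = 45.0
    leak_fraction: float = 0.02         # of upgraded RNG volume, leaked as CH4
    residual_ch4_biomass: float = 57.0  # m3/dry tonne, all-biomass
    residual_ch4_manure: float = 139.0  # m3/dry tonne, all-manure
    thermal_yield_biomass: float = 0.8360
    thermal_yield_manure: float = 0.7510
    capture_residual_ch4: bool = True   # add digestate CH4 to the RNG product
    ch4_energy_MJ_kg: float = 52.5      # RNG/CH4 energy content
    ng_energy_MJ_kg: float = 52.5       # purchased natural gas
    combustion_efficiency: float = 0.80
    heat_MJ_per_m3_feed: float = 40.0   # digester + digestate heat duty
    power_kWh_per_m3_feed: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.combust_fraction < 1.0:
            raise ValueError("combust_fraction must be in [0, 1)")
        if not 0.0 <= self.co2_removal <= 1.0:
            raise ValueError("co2_removal must be in [0, 1]")
        if not 0.0 <= self.leak_fraction < 1.0:
            raise ValueError("leak_fraction must be in [0, 1)")


@dataclass
class PlantBalance:
    """Stream table of one co-digestion scenario (kg/hr, GJ/hr)."""

    # feed logistics
    biomass_wet: float = 0.0
    biomass_dry: float = 0.0
    biomass_vs: float = 0.0
    manure_wet: float = 0.0
    manure_dry: float = 0.0
    manure_vs: float = 0.0
    dilution_water: float = 0.0
    feed_volume_m3_hr: float = 0.0
    vs_ratio_biomass: float = 0.0
    # raw biogas from the digester
    biogas_ch4: float = 0.0
    biogas_co2: float = 0.0
    # conditioning
    combusted_ch4: float = 0.0
    combusted_co2: float = 0.0
    co2_vented: float = 0.0
    mea_makeup: float = 0.0
    leak_ch4: float = 0.0
    rng_ch4: float = 0.0
    rng_co2: float = 0.0
    # digestate
    digestate_solids: float = 0.0
    biochar: float = 0.0
    residual_ch4: float = 0.0
    # utilities
    heat_demand: float = 0.0
    power_demand: float = 0.0
    combustion_energy: float = 0.0
    ng_purchase: float = 0.0
    ng_energy: float = 0.0
    energy_surplus: float = 0.0
    # products
    rng_GJ_hr: float = 0.0
    rng_GJ_per_dry_tonne: float = 0.0
    biochar_kg_per_dry_tonne: float = 0.0

    @property
    def dry_feed(self) -> float:
        return self.biomass_dry + self.manure_dry

    @property
    def total_rng_ch4(self) -> float:
        """CH4 mass in the delivered product, kg/hr."""
        return self.rng_ch4 + self.residual_ch4

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_stream_table(self) -> pd.DataFrame:
        """Long-format stream table (stream, phase, species, kg/hr)."""
        rows = [
            ("biomass_feed", "solid", "wet_mass", self.biomass_wet),
            ("manure_feed", "solid", "wet_mass", self.manure_wet),
            ("dilution_water", "liquid", "H2O", self.dilution_water),
            ("raw_biogas", "gas", "CH4", self.biogas_ch4),
            ("raw_biogas", "gas", "CO2", self.biogas_co2),
            ("combusted", "gas", "CH4", self.combusted_ch4),
            ("combusted", "gas", "CO2", self.combusted_co2),
            ("co2_vent", "gas", "CO2", self.co2_vented),
            ("mea_makeup", "liquid", "MEA", self.mea_makeup),
            ("ch4_leak", "gas", "CH4", self.leak_ch4),
            ("rng_product", "gas", "CH4", self.rng_ch4),
            ("rng_product", "gas", "CO2", self.rng_co2),
            ("residual_ch4", "gas", "CH4", self.residual_ch4),
            ("natural_gas", "gas", "CH4", self.ng_purchase),
            ("digestate", "solid", "solids", self.digestate_solids),
            ("biochar", "solid", "solids", self.biochar),
        ]
        return pd.DataFrame(rows, columns=["stream", "phase", "species", "kg_hr"])


def feed_flows(
    vs_ratio_biomass: float,
    biomass: FeedstockComposition,
    manure: FeedstockComposition,
    total_vs_rate: float = 1000.0,
    reactor_ts: float = 0.10,
    rho: float = 1000.0,
) -> PlantBalance:
    """Wet/dry/VS feed flows (kg/hr) and dilution water to the reactor TS.

    Wet flow per feedstock = VS share x total rate / (TS x VS); dilution
    water closes the reactor total-solids target. A feed already below the
    target gets no water, with a warning.
    """
    if not 0.0 <= vs_ratio_biomass <= 1.0:
        raise ValueError("vs_ratio_biomass must be in [0, 1]")
    if total_vs_rate <= 0:
        raise ValueError("total_vs_rate must be > 0")
    bal = PlantBalance(vs_ratio_biomass=vs_ratio_biomass)
    bal.biomass_vs = vs_ratio_biomass * total_vs_rate
    bal.manure_vs = (1.0 - vs_ratio_biomass) * total_vs_rate
    if bal.biomass_vs > 0:
        bal.biomass_wet = bal.biomass_vs / (biomass.TS * biomass.VS)
        bal.biomass_dry = bal.biomass_wet * biomass.TS
    if bal.manure_vs > 0:
        bal.manure_wet = bal.manure_vs / (manure.TS * manure.VS)
        bal.manure_dry = bal.manure_wet * manure.TS
    wet = bal.biomass_wet + bal.manure_wet
    dry = bal.dry_feed
    if dry / wet > reactor_ts:
        bal.dilution_water = dry / reactor_ts - wet
    else:
        warnings.warn(
            f"feed TS {dry / wet:.3f} already at or below reactor target "
            f"{reactor_ts}; no dilution water added", stacklevel=2)
    bal.feed_volume_m3_hr = (wet + bal.dilution_water) / rho
    return bal


def biogas_conditioning(
    bal: PlantBalance, params: PlantParameters = PlantParameters()
) -> PlantBalance:
    """Split raw biogas into combustion, upgraded RNG, vent, leak and MEA.

    ``combust_fraction`` of the raw biogas (both species) is burned on site;
    the scrubber removes ``co2_removal`` of the remaining CO2 with MEA makeup
    proportional to the CO2 captured; the CH4 leak is ``leak_fraction`` of
    the upgraded RNG volumetric flow, speciated as pure CH4 and taken out of
    the product.
    """
    f = params.combust_fraction
    bal.combusted_ch4 = f * bal.biogas_ch4
    bal.combusted_co2 = f * bal.biogas_co2
    ch4 = bal.biogas_ch4 - bal.combusted_ch4
    co2 = bal.biogas_co2 - bal.combusted_co2
    captured = params.co2_removal * co2
    bal.co2_vented = captured
    bal.mea_makeup = params.mea_makeup_kg_per_t_co2 * captured / 1000.0
    rng_co2 = co2 - captured
    # leak on the volumetric (molar) flow of the collected product
    n_rng = ch4 / CH4_MOLAR_MASS + rng_co2 / CO2_MOLAR_MASS
    bal.leak_ch4 = params.leak_fraction * n_rng * CH4_MOLAR_MASS
    bal.rng_ch4 = ch4 - bal.leak_ch4
    bal.rng_co2 = rng_co2
    return bal


def digestate_products(
    bal: PlantBalance,
    biomass: FeedstockComposition,
    manure: FeedstockComposition,
    params: PlantParameters = PlantParameters(),
) -> PlantBalance:
    """Digestate solids, biochar and residual digestate CH4.

    Undegraded solids = dry feed minus the degraded VS at each feedstock's
    characterization-level degradability D_VS. Biochar applies the calibrated
    thermal-yield factor, interpolated on the biomass VS share; residual CH4
    (m3/dry tonne, STP) interpolates between the configured endpoints and is
    converted to mass.
    """
    if bal.dry_feed <= 0:
        raise ValueError("dry feed must be positive")
    undegraded = (bal.biomass_dry - bal.biomass_vs * biomass.D_VS
                  + bal.manure_dry - bal.manure_vs * manure.D_VS)
    if undegraded < 0:
        raise ValueError("negative undegraded solids; check D_VS values")
    bal.digestate_solids = undegraded
    s = bal.vs_ratio_biomass
    thermal_yield = (s * params.thermal_yield_biomass
                     + (1.0 - s) * params.thermal_yield_manure)
    bal.biochar = undegraded * thermal_yield
    resid_m3_per_t = (s * params.residual_ch4_biomass
                      + (1.0 - s) * params.residual_ch4_manure)
    dry_tonnes = bal.dry_feed / 1000.0
    bal.residual_ch4 = (resid_m3_per_t * dry_tonnes
                        / MOLAR_VOLUME_STP * CH4_MOLAR_MASS)
    return bal


def utility_balance(
    bal: PlantBalance, params: PlantParameters = PlantParameters()
) -> PlantBalance:
    """Heat/power closure: on-site combustion first, then purchased gas.

    Demands are per-m3-of-feed coefficients; the energy from the combusted
    biogas share is credited first and any deficit is met by natural gas at
    its heating value. A surplus is carried as ``energy_surplus``.
    """
    bal.heat_demand = params.heat_MJ_per_m3_feed * bal.feed_volume_m3_hr / 1000.0
    bal.power_demand = (params.power_kWh_per_m3_feed * bal.feed_volume_m3_hr
                        * 3.6 / 1000.0)
    demand = bal.heat_demand + bal.power_demand
    bal.combustion_energy = (bal.combusted_ch4 * params.ch4_energy_MJ_kg
                             * params.combustion_efficiency / 1000.0)
    deficit = demand - bal.combustion_energy
    if deficit > 0:
        bal.ng_energy = deficit
        bal.ng_purchase = (deficit * 1000.0
                           / (params.ng_energy_MJ_kg
                              * params.combustion_efficiency))
        bal.energy_surplus = 0.0
    else:
        bal.ng_energy = 0.0
        bal.ng_purchase = 0.0
        bal.energy_surplus = -deficit
    return bal


def rng_yield(
    bal: PlantBalance, params: PlantParameters = PlantParameters()
) -> PlantBalance:
    """RNG energy rate and per-dry-tonne product yields."""
    if bal.dry_feed <= 0:
        raise ValueError("dry feed must be positive")
    ch4_mass = bal.rng_ch4
    if params.capture_residual_ch4:
        ch4_mass += bal.residual_ch4
    bal.rng_GJ_hr = ch4_mass * params.ch4_energy_MJ_kg / 1000.0
    dry_tonnes = bal.dry_feed / 1000.0
    bal.rng_GJ_per_dry_tonne = bal.rng_GJ_hr / dry_tonnes
    bal.biochar_kg_per_dry_tonne = bal.biochar / dry_tonnes
    return bal


def build_balance(
    vs_ratio_biomass: float,
    biomass: FeedstockComposition,
    manure: FeedstockComposition,
    ch4_kg_hr: float,
    co2_kg_hr: float,
    total_vs_rate: float = 1000.0,
    params: PlantParameters = PlantParameters(),
) -> PlantBalance:
    """Assemble the full plant balance for one scenario.

    ``ch4_kg_hr`` / ``co2_kg_hr`` are the digester's raw biogas species
    flows (from the ADM1 steady state).
    """
    bal = feed_flows(vs_ratio_biomass, biomass, manure, total_vs_rate,
                     params.reactor_ts)
    bal.biogas_ch4 = ch4_kg_hr
    bal.biogas_co2 = co2_kg_hr
    biogas_conditioning(bal, params)
    digestate_products(bal, biomass, manure, params)
    utility_balance(bal, params)
    rng_yield(bal, params)
    return bal


def load_production_rates() -> pd.DataFrame:
    """Packaged observed production rates per scenario (biochar kg/dry tonne,
    RNG GJ/dry tonne). The B3:M7 biochar entry is stored as 472, correcting
    an apparent transcription error (47) that breaks the uniform ~12 kg/dry
    tonne step of the series."""
    ref = resources.files("codigest.data") / "production_rates.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def default_plant_parameters(
    biomass: FeedstockComposition, manure: FeedstockComposition
) -> PlantParameters:
    """Plant parameters with thermal-yield factors calibrated to the packaged
    mono-digestion biochar production rates."""
    rates = load_production_rates().set_index("scenario")
    per_t_biomass = 1000.0 - 1000.0 * biomass.VS * biomass.D_VS
    per_t_manure = 1000.0 - 1000.0 * manure.VS * manure.D_VS
    return PlantParameters(
        thermal_yield_biomass=(
            rates.loc["B10:M0", "biochar_kg_per_dry_tonne"] / per_t_biomass),
        thermal_yield_manure=(
            rates.loc["B0:M10", "biochar_kg_per_dry_tonne"] / per_t_manure),
    )
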