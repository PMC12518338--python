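"""Feedstock characterization: fiber/proximate analysis to ADM1 influent fractions.

Anaerobic digestion models quantify organic matter as chemical oxygen demand
(COD). This module converts a conventional substrate characterization — total
solids (TS), volatile solids (VS), raw lipid/fiber/protein, and the detergent
fiber series (NDF, ADF, ADL) — into the composite particulate COD ``X_c``, the
disintegration partition coefficients (f-factors) that split ``X_c`` into
carbohydrate, protein, lipid and inert pools, and (for pre-hydrolysed
substrates such as ruminant manure) the soluble COD components released before
digestion.

All compositional quantities are stored as unitless mass fractions (not
percent). Readers converting from %TS tables divide by 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "FeedstockComposition",
    "ElementalFormula",
    "ThODSet",
    "SolubleFractions",
    "DisintegrationPartition",
    "InfluentSpec",
    "InvalidCompositionError",
    "nfe_raw_fiber",
    "thod_from_formula",
    "composite_cod",
    "degradation_coefficient",
    "disintegration_partition",
    "soluble_partition",
    "blend_influent",
    "characterize",
    "read_feedstock_table",
    "write_feedstock_table",
    "load_reference_feedstocks",
    "PROTEIN_FORMULA",
    "LIPID_FORMULA",
    "CARBOHYDRATE_FORMULA",
    "LIGNIN_FORMULA",
    "DEFAULT_THOD",
    "MANURE_SOLUBLES",
]

#: Nominal integer atomic masses (g/mol). Published ThOD tables for substrate
#: fractions are computed with these, not IUPAC masses; the difference moves
#: the second decimal (e.g. protein 1.42 vs 1.41).
NOMINAL_ATOMIC_MASSES: Mapping[str, float] = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0}

#: Oxygen mass per mole of O2.
_O2_MASS = 32.0


class InvalidCompositionError(ValueError):
    """A feedstock composition violates a physical constraint."""


@dataclass(frozen=True)
class FeedstockComposition:
    """Proximate/fiber analysis of one substrate, all fractions unitless.

    Parameters
    ----------
    TS : total solids, fraction of wet mass.
    VS : volatile solids, fraction of TS.
    R_L, R_F, R_P : raw lipid, raw fiber, raw protein, fractions of TS.
    NDF, ADF, ADL : neutral/acid detergent fiber and acid detergent lignin,
        fractions of TS. ``NDF >= ADF >= ADL`` must hold.
    D_VS : observed VS degradation fraction of the substrate (0-1).
    """

    name: str
    TS: float
    VS: float
    R_L: float
    R_F: float
    R_P: float
    NDF: float
    ADF: float
    ADL: float
    D_VS: float

    def __post_init__(self) -> None:
        fracs = {
            "TS": self.TS, "VS": self.VS, "R_L": self.R_L, "R_F": self.R_F,
            "R_P": self.R_P, "NDF": self.NDF, "ADF": self.ADF, "ADL": self.ADL,
            "D_VS": self.D_VS,
        }
        bad = [k for k, v in fracs.items() if not (0.0 <= v <= 1.0)]
        if bad:
            raise InvalidCompositionError(
                f"{self.name}: fractions outside [0, 1]: {', '.join(bad)}"
            )
        if not (self.NDF >= self.ADF >= self.ADL):
            raise InvalidCompositionError(
                f"{self.name}: detergent fiber ordering violated "
                f"(NDF={self.NDF} >= ADF={self.ADF} >= ADL={self.ADL} required)"
            )
        if self.R_P + self.R_L > self.VS + 1e-12:
            raise InvalidCompositionError(
                f"{self.name}: R_P + R_L = {self.R_P + self.R_L:.4f} exceeds "
                f"VS = {self.VS:.4f}"
            )


@dataclass(frozen=True)
class ElementalFormula:
    """CHON formula with real-valued atom counts (lignin is non-integer)."""

    C: float
    H: float
    O: float = 0.0
    N: float = 0.0

    def __post_init__(self) -> None:
        if min(self.C, self.H, self.O, self.N) < 0:
            raise ValueError("atom counts must be >= 0")
        if self.C <= 0 and self.H <= 0:
            raise ValueError("formula must contain carbon or hydrogen")

    def molar_mass(self, masses: Mapping[str, float] = NOMINAL_ATOMIC_MASSES) -> float:
        return (self.C * masses["C"] + self.H * masses["H"]
                + self.O * masses["O"] + self.N * masses["N"])


#: Substrate-fraction model compounds.
PROTEIN_FORMULA = ElementalFormula(C=5, H=7, O=2, N=1)
LIPID_FORMULA = ElementalFormula(C=57, H=104, O=6)          # triolein
CARBOHYDRATE_FORMULA = ElementalFormula(C=6, H=10, O=5)     # anhydroglucose unit
LIGNIN_FORMULA = ElementalFormula(C=10.92, H=14.24, O=5.76)  # empirical, grass lignin


@dataclass(frozen=True)
class ThODSet:
    """Theoretical oxygen demand of the four substrate fractions, g O2/g."""

    ThOD_P: float
    ThOD_L: float
    ThOD_Ch: float
    ThOD_I: float

    def __post_init__(self) -> None:
        if min(self.ThOD_P, self.ThOD_L, self.ThOD_Ch, self.ThOD_I) <= 0:
            raise ValueError("all ThOD values must be > 0")


@dataclass(frozen=True)
class SolubleFractions:
    """Soluble COD shares (of composite COD) released before digestion."""

    S_su: float = 0.0
    S_aa: float = 0.0
    S_fa: float = 0.0
    S_i: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.S_su, self.S_aa, self.S_fa, self.S_i)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("soluble shares must be in [0, 1]")
        if sum(vals) >= 1.0:
            raise ValueError("soluble shares must sum to < 1")

    @property
    def total(self) -> float:
        return self.S_su + self.S_aa + self.S_fa + self.S_i


#: Soluble COD shares of cattle manure (pre-hydrolysed in the rumen).
#: Acetate solubility is 0 and is not modelled.
MANURE_SOLUBLES = SolubleFractions(S_su=0.108, S_aa=0.027, S_fa=0.008, S_i=0.057)


@dataclass(frozen=True)
class DisintegrationPartition:
    """COD/COD partition of composite material into ADM1 pools.

    ``d`` is the degradable share of structural carbohydrates (NDF − ADL);
    the f-factors close to 1 so disintegration conserves COD.
    """

    d: float
    f_Ch_xc: float
    f_L_xc: float
    f_P_xc: float
    f_I_xc: float

    def __post_init__(self) -> None:
        total = self.f_Ch_xc + self.f_L_xc + self.f_P_xc + self.f_I_xc
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"f-factors must sum to 1 (got {total!r})")
        for name in ("d", "f_Ch_xc", "f_L_xc", "f_P_xc", "f_I_xc"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass(frozen=True)
class InfluentSpec:
    """Digester influent: composite + soluble COD concentrations and flow.

    Concentrations in kgCOD/m3 (S_IN in kmol N/m3), flow in m3/d.
    """

    X_c: float
    S_su: float = 0.0
    S_aa: float = 0.0
    S_fa: float = 0.0
    S_I: float = 0.0
    partition: DisintegrationPartition = field(
        default=DisintegrationPartition(d=0.0, f_Ch_xc=0.25, f_L_xc=0.25,
                                        f_P_xc=0.25, f_I_xc=0.25))
    S_IN: float = 0.0
    flow: float = 1.0

    def __post_init__(self) -> None:
        for name in ("X_c", "S_su", "S_aa", "S_fa", "S_I", "S_IN"):
            if getattr(self, name) < 0:
                raise ValueError(f"influent {name} must be >= 0")
        if self.flow <= 0:
            raise ValueError("influent flow must be > 0")

    @property
    def total_cod(self) -> float:
        return self.X_c + self.S_su + self.S_aa + self.S_fa + self.S_I


def nfe_raw_fiber(comp: FeedstockComposition) -> float:
    """Combined nitrogen-free extract + raw fiber carbohydrate pool (of TS).

    NfE + R_F = VS − R_P − R_L: everything volatile that is neither protein
    nor lipid is carbohydrate (starch + cellulose + hemicellulose + lignin
    before the fiber split).
    """
    pool = comp.VS - comp.R_P - comp.R_L
    if pool < -1e-12:
        raise InvalidCompositionError(
            f"{comp.name}: VS ({comp.VS}) < R_P + R_L "
            f"({comp.R_P} + {comp.R_L}); no carbohydrate pool remains"
        )
    return max(pool, 0.0)


def thod_from_formula(
    f: ElementalFormula,
    masses: Mapping[str, float] = NOMINAL_ATOMIC_MASSES,
) -> float:
    """Theoretical oxygen demand of C_cH_hO_oN_n, g O2 per g substance.

    Full oxidation to CO2 and H2O with nitrogen leaving as NH3:
    ``ThOD = 32 (C + H/4 − O/2 − 3N/4) / M``. Uses nominal integer atomic
    masses by default, matching published substrate-fraction ThOD tables.
    """
    mol_o2 = f.C + f.H / 4.0 - f.O / 2.0 - 0.75 * f.N
    if mol_o2 < 0:
        raise ValueError(f"over-oxygenated formula: negative O2 demand ({mol_o2})")
    m = f.molar_mass(masses)
    if m <= 0:
        raise ValueError("molar mass must be > 0")
    return _O2_MASS * mol_o2 / m


#: Default ThOD of the four fractions (g O2/g), derived from the model
#: compounds above. Protein 1.42, lipid 2.90, carbohydrate 1.19, lignin 1.56
#: at 2 dp.
DEFAULT_THOD = ThODSet(
    ThOD_P=thod_from_formula(PROTEIN_FORMULA),
    ThOD_L=thod_from_formula(LIPID_FORMULA),
    ThOD_Ch=thod_from_formula(CARBOHYDRATE_FORMULA),
    ThOD_I=thod_from_formula(LIGNIN_FORMULA),
)


def composite_cod(
    comp: FeedstockComposition,
    thod: ThODSet = DEFAULT_THOD,
    rho: float = 1000.0,
) -> float:
    """Composite COD concentration X_C of the wet substrate, kgCOD/m3.

    X_C = ρ·TS·(R_P·ThOD_P + R_L·ThOD_L + ADL·ThOD_I + (R_F+NfE−ADL)·ThOD_Ch)
    with ρ the wet density (default 1,000 kg/m3). Lignin (ADL) is charged at
    the inert ThOD; the remaining carbohydrate (starch, cellulose,
    hemicellulose) at the anhydroglucose ThOD.
    """
    if rho <= 0:
        raise ValueError("density must be > 0")
    carb = nfe_raw_fiber(comp) - comp.ADL
    if carb < -1e-12:
        raise InvalidCompositionError(
            f"{comp.name}: non-lignin carbohydrate pool negative "
            f"(R_F+NfE = {nfe_raw_fiber(comp):.4f} < ADL = {comp.ADL:.4f})"
        )
    return rho * comp.TS * (
        comp.R_P * thod.ThOD_P
        + comp.R_L * thod.ThOD_L
        + comp.ADL * thod.ThOD_I
        + max(carb, 0.0) * thod.ThOD_Ch
    )


def degradation_coefficient(comp: FeedstockComposition) -> float:
    """Degradable share d of structural carbohydrates (NDF − ADL).

    d = (NDF − VS(1 − D_VS)) / (NDF − ADL): the observed overall VS
    degradability D_VS is attributed to the fully degradable pools (protein,
    lipid, starch) first; d is the cellulose+hemicellulose degradability that
    makes the budget close. Clamped to [0, 1] with a warning when the
    composition and D_VS are inconsistent.
    """
    denom = comp.NDF - comp.ADL
    if denom <= 0:
        raise ZeroDivisionError(
            f"{comp.name}: NDF must exceed ADL to define the degradation "
            f"coefficient (NDF={comp.NDF}, ADL={comp.ADL})"
        )
    d = (comp.NDF - comp.VS * (1.0 - comp.D_VS)) / denom
    if d < 0.0 or d > 1.0:
        warnings.warn(
            f"{comp.name}: degradation coefficient {d:.4f} outside [0, 1]; "
            "clamped. Check D_VS against the fiber composition.",
            stacklevel=2,
        )
        d = min(max(d, 0.0), 1.0)
    return d


def disintegration_partition(
    comp: FeedstockComposition, d: float | None = None
) -> DisintegrationPartition:
    """f-factors splitting composite COD into ADM1 pools after disintegration.

    f_Ch = (R_F+NfE − NDF + (NDF−ADL)·d)/VS  (starch + degradable fiber)
    f_L  = R_L/VS,  f_P = R_P/VS
    f_I  = (ADL + (NDF−ADL)(1−d))/VS         (lignin + undegradable fiber)

    The four close to 1 by construction (substituting R_F+NfE = VS−R_P−R_L).
    A negative starch term (R_F+NfE < NDF) is clamped to zero with a warning
    and the deficit is moved into the inert pool so closure holds.
    """
    if d is None:
        d = degradation_coefficient(comp)
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"d = {d} outside [0, 1]")
    vs = comp.VS
    if vs <= 0:
        raise InvalidCompositionError(f"{comp.name}: VS must be > 0")
    pool = nfe_raw_fiber(comp)
    starch = pool - comp.NDF
    fiber = comp.NDF - comp.ADL
    f_ch = (starch + fiber * d) / vs
    f_l = comp.R_L / vs
    f_p = comp.R_P / vs
    f_i = (comp.ADL + fiber * (1.0 - d)) / vs
    if starch < 0:
        warnings.warn(
            f"{comp.name}: starch pool negative (R_F+NfE = {pool:.4f} < "
            f"NDF = {comp.NDF:.4f}); clamped to 0 and moved to inerts.",
            stacklevel=2,
        )
        f_ch = max(fiber * d / vs, 0.0)
        f_i = 1.0 - f_ch - f_l - f_p
    if f_ch < 0:
        f_i += f_ch
        f_ch = 0.0
    return DisintegrationPartition(d=d, f_Ch_xc=f_ch, f_L_xc=f_l,
                                   f_P_xc=f_p, f_I_xc=f_i)


def soluble_partition(
    Xc_total: float,
    sol: SolubleFractions,
    partition: DisintegrationPartition,
) -> tuple[float, dict[str, float], DisintegrationPartition]:
    """Split composite COD into soluble components and residual particulate.

    Soluble monosaccharide, amino-acid, LCFA and inert COD are taken as
    fixed shares of the composite COD and subtracted from the carbohydrate,
    protein, lipid and inert pools respectively. Returns
    ``(X_c, solubles, adjusted_partition)`` where the adjusted f-factors
    re-close to 1 over the remaining particulate COD.
    """
    if Xc_total < 0:
        raise ValueError("composite COD must be >= 0")
    solubles = {
        "S_su": sol.S_su * Xc_total,
        "S_aa": sol.S_aa * Xc_total,
        "S_fa": sol.S_fa * Xc_total,
        "S_I": sol.S_i * Xc_total,
    }
    pools = {
        "carbohydrate": partition.f_Ch_xc * Xc_total - solubles["S_su"],
        "protein": partition.f_P_xc * Xc_total - solubles["S_aa"],
        "lipid": partition.f_L_xc * Xc_total - solubles["S_fa"],
        "inert": partition.f_I_xc * Xc_total - solubles["S_I"],
    }
    for pool_name, remaining in pools.items():
        if remaining < -1e-9 * max(Xc_total, 1.0):
            raise ValueError(
                f"soluble share drives the {pool_name} pool negative "
                f"({remaining:.4g} kgCOD/m3)"
            )
    X_c = Xc_total * (1.0 - sol.total)
    if X_c > 0:
        adjusted = DisintegrationPartition(
            d=partition.d,
            f_Ch_xc=max(pools["carbohydrate"], 0.0) / X_c,
            f_P_xc=max(pools["protein"], 0.0) / X_c,
            f_L_xc=max(pools["lipid"], 0.0) / X_c,
            f_I_xc=max(pools["inert"], 0.0) / X_c,
        )
    else:
        adjusted = partition
    return X_c, solubles, adjusted


@dataclass(frozen=True)
class CharacterizedFeedstock:
    """One substrate fully characterized at digester dilution."""

    composition: FeedstockComposition
    Xc_undiluted: float            # kgCOD/m3 at the substrate's own TS
    partition: DisintegrationPartition
    solubles: SolubleFractions


def characterize(
    comp: FeedstockComposition,
    thod: ThODSet = DEFAULT_THOD,
    rho: float = 1000.0,
    solubles: SolubleFractions | None = None,
) -> CharacterizedFeedstock:
    """Characterize one substrate: composite COD, d, f-factors, solubles."""
    d = degradation_coefficient(comp)
    part = disintegration_partition(comp, d)
    return CharacterizedFeedstock(
        composition=comp,
        Xc_undiluted=composite_cod(comp, thod, rho),
        partition=part,
        solubles=solubles if solubles is not None else SolubleFractions(),
    )


def _organically_bound_n_per_protein_mass(thod_p: float, n_aa: float) -> float:
    """kg N bound in amino-acid/protein COD per kg protein (ADM1's N_aa)."""
    return n_aa * thod_p * 14.0  # kmolN/kgCOD * kgCOD/kg * kg/kmol


def blend_influent(
    biomass: FeedstockComposition,
    manure: FeedstockComposition,
    vs_ratio_biomass: float,
    total_vs_rate: float = 1000.0,
    *,
    thod: ThODSet = DEFAULT_THOD,
    rho: float = 1000.0,
    manure_solubles: SolubleFractions = MANURE_SOLUBLES,
    reactor_ts: float = 0.10,
    protein_N_mass_fraction: float = 0.16,
    n_aa: float = 0.007,
    blend_strategy: str = "characterize-then-sum",
) -> InfluentSpec:
    """Digester influent for a biomass:manure blend at a prescribed VS ratio.

    Each feedstock's wet-mass flow delivers its VS share of ``total_vs_rate``
    (kgVS/hr); dilution water brings the mixed stream to ``reactor_ts`` total
    solids. With the default strategy each feedstock is characterized
    separately (its own X_c, d, f-factors, solubles) and the influent is the
    flow-weighted sum of the COD streams; ``blend_strategy="blend-composition"``
    instead mass-averages the two compositions first and characterizes the
    mixture once.

    Influent inorganic nitrogen is the protein nitrogen
    (``protein_N_mass_fraction`` of protein mass) not already bound in
    protein/amino-acid COD at ADM1's amino-acid N content ``n_aa``
    (kmol N/kgCOD).

    Returns an :class:`InfluentSpec` with flow in m3/d.
    """
    if not 0.0 <= vs_ratio_biomass <= 1.0:
        raise ValueError(f"vs_ratio_biomass = {vs_ratio_biomass} outside [0, 1]")
    if total_vs_rate <= 0:
        raise ValueError("total_vs_rate must be > 0")
    if blend_strategy not in ("characterize-then-sum", "blend-composition"):
        raise ValueError(f"unknown blend strategy {blend_strategy!r}")

    shares = {"biomass": vs_ratio_biomass, "manure": 1.0 - vs_ratio_biomass}
    comps = {"biomass": biomass, "manure": manure}
    sols = {"biomass": SolubleFractions(), "manure": manure_solubles}

    # Wet-mass flows (kg/hr) delivering the VS split, and dilution to target TS.
    wet, dry = {}, {}
    for k, s in shares.items():
        c = comps[k]
        vs_rate = s * total_vs_rate
        wet[k] = vs_rate / (c.TS * c.VS) if vs_rate > 0 else 0.0
        dry[k] = wet[k] * c.TS
    total_wet = sum(wet.values())
    total_dry = sum(dry.values())
    mix_ts = total_dry / total_wet if total_wet > 0 else 0.0
    if mix_ts > reactor_ts:
        water = total_dry / reactor_ts - total_wet
    else:
        warnings.warn(
            f"feed already at TS = {mix_ts:.3f} <= target {reactor_ts}; "
            "no dilution water added.", stacklevel=2)
        water = 0.0
    flow_m3_d = (total_wet + water) / rho * 24.0  # wet density rho kg/m3

    if blend_strategy == "blend-composition":
        w = {k: dry[k] / total_dry for k in comps}  # dry-mass weights
        mixed = FeedstockComposition(
            name=f"blend(B{vs_ratio_biomass:.2f})",
            TS=total_dry / (total_wet + water),
            VS=sum(w[k] * comps[k].VS for k in comps),
            R_L=sum(w[k] * comps[k].R_L for k in comps),
            R_F=sum(w[k] * comps[k].R_F for k in comps),
            R_P=sum(w[k] * comps[k].R_P for k in comps),
            NDF=sum(w[k] * comps[k].NDF for k in comps),
            ADF=sum(w[k] * comps[k].ADF for k in comps),
            ADL=sum(w[k] * comps[k].ADL for k in comps),
            D_VS=sum(w[k] * comps[k].D_VS for k in comps),
        )
        sol_mix = SolubleFractions(
            S_su=shares["manure"] * manure_solubles.S_su,
            S_aa=shares["manure"] * manure_solubles.S_aa,
            S_fa=shares["manure"] * manure_solubles.S_fa,
            S_i=shares["manure"] * manure_solubles.S_i,
        )
        char = {"mix": (mixed, sol_mix, 1.0)}
    else:
        char = {k: (comps[k], sols[k], None) for k in comps if shares[k] > 0}

    # COD loads (kgCOD/hr) per feedstock, partitioned; then flow-weighted sum.
    total_xc_load = 0.0
    sol_loads = {"S_su": 0.0, "S_aa": 0.0, "S_fa": 0.0, "S_I": 0.0}
    f_load = {"f_Ch_xc": 0.0, "f_L_xc": 0.0, "f_P_xc": 0.0, "f_I_xc": 0.0}
    d_load = 0.0
    protein_mass_rate = 0.0  # kg protein/hr
    for k, (c, sol, _) in char.items():
        fs = characterize(c, thod, rho, sol)
        dry_rate = total_dry if k == "mix" else dry[k]
        cod_load = fs.Xc_undiluted / (rho * c.TS) * dry_rate  # kgCOD/hr
        xc, sol_conc, part = soluble_partition(cod_load, fs.solubles, fs.partition)
        total_xc_load += xc
        for s in sol_loads:
            sol_loads[s] += sol_conc[s]
        for fname in f_load:
            f_load[fname] += getattr(part, fname) * xc
        d_load += part.d * xc
        protein_mass_rate += c.R_P * dry_rate

    if total_xc_load > 0:
        partition = DisintegrationPartition(
            d=d_load / total_xc_load,
            **{fn: f_load[fn] / total_xc_load for fn in f_load},
        )
    else:
        partition = DisintegrationPartition(d=0.0, f_Ch_xc=0.25, f_L_xc=0.25,
                                            f_P_xc=0.25, f_I_xc=0.25)

    # Inorganic N: protein N beyond what ADM1 carries organically.
    n_total = protein_N_mass_fraction * protein_mass_rate          # kg N/hr
    n_bound = _organically_bound_n_per_protein_mass(thod.ThOD_P, n_aa) \
        * protein_mass_rate
    s_in = max(n_total - n_bound, 0.0) / 14.0 / (flow_m3_d / 24.0)  # kmol/m3

    vol_per_hr = flow_m3_d / 24.0
    return InfluentSpec(
        X_c=total_xc_load / vol_per_hr,
        S_su=sol_loads["S_su"] / vol_per_hr,
        S_aa=sol_loads["S_aa"] / vol_per_hr,
        S_fa=sol_loads["S_fa"] / vol_per_hr,
        S_I=sol_loads["S_I"] / vol_per_hr,
        partition=partition,
        S_IN=s_in,
        flow=flow_m3_d,
    )


# ---------------------------------------------------------------------------
# Table I/O

_TABLE_COLUMNS = ["name", "TS", "VS", "RL", "RF", "RP", "NDF", "ADF", "ADL", "DVS"]


def read_feedstock_table(path_or_buf) -> dict[str, FeedstockComposition]:
    """Read a feedstock characterization CSV (percent basis) into compositions.

    Columns: ``name,TS,VS,RL,RF,RP,NDF,ADF,ADL,DVS`` with TS as % of wet mass
    and the rest as %TS (DVS as % of VS).
    """
    df = pd.read_csv(path_or_buf)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feedstock table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[row["name"]] = FeedstockComposition(
            name=row["name"],
            TS=row["TS"] / 100.0, VS=row["VS"] / 100.0,
            R_L=row["RL"] / 100.0, R_F=row["RF"] / 100.0, R_P=row["RP"] / 100.0,
            NDF=row["NDF"] / 100.0, ADF=row["ADF"] / 100.0, ADL=row["ADL"] / 100.0,
            D_VS=row["DVS"] / 100.0,
        )
    return out


def write_feedstock_table(comps: Mapping[str, FeedstockComposition], path) -> None:
    """Write compositions back to the percent-basis CSV layout."""
    rows = []
    for c in comps.values():
        rows.append({
            "name": c.name, "TS": c.TS * 100, "VS": c.VS * 100,
            "RL": c.R_L * 100, "RF": c.R_F * 100, "RP": c.R_P * 100,
            "NDF": c.NDF * 100, "ADF": c.ADF * 100, "ADL": c.ADL * 100,
            "DVS": c.D_VS * 100,
        })
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def load_reference_feedstocks() -> dict[str, FeedstockComposition]:
    """Packaged literature characterization of cattle manure and prairie
    biomass (prairie = unweighted mean of switchgrass, indiangrass and big
    bluestem)."""
    ref = resources.files("codigest.data") / "feedstocks.csv"
    with resources.as_file(ref) as p:
        return read_feedstock_table(p)


def blended_composition_name(vs_ratio_biomass: float) -> str:
    """Scenario label B<x>:M<y> on tenths for a biomass VS share."""
    b = round(vs_ratio_biomass * 10)
    return f"B{b}:M{10 - b}"
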