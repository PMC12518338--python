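"""End-to-end co-digestion scenarios, sensitivity tornados and fixtures.

A scenario label ``B<x>:M<y>`` sets the volatile-solids split between
prairie biomass (B) and cattle manure (M); ``run_scenario`` wires
feedstock characterization -> ADM1 digestion -> plant balance -> TEA -> LCA
for one ratio, ``sweep`` runs the standard eleven ratios, and ``tornado``
perturbs one parameter at a time by a relative amount (default +/-20%) to
rank drivers of the MFSP or the net global warming potential.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import feedstock as fsmod
from . import lca as lcamod
from . import plant as plantmod
from . import tea as teamod
from .adm1 import ADM1Parameters, simulate_cstr, yield_report
from .feedstock import FeedstockComposition

__all__ = [
    "ScenarioConfig", "ScenarioResult", "SensitivityResult", "RATIO_LABELS",
    "parse_ratio", "run_scenario", "sweep", "tornado", "fixture_generator",
    "load_config",
]

#: the eleven standard blend labels, all-biomass to all-manure
RATIO_LABELS = [f"B{b}:M{10 - b}" for b in range(10, -1, -1)]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run a scenario deterministically."""

    biomass_name: str = "prairie_biomass"
    manure_name: str = "cattle_manure"
    feedstock_table: str | None = None      # CSV path; None = packaged table
    rho: float = 1000.0
    protein_N_mass_fraction: float = 0.16
    blend_strategy: str = "characterize-then-sum"
    total_vs_rate: float = 1000.0           # kgVS/hr
    HRT: float = 30.0                       # d
    gas_reference: str = "STP"
    influent_S_IC: float = 0.01
    influent_S_cat: float = 0.04
    influent_S_an: float = 0.02
    adm1_overrides: dict = field(default_factory=dict)
    plant: plantmod.PlantParameters | None = None   # None = calibrated default
    cost: teamod.CostParameters = field(default_factory=teamod.CostParameters)
    lca: lcamod.LCAParameters = field(default_factory=lcamod.LCAParameters)
    seed: int = 0

    def feedstocks(self) -> tuple[FeedstockComposition, FeedstockComposition]:
        if self.feedstock_table is None:
            table = fsmod.load_reference_feedstocks()
        else:
            table = fsmod.read_feedstock_table(self.feedstock_table)
        return table[self.biomass_name], table[self.manure_name]

    def adm1_params(self) -> ADM1Parameters:
        return ADM1Parameters().with_overrides(self.adm1_overrides)

    def plant_params(self, biomass, manure) -> plantmod.PlantParameters:
        if self.plant is not None:
            return self.plant
        return plantmod.default_plant_parameters(biomass, manure)


def load_config(path) -> ScenarioConfig:
    """Load a YAML config; missing keys keep their defaults.

    Sections: ``feedstock`` (rho, protein_N_mass_fraction, blend_strategy,
    table, biomass, manure), ``scenario`` (total_vs_rate, HRT,
    gas_reference, influent_*), ``adm1`` (parameter overrides), ``plant``,
    ``tea``, ``lca`` (field overrides), ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw: dict = {}
    fs = raw.get("feedstock", {})
    for src, dst in (("rho", "rho"),
                     ("protein_N_mass_fraction", "protein_N_mass_fraction"),
                     ("blend_strategy", "blend_strategy"),
                     ("table", "feedstock_table"),
                     ("biomass", "biomass_name"), ("manure", "manure_name")):
        if src in fs:
            kw[dst] = fs[src]
    sc = raw.get("scenario", {})
    for k in ("total_vs_rate", "HRT", "gas_reference", "influent_S_IC",
              "influent_S_cat", "influent_S_an"):
        if k in sc:
            kw[k] = sc[k]
    if "adm1" in raw:
        kw["adm1_overrides"] = dict(raw["adm1"])
    if "plant" in raw:
        kw["plant"] = plantmod.PlantParameters(**raw["plant"])
    if "tea" in raw:
        kw["cost"] = teamod.CostParameters(**raw["tea"])
    if "lca" in raw:
        kw["lca"] = lcamod.LCAParameters(**raw["lca"])
    if "seed" in raw:
        kw["seed"] = int(raw["seed"])
    return ScenarioConfig(**kw)


def parse_ratio(ratio) -> tuple[float, str]:
    """Biomass VS share and canonical label from ``B<x>:M<y>`` or a number."""
    if isinstance(ratio, str):
        m = re.fullmatch(r"[Bb](\d+(?:\.\d+)?):[Mm](\d+(?:\.\d+)?)", ratio.strip())
        if not m:
            raise ValueError(f"cannot parse ratio label {ratio!r}; "
                             "expected e.g. 'B1:M9'")
        b, mm = float(m.group(1)), float(m.group(2))
        if b + mm <= 0:
            raise ValueError("ratio parts must not both be zero")
        share = b / (b + mm)
    else:
        share = float(ratio)
    if not 0.0 <= share <= 1.0:
        raise ValueError(f"biomass VS share {share} outside [0, 1]")
    return share, fsmod.blended_composition_name(share)


@dataclass
class ScenarioResult:
    """Everything one blend ratio produces across the pipeline."""

    label: str
    vs_ratio_biomass: float
    ch4_yield: float              # mL/gVS
    biogas_yield: float           # mL/gVS
    ch4_fraction: float
    digester_pH: float
    balance: plantmod.PlantBalance
    tea: teamod.TEAResult
    impacts: lcamod.ImpactResult
    allocation: dict[str, dict[str, float]]   # basis -> product -> %

    @property
    def mfsp(self) -> float:
        return self.tea.mfsp

    @property
    def net_gwp(self) -> float:
        return self.impacts.net("global_warming")

    def summary(self) -> dict[str, float]:
        out = {
            "label": self.label,
            "vs_ratio_biomass": self.vs_ratio_biomass,
            "ch4_yield_mL_gVS": self.ch4_yield,
            "biogas_yield_mL_gVS": self.biogas_yield,
            "ch4_fraction": self.ch4_fraction,
            "digester_pH": self.digester_pH,
            "rng_GJ_per_dry_tonne": self.balance.rng_GJ_per_dry_tonne,
            "biochar_kg_per_dry_tonne": self.balance.biochar_kg_per_dry_tonne,
            "capital_usd": self.tea.capital,
            "mfsp_usd_per_GJ": self.tea.mfsp,
        }
        for cat in lcamod.CATEGORIES:
            out[f"net_{cat}"] = self.impacts.net(cat)
        return out


def run_scenario(ratio, config: ScenarioConfig = ScenarioConfig(),
                 out_dir=None) -> ScenarioResult:
    """Run one blend ratio end to end; deterministic given the config.

    Writes trajectory/summary/report files under ``out_dir`` when given.
    """
    share, label = parse_ratio(ratio)
    biomass, manure = config.feedstocks()
    params = config.adm1_params()
    influent = fsmod.blend_influent(
        biomass, manure, share,
        total_vs_rate=config.total_vs_rate, rho=config.rho,
        reactor_ts=config.plant_params(biomass, manure).reactor_ts,
        protein_N_mass_fraction=config.protein_N_mass_fraction,
        n_aa=params.N_aa, blend_strategy=config.blend_strategy)
    sim = simulate_cstr(
        influent, params, HRT=config.HRT,
        influent_S_IC=config.influent_S_IC,
        influent_S_cat=config.influent_S_cat,
        influent_S_an=config.influent_S_an)
    vs_rate_d = config.total_vs_rate * 24.0
    yields = yield_report(sim, vs_rate=vs_rate_d,
                          reference=config.gas_reference)

    pparams = config.plant_params(biomass, manure)
    bal = plantmod.build_balance(
        share, biomass, manure,
        ch4_kg_hr=yields.ch4_mass_rate / 24.0,
        co2_kg_hr=yields.co2_mass_rate / 24.0,
        total_vs_rate=config.total_vs_rate, params=pparams)
    tea = teamod.evaluate(bal, config.cost)
    flows = lcamod.inventory_flows(bal, config.lca)
    impacts = lcamod.category_impacts(flows, bal.rng_GJ_hr, params=config.lca)
    allocation = {
        basis: lcamod.allocation_shares(
            bal.biochar_kg_per_dry_tonne, bal.rng_GJ_per_dry_tonne, basis,
            biochar_price=config.cost.price_biochar, rng_price=tea.mfsp,
            params=config.lca)
        for basis in ("mass", "energy", "economic")
    }
    result = ScenarioResult(
        label=label, vs_ratio_biomass=share,
        ch4_yield=yields.ch4_yield, biogas_yield=yields.biogas_yield,
        ch4_fraction=yields.ch4_fraction, digester_pH=sim.pH,
        balance=bal, tea=tea, impacts=impacts, allocation=allocation)
    if out_dir is not None:
        _write_scenario(result, sim, yields, config, Path(out_dir))
    return result


def _write_scenario(result, sim, yields, config, out_dir: Path) -> None:
    from .adm1 import write_summary, write_trajectory
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = result.label.replace(":", "_")
    write_trajectory(sim, out_dir / f"{tag}_trajectory.csv")
    write_summary(sim, yields, out_dir / f"{tag}_digester.json")
    result.balance.to_stream_table().to_csv(
        out_dir / f"{tag}_streams.csv", index=False)
    teamod.write_report(result.tea, out_dir / f"{tag}_tea.json",
                        out_dir / f"{tag}_cashflow.csv", config.cost)
    lcamod.write_results(result.impacts, out_dir / f"{tag}_lca.csv",
                         scenario=result.label)
    with open(out_dir / f"{tag}_summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)


def sweep(config: ScenarioConfig = ScenarioConfig(), labels=None,
          out_dir=None) -> tuple[list[ScenarioResult], pd.DataFrame]:
    """Run the standard eleven ratios (or ``labels``); returns results and a
    summary table ordered from all-biomass to all-manure."""
    labels = list(labels) if labels is not None else RATIO_LABELS
    results = [run_scenario(lab, config, out_dir=out_dir) for lab in labels]
    table = pd.DataFrame([r.summary() for r in results])
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "sweep_summary.csv", index=False)
    return results, table


# ---------------------------------------------------------------------------
# sensitivity tornado

@dataclass
class SensitivityResult:
    parameter: str
    low: float          # output at -rel
    high: float         # output at +rel
    baseline: float
    rank: int = 0

    @property
    def span(self) -> float:
        return abs(self.high - self.low)


MFSP_PARAMETERS = ["rng_yield", "manure_price", "biomass_price",
                   "biochar_price", "natural_gas_price", "irr"]
GWP_PARAMETERS = ["rng_yield", "manure_flow", "biomass_flow",
                  "manure_factor", "biomass_factor",
                  "n_fertilizer_displacement", "ch4_leak_factor",
                  "natural_gas_factor"]


def tornado(config: ScenarioConfig = ScenarioConfig(), output: str = "mfsp",
            parameters=None, baseline_ratio: str = "B1:M9",
            rel: float = 0.2,
            baseline_result: ScenarioResult | None = None
            ) -> list[SensitivityResult]:
    """One-at-a-time +/-``rel`` sensitivity of MFSP ($/GJ) or net GWP
    (kg CO2 eq./GJ) around a baseline scenario, ranked by span.

    Perturbations act downstream of the digester (prices, rates, factors,
    flows); the ADM1 steady state is computed once for the baseline.
    """
    output = output.lower()
    if output not in ("mfsp", "gwp"):
        raise ValueError("output must be 'mfsp' or 'gwp'")
    base = baseline_result or run_scenario(baseline_ratio, config)
    valid = MFSP_PARAMETERS if output == "mfsp" else GWP_PARAMETERS
    parameters = list(parameters) if parameters is not None else valid
    unknown = set(parameters) - set(valid)
    if unknown:
        raise ValueError(f"unknown {output} parameters {sorted(unknown)}; "
                         f"valid: {valid}")

    def mfsp_at(param: str, f: float) -> float:
        bal, cost = base.balance, config.cost
        if param == "rng_yield":
            annual = bal.rng_GJ_hr * f * cost.annual_hours
            return teamod.mfsp_solve(base.tea.capital, base.tea.total_opex,
                                     base.tea.biochar_revenue, annual, cost)
        fieldmap = {"manure_price": "price_manure",
                    "biomass_price": "price_biomass",
                    "biochar_price": "price_biochar",
                    "natural_gas_price": "price_natural_gas", "irr": "irr"}
        cost2 = replace(cost, **{fieldmap[param]:
                                 getattr(cost, fieldmap[param]) * f})
        return teamod.evaluate(bal, cost2).mfsp

    def gwp_at(param: str, f: float) -> float:
        flows = dict(base.impacts.flows_kg_hr)
        fm = lcamod.load_impact_factors().copy()
        rng = base.balance.rng_GJ_hr
        if param == "rng_yield":
            rng *= f
        elif param == "manure_flow":
            flows["cattle_manure"] *= f
        elif param == "biomass_flow":
            flows["prairie_biomass"] *= f
        elif param == "n_fertilizer_displacement":
            flows["avoided_n_fertilizer"] *= f
        else:
            stream = {"manure_factor": "cattle_manure",
                      "biomass_factor": "prairie_biomass",
                      "ch4_leak_factor": "ch4_leak",
                      "natural_gas_factor": "natural_gas"}[param]
            sel = (fm["stream"] == stream) & (fm["category"] == "global_warming")
            fm.loc[sel, "factor"] *= f
        res = lcamod.category_impacts(flows, rng, factors=fm,
                                      params=config.lca)
        return res.net("global_warming")

    evaluate = mfsp_at if output == "mfsp" else gwp_at
    base_value = base.mfsp if output == "mfsp" else base.net_gwp
    results = [SensitivityResult(parameter=p, low=evaluate(p, 1.0 - rel),
                                 high=evaluate(p, 1.0 + rel),
                                 baseline=base_value)
               for p in parameters]
    results.sort(key=lambda r: r.span, reverse=True)
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


# ---------------------------------------------------------------------------
# randomized fixtures

def fixture_generator(seed: int, n: int) -> list[FeedstockComposition]:
    """``n`` random valid feedstock compositions, reproducible from ``seed``.

    Constructive sampling: every draw satisfies the composition invariants
    (fractions in [0,1], NDF >= ADF >= ADL, R_P + R_L <= VS, carbohydrate
    pool >= ADL) and yields a degradation coefficient in [0, 1]. About one
    draw in ten has NDF exceeding the carbohydrate pool, exercising the
    negative-starch clamp, and every 25th draw sits at the starch boundary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[FeedstockComposition] = []
    while len(out) < n:
        i = len(out)
        ts = rng.uniform(0.05, 0.95)
        vs = rng.uniform(0.6, 0.97)
        rp = rng.uniform(0.02, 0.25) * vs
        rl = rng.uniform(0.01, 0.15) * vs
        if rp + rl > 0.6 * vs:
            continue
        carb = vs - rp - rl
        if i % 25 == 24:
            u = 1.0 + rng.uniform(-1e-6, 1e-6)   # starch boundary
        else:
            u = rng.uniform(0.5, 1.1)            # >1 => starch clamp branch
        ndf = min(carb * u, 0.99)
        adl = ndf * rng.uniform(0.03, 0.35)
        if adl >= 0.95 * min(ndf, carb):
            continue
        adf = adl + (ndf - adl) * rng.uniform(0.3, 0.9)
        d_target = rng.uniform(0.02, 0.98)
        dvs = 1.0 - (ndf - d_target * (ndf - adl)) / vs
        if not 0.0 <= dvs <= 1.0:
            continue
        rf = rng.uniform(0.3, 0.9) * carb
        out.append(FeedstockComposition(
            name=f"fixture_{seed}_{i}", TS=ts, VS=vs, R_L=rl, R_F=rf,
            R_P=rp, NDF=ndf, ADF=adf, ADL=adl, D_VS=dvs))
    return out
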