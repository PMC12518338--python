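"""ADM1 parameter set, BSM2 parameterization.

Defaults follow the Benchmark Simulation Model no. 2 convention for ADM1
(Rosen & Jeppsson implementation): COD-based stoichiometry, first-order
disintegration/hydrolysis/decay, Monod uptake with pH / hydrogen / free-
ammonia inhibition, temperature-corrected acid-base and Henry constants.

Units: rates in 1/d, concentrations kgCOD/m3 or kmol/m3, temperatures K,
pressures bar, equilibrium constants on the molar scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Any, Mapping

import yaml

R_GAS = 0.083145  # bar m3 / (kmol K)
T_BASE = 298.15   # K, reference for equilibrium constants


def _vant_hoff(k_base: float, delta_h: float, t_op: float) -> float:
    """Temperature correction: K(T) = K_base exp(ΔH/(100R) (1/T_base − 1/T))."""
    return k_base * math.exp(delta_h / (100.0 * R_GAS) * (1.0 / T_BASE - 1.0 / t_op))


@dataclass(frozen=True)
class ADM1Parameters:
    """Kinetic, stoichiometric and physico-chemical constants (BSM2 defaults)."""

    # -- operating
    T_op: float = 308.15          # K; mesophilic, 35 C
    P_atm: float = 1.013          # bar

    # -- disintegration / hydrolysis (1/d)
    k_dis: float = 0.5
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0

    # -- composite disintegration products (defaults for decayed biomass;
    #    influent composite uses feedstock-derived f-factors instead)
    f_sI_xc: float = 0.1
    f_ch_xc: float = 0.2
    f_pr_xc: float = 0.2
    f_li_xc: float = 0.3
    f_xI_xc: float = 0.2

    # -- carbon contents, kmol C / kgCOD
    C_su: float = 0.0313
    C_aa: float = 0.03
    C_fa: float = 0.0217
    C_va: float = 0.024
    C_bu: float = 0.025
    C_pro: float = 0.0268
    C_ac: float = 0.0313
    C_ch4: float = 0.0156
    C_sI: float = 0.03
    C_ch: float = 0.0313
    C_pr: float = 0.03
    C_li: float = 0.022
    C_xI: float = 0.03
    C_bac: float = 0.0313

    # -- nitrogen contents, kmol N / kgCOD
    N_aa: float = 0.007
    N_I: float = 0.06 / 14.0
    N_bac: float = 0.08 / 14.0

    # -- acidogenesis / acetogenesis product fractions (COD/COD)
    f_fa_li: float = 0.95
    f_h2_su: float = 0.19
    f_bu_su: float = 0.13
    f_pro_su: float = 0.27
    f_ac_su: float = 0.41
    f_h2_aa: float = 0.06
    f_va_aa: float = 0.23
    f_bu_aa: float = 0.26
    f_pro_aa: float = 0.05
    f_ac_aa: float = 0.40

    # -- biomass yields (kgCOD_X / kgCOD_S)
    Y_su: float = 0.1
    Y_aa: float = 0.08
    Y_fa: float = 0.06
    Y_c4: float = 0.06
    Y_pro: float = 0.04
    Y_ac: float = 0.05
    Y_h2: float = 0.06

    # -- Monod maxima (1/d) and half-saturations (kgCOD/m3)
    k_m_su: float = 30.0
    K_S_su: float = 0.5
    k_m_aa: float = 50.0
    K_S_aa: float = 0.3
    k_m_fa: float = 6.0
    K_S_fa: float = 0.4
    k_m_c4: float = 20.0
    K_S_c4: float = 0.2
    k_m_pro: float = 13.0
    K_S_pro: float = 0.1
    k_m_ac: float = 8.0
    K_S_ac: float = 0.15
    k_m_h2: float = 35.0
    K_S_h2: float = 7e-6

    # -- decay rates (1/d)
    k_dec_su: float = 0.02
    k_dec_aa: float = 0.02
    k_dec_fa: float = 0.02
    k_dec_c4: float = 0.02
    k_dec_pro: float = 0.02
    k_dec_ac: float = 0.02
    k_dec_h2: float = 0.02

    # -- inhibition
    K_S_IN: float = 1e-4          # kmol N/m3, nitrogen limitation
    K_I_h2_fa: float = 5e-6       # kgCOD/m3
    K_I_h2_c4: float = 1e-5
    K_I_h2_pro: float = 3.5e-6
    K_I_nh3: float = 0.0018       # kmol N/m3, free ammonia on acetoclasts
    pH_UL_aa: float = 5.5
    pH_LL_aa: float = 4.0
    pH_UL_ac: float = 7.0
    pH_LL_ac: float = 6.0
    pH_UL_h2: float = 6.0
    pH_LL_h2: float = 5.0

    # -- gas transfer & headspace
    k_L_a: float = 200.0              # 1/d
    headspace_fraction: float = 0.1   # V_gas / V_liq
    pipe_resistance_per_m3: float = 100.0  # m3 gas /(d bar m3 liquid)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("k_", "K_", "C_", "N_", "f_")) and v < 0:
                raise ValueError(f"{f.name} must be >= 0 (got {v})")
        for y in ("Y_su", "Y_aa", "Y_fa", "Y_c4", "Y_pro", "Y_ac", "Y_h2"):
            if not 0.0 < getattr(self, y) < 1.0:
                raise ValueError(f"{y} must be in (0, 1)")
        for grp in ("aa", "ac", "h2"):
            if getattr(self, f"pH_UL_{grp}") <= getattr(self, f"pH_LL_{grp}"):
                raise ValueError(f"pH_UL_{grp} must exceed pH_LL_{grp}")

    # -- temperature-corrected physico-chemistry ---------------------------

    @property
    def K_w(self) -> float:
        return _vant_hoff(1e-14, 55900.0, self.T_op)

    @property
    def K_a_va(self) -> float:
        return 10.0 ** -4.86

    @property
    def K_a_bu(self) -> float:
        return 10.0 ** -4.82

    @property
    def K_a_pro(self) -> float:
        return 10.0 ** -4.88

    @property
    def K_a_ac(self) -> float:
        return 10.0 ** -4.76

    @property
    def K_a_co2(self) -> float:
        return _vant_hoff(10.0 ** -6.35, 7646.0, self.T_op)

    @property
    def K_a_IN(self) -> float:
        return _vant_hoff(10.0 ** -9.25, 51965.0, self.T_op)

    @property
    def K_H_co2(self) -> float:  # kmol/(m3 bar)
        return _vant_hoff(0.035, -19410.0, self.T_op)

    @property
    def K_H_ch4(self) -> float:
        return _vant_hoff(0.0014, -14240.0, self.T_op)

    @property
    def K_H_h2(self) -> float:
        return _vant_hoff(7.8e-4, -4180.0, self.T_op)

    @property
    def p_h2o(self) -> float:  # bar, water vapour over the digester liquor
        return 0.0313 * math.exp(5290.0 * (1.0 / T_BASE - 1.0 / self.T_op))

    # -- overrides ---------------------------------------------------------

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ADM1Parameters":
        """New parameter set with ``overrides`` merged key-by-key."""
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise KeyError(f"unknown ADM1 parameters: {sorted(unknown)}")
        return replace(self, **dict(overrides))

    @classmethod
    def from_yaml(cls, path) -> "ADM1Parameters":
        """Load a parameter file; keys not present fall back to BSM2 defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls().with_overrides(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)},
                           fh, sort_keys=True)
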