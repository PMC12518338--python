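"""ADM1 biochemical/physico-chemical core for a CSTR digester.

State layout (29 dynamic states):

* 0-11  soluble COD / molar pools: S_su, S_aa, S_fa, S_va, S_bu, S_pro,
        S_ac, S_h2, S_ch4, S_IC (kmol C/m3), S_IN (kmol N/m3), S_I
* 12-23 particulates: X_c, X_ch, X_pr, X_li, X_su, X_aa, X_fa, X_c4,
        X_pro, X_ac, X_h2, X_I
* 24-25 ions: S_cat, S_an (kmol/m3)
* 26-28 gas phase: S_gas_h2, S_gas_ch4 (kgCOD/m3), S_gas_co2 (kmol/m3)

The 19 biochemical processes are: disintegration; hydrolysis of
carbohydrate/protein/lipid; Monod uptake of sugar, amino acids, LCFA,
valerate, butyrate, propionate, acetate and hydrogen; and first-order decay
of the seven biomass groups. Ion speciation (the eight algebraic variables:
the ionized forms of the four VFAs, bicarbonate, ammonia, hydroxide and H+)
is solved from the charge balance at every evaluation, the standard
DAE-as-ODE treatment.

Inorganic carbon and nitrogen stoichiometry are closed per process from the
carbon/nitrogen contents of every other state, so the Petersen matrix
conserves COD, C and N exactly by construction.
"""

from __future__ import annotations

import numpy as np

from ..feedstock import DisintegrationPartition, InfluentSpec
from .parameters import ADM1Parameters, R_GAS

__all__ = [
    "STATE_NAMES", "IDX", "N_STATES", "ADM1Model", "solve_ph", "IonSpeciation",
]

STATE_NAMES = [
    "S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac", "S_h2",
    "S_ch4", "S_IC", "S_IN", "S_I",
    "X_c", "X_ch", "X_pr", "X_li", "X_su", "X_aa", "X_fa", "X_c4",
    "X_pro", "X_ac", "X_h2", "X_I",
    "S_cat", "S_an",
    "S_gas_h2", "S_gas_ch4", "S_gas_co2",
]
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)
N_LIQUID = 26

#: grams COD per mole for the charge-per-COD conversion of the VFAs
_COD_VA, _COD_BU, _COD_PRO, _COD_AC = 208.0, 160.0, 112.0, 64.0


class IonSpeciation:
    """Solved algebraic ion states at one liquid composition."""

    __slots__ = ("S_H", "pH", "S_hco3", "S_co2", "S_nh3", "S_nh4",
                 "S_va_ion", "S_bu_ion", "S_pro_ion", "S_ac_ion", "S_oh",
                 "residual")

    def __init__(self, **kw):
        for k in self.__slots__:
            setattr(self, k, kw[k])


def _charge_balance(h, s_cat, s_an, s_in, s_ic, s_va, s_bu, s_pro, s_ac, p):
    """Net charge (kmol/m3) and its derivative wrt H at concentration h."""
    kw, ka_in, ka_co2 = p.K_w, p.K_a_IN, p.K_a_co2
    nh4 = s_in * h / (ka_in + h)
    hco3 = s_ic * ka_co2 / (ka_co2 + h)
    va = s_va * p.K_a_va / (p.K_a_va + h) / _COD_VA
    bu = s_bu * p.K_a_bu / (p.K_a_bu + h) / _COD_BU
    pro = s_pro * p.K_a_pro / (p.K_a_pro + h) / _COD_PRO
    ac = s_ac * p.K_a_ac / (p.K_a_ac + h) / _COD_AC
    f = s_cat + nh4 + h - hco3 - va - bu - pro - ac - s_an - kw / h
    df = (1.0 + kw / h**2
          + s_in * ka_in / (ka_in + h) ** 2
          + s_ic * ka_co2 / (ka_co2 + h) ** 2
          + s_va * p.K_a_va / (p.K_a_va + h) ** 2 / _COD_VA
          + s_bu * p.K_a_bu / (p.K_a_bu + h) ** 2 / _COD_BU
          + s_pro * p.K_a_pro / (p.K_a_pro + h) ** 2 / _COD_PRO
          + s_ac * p.K_a_ac / (p.K_a_ac + h) ** 2 / _COD_AC)
    return f, df


def solve_ph(state: np.ndarray, params: ADM1Parameters,
             h_guess: float = 1e-7) -> IonSpeciation:
    """Solve the charge balance for H+ and the ionized species.

    Newton iteration on the H+ concentration with a bisection fallback over
    pH 0-14; the returned root has |residual| below 1e-12 kmol/m3 wherever
    the balance is bracketed.
    """
    p = params
    s_cat, s_an = state[IDX["S_cat"]], state[IDX["S_an"]]
    s_in, s_ic = state[IDX["S_IN"]], state[IDX["S_IC"]]
    s_va, s_bu = state[IDX["S_va"]], state[IDX["S_bu"]]
    s_pro, s_ac = state[IDX["S_pro"]], state[IDX["S_ac"]]

    args = (s_cat, s_an, s_in, s_ic, s_va, s_bu, s_pro, s_ac, p)
    h = min(max(h_guess, 1e-14), 1.0)
    converged = False
    for _ in range(60):
        f, df = _charge_balance(h, *args)
        step = f / df
        h_new = h - step
        if h_new <= 0:
            h_new = h / 2.0
        h = h_new
        if abs(f) < 1e-13 and abs(step) < 1e-12 * max(h, 1e-12):
            converged = True
            break
    if not converged or not np.isfinite(h):
        lo, hi = 1e-14, 1.0
        f_lo, _ = _charge_balance(lo, *args)
        f_hi, _ = _charge_balance(hi, *args)
        if f_lo * f_hi > 0:
            raise RuntimeError(
                "charge balance has no root in pH 0-14; state is unphysical")
        for _ in range(200):
            mid = np.sqrt(lo * hi)  # bisect in log space
            f_mid, _ = _charge_balance(mid, *args)
            if abs(f_mid) < 1e-13:
                break
            if f_lo * f_mid <= 0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
        h = mid

    f, _ = _charge_balance(h, *args)
    nh4 = s_in * h / (p.K_a_IN + h)
    hco3 = s_ic * p.K_a_co2 / (p.K_a_co2 + h)
    return IonSpeciation(
        S_H=h, pH=-np.log10(h),
        S_hco3=hco3, S_co2=s_ic - hco3,
        S_nh4=nh4, S_nh3=s_in - nh4,
        S_va_ion=s_va * p.K_a_va / (p.K_a_va + h),
        S_bu_ion=s_bu * p.K_a_bu / (p.K_a_bu + h),
        S_pro_ion=s_pro * p.K_a_pro / (p.K_a_pro + h),
        S_ac_ion=s_ac * p.K_a_ac / (p.K_a_ac + h),
        S_oh=p.K_w / h,
        residual=f,
    )


def _hill_inhibition(h: float, ph_ul: float, ph_ll: float) -> float:
    """Lower-pH-only Hill inhibition (BSM2 form), 1 above pH_UL."""
    k = 10.0 ** (-(ph_ul + ph_ll) / 2.0)
    n = 3.0 / (ph_ul - ph_ll)
    return k**n / (h**n + k**n)


# process order
PROCESS_NAMES = [
    "disintegration", "hydrolysis_ch", "hydrolysis_pr", "hydrolysis_li",
    "uptake_su", "uptake_aa", "uptake_fa", "uptake_va", "uptake_bu",
    "uptake_pro", "uptake_ac", "uptake_h2",
    "decay_X_su", "decay_X_aa", "decay_X_fa", "decay_X_c4", "decay_X_pro",
    "decay_X_ac", "decay_X_h2",
]
N_PROCESSES = len(PROCESS_NAMES)


def build_stoichiometry(params: ADM1Parameters,
                        partition: DisintegrationPartition | None = None,
                        f_sI: float = 0.0) -> np.ndarray:
    """Petersen matrix (19 processes x 26 liquid states).

    ``partition`` gives the composite disintegration split (feedstock
    f-factors); when omitted the BSM2 default composite split (with its
    soluble-inert fraction) is used. Inorganic C and N columns are closed per
    process so the matrix conserves COD, carbon and nitrogen exactly.
    """
    p = params
    if partition is None:
        f_ch, f_pr, f_li, f_xI = p.f_ch_xc, p.f_pr_xc, p.f_li_xc, p.f_xI_xc
        f_sI = p.f_sI_xc
    else:
        f_ch, f_pr = partition.f_Ch_xc, partition.f_P_xc
        f_li, f_xI = partition.f_L_xc, partition.f_I_xc
    total = f_ch + f_pr + f_li + f_xI + f_sI
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"disintegration fractions sum to {total}, not 1")

    nu = np.zeros((N_PROCESSES, N_LIQUID))
    ix = IDX

    def setp(proc, **coeffs):
        j = PROCESS_NAMES.index(proc)
        for name, v in coeffs.items():
            nu[j, ix[name]] = v

    setp("disintegration", X_c=-1.0, S_I=f_sI, X_ch=f_ch, X_pr=f_pr,
         X_li=f_li, X_I=f_xI)
    setp("hydrolysis_ch", X_ch=-1.0, S_su=1.0)
    setp("hydrolysis_pr", X_pr=-1.0, S_aa=1.0)
    setp("hydrolysis_li", X_li=-1.0, S_su=1.0 - p.f_fa_li, S_fa=p.f_fa_li)

    setp("uptake_su", S_su=-1.0,
         S_bu=(1 - p.Y_su) * p.f_bu_su, S_pro=(1 - p.Y_su) * p.f_pro_su,
         S_ac=(1 - p.Y_su) * p.f_ac_su, S_h2=(1 - p.Y_su) * p.f_h2_su,
         X_su=p.Y_su)
    setp("uptake_aa", S_aa=-1.0,
         S_va=(1 - p.Y_aa) * p.f_va_aa, S_bu=(1 - p.Y_aa) * p.f_bu_aa,
         S_pro=(1 - p.Y_aa) * p.f_pro_aa, S_ac=(1 - p.Y_aa) * p.f_ac_aa,
         S_h2=(1 - p.Y_aa) * p.f_h2_aa, X_aa=p.Y_aa)
    setp("uptake_fa", S_fa=-1.0, S_ac=(1 - p.Y_fa) * 0.7,
         S_h2=(1 - p.Y_fa) * 0.3, X_fa=p.Y_fa)
    setp("uptake_va", S_va=-1.0, S_pro=(1 - p.Y_c4) * 0.54,
         S_ac=(1 - p.Y_c4) * 0.31, S_h2=(1 - p.Y_c4) * 0.15, X_c4=p.Y_c4)
    setp("uptake_bu", S_bu=-1.0, S_ac=(1 - p.Y_c4) * 0.8,
         S_h2=(1 - p.Y_c4) * 0.2, X_c4=p.Y_c4)
    setp("uptake_pro", S_pro=-1.0, S_ac=(1 - p.Y_pro) * 0.57,
         S_h2=(1 - p.Y_pro) * 0.43, X_pro=p.Y_pro)
    setp("uptake_ac", S_ac=-1.0, S_ch4=1 - p.Y_ac, X_ac=p.Y_ac)
    setp("uptake_h2", S_h2=-1.0, S_ch4=1 - p.Y_h2, X_h2=p.Y_h2)

    for grp in ("su", "aa", "fa", "c4", "pro", "ac", "h2"):
        setp(f"decay_X_{grp}", **{f"X_{grp}": -1.0, "X_c": 1.0})

    # carbon / nitrogen contents per state (kmol per kgCOD, or per state unit)
    c_xc = (f_sI * p.C_sI + f_ch * p.C_ch + f_pr * p.C_pr
            + f_li * p.C_li + f_xI * p.C_xI)
    n_xc = f_pr * p.N_aa + (f_sI + f_xI) * p.N_I
    carbon = np.zeros(N_LIQUID)
    nitrogen = np.zeros(N_LIQUID)
    for name, c in (("S_su", p.C_su), ("S_aa", p.C_aa), ("S_fa", p.C_fa),
                    ("S_va", p.C_va), ("S_bu", p.C_bu), ("S_pro", p.C_pro),
                    ("S_ac", p.C_ac), ("S_ch4", p.C_ch4), ("S_I", p.C_sI),
                    ("X_c", c_xc), ("X_ch", p.C_ch), ("X_pr", p.C_pr),
                    ("X_li", p.C_li), ("X_I", p.C_xI)):
        carbon[ix[name]] = c
    for grp in ("su", "aa", "fa", "c4", "pro", "ac", "h2"):
        carbon[ix[f"X_{grp}"]] = p.C_bac
        nitrogen[ix[f"X_{grp}"]] = p.N_bac
    nitrogen[ix["S_aa"]] = p.N_aa
    nitrogen[ix["X_pr"]] = p.N_aa
    nitrogen[ix["S_I"]] = p.N_I
    nitrogen[ix["X_I"]] = p.N_I
    nitrogen[ix["X_c"]] = n_xc

    # close inorganic C and N per process
    nu[:, ix["S_IC"]] = -nu @ carbon
    nu[:, ix["S_IN"]] = -nu @ nitrogen
    return nu


class ADM1Model:
    """CSTR digester: wires an influent spec to the ADM1 kinetics.

    Parameters
    ----------
    influent : InfluentSpec
        Feed concentrations, disintegration partition and flow (m3/d).
    params : ADM1Parameters
    HRT : float
        Hydraulic retention time, d. Liquid volume = flow * HRT; headspace
        volume is ``params.headspace_fraction`` of the liquid volume.
    influent_S_IC, influent_S_cat, influent_S_an : float
        Inorganic carbon (kmol/m3) and strong-ion (kmoleq/m3) content of the
        feed; the cation/anion gap sets the feed alkalinity.
    """

    def __init__(self, influent: InfluentSpec, params: ADM1Parameters,
                 HRT: float = 30.0, *, influent_S_IC: float = 0.01,
                 influent_S_cat: float = 0.04, influent_S_an: float = 0.02):
        if HRT <= 0:
            raise ValueError("HRT must be > 0")
        self.influent = influent
        self.params = params
        self.HRT = HRT
        self.V_liq = influent.flow * HRT
        self.V_gas = params.headspace_fraction * self.V_liq
        self.k_p = params.pipe_resistance_per_m3 * self.V_liq
        self.nu = build_stoichiometry(params, influent.partition)
        self.feed = np.zeros(N_STATES)
        for name, val in (("S_su", influent.S_su), ("S_aa", influent.S_aa),
                          ("S_fa", influent.S_fa), ("S_I", influent.S_I),
                          ("X_c", influent.X_c), ("S_IN", influent.S_IN),
                          ("S_IC", influent_S_IC), ("S_cat", influent_S_cat),
                          ("S_an", influent_S_an)):
            self.feed[IDX[name]] = val
        self._h_last = 1e-7

    # -- kinetics ----------------------------------------------------------

    def process_rates(self, state: np.ndarray,
                      ions: IonSpeciation | None = None):
        """The 19 biochemical rates (kgCOD/m3/d) plus inhibition diagnostics."""
        p = self.params
        y = np.maximum(state, 0.0)
        if ions is None:
            ions = solve_ph(y, p, self._h_last)
            self._h_last = ions.S_H
        g = lambda n: y[IDX[n]]  # noqa: E731

        i_ph_aa = _hill_inhibition(ions.S_H, p.pH_UL_aa, p.pH_LL_aa)
        i_ph_ac = _hill_inhibition(ions.S_H, p.pH_UL_ac, p.pH_LL_ac)
        i_ph_h2 = _hill_inhibition(ions.S_H, p.pH_UL_h2, p.pH_LL_h2)
        i_in = g("S_IN") / (g("S_IN") + p.K_S_IN)
        i_h2_fa = 1.0 / (1.0 + g("S_h2") / p.K_I_h2_fa)
        i_h2_c4 = 1.0 / (1.0 + g("S_h2") / p.K_I_h2_c4)
        i_h2_pro = 1.0 / (1.0 + g("S_h2") / p.K_I_h2_pro)
        i_nh3 = 1.0 / (1.0 + ions.S_nh3 / p.K_I_nh3)

        monod = lambda s, k: s / (k + s) if s > 0 else 0.0  # noqa: E731
        c4_total = g("S_va") + g("S_bu")
        rho = np.array([
            p.k_dis * g("X_c"),
            p.k_hyd_ch * g("X_ch"),
            p.k_hyd_pr * g("X_pr"),
            p.k_hyd_li * g("X_li"),
            p.k_m_su * monod(g("S_su"), p.K_S_su) * g("X_su") * i_ph_aa * i_in,
            p.k_m_aa * monod(g("S_aa"), p.K_S_aa) * g("X_aa") * i_ph_aa * i_in,
            p.k_m_fa * monod(g("S_fa"), p.K_S_fa) * g("X_fa")
            * i_ph_aa * i_in * i_h2_fa,
            p.k_m_c4 * monod(g("S_va"), p.K_S_c4) * g("X_c4")
            * (g("S_va") / c4_total if c4_total > 0 else 0.0)
            * i_ph_aa * i_in * i_h2_c4,
            p.k_m_c4 * monod(g("S_bu"), p.K_S_c4) * g("X_c4")
            * (g("S_bu") / c4_total if c4_total > 0 else 0.0)
            * i_ph_aa * i_in * i_h2_c4,
            p.k_m_pro * monod(g("S_pro"), p.K_S_pro) * g("X_pro")
            * i_ph_aa * i_in * i_h2_pro,
            p.k_m_ac * monod(g("S_ac"), p.K_S_ac) * g("X_ac")
            * i_ph_ac * i_in * i_nh3,
            p.k_m_h2 * monod(g("S_h2"), p.K_S_h2) * g("X_h2")
            * i_ph_h2 * i_in,
            p.k_dec_su * g("X_su"), p.k_dec_aa * g("X_aa"),
            p.k_dec_fa * g("X_fa"), p.k_dec_c4 * g("X_c4"),
            p.k_dec_pro * g("X_pro"), p.k_dec_ac * g("X_ac"),
            p.k_dec_h2 * g("X_h2"),
        ])
        diagnostics = {
            "pH": ions.pH, "I_pH_aa": i_ph_aa, "I_pH_ac": i_ph_ac,
            "I_pH_h2": i_ph_h2, "I_IN": i_in, "I_h2_fa": i_h2_fa,
            "I_h2_c4": i_h2_c4, "I_h2_pro": i_h2_pro, "I_nh3": i_nh3,
        }
        return rho, diagnostics

    # -- gas phase ---------------------------------------------------------

    def gas_pressures(self, state: np.ndarray):
        """Partial pressures (bar), total headspace pressure, gas flow m3/d."""
        p = self.params
        rt = R_GAS * p.T_op
        p_h2 = max(state[IDX["S_gas_h2"]], 0.0) * rt / 16.0
        p_ch4 = max(state[IDX["S_gas_ch4"]], 0.0) * rt / 64.0
        p_co2 = max(state[IDX["S_gas_co2"]], 0.0) * rt
        p_tot = p_h2 + p_ch4 + p_co2 + p.p_h2o
        q_gas = max(self.k_p * (p_tot - p.P_atm) * p_tot / p.P_atm, 0.0)
        return p_h2, p_ch4, p_co2, p_tot, q_gas

    def transfer_rates(self, state: np.ndarray, ions: IonSpeciation):
        """Liquid-to-gas transfer (kgCOD or kmol /m3_liq/d) for H2, CH4, CO2."""
        p = self.params
        p_h2, p_ch4, p_co2, _, _ = self.gas_pressures(state)
        y = np.maximum(state, 0.0)
        rt_h2 = p.k_L_a * (y[IDX["S_h2"]] - 16.0 * p.K_H_h2 * p_h2)
        rt_ch4 = p.k_L_a * (y[IDX["S_ch4"]] - 64.0 * p.K_H_ch4 * p_ch4)
        rt_co2 = p.k_L_a * (ions.S_co2 - p.K_H_co2 * p_co2)
        return rt_h2, rt_ch4, rt_co2

    # -- mass balances -----------------------------------------------------

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        """Time derivatives of the 29 states (d^-1)."""
        y = np.maximum(state, 0.0)
        ions = solve_ph(y, self.params, self._h_last)
        self._h_last = ions.S_H
        rho, _ = self.process_rates(y, ions)
        rt_h2, rt_ch4, rt_co2 = self.transfer_rates(y, ions)
        _, _, _, _, q_gas = self.gas_pressures(y)

        dy = np.zeros(N_STATES)
        dy[:N_LIQUID] = (self.feed[:N_LIQUID] - y[:N_LIQUID]) / self.HRT
        dy[:N_LIQUID] += self.nu.T @ rho
        dy[IDX["S_h2"]] -= rt_h2
        dy[IDX["S_ch4"]] -= rt_ch4
        dy[IDX["S_IC"]] -= rt_co2

        vr = self.V_liq / self.V_gas
        dy[IDX["S_gas_h2"]] = -y[IDX["S_gas_h2"]] * q_gas / self.V_gas + rt_h2 * vr
        dy[IDX["S_gas_ch4"]] = -y[IDX["S_gas_ch4"]] * q_gas / self.V_gas + rt_ch4 * vr
        dy[IDX["S_gas_co2"]] = -y[IDX["S_gas_co2"]] * q_gas / self.V_gas + rt_co2 * vr
        return dy

    def default_initial_state(self, inoculum_fraction: float = 0.1) -> np.ndarray:
        """Generic feasible start: feed-derived substrate plus an inoculum.

        The biomass seed scales with the influent COD load
        (``inoculum_fraction`` of total influent COD, distributed over the
        seven groups weighted toward the slow-growing methanogens) — an
        acclimated-inoculum startup. Too small a seed lets acidogenesis
        outpace methanogenesis and sours the reactor, as in a real digester
        started without inoculum.
        """
        y0 = self.feed.copy()
        y0[IDX["X_c"]] *= 0.5
        cod_in = self.influent.total_cod
        weights = {"su": 0.12, "aa": 0.08, "fa": 0.08, "c4": 0.08,
                   "pro": 0.08, "ac": 0.36, "h2": 0.20}
        for grp, w in weights.items():
            y0[IDX[f"X_{grp}"]] = inoculum_fraction * cod_in * w
        y0[IDX["S_IC"]] = max(y0[IDX["S_IC"]], 0.1)
        y0[IDX["S_IN"]] = max(y0[IDX["S_IN"]], 0.05)
        p = self.params
        rt = R_GAS * p.T_op
        y0[IDX["S_gas_ch4"]] = 0.55 * (p.P_atm - p.p_h2o) / rt * 64.0
        y0[IDX["S_gas_co2"]] = 0.44 * (p.P_atm - p.p_h2o) / rt
        y0[IDX["S_gas_h2"]] = 0.01 * (p.P_atm - p.p_h2o) / rt * 16.0
        return y0
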