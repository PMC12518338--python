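"""Feedstock characterization: ThOD stoichiometry, COD fractionation,
f-factor closure and blending."""

import io
import math

import numpy as np
import pytest

from codigest import feedstock as fs


class TestThOD:
    @pytest.mark.parametrize("formula, expected", [
        (fs.PROTEIN_FORMULA, 1.42),
        (fs.LIPID_FORMULA, 2.90),
        (fs.CARBOHYDRATE_FORMULA, 1.19),
        (fs.LIGNIN_FORMULA, 1.56),
        (fs.ElementalFormula(C=1, H=4), 4.00),   # methane: 2 mol O2 / 16 g
    ])
    def test_reference_compounds(self, formula, expected):
        assert round(fs.thod_from_formula(formula), 2) == expected

    def test_over_oxygenated_formula_rejected(self):
        with pytest.raises(ValueError, match="over-oxygenated"):
            fs.thod_from_formula(fs.ElementalFormula(C=1, H=0, O=4))

    def test_iupac_masses_shift_second_decimal(self):
        masses = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}
        assert fs.thod_from_formula(fs.PROTEIN_FORMULA, masses) < 1.415

    def test_ordering_required_for_fraction_formulas(self):
        # lipid > lignin > protein > carbohydrate (2.90 > 1.56 > 1.42 > 1.19)
        t = fs.DEFAULT_THOD
        assert t.ThOD_L > t.ThOD_I > t.ThOD_P > t.ThOD_Ch


class TestCarbohydratePool:
    def test_reference_values(self, manure, prairie):
        assert fs.nfe_raw_fiber(manure) == pytest.approx(0.6774, abs=1e-4)
        assert fs.nfe_raw_fiber(prairie) == pytest.approx(0.7848, abs=1e-4)

    def test_boundary_zero(self):
        c = fs.FeedstockComposition("edge", TS=0.2, VS=0.5, R_L=0.2, R_F=0.0,
                                    R_P=0.3, NDF=0.0, ADF=0.0, ADL=0.0,
                                    D_VS=0.5)
        assert fs.nfe_raw_fiber(c) == 0.0

    def test_protein_lipid_exceeding_vs_rejected(self):
        with pytest.raises(fs.InvalidCompositionError):
            fs.FeedstockComposition("bad", TS=0.2, VS=0.4, R_L=0.3, R_F=0.1,
                                    R_P=0.2, NDF=0.1, ADF=0.05, ADL=0.02,
                                    D_VS=0.5)


class TestCompositeCOD:
    def test_prairie_printed_value(self, prairie):
        assert fs.composite_cod(prairie) == pytest.approx(1136.0, rel=0.005)

    def test_manure_pre_partition(self, manure):
        # direct arithmetic from the characterization table
        assert fs.composite_cod(manure) == pytest.approx(207.0, rel=0.005)

    def test_zero_feed(self, manure):
        import dataclasses
        dry = dataclasses.replace(manure, TS=0.0)
        assert fs.composite_cod(dry) == 0.0

    def test_strictly_increasing_in_ts(self, manure):
        import dataclasses
        vals = [fs.composite_cod(dataclasses.replace(manure, TS=t))
                for t in (0.05, 0.10, 0.18, 0.30)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rho_scaling(self, prairie):
        assert fs.composite_cod(prairie, rho=500.0) == pytest.approx(
            0.5 * fs.composite_cod(prairie))


class TestDegradationCoefficient:
    def test_reference_values(self, manure, prairie):
        assert fs.degradation_coefficient(manure) == pytest.approx(0.151, abs=0.001)
        assert fs.degradation_coefficient(prairie) == pytest.approx(0.165, abs=0.001)

    def test_zero_numerator(self):
        # D_VS chosen so VS (1 - D_VS) = NDF exactly
        c = fs.FeedstockComposition("z", TS=0.2, VS=0.8, R_L=0.05, R_F=0.3,
                                    R_P=0.05, NDF=0.4, ADF=0.2, ADL=0.1,
                                    D_VS=0.5)
        assert fs.degradation_coefficient(c) == pytest.approx(0.0, abs=1e-12)

    def test_ndf_equal_adl_rejected(self):
        c = fs.FeedstockComposition("flat", TS=0.2, VS=0.8, R_L=0.05,
                                    R_F=0.3, R_P=0.05, NDF=0.2, ADF=0.2,
                                    ADL=0.2, D_VS=0.5)
        with pytest.raises(ZeroDivisionError):
            fs.degradation_coefficient(c)

    def test_clamp_warns(self):
        c = fs.FeedstockComposition("hot", TS=0.2, VS=0.8, R_L=0.05, R_F=0.3,
                                    R_P=0.05, NDF=0.3, ADF=0.2, ADL=0.1,
                                    D_VS=0.9)  # implies d > 1
        with pytest.warns(UserWarning, match="clamped"):
            assert fs.degradation_coefficient(c) == 1.0


class TestDisintegrationPartition:
    def test_manure_protein_factor(self, manure):
        part = fs.disintegration_partition(manure)
        assert part.f_P_xc == pytest.approx(0.1374 / 0.8474, abs=1e-6)

    def test_closure_on_randomized_compositions(self, random_compositions):
        import warnings
        for comp in random_compositions:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                part = fs.disintegration_partition(comp)
            total = (part.f_Ch_xc + part.f_L_xc + part.f_P_xc + part.f_I_xc)
            assert abs(total - 1.0) < 1e-9

    def test_fully_degradable_fiber_limit(self, manure):
        part = fs.disintegration_partition(manure, d=1.0)
        assert part.f_I_xc == pytest.approx(manure.ADL / manure.VS)

    def test_starch_clamp_renormalizes(self):
        c = fs.FeedstockComposition("grassy", TS=0.9, VS=0.9, R_L=0.02,
                                    R_F=0.5, R_P=0.02, NDF=0.88, ADF=0.5,
                                    ADL=0.05, D_VS=0.3)
        with pytest.warns(UserWarning, match="starch"):
            part = fs.disintegration_partition(c)
        assert part.f_Ch_xc >= 0.0
        total = part.f_Ch_xc + part.f_L_xc + part.f_P_xc + part.f_I_xc
        assert total == pytest.approx(1.0, abs=1e-9)


class TestSolublePartition:
    def test_manure_printed_particulate(self, manure):
        xc = fs.composite_cod(manure)
        part = fs.disintegration_partition(manure)
        x_c, sol, _ = fs.soluble_partition(xc, fs.MANURE_SOLUBLES, part)
        assert x_c == pytest.approx(166.0, rel=0.005)
        assert fs.MANURE_SOLUBLES.total == pytest.approx(0.200)

    def test_cod_closure(self, manure):
        xc = fs.composite_cod(manure)
        part = fs.disintegration_partition(manure)
        x_c, sol, _ = fs.soluble_partition(xc, fs.MANURE_SOLUBLES, part)
        assert x_c + sum(sol.values()) == pytest.approx(xc, abs=1e-9)

    def test_zero_solubles_identity(self, prairie):
        xc = fs.composite_cod(prairie)
        part = fs.disintegration_partition(prairie)
        x_c, sol, part2 = fs.soluble_partition(xc, fs.SolubleFractions(), part)
        assert x_c == xc
        assert all(v == 0 for v in sol.values())
        assert part2.f_Ch_xc == part.f_Ch_xc

    def test_pool_overdraw_rejected(self, manure):
        xc = fs.composite_cod(manure)
        part = fs.disintegration_partition(manure)
        greedy = fs.SolubleFractions(S_su=0.5)  # > carbohydrate pool share
        with pytest.raises(ValueError, match="carbohydrate"):
            fs.soluble_partition(xc, greedy, part)

    def test_share_of_one_rejected_by_type(self):
        with pytest.raises(ValueError):
            fs.SolubleFractions(S_su=1.0)


class TestBlendInfluent:
    def test_manure_wet_flow(self, manure, prairie):
        # 1,000 kgVS/hr of manure alone
        wet = 1000.0 / (manure.TS * manure.VS)
        assert wet == pytest.approx(6560.0, rel=0.001)

    def test_mono_identity(self, manure, prairie):
        inf0 = fs.blend_influent(prairie, manure, 0.0)
        xc = fs.composite_cod(manure)
        part = fs.disintegration_partition(manure)
        x_c_exp, _, _ = fs.soluble_partition(xc, fs.MANURE_SOLUBLES, part)
        # concentration at reactor dilution: scale by TS ratio
        assert inf0.X_c == pytest.approx(x_c_exp * 0.10 / manure.TS, rel=1e-9)

    def test_blend_cod_conservation(self, manure, prairie):
        """50:50 influent COD load equals the sum of the pure streams'."""
        inf = fs.blend_influent(prairie, manure, 0.5)
        loads = []
        for comp, sol, share in ((prairie, fs.SolubleFractions(), 0.5),
                                 (manure, fs.MANURE_SOLUBLES, 0.5)):
            cod_per_ts = fs.composite_cod(comp) / (1000.0 * comp.TS)
            dry = share * 1000.0 / comp.VS
            loads.append(cod_per_ts * dry)
        total_load = sum(loads)  # kgCOD/hr
        assert inf.total_cod * inf.flow / 24.0 == pytest.approx(
            total_load, rel=1e-9)

    def test_partition_closure_after_blend(self, manure, prairie):
        inf = fs.blend_influent(prairie, manure, 0.3)
        p = inf.partition
        assert (p.f_Ch_xc + p.f_L_xc + p.f_P_xc + p.f_I_xc
                == pytest.approx(1.0, abs=1e-9))

    def test_ratio_bounds(self, manure, prairie):
        with pytest.raises(ValueError):
            fs.blend_influent(prairie, manure, 1.2)

    def test_blend_composition_strategy_runs(self, manure, prairie):
        inf = fs.blend_influent(prairie, manure, 0.5,
                                blend_strategy="blend-composition")
        assert inf.X_c > 0
        assert inf.flow > 0


class TestTableIO:
    def test_roundtrip(self, reference_feedstocks):
        buf = io.StringIO()
        fs.write_feedstock_table(reference_feedstocks, buf)
        buf.seek(0)
        back = fs.read_feedstock_table(buf)
        for name, comp in reference_feedstocks.items():
            assert back[name].NDF == pytest.approx(comp.NDF, abs=1e-12)
            assert back[name].D_VS == pytest.approx(comp.D_VS, abs=1e-12)

    def test_prairie_is_species_mean(self, reference_feedstocks):
        species = [reference_feedstocks[n]
                   for n in ("switchgrass", "indiangrass", "big_bluestem")]
        prairie = reference_feedstocks["prairie_biomass"]
        for attr in ("VS", "NDF", "ADF"):
            mean = sum(getattr(s, attr) for s in species) / 3.0
            assert getattr(prairie, attr) == pytest.approx(mean, abs=5e-4)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            fs.read_feedstock_table(io.StringIO("name,TS\nx,10\n"))
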