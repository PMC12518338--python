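"""Simulate manure mono-digestion in a 30-day mesophilic CSTR.

Builds the digester influent for 1,000 kgVS/hr of cattle manure diluted to
10% total solids, runs the ADM1 model to steady state (staged startup:
settled at 10% load, then load-stepped to 100%), and reports gas yields at
standard temperature and pressure.
"""

from codigest import feedstock as fs
from codigest.adm1 import ADM1Parameters, simulate_cstr, yield_report

comps = fs.load_reference_feedstocks()
prairie, manure = comps["prairie_biomass"], comps["cattle_manure"]

influent = fs.blend_influent(prairie, manure, vs_ratio_biomass=0.0,
                             total_vs_rate=1000.0)
print(f"influent: X_c {influent.X_c:.1f} kgCOD/m3, "
      f"solubles {influent.total_cod - influent.X_c:.1f} kgCOD/m3, "
      f"flow {influent.flow:.0f} m3/d")

result = simulate_cstr(influent, ADM1Parameters(), HRT=30.0)
yields = yield_report(result, vs_rate=24_000.0)  # 1,000 kgVS/hr

print(f"steady state reached: {result.is_steady}, digester pH {result.pH:.2f}")
print(f"CH4 yield   : {yields.ch4_yield:6.1f} mL/gVS (literature band for "
      "manure: 181-270)")
print(f"biogas yield: {yields.biogas_yield:6.1f} mL/gVS, "
      f"CH4 fraction {yields.ch4_fraction:.1%}")
print(f"free-ammonia inhibition of acetoclastic methanogens: "
      f"{result.diagnostics['I_nh3']:.2f} (1 = uninhibited)")
print("\nThe ammonia term is the binding inhibition for this nitrogen-rich "
      "feed; the pH sits in the methanogenic window without added alkali.")
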