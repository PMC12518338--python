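"""Split environmental responsibility between RNG and biochar.

Uses the packaged observed production rates for the two mono-digestion
scenarios and compares mass, energy and economic allocation. Mass allocation
burdens the heavy biochar stream; energy allocation favours RNG's 52.5 MJ/kg
over biochar's 22 MJ/kg; economic allocation follows revenue.
"""

from codigest import lca
from codigest.plant import load_production_rates

rates = load_production_rates().set_index("scenario")

for scen in ("B10:M0", "B0:M10"):
    biochar = rates.loc[scen, "biochar_kg_per_dry_tonne"]
    rng = rates.loc[scen, "rng_GJ_per_dry_tonne"]
    print(f"\n{scen}: {biochar:.0f} kg biochar and {rng:.1f} GJ RNG "
          "per dry tonne")
    for basis in ("mass", "energy", "economic"):
        shares = lca.allocation_shares(biochar, rng, basis,
                                       rng_price=45.0, biochar_price=150.0)
        print(f"  {basis:9s}: biochar {shares['biochar']:6.2f}%  "
              f"RNG {shares['rng']:6.2f}%")

total_gwp = 19.32  # un-expanded all-biomass GWP, kg CO2 eq./GJ
alloc = lca.allocate_impacts(total_gwp, {"biochar": 20.57, "rng": 79.43})
print(f"\neconomic allocation of a {total_gwp} kg CO2 eq./GJ total puts "
      f"{alloc['rng']:.2f} on the RNG and {alloc['biochar']:.2f} on the "
      "biochar (parts sum to the total).")
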