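"""Generate a synthetic study area and look at its structure.

Builds a Paris-like configuration: 20 spatial units and 9 monitoring
stations in 7 temporal-trend clusters, annual means for 2002-2012 plus a
hidden 1992-2001 pre-period, and a 5-year census mobility matrix.
"""

from cumulair import SimulationSpec, simulate_area

synth = simulate_area(SimulationSpec(rng_seed=1))
b = synth.bundle

print(f"units: {len(b.area.units)}, stations: {len(b.stations)}")
print(f"modelled years: {b.field.years[0]}-{b.field.years[-1]}")
print(f"hidden pre-period: {synth.truth.hidden_field.years[0]}-"
      f"{synth.truth.hidden_field.years[-1]}")

f = b.field.values
print(f"\ncity annual mean 2002: {f[2002].mean():.1f} µg/m³ "
      f"(range {f[2002].min():.1f}-{f[2002].max():.1f})")
print(f"city annual mean 2012: {f[2012].mean():.1f} µg/m³ "
      f"(range {f[2012].min():.1f}-{f[2012].max():.1f})")

deg = b.mobility.degree_of_mobility()
print(f"\ndegree of mobility: mean {deg.mean():.1f} %, "
      f"range {deg.min():.1f}-{deg.max():.1f} %")
print("(share of current residents who lived elsewhere one census "
      "period earlier)")
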