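"""Why islands depress ProtConn but not ProtConn_Bound.

A country of two equal islands protects 10% of its land on each island.
Coverage is 20%, but the sea stops any movement between the two PAs, so
the connected protected land is only 100 * a * sqrt(2) / A_L = 14.1%.
The partition attributes the whole 5.9-point loss to the sea — isolation
the country cannot act on — so ProtConn_Bound stays at 20% and the
country is not penalised for its geography.
"""

from protconn import (
    CountryContext,
    compute_indicators,
    preprocess_country,
    preset_scenario,
)
from protconn.geometry import country_land_area

scenario = preset_scenario("two_islands", seed=0)
nodes, distances = preprocess_country(scenario.pa_sites, scenario.land, "AAA")
context = CountryContext("AAA", country_land_area(scenario.land, "AAA"))
ind = compute_indicators([n.to_pa_node() for n in nodes], distances, context,
                         d_med=10.0)

print(f"Prot              = {ind.prot:5.1f} %   (PA coverage)")
print(f"ProtConn          = {ind.protconn:5.1f} %   (protected AND connected)")
print(f"ProtUnconn[Sea]   = {ind.protunconn_sea:5.1f} %   (lost to the sea)")
print(f"ProtUnconn[Outland]= {ind.protunconn_outland:4.1f} %")
print(f"ProtUnconn[Design]= {ind.protunconn_design:5.1f} %")
print(f"ProtConn_Bound    = {ind.protconn_bound:5.1f} %   "
      "(connectivity the country can influence)")
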