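"""Foreign protected areas as stepping stones across foreign land.

A foreign strip splits the focal country into two portions; its two PAs
cannot be linked directly across unprotected foreign territory, so the
isolation is attributed to ProtUnconn[Outland].  Designating a PA inside
the foreign strip creates an admissible two-hop route: ProtConn rises and
part of the connected land is credited to the transboundary fraction.
"""

from protconn import (
    CountryContext,
    compute_indicators,
    generate_scenario,
    preprocess_country,
)
from protconn.geometry import country_land_area
from protconn.synthetic import PRESETS, PAPlacement
import dataclasses

spec = PRESETS["enclave"](seed=0)

for label, placements in [
    ("no foreign PA", spec.placements),
    ("foreign stepping stone",
     spec.placements + (PAPlacement("BBB", 0, 900.0, (150, 50)),)),
]:
    variant = dataclasses.replace(spec, placements=placements, truth=None)
    scenario = generate_scenario(variant)
    nodes, distances = preprocess_country(scenario.pa_sites, scenario.land, "AAA")
    context = CountryContext("AAA", country_land_area(scenario.land, "AAA"))
    ind = compute_indicators([n.to_pa_node() for n in nodes], distances,
                             context, d_med=100.0)
    print(f"{label}:")
    print(f"  ProtConn = {ind.protconn:.2f} %   "
          f"ProtUnconn[Outland] = {ind.protunconn_outland:.2f} %   "
          f"ProtConn[Trans] = {ind.protconn_trans:.1f} % of ProtConn")
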