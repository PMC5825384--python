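import math

import pytest

from protconn import (
    CountryContext,
    assemble_indicator_set,
    compute_indicators,
    preprocess_country,
    preset_scenario,
)
from protconn.geometry import country_land_area


@pytest.fixture(params=["single_pa", "two_islands", "enclave"])
def preset_name(request):
    return request.param


def run_scenario(scenario, iso3="AAA", d_med=10.0, contiguity_tol_km=0.0):
    """Full geometry -> network -> indicators chain for one scenario."""
    nodes, distances = preprocess_country(scenario.pa_sites, scenario.land, iso3)
    context = CountryContext(iso3, country_land_area(scenario.land, iso3))
    pa_nodes = [n.to_pa_node() for n in nodes]
    return compute_indicators(
        pa_nodes, distances, context, d_med, contiguity_tol_km=contiguity_tol_km
    )


def make_indicator_set(
    iso3,
    prot,
    design=0.0,
    sea=0.0,
    outland=0.0,
    within=100.0,
    contig=0.0,
    unprot=0.0,
    trans=0.0,
    d_med=10.0,
):
    """Consistent indicator set from the free components (ProtConn derived)."""
    protconn_value = prot - sea - outland - design
    return assemble_indicator_set(
        iso3=iso3, d_med=d_med, protconn_value=protconn_value,
        sea=sea, outland=outland, design=design,
        within=within, contig=contig, unprot=unprot, trans=trans,
        no_connected_land=protconn_value <= 0,
    )
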