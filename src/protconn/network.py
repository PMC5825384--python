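"""Probabilistic protected-area graph: dispersal kernel, admissible links,
maximum-product paths and the Equivalent Connected Area (ECA).

The network model treats each terrestrial protected area (PA) as a node.
A negative-exponential dispersal kernel converts the edge-to-edge distance
between two PAs into a direct dispersal probability ``p_ij``, calibrated so
that ``p = 0.5`` at the median dispersal distance ``d_med``.  The best
multi-step route between two nodes is the path maximising the product of
link probabilities (``p*_ij``), found as a shortest path on ``-ln p``
weights.  ECA is the size of the single PA that would provide the same
probability-weighted reachable area as the whole network:

    ECA = sqrt( sum_ij a_i * a_j * p*_ij )

where the attribute ``a`` is the PA area for nodes of the focal country and
0 for transboundary nodes (foreign PAs count as stepping stones, never as
protected area of the country).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "KernelParams",
    "LinkScenario",
    "PANode",
    "PANetwork",
    "kernel_probability",
    "admissible_links",
    "build_network",
    "max_product_paths",
    "equivalent_connected_area",
    "pair_key",
]

#: direct-dispersal probabilities below this are pruned before path search;
#: corresponds to a gap of about 20 * d_med, far beyond any plausible route.
PRUNE_PROBABILITY = 1e-6

LN_HALF = math.log(0.5)


@dataclass(frozen=True)
class KernelParams:
    """Negative-exponential dispersal kernel, parameterised by the median
    dispersal distance ``d_med`` (km): p(d_med) = 0.5."""

    d_med: float

    def __post_init__(self) -> None:
        if self.d_med <= 0:
            raise ValueError(f"d_med must be positive, got {self.d_med}")


class LinkScenario(str, Enum):
    """Nested link classes used to decompose ProtConn into its fractions.

    WITHIN   -- no inter-PA links (movement inside single PAs only)
    CONTIG   -- only links between contiguous PAs of the focal country
    COUNTRY  -- all links between focal-country PAs (through unprotected
                national land)
    FULL     -- COUNTRY plus links involving transboundary (foreign) PAs
    """

    WITHIN = "WITHIN"
    CONTIG = "CONTIG"
    COUNTRY = "COUNTRY"
    FULL = "FULL"


@dataclass(frozen=True)
class PANode:
    """Graph abstraction of one dissolved terrestrial PA polygon.

    ``area`` is the equal-area (or planar) polygon area in km².  The node
    attribute used in ECA sums is ``area`` for focal-country nodes and 0 for
    transboundary nodes.  ``portion_id`` identifies the contiguous land
    portion of the node's country; ``landmass_id`` the connected component
    of all land.  A portion never spans two landmasses.
    """

    node_id: str
    area: float
    iso3: str
    portion_id: str
    landmass_id: str
    is_transboundary: bool = False

    @property
    def attribute(self) -> float:
        return 0.0 if self.is_transboundary else self.area


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered node pair."""
    return (a, b) if a <= b else (b, a)


def kernel_probability(distance_km: float, params: KernelParams) -> float:
    """Direct dispersal probability at a given edge-to-edge distance.

    p(d) = 0.5 ** (d / d_med): 1 at contact, 0.5 at the median dispersal
    distance, strictly decreasing beyond.
    """
    if distance_km < 0:
        raise ValueError(f"distance must be non-negative, got {distance_km}")
    return math.exp(distance_km * LN_HALF / params.d_med)


def _pair_admissible(i: PANode, j: PANode) -> bool:
    # sea is an absolute barrier to terrestrial movement
    if i.landmass_id != j.landmass_id:
        return False
    # foreign protected nodes may bridge portions; direct focal-focal links
    # across unprotected foreign land are barred
    if i.is_transboundary or j.is_transboundary:
        return True
    return i.portion_id == j.portion_id


def admissible_links(
    nodes: Iterable[PANode],
    distances: Mapping[tuple[str, str], float],
    scenario: LinkScenario | str,
    params: KernelParams,
    contiguity_tol_km: float = 0.0,
    prune_probability: float = PRUNE_PROBABILITY,
) -> dict[tuple[str, str], float]:
    """Compute the admissible link set with direct probabilities p_ij.

    A link i-j is admissible iff (a) i and j share a landmass, (b) they
    share a portion or at least one endpoint is transboundary, and (c) the
    scenario admits the link class (see :class:`LinkScenario`).  Links with
    p below ``prune_probability`` are dropped; the error this induces on any
    indicator is orders of magnitude below reporting precision.
    """
    scenario = LinkScenario(scenario)
    node_list = sorted(nodes, key=lambda n: n.node_id)
    links: dict[tuple[str, str], float] = {}
    if scenario is LinkScenario.WITHIN:
        return links
    for idx, i in enumerate(node_list):
        for j in node_list[idx + 1:]:
            if not _pair_admissible(i, j):
                continue
            involves_trans = i.is_transboundary or j.is_transboundary
            if involves_trans and scenario is not LinkScenario.FULL:
                continue
            key = pair_key(i.node_id, j.node_id)
            try:
                d = distances[key]
            except KeyError:
                raise KeyError(f"no distance for admissible pair {key}") from None
            if scenario is LinkScenario.CONTIG and d > contiguity_tol_km:
                continue
            p = kernel_probability(d, params)
            if p >= prune_probability:
                links[key] = p
    return links


@dataclass
class PANetwork:
    """A PA node set plus its admissible links for one scenario."""

    nodes: list[PANode]
    links: dict[tuple[str, str], float]
    scenario: LinkScenario
    params: KernelParams
    _pstar: dict[tuple[str, str], float] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_focal(self) -> int:
        return sum(1 for n in self.nodes if not n.is_transboundary)

    @property
    def n_transboundary(self) -> int:
        return sum(1 for n in self.nodes if n.is_transboundary)


def build_network(
    nodes: Iterable[PANode],
    distances: Mapping[tuple[str, str], float],
    params: KernelParams,
    scenario: LinkScenario | str = LinkScenario.FULL,
    contiguity_tol_km: float = 0.0,
) -> PANetwork:
    node_list = sorted(nodes, key=lambda n: n.node_id)
    links = admissible_links(
        node_list, distances, scenario, params, contiguity_tol_km
    )
    return PANetwork(node_list, links, LinkScenario(scenario), params)


def max_product_paths(network: PANetwork) -> dict[tuple[str, str], float]:
    """Maximum-product path probabilities p*_ij for every node pair.

    Computed exactly as shortest paths on -ln(p) link weights (Dijkstra).
    p*_ii = 1; p*_ij = 0 for pairs with no connecting path (a valid
    outcome, e.g. PAs on different islands).  Only pairs with p* > 0 are
    stored; the diagonal is implicit.
    """
    if network._pstar is not None:
        return network._pstar
    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in network.nodes)
    for (u, v), p in network.links.items():
        g.add_edge(u, v, weight=-math.log(p))
    pstar: dict[tuple[str, str], float] = {}
    ids = sorted(g.nodes)
    for u in ids:
        lengths = nx.single_source_dijkstra_path_length(g, u)
        for v, w in lengths.items():
            if v <= u:
                continue
            pstar[(u, v)] = math.exp(-w)
    network._pstar = pstar
    return pstar


def equivalent_connected_area(network: PANetwork) -> float:
    """ECA (km²) of the network: sqrt of the attribute-weighted double sum
    over all node pairs, the i = j terms included (intra-PA connectivity).

    Transboundary nodes carry attribute 0, so they shape the sum only
    through the p* routes they enable.  ECA lies between
    sqrt(sum a_i²) (all PAs isolated) and sum a_i (all fully connected).
    """
    attrs = {n.node_id: n.attribute for n in network.nodes}
    total = sum(a * a for a in attrs.values())
    pstar = max_product_paths(network)
    for (u, v), p in pstar.items():
        au = attrs[u]
        av = attrs[v]
        if au and av:
            total += 2.0 * au * av * p
    return math.sqrt(total)
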