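"""The Protected Connected (ProtConn) indicator family for one country.

All headline indicators are percentages of the country land area A_L:

* ``Prot``            -- PA coverage, 100 * sum(a_i) / A_L
* ``ProtConn``        -- protected AND connected land, 100 * ECA / A_L
* ``ProtUnconn``      -- Prot - ProtConn, partitioned by cause of isolation
  into ``Sea`` (islands/landmasses separated by sea), ``Outland`` (portions
  of the country separated by unprotected foreign land) and ``Design``
  (shortcomings of the PA system itself);
* ``ProtConn_Bound``  -- Prot - ProtUnconn[Design]: connectivity bounded to
  what the country can influence, i.e. not penalising isolation by sea or
  foreign territory.

The partition is computed by telescoping three nested connectivity levels:

    sum over portions g of ECA_g    -> ProtConn_Bound  (sea and foreign-land
                                       barriers both forgiven)
    sum over landmasses m of ECA_m  -> intermediate level (sea forgiven
                                       between landmasses, foreign land not)
    ECA of the whole network        -> ProtConn

so Design = Prot - Bound, Outland = Bound - LM-level, Sea = LM-level -
ProtConn, and the three terms sum to ProtUnconn exactly.  Each per-portion
subnetwork keeps the transboundary nodes of its landmass, so foreign
stepping stones still count toward ProtConn_Bound.

The four ProtConn fractions (Within / Contig / Unprot / Trans) are shares
of ProtConn obtained from the nested link scenarios of
:class:`~protconn.network.LinkScenario`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .network import (
    KernelParams,
    LinkScenario,
    PANetwork,
    PANode,
    build_network,
    equivalent_connected_area,
)

__all__ = [
    "CountryContext",
    "IndicatorSet",
    "prot",
    "protconn",
    "protconn_fractions",
    "protunconn_partition",
    "compute_indicators",
    "assemble_indicator_set",
]

#: identities are enforced to this absolute tolerance (percentage points)
IDENTITY_TOL = 1e-9


@dataclass(frozen=True)
class CountryContext:
    """Country-level constants needed by the indicators.

    ``area_km2`` is the country land area A_L (disputed territories
    excluded).  ``region``/``continent`` feed the aggregation stage.
    """

    iso3: str
    area_km2: float
    region: str | None = None
    continent: str | None = None

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"country land area must be positive for {self.iso3}")


@dataclass
class IndicatorSet:
    """All ProtConn-related indicators for one (country, d_med) pair.

    Percent-of-country indicators: prot, protconn, protconn_bound,
    protunconn and its three cause fractions.  The four protconn_*
    movement fractions are percent of the ProtConn value and sum to 100
    whenever protconn > 0 (``no_connected_land`` flags the degenerate
    case, where they are reported as 0).
    """

    iso3: str
    d_med: float
    prot: float
    protconn: float
    protconn_bound: float
    protunconn: float
    protunconn_sea: float
    protunconn_outland: float
    protunconn_design: float
    protconn_within: float
    protconn_contig: float
    protconn_unprot: float
    protconn_trans: float
    no_connected_land: bool = False

    COLUMNS = (
        "iso3", "d_med", "prot", "protconn", "protconn_bound", "protunconn",
        "protunconn_sea", "protunconn_outland", "protunconn_design",
        "protconn_within", "protconn_contig", "protconn_unprot",
        "protconn_trans", "no_connected_land",
    )

    def validate(self, tol: float = 1e-6) -> None:
        """Check every internal identity; raise naming the failing one."""
        checks = {
            "Prot = ProtConn + ProtUnconn":
                abs(self.prot - (self.protconn + self.protunconn)),
            "ProtUnconn = Sea + Outland + Design":
                abs(self.protunconn - (self.protunconn_sea
                                       + self.protunconn_outland
                                       + self.protunconn_design)),
            "ProtConn_Bound = Prot - Design":
                abs(self.protconn_bound - (self.prot - self.protunconn_design)),
        }
        for name, err in checks.items():
            if err > tol:
                raise ValueError(f"indicator identity violated: {name} (err={err:g})")
        if not (self.protconn - tol <= self.protconn_bound <= self.prot + tol):
            raise ValueError(
                "indicator identity violated: ProtConn <= ProtConn_Bound <= Prot"
            )
        for name in ("prot", "protconn", "protconn_bound", "protunconn",
                     "protunconn_sea", "protunconn_outland", "protunconn_design",
                     "protconn_within", "protconn_contig", "protconn_unprot",
                     "protconn_trans"):
            if getattr(self, name) < -tol:
                raise ValueError(f"indicator identity violated: {name} >= 0")
        frac_sum = (self.protconn_within + self.protconn_contig
                    + self.protconn_unprot + self.protconn_trans)
        if self.no_connected_land:
            if frac_sum > tol:
                raise ValueError(
                    "indicator identity violated: fractions 0 when ProtConn = 0"
                )
        elif abs(frac_sum - 100.0) > max(tol, 1e-6):
            raise ValueError(
                f"indicator identity violated: ProtConn fractions sum to 100 "
                f"(got {frac_sum!r})"
            )

    def as_dict(self) -> dict:
        return asdict(self)


def prot(nodes: list[PANode], context: CountryContext) -> float:
    """PA coverage: percent of the country covered by (focal) PAs."""
    return 100.0 * sum(n.attribute for n in nodes) / context.area_km2


def protconn(network: PANetwork, context: CountryContext) -> float:
    """Percent of the country that is protected and connected (FULL links)."""
    return 100.0 * equivalent_connected_area(network) / context.area_km2


def protconn_fractions(
    networks: dict[LinkScenario, PANetwork], context: CountryContext
) -> tuple[float, float, float, float, bool]:
    """Split ProtConn into Within / Contig / Unprot / Trans shares.

    Uses the four nested scenarios: with P_k = 100 * ECA_k / A_L for
    k = WITHIN, CONTIG, COUNTRY, FULL, the fractions are the successive
    increments normalised by P_FULL (so they sum to 100).  Returns the
    four fractions plus a flag for the ProtConn = 0 degenerate case.
    """
    p = {
        s: 100.0 * equivalent_connected_area(networks[s]) / context.area_km2
        for s in LinkScenario
    }
    p4 = p[LinkScenario.FULL]
    if p4 <= 0.0:
        return 0.0, 0.0, 0.0, 0.0, True
    within = 100.0 * p[LinkScenario.WITHIN] / p4
    contig = 100.0 * (p[LinkScenario.CONTIG] - p[LinkScenario.WITHIN]) / p4
    unprot = 100.0 * (p[LinkScenario.COUNTRY] - p[LinkScenario.CONTIG]) / p4
    trans = 100.0 * (p4 - p[LinkScenario.COUNTRY]) / p4
    return within, contig, unprot, trans, False


def _restrict(distances, node_ids):
    ids = set(node_ids)
    return {k: v for k, v in distances.items() if k[0] in ids and k[1] in ids}


def _group_eca_sum(
    groups: dict[str, list[PANode]],
    trans_by_landmass: dict[str, list[PANode]],
    group_landmass: dict[str, str],
    distances,
    params: KernelParams,
) -> float:
    """Sum of ECAs of the subnetworks induced by each group's focal nodes
    plus the transboundary nodes of the group's landmass (FULL links)."""
    total = 0.0
    for gid in sorted(groups):
        sub = list(groups[gid]) + trans_by_landmass.get(group_landmass[gid], [])
        net = build_network(
            sub, _restrict(distances, [n.node_id for n in sub]),
            params, LinkScenario.FULL,
        )
        total += equivalent_connected_area(net)
    return total


def protunconn_partition(
    nodes: list[PANode],
    distances,
    params: KernelParams,
    context: CountryContext,
    protconn_value: float | None = None,
) -> tuple[float, float, float, float]:
    """Partition ProtUnconn by cause; returns (Sea, Outland, Design, Bound).

    Sea + Outland + Design telescopes to Prot - ProtConn exactly.  A
    negative component beyond rounding noise means an admissibility rule
    was violated upstream and is raised as an error.
    """
    focal = [n for n in nodes if not n.is_transboundary]
    trans_by_lm: dict[str, list[PANode]] = {}
    for n in nodes:
        if n.is_transboundary:
            trans_by_lm.setdefault(n.landmass_id, []).append(n)

    portions: dict[str, list[PANode]] = {}
    portion_lm: dict[str, str] = {}
    landmasses: dict[str, list[PANode]] = {}
    for n in focal:
        portions.setdefault(n.portion_id, []).append(n)
        portion_lm[n.portion_id] = n.landmass_id
        landmasses.setdefault(n.landmass_id, []).append(n)

    prot_value = prot(nodes, context)
    if protconn_value is None:
        full = build_network(nodes, distances, params, LinkScenario.FULL)
        protconn_value = protconn(full, context)

    bound = 100.0 * _group_eca_sum(
        portions, trans_by_lm, portion_lm, distances, params
    ) / context.area_km2
    lm_level = 100.0 * _group_eca_sum(
        landmasses, trans_by_lm, {m: m for m in landmasses}, distances, params
    ) / context.area_km2

    sea = lm_level - protconn_value
    outland = bound - lm_level
    design = prot_value - bound
    parts = {"Sea": sea, "Outland": outland, "Design": design}
    for name, val in parts.items():
        if val < -1e-9:
            raise ValueError(
                f"ProtUnconn[{name}] = {val:g} < 0: admissibility rules violated"
            )
        parts[name] = max(val, 0.0)
    return parts["Sea"], parts["Outland"], parts["Design"], bound


def compute_indicators(
    nodes: list[PANode],
    distances,
    context: CountryContext,
    d_med: float,
    contiguity_tol_km: float = 0.0,
) -> IndicatorSet:
    """Full indicator set for one country at one median dispersal distance."""
    params = KernelParams(d_med)
    networks = {
        s: build_network(nodes, distances, params, s, contiguity_tol_km)
        for s in LinkScenario
    }
    prot_value = prot(nodes, context)
    pc = protconn(networks[LinkScenario.FULL], context)
    within, contig, unprot, trans, flag = protconn_fractions(networks, context)
    sea, outland, design, bound = protunconn_partition(
        nodes, distances, params, context, protconn_value=pc
    )
    return assemble_indicator_set(
        iso3=context.iso3, d_med=d_med, prot_value=prot_value,
        protconn_value=pc, bound=bound, sea=sea, outland=outland,
        design=design, within=within, contig=contig, unprot=unprot,
        trans=trans, no_connected_land=flag,
    )


def assemble_indicator_set(
    iso3: str,
    d_med: float,
    protconn_value: float,
    sea: float,
    outland: float,
    design: float,
    within: float,
    contig: float,
    unprot: float,
    trans: float,
    prot_value: float | None = None,
    bound: float | None = None,
    no_connected_land: bool = False,
) -> IndicatorSet:
    """Assemble and validate an :class:`IndicatorSet` from its components.

    Components omitted are recovered from the defining identities: Prot as
    ProtConn + Sea + Outland + Design, and ProtConn_Bound as Prot -
    ProtUnconn[Design].  All internal identities are checked before the
    set is returned.
    """
    if prot_value is None:
        prot_value = protconn_value + sea + outland + design
    if bound is None:
        bound = prot_value - design
    ind = IndicatorSet(
        iso3=iso3,
        d_med=d_med,
        prot=prot_value,
        protconn=protconn_value,
        protconn_bound=bound,
        protunconn=prot_value - protconn_value,
        protunconn_sea=sea,
        protunconn_outland=outland,
        protunconn_design=design,
        protconn_within=within,
        protconn_contig=contig,
        protconn_unprot=unprot,
        protconn_trans=trans,
        no_connected_land=no_connected_land,
    )
    ind.validate()
    return ind
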