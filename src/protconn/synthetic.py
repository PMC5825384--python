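"""Synthetic multi-landmass, multi-country PA systems with known
ground-truth indicator values.

Worlds are built on a flat plane with kilometre coordinates (areas in km²
come straight from polygon area, distances from boundary distance), which
isolates the indicator mathematics from any projection concern.  A world
consists of rectangular landmasses, each partitioned into vertical
territory strips assigned to countries (an enclave arises when a foreign
strip splits a country into two portions), plus square or disc PAs placed
either explicitly or by a seeded rejection-sampling rule that keeps PAs of
the same country disjoint.

Three closed-form presets carry exact analytic truth values, exercising
each barrier type in isolation:

``single_pa``    one country, one landmass, a single PA covering 17% of
                 the land: Prot = ProtConn = ProtConn_Bound = 17.
``two_islands``  one country on two equal islands, one PA per island each
                 covering 10% of the country: sea is the only barrier, so
                 ProtConn = 100*a*sqrt(2)/A_L and
                 ProtUnconn[Sea] = Prot - ProtConn.
``enclave``      a foreign strip with no PAs splits the country in two
                 portions on one landmass: foreign land is the only
                 barrier, ProtUnconn[Outland] = Prot - ProtConn, Sea = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, box

from .geometry import LandFeature, RawPASite
from .indicators import IndicatorSet, assemble_indicator_set

__all__ = [
    "Landmass",
    "Territory",
    "PAPlacement",
    "RandomPARule",
    "ScenarioSpec",
    "Scenario",
    "generate_scenario",
    "preset_scenario",
    "random_country_scenario",
    "PRESETS",
]


@dataclass(frozen=True)
class Landmass:
    """Axis-aligned rectangular island/continent; km coordinates."""

    x0: float
    y0: float
    width: float
    height: float

    @property
    def geometry(self):
        return box(self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)


@dataclass(frozen=True)
class Territory:
    """A vertical strip [x_min, x_max] of one landmass owned by a country."""

    iso3: str
    landmass: int
    x_min: float
    x_max: float
    disputed: bool = False


@dataclass(frozen=True)
class PAPlacement:
    """Explicit PA placement: square or disc of given area at a centroid."""

    iso3: str
    landmass: int
    area_km2: float
    centroid: tuple[float, float]
    shape: str = "square"          # "square" | "disc" | "point"
    status: str = "Designated"
    designation_type: str = ""


@dataclass(frozen=True)
class RandomPARule:
    """Seeded stochastic placement of disjoint square PAs in one country."""

    iso3: str
    count: int
    area_range: tuple[float, float] = (5.0, 100.0)
    max_tries: int = 200


@dataclass(frozen=True)
class ScenarioSpec:
    seed: int
    landmasses: tuple[Landmass, ...]
    territories: tuple[Territory, ...]
    placements: tuple[PAPlacement, ...] = ()
    random_rules: tuple[RandomPARule, ...] = ()
    truth: IndicatorSet | None = None

    def validate(self) -> None:
        for t in self.territories:
            lm = self.landmasses[t.landmass]
            if not (lm.x0 - 1e-9 <= t.x_min < t.x_max <= lm.x0 + lm.width + 1e-9):
                raise ValueError(f"territory {t} outside its landmass")
        for i, t in enumerate(self.territories):
            for u in self.territories[i + 1:]:
                if t.landmass == u.landmass and \
                        t.x_min < u.x_max and u.x_min < t.x_max:
                    raise ValueError(
                        f"overlapping territories on landmass {t.landmass}: {t}, {u}"
                    )
        for p in self.placements:
            lm = self.landmasses[p.landmass]
            if p.area_km2 <= 0:
                raise ValueError(f"non-positive PA area in {p}")
            if p.area_km2 > lm.width * lm.height:
                raise ValueError(f"PA larger than its landmass: {p}")


@dataclass
class Scenario:
    """Generated layers: PA sites + land features (planar km), with the
    analytically known indicator truth for closed-form presets."""

    pa_sites: list[RawPASite]
    land: list[LandFeature]
    truth: IndicatorSet | None = None
    planar: bool = True


def _placement_geometry(p: PAPlacement):
    cx, cy = p.centroid
    if p.shape == "square":
        half = math.sqrt(p.area_km2) / 2.0
        return box(cx - half, cy - half, cx + half, cy + half)
    if p.shape == "disc":
        r = math.sqrt(p.area_km2 / math.pi)
        return Point(cx, cy).buffer(r, quad_segs=256)
    if p.shape == "point":
        return Point(cx, cy)
    raise ValueError(f"unknown PA shape {p.shape!r}")


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Realise a scenario spec into PA and land layers.

    The seed fully determines stochastic placements; rejection sampling
    keeps random PAs of one country pairwise disjoint and strictly inside
    a single territory of that country.
    """
    spec.validate()
    land = [
        LandFeature(
            geometry=box(
                t.x_min,
                spec.landmasses[t.landmass].y0,
                t.x_max,
                spec.landmasses[t.landmass].y0 + spec.landmasses[t.landmass].height,
            ),
            iso3=t.iso3,
            disputed=t.disputed,
        )
        for t in spec.territories
    ]

    sites: list[RawPASite] = []
    for k, p in enumerate(spec.placements):
        geom = _placement_geometry(p)
        sites.append(
            RawPASite(
                site_id=f"{p.iso3}-S{k:03d}",
                geometry=geom,
                iso3=p.iso3,
                status=p.status,
                designation_type=p.designation_type,
                reported_area_km2=p.area_km2,
            )
        )

    rng = np.random.default_rng(spec.seed)
    for rule in spec.random_rules:
        terrs = [t for t in spec.territories if t.iso3 == rule.iso3 and not t.disputed]
        if not terrs:
            raise ValueError(f"no territory for random rule country {rule.iso3}")
        placed = []
        for k in range(rule.count):
            geom = None
            for _ in range(rule.max_tries):
                t = terrs[int(rng.integers(len(terrs)))]
                lm = spec.landmasses[t.landmass]
                area = float(rng.uniform(*rule.area_range))
                half = math.sqrt(area) / 2.0
                if t.x_max - t.x_min <= 2 * half or lm.height <= 2 * half:
                    continue
                cx = float(rng.uniform(t.x_min + half, t.x_max - half))
                cy = float(rng.uniform(lm.y0 + half, lm.y0 + lm.height - half))
                cand = box(cx - half, cy - half, cx + half, cy + half)
                if all(not cand.intersects(g) for g in placed):
                    geom = cand
                    break
            if geom is None:
                continue  # crowded territory: place fewer PAs
            placed.append(geom)
            sites.append(
                RawPASite(
                    site_id=f"{rule.iso3}-R{len(placed):03d}",
                    geometry=geom,
                    iso3=rule.iso3,
                    reported_area_km2=geom.area,
                )
            )
    return Scenario(pa_sites=sites, land=land, truth=spec.truth)


# ---------------------------------------------------------------------------
# closed-form presets


def _single_pa_spec(seed: int) -> ScenarioSpec:
    lm = Landmass(0, 0, 100, 100)
    a, A = 1700.0, 10000.0
    truth = assemble_indicator_set(
        iso3="AAA", d_med=10.0,
        protconn_value=100 * a / A, sea=0.0, outland=0.0, design=0.0,
        within=100.0, contig=0.0, unprot=0.0, trans=0.0,
    )
    return ScenarioSpec(
        seed=seed,
        landmasses=(lm,),
        territories=(Territory("AAA", 0, 0, 100),),
        placements=(PAPlacement("AAA", 0, a, (50, 50)),),
        truth=truth,
    )


def _two_islands_spec(seed: int) -> ScenarioSpec:
    # two equal 100x100 islands of one country, one PA per island covering
    # 10% of the country area; sea is the only barrier between them
    islands = (Landmass(0, 0, 100, 100), Landmass(300, 0, 100, 100))
    a, A = 2000.0, 20000.0
    pc = 100 * a * math.sqrt(2.0) / A
    prot = 100 * 2 * a / A
    truth = assemble_indicator_set(
        iso3="AAA", d_med=10.0,
        protconn_value=pc, sea=prot - pc, outland=0.0, design=0.0,
        within=100.0, contig=0.0, unprot=0.0, trans=0.0,
    )
    return ScenarioSpec(
        seed=seed,
        landmasses=islands,
        territories=(Territory("AAA", 0, 0, 100), Territory("AAA", 1, 300, 400)),
        placements=(
            PAPlacement("AAA", 0, a, (50, 50)),
            PAPlacement("AAA", 1, a, (350, 50)),
        ),
        truth=truth,
    )


def _enclave_spec(seed: int) -> ScenarioSpec:
    # one 300x100 landmass; foreign strip BBB (no PAs) splits country AAA
    # into two portions, so foreign land is the only barrier
    lm = Landmass(0, 0, 300, 100)
    a, A = 1000.0, 20000.0
    pc = 100 * a * math.sqrt(2.0) / A
    prot = 100 * 2 * a / A
    truth = assemble_indicator_set(
        iso3="AAA", d_med=10.0,
        protconn_value=pc, sea=0.0, outland=prot - pc, design=0.0,
        within=100.0, contig=0.0, unprot=0.0, trans=0.0,
    )
    return ScenarioSpec(
        seed=seed,
        landmasses=(lm,),
        territories=(
            Territory("AAA", 0, 0, 100),
            Territory("BBB", 0, 100, 200),
            Territory("AAA", 0, 200, 300),
        ),
        placements=(
            PAPlacement("AAA", 0, a, (50, 50)),
            PAPlacement("AAA", 0, a, (250, 50)),
        ),
        truth=truth,
    )


PRESETS = {
    "single_pa": _single_pa_spec,
    "two_islands": _two_islands_spec,
    "enclave": _enclave_spec,
}


def preset_scenario(name: str, seed: int = 0) -> Scenario:
    """Generate one of the closed-form presets by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return generate_scenario(factory(seed))


def random_country_scenario(
    seed: int,
    n_landmasses: int | None = None,
    foreign_neighbour: bool | None = None,
    n_pas: int | None = None,
) -> Scenario:
    """A random focal country "AAA" for property testing.

    Draws 1-3 landmasses of 150-400 km side, optionally splits the first
    landmass with a foreign country "BBB" (which may hold its own PAs,
    creating transboundary stepping stones), and scatters 2-10 disjoint
    square PAs per country.  Unspecified settings are drawn from the seed.
    """
    rng = np.random.default_rng(seed)
    if n_landmasses is None:
        n_landmasses = int(rng.integers(1, 4))
    if foreign_neighbour is None:
        foreign_neighbour = bool(rng.integers(0, 2))
    if n_pas is None:
        n_pas = int(rng.integers(2, 11))

    landmasses: list[Landmass] = []
    x_cursor = 0.0
    for _ in range(n_landmasses):
        w = float(rng.uniform(150, 400))
        h = float(rng.uniform(150, 400))
        landmasses.append(Landmass(x_cursor, 0.0, w, h))
        x_cursor += w + float(rng.uniform(50, 200))  # sea gap

    territories: list[Territory] = []
    lm0 = landmasses[0]
    if foreign_neighbour and lm0.width > 150:
        # AAA | BBB | AAA strips: enclave geometry with possible stepping
        # stones when BBB has PAs
        b0 = lm0.x0 + lm0.width * float(rng.uniform(0.25, 0.4))
        b1 = lm0.x0 + lm0.width * float(rng.uniform(0.55, 0.7))
        territories += [
            Territory("AAA", 0, lm0.x0, b0),
            Territory("BBB", 0, b0, b1),
            Territory("AAA", 0, b1, lm0.x0 + lm0.width),
        ]
    else:
        territories.append(Territory("AAA", 0, lm0.x0, lm0.x0 + lm0.width))
    for i, lm in enumerate(landmasses[1:], start=1):
        territories.append(Territory("AAA", i, lm.x0, lm.x0 + lm.width))

    rules = [RandomPARule("AAA", n_pas, area_range=(10.0, 2000.0))]
    if any(t.iso3 == "BBB" for t in territories):
        rules.append(RandomPARule("BBB", int(rng.integers(0, 4)),
                                  area_range=(10.0, 2000.0)))
    spec = ScenarioSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        landmasses=tuple(landmasses),
        territories=tuple(territories),
        random_rules=tuple(rules),
    )
    return generate_scenario(spec)
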