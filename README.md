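# protconn

Connectivity indicators for terrestrial protected-area (PA) systems.

International biodiversity policy asks countries not just to protect 17%
of their land but to do so with *well-connected* PA systems. This package
measures that: given a country's PA polygons and its land/boundary layer
(or an abstract node/distance network), it computes the **Protected
Connected** family of indicators on a spatial dispersal graph, partitions
the isolated protected land by cause, and classifies each country's
priority actions. It is written for conservation scientists and indicator
producers who want these metrics reproducibly from Python or the shell.

## The indicators

Each PA is a graph node; the probability of a direct dispersal movement
between PAs *i* and *j* declines with their edge-to-edge distance *d_ij*
through a negative-exponential kernel calibrated at the median dispersal
distance *d_med*:

    p_ij = 0.5^(d_ij / d_med)

The best multi-step route has probability `p*_ij`, the maximum product of
link probabilities over all paths (computed exactly via shortest paths on
−ln p weights). With PA areas `a_i` (0 for PAs outside the focal country,
which act only as stepping stones) and country land area `A_L`, the
Equivalent Connected Area is

    ECA = sqrt( Σ_i Σ_j a_i a_j p*_ij )      (i = j included)

and the indicators, all percentages, are

    Prot      = 100 Σ a_i / A_L                    (coverage)
    ProtConn  = 100 ECA / A_L                      (protected AND connected)
    ProtUnconn = Prot − ProtConn
               = ProtUnconn[Sea] + ProtUnconn[Outland] + ProtUnconn[Design]
    ProtConn_Bound = Prot − ProtUnconn[Design]

The sea is an absolute barrier (no links across landmasses) and direct
links between two portions of a country separated by foreign land are
barred unless a foreign protected node bridges them. Recomputing ECA at
the portion level, the landmass level and the full network telescopes
`ProtUnconn` into the three causes, so `ProtConn_Bound` scores only the
isolation a country can act on — it does not penalise archipelagos or
Alaska-like exclaves for their geography. Four nested link scenarios
further split ProtConn into the shares reachable within single PAs,
through contiguous PAs, across unprotected national land, and via foreign
stepping stones; these are the basis for the priority classes (A1/A2:
designate new PAs; B1/B2/B3: manage permeability, contiguity or the PAs
themselves; C: coordinate across borders).

## Worked example

An island country protects 10% of its land on each of its two equal
islands (`examples/island_country.py`):

```
Prot              =  20.0 %   (PA coverage)
ProtConn          =  14.1 %   (protected AND connected)
ProtUnconn[Sea]   =   5.9 %   (lost to the sea)
ProtUnconn[Outland]=  0.0 %
ProtUnconn[Design]=   0.0 %
ProtConn_Bound    =  20.0 %   (connectivity the country can influence)
```

Coverage is 20%, but no dispersal crosses the sea, so the connected
protected land is only `100·a·√2/A_L = 14.1%` (the two PAs contribute
through intra-PA terms alone). The entire 5.9-point loss is attributed to
the sea, so the bounded indicator returns 20%: this country's PA system
design is not the problem. The other scripts in `examples/` walk through
the kernel and ECA algebra, foreign stepping stones across an enclave
border, and cohort classification/aggregation.

The same works from the shell:

```
protconn simulate --preset two_islands --seed 42 --out-dir work/
protconn indicators --pas work/pas.geojson --land work/land.geojson --country AAA
protconn run --preset two_islands --out-dir work/run
```

## Layout

- `src/protconn/synthetic.py` — synthetic countries/landmasses/PA systems
  with closed-form truth presets
- `src/protconn/geometry.py` — layer preprocessing to nodes + distances
- `src/protconn/network.py` — kernel, admissible links, max-product
  paths, ECA
- `src/protconn/indicators.py` — the indicator family and its identities
- `src/protconn/classification.py`, `src/protconn/aggregation.py` —
  priorities and area-weighted group averages
- `src/protconn/pipeline.py`, `src/protconn/cli.py` — end-to-end runs
- `docs/methods.md` — model assumptions, parameters and numerical choices
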