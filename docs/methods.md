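# Methods

## Model

A country's terrestrial protected areas (PAs) form a spatial graph. Nodes
are the dissolved, land-clipped PA polygons; the node attribute is the PA
area for the focal country's PAs and 0 for foreign ("transboundary") PAs,
which can route dispersal but contribute no protected area to the
country. The direct dispersal probability between two PAs is a negative
exponential in their edge-to-edge distance, `p(d) = 0.5^(d/d_med)`, i.e.
calibrated so a movement over the median dispersal distance succeeds with
probability one half. The probability of the best (possibly multi-step)
route, `p*_ij`, is the maximum over paths of the product of link
probabilities; it is computed exactly as a Dijkstra shortest path on
`−ln p` edge weights, which is the standard reduction (products of
probabilities in (0,1] map to sums of non-negative weights).

The Equivalent Connected Area is `ECA = sqrt(ΣΣ a_i a_j p*_ij)` over all
node pairs including `i = j` (movement inside a PA is unrestricted by
assumption). The square root puts ECA in km²: a single PA of area A has
ECA = A, and a fully connected system has ECA equal to its total area, so
`ProtConn = 100·ECA/A_L` equals coverage exactly when everything is
reachable. ECA is bounded by `sqrt(Σ a_i²)` (all PAs mutually
unreachable) and `Σ a_i`, is non-decreasing under any added link or
raised probability, and is invariant to replacing two contiguous PAs by
their union.

## Barrier rules and the cause partition

Two admissibility rules encode the barrier semantics:

1. **Sea is absolute.** A link requires both endpoints on the same
   landmass (connected component of all land). Terrestrial dispersal does
   not cross water, at any distance.
2. **Unprotected foreign land blocks direct movement.** Two focal PAs in
   different portions of their country (connected components of the
   country's own land — portions differ when separated by sea *or* by
   foreign territory) may not link directly; a foreign protected node may
   bridge them as a stepping stone, since movement then stays within
   protected land across the border region.

ProtUnconn = Prot − ProtConn is split by cause through three nested
connectivity levels, each a sum of ECAs over finer groupings of the focal
nodes (every subnetwork keeps the transboundary nodes of its landmass, so
foreign stepping stones always count):

- per-portion ECAs → `ProtConn_Bound` (sea and foreign-land isolation
  both forgiven);
- per-landmass ECAs → an intermediate level (sea between landmasses
  forgiven, foreign land not);
- the full network → ProtConn.

Successive differences give `Design = Prot − Bound`,
`Outland = Bound − LM-level`, `Sea = LM-level − ProtConn`; the telescoping
makes the three parts sum to ProtUnconn identically. Sea ≥ 0 follows from
the sub-additivity of the square root over disjoint landmass blocks;
Design ≥ 0 from `p* ≤ 1`. Outland ≥ 0 is enforced (a violation beyond
−1e-9 raises, as it indicates an admissibility bug) and holds across the
property suite; tiny negative rounding residues are clamped to zero. The
ordering — attributing the landmass-internal loss to foreign land and the
cross-landmass loss to the sea — is the one consistent with the expected
qualitative behaviour: archipelago countries show Sea > 0, Outland = 0;
enclave-split countries show Outland > 0, Sea = 0.

The four ProtConn fractions come from four nested link scenarios (no
links; contiguous focal pairs only; all focal pairs; plus transboundary
links). With `P_k = 100·ECA_k/A_L`, the fractions are the successive
increments normalised by the full value, hence non-negative and summing
to 100. When ProtConn = 0 the fractions are reported as flagged zeros
rather than undefined, which keeps group aggregation total-safe.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `d_med` | 1, 10, 30, 100 (reference 10) | km | kernel median dispersal distance; the range spans most terrestrial vertebrates, 10 km is the log-midpoint |
| transboundary buffer | 500 | km | search radius for foreign PAs; at `d_med` = 100 km a 500 km movement has probability 0.03, so farther PAs are irrelevant |
| minimum PA area | 1 | km² | drops slivers after clipping; keeps computation tractable without materially changing coverage |
| simplification tolerance | 100 | m | vertex reduction after dissolve, before distance computation |
| contiguity tolerance | 0 | m | boundary distance treated as "contiguous"; raise to 1–100 m for dirty data |
| target | 17 | % of A_L | coverage/connectivity reference level for the priority classes |
| link prune threshold | 1e-6 | probability | direct links weaker than this (≈ 20·d_med gaps) are dropped before path search; induced error is orders of magnitude below the 0.1-point reporting precision |

## Priority classification

A country is class A when `ProtConn_Bound < target` (new PAs needed): A1
when the coverage gap `target − Prot` exceeds `ProtUnconn[Design]` (the
shortfall is mostly missing coverage), A2 otherwise (mostly misplaced
coverage). Class B otherwise: B1/B2 when `ProtConn[Unprot]` /
`ProtConn[Contig]` is strictly above the median of the B countries
(midpoint-of-two median; both may hold), B3 when neither. C — reliance on
foreign stepping stones — flags any country whose `ProtConn[Trans]` is at
or above the nearest-rank 67th percentile over all countries (the top
third, inclusively at the cut; the comparison is against all countries,
not only B, hence the stricter third rather than half). The A/B cut
carries a 1e-9 numeric slack so that values that are exactly at the
target up to floating-point noise from geometry (e.g. a square of side
√1700 km) fall on the inclusive B side; the slack is seven orders of
magnitude below the reporting precision. With fewer than two B countries
the medians are undefined and B subclassification is skipped with a
warning.

## Aggregation

Group values are weighted means over member countries: weight `A_L` for
all percent-of-country indicators, weight `A_L·ProtConn` for the four
ProtConn fractions (a fraction of ProtConn weighted by the amount of
ProtConn it describes). Using one weight per family preserves every
additive identity exactly at the group level; ProtConn = 0 countries
contribute zero fraction weight.

## Synthetic worlds

The generator emulates the multi-landmass, multi-country settings the
indicators must distinguish: rectangular landmasses on a flat km plane,
vertical territory strips (foreign strips create enclaves), and square or
disc PAs placed explicitly or by seeded rejection sampling that keeps a
country's PAs disjoint (overlap handling is exercised separately with
deliberately overlapping fixtures). Planar coordinates make areas and
distances exact, isolating the indicator mathematics from projection
error. Three presets carry closed-form truths — a single PA at 17%
coverage; two equal island PAs (ProtConn = 100·a·√2/A_L, the rest Sea);
an enclave pair (the same form, the rest Outland). The random country
generator draws 1–3 landmasses of 150–400 km side, an optional foreign
neighbour with 0–3 PAs, and 2–10 focal PAs of 10–2,000 km², giving
coverages from under 1% to above 20% — the realistic national range.

What the generator does **not** emulate: real coastline complexity,
heterogeneous landscape resistance between PAs (all unprotected land is
equally traversable), within-PA movement limits, and geodesic geometry —
coordinates are planar km throughout, so results on synthetic worlds
validate the indicator algebra and barrier logic, not map-projection
handling of global datasets.

## Numerical choices

- Node iteration and all reductions use sorted node ids; reruns are
  byte-identical.
- Identity validation tolerance is 1e-9 percentage points in tests (1e-6
  at the public `validate()` default, to accommodate values read back
  from rounded files).
- Indicator CSVs carry full precision; rounding to the conventional one
  decimal is presentation-only.
- Point sites are buffered with 256 segments per quarter circle, making
  the polygon area match the reported area to well within 0.1%.
- Degenerate inputs: a country with no nodes yields an empty network
  (distinct from an error); no-focal-node networks have ECA 0; disputed
  territories are excluded from `A_L` but remain part of the land mask.

## Limitations

Landscape-matrix resistance, management effectiveness and habitat- or
species-stratified variants are out of scope; the indicator treats PAs as
internally traversable and all unprotected land as uniformly hostile.
Geodesic support (true geographic layers) would require a projection
library and is not part of this version.
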