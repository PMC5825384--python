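"""Area-weighted aggregation of country indicator sets to regional,
continental, global or custom groupings.

Indicators expressed as a percentage of country land area (Prot, ProtConn,
ProtConn_Bound, ProtUnconn and its cause fractions) are averaged with the
country land area A_L as the weight.  The four ProtConn movement fractions
are percentages of ProtConn itself, so their weight is A_L * ProtConn;
countries with ProtConn = 0 then contribute zero weight, which keeps the
aggregate total-safe.  Because the same weights apply within each family,
every additive identity of the country-level sets carries over exactly to
the aggregate.
"""

from __future__ import annotations

from .indicators import CountryContext, IndicatorSet

__all__ = ["GroupingTable", "aggregate", "aggregate_groups"]

_AREA_PCT_FIELDS = (
    "prot", "protconn", "protconn_bound", "protunconn",
    "protunconn_sea", "protunconn_outland", "protunconn_design",
)
_FRACTION_FIELDS = (
    "protconn_within", "protconn_contig", "protconn_unprot", "protconn_trans",
)


class GroupingTable:
    """iso3 -> group label mapping for one grouping level (e.g. M49
    region or continent); each country appears at most once."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def from_rows(cls, rows, level: str) -> "GroupingTable":
        mapping: dict[str, str] = {}
        for row in rows:
            iso3 = row["iso3"]
            if iso3 in mapping:
                raise ValueError(f"{iso3} listed twice in grouping table")
            mapping[iso3] = row[level]
        return cls(mapping)

    def members(self, group: str) -> list[str]:
        return sorted(k for k, v in self.mapping.items() if v == group)

    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def aggregate(
    indicator_sets: list[IndicatorSet],
    contexts: dict[str, CountryContext],
    label: str,
) -> IndicatorSet:
    """Weighted average of the member countries into one indicator set."""
    if not indicator_sets:
        raise ValueError(f"empty group {label!r}")
    missing = [s.iso3 for s in indicator_sets if s.iso3 not in contexts]
    if missing:
        raise ValueError(f"missing country context for: {', '.join(missing)}")
    d_meds = {s.d_med for s in indicator_sets}
    if len(d_meds) != 1:
        raise ValueError(f"mixed d_med values in group {label!r}: {sorted(d_meds)}")

    area_w = {s.iso3: contexts[s.iso3].area_km2 for s in indicator_sets}
    frac_w = {s.iso3: area_w[s.iso3] * s.protconn for s in indicator_sets}
    area_total = sum(area_w.values())
    frac_total = sum(frac_w.values())

    values: dict[str, float] = {}
    for f in _AREA_PCT_FIELDS:
        values[f] = sum(area_w[s.iso3] * getattr(s, f) for s in indicator_sets) \
            / area_total
    for f in _FRACTION_FIELDS:
        values[f] = (
            sum(frac_w[s.iso3] * getattr(s, f) for s in indicator_sets) / frac_total
            if frac_total > 0 else 0.0
        )

    agg = IndicatorSet(
        iso3=label,
        d_med=d_meds.pop(),
        no_connected_land=frac_total <= 0,
        **values,
    )
    agg.validate()
    return agg


def aggregate_groups(
    indicator_sets: list[IndicatorSet],
    contexts: dict[str, CountryContext],
    grouping: GroupingTable,
) -> list[IndicatorSet]:
    """Aggregate every group of a grouping table; a grouped country missing
    from the inputs is an error naming the iso3."""
    by_iso = {s.iso3: s for s in indicator_sets}
    out: list[IndicatorSet] = []
    for group in grouping.groups():
        members = grouping.members(group)
        missing = [m for m in members if m not in by_iso]
        if missing:
            raise ValueError(
                f"group {group!r} members absent from indicators: "
                f"{', '.join(missing)}"
            )
        out.append(aggregate([by_iso[m] for m in members], contexts, group))
    return out
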