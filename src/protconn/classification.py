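"""Country priority classification for PA connectivity.

Given each country's indicator set at the reference median dispersal
distance, assign the strategic priority for improving or sustaining PA
connectivity relative to a coverage-and-connectivity target (17% of land
by default, the Aichi Target 11 level):

A  (ProtConn_Bound < target): new PAs are required.
   A1 -- general increase of coverage, when the coverage gap
         (target - Prot) exceeds the isolation due to PA-system design;
   A2 -- targeted designation of stepping-stone/corridor PAs otherwise.
B  (ProtConn_Bound >= target): the system is well designed; the priority
   is management rather than designation.
   B1 -- permeability of unprotected land, when ProtConn[Unprot] is above
         the median of the B countries;
   B2 -- coordinated management of contiguous PAs, when ProtConn[Contig]
         is above the B-country median (B1 and B2 may co-occur);
   B3 -- neither: management effectiveness of the (large) individual PAs.
C  (any country): transboundary coordination, when ProtConn[Trans] is in
   the top third across all countries; co-occurs with any A/B class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .indicators import IndicatorSet

__all__ = ["PriorityAssignment", "classify"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorityAssignment:
    iso3: str
    a1: bool
    a2: bool
    b1: bool
    b2: bool
    b3: bool
    c: bool
    #: thresholds actually applied: B-median of Unprot/Contig, Trans cut
    diagnostics: dict

    @property
    def labels(self) -> list[str]:
        out = [k.upper() for k in ("a1", "a2", "b1", "b2", "b3") if getattr(self, k)]
        if self.c:
            out.append("C")
        return out


def _median(values: list[float]) -> float:
    """Midpoint-of-two-central-values median on the sorted list."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def _nearest_rank_percentile(values: list[float], pct: float) -> float:
    """Nearest-rank percentile (pct in [0, 100]) on the sorted list."""
    s = sorted(values)
    rank = max(1, int(-(-pct * len(s) // 100)))  # ceil(pct/100 * n)
    return s[min(rank, len(s)) - 1]


#: numeric slack on the A/B target cut, absorbing floating-point noise in
#: indicator values computed from geometry (far below the 0.1-point
#: reporting precision); the target comparison itself stays inclusive (>=).
TARGET_TOL = 1e-9


def classify(
    indicator_sets: list[IndicatorSet],
    target: float = 17.0,
    trans_top_share: float = 1.0 / 3.0,
) -> list[PriorityAssignment]:
    """Assign priority classes to a cohort of countries.

    The B-subclass medians are computed over the B countries only; the
    transboundary cut is the (1 - trans_top_share) nearest-rank percentile
    of ProtConn[Trans] over all countries, applied inclusively (>=).
    With fewer than two B countries the medians are undefined and B
    subclassification is skipped (warning).
    """
    b_sets = [s for s in indicator_sets if s.protconn_bound >= target - TARGET_TOL]
    b_unprot_median = b_contig_median = None
    if len(b_sets) >= 2:
        b_unprot_median = _median([s.protconn_unprot for s in b_sets])
        b_contig_median = _median([s.protconn_contig for s in b_sets])
    elif b_sets:
        logger.warning(
            "only %d country meets the target: B subclassification skipped",
            len(b_sets),
        )
    trans_cut = _nearest_rank_percentile(
        [s.protconn_trans for s in indicator_sets],
        100.0 * (1.0 - trans_top_share),
    )

    out: list[PriorityAssignment] = []
    for s in indicator_sets:
        a = s.protconn_bound < target - TARGET_TOL
        a1 = a and (target - s.prot) > s.protunconn_design
        a2 = a and not a1
        b = not a
        b1 = b2 = b3 = False
        if b and b_unprot_median is not None:
            b1 = s.protconn_unprot > b_unprot_median
            b2 = s.protconn_contig > b_contig_median
            b3 = not (b1 or b2)
        c = s.protconn_trans >= trans_cut
        out.append(
            PriorityAssignment(
                iso3=s.iso3, a1=a1, a2=a2, b1=b1, b2=b2, b3=b3, c=c,
                diagnostics={
                    "target": target,
                    "b_unprot_median": b_unprot_median,
                    "b_contig_median": b_contig_median,
                    "trans_cut": trans_cut,
                },
            )
        )
    return out
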