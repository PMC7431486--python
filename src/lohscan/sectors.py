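"""Paired-sector crossover mapping and DSB cell-cycle phase inference.

A white/red-sectored colony records a single first-division event: the two
sectors are the two daughter lineages.  For a reciprocal crossover on the
chr IV right arm, each sector is homozygous for the opposite parent distal
to its exchange point, and the interval between the two sectors' signal
transitions is the crossover-associated gene conversion tract.

Summing homolog copies over the two sectors reconstructs the allele
representation across the four chromatids of the dividing cell.  Outside
any event this combined representation is 2:2.  Inside the tract:

* a 3:1 region (one sector converted, the other heterozygous) indicates a
  lesion on a single chromatid, i.e. a DSB after replication (S/G2);
* a 4:0 core (both sectors converted) requires both sister chromatids to
  have been broken at the same position, i.e. a G1 DSB replicated before
  repair.

The phase rule is deterministic: a pure 3:1 tract is S/G2-consistent, a
tract containing a 4:0 core is G1-consistent, and a crossover with no
detectable tract leaves the phase undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import CopyProfile, Segment

__all__ = [
    "TractCall",
    "combine_sectors",
    "call_tract",
    "summarize_phase",
]

PHASE_LABELS = {
    "three_to_one": "s_g2_consistent",
    "complex": "g1_consistent",
    "no_tract": "undetermined",
}


@dataclass(frozen=True)
class TractCall:
    """Reconstructed conversion tract of one sectored colony.

    Boundary intervals are open (bp, bp) intervals bracketing each
    sector's distal-homozygosity transition; ``tract_span`` quotes the
    outermost marker coordinates of the combined non-2:2 region, or None
    when no tract is detectable.
    """

    white_transition: tuple[int, int]
    red_transition: tuple[int, int]
    tract_span: tuple[int, int] | None
    pattern: str  # no_tract | three_to_one | complex
    inferred_phase: str  # s_g2_consistent | g1_consistent | undetermined

    def __post_init__(self) -> None:
        if (self.pattern == "no_tract") != (self.tract_span is None):
            raise ValueError("no_tract iff tract_span is None")
        if self.inferred_phase != PHASE_LABELS[self.pattern]:
            raise ValueError("phase must follow the pattern rule")


def combine_sectors(copies_white: CopyProfile, copies_red: CopyProfile) -> np.ndarray:
    """Per-marker combined representation (n_W, n_Y) out of four chromatids.

    Element-wise sum of the two sectors' homolog copies; outside events
    this is (2, 2).  Both profiles must share one marker map.
    """
    if copies_white.markers is not copies_red.markers and not copies_white.markers.table[
        "marker_id"
    ].equals(copies_red.markers.table["marker_id"]):
        raise ValueError("sector profiles cover different markers")
    return copies_white.copies + copies_red.copies


def _distal_transition(
    segments: list[Segment], chromosome: str
) -> tuple[int, int] | None:
    """Open bp interval where the sector enters its distal homozygous state.

    The crossover transition of a sector is the left boundary of the
    terminal segment (the one reaching the chromosome's last marker) when
    that segment is homozygous (2,0)/(0,2).  Returns None when the sector
    never transitions (single uniform state, e.g. the unconverted lineage
    of a BIR colony).
    """
    segs = sorted((s for s in segments if s.chromosome == chromosome), key=lambda s: s.first)
    if len(segs) < 2:
        return None
    last = segs[-1]
    if last.state in ((2, 0), (0, 2)):
        return last.left_boundary
    return None


def call_tract(
    segments_white: list[Segment],
    segments_red: list[Segment],
    combined: np.ndarray,
    markers,
    chromosome: str = "IV",
    min_40_run: int = 2,
    min_tract_run: int = 2,
) -> TractCall:
    """Map the crossover and classify its conversion tract.

    The tract is the maximal run of markers with combined representation
    != 2:2 between the two sectors' transition intervals.  A tract is
    ``complex`` (G1-consistent) when it contains a run of at least
    ``min_40_run`` consecutive markers at 4:0/0:4; otherwise it is a
    ``three_to_one`` (S/G2-consistent) tract.  Identical transitions with
    no intervening non-2:2 marker mean no detectable tract, as does a
    non-2:2 run shorter than ``min_tract_run`` markers: a single
    boundary-marker miscall can shift one sector's transition by one
    marker, so one-marker tracts are not trusted (at the dense-arm marker
    spacing this sacrifices only sub-kb tracts, which the array cannot
    resolve anyway).
    """
    tw = _distal_transition(segments_white, chromosome)
    tr = _distal_transition(segments_red, chromosome)
    if tw is None and tr is None:
        raise ValueError(f"no signal transition on chr {chromosome} in either sector")
    # BIR-like colonies transition in one sector only; treat the other
    # sector's transition as coincident for tract delimitation
    if tw is None:
        tw = tr
    if tr is None:
        tr = tw

    sl = markers.chrom_slice(chromosome)
    pos = markers.positions[sl]
    comb = combined[sl]
    non22 = (comb[:, 0] != 2) | (comb[:, 1] != 2)

    # restrict to the window spanned by the two transition intervals
    lo = min(tw[0], tr[0])
    hi = max(tw[1], tr[1])
    in_window = (pos >= lo) & (pos <= hi)
    candidates = np.flatnonzero(non22 & in_window)
    if candidates.size == 0:
        return TractCall(tw, tr, None, "no_tract", PHASE_LABELS["no_tract"])

    # maximal contiguous run of non-2:2 markers inside the window
    breaks = np.flatnonzero(np.diff(candidates) > 1)
    runs = np.split(candidates, breaks + 1)
    run = max(runs, key=len)
    if len(run) < min_tract_run:
        return TractCall(tw, tr, None, "no_tract", PHASE_LABELS["no_tract"])
    first, last = int(run[0]), int(run[-1])
    # quote the tract from the outer hull of the two transition intervals:
    # the flanking 2:2 marker on each side brackets the converted region
    span = (int(lo), int(hi))

    four0 = (comb[:, 0] == 0) | (comb[:, 1] == 0)
    in_tract = np.zeros(len(pos), dtype=bool)
    in_tract[first : last + 1] = True
    best = 0
    cur = 0
    for flag in four0 & in_tract:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    pattern = "complex" if best >= min_40_run else "three_to_one"
    return TractCall(tw, tr, span, pattern, PHASE_LABELS[pattern])


def summarize_phase(calls: list[TractCall]) -> dict:
    """Tally tract patterns and the S/G2 fraction among tract-bearing events.

    Colonies with no detectable tract carry no phase information and are
    excluded from the denominator.  The fraction is None when no
    tract-bearing events exist.
    """
    if not calls:
        raise ValueError("need at least one tract call")
    n_no = sum(1 for c in calls if c.pattern == "no_tract")
    n_31 = sum(1 for c in calls if c.pattern == "three_to_one")
    n_cx = sum(1 for c in calls if c.pattern == "complex")
    denom = n_31 + n_cx
    return {
        "n_no_tract": n_no,
        "n_three_to_one": n_31,
        "n_complex": n_cx,
        "fraction_s_g2": (n_31 / denom) if denom else None,
    }
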