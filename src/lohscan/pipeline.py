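"""End-to-end drivers: raw signals to called events and tract calls."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .events import Event, Karyotype, call_karyotype, classify_events
from .genome import MarkerMap
from .sectors import TractCall, call_tract, combine_sectors
from .signal import (
    CopyProfile,
    Segment,
    call_copies,
    normalize_hr,
    profile_from_segments,
    segment_profile,
)

__all__ = ["IsolateCalls", "process_isolate", "analyze_sector_pair"]


@dataclass
class IsolateCalls:
    """Everything called from one isolate's array."""

    isolate_id: str
    copies: CopyProfile
    segments: list[Segment]
    events: list[Event]
    karyotype: Karyotype


def process_isolate(
    signals: pd.DataFrame,
    markers: MarkerMap,
    isolate_id: str = "isolate",
    min_run: int = 3,
    concordance: float = 0.9,
) -> IsolateCalls:
    """Normalize, call copies, segment, classify, and karyotype one array."""
    hr = normalize_hr(signals, markers)
    copies = call_copies(hr)
    segments = segment_profile(copies, min_run=min_run)
    events = classify_events(segments, markers, isolate_id)
    karyotype = call_karyotype(copies, concordance=concordance, isolate_id=isolate_id)
    return IsolateCalls(isolate_id, copies, segments, events, karyotype)


def analyze_sector_pair(
    signals_white: pd.DataFrame,
    signals_red: pd.DataFrame,
    markers: MarkerMap,
    chromosome: str = "IV",
    min_run: int = 3,
    min_40_run: int = 2,
    min_tract_run: int = 2,
) -> TractCall:
    """Map the crossover of one sectored colony and classify its tract.

    Each sector is normalized, called and segmented independently; the
    combined four-chromatid representation is computed from the
    segmentation-smoothed profiles so isolated miscalled markers cannot
    masquerade as tract structure.
    """
    seg_w = segment_profile(call_copies(normalize_hr(signals_white, markers)), min_run)
    seg_r = segment_profile(call_copies(normalize_hr(signals_red, markers)), min_run)
    smooth_w = profile_from_segments(seg_w, markers)
    smooth_r = profile_from_segments(seg_r, markers)
    combined = combine_sectors(smooth_w, smooth_r)
    return call_tract(seg_w, seg_r, combined, markers, chromosome, min_40_run, min_tract_run)
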