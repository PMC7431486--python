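"""Event classification, karyotyping, and diagnostics.

Turns segmented copy-number profiles into the event taxonomy of the
sectored-colony / heat-shock instability analysis:

* segmental events -- terminal LOH (a1-a4), gene conversion (b1, b2, c1),
  interstitial deletion (d1);
* whole-chromosome events -- monosomy, trisomy, tetrasomy, pentasomy and
  uniparental disomy (UPD), called from marker concordance;
* paired nondisjunction detection across the two sectors of a colony;
* the chr IV left-arm PCR heterozygosity diagnostic;
* region-of-interest (e.g. SSD1) zygosity annotation.

Whole-chromosome states are called first; segmental rules apply only to
chromosomes that are not uniformly aberrant.  "Terminal" means the
segment contains the first or last marker of the chromosome -- the array
edge proxies the telomere.

Subclass codes mirror the event-pattern taxonomy figure-style labels:
a1/a2 = terminal LOH retaining W on the left/right arm, a3/a4 the same
for Y; b1/b2 = single-tract conversion retaining W/Y; c1 = complex
conversion (two or more homozygous tracts separated by heterozygous
markers on one chromosome); d1 = interstitial deletion.  The code->
(parent, arm) mapping is a convention of this package.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MarkerMap, RegionOfInterest
from .signal import CopyProfile, Segment, segment_profile

__all__ = [
    "Event",
    "Karyotype",
    "classify_events",
    "call_karyotype",
    "detect_paired_nondisjunction",
    "pcr_band_diagnostic",
    "annotate_region",
]

#: PCR product sizes (bp) of the chr IV left-arm deletion polymorphism:
#: the W-derived allele retains the 435,284-435,391 segment (404 bp band),
#: the Y-derived allele deletes it (296 bp band).
PCR_BAND_W = 404
PCR_BAND_Y = 296

_KARYOTYPE_STATES = {
    (1, 1): ("normal", None),
    (2, 0): ("UPD", "W"),
    (0, 2): ("UPD", "Y"),
    (1, 0): ("monosomy", "Y"),  # parent = the missing homolog
    (0, 1): ("monosomy", "W"),
    (2, 1): ("trisomy", "W"),  # parent = the gained homolog
    (1, 2): ("trisomy", "Y"),
    (3, 1): ("tetrasomy", "W"),
    (1, 3): ("tetrasomy", "Y"),
    (2, 2): ("tetrasomy", "WY"),
    (3, 2): ("pentasomy", "W"),
    (2, 3): ("pentasomy", "Y"),
}


@dataclass(frozen=True)
class Event:
    """A classified genomic alteration in one isolate."""

    isolate_id: str
    event_class: str  # as EventSpec classes, plus "complex"
    subclass: str  # a1-a4, b1, b2, c1, d1, or ""
    chromosome: str
    start: int  # bp of first affected marker
    end: int  # bp of last affected marker
    parent: str  # retained (LOH/deletion/UPD/monosomy) or gained parent
    state: tuple[int, int] = (1, 1)


@dataclass
class Karyotype:
    """Per-chromosome whole-chromosome state of one isolate.

    ``states[chrom] = (label, parent)`` where label is normal, monosomy,
    trisomy, tetrasomy, pentasomy or UPD.  For monosomy the parent is the
    *missing* homolog and for trisomy the *gained* one, so a paired
    nondisjunction shows the same parent in both sectors.
    """

    isolate_id: str
    states: dict[str, tuple[str, str | None]]

    def non_normal(self) -> dict[str, tuple[str, str | None]]:
        return {c: s for c, s in self.states.items() if s[0] != "normal"}

    def count(self, label: str) -> int:
        return sum(1 for s in self.states.values() if s[0] == label)


def _terminal_subclass(parent: str, arm: str) -> str:
    return {("W", "left"): "a1", ("W", "right"): "a2", ("Y", "left"): "a3", ("Y", "right"): "a4"}[
        (parent, arm)
    ]


def classify_events(
    segments: list[Segment],
    markers: MarkerMap,
    isolate_id: str = "isolate",
) -> list[Event]:
    """Classify one isolate's segments into the event taxonomy.

    Chromosomes whose single segment is a uniform non-(1,1) state become
    whole-chromosome events (UPD or aneuploidy).  Otherwise each
    non-(1,1) segment is classified by its state and position: homozygous
    (2,0)/(0,2) runs reaching a chromosome end are terminal LOH, interior
    ones gene conversions; hemizygous (1,0)/(0,1) runs are interstitial
    deletions.  Anything else is flagged ``complex`` -- never dropped.
    """
    pos = markers.positions
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)

    events: list[Event] = []
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.first)
        n_chrom_markers = sum(s.n_markers for s in segs)

        if len(segs) == 1 and segs[0].state != (1, 1):
            st = segs[0].state
            label, parent = _KARYOTYPE_STATES.get(st, ("complex", ""))
            s = segs[0]
            if label == "normal":
                continue
            cls = label if label != "complex" else "complex"
            events.append(
                Event(isolate_id, cls, "", chrom, int(pos[s.first]), int(pos[s.last]),
                      parent or "", st)
            )
            continue

        # count homozygous conversion-like tracts to recognise complex (c1)
        conv_like = [
            s for s in segs
            if s.state in ((2, 0), (0, 2))
            and s.first != segs[0].first and s.last != segs[-1].last
        ]
        for s in segs:
            if s.state == (1, 1):
                continue
            start, end = int(pos[s.first]), int(pos[s.last])
            is_terminal = s.first == segs[0].first or s.last == segs[-1].last
            if s.state in ((2, 0), (0, 2)):
                parent = "W" if s.state == (2, 0) else "Y"
                if is_terminal:
                    arm = "right" if s.last == segs[-1].last else "left"
                    events.append(
                        Event(isolate_id, "terminal_LOH", _terminal_subclass(parent, arm),
                              chrom, start, end, parent, s.state)
                    )
                else:
                    sub = "c1" if len(conv_like) > 1 else ("b1" if parent == "W" else "b2")
                    events.append(
                        Event(isolate_id, "gene_conversion", sub, chrom, start, end,
                              parent, s.state)
                    )
            elif s.state in ((1, 0), (0, 1)):
                parent = "W" if s.state == (1, 0) else "Y"
                events.append(
                    Event(isolate_id, "interstitial_deletion", "d1", chrom, start, end,
                          parent, s.state)
                )
            else:
                label, parent = _KARYOTYPE_STATES.get(s.state, ("complex", ""))
                if label in ("trisomy", "monosomy", "tetrasomy", "pentasomy", "UPD") and \
                        s.n_markers == n_chrom_markers:
                    events.append(
                        Event(isolate_id, label, "", chrom, start, end, parent or "", s.state)
                    )
                else:
                    events.append(
                        Event(isolate_id, "complex", "", chrom, start, end, "", s.state)
                    )
    return events


def call_karyotype(
    copies: CopyProfile, concordance: float = 0.9, isolate_id: str = "isolate"
) -> Karyotype:
    """Whole-chromosome state per chromosome from marker concordance.

    A chromosome is labeled with a non-normal state only when its modal
    marker state is non-(1,1), maps to a defined whole-chromosome state,
    and is supported by at least ``concordance`` of the chromosome's
    markers; otherwise the chromosome is ``normal`` (segmental events are
    the province of :func:`classify_events`).
    """
    if not (0.5 < concordance <= 1.0):
        raise ValueError("concordance must be in (0.5, 1]")
    states: dict[str, tuple[str, str | None]] = {}
    for chrom in copies.markers.chrom_names_with_markers():
        sl = copies.markers.chrom_slice(chrom)
        rows = [tuple(r) for r in copies.copies[sl]]
        modal, n_modal = Counter(rows).most_common(1)[0]
        if modal != (1, 1) and n_modal / len(rows) >= concordance and modal in _KARYOTYPE_STATES:
            states[chrom] = _KARYOTYPE_STATES[modal]
        else:
            states[chrom] = ("normal", None)
    return Karyotype(isolate_id, states)


def detect_paired_nondisjunction(
    karyotype_white: Karyotype, karyotype_red: Karyotype
) -> list[tuple[str, str]]:
    """Chromosomes monosomic in one sector and trisomic in the other.

    Both calls must involve the same parental homolog: nondisjunction
    deposits both copies of one homolog into one daughter cell, so the
    sector missing parent P is mirrored by the sector gaining P.
    """
    out = []
    for chrom in karyotype_white.states:
        a = karyotype_white.states[chrom]
        b = karyotype_red.states.get(chrom, ("normal", None))
        for mono, tri in ((a, b), (b, a)):
            if mono[0] == "monosomy" and tri[0] == "trisomy" and mono[1] == tri[1]:
                out.append((chrom, mono[1]))
                break
    return out


def pcr_band_diagnostic(copies_w: int, copies_y: int) -> set[int]:
    """Diagnostic PCR bands for the chr IV left-arm deletion marker.

    The primer pair flanks a 108 bp segment present on the W homolog and
    deleted on the Y homolog: any W copy yields the 404 bp product, any Y
    copy the 296 bp product, a heterozygous template both.
    """
    if copies_w < 0 or copies_y < 0:
        raise ValueError("copy numbers must be >= 0")
    if copies_w == 0 and copies_y == 0:
        warnings.warn("zero template copies: no PCR product expected", stacklevel=2)
        return set()
    bands = set()
    if copies_w > 0:
        bands.add(PCR_BAND_W)
    if copies_y > 0:
        bands.add(PCR_BAND_Y)
    return bands


def annotate_region(events: list[Event], roi: RegionOfInterest) -> pd.DataFrame:
    """Flag events whose span covers a region of interest.

    Returns one row per event with ``covers_roi`` and, where the event
    renders the region homozygous (terminal LOH, gene conversion, UPD) or
    hemizygous (deletion, monosomy), the parent whose haplotype remains
    (``roi_parent``).  Balanced gains (trisomy and up) cover the region
    without removing either haplotype.
    """
    rows = []
    for ev in events:
        covers = ev.chromosome == roi.chromosome and ev.start <= roi.start and ev.end >= roi.end
        homozygous = covers and ev.event_class in (
            "terminal_LOH", "gene_conversion", "UPD"
        )
        hemizygous = covers and ev.event_class in ("interstitial_deletion", "monosomy")
        if ev.event_class == "monosomy":
            # karyotype-style events carry the missing parent; the retained
            # haplotype is the other one
            retained = {"W": "Y", "Y": "W"}.get(ev.parent, "")
        else:
            retained = ev.parent
        rows.append(
            {
                "isolate_id": ev.isolate_id,
                "event_class": ev.event_class,
                "chromosome": ev.chromosome,
                "start": ev.start,
                "end": ev.end,
                "covers_roi": covers,
                "roi_homozygous": homozygous,
                "roi_hemizygous": hemizygous,
                "roi_parent": retained if (homozygous or hemizygous) else "",
            }
        )
    return pd.DataFrame(rows)


def events_from_profile(
    copies: CopyProfile, isolate_id: str = "isolate", min_run: int = 3
) -> list[Event]:
    """Convenience: segment a copy profile and classify its events."""
    return classify_events(segment_profile(copies, min_run=min_run), copies.markers, isolate_id)
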