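"""Two-channel signal normalization, copy-number calling, segmentation.

The array compares experimental DNA (Cy5) against DNA from a uniformly
heterozygous control diploid (Cy3) co-hybridized on the same slide.  The
hybridization ratio (HR) of each probe is its Cy5/Cy3 ratio normalized to
the array-wide ratio; the per-marker, per-parent HR is the mean of the two
replicate probes for that parental allele.  Empirical anchors: HR ~0.2,
1.0 and 1.5 for 0, 1 and 2 copies of a homolog -- the 0.2 floor is
cross-hybridization of the mismatched allele, and the sub-linear gain from
1 to 2 copies reflects probe saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MarkerMap

__all__ = [
    "HR_BASELINE",
    "MAX_COPIES",
    "HRProfile",
    "CopyProfile",
    "Segment",
    "expected_hr",
    "normalize_hr",
    "call_copies",
    "segment_profile",
]

#: Cross-hybridization floor: HR of a probe whose target allele is absent.
HR_BASELINE = 0.2
#: Largest modeled per-parent copy number (total ploidy capped at 5).
MAX_COPIES = 4

# Saturation curve hr(c) = b + s*c/(1 + g*c) anchored at hr(1)=1, hr(2)=1.5
# with b = 0.2: solving the two anchor equations gives g = 0.3, s = 1.04.
_SAT_S = 1.04
_SAT_G = 0.3


def expected_hr(copies):
    """Expected hybridization ratio for ``copies`` of the probed homolog.

    Saturation form ``0.2 + 1.04*c / (1 + 0.3*c)``; exactly 0.2, 1.0, 1.5
    at 0, 1, 2 copies and strictly increasing up to the 4-copy cap.
    Accepts scalars or arrays.
    """
    c = np.asarray(copies)
    if np.any((c < 0) | (c > MAX_COPIES)):
        raise ValueError(f"copies must be in 0..{MAX_COPIES}")
    out = HR_BASELINE + _SAT_S * c / (1.0 + _SAT_G * c)
    return float(out) if np.isscalar(copies) else out


# Geometric midpoints between adjacent expected HRs: thresholds for
# log-space nearest-level calling (ratio noise is multiplicative).
_LEVELS = expected_hr(np.arange(MAX_COPIES + 1))
_THRESHOLDS = np.sqrt(_LEVELS[:-1] * _LEVELS[1:])


@dataclass
class HRProfile:
    """Per-marker, per-parent normalized hybridization ratios.

    ``hr`` has shape (n_markers, 2); column 0 is parent W, column 1 is Y,
    rows in the canonical marker order of ``markers``.
    """

    hr: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        if self.hr.shape != (len(self.markers), 2):
            raise ValueError("hr must be (n_markers, 2)")
        if not np.all(np.isfinite(self.hr)) or np.any(self.hr < 0):
            raise ValueError("hr values must be finite and nonnegative")


@dataclass
class CopyProfile:
    """Called integer copies of each parental homolog per marker."""

    copies: np.ndarray  # (n_markers, 2) ints, column 0 = W, 1 = Y
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if self.copies.shape != (len(self.markers), 2):
            raise ValueError("copies must be (n_markers, 2)")
        if np.any(self.copies < 0) or np.any(self.copies > MAX_COPIES):
            raise ValueError(f"copies must be in 0..{MAX_COPIES}")

    def states(self) -> list[tuple[int, int]]:
        return [tuple(row) for row in self.copies]


@dataclass(frozen=True)
class Segment:
    """Maximal run of markers sharing one (copies_W, copies_Y) state.

    ``first``/``last`` are row indices into the marker map; boundary
    intervals are open (bp, bp) intervals bracketing the state change, the
    outer ones clamped to the chromosome ends.
    """

    chromosome: str
    first: int
    last: int
    state: tuple[int, int]
    left_boundary: tuple[int, int]
    right_boundary: tuple[int, int]

    @property
    def n_markers(self) -> int:
        return self.last - self.first + 1


def normalize_hr(signals: pd.DataFrame, markers: MarkerMap) -> HRProfile:
    """Normalize raw two-channel intensities to per-marker parental HRs.

    ``signals`` columns: probe_id, marker_id, target_parent, cy3, cy5 (one
    array, i.e. one isolate).  Each probe's Cy5/Cy3 ratio is divided by the
    median ratio over all probes on the array; the median (rather than the
    mean) keeps the normalizer anchored to the heterozygous majority even
    when large events shift part of the genome.  Per-marker per-parent HR
    is the arithmetic mean of the two replicate probes.
    """
    cy3 = signals["cy3"].to_numpy(dtype=float)
    cy5 = signals["cy5"].to_numpy(dtype=float)
    bad = np.flatnonzero((cy3 <= 0) | (cy5 <= 0))
    if bad.size:
        pid = signals["probe_id"].iloc[int(bad[0])]
        raise ValueError(f"nonpositive intensity at probe {pid}")
    ratio = cy5 / cy3
    ratio = ratio / np.median(ratio)

    # canonical probe order: per marker W1, W2, Y1, Y2 (as emitted by
    # build_probe_set / simulate_signals); fall back to a merge otherwise
    n = len(markers)
    if len(signals) == 4 * n and np.array_equal(
        signals["marker_id"].to_numpy()[::4], markers.table["marker_id"].to_numpy()
    ):
        r = ratio.reshape(n, 4)
        hr = np.column_stack([r[:, :2].mean(axis=1), r[:, 2:].mean(axis=1)])
    else:
        df = signals.assign(nratio=ratio)
        piv = df.pivot_table(
            index="marker_id", columns="target_parent", values="nratio", aggfunc="mean"
        )
        piv = piv.reindex(markers.table["marker_id"])
        hr = piv[["W", "Y"]].to_numpy()
    return HRProfile(hr, markers)


def call_copies(profile: HRProfile) -> CopyProfile:
    """Assign each per-parent HR the copy level nearest in log space.

    Equivalent to thresholding at geometric midpoints of adjacent expected
    HRs; exact midpoints break toward the lower copy number.
    """
    calls = np.searchsorted(_THRESHOLDS, profile.hr, side="left")
    return CopyProfile(calls, profile.markers)


def _runs(values: list[tuple[int, int]]) -> list[tuple[int, int, tuple[int, int]]]:
    """Run-length encode: list of (first_idx, last_idx, state)."""
    out = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            out.append((start, i - 1, values[start]))
            start = i
    return out


def segment_profile(copies: CopyProfile, min_run: int = 3) -> list[Segment]:
    """Segment each chromosome into constant-state runs of >= min_run markers.

    Runs shorter than ``min_run`` are absorbed into the flanking run with
    more markers (ties: the preceding run), which suppresses isolated
    miscalled markers.  Short runs sandwiched between two flanks of the
    same state are absorbed first: such a blip is a lone miscall inside a
    uniform run, and healing it before anything else keeps a genuine short
    feature (e.g. a small conversion tract split by one miscalled marker)
    from being eroded flank-by-flank.  Each internal boundary is reported
    as the open bp interval between the last marker of the left run and
    the first marker of the right run -- the true breakpoint lies
    somewhere inside it.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if len(copies.markers) == 0:
        raise ValueError("empty profile")
    segments: list[Segment] = []
    for chrom in copies.markers.chrom_names_with_markers():
        sl = copies.markers.chrom_slice(chrom)
        states = [tuple(r) for r in copies.copies[sl]]
        pos = copies.markers.positions[sl]
        runs = _runs(states)
        # iteratively absorb short runs (shortest first for stability)
        while len(runs) > 1:
            lengths = [r[1] - r[0] + 1 for r in runs]
            short = [i for i, n in enumerate(lengths) if n < min_run]
            if not short:
                break

            def sandwiched(k: int) -> bool:
                return 0 < k < len(runs) - 1 and runs[k - 1][2] == runs[k + 1][2]

            i = min(short, key=lambda k: (not sandwiched(k), lengths[k], k))
            if i == 0:
                tgt = 1
            elif i == len(runs) - 1:
                tgt = i - 1
            else:
                tgt = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
            a, b = (tgt, i) if tgt < i else (i, tgt)
            merged = (runs[a][0], runs[b][1], runs[tgt][2])
            runs[a : b + 1] = [merged]
            # re-merge adjacent runs that now share a state
            j = 0
            while j < len(runs) - 1:
                if runs[j][2] == runs[j + 1][2]:
                    runs[j : j + 2] = [(runs[j][0], runs[j + 1][1], runs[j][2])]
                else:
                    j += 1
        chrom_len = copies.markers.genome[chrom].length
        for k, (first, last, state) in enumerate(runs):
            left = (0, int(pos[first])) if k == 0 else (int(pos[runs[k - 1][1]]), int(pos[first]))
            right = (
                (int(pos[last]), chrom_len + 1)
                if k == len(runs) - 1
                else (int(pos[last]), int(pos[runs[k + 1][0]]))
            )
            segments.append(
                Segment(chrom, sl.start + first, sl.start + last, state, left, right)
            )
    return segments


def profile_from_segments(segments: list[Segment], markers: MarkerMap) -> CopyProfile:
    """Per-marker states implied by a segmentation (noise-smoothed profile)."""
    copies = np.ones((len(markers), 2), dtype=np.int64)
    for s in segments:
        copies[s.first : s.last + 1] = s.state
    return CopyProfile(copies, markers)


def segments_to_frame(segments: list[Segment], markers: MarkerMap) -> pd.DataFrame:
    """Tabular view of segments with 1-based coordinates."""
    pos = markers.positions
    return pd.DataFrame(
        {
            "chrom": [s.chromosome for s in segments],
            "start": [int(pos[s.first]) for s in segments],
            "end": [int(pos[s.last]) for s in segments],
            "copies_W": [s.state[0] for s in segments],
            "copies_Y": [s.state[1] for s in segments],
            "n_markers": [s.n_markers for s in segments],
            "left_bound_lo": [s.left_boundary[0] for s in segments],
            "left_bound_hi": [s.left_boundary[1] for s in segments],
            "right_bound_lo": [s.right_boundary[0] for s in segments],
            "right_bound_hi": [s.right_boundary[1] for s in segments],
        }
    )
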