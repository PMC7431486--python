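"""Diploid genome model, SNP marker maps, and probe layout.

The experimental system is a diploid *Saccharomyces cerevisiae* hybrid of
two sequenced haploids ("W", a W303-1A-like parent, and "Y", a
YJM789-like parent) that is heterozygous at thousands of SNPs genome-wide.
Two custom allele-specific array designs are modeled:

* ``whole_genome`` -- roughly 13,000 markers spread over all 16 chromosomes
  in proportion to chromosome length;
* ``chr4_specific`` -- 2,300 densely spaced markers on the 1.1 Mb arrayed
  span of the chromosome IV right arm (giving ~0.5 kb breakpoint
  resolution) plus sparse markers elsewhere for karyotyping.

Each marker is interrogated by four 25-mer probes, two specific to each
parental allele.  Coordinates are 1-based inclusive throughout (SGD
convention); BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeMap",
    "MarkerMap",
    "ProbeSet",
    "RegionOfInterest",
    "SSD1",
    "CHR4_DENSE_ARM_SPAN",
    "build_default_genome",
    "build_marker_map",
    "build_probe_set",
    "mean_resolution",
]

#: Arrayed span of the chr IV right arm on the dense design (bp).
CHR4_DENSE_ARM_SPAN = 1_100_000

# sacCer3 chromosome lengths and centromere midpoints (bp, 1-based).
_SACCER3 = [
    ("I", 230_218, 151_465),
    ("II", 813_184, 238_207),
    ("III", 316_620, 114_385),
    ("IV", 1_531_933, 449_711),
    ("V", 576_874, 151_987),
    ("VI", 270_161, 148_510),
    ("VII", 1_090_940, 496_920),
    ("VIII", 562_643, 105_586),
    ("IX", 439_888, 355_629),
    ("X", 745_751, 436_307),
    ("XI", 666_816, 440_129),
    ("XII", 1_078_177, 150_828),
    ("XIII", 924_431, 268_031),
    ("XIV", 784_333, 628_758),
    ("XV", 1_091_291, 326_584),
    ("XVI", 948_066, 555_957),
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"centromere of chr {self.name} must lie strictly inside "
                f"(got {self.centromere} on length {self.length})"
            )


@dataclass(frozen=True)
class GenomeMap:
    """Ordered set of the 16 yeast chromosomes."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.names,
                "length": [c.length for c in self.chromosomes],
                "centromere": [c.centromere for c in self.chromosomes],
            }
        )


@dataclass(frozen=True)
class RegionOfInterest:
    """A named 1-based inclusive interval, e.g. a gene locus."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"ROI {self.name}: start > end")


#: SSD1 locus on the chr IV right arm; homozygosity for the Y-derived
#: (functional) allele here is the candidate driver of ethanol tolerance.
SSD1 = RegionOfInterest("SSD1", "IV", 1_045_640, 1_049_392)


@dataclass
class MarkerMap:
    """Ordered heterozygous SNP positions with parental allele labels.

    ``table`` has columns ``marker_id, chrom, pos, allele_W, allele_Y``
    sorted by (chromosome order, position); positions are unique within a
    chromosome.  The row order of this table is the canonical marker order
    used by every downstream array (genotypes, HR profiles, copy calls).
    """

    table: pd.DataFrame
    genome: GenomeMap
    _chrom_slices: dict[str, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        req = {"marker_id", "chrom", "pos", "allele_W", "allele_Y"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"marker table missing columns {sorted(missing)}")
        order = {name: i for i, name in enumerate(self.genome.names)}
        chrom_idx = self.table["chrom"].map(order)
        if chrom_idx.isna().any():
            bad = self.table.loc[chrom_idx.isna(), "chrom"].unique()
            raise ValueError(f"markers on unknown chromosomes: {list(bad)}")
        key = chrom_idx.to_numpy() * 10**9 + self.table["pos"].to_numpy()
        if not np.all(np.diff(key) > 0):
            raise ValueError("markers must be sorted with unique positions")
        self.table = self.table.reset_index(drop=True)
        for name in self.genome.names:
            idx = np.flatnonzero((self.table["chrom"] == name).to_numpy())
            if idx.size:
                self._chrom_slices[name] = slice(int(idx[0]), int(idx[-1]) + 1)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def chrom_slice(self, name: str) -> slice:
        """Contiguous row slice of markers on one chromosome."""
        if name not in self._chrom_slices:
            raise KeyError(f"no markers on chromosome {name}")
        return self._chrom_slices[name]

    def chrom_names_with_markers(self) -> list[str]:
        return [n for n in self.genome.names if n in self._chrom_slices]

    def marker_indices(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Row indices of markers within [start, end] on a chromosome."""
        sl = self.chrom_slice(chromosome)
        pos = self.positions[sl]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return np.arange(sl.start + lo, sl.start + hi)


@dataclass(frozen=True)
class ProbeSet:
    """Four allele-specific probes per marker, two per parent.

    ``table`` columns: ``probe_id, marker_id, target_parent`` with rows in
    marker order, replicate probes adjacent (W1, W2, Y1, Y2).
    """

    table: pd.DataFrame
    n_markers: int

    def __post_init__(self) -> None:
        counts = self.table.groupby("marker_id", sort=False)["target_parent"].agg(
            lambda s: (list(s).count("W"), list(s).count("Y"))
        )
        if not all(c == (2, 2) for c in counts):
            raise ValueError("each marker needs exactly 2 W and 2 Y probes")


def build_default_genome() -> GenomeMap:
    """The 16 sacCer3 chromosomes with fixed lengths and centromeres."""
    return GenomeMap(tuple(Chromosome(*row) for row in _SACCER3))


def chr4_dense_arm(genome: GenomeMap) -> tuple[int, int]:
    """1-based inclusive span of the dense array region on chr IV.

    The arrayed span is 1.1 Mb ending at the right telomere; it covers the
    whole right arm plus a short centromere-proximal stretch.
    """
    chr4 = genome["IV"]
    return chr4.length - CHR4_DENSE_ARM_SPAN + 1, chr4.length


def _uniform_positions(
    start: int, end: int, n: int, rng: np.random.Generator | None, jitter: float
) -> np.ndarray:
    """n positions evenly spaced over [start, end], optionally jittered.

    Jitter displaces each marker by up to ``jitter`` times the nominal gap,
    preserving order and uniqueness.
    """
    if n <= 0:
        raise ValueError("marker count must be positive")
    if n == 1:
        return np.array([(start + end) // 2], dtype=np.int64)
    pos = np.linspace(start, end, n)
    if jitter > 0:
        if rng is None:
            raise ValueError("jitter requires a seeded rng")
        gap = (end - start) / (n - 1)
        pos = pos + rng.uniform(-jitter * gap, jitter * gap, size=n)
    pos = np.clip(np.round(pos).astype(np.int64), start, end)
    # enforce strictly increasing (collisions only possible at extreme jitter)
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def build_marker_map(
    genome: GenomeMap,
    design: str = "whole_genome",
    seed: int | None = 0,
    n_whole_genome: int = 13_000,
    n_dense: int = 2_300,
    sparse_per_chrom: int = 20,
    jitter: float = 0.0,
) -> MarkerMap:
    """Lay out heterozygous SNP markers for one of the two array designs.

    ``whole_genome`` distributes ``n_whole_genome`` markers across all
    chromosomes proportionally to length.  ``chr4_specific`` places
    ``n_dense`` markers on the 1.1 Mb chr IV dense arm and
    ``sparse_per_chrom`` markers on every other chromosome (and on the
    non-arrayed part of chr IV), enough to karyotype whole-chromosome
    events.  Markers are evenly spaced; ``jitter`` (fraction of the nominal
    gap, default off) perturbs positions reproducibly from ``seed``.
    """
    if design not in ("whole_genome", "chr4_specific"):
        raise ValueError(f"unknown design {design!r}")
    if n_whole_genome <= 0 or n_dense <= 0 or sparse_per_chrom <= 0:
        raise ValueError("marker counts must be positive")
    rng = np.random.default_rng(seed)

    rows: list[tuple[str, np.ndarray]] = []
    if design == "whole_genome":
        total = genome.total_length
        for c in genome.chromosomes:
            n_c = max(2, int(round(n_whole_genome * c.length / total)))
            pad = max(1, c.length // (n_c + 1) // 2)
            rows.append((c.name, _uniform_positions(pad, c.length - pad, n_c, rng, jitter)))
    else:
        dense_start, dense_end = chr4_dense_arm(genome)
        for c in genome.chromosomes:
            if c.name == "IV":
                sparse = _uniform_positions(
                    5_000, dense_start - 5_000, sparse_per_chrom, rng, jitter
                )
                dense = _uniform_positions(dense_start, dense_end, n_dense, rng, jitter)
                rows.append((c.name, np.concatenate([sparse, dense])))
            else:
                pad = max(1, c.length // (sparse_per_chrom + 1) // 2)
                rows.append(
                    (c.name, _uniform_positions(pad, c.length - pad, sparse_per_chrom, rng, jitter))
                )

    chroms = np.concatenate([np.repeat(name, len(p)) for name, p in rows])
    positions = np.concatenate([p for _, p in rows])
    n = len(positions)
    a_w = rng.integers(0, 4, size=n)
    a_y = (a_w + rng.integers(1, 4, size=n)) % 4  # always differs from W
    table = pd.DataFrame(
        {
            "marker_id": [f"m{i:05d}" for i in range(n)],
            "chrom": chroms,
            "pos": positions,
            "allele_W": _BASES[a_w],
            "allele_Y": _BASES[a_y],
        }
    )
    return MarkerMap(table, genome)


def build_probe_set(markers: MarkerMap) -> ProbeSet:
    """Four probes per marker: replicates 1 and 2 for each parental allele."""
    ids = markers.table["marker_id"].to_numpy()
    probe_id = np.char.add(
        np.repeat(ids, 4).astype(str), np.tile(["_W1", "_W2", "_Y1", "_Y2"], len(ids))
    )
    table = pd.DataFrame(
        {
            "probe_id": probe_id,
            "marker_id": np.repeat(ids, 4),
            "target_parent": np.tile(["W", "W", "Y", "Y"], len(ids)),
        }
    )
    return ProbeSet(table, n_markers=len(ids))


def mean_resolution(markers: MarkerMap, chromosome: str, arm: str = "right") -> float:
    """Mean adjacent-marker gap (bp) on one chromosome arm.

    This is the expected width of a breakpoint localization interval: a
    state transition is bracketed by the two markers flanking it.
    """
    if arm not in ("left", "right", "both"):
        raise ValueError("arm must be left, right or both")
    cen = markers.genome[chromosome].centromere
    sl = markers.chrom_slice(chromosome)
    pos = markers.positions[sl]
    if arm == "left":
        pos = pos[pos <= cen]
    elif arm == "right":
        pos = pos[pos > cen]
    if len(pos) < 2:
        raise ValueError(f"fewer than 2 markers on chr {chromosome} {arm} arm")
    return float(np.mean(np.diff(pos)))
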