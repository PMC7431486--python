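"""Reference event tallies and synthetic cohort builders.

The heat-shock instability screen this package models reports its results
as aggregate event tallies: per-class LOH counts in 21 heat-shocked
isolates, per-class aneuploidy counts in the same isolates and in 40
carbendazim-treated isolates, and the tract-pattern breakdown of 16
sectored-colony crossovers.  The per-isolate coordinates behind those
tallies are not part of the printed record, so the builders here expand
each tally into a concrete synthetic roster: event classes and counts are
fixed by the tally, while isolates, chromosomes, positions and parental
orientations are drawn reproducibly from a seed.

Recovering the tallies from signals simulated off these rosters is the
pipeline's end-to-end regression check.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeMap, chr4_dense_arm
from .simulate import EventSpec, SectorPairSpec

__all__ = [
    "HEAT_LOH_TALLY",
    "HEAT_ANEUPLOIDY_TALLY",
    "CARBENDAZIM_ANEUPLOIDY_TALLY",
    "TRACT_PATTERN_TALLY",
    "SECTOR_ANEUPLOIDY",
    "SPONTANEOUS_LOH",
    "SPONTANEOUS_ANEUPLOIDY",
    "MONOSOMY_TRISOMY_TABLE",
    "heat_loh_roster",
    "heat_aneuploidy_roster",
    "carbendazim_roster",
    "tract_roster",
    "ethanol_tolerant_roster",
]

#: LOH events called in the 21 heat-shocked isolates (17 total).
HEAT_LOH_TALLY = {"gene_conversion": 11, "terminal_LOH": 5, "interstitial_deletion": 1}

#: Whole-chromosome events in the same 21 isolates (34 total), spread over
#: 11 aneuploid isolates.
HEAT_ANEUPLOIDY_TALLY = {
    "trisomy": 26,
    "UPD": 4,
    "monosomy": 2,
    "pentasomy": 1,
    "tetrasomy": 1,
}
HEAT_N_ISOLATES = 21
HEAT_N_ANEUPLOID_ISOLATES = 11

#: Whole-chromosome events in the 40 carbendazim-treated isolates
#: (68 total); 25 of the 27 UPDs concentrate in two UPD-rich isolates.
CARBENDAZIM_ANEUPLOIDY_TALLY = {
    "monosomy": 28,
    "trisomy": 9,
    "tetrasomy": 4,
    "UPD": 27,
}
CARBENDAZIM_N_ISOLATES = 40
CARBENDAZIM_N_ANEUPLOID_ISOLATES = 18
CARBENDAZIM_UPD_RICH = {"MT3": 13, "MT12": 12}

#: Terminal LOH events seen alongside the carbendazim aneuploidies.
CARBENDAZIM_TERMINAL_LOH_CHROMS = ["II", "II", "IV", "IV", "IV", "VII", "VII", "VII", "X", "XVI"]

#: Tract-pattern breakdown of the 16 mapped sectored-colony crossovers.
TRACT_PATTERN_TALLY = {"no_tract": 4, "three_to_one": 7, "complex": 5}

#: Whole-chromosome events in the sectored colonies: monosomic and
#: trisomic chromosomes, three of them as paired nondisjunctions (chr III).
SECTOR_ANEUPLOIDY = {"monosomy": ["III", "IX", "VI"], "trisomy": ["III", "IX", "VI", "VIII", "XVI"]}

#: Spontaneous baselines from published wild-type screens:
#: (n_events, n_isolates, divisions_per_isolate).
SPONTANEOUS_LOH = (10, 10, 500)  # 10 events over 5,000 divisions
SPONTANEOUS_ANEUPLOIDY = (31, 1, 311_000)  # 31 events over ~311,000 divisions

#: 2x2 monosomy/trisomy counts: rows heat shock, carbendazim.
MONOSOMY_TRISOMY_TABLE = [[2, 26], [28, 9]]

#: Ethanol-tolerant isolates: 7 events in 5 mutants, 5 of them on chr IV
#: (1 UPD + 4 terminal LOH) all leaving the right arm homozygous Y.
#: Synthetic stand-in roster: the two non-chr IV events are placed
#: arbitrarily (a conversion and a trisomy).


def _parents(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(["W", "Y"], size=n))


def heat_loh_roster(genome: GenomeMap, seed: int = 0) -> list[EventSpec]:
    """Expand the 17-event LOH tally into 21 whole-genome isolates.

    Gene-conversion tracts are 5-20 kb, the deletion 10 kb, terminal LOH
    from a mid-arm position to the chromosome end; every event gets its
    own (isolate, chromosome) slot so events never overlap.
    """
    rng = np.random.default_rng(seed)
    isolates = [f"JP{i}" for i in range(1, HEAT_N_ISOLATES + 1)]
    classes = (
        ["gene_conversion"] * HEAT_LOH_TALLY["gene_conversion"]
        + ["terminal_LOH"] * HEAT_LOH_TALLY["terminal_LOH"]
        + ["interstitial_deletion"] * HEAT_LOH_TALLY["interstitial_deletion"]
    )
    used: set[tuple[str, str]] = set()
    events = []
    for k, cls in enumerate(classes):
        iso = isolates[k % HEAT_N_ISOLATES]
        chrom = None
        for name in rng.permutation(genome.names):
            if (iso, name) not in used:
                chrom = genome[str(name)]
                break
        used.add((iso, chrom.name))
        parent = "W" if rng.random() < 0.5 else "Y"
        if cls == "terminal_LOH":
            start = int(rng.integers(chrom.centromere + 10_000, chrom.length - 50_000))
            events.append(EventSpec(iso, cls, chrom.name, start, chrom.length, parent))
        else:
            span = 10_000 if cls == "interstitial_deletion" else int(rng.integers(5_000, 20_000))
            start = int(rng.integers(50_000, chrom.length - span - 50_000))
            events.append(EventSpec(iso, cls, chrom.name, start, start + span, parent))
    return events


def _spread_aneuploidies(
    tally: dict[str, int],
    isolate_ids: list[str],
    carrier_ids: list[str],
    genome: GenomeMap,
    rng: np.random.Generator,
    exclude_chroms: tuple[str, ...] = (),
    preassigned: dict[str, list[str]] | None = None,
) -> list[EventSpec]:
    """Distribute whole-chromosome events over carrier isolates.

    ``preassigned`` maps isolate -> list of classes fixed to that isolate
    (used for the UPD-rich carbendazim mutants); remaining events cycle
    over the carriers.  Each isolate receives at most one event per
    chromosome.
    """
    pool = [c for c in genome.names if c not in exclude_chroms]
    per_isolate: dict[str, list[str]] = {i: [] for i in isolate_ids}
    events: list[EventSpec] = []
    remaining = {k: v for k, v in tally.items()}

    def place(iso: str, cls: str) -> None:
        free = [c for c in pool if c not in per_isolate[iso]]
        chrom = str(rng.choice(free))
        per_isolate[iso].append(chrom)
        if cls == "tetrasomy":
            parent = str(rng.choice(["W", "Y", "WY"]))
        else:
            parent = str(rng.choice(["W", "Y"]))
        events.append(EventSpec(iso, cls, chrom, parent=parent))

    if preassigned:
        for iso, classes in preassigned.items():
            for cls in classes:
                place(iso, cls)
                remaining[cls] -= 1

    flat = [cls for cls, n in remaining.items() for _ in range(n)]
    carriers = [i for i in carrier_ids if not (preassigned and i in preassigned)]
    for k, cls in enumerate(flat):
        place(carriers[k % len(carriers)], cls)
    return events


def heat_aneuploidy_roster(genome: GenomeMap, seed: int = 0) -> list[EventSpec]:
    """Expand the 34-event aneuploidy tally over 11 of 21 heat isolates."""
    rng = np.random.default_rng(seed)
    isolates = [f"JP{i}" for i in range(1, HEAT_N_ISOLATES + 1)]
    carriers = list(rng.choice(isolates, size=HEAT_N_ANEUPLOID_ISOLATES, replace=False))
    return _spread_aneuploidies(HEAT_ANEUPLOIDY_TALLY, isolates, carriers, genome, rng)


def carbendazim_roster(
    genome: GenomeMap, seed: int = 0, include_loh: bool = True
) -> list[EventSpec]:
    """Expand the carbendazim tallies over 40 chr4-array isolates.

    The two UPD-rich mutants take 25 of the 27 UPDs; the other aneuploid
    isolates share the rest.  Chr IV is kept euploid (its segmental events
    are the terminal LOH entries), so the dense arm stays a valid
    normalization anchor on the chr IV-specific design.
    """
    rng = np.random.default_rng(seed)
    isolates = [f"MT{i}" for i in range(1, CARBENDAZIM_N_ISOLATES + 1)]
    preassigned = {iso: ["UPD"] * n for iso, n in CARBENDAZIM_UPD_RICH.items()}
    others = [i for i in isolates if i not in preassigned]
    n_other_carriers = CARBENDAZIM_N_ANEUPLOID_ISOLATES - len(preassigned)
    carriers = list(rng.choice(others, size=n_other_carriers, replace=False))
    events = _spread_aneuploidies(
        CARBENDAZIM_ANEUPLOIDY_TALLY,
        isolates,
        list(preassigned) + carriers,
        genome,
        rng,
        exclude_chroms=("IV",),
        preassigned=preassigned,
    )
    if include_loh:
        aneuploid_chroms = {(e.isolate_id, e.chromosome) for e in events}
        k = 0
        for chrom_name in CARBENDAZIM_TERMINAL_LOH_CHROMS:
            chrom = genome[chrom_name]
            while (isolates[k % len(isolates)], chrom_name) in aneuploid_chroms:
                k += 1
            iso = isolates[k % len(isolates)]
            k += 1
            if chrom_name == "IV":
                dense_start, _ = chr4_dense_arm(genome)
                start = int(rng.integers(dense_start + 100_000, chrom.length - 200_000))
            else:
                start = int(rng.integers(chrom.centromere + 10_000, chrom.length - 50_000))
            parent = "W" if rng.random() < 0.5 else "Y"
            events.append(EventSpec(iso, "terminal_LOH", chrom_name, start, chrom.length, parent))
    return events


def tract_roster(genome: GenomeMap, seed: int = 0) -> list[SectorPairSpec]:
    """16 sectored-colony crossover specs matching the tract-pattern tally.

    Breakpoints are spread over the chr IV dense arm; tract lengths are
    drawn from 4-8 kb (tract-length distributions are not part of the
    printed record -- these are free simulation parameters).
    """
    rng = np.random.default_rng(seed)
    dense_start, dense_end = chr4_dense_arm(genome)
    lo = dense_start + 60_000
    hi = dense_end - 60_000
    n = sum(TRACT_PATTERN_TALLY.values())
    breakpoints = np.linspace(lo, hi, n).astype(int)
    phases = (
        ["none"] * TRACT_PATTERN_TALLY["no_tract"]
        + ["S_G2"] * TRACT_PATTERN_TALLY["three_to_one"]
        + ["G1"] * TRACT_PATTERN_TALLY["complex"]
    )
    order = rng.permutation(n)
    specs = []
    for k, idx in enumerate(order):
        phase = phases[int(idx)]
        span = 0 if phase == "none" else int(rng.integers(4_000, 8_000))
        specs.append(
            SectorPairSpec(
                mechanism="reciprocal_crossover",
                dsb_phase=phase,
                breakpoint=int(breakpoints[k]),
                tract_span=span,
                core_span=2_000,
            )
        )
    return specs


def ethanol_tolerant_roster(genome: GenomeMap, seed: int = 0) -> list[EventSpec]:
    """Synthetic roster for the five ethanol-tolerant mutants (7 events).

    Five events sit on chr IV -- one UPD and four terminal LOH of the
    right arm -- all leaving the arm (and the SSD1 locus on it)
    homozygous for the Y-derived haplotype.  The remaining two events are
    synthetic placeholders on other chromosomes.
    """
    rng = np.random.default_rng(seed)
    chr4 = genome["IV"]
    events = [EventSpec("E1", "UPD", "IV", parent="Y")]
    for k, iso in enumerate(["E2", "E3", "E4", "E5"], start=0):
        start = int(rng.integers(chr4.centromere + 10_000, 1_000_000))
        events.append(EventSpec(iso, "terminal_LOH", "IV", start, chr4.length, "Y"))
    events.append(EventSpec("E2", "gene_conversion", "VII", 400_000, 410_000, "W"))
    events.append(EventSpec("E4", "trisomy", "IX", parent="Y"))
    return events
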