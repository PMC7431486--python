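"""Ground-truth genotype simulation and two-channel signal synthesis.

Generates per-isolate homolog copy matrices with implanted genetic events
(LOH tracts, deletions, uniparental disomy, whole-chromosome aneuploidy),
then renders them as raw two-channel probe intensities with the
statistical structure the calling pipeline assumes.  Also simulates the
two sectors of a white/red colony arising from a single first-division
recombination or missegregation event, and colony plating counts.

Noise model
-----------
Each probe spot carries a lognormal spot-level factor of scale ``sigma``
(variation in deposited oligo and local hybridization conditions) that
multiplies *both* channels and therefore cancels in the Cy5/Cy3 ratio --
this is the point of co-hybridized two-colour designs.  Each channel
additionally carries an independent lognormal residual of scale
``channel_noise_fraction * sigma`` (dye incorporation and scanner noise)
that does not cancel.  At the defaults (sigma 0.15, fraction 0.25) the
per-probe ratio has log-sd ~0.053, small enough that per-marker genotype
calls on a heterozygous genome are >99% accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap, MarkerMap, ProbeSet, build_probe_set, chr4_dense_arm
from .signal import MAX_COPIES, expected_hr

__all__ = [
    "EVENT_CLASSES",
    "EventSpec",
    "GenotypeMatrix",
    "NoiseModel",
    "SectorPairSpec",
    "implant_events",
    "simulate_signals",
    "simulate_sector_pair",
    "simulate_plating",
]

EVENT_CLASSES = (
    "terminal_LOH",
    "gene_conversion",
    "interstitial_deletion",
    "UPD",
    "monosomy",
    "trisomy",
    "tetrasomy",
    "pentasomy",
)

#: Classes whose span is forced to the whole chromosome.
WHOLE_CHROM_CLASSES = ("UPD", "monosomy", "trisomy", "tetrasomy", "pentasomy")


@dataclass(frozen=True)
class EventSpec:
    """One genetic event to implant into one isolate.

    ``parent`` is the retained parent for terminal_LOH, gene_conversion,
    interstitial_deletion, UPD and monosomy, and the gained parent for
    trisomy and pentasomy.  Tetrasomy accepts "W"/"Y" for the unbalanced
    (3,1)/(1,3) forms or "WY" for the balanced (2,2) form.  ``start`` and
    ``end`` (1-based inclusive) are ignored for whole-chromosome classes.
    """

    isolate_id: str
    event_class: str
    chromosome: str
    start: int = 0
    end: int = 0
    parent: str = "Y"

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        ok_parents = ("W", "Y", "WY") if self.event_class == "tetrasomy" else ("W", "Y")
        if self.parent not in ok_parents:
            raise ValueError(f"parent must be one of {ok_parents}")


def _event_state(ev: EventSpec) -> tuple[int, int]:
    """(copies_W, copies_Y) that the event writes across its span."""
    w_first = ev.parent == "W"

    def oriented(a: int, b: int) -> tuple[int, int]:
        return (a, b) if w_first else (b, a)

    return {
        "terminal_LOH": oriented(2, 0),
        "gene_conversion": oriented(2, 0),
        "interstitial_deletion": oriented(1, 0),
        "UPD": oriented(2, 0),
        "monosomy": oriented(1, 0),
        "trisomy": oriented(2, 1),  # gained parent carries 2 copies
        "tetrasomy": (2, 2) if ev.parent == "WY" else oriented(3, 1),
        "pentasomy": oriented(3, 2),  # gained parent gets 3
    }[ev.event_class]


@dataclass
class GenotypeMatrix:
    """Per-isolate, per-marker integer copies of each parental homolog.

    ``copies[isolate]`` is an (n_markers, 2) int array, column 0 = W,
    column 1 = Y, rows in canonical marker order.  The unedited state is
    (1, 1) everywhere: a heterozygous diploid.
    """

    markers: MarkerMap
    copies: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def baseline(cls, markers: MarkerMap, isolate_ids: list[str]) -> "GenotypeMatrix":
        n = len(markers)
        return cls(markers, {i: np.ones((n, 2), dtype=np.int64) for i in isolate_ids})

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.copies)

    def validate(self) -> None:
        for iso, arr in self.copies.items():
            if np.any(arr < 0) or np.any(arr > MAX_COPIES) or np.any(arr.sum(axis=1) > 5):
                raise ValueError(f"isolate {iso}: copies out of modeled ploidy bounds")


def implant_events(base: GenotypeMatrix, events: list[EventSpec]) -> GenotypeMatrix:
    """Apply events to a copy of ``base``, in order, left to right.

    Later events overwrite earlier ones where they overlap.  Contradictory
    compositions are rejected: a loss-type event (interstitial_deletion,
    monosomy) whose lost parent is already absent somewhere in its span
    would delete a homolog that does not exist.
    """
    out = GenotypeMatrix(base.markers, {k: v.copy() for k, v in base.copies.items()})
    for ev in events:
        if ev.isolate_id not in out.copies:
            raise ValueError(f"unknown isolate {ev.isolate_id!r}")
        if ev.chromosome not in base.markers.genome:
            raise ValueError(f"unknown chromosome {ev.chromosome!r}")
        chrom = base.markers.genome[ev.chromosome]
        if ev.event_class in WHOLE_CHROM_CLASSES:
            idx = np.arange(
                base.markers.chrom_slice(ev.chromosome).start,
                base.markers.chrom_slice(ev.chromosome).stop,
            )
        else:
            if not (1 <= ev.start <= ev.end <= chrom.length):
                raise ValueError(
                    f"event span {ev.start}-{ev.end} outside chr {ev.chromosome}"
                )
            if ev.event_class == "terminal_LOH" and ev.start > 1 and ev.end < chrom.length:
                raise ValueError("terminal_LOH span must reach a chromosome end")
            idx = base.markers.marker_indices(ev.chromosome, ev.start, ev.end)
        arr = out.copies[ev.isolate_id]
        state = _event_state(ev)
        if ev.event_class in ("interstitial_deletion", "monosomy"):
            lost_col = 1 if ev.parent == "W" else 0  # column of the lost parent
            if np.any(arr[idx, lost_col] == 0):
                raise ValueError(
                    f"contradictory events: {ev.event_class} on {ev.isolate_id} "
                    f"chr {ev.chromosome} deletes an absent homolog"
                )
        arr[idx] = state
    out.validate()
    return out


@dataclass
class NoiseModel:
    """Noise and response parameters of the simulated array.

    sigma : lognormal scale of the spot-level factor shared by both
        channels of a probe (cancels in the ratio).
    channel_noise_fraction : channel-specific residual scale as a fraction
        of sigma; this is what survives into HR noise.
    baseline_hr : cross-hybridization floor, the HR of a probe whose
        target allele is absent (0 copies).
    """

    sigma: float = 0.15
    channel_noise_fraction: float = 0.25
    baseline_hr: float = 0.2
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 < self.baseline_hr < 1):
            raise ValueError("baseline_hr must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_signals(
    genotype: GenotypeMatrix,
    probes: ProbeSet | None = None,
    noise: NoiseModel | None = None,
) -> dict[str, pd.DataFrame]:
    """Render each isolate's genotype as a raw two-channel signal table.

    Returns one table per isolate with columns probe_id, marker_id,
    target_parent, cy3, cy5.  The experimental-channel intensity of a
    probe targeting parent P at a marker carrying c copies of P is
    proportional to ``expected_hr(c)`` times noise; the control channel
    reflects the uniformly heterozygous control genome.  Fully reproducible
    from ``noise.seed``.
    """
    if probes is None:
        probes = build_probe_set(genotype.markers)
    if noise is None:
        noise = NoiseModel()
    rng = noise.rng()
    out = {}
    for iso in genotype.isolate_ids:
        c = genotype.copies[iso]
        # per-probe copies in the probe layout order W1 W2 Y1 Y2
        cc = np.repeat(c, 2, axis=1)
        out[iso] = _render_one_probes(cc, probes, rng, noise)
    return out


def _render_one_probes(
    copies4: np.ndarray, probes: ProbeSet, rng: np.random.Generator, noise: NoiseModel
) -> pd.DataFrame:
    n4 = copies4.size
    exp_probe = expected_hr(copies4.reshape(-1))
    base = 1000.0
    sig_ch = noise.sigma * noise.channel_noise_fraction
    spot = np.exp(rng.normal(0.0, noise.sigma, size=n4)) if noise.sigma > 0 else 1.0
    if sig_ch > 0:
        e3 = np.exp(rng.normal(0.0, sig_ch, size=n4))
        e5 = np.exp(rng.normal(0.0, sig_ch, size=n4))
    else:
        e3 = e5 = 1.0
    out = probes.table.copy()
    out["cy3"] = base * expected_hr(1) * spot * e3
    out["cy5"] = base * exp_probe * spot * e5
    return out


@dataclass(frozen=True)
class SectorPairSpec:
    """A single first-division event producing a two-sector colony.

    mechanism : reciprocal_crossover, BIR, or chromosome_loss.
    dsb_phase : G1, S_G2, or none -- for crossovers, controls the
        conversion-tract geometry; must be "none" for chromosome_loss.
    breakpoint : crossover position (bp) on the chr IV dense arm.
    tract_span : total conversion-tract length (bp).
    core_span : length of the shared 4:0 core for G1 tracts.
    chromosome : affected chromosome for chromosome_loss.
    """

    mechanism: str = "reciprocal_crossover"
    dsb_phase: str = "S_G2"
    breakpoint: int = 750_000
    tract_span: int = 5_000
    core_span: int = 2_000
    chromosome: str = "IV"

    def __post_init__(self) -> None:
        if self.mechanism not in ("reciprocal_crossover", "BIR", "chromosome_loss"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.dsb_phase not in ("G1", "S_G2", "none"):
            raise ValueError(f"unknown dsb_phase {self.dsb_phase!r}")
        if self.mechanism == "chromosome_loss" and self.dsb_phase != "none":
            raise ValueError("chromosome_loss carries no conversion tract phase")
        if self.tract_span < 0 or self.core_span < 0:
            raise ValueError("spans must be >= 0")


def sector_pair_genotypes(
    spec: SectorPairSpec, markers: MarkerMap
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (white, red) genotype arrays for a sectored colony.

    Reciprocal crossover: the white sector is homozygous Y and the red
    sector homozygous W distal to the exchange point on the chr IV right
    arm.  An S/G2-phase DSB leaves a conversion tract in one sector only
    (combined representation 3:1 across the four chromatids); a G1-phase
    DSB is replicated onto both sister chromatids, so the tract core is
    converted in both sectors (4:0), optionally flanked by 3:1 margins.
    BIR transfers the distal arm nonreciprocally: one sector converts, the
    other remains heterozygous.  Chromosome loss yields monosomy in one
    sector and the paired trisomy in the other (nondisjunction).
    """
    genome = markers.genome
    n = len(markers)
    white = np.ones((n, 2), dtype=np.int64)
    red = np.ones((n, 2), dtype=np.int64)

    if spec.mechanism == "chromosome_loss":
        idx = np.arange(
            markers.chrom_slice(spec.chromosome).start,
            markers.chrom_slice(spec.chromosome).stop,
        )
        red[idx] = (1, 0)  # lost the Y homolog
        white[idx] = (1, 2)  # gained it
        return white, red

    dense_start, dense_end = chr4_dense_arm(genome)
    if not (dense_start <= spec.breakpoint <= dense_end):
        raise ValueError("breakpoint must lie on the chr IV dense arm")
    chrom_len = genome["IV"].length

    def set_state(arr: np.ndarray, start: int, end: int, state: tuple[int, int]) -> None:
        idx = markers.marker_indices("IV", start, min(end, chrom_len))
        arr[idx] = state

    if spec.mechanism == "BIR":
        # nonreciprocal: only one lineage converts distal to the break
        set_state(white, spec.breakpoint, chrom_len, (0, 2))
        return white, red

    # reciprocal crossover
    if spec.dsb_phase == "none" or spec.tract_span == 0:
        set_state(white, spec.breakpoint, chrom_len, (0, 2))
        set_state(red, spec.breakpoint, chrom_len, (2, 0))
    elif spec.dsb_phase == "S_G2":
        # tract abuts the exchange point on the distal side, one sector only:
        # white converts from the tract start, red only distal of tract end
        t1, t2 = spec.breakpoint, spec.breakpoint + spec.tract_span
        set_state(white, t1, chrom_len, (0, 2))
        set_state(red, t2 + 1, chrom_len, (2, 0))
    else:  # G1: 4:0 core shared by both sectors, 3:1 flanks
        t1, t2 = spec.breakpoint, spec.breakpoint + spec.tract_span
        flank = max(0, (spec.tract_span - spec.core_span) // 2)
        c1, c2 = t1 + flank, t2 - flank
        set_state(white, t1, chrom_len, (0, 2))
        set_state(red, c1, c2, (0, 2))
        set_state(red, t2 + 1, chrom_len, (2, 0))
    return white, red


def simulate_sector_pair(
    spec: SectorPairSpec, markers: MarkerMap, noise: NoiseModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signal tables for the (white, red) sectors of one colony."""
    if noise is None:
        noise = NoiseModel()
    white, red = sector_pair_genotypes(spec, markers)
    gm = GenotypeMatrix(markers, {"white": white, "red": red})
    sig = simulate_signals(gm, noise=noise)
    return sig["white"], sig["red"]


def simulate_plating(
    n_cells: int, sectored_event_prob: float, seed: int | None = 0
) -> tuple[int, int]:
    """Plate ``n_cells`` and count colonies with a first-division event.

    Every plated cell forms a colony; each colony independently carries a
    sectoring first-division event with probability ``sectored_event_prob``
    (Bernoulli), so n_sectored/n_colonies is an unbiased frequency
    estimator.  Returns (n_colonies, n_sectored).
    """
    if not (0.0 <= sectored_event_prob <= 1.0):
        raise ValueError("probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sectored = int(rng.binomial(n_cells, sectored_event_prob))
    return n_cells, n_sectored
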