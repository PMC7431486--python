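# Methods

## System modeled

The modeled strain is a diploid hybrid of two sequenced *S. cerevisiae*
haploids, "W" (W303-1A-like) and "Y" (YJM789-like), heterozygous at every
modeled marker. Chromosome lengths and centromere positions are sacCer3
constants. Two array designs are generated:

* **whole_genome** — ~13,000 markers allocated to chromosomes in
  proportion to length, evenly spaced (optional uniform jitter of ±40% of
  the nominal gap, seeded, off by default so spacing arithmetic stays
  closed-form);
* **chr4_specific** — 2,300 markers over a 1.1 Mb span ending at the chr
  IV right telomere, plus 20 sparse markers per chromosome elsewhere for
  karyotyping. The 1.1 Mb figure is taken as the arrayed arm span; since
  the full chromosome is 1,531,933 bp with CEN4 at 449,711, the dense
  region begins at 431,934, slightly centromere-proximal of CEN4. Mean
  dense-arm spacing is 1.1 Mb / 2,300 ≈ 478 bp, which is the expected
  width of a breakpoint-localization interval.

Coordinates are 1-based inclusive throughout; BED export shifts to
0-based half-open.

## Copy→HR response

Each marker is probed by four 25-mers, two per parental allele. The
expected hybridization ratio for *c* copies of the probed homolog is a
saturating curve

    hr(c) = 0.2 + 1.04·c / (1 + 0.3·c)

anchored so that hr(0) = 0.2 (cross-hybridization floor), hr(1) = 1.0 and
hr(2) = 1.5 — the empirical anchors of this array chemistry. The two free
parameters follow analytically from the anchors. Values above 2 copies
(hr(3) ≈ 1.84, hr(4) ≈ 2.09) are an extrapolation of the same curve: no
empirical anchor exists for them, and the compression of the upper levels
is the main noise sensitivity of high-copy calling. Per-parent copies are
capped at 4 and total ploidy at 5 (pentasomy is the largest modeled
class).

## Noise model

Raw intensities are rendered as

    cy3 = A · hr(1) · exp(σ·z_spot) · exp(σ_ch·z_3)
    cy5 = A · hr(c) · exp(σ·z_spot) · exp(σ_ch·z_5)

with one standard-normal z_spot per probe shared by both channels and
independent z_3, z_5 per channel; σ = 0.15 and σ_ch = 0.25·σ by default.
The spot-level factor models variation in deposited oligo and local
hybridization efficiency; because the two channels are co-hybridized on
the same spot it cancels in the Cy5/Cy3 ratio — this cancellation is the
reason two-colour designs work. Only the channel-specific residual
(dye incorporation, scanner gain) survives into HR noise, giving a
per-probe ratio log-sd of √2·σ_ch ≈ 0.053 and a per-marker (mean of two
probes) log-sd of ≈ 0.037. At these defaults a heterozygous marker is
miscalled with probability ~10⁻⁷ and a 2-copy marker is up-miscalled to 3
with probability ~2% — the latter is what the segmentation and
concordance rules must absorb. A single σ knob with a fixed channel
fraction keeps the interface simple; both are fields of `NoiseModel`.

All randomness flows from one explicit seed per `NoiseModel`; rosters and
marker maps take their own seeds, so every analysis is reproducible from
a handful of small integers.

## Normalization and calling

Per probe, HR = (cy5/cy3) divided by the **median** ratio over all probes
on the array; per-marker per-parent HR is the arithmetic mean of the two
replicate probes. The median (not the mean) is used for the array-level
normalizer so that large events covering part of the genome do not drag
the baseline; on both designs the heterozygous majority anchors the
median at 1, and because homozygous regions contribute symmetric low
(0.2) and high (1.5) probe populations, even a sector with half the dense
arm converted keeps its median at the heterozygous level.

Copy calling assigns each per-parent HR the level 0–4 whose expected HR
is nearest in **log** space (ratio noise is multiplicative), equivalent
to thresholds at geometric midpoints of adjacent levels; exact midpoints
break toward the lower copy number.

## Segmentation

Chromosomes are segmented into maximal constant-state runs; runs shorter
than `min_run` (default 3 markers, ≈1.5 kb on the dense arm) are absorbed
into the flanking run with more markers (ties: the preceding run). Short
runs sandwiched between two flanks of the *same* state are absorbed
first: such a blip is a single miscalled marker inside a uniform run, and
healing it before anything else prevents a genuine short feature — e.g. a
four-marker 4:0 conversion core split by one 2→3 up-miscall — from being
eroded flank-by-flank into nothing. Each internal boundary is reported as
the open bp interval between the last marker of the left run and the
first marker of the right run; at zero noise this interval always
brackets the true breakpoint.

## Event classification and karyotyping

Whole-chromosome states take precedence: a chromosome whose markers
support a single non-heterozygous state becomes a UPD or aneuploidy
event; segmental rules apply otherwise. Homozygous (2,0)/(0,2) runs
reaching the chromosome's first or last marker (the array edge proxies
the telomere) are terminal LOH; interior ones are gene conversions;
hemizygous (1,0)/(0,1) runs are interstitial deletions; anything else is
flagged `complex`, never dropped.

`call_karyotype` labels a chromosome with a non-normal state only when
the modal marker state is non-(1,1), maps to a defined whole-chromosome
state, and is supported by ≥ `concordance` (default 0.9) of the
chromosome's markers. With 20 sparse markers per chromosome and the
default noise, per-marker support is ≥97% for every modeled state, so
the 0.9 threshold separates real whole-chromosome events from noise with
large margin in both directions.

Parent semantics differ deliberately between layers: an implanted
monosomy names the *retained* parent (that is what the copy table needs),
while a called monosomy reports the *missing* homolog — so a paired
nondisjunction (monosomy in one sector, trisomy in the other) shows the
same parent on both sides.

## Sector analysis and phase inference

The two sectors of a white/red colony are called and segmented
independently; the combined four-chromatid representation is the
marker-wise sum of the two segmentation-smoothed profiles. Each sector's
crossover transition is the left boundary of its terminal homozygous
segment. The conversion tract is the maximal run of non-2:2 markers
between the two transitions, quoted as the outer hull of the two
transition intervals (the flanking 2:2 markers bracket the converted
region). Pattern rules: a run of ≥2 consecutive 4:0/0:4 markers makes
the tract `complex` (G1-consistent); otherwise it is `three_to_one`
(S/G2-consistent); fewer than 2 non-2:2 markers total means `no_tract`
(phase undetermined) — one-marker "tracts" are not trusted because a
single boundary-marker miscall can shift one sector's transition by one
marker, and at 478 bp spacing a real sub-kb tract is below the array's
resolution anyway. Phase labels are emitted as `s_g2_consistent` /
`g1_consistent` rather than hard assignments: the rule is deterministic
but the biology it encodes is an inference, not an observation.

The S/G2 fraction is reported among tract-bearing events only; colonies
without a detectable tract carry no phase information.

## Synthetic cohorts

The generator's cohort builders (`lohscan.rosters`) expand the screen's
aggregate tallies into concrete rosters: 17 LOH events (11 conversions,
5 terminal, 1 deletion) over 21 whole-genome isolates; 34
whole-chromosome events (26 trisomy, 4 UPD, 2 monosomy, 1 pentasomy,
1 tetrasomy) over 11 of those 21; 68 whole-chromosome events (28
monosomy, 9 trisomy, 4 tetrasomy, 27 UPD — 25 of the UPDs in two
UPD-rich mutants) plus 10 terminal LOH over 40 chr IV-array isolates;
and 16 sectored-colony crossovers (4 no-tract, 7 S/G2, 5 G1). Classes
and counts are fixed by the tallies; isolate assignment, chromosome
choice, positions and parental orientations are seeded draws. Free
parameters not fixed by the tallies: conversion tracts 5–20 kb
(whole-genome events), sector tracts 4–8 kb with a 2 kb G1 core —
typical mitotic gene-conversion tract scales — and 25 cell divisions per
colony (a growth assumption, exposed as a parameter). In the carbendazim
cohort chr IV is kept euploid (its segmental events are the terminal LOH
entries), so the dense arm remains a valid normalization anchor on the
chr IV-specific design.

What the simulation does **not** emulate: spatial array artifacts,
print-tip or background effects (handled upstream by scanner software in
the real workflow), real probe sequences and their thermodynamics,
tract-length distributions estimated from data (unknown), selection
effects on which events survive to be scored, and colony pigment
chemistry. Passing recovery tests therefore demonstrates that the
calling logic is correct under the stated noise model, not that the
noise model captures every failure mode of real arrays.

## Statistics

Event rates are exact rationals (`fractions.Fraction`), rounded only for
reporting (one significant figure by default, e.g. 17/(21·25) = 0.0324 →
3 × 10⁻²). Fold elevations come in two flavours: exact ratios, and
ratios of the rounded rates (0.03/0.002 = 15) — the arithmetic used when
headline numbers are quoted from already-rounded rates.

Fisher's exact test enumerates the full hypergeometric support with
exact rational arithmetic; the two-tailed p sums the probabilities of
all tables (at the observed margins) no more probable than the observed
one — the convention of the classic online calculators. scipy's
implementation serves as an independent cross-check in the tests, never
as the implementation.

Karyotype clustering encodes each chromosome as its copy deviation from
disomy (monosomy −1 … pentasomy +3) with UPD at 0 plus a parallel UPD
indicator column, then complete-linkage Euclidean clustering of both
axes (deterministic given input order).

## Problem sizes and numerical choices

The test suite and analysis drivers run the full pipeline at the
screen's own scale (21 whole-genome isolates ≈ 1.1 M probes, 40 chr
IV-array isolates, 16 sector pairs); the Fisher cross-check sweeps every
2×2 table with total n ≤ 40. Degenerate inputs are defined errors:
empty profiles, non-positive intensities (reported with the offending
probe id), contradictory event compositions (deleting an absent
homolog), and tables with an empty margin (p = 1).

## Known limitations

* The copy→HR curve above 2 copies is an extrapolation; 3-vs-4-copy
  distinctions lean on a compressed (~0.063 in log space) gap and are
  the first casualty of added noise.
* `classify_events` assumes events on one chromosome do not abut; two
  adjacent implanted events that merge into one run are reported as the
  merged state, with no attempt to split them.
* Phase inference is purely geometric; it cannot distinguish a
  reciprocal crossover from a BIR event using one colony, and does not
  model heteroduplex repair direction.
* The simulated control channel is an idealized uniformly heterozygous
  genome; real control DNA carries its own events and batch structure.
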