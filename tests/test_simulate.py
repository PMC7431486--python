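import numpy as np
import pytest

from lohscan import (
    EventSpec,
    GenotypeMatrix,
    NoiseModel,
    SectorPairSpec,
    implant_events,
    simulate_plating,
    simulate_sector_pair,
    simulate_signals,
)
from lohscan.simulate import sector_pair_genotypes

# (class, parent) -> expected (copies_W, copies_Y) across the span
STATE_TABLE = {
    ("terminal_LOH", "W"): (2, 0),
    ("terminal_LOH", "Y"): (0, 2),
    ("gene_conversion", "W"): (2, 0),
    ("gene_conversion", "Y"): (0, 2),
    ("interstitial_deletion", "W"): (1, 0),
    ("interstitial_deletion", "Y"): (0, 1),
    ("UPD", "W"): (2, 0),
    ("UPD", "Y"): (0, 2),
    ("monosomy", "W"): (1, 0),
    ("monosomy", "Y"): (0, 1),
    ("trisomy", "W"): (2, 1),
    ("trisomy", "Y"): (1, 2),
    ("tetrasomy", "W"): (3, 1),
    ("tetrasomy", "Y"): (1, 3),
    ("tetrasomy", "WY"): (2, 2),
    ("pentasomy", "W"): (3, 2),
    ("pentasomy", "Y"): (2, 3),
}


class TestImplantEvents:
    def test_empty_event_list_is_identity(self, baseline_one):
        out = implant_events(baseline_one, [])
        assert np.array_equal(out.copies["iso"], baseline_one.copies["iso"])
        assert np.all(baseline_one.copies["iso"] == 1)

    def test_trisomy_chr8_sets_all_markers_1_2(self, baseline_one, markers_small):
        out = implant_events(baseline_one, [EventSpec("iso", "trisomy", "VIII", parent="Y")])
        sl = markers_small.chrom_slice("VIII")
        assert np.all(out.copies["iso"][sl] == (1, 2))
        other = np.ones(len(markers_small), dtype=bool)
        other[sl] = False
        assert np.all(out.copies["iso"][other] == 1)

    @pytest.mark.parametrize("cls,parent", sorted(STATE_TABLE))
    def test_every_class_matches_its_copy_table(self, baseline_one, markers_small, cls, parent):
        whole = cls in ("UPD", "monosomy", "trisomy", "tetrasomy", "pentasomy")
        chrom = markers_small.genome["VII"]
        ev = (
            EventSpec("iso", cls, "VII", parent=parent)
            if whole
            else EventSpec(
                "iso", cls, "VII",
                chrom.length - 200_000 if cls == "terminal_LOH" else 300_000,
                chrom.length if cls == "terminal_LOH" else 500_000,
                parent,
            )
        )
        out = implant_events(baseline_one, [ev])
        idx = (
            np.arange(markers_small.chrom_slice("VII").start, markers_small.chrom_slice("VII").stop)
            if whole
            else markers_small.marker_indices("VII", ev.start, ev.end)
        )
        assert idx.size > 0
        # brute-force recomputation of totals across the span
        got = out.copies["iso"][idx]
        assert np.all(got == STATE_TABLE[(cls, parent)])

    def test_upd_preserves_total_copies(self, baseline_one, markers_small):
        out = implant_events(baseline_one, [EventSpec("iso", "UPD", "X", parent="Y")])
        sl = markers_small.chrom_slice("X")
        totals = out.copies["iso"][sl].sum(axis=1)
        assert np.all(totals == 2)
        assert np.all(out.copies["iso"][sl, 0] == 0)

    def test_terminal_loh_must_reach_an_end(self, baseline_one):
        with pytest.raises(ValueError, match="chromosome end"):
            implant_events(
                baseline_one, [EventSpec("iso", "terminal_LOH", "VII", 100_000, 200_000, "W")]
            )

    def test_contradictory_composition_rejected(self, baseline_one):
        events = [
            EventSpec("iso", "monosomy", "IX", parent="W"),  # Y homolog lost
            EventSpec("iso", "interstitial_deletion", "IX", 100_000, 150_000, "W"),
        ]
        with pytest.raises(ValueError, match="contradictory"):
            implant_events(baseline_one, events)

    def test_later_events_overwrite_earlier(self, baseline_one, markers_small):
        events = [
            EventSpec("iso", "gene_conversion", "XII", 200_000, 400_000, "W"),
            EventSpec("iso", "gene_conversion", "XII", 250_000, 300_000, "Y"),
        ]
        out = implant_events(baseline_one, events)
        inner = markers_small.marker_indices("XII", 250_000, 300_000)
        assert np.all(out.copies["iso"][inner] == (0, 2))


class TestSimulateSignals:
    def test_fixed_seed_reproducible(self, baseline_one):
        a = simulate_signals(baseline_one, noise=NoiseModel(sigma=0.1, seed=4))["iso"]
        b = simulate_signals(baseline_one, noise=NoiseModel(sigma=0.1, seed=4))["iso"]
        assert a.equals(b)

    def test_zero_noise_baseline_ratio_one(self, baseline_one, markers_small):
        sig = simulate_signals(baseline_one, noise=NoiseModel(sigma=0.0))["iso"]
        assert np.allclose(sig["cy5"] / sig["cy3"], 1.0)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(sigma=-0.1)
        with pytest.raises(ValueError):
            NoiseModel(baseline_hr=1.5)


class TestSectorPairs:
    def test_reciprocal_crossover_opposite_distal_homozygosity(self, markers_chr4):
        spec = SectorPairSpec("reciprocal_crossover", "none", 800_000, 0)
        white, red = sector_pair_genotypes(spec, markers_chr4)
        idx = markers_chr4.marker_indices("IV", 800_000, markers_chr4.genome["IV"].length)
        assert np.all(white[idx] == (0, 2))
        assert np.all(red[idx] == (2, 0))

    def test_combined_conservation_outside_aneuploidy(self, markers_chr4):
        for phase, span in (("none", 0), ("S_G2", 5_000), ("G1", 6_000)):
            spec = SectorPairSpec("reciprocal_crossover", phase, 800_000, span)
            white, red = sector_pair_genotypes(spec, markers_chr4)
            combined = white + red
            if phase == "none":
                assert np.all(combined.sum(axis=1) == 4)
            else:
                tract = markers_chr4.marker_indices("IV", 800_000, 800_000 + span)
                outside = np.ones(len(markers_chr4), dtype=bool)
                outside[tract] = False
                assert np.all(combined[outside].sum(axis=1) == 4)

    def test_s_g2_tract_is_3_to_1_in_one_sector_only(self, markers_chr4):
        spec = SectorPairSpec("reciprocal_crossover", "S_G2", 749_244, 4_813)
        white, red = sector_pair_genotypes(spec, markers_chr4)
        tract = markers_chr4.marker_indices("IV", 749_244, 754_057)
        combined = white[tract] + red[tract]
        assert np.all(combined[:, 1] == 3) and np.all(combined[:, 0] == 1)

    def test_g1_tract_has_4_to_0_core(self, markers_chr4):
        spec = SectorPairSpec("reciprocal_crossover", "G1", 800_000, 6_000, core_span=2_000)
        white, red = sector_pair_genotypes(spec, markers_chr4)
        combined = white + red
        core = markers_chr4.marker_indices("IV", 802_000, 804_000)
        assert np.any((combined[core, 1] == 4) & (combined[core, 0] == 0))

    def test_chromosome_loss_pairs_monosomy_with_trisomy(self, markers_chr4):
        spec = SectorPairSpec("chromosome_loss", "none", chromosome="III")
        white, red = sector_pair_genotypes(spec, markers_chr4)
        sl = markers_chr4.chrom_slice("III")
        assert np.all(red[sl] == (1, 0))
        assert np.all(white[sl] == (1, 2))
        # conservation across the pair holds even for the missegregation
        assert np.all((white[sl] + red[sl]).sum(axis=1) == 4)

    def test_invalid_mechanism_phase_combo_rejected(self):
        with pytest.raises(ValueError):
            SectorPairSpec("chromosome_loss", "G1")

    def test_breakpoint_must_be_on_dense_arm(self, markers_chr4):
        spec = SectorPairSpec("reciprocal_crossover", "none", 100_000, 0)
        with pytest.raises(ValueError, match="dense arm"):
            sector_pair_genotypes(spec, markers_chr4)

    def test_signal_tables_cover_both_sectors(self, markers_chr4, noiseless):
        spec = SectorPairSpec("reciprocal_crossover", "S_G2", 900_000, 5_000)
        w, r = simulate_sector_pair(spec, markers_chr4, noiseless)
        assert len(w) == len(r) == 4 * len(markers_chr4)


class TestSimulatePlating:
    def test_zero_probability_zero_sectored(self):
        assert simulate_plating(10_000, 0.0, seed=1)[1] == 0

    def test_unit_probability_all_sectored(self):
        n, s = simulate_plating(10_000, 1.0, seed=1)
        assert s == n == 10_000

    def test_estimator_within_3_binomial_se(self):
        n, s = simulate_plating(10**7, 3e-5, seed=12)
        p_hat = s / n
        se = np.sqrt(3e-5 * (1 - 3e-5) / n)
        assert abs(p_hat - 3e-5) <= 3 * se

    def test_probability_validated(self):
        with pytest.raises(ValueError):
            simulate_plating(100, 1.5)
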