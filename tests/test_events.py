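import numpy as np
import pytest

from lohscan import (
    EventSpec,
    GenotypeMatrix,
    Karyotype,
    SSD1,
    annotate_region,
    call_karyotype,
    detect_paired_nondisjunction,
    events_from_profile,
    implant_events,
    pcr_band_diagnostic,
)
from lohscan.signal import CopyProfile


def _profile(markers, events):
    gm = GenotypeMatrix.baseline(markers, ["iso"])
    gt = implant_events(gm, events)
    return CopyProfile(gt.copies["iso"], markers)


class TestClassifyEvents:
    def test_interior_homozygous_run_is_gene_conversion(self, markers_wg):
        prof = _profile(
            markers_wg, [EventSpec("iso", "gene_conversion", "XII", 235_000, 245_000, "Y")]
        )
        evs = events_from_profile(prof, "iso")
        assert len(evs) == 1
        ev = evs[0]
        assert ev.event_class == "gene_conversion"
        assert ev.subclass == "b2"
        assert ev.chromosome == "XII"
        assert 230_000 <= ev.start and ev.end <= 250_000

    def test_homozygosity_to_right_end_is_terminal_loh(self, markers_wg):
        chrom = markers_wg.genome["XII"]
        prof = _profile(
            markers_wg,
            [EventSpec("iso", "terminal_LOH", "XII", 625_000, chrom.length, "Y")],
        )
        evs = events_from_profile(prof, "iso")
        assert [e.event_class for e in evs] == ["terminal_LOH"]
        assert evs[0].subclass == "a4"  # Y retained, right arm
        assert evs[0].parent == "Y"

    def test_whole_chromosome_1_2_is_trisomy_of_Y(self, markers_wg):
        prof = _profile(markers_wg, [EventSpec("iso", "trisomy", "VIII", parent="Y")])
        evs = events_from_profile(prof, "iso")
        assert [(e.event_class, e.parent) for e in evs] == [("trisomy", "Y")]

    def test_hemizygous_run_is_deletion(self, markers_wg):
        prof = _profile(
            markers_wg,
            [EventSpec("iso", "interstitial_deletion", "V", 200_000, 215_000, "W")],
        )
        evs = events_from_profile(prof, "iso")
        assert [(e.event_class, e.subclass) for e in evs] == [("interstitial_deletion", "d1")]

    def test_unmapped_state_flagged_complex_not_dropped(self, markers_small):
        copies = np.ones((len(markers_small), 2), dtype=np.int64)
        sl = markers_small.chrom_slice("XI")
        copies[sl.start + 4 : sl.start + 12] = (3, 0)  # no defined class
        evs = events_from_profile(CopyProfile(copies, markers_small), "iso")
        assert [e.event_class for e in evs] == ["complex"]

    def test_every_marker_in_exactly_one_segment(self, markers_wg):
        from lohscan.signal import segment_profile

        prof = _profile(
            markers_wg,
            [
                EventSpec("iso", "gene_conversion", "II", 300_000, 320_000, "W"),
                EventSpec("iso", "trisomy", "IX", parent="W"),
            ],
        )
        segs = segment_profile(prof)
        covered = np.zeros(len(markers_wg), dtype=int)
        for s in segs:
            covered[s.first : s.last + 1] += 1
        assert np.all(covered == 1)


class TestCallKaryotype:
    def test_uniform_0_2_is_upd(self, markers_small):
        prof = _profile(markers_small, [EventSpec("iso", "UPD", "X", parent="Y")])
        k = call_karyotype(prof)
        assert k.states["X"] == ("UPD", "Y")

    def test_all_heterozygous_is_normal_everywhere(self, markers_small):
        prof = _profile(markers_small, [])
        k = call_karyotype(prof)
        assert all(label == "normal" for label, _ in k.states.values())

    def test_trisomy_called_at_95_percent_concordance(self, markers_small):
        # counting oracle: 19/20 markers at (1,2) passes the 0.9 default
        copies = np.ones((len(markers_small), 2), dtype=np.int64)
        sl = markers_small.chrom_slice("I")
        copies[sl] = (1, 2)
        copies[sl.start] = (1, 3)  # one discordant marker of 20
        k = call_karyotype(CopyProfile(copies, markers_small))
        assert k.states["I"] == ("trisomy", "Y")

    def test_below_concordance_stays_normal(self, markers_small):
        copies = np.ones((len(markers_small), 2), dtype=np.int64)
        sl = markers_small.chrom_slice("I")
        n = sl.stop - sl.start
        copies[sl.start : sl.start + int(0.8 * n)] = (1, 2)
        k = call_karyotype(CopyProfile(copies, markers_small))
        assert k.states["I"][0] == "normal"

    def test_concordance_validated(self, markers_small):
        prof = _profile(markers_small, [])
        with pytest.raises(ValueError):
            call_karyotype(prof, concordance=0.4)


class TestPairedNondisjunction:
    def _kary(self, iso, **chrom_states):
        states = {c: ("normal", None) for c in "I II III IV V".split()}
        states.update(chrom_states)
        return Karyotype(iso, states)

    def test_paired_monosomy_trisomy_same_parent(self):
        kw = self._kary("white", III=("trisomy", "Y"))
        kr = self._kary("red", III=("monosomy", "Y"))
        assert detect_paired_nondisjunction(kw, kr) == [("III", "Y")]

    def test_normal_pair_empty(self):
        assert detect_paired_nondisjunction(self._kary("w"), self._kary("r")) == []

    def test_different_parent_not_paired(self):
        kw = self._kary("white", III=("trisomy", "Y"))
        kr = self._kary("red", III=("monosomy", "W"))
        assert detect_paired_nondisjunction(kw, kr) == []

    def test_three_implanted_pairs_all_recovered(self, markers_small, noiseless):
        from lohscan import SectorPairSpec, simulate_sector_pair
        from lohscan.pipeline import process_isolate

        pairs = []
        for chrom in ("III", "IX", "VI"):
            spec = SectorPairSpec("chromosome_loss", "none", chromosome=chrom)
            w, r = simulate_sector_pair(spec, markers_small, noiseless)
            kw = process_isolate(w, markers_small, "white").karyotype
            kr = process_isolate(r, markers_small, "red").karyotype
            pairs.extend(detect_paired_nondisjunction(kw, kr))
        assert pairs == [("III", "Y"), ("IX", "Y"), ("VI", "Y")]


class TestPcrDiagnostic:
    @pytest.mark.parametrize(
        "copies,expected",
        [((1, 1), {404, 296}), ((2, 0), {404}), ((0, 2), {296}), ((2, 1), {404, 296})],
    )
    def test_band_logic(self, copies, expected):
        assert pcr_band_diagnostic(*copies) == expected

    def test_zero_copies_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert pcr_band_diagnostic(0, 0) == set()


class TestAnnotateRegion:
    def test_terminal_loh_over_ssd1_flags_homozygous_Y(self, markers_wg):
        chrom = markers_wg.genome["IV"]
        prof = _profile(
            markers_wg, [EventSpec("iso", "terminal_LOH", "IV", 700_000, chrom.length, "Y")]
        )
        df = annotate_region(events_from_profile(prof, "iso"), SSD1)
        assert df["covers_roi"].tolist() == [True]
        assert df["roi_homozygous"].tolist() == [True]
        assert df["roi_parent"].tolist() == ["Y"]

    def test_event_on_other_chromosome_not_flagged(self, markers_wg):
        prof = _profile(
            markers_wg, [EventSpec("iso", "gene_conversion", "VII", 400_000, 420_000, "W")]
        )
        df = annotate_region(events_from_profile(prof, "iso"), SSD1)
        assert not df["covers_roi"].any()

    def test_upd_of_chr4_covers_any_chr4_roi(self, markers_wg):
        prof = _profile(markers_wg, [EventSpec("iso", "UPD", "IV", parent="Y")])
        df = annotate_region(events_from_profile(prof, "iso"), SSD1)
        assert df["covers_roi"].tolist() == [True]
        assert df["roi_parent"].tolist() == ["Y"]
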