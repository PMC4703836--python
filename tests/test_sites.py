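"""Seed / nucleation-bulge pattern generation and transcript scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipivot.guides import GuideStrand, make_variant, wc_complement
from sipivot.sites import (
    TranscriptRecord,
    all_patterns,
    classify,
    nucleation_bulge_pattern,
    perfect_match_pattern,
    scan,
    seed_patterns,
)

PCSK9_SEED_INSERT = "AUUCGGAAAUUCGGAA"
PCSK9_NUC_INSERT = "AUUUCGGAAAUUUCGGAA"


def naive_scan(seq: str, motif: str) -> list[tuple[int, int]]:
    """All-substrings comparison oracle."""
    return [
        (i, i + len(motif))
        for i in range(len(seq) - len(motif) + 1)
        if seq[i : i + len(motif)] == motif
    ]


class TestSeedPatterns:
    def test_span_2_8_motif_for_pcsk9(self, sipcsk9):
        pats = {p.guide_span: p.target_motif for p in seed_patterns(sipcsk9, (7,))}
        assert pats[(2, 8)] == "AUUCGGA"

    def test_span_1_8_motif_for_sirl(self, sirl):
        (p,) = seed_patterns(sirl, (8,))
        assert p.target_motif == "ACUCCUAC"
        assert p.guide_span == (1, 8)

    def test_window_counts_per_length(self, sirl):
        assert len(seed_patterns(sirl, (6,))) == 3
        assert len(seed_patterns(sirl, (7,))) == 2
        assert len(seed_patterns(sirl, (8,))) == 1

    def test_abasic_pivot_removes_all_windows(self, sirl):
        assert seed_patterns(make_variant(sirl.base, "6pi")) == []

    def test_abasic_position_2_spares_window_3_8(self, sirl):
        spans = {p.guide_span for p in seed_patterns(make_variant(sirl.base, "2pi"))}
        assert spans == {(3, 8)}

    def test_short_guide_rejected(self):
        with pytest.raises(ValueError):
            seed_patterns(GuideStrand(name="x", core_sequence="ACGUACG"))

    def test_pure_function_of_guide(self, sipcsk9):
        assert seed_patterns(sipcsk9) == seed_patterns(sipcsk9)


class TestNucleationBulgePattern:
    def test_pcsk9_motif_and_bulge(self, sipcsk9):
        p = nucleation_bulge_pattern(sipcsk9)
        assert p.target_motif == "UUUCGGA"
        assert p.bulge_nt == "U"
        assert len(p.target_motif) == 7

    def test_mir124_bulge_is_g(self, mir124):
        assert nucleation_bulge_pattern(mir124).bulge_nt == "G"

    def test_abasic_pivot_yields_no_pattern(self, sipcsk9):
        for code in ("6pi", "6c3", "6pi-r"):
            assert nucleation_bulge_pattern(make_variant(sipcsk9.base, code)) is None

    def test_bulge_pairs_pivot_for_all_four_bases(self):
        for pivot in "ACGU":
            core = "AACAG" + pivot + "GGCCAAUUGGCC"
            g = GuideStrand(name="x", core_sequence=core)
            p = nucleation_bulge_pattern(g)
            assert p.bulge_nt == wc_complement(pivot)

    def test_deleting_bulge_recovers_seed_2_7_motif(self, sirl, sipcsk9, mir124):
        for guide in (sirl, sipcsk9, mir124):
            nuc = nucleation_bulge_pattern(guide)
            seed_2_7 = next(
                p.target_motif
                for p in seed_patterns(guide, (6,))
                if p.guide_span == (2, 7)
            )
            without_bulge = nuc.target_motif[:2] + nuc.target_motif[3:]
            assert without_bulge == seed_2_7


class TestScan:
    def test_two_seed_hits_on_tandem_insert(self, sipcsk9):
        rec = TranscriptRecord("ins", PCSK9_SEED_INSERT)
        pat = next(p for p in seed_patterns(sipcsk9, (7,)) if p.guide_span == (2, 8))
        hits = scan([rec], [pat])
        assert [(h.start, h.end) for h in hits] == [(0, 7), (8, 15)]

    def test_nuc_insert_has_two_nuc_and_zero_seed28_hits(self, sipcsk9):
        rec = TranscriptRecord("ins", PCSK9_NUC_INSERT)
        nuc = nucleation_bulge_pattern(sipcsk9)
        seed28 = next(p for p in seed_patterns(sipcsk9, (7,)) if p.guide_span == (2, 8))
        assert len(scan([rec], [nuc])) == 2
        assert scan([rec], [seed28]) == []

    def test_empty_pattern_list(self, sipcsk9):
        assert scan([TranscriptRecord("t", "ACGUACGU")], []) == []

    def test_utr3_only_restricts_and_skips(self, sipcsk9):
        pat = next(p for p in seed_patterns(sipcsk9, (7,)) if p.guide_span == (2, 8))
        motif = pat.target_motif
        seq = motif + "CCCC" + motif
        with_utr = TranscriptRecord("a", seq, utr3_interval=(len(motif) + 4, len(seq)))
        without = TranscriptRecord("b", seq)
        hits = scan([with_utr, without], [pat], region_mode="utr3_only")
        assert [(h.transcript_id, h.start) for h in hits] == [("a", len(motif) + 4)]
        assert all(h.region == "utr3" for h in hits)

    def test_overlapping_occurrences_all_reported(self):
        pat = seed_patterns(GuideStrand(name="x", core_sequence="UUUUUUUUAACCGGCCAAG"), (6,))
        aaa = next(p for p in pat if p.guide_span == (1, 6))  # motif AAAAAA
        hits = scan([TranscriptRecord("t", "A" * 8)], [aaa])
        assert len(hits) == 3

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_scan_equals_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(200, 2001))))
        rec = TranscriptRecord("t", seq)
        guide = GuideStrand(
            name="g", core_sequence="".join(rng.choice(list("ACGU"), size=19))
        )
        pats = all_patterns(guide) + [perfect_match_pattern(guide)]
        got = {
            (h.start, h.end, h.pattern.target_motif) for h in scan([rec], pats)
        }
        expect = {
            (s, e, p.target_motif)
            for p in pats
            for s, e in naive_scan(seq, p.target_motif)
        }
        assert got == expect


class TestClassify:
    def test_hierarchy_seed_beats_nuc(self, sirl):
        seq = "ACUCCUAC" + "GGG" + nucleation_bulge_pattern(sirl).target_motif
        rec = TranscriptRecord("t", seq)
        hits = scan([rec], all_patterns(sirl))
        (a,) = classify([rec], hits, scheme="any_seed")
        assert a.site_class == "Seed"
        assert a.n_nuc_hits >= 1

    def test_nuc_insert_is_nuc_under_matched_7mer(self, sipcsk9):
        rec = TranscriptRecord("t", PCSK9_NUC_INSERT)
        hits = scan([rec], all_patterns(sipcsk9))
        (a,) = classify([rec], hits, scheme="matched_7mer")
        assert a.site_class == "Nuc"
        # a 6-mer seed match is embedded in the bulge motif but no 7-mer
        (a6,) = classify([rec], hits, scheme="any_seed")
        assert a6.site_class == "Seed"

    def test_no_matches_is_nosite(self, sirl):
        rec = TranscriptRecord("t", "A" * 100)
        hits = scan([rec], all_patterns(sirl))
        (a,) = classify([rec], hits)
        assert (a.site_class, a.n_seed_hits, a.n_nuc_hits) == ("NoSite", 0, 0)

    def test_unknown_transcript_in_hits_rejected(self, sirl):
        rec = TranscriptRecord("t", "A" * 50)
        other = TranscriptRecord("other", "ACUCCUAC" + "A" * 40)
        hits = scan([other], all_patterns(sirl))
        with pytest.raises(KeyError):
            classify([rec], hits)

    def test_every_record_gets_exactly_one_class(self, sirl, rng):
        records = [
            TranscriptRecord(f"t{i}", "".join(rng.choice(list("ACGU"), size=300)))
            for i in range(25)
        ]
        hits = scan(records, all_patterns(sirl))
        assigns = classify(records, hits)
        assert sorted(a.transcript_id for a in assigns) == sorted(r.id for r in records)
        assert all(a.site_class in ("Seed", "Nuc", "NoSite") for a in assigns)
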