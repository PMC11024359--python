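import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_scan, naive_window_score
from rtkclass.alphabet import AA20
from rtkclass.motif_model import (
    AnchorPair,
    best_match,
    compile_motif,
    find_anchored_region,
    locate_kinase_landmarks,
    match_at,
    motif_from_sets,
    scan,
)
from rtkclass.sequence_io import SequenceRecord


class TestCompileMotif:
    def test_catalytic_decamer_all_bold(self):
        m = compile_motif("VHRDLAARNC", bold_positions=range(1, 11))
        assert len(m) == 10
        assert m.fixed_total == 10
        assert all(m.universal_mask)

    def test_pxkw(self):
        m = compile_motif("PxKW", bold_positions={1, 3, 4})
        assert len(m) == 4
        assert m.fixed_total == 3
        assert m.positions[1] is None
        assert m.universal_mask == (True, False, True, True)

    def test_all_wildcards_rejected(self):
        with pytest.raises(ValueError, match="no fixed position"):
            compile_motif("xxx")

    def test_bold_on_wildcard_rejected(self):
        with pytest.raises(ValueError, match="wildcard"):
            compile_motif("PxKW", bold_positions={2})

    def test_character_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="outside motif alphabet"):
            compile_motif("PZKW")

    def test_no_wildcards_means_fixed_total_equals_length(self):
        m = compile_motif("RYAVYVETDTVADADIGARS")
        assert m.fixed_total == len(m) == 20

    def test_consensus_string_roundtrip(self):
        m = compile_motif("GxGxFG")
        assert m.consensus_string() == "GxGxFG"


class TestMatchAt:
    def test_identity_match(self):
        m = compile_motif("VHRDLAARNC", bold_positions=range(1, 11))
        seq = SequenceRecord(id="s", residues="AAVHRDLAARNCAA")
        hit = match_at(seq, m, 2)
        assert hit.score == 1.0
        assert hit.universal_ok
        assert (hit.start, hit.end) == (2, 12)

    def test_single_mismatch_scores_nine_tenths(self):
        m = compile_motif("VHRDLAARNC", bold_positions=range(1, 11))
        hit = match_at("VHRDLAARNA", m, 0)
        assert hit.score == pytest.approx(0.9)
        assert hit.fixed_matched == 9
        assert not hit.universal_ok

    def test_gly_loop_derived_example(self):
        # brute-force check: offset 2 is the only full-score window
        m = compile_motif("GxGxFG")
        subject = "AAGAGTFGAA"
        full = [
            off
            for off in range(len(subject) - len(m) + 1)
            if naive_window_score(subject, m, off)[0] == 1.0
        ]
        assert full == [2]
        assert match_at(subject, m, 2).score == 1.0

    def test_x_never_matches_fixed_position(self):
        m = compile_motif("DFG")
        assert match_at("DXG", m, 0).score == pytest.approx(2 / 3)

    def test_wildcard_contributes_nothing(self):
        m = compile_motif("PxKW", bold_positions={1, 3, 4})
        assert match_at("PAKW", m, 0).score == 1.0
        assert match_at("PXKW", m, 0).score == 1.0  # X under a wildcard is free

    def test_offset_out_of_range(self):
        m = compile_motif("DFG")
        with pytest.raises(ValueError, match="out of range"):
            match_at("DFG", m, 1)


class TestScan:
    def test_embedded_motif_found_uniquely(self):
        rng = np.random.default_rng(1234)
        motif_str = "VHRDLAARNC"
        m = compile_motif(motif_str)
        background = "".join(rng.choice(list(AA20), 120))
        offset = 57
        subject = background[:offset] + motif_str + background[offset:]
        hits = scan(subject, m, min_score=1.0)
        # the oracle confirms uniqueness for this seed
        assert [h.start for h in naive_scan(subject, m, 1.0)] == [offset]
        assert [h.start for h in hits] == [offset]

    def test_min_score_zero_returns_every_window(self):
        m = compile_motif("DFG")
        subject = "A" * 30
        hits = scan(subject, m, min_score=0.0)
        assert len(hits) == 30 - 3 + 1
        assert sorted(h.start for h in hits) == list(range(28))

    def test_sequence_shorter_than_motif_yields_empty(self):
        m = compile_motif("VHRDLAARNC")
        assert scan("ACD", m, min_score=0.0) == []

    def test_sorted_by_score_then_start(self):
        m = compile_motif("AA")
        hits = scan("AACAA", m, min_score=0.0)
        assert [(h.start, h.score) for h in hits[:2]] == [(0, 1.0), (3, 1.0)]
        assert all(hits[i].score >= hits[i + 1].score for i in range(len(hits) - 1))

    def test_best_match_agrees_with_scan(self):
        m = compile_motif("GxGxFG")
        subject = "AAGAGTFGAAGCGTFGAA"
        assert best_match(subject, m) == scan(subject, m, min_score=0.0)[0]

    @settings(max_examples=150, deadline=None)
    @given(
        seq=st.text(alphabet=AA20 + "X", min_size=1, max_size=200),
        consensus=st.text(alphabet=AA20 + "x", min_size=1, max_size=20),
        min_score=st.sampled_from([0.0, 0.5, 0.8, 1.0]),
    )
    def test_scan_equals_bruteforce_oracle(self, seq, consensus, min_score):
        if all(c == "x" for c in consensus):
            consensus = "A" + consensus[1:]
        m = compile_motif(consensus)
        assert scan(seq, m, min_score) == naive_scan(seq, m, min_score)


class TestAnchoredRegion:
    def _subject(self, interior: int, seed: int = 0) -> str:
        rng = np.random.default_rng(seed)
        filler = "".join(rng.choice(list(AA20.replace("V", "").replace("H", "")), interior))
        pad = "".join(rng.choice(list(AA20.replace("V", "").replace("H", "")), 15))
        return pad + "VAVK" + filler + "HRDLA" + pad

    def test_single_region_within_bounds(self):
        anchors = AnchorPair(compile_motif("VAVK"), compile_motif("HRDLA"), 100, 125)
        regions = find_anchored_region(self._subject(104), anchors)
        assert len(regions) == 1
        start, end, interior = regions[0]
        assert interior == 104
        assert end - start == 4 + 104 + 5

    def test_no_downstream_c_anchor_yields_empty(self):
        anchors = AnchorPair(compile_motif("VAVK"), compile_motif("HRDLA"), 0, 500)
        assert find_anchored_region("AAAVAVKAAA", anchors) == []

    def test_interior_outside_bounds_discarded(self):
        anchors = AnchorPair(compile_motif("VAVK"), compile_motif("HRDLA"), 100, 125)
        assert find_anchored_region(self._subject(50), anchors) == []

    def test_relaxed_catloop_variant_anchor(self):
        # HRDLA admitted at the n-anchor when the G position is relaxed
        n_anchor = motif_from_sets(["H", "GR", "D", "L", "A"], name="relaxed")
        anchors = AnchorPair(n_anchor, compile_motif("PxKW", bold_positions=(1, 3, 4)), 30, 60)
        subject = "AAA" + "HRDLA" + "W" * 37 + "PAKW" + "AAA"
        regions = find_anchored_region(subject, anchors)
        assert len(regions) == 1
        assert regions[0][2] == 37

    def test_innermost_pairing(self):
        anchors = AnchorPair(compile_motif("VAVK"), compile_motif("HRDLA"), 0, 100)
        subject = "VAVK" + "A" * 10 + "HRDLA" + "A" * 10 + "HRDLA"
        regions = find_anchored_region(subject, anchors)
        assert len(regions) == 1
        assert regions[0][2] == 10  # closest downstream c-anchor wins

    def test_gap_bounds_validated(self):
        with pytest.raises(ValueError):
            AnchorPair(compile_motif("VAVK"), compile_motif("HRDLA"), 10, 5)


class TestKinaseLandmarks:
    def test_synthetic_cassette_found_in_order(self):
        from rtkclass.synthetic_data import SyntheticSpec, generate_sequence

        spec = SyntheticSpec(rtk_class="InsR", subtype="InsR2", seed=3)
        rec, truth = generate_sequence(spec)
        lm = locate_kinase_landmarks(rec)
        assert lm.complete
        assert lm.gly_loop.start < lm.catalytic_loop.start < lm.dfg.start
        assert lm.gly_loop.start == truth.motif_offsets["gly_loop"]

    def test_truncated_sequence_has_no_landmarks(self):
        from rtkclass.synthetic_data import SyntheticSpec, generate_sequence

        spec = SyntheticSpec(rtk_class="InsR", subtype="InsR1",
                             truncation="c_terminal", retained_fraction=0.4, seed=17)
        rec, truth = generate_sequence(spec)
        lm = locate_kinase_landmarks(rec)
        assert lm.gly_loop is None
        assert lm.catalytic_loop is None
        assert lm.dfg is None

    def test_dfg_before_gly_loop_leaves_catalytic_none(self):
        subject = "AA" + "DFG" + "A" * 10 + "GAGTFG" + "AA"
        lm = locate_kinase_landmarks(subject)
        assert lm.catalytic_loop is None
        assert lm.gly_loop is not None
        assert lm.dfg is not None

    def test_catalytic_loop_accepts_g_and_r_forms(self):
        base = "GAGTFG" + "A" * 30
        for loop in ("HRDLA", "HGDLA"):
            lm = locate_kinase_landmarks(base + loop + "A" * 5 + "DFG" + "A" * 10)
            assert lm.complete, loop


class TestMotifLibrary:
    def test_expected_motifs_present(self, library):
        assert set(library.motifs) == {
            "InsR1_FN3", "InsR2_FN3", "InsR3_FN3", "InsR_catalytic",
            "FGFR1_catalytic", "FGFR2_catalytic", "FGFR3_catalytic",
            "PVR1_catalytic", "PVR2A_catalytic", "PVR2B_catalytic",
            "EGFR1_catalytic",
        }

    def test_lengths(self, library):
        assert len(library["InsR_catalytic"]) == 10
        assert all(len(library[f"InsR{i}_FN3"]) == 20 for i in (1, 2, 3))
        assert len(library["FGFR1_catalytic"]) == 118
        assert len(library["FGFR2_catalytic"]) == 117  # gap artifact stripped
        assert len(library["FGFR3_catalytic"]) == 117
        assert all(len(library[f"PVR{s}_catalytic"]) == 62 for s in ("1", "2A", "2B"))

    def test_gap_artifact_kept_verbatim(self, library):
        assert "-" in library.raw_consensus["FGFR2_catalytic"]
        assert "-" not in library["FGFR2_catalytic"].consensus_string()

    def test_universal_positions_are_fixed(self, library):
        for m in library.motifs.values():
            for pos, uni in zip(m.positions, m.universal_mask):
                if uni:
                    assert pos is not None

    def test_subtype_views(self, library):
        assert {m.subtype for m in library.subtype_motifs("InsR")} == {
            "InsR1", "InsR2", "InsR3"}
        assert {m.subtype for m in library.subtype_motifs("FGFR")} == {
            "FGFR1", "FGFR2", "FGFR3"}
        assert {m.subtype for m in library.subtype_motifs("PVR")} == {
            "PVR1", "PVR2A", "PVR2B"}

    def test_relaxed_catloop_admits_r_in_pvr(self, library):
        relaxed = library.with_relaxed_catloop()
        m = relaxed["PVR1_catalytic"]
        strict = library["PVR1_catalytic"]
        variant = strict.consensus_string().replace("HGDLA", "HRDLA")
        variant = variant.replace("x", "A")
        assert best_match(variant, m).score == 1.0
        assert best_match(variant, strict).score < 1.0
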