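"""Haplotype composition segments, color status, lengths and naming."""

import numpy as np
import pytest

from periclinal.classify import (
    CHROMOSOME_END,
    ColorStatus,
    SegmentOrigin,
    classify_haplotype,
    functional_color_status,
    has_replacement_tract,
    infer_composition_segments,
    match_to_library,
    tract_length_bounds,
)
from periclinal.model import NULL, UNKNOWN, Haplotype, MarkerDef, MarkerPanel
from periclinal.pinot import CHROMOSOME_LENGTH_BP, canonical_library, pinot_panel
from periclinal.simulate import SomaticEvent, SomaticEventKind, apply_somatic_event


@pytest.fixture(scope="module")
def refs(sim_library):
    return sim_library["c188"], sim_library["w216"]


class TestColorStatus:
    def test_canonical_references(self, library):
        by_name = {h.name: h for h in library}
        assert functional_color_status(by_name["c188"]) is ColorStatus.COLORED
        assert functional_color_status(by_name["w216"]) is ColorStatus.WHITE
        # the deletion spanning the color locus is white too
        assert functional_color_status(by_name["w188-1"]) is ColorStatus.WHITE

    def test_unresolved_color_locus_is_undetermined(self, panel):
        h = Haplotype("x", {m.name: UNKNOWN for m in panel})
        assert functional_color_status(h) is ColorStatus.UNDETERMINED


class TestCompositionSegments:
    def test_distal_replacement_yields_two_segments(self, panel, sim_library, refs):
        segs = infer_composition_segments(sim_library["w188-2"], *refs, panel)
        assert [s.origin for s in segs] == [
            SegmentOrigin.COLORED_BACKBONE,
            SegmentOrigin.WHITE_DONOR,
        ]
        colored, white = segs
        assert (colored.inner_start_marker, colored.inner_end_marker) == ("VMC5g7", "P2-298")
        assert (white.inner_start_marker, white.inner_end_marker) == ("P2-442", "VMC7g3")
        assert white.outer_start_marker == "P2-298"
        assert white.outer_end_marker == CHROMOSOME_END

    def test_reference_against_itself_is_one_segment(self, panel, sim_library, refs):
        segs = infer_composition_segments(sim_library["c188"], *refs, panel)
        assert len(segs) == 1
        assert segs[0].origin is SegmentOrigin.COLORED_BACKBONE

    def test_conversion_with_deletion_tiling(self, panel, sim_library, refs):
        segs = infer_composition_segments(sim_library["w188-1"], *refs, panel)
        assert [s.origin for s in segs] == [
            SegmentOrigin.COLORED_BACKBONE,
            SegmentOrigin.WHITE_DONOR,
            SegmentOrigin.DELETED,
            SegmentOrigin.COLORED_BACKBONE,
        ]
        white = segs[1]
        assert (white.inner_start_marker, white.inner_end_marker) == ("VVNTm1", "VVNTm2")
        deleted = segs[2]
        assert (deleted.inner_start_marker, deleted.inner_end_marker) == ("Gret1", "Gret1")
        assert (deleted.outer_start_marker, deleted.outer_end_marker) == ("VVNTm2", "VVNTm3")

    def test_unmatched_allele_becomes_unknown_origin(self, panel, sim_library, refs):
        w198 = sim_library["w198"]
        segs = infer_composition_segments(w198, *refs, panel)
        assert segs[0].origin is SegmentOrigin.UNKNOWN  # allele 198 matches neither
        assert segs[1].origin is SegmentOrigin.WHITE_DONOR

    def test_identical_references_are_rejected(self, panel, refs):
        with pytest.raises(ValueError, match="differ"):
            infer_composition_segments(refs[0], refs[0], refs[0], panel)

    def test_segment_tiling_is_ordered_and_disjoint(self, panel, sim_library, refs):
        for name in ("w188-1", "w188-2", "w188-3", "w216"):
            segs = infer_composition_segments(sim_library[name], *refs, panel)
            idx = [
                (panel.index(s.inner_start_marker), panel.index(s.inner_end_marker))
                for s in segs
            ]
            assert all(a <= b for a, b in idx)
            assert all(b < a2 for (_, b), (a2, _) in zip(idx, idx[1:]))
            # tiling covers the panel from first to last marker
            assert idx[0][0] == 0 and idx[-1][1] == len(panel) - 1


class TestTractLengthBounds:
    def test_constructed_panel_arithmetic(self):
        panel = MarkerPanel(
            [MarkerDef(n, "c", p) for n, p in [("a", 100), ("b", 200), ("c", 300), ("d", 400)]]
        )
        h = Haplotype("x", {"a": "1", "b": "2", "c": "2", "d": "1"})
        c = Haplotype("colored", {k: "1" for k in "abcd"})
        w = Haplotype("white", {k: "2" for k in "abcd"})
        segs = infer_composition_segments(h, c, w, panel)
        white = [s for s in segs if s.origin is SegmentOrigin.WHITE_DONOR][0]
        assert tract_length_bounds(white, panel, 1000) == (100, 300)

    def test_retrotransposon_interval_length(self, panel):
        # the two retrotransposon insertion sites bound a 1.61 Mb interval
        from periclinal.classify import CompositionSegment

        seg = CompositionSegment(
            SegmentOrigin.WHITE_DONOR, "Gret1", "Noble225", "VVNTm2", "VVIu20.1"
        )
        min_len, _ = tract_length_bounds(seg, panel, CHROMOSOME_LENGTH_BP)
        assert min_len == 1_610_000

    def test_whole_studied_region_span(self, panel):
        from periclinal.classify import CompositionSegment

        seg = CompositionSegment(
            SegmentOrigin.COLORED_BACKBONE, "VMC5g7", "VMC7g3", CHROMOSOME_END, CHROMOSOME_END
        )
        min_len, max_len = tract_length_bounds(seg, panel, CHROMOSOME_LENGTH_BP)
        assert min_len == 10_070_000  # 10.07 Mb between the flanking SSRs
        assert max_len == CHROMOSOME_LENGTH_BP


class TestMatchToLibrary:
    def test_canonical_names(self, panel, library, sim_library):
        assert match_to_library(sim_library["w216"], library, panel) == "w216"
        # concrete SC8 phase still matches the UNKNOWN-bearing library entry
        assert match_to_library(sim_library["w188-1"], library, panel) == "w188-1"

    def test_novel_pattern_gets_generated_name(self, panel, library, sim_library):
        novel = sim_library["c188"].with_name("x")
        novel.alleles["VVNTm3"] = NULL
        name = match_to_library(novel, library, panel)
        assert name == "c188-1"

    def test_novel_white_numbering_continues_series(self, panel, library, sim_library):
        novel = sim_library["w188-1"].with_name("x")
        novel.alleles["VMC7g3"] = NULL
        assert match_to_library(novel, library, panel) == "w188-4"


class TestEventRecovery:
    """Simulator round-trip: composition segments bound the true event."""

    def _positions(self, panel, seg, chrom_len):
        start_lo = (
            0
            if seg.outer_start_marker == CHROMOSOME_END
            else panel.position(seg.outer_start_marker)
        )
        end_hi = (
            chrom_len
            if seg.outer_end_marker == CHROMOSOME_END
            else panel.position(seg.outer_end_marker)
        )
        return (
            start_lo,
            panel.position(seg.inner_start_marker),
            panel.position(seg.inner_end_marker),
            end_hi,
        )

    def test_random_conversion_tracts_recovered(self, panel, sim_library, refs):
        rng = np.random.default_rng(99)
        positions = [m.position_bp for m in panel]
        hit = 0
        trials = 100
        for _ in range(trials):
            i = int(rng.integers(0, len(positions) - 1))
            j = int(rng.integers(i + 1, len(positions)))  # tract covers >= 2 markers
            start = positions[i] - int(rng.integers(1, 1000))
            end = positions[j] + int(rng.integers(0, 1000))
            event = SomaticEvent(
                SomaticEventKind.CONVERSION_INTERNAL, "c188", "w216", start, end
            )
            mutated = apply_somatic_event(
                (sim_library["c188"], sim_library["w216"]), event, panel,
                chromosome_length_bp=CHROMOSOME_LENGTH_BP,
            )
            segs = infer_composition_segments(mutated, *refs, panel)
            white = [s for s in segs if s.origin is SegmentOrigin.WHITE_DONOR]
            assert len(white) == 1
            lo, inner_lo, inner_hi, hi = self._positions(panel, white[0], CHROMOSOME_LENGTH_BP)
            if lo < start <= inner_lo and inner_hi <= end < hi or (
                lo <= start <= inner_lo and inner_hi <= end <= hi
            ):
                hit += 1
        assert hit == trials

    def test_classification_flags_replacement(self, panel, library, sim_library, refs):
        cl = classify_haplotype(sim_library["w188-2"], *refs, library, panel)
        assert has_replacement_tract(cl)
        assert cl.matched_name == "w188-2"
        cl2 = classify_haplotype(sim_library["w216"], *refs, library, panel)
        assert not has_replacement_tract(cl2)
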