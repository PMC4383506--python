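"""Somatic events, Mendelian selfing simulation and tissue sampling."""

import numpy as np
import pytest

from periclinal.io import write_genotype_table
from periclinal.model import NULL, UNKNOWN, CloneLayerModel
from periclinal.pinot import build_canonical_haplotypes, pinot_panel
from periclinal.simulate import (
    SimulationConfig,
    SomaticEvent,
    SomaticEventKind,
    apply_somatic_event,
    simulate_clone_tissues,
    simulate_selfed_progeny,
)


class TestCanonicalHaplotypes:
    def test_reference_alleles(self, canonical):
        colored, white = canonical
        assert colored["VMC5g7"] == "188"
        assert white["VVNTm1"] == "168" and white["VVNTm2"] == "387"
        assert colored["Gret1"] == "empty" and white["Gret1"] == "full"

    def test_phased_alleles_partition_each_heterozygous_locus(self, panel, canonical, table1):
        colored, white = canonical
        gI = table1.sample("genotype_I")
        for m in panel:
            if colored[m.name] is UNKNOWN or white[m.name] is UNKNOWN:
                continue
            # leaf insertion-pair cells encode presence; compare SSRs directly
            if m.assay_type.value == "CODOMINANT_SSR":
                assert {colored[m.name], white[m.name]} == set(gI.call(m.name).alleles)

    def test_incomplete_panel_is_rejected(self, panel):
        from periclinal.model import MarkerPanel

        with pytest.raises(ValueError, match="lacks"):
            build_canonical_haplotypes(MarkerPanel(panel.markers[:5]))


class TestSomaticEvents:
    def test_conversion_to_end_builds_distal_replacement(self, panel, sim_library):
        # tract opening between P2-298 and P2-442 and running to the
        # chromosome end: the w188-2 pattern
        event = SomaticEvent(
            SomaticEventKind.CONVERSION_TO_END, "c188", "w216", 13_700_000, 13_700_000
        )
        mutated = apply_somatic_event(
            (sim_library["c188"], sim_library["w216"]), event, panel
        )
        expected = sim_library["w188-2"]
        assert all(mutated[m.name] == expected[m.name] for m in panel)

    def test_zero_length_tract_off_marker_is_identity(self, panel, sim_library):
        pair = (sim_library["c188"], sim_library["w216"])
        event = SomaticEvent(
            SomaticEventKind.CONVERSION_INTERNAL, "c188", "w216", 9_000_000, 9_000_000
        )
        mutated = apply_somatic_event(pair, event, panel)
        assert all(mutated[m.name] == sim_library["c188"][m.name] for m in panel)

    def test_conversion_with_deletion_builds_w188_1(self, panel, sim_library):
        # replacement over the VVNTm1..VVNTm2 interval plus deletion of
        # the color locus up to just before VVNTm3
        event = SomaticEvent(
            SomaticEventKind.CONVERSION_WITH_DELETION,
            "c188",
            "w216",
            14_100_000,
            14_200_000,
            deletion_start_bp=14_200_001,
            deletion_end_bp=14_270_000,
        )
        mutated = apply_somatic_event(
            (sim_library["c188"], sim_library["w216"]), event, panel
        )
        expected = sim_library["w188-1"]
        assert mutated["Gret1"] is NULL
        assert all(mutated[m.name] == expected[m.name] for m in panel)

    def test_event_outside_chromosome_is_rejected(self, panel, sim_library):
        event = SomaticEvent(
            SomaticEventKind.CONVERSION_INTERNAL, "c188", "w216", 25_000_000, 26_000_000
        )
        with pytest.raises(ValueError, match="outside"):
            apply_somatic_event(
                (sim_library["c188"], sim_library["w216"]), event, panel,
                chromosome_length_bp=18_780_000,
            )


class TestSelfedProgeny:
    def test_no_recombination_gives_three_diplotypes(self, panel, sim_library):
        cfg = SimulationConfig(
            n_progeny=60, genetic_map_cM=[0.0] * (len(panel) - 1), seed=5
        )
        table = simulate_selfed_progeny(
            (sim_library["c188"], sim_library["w216"]), cfg, panel
        )
        patterns = {
            tuple(tuple(sorted(s.call(m.name).alleles)) for m in panel) for s in table
        }
        assert len(patterns) == 3

    def test_dominant_color_locus_segregates_three_to_one(self, panel, sim_library):
        n = 10_000
        cfg = SimulationConfig(n_progeny=n, seed=1)
        table = simulate_selfed_progeny(
            (sim_library["c188"], sim_library["w216"]), cfg, panel
        )
        frac = sum(1 for s in table if "empty" in s.call("Gret1").alleles) / n
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(frac - 0.75) < 3 * se

    def test_null_null_class_fails_to_amplify_in_one_quarter(self, panel, sim_library):
        n = 10_000
        cfg = SimulationConfig(n_progeny=n, seed=2)
        table = simulate_selfed_progeny(
            (sim_library["w216"], sim_library["w188-3"]), cfg, panel
        )
        frac = sum(1 for s in table if s.call("VMC7g3").no_amplification) / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * se

    def test_codominant_locus_fits_1_2_1(self, panel, sim_library):
        from periclinal.segregation import chi_square_gof

        cfg = SimulationConfig(n_progeny=10_000, seed=3)
        table = simulate_selfed_progeny(
            (sim_library["c188"], sim_library["w216"]), cfg, panel
        )
        counts = {"188": 0, "both": 0, "216": 0}
        for s in table:
            a = s.call("VMC5g7").alleles
            if a == frozenset({"188"}):
                counts["188"] += 1
            elif a == frozenset({"216"}):
                counts["216"] += 1
            else:
                counts["both"] += 1
        res = chi_square_gof(list(counts.values()), [1, 2, 1])
        assert res.p_value > 0.001

    def test_progeny_alleles_subset_of_parental_universe(self, panel, sim_library):
        cfg = SimulationConfig(n_progeny=200, seed=4)
        pair = (sim_library["w198"], sim_library["w188-1"])
        universe = {
            m.name: {str(h[m.name]) for h in pair if h[m.name] is not NULL}
            for m in panel
        }
        table = simulate_selfed_progeny(pair, cfg, panel)
        for s in table:
            for m in panel:
                assert set(s.call(m.name).alleles) <= universe[m.name]

    def test_seeded_determinism_is_byte_identical(self, panel, sim_library, tmp_path):
        cfg = SimulationConfig(n_progeny=50, seed=7)
        pair = (sim_library["c188"], sim_library["w216"])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_genotype_table(simulate_selfed_progeny(pair, cfg, panel), p1)
        write_genotype_table(simulate_selfed_progeny(pair, cfg, panel), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_genotyping_error_introduces_other_alleles(self, panel, sim_library):
        cfg = SimulationConfig(n_progeny=500, seed=8, genotyping_error_rate=0.1)
        table = simulate_selfed_progeny(
            (sim_library["c188"], sim_library["w216"]), cfg, panel
        )
        n_single = sum(
            1 for s in table for m in panel if len(s.call(m.name).alleles) == 1
        )
        assert n_single > 0  # substitutions collapse some calls


class TestCloneTissues:
    def test_chimeric_clone_leaf_is_triallelic(self, panel, models):
        leaf, _ = simulate_clone_tissues(models["PG3106"], panel)
        assert leaf.call("VMC5g7").alleles == frozenset({"188", "198", "216"})

    def test_homogeneous_clone_has_identical_tissues(self, panel, models):
        leaf, l2 = simulate_clone_tissues(models["PB54"], panel)
        for m in panel:
            assert leaf.call(m.name) == l2.call(m.name)

    def test_l1_only_state_missing_from_l2_tissue(self, panel, models):
        leaf, l2 = simulate_clone_tissues(models["PG52"], panel)
        assert "empty" in leaf.call("Gret1").alleles
        assert "empty" not in l2.call("Gret1").alleles
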