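"""L2 haplotype resolution from selfed progenies."""

import numpy as np
import pytest

from periclinal.model import (
    NULL,
    UNKNOWN,
    AlleleCall,
    CloneLayerModel,
    GenotypeTable,
    Haplotype,
    MISSING_CALL,
    SampleGenotype,
    Tissue,
)
from periclinal.phasing import (
    deduce_l2_from_tissue,
    find_nonrecombinant_homozygotes,
    resolve_L2_haplotypes,
)
from periclinal.pinot import canonical_library, table1_genotypes
from periclinal.simulate import (
    SimulationConfig,
    random_haplotype_pair,
    simulate_clone_tissues,
    simulate_selfed_progeny,
)


def _mismatches(pair, truth, panel):
    """Mis-assigned truly-segregating loci, minimized over label swap."""

    def count(a, b):
        n = 0
        for m in panel:
            ta, tb = truth[0][m.name], truth[1][m.name]
            if ta == tb:
                continue
            pa, pb = a[m.name], b[m.name]
            if pa is UNKNOWN or pb is UNKNOWN or (pa, pb) != (ta, tb):
                n += 1
        return n

    return min(count(*pair), count(*pair[::-1]))


class TestNonRecombinantHomozygotes:
    def test_no_recombination_determines_flank_pairing(self, panel, sim_library):
        pair = (sim_library["c188"], sim_library["w216"])
        cfg = SimulationConfig(
            n_progeny=100, genetic_map_cM=[0.0] * (len(panel) - 1), seed=21
        )
        table = simulate_selfed_progeny(pair, cfg, panel)
        part = find_nonrecombinant_homozygotes(table, "VMC5g7", "VMC7g3")
        assert not part.excluded
        assert set(part.groups) <= {("188", "132"), ("216", "116")}
        n_homozygous_a = sum(
            1 for s in table if s.call("VMC5g7").alleles in ({"188"}, {"216"})
        )
        assert sum(len(v) for v in part.groups.values()) == n_homozygous_a

    def test_hand_built_double_recombinant_is_excluded(self, panel):
        def row(i, a, b):
            calls = {m.name: MISSING_CALL for m in panel}
            calls["VMC5g7"] = AlleleCall.of(a)
            calls["VMC7g3"] = AlleleCall.of(b)
            return SampleGenotype(f"p{i}", Tissue.PROGENY, calls)

        rows = [
            row(1, "188", "132"),
            row(2, "188", "132"),
            row(3, "216", "116"),
            row(4, "216", "116"),
            row(5, "188", "132"),
            row(6, "188", "116"),  # repulsion combination: double recombinant
        ]
        part = find_nonrecombinant_homozygotes(
            GenotypeTable(panel, rows), "VMC5g7", "VMC7g3"
        )
        assert sum(len(v) for v in part.groups.values()) == 5
        assert part.excluded == ["p6"]

    def test_partitions_read_off_pure_haplotypes(self, panel, models):
        # the returned non-recombinants are the individuals from which the
        # canonical haplotypes can be read directly: their homozygous
        # internal reads must match the co-phased parental haplotype
        cfg = SimulationConfig(n_progeny=51, seed=22)
        table = simulate_selfed_progeny(models["PN162"].L2, cfg, panel)
        part = find_nonrecombinant_homozygotes(table, "VMC5g7", "VMC7g3")
        truth = {str(h["VMC5g7"]): h for h in models["PN162"].L2}
        impure = 0
        for (a, _b), sample_ids in part.groups.items():
            hap = truth[a]
            for sid in sample_ids:
                s = table.sample(sid)
                for m in panel:
                    call = s.call(m.name)
                    if len(call.alleles) == 1 and set(call.alleles) != {str(hap[m.name])}:
                        impure += 1
        assert impure == 0

    def test_empty_result_carries_warning(self, panel):
        calls = {m.name: MISSING_CALL for m in panel}
        calls["VMC5g7"] = AlleleCall.of("188", "216")
        calls["VMC7g3"] = AlleleCall.of("116", "132")
        table = GenotypeTable(panel, [SampleGenotype("p", Tissue.PROGENY, calls)])
        part = find_nonrecombinant_homozygotes(table, "VMC5g7", "VMC7g3")
        assert not part.groups and part.warnings


class TestResolveL2:
    def test_reference_clone_recovers_canonical_pair(self, panel, models):
        model = models["PN162"]
        leaf, _ = simulate_clone_tissues(model, panel)
        cfg = SimulationConfig(n_progeny=51, seed=23)
        progeny = simulate_selfed_progeny(model.L2, cfg, panel)
        res = resolve_L2_haplotypes(progeny, leaf, panel)
        assert res.anchor_marker == "Gret1"  # color insertion pair preferred
        assert _mismatches(res.haplotype_pair, model.L2, panel) == 0

    def test_conversion_clone_shows_fixed_run_and_null(self, panel, models):
        model = models["PG52"]
        leaf, _ = simulate_clone_tissues(model, panel)
        cfg = SimulationConfig(n_progeny=24, seed=24)
        progeny = simulate_selfed_progeny(model.L2, cfg, panel)
        res = resolve_L2_haplotypes(progeny, leaf, panel)
        h1, h2 = res.haplotype_pair
        assert h1["VVNTm1"] == h2["VVNTm1"] == "168"
        assert h1["VVNTm2"] == h2["VVNTm2"] == "387"
        assert {h1["Gret1"], h2["Gret1"]} == {NULL, "full"}
        # L1-only alleles (the chimeric layer) flagged from the leaf
        assert {"VVNTm1", "VVNTm2", "Gret1"} <= set(res.chimera_signals)
        assert _mismatches(res.haplotype_pair, model.L2, panel) == 0

    def test_row_order_invariance(self, panel, models):
        model = models["PG53"]
        leaf, _ = simulate_clone_tissues(model, panel)
        cfg = SimulationConfig(n_progeny=18, seed=25)
        progeny = simulate_selfed_progeny(model.L2, cfg, panel)
        res1 = resolve_L2_haplotypes(progeny, leaf, panel)
        reversed_table = GenotypeTable(panel, list(reversed(progeny.samples)))
        res2 = resolve_L2_haplotypes(reversed_table, leaf, panel)
        assert _mismatches(res1.haplotype_pair, res2.haplotype_pair, panel) == 0

    def test_progeny_allele_union_matches_resolved_pair(self, panel, models):
        model = models["PG3106"]
        leaf, _ = simulate_clone_tissues(model, panel)
        cfg = SimulationConfig(n_progeny=24, seed=26)
        progeny = simulate_selfed_progeny(model.L2, cfg, panel)
        res = resolve_L2_haplotypes(progeny, leaf, panel)
        h1, h2 = res.haplotype_pair
        for m in panel:
            transmitted = set()
            for s in progeny:
                transmitted |= set(s.call(m.name).alleles)
            resolved = {
                str(x) for x in (h1[m.name], h2[m.name]) if x not in (NULL, UNKNOWN)
            }
            assert resolved == transmitted, m.name

    def test_too_few_progeny_rejected(self, panel, models):
        cfg = SimulationConfig(n_progeny=5, seed=27)
        progeny = simulate_selfed_progeny(models["PN162"].L2, cfg, panel)
        with pytest.raises(ValueError, match="progeny"):
            resolve_L2_haplotypes(progeny, None, panel)

    def test_fully_homozygous_parent_cannot_be_phased(self, panel, sim_library):
        hom = sim_library["w216"]
        cfg = SimulationConfig(n_progeny=20, seed=28)
        progeny = simulate_selfed_progeny((hom, hom), cfg, panel)
        with pytest.raises(ValueError, match="no segregation"):
            resolve_L2_haplotypes(progeny, None, panel)

    def test_random_parents_are_recovered_exactly(self, panel):
        failures = 0
        for seed in range(30):
            rng = np.random.default_rng([seed, 404])
            pair = random_haplotype_pair(panel, rng)
            if all(pair[0][m.name] == pair[1][m.name] for m in panel):
                continue
            progeny = simulate_selfed_progeny(
                pair, SimulationConfig(n_progeny=200, seed=seed), panel, rng=rng
            )
            leaf, _ = simulate_clone_tissues(CloneLayerModel("t", pair, pair), panel)
            res = resolve_L2_haplotypes(progeny, leaf, panel)
            failures += _mismatches(res.haplotype_pair, pair, panel) > 0
        assert failures == 0


class TestDeduceFromTissue:
    def test_bud_sport_pith_splits_into_canonical_plus_tract(self, panel, table1):
        # the green-yellow bud-sport genotype: single white alleles from
        # P2-106 to VVNTm5, heterozygous outside
        tissue = table1.sample("genotype_VI")
        tissue.tissue = Tissue.L2_DERIVED
        pair, notes = deduce_l2_from_tissue(tissue, canonical_library(), panel)
        known, partner = pair
        assert known.name == "w216"
        assert partner["VMC5g7"] == "188"
        assert partner["P2-106"] == "262" and partner["VVNTm5"] == "288"
        assert partner["Gret1"] == "full"
        assert partner["Noble225"] == "empty" and partner["VMC7g3"] == "132"
        assert any("hemizygosity not excluded" in n for n in notes)

    def test_inconsistent_tissue_is_rejected(self, panel):
        calls = {m.name: AlleleCall.of("999") for m in panel}
        tissue = SampleGenotype("x", Tissue.L2_DERIVED, calls)
        with pytest.raises(ValueError, match="consistent"):
            deduce_l2_from_tissue(tissue, canonical_library(), panel)
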