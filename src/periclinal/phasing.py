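"""Resolution of the two L2 haplotypes of a clone from its selfed progeny.

Because gametes derive from the L2 meristem layer only, allele segregation
in a self-progeny reveals the L2 haplotype pair — including states that
whole-leaf genotyping cannot see: runs fixed by somatic replacement
(homozygous in L2 though the leaf is heterozygous) and null alleles
(deleted on one haplotype).

The procedure mirrors the classical selfed-progeny design: pick an anchor
locus with clear codominant-equivalent segregation (the berry-color
insertion pair when available), then read the internal alleles off progeny
that are homozygous at the anchor and non-recombinant in between — any
progeny whose internal allele conflicts with an already-phased locus is
treated as recombinant and excluded from phasing farther loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    NULL,
    UNKNOWN,
    AssayType,
    GenotypeTable,
    Haplotype,
    MarkerPanel,
    SampleGenotype,
)
from .segregation import (
    LocusSegregation,
    SegClass,
    _em_rf,
    classify_locus_segregation,
)

__all__ = [
    "PhasedResult",
    "NonRecombinantPartition",
    "find_nonrecombinant_homozygotes",
    "resolve_L2_haplotypes",
    "deduce_l2_from_tissue",
]


@dataclass
class PhasedResult:
    haplotype_pair: tuple[Haplotype, Haplotype]
    per_marker_support: dict[str, int]
    conflicts: list[str]
    anchor_marker: str
    chimera_signals: list[str] = field(default_factory=list)
    segregations: dict[str, LocusSegregation] = field(default_factory=dict)


@dataclass
class NonRecombinantPartition:
    """Progeny homozygous at two flanking markers, split by gamete phase.

    ``groups`` maps the two coupling flank-allele combinations to sample
    ids; progeny homozygous for a repulsion combination (double
    recombinants between the flanks) are listed in ``excluded``.
    """

    groups: dict[tuple[str, str], list[str]]
    excluded: list[str]
    warnings: list[str] = field(default_factory=list)


def _hom_allele(call) -> str | None:
    if not call.missing and not call.no_amplification and len(call.alleles) == 1:
        return next(iter(call.alleles))
    return None


def find_nonrecombinant_homozygotes(
    progeny: GenotypeTable, flank_a: str, flank_b: str
) -> NonRecombinantPartition:
    """Partition progeny homozygous at both flanks by consistent gamete phase.

    The two flank-allele combinations kept are the perfect matching of
    flank alleles with the highest joint count (the coupling combinations
    when recombination between the flanks is below 50%).
    """
    combos: dict[tuple[str, str], list[str]] = {}
    for s in progeny:
        a = _hom_allele(s.call(flank_a))
        b = _hom_allele(s.call(flank_b))
        if a is not None and b is not None:
            combos.setdefault((a, b), []).append(s.sample_id)
    if not combos:
        return NonRecombinantPartition({}, [], ["no progeny homozygous at both flanks"])
    alleles_a = sorted({a for a, _ in combos})
    alleles_b = sorted({b for _, b in combos})
    if len(alleles_a) == 2 and len(alleles_b) == 2:
        m1 = [(alleles_a[0], alleles_b[0]), (alleles_a[1], alleles_b[1])]
        m2 = [(alleles_a[0], alleles_b[1]), (alleles_a[1], alleles_b[0])]
        count = lambda m: sum(len(combos.get(c, [])) for c in m)
        keep = m1 if count(m1) >= count(m2) else m2
    else:
        keep = sorted(combos)
    groups = {c: combos[c] for c in keep if c in combos}
    excluded = [sid for c, sids in combos.items() if c not in keep for sid in sids]
    return NonRecombinantPartition(groups, sorted(excluded))


def _refine_phase_consistency(
    progeny: GenotypeTable,
    panel: MarkerPanel,
    hap1: dict,
    hap2: dict,
    conflicts: list[str],
    max_sweeps: int = 3,
) -> None:
    """Make per-locus phase assignments mutually consistent.

    Chained phasing decides each locus against one nearby anchor; with a
    small progeny and a wide marker gap a single wrong decision flips a
    whole block against the rest.  Each phased locus is re-evaluated
    against its nearest phased neighbors (two per side) by summed
    two-point log-likelihood ratios and flipped when the joint evidence
    says so; the minority orientation loses, restoring a self-consistent
    pair (labels being arbitrary, global consistency is what matters).
    """
    seg_loci = [
        m.name
        for m in panel
        if hap1.get(m.name) is not None
        and hap1[m.name] is not UNKNOWN
        and hap2[m.name] is not UNKNOWN
        and hap1[m.name] != hap2[m.name]
    ]
    if len(seg_loci) < 2:
        return
    calls = {m: [s.call(m) for s in progeny] for m in seg_loci}
    cc_cache: dict = {}

    def class_counts(a: str, b: str) -> dict:
        if (a, b) not in cc_cache:
            cc: dict = {}
            for ca, cb in zip(calls[a], calls[b]):
                if ca.missing or cb.missing:
                    continue
                key = (ca.alleles, cb.alleles)
                cc[key] = cc.get(key, 0) + 1
            cc_cache[(a, b)] = cc
        return cc_cache[(a, b)]

    to_state = lambda s: None if s is NULL else str(s)

    def llr_keep(ref: str, m: str) -> float:
        cc = class_counts(ref, m)
        sa = (to_state(hap1[ref]), to_state(hap2[ref]))
        sb = (to_state(hap1[m]), to_state(hap2[m]))
        _, ll_keep = _em_rf(cc, sa, sb)
        _, ll_flip = _em_rf(cc, sa, sb[::-1])
        return ll_keep - ll_flip

    for _ in range(max_sweeps):
        changed = False
        for i, m in enumerate(seg_loci):
            refs = seg_loci[max(0, i - 2) : i] + seg_loci[i + 1 : i + 3]
            total = sum(llr_keep(ref, m) for ref in refs)
            if total < -1e-9:
                hap1[m], hap2[m] = hap2[m], hap1[m]
                conflicts.append(f"{m}: phase flipped by joint-likelihood consistency sweep")
                changed = True
        if not changed:
            break


def _phase_by_likelihood(
    progeny: GenotypeTable,
    ref_marker: str,
    ref_states: tuple,
    marker: str,
    options: tuple,
) -> int | None:
    """Index (0/1) of the hap1 state at ``marker`` maximizing the two-point
    likelihood against an already-phased reference locus, or None on a tie."""
    to_state = lambda s: None if s is NULL else str(s)
    states_ref = (to_state(ref_states[0]), to_state(ref_states[1]))
    class_counts: dict[tuple, int] = {}
    for s in progeny:
        ca, cb = s.call(ref_marker), s.call(marker)
        if ca.missing or cb.missing:
            continue
        key = (ca.alleles, cb.alleles)
        class_counts[key] = class_counts.get(key, 0) + 1
    if not class_counts:
        return None
    _, ll0 = _em_rf(class_counts, states_ref, (to_state(options[0]), to_state(options[1])))
    _, ll1 = _em_rf(class_counts, states_ref, (to_state(options[1]), to_state(options[0])))
    if ll0 == ll1:
        return None
    return 0 if ll0 > ll1 else 1


def _pick_anchor(
    panel: MarkerPanel,
    segs: dict[str, LocusSegregation],
    color_marker: str | None,
) -> str:
    segregating = [m for m in panel if segs[m.name].classification is SegClass.SEGREGATING]
    if not segregating:
        raise ValueError("no segregation to phase: all loci are fixed, monomorphic or irregular")
    if color_marker is not None:
        for m in segregating:
            if m.name == color_marker and m.assay_type is AssayType.INSERTION_SITE_PAIR:
                return m.name
    # most informative progeny, then smallest physical position
    best = max(segregating, key=lambda m: (segs[m.name].n_informative, -m.position_bp))
    return best.name


def resolve_L2_haplotypes(
    progeny: GenotypeTable,
    parent_leaf: SampleGenotype | None,
    panel: MarkerPanel,
    *,
    error_rate: float = 0.0,
    dropout_rate: float = 0.0,
    min_progeny: int = 10,
    min_nonrecombinants: int = 2,
    color_marker: str | None = "Gret1",
) -> PhasedResult:
    """Resolve the parent's L2 haplotype pair from a selfed-progeny table.

    Per-locus segregation classes drive the assignment: SEGREGATING loci
    are phased from anchor-homozygous non-recombinant progeny (with the
    complementary allele on the other haplotype), FIXED and MONOMORPHIC
    loci put the same allele on both haplotypes, NULL_SEGREGATING loci put
    NULL on the haplotype whose co-phased progeny class fails to amplify.
    Loci that cannot be phased from at least ``min_nonrecombinants``
    non-recombinant homozygotes stay UNKNOWN with a conflict note.

    Alleles present in the parent leaf but never transmitted to progeny
    are reported in ``chimera_signals``: they mark L1-only states of a
    periclinal chimera.
    """
    if len(progeny) < min_progeny:
        raise ValueError(f"need >= {min_progeny} progeny, got {len(progeny)}")
    segs = {
        m.name: classify_locus_segregation(
            progeny, m.name, parent_leaf, error_rate=error_rate, dropout_rate=dropout_rate
        )
        for m in panel
    }
    anchor = _pick_anchor(panel, segs, color_marker)
    s1, s2 = segs[anchor].alleles  # deterministic label order

    # side of each progeny: 0/1 if homozygous at the anchor, else None
    side: dict[str, int] = {}
    for s in progeny:
        a = _hom_allele(s.call(anchor))
        if a == s1:
            side[s.sample_id] = 0
        elif a == s2:
            side[s.sample_id] = 1

    hap1: dict = {}
    hap2: dict = {}
    support: dict[str, int] = {}
    conflicts: list[str] = []

    hap1[anchor] = s1
    hap2[anchor] = s2
    support[anchor] = sum(1 for v in side.values())

    anchor_idx = panel.index(anchor)
    order = sorted(range(len(panel)), key=lambda i: (abs(i - anchor_idx), i))
    # Phase is chained outward: each locus is read against the nearest
    # already-phased codominant locus on its anchor side, so the linkage
    # exploited is always the tightest available and distal loci do not
    # run out of non-recombinant anchor homozygotes.
    local_anchor = {+1: anchor, -1: anchor}

    def sides_at(marker: str) -> dict[str, int]:
        a1, a2 = hap1[marker], hap2[marker]
        out: dict[str, int] = {}
        for s in progeny:
            h = _hom_allele(s.call(marker))
            if h == a1:
                out[s.sample_id] = 0
            elif h == a2:
                out[s.sample_id] = 1
        return out

    for idx in order:
        m = panel.markers[idx]
        if m.name == anchor:
            continue
        direction = +1 if idx > anchor_idx else -1
        seg = segs[m.name]
        cls = seg.classification
        if cls in (SegClass.FIXED, SegClass.MONOMORPHIC):
            if len(seg.alleles) == 1:
                hap1[m.name] = hap2[m.name] = seg.alleles[0]
                support[m.name] = seg.n_informative
            else:
                hap1[m.name] = hap2[m.name] = UNKNOWN
                conflicts.append(f"{m.name}: fixed heterozygous pattern cannot be phased")
            continue
        if cls is SegClass.IRREGULAR:
            hap1[m.name] = hap2[m.name] = UNKNOWN
            conflicts.append(f"{m.name}: irregular segregation")
            continue

        if cls is SegClass.SEGREGATING:
            a, b = seg.alleles
            options = (a, b)  # candidate states for hap1 (hap2 complementary)
        else:  # NULL_SEGREGATING
            (a,) = seg.alleles
            options = (a, NULL)

        ref = local_anchor[direction]
        ref_side = sides_at(ref)
        votes = {options[0]: 0, options[1]: 0}
        for s in progeny:
            sd = ref_side.get(s.sample_id)
            if sd is None:
                continue
            call = s.call(m.name)
            if call.no_amplification and cls is SegClass.NULL_SEGREGATING:
                read: object = NULL
            elif call.no_amplification or call.missing:
                continue
            else:
                read = _hom_allele(call)
                if read not in (options[0], options[1]):
                    continue
            # a side-0 homozygote read supports hap1 = read;
            # a side-1 homozygote read supports hap2 = read, i.e. hap1 = other
            implied_hap1 = read if sd == 0 else (options[1] if read == options[0] else options[0])
            votes[implied_hap1] += 1

        total = votes[options[0]] + votes[options[1]]
        winner = max(options, key=lambda o: votes[o])
        loser = options[0] if winner == options[1] else options[1]
        if total == 0:
            hap1[m.name] = hap2[m.name] = UNKNOWN
            conflicts.append(
                f"{m.name}: never observed homozygous in non-recombinant progeny"
            )
            continue
        if total < min_nonrecombinants:
            # a single supporting homozygote is below the evidence floor on
            # its own; accept it only if the two-point likelihood over the
            # whole progeny points the same way
            choice = _phase_by_likelihood(progeny, ref, (hap1[ref], hap2[ref]), m.name, options)
            if choice is None or options[choice] != winner or votes[loser] > 0:
                hap1[m.name] = hap2[m.name] = UNKNOWN
                conflicts.append(
                    f"{m.name}: insufficient non-recombinant support "
                    f"({total} < {min_nonrecombinants})"
                )
                continue
            conflicts.append(
                f"{m.name}: phased from {total} homozygote(s) backed by two-point likelihood"
            )
        if votes[loser] > 0:
            # conflicting non-recombinant reads mean recombination between
            # the anchor and this locus; a bare homozygote majority is then
            # unreliable with small progenies, so the phase is decided by
            # the two-point likelihood over the whole progeny (which also
            # uses heterozygous and amplification-failure classes)
            conflicts.append(
                f"{m.name}: {votes[loser]} conflicting non-recombinant read(s) "
                f"against anchor {ref}"
            )
            choice = _phase_by_likelihood(progeny, ref, (hap1[ref], hap2[ref]), m.name, options)
            if choice is not None:
                winner = options[choice]
                loser = options[1 - choice]
            elif votes[winner] == votes[loser]:
                hap1[m.name] = hap2[m.name] = UNKNOWN
                conflicts.append(
                    f"{m.name}: tied phase support ({votes[winner]} vs {votes[loser]})"
                )
                continue
        hap1[m.name] = winner
        hap2[m.name] = loser
        support[m.name] = votes[winner]
        if cls is SegClass.SEGREGATING:
            local_anchor[direction] = m.name

    _refine_phase_consistency(progeny, panel, hap1, hap2, conflicts)

    chimera_signals: list[str] = []
    if parent_leaf is not None:
        for m in panel:
            leaf_call = parent_leaf.call(m.name)
            if leaf_call.missing:
                continue
            transmitted = set()
            for s in progeny:
                c = s.call(m.name)
                if not c.missing:
                    transmitted |= set(c.alleles)
            if set(leaf_call.alleles) - transmitted:
                chimera_signals.append(m.name)

    parent_id = parent_leaf.sample_id if parent_leaf is not None else "parent"
    pair = (
        Haplotype(f"{parent_id}.h1", hap1),
        Haplotype(f"{parent_id}.h2", hap2),
    )
    return PhasedResult(pair, support, conflicts, anchor, chimera_signals, segs)


def deduce_l2_from_tissue(
    l2_tissue: SampleGenotype,
    library: list[Haplotype],
    panel: MarkerPanel,
) -> tuple[tuple[Haplotype, Haplotype], list[str]]:
    """Deduce an L2 haplotype pair from an L2-derived tissue genotype alone.

    Without progeny, an L2 genotype (roots, stem pith) can still be split
    when one library haplotype is consistent with it at every assayed
    locus: the partner haplotype is obtained by subtraction.  At loci
    where the tissue shows a single allele the partner is assigned the
    same allele, with the explicit caveat that hemizygosity (a null
    allele) cannot be excluded without progeny data.
    """
    def consistent(h: Haplotype) -> bool:
        for m in panel:
            call = l2_tissue.call(m.name)
            if call.missing:
                continue
            state = h[m.name]
            if state is UNKNOWN:
                continue
            if call.no_amplification:
                if state is not NULL:
                    return False
            elif state is not NULL and str(state) not in call.alleles:
                return False
        return True

    def concreteness(h: Haplotype) -> int:
        return sum(1 for m in panel if h[m.name] is not UNKNOWN)

    candidates = [h for h in library if consistent(h)]
    if not candidates:
        raise ValueError(
            f"no library haplotype is consistent with tissue genotype {l2_tissue.sample_id!r}"
        )
    candidates.sort(key=concreteness, reverse=True)  # stable: library order breaks ties
    known = candidates[0]
    annotations: list[str] = []
    partner: dict = {}
    for m in panel:
        call = l2_tissue.call(m.name)
        if call.missing:
            partner[m.name] = UNKNOWN
            continue
        if call.no_amplification:
            partner[m.name] = NULL
            continue
        state = known[m.name]
        if state is UNKNOWN:
            partner[m.name] = UNKNOWN
            if len(call.alleles) > 1:
                annotations.append(f"{m.name}: phase unresolved ({'/'.join(sorted(call.alleles))})")
            continue
        residual = set(call.alleles) - ({str(state)} if state is not NULL else set())
        if len(residual) == 1:
            partner[m.name] = next(iter(residual))
        elif not residual:
            partner[m.name] = str(state)
            annotations.append(f"{m.name}: homozygous in tissue; hemizygosity not excluded")
        else:
            partner[m.name] = UNKNOWN
            annotations.append(f"{m.name}: {len(call.alleles)} alleles cannot be split")
    pair = (known, Haplotype(f"{l2_tissue.sample_id}.deduced", partner))
    return pair, annotations
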