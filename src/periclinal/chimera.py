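"""Periclinal chimera detection, L1 deduction and berry-color phenotype.

A periclinal chimera carries distinct genotypes in the L1 (epidermal) and
L2 (subepidermal) meristem layers.  Whole-leaf DNA pools both layers, so a
chimera betrays itself by tri-allelic SSR profiles or by leaf alleles
absent from L2-derived tissue and progeny.  Once the L2 haplotype pair is
resolved, candidate L1 pairs are those explaining the leaf allele pool,
ranked by parsimony: a single somatic mutation separates the layers, so
pairs sharing a haplotype with L2 and drawn from known haplotypes are
preferred.

Berry color follows the layers: anthocyanin in the berry skin comes from
the L1-derived epidermis (grey berries = colored L1 over white L2), while
a fully white plant is green-yellow and any colored L2 under a white L1
still yields blue-black fruit.  The functional colored allele is dominant
within a layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .classify import ColorStatus, functional_color_status
from .model import (
    NULL,
    UNKNOWN,
    CloneLayerModel,
    Haplotype,
    MarkerPanel,
    SampleGenotype,
)

__all__ = [
    "ChimeraCall",
    "LayerDeduction",
    "PhenotypePrediction",
    "RearrangementKind",
    "detect_chimera",
    "deduce_L1",
    "predict_phenotype",
    "apply_layer_rearrangement",
]


@dataclass
class ChimeraCall:
    is_chimeric: bool
    triallelic_loci: list[str]
    leaf_only_states: dict[str, set[str]]


@dataclass
class LayerDeduction:
    """Ranked candidate L1 haplotype pairs.

    The parsimony score is (haplotypes not shared with L2, haplotypes not
    drawn from the library); lower sorts first.  Co-ranked candidates are
    all reported rather than silently tie-broken.
    """

    candidate_L1_pairs: list[tuple[tuple[Haplotype, Haplotype], tuple[int, int]]]
    contains_unknown: bool = False


@dataclass(frozen=True)
class PhenotypePrediction:
    oiv225: int  # OIV descriptor 225: 1 green-yellow, 4 grey, 6 blue-black
    rationale: str


class RearrangementKind(str, enum.Enum):
    DISPLACEMENT = "DISPLACEMENT"  # L2 cells invade L1
    REPLACEMENT = "REPLACEMENT"  # L1 cells invade L2


def _l2_alleles(l2, panel: MarkerPanel) -> dict[str, set[str]]:
    """Per-marker L2 allele sets from a tissue genotype or a haplotype pair."""
    out: dict[str, set[str]] = {}
    if isinstance(l2, SampleGenotype):
        for m in panel:
            call = l2.call(m.name)
            out[m.name] = set() if call.missing else set(call.alleles)
        return out
    for m in panel:
        out[m.name] = {str(h[m.name]) for h in l2 if h[m.name] not in (NULL, UNKNOWN)}
    return out


def detect_chimera(leaf: SampleGenotype, l2, panel: MarkerPanel) -> ChimeraCall:
    """Compare a leaf genotype with the L2 state (tissue or resolved pair).

    Tri-allelic leaf profiles and leaf alleles absent from L2 both mark a
    chimeric plant (the extra states live in L1 only).  Markers not
    assayed in the L2 tissue, or whose extra alleles could hide behind
    unresolved (UNKNOWN) L2 states, are not counted as evidence.
    """
    l2_sets = _l2_alleles(l2, panel)
    is_pair = not isinstance(l2, SampleGenotype)
    triallelic: list[str] = []
    leaf_only: dict[str, set[str]] = {}
    for m in panel:
        call = leaf.call(m.name)
        if call.missing:
            continue
        if len(call.alleles) >= 3:
            triallelic.append(m.name)
        if is_pair:
            hidden = sum(1 for h in l2 if h[m.name] is UNKNOWN)
        else:
            if l2.call(m.name).missing:
                continue
            hidden = 0
        extra = set(call.alleles) - l2_sets[m.name]
        if len(extra) > hidden:
            leaf_only[m.name] = extra
    return ChimeraCall(bool(triallelic or leaf_only), triallelic, leaf_only)


def _pair_score(
    pair: tuple[Haplotype, Haplotype],
    L2_pair: tuple[Haplotype, Haplotype],
    library_names: set[str],
) -> tuple[int, int]:
    # multiset sharing: (h, h) against an (h, k) L2 pair shares one
    # haplotype only — reusing the same L2 haplotype twice implies an
    # extra somatic event and must not outrank the unchanged L2 pair
    remaining = [h.name for h in L2_pair]
    not_shared = 0
    for h in pair:
        if h.name in remaining:
            remaining.remove(h.name)
        else:
            not_shared += 1
    l2_names = {h.name for h in L2_pair}
    non_library = sum(1 for h in pair if h.name not in library_names and h.name not in l2_names)
    return (not_shared, non_library)


def deduce_L1(
    leaf: SampleGenotype,
    L2_pair: tuple[Haplotype, Haplotype],
    library: list[Haplotype],
    panel: MarkerPanel,
) -> LayerDeduction:
    """Candidate L1 haplotype pairs explaining the leaf allele pool.

    Pairs are drawn from the library plus the L2 haplotypes and must
    reproduce the leaf exactly: at every assayed marker the union of the
    four haplotypes' amplifiable states equals the leaf allele set.  When
    no such pair exists, a minimal partner haplotype is synthesized from
    the residual leaf alleles (UNKNOWN elsewhere) and flagged.
    """
    l2_sets = _l2_alleles(L2_pair, panel)
    leaf_sets: dict[str, set[str] | None] = {}
    for m in panel:
        call = leaf.call(m.name)
        leaf_sets[m.name] = None if call.missing else set(call.alleles)
        if leaf_sets[m.name] is not None and not l2_sets[m.name] <= leaf_sets[m.name]:
            raise ValueError(
                f"leaf/L2 inconsistency at {m.name}: L2 alleles "
                f"{sorted(l2_sets[m.name])} not all present in leaf"
            )

    def concrete(h: Haplotype, marker: str) -> set[str]:
        s = h[marker]
        return set() if s in (NULL, UNKNOWN) else {str(s)}

    def n_unknown(haps, marker: str) -> int:
        return sum(1 for h in haps if h[marker] is UNKNOWN)

    def satisfies(pair: tuple[Haplotype, Haplotype]) -> bool:
        for m in panel:
            want = leaf_sets[m.name]
            if want is None:
                continue
            got = l2_sets[m.name] | concrete(pair[0], m.name) | concrete(pair[1], m.name)
            # a concrete allele outside the leaf pool disproves the pair;
            # leaf alleles not covered must be attributable to unresolved
            # (UNKNOWN) states, each of which can hide one allele
            if got - want:
                return False
            if len(want - got) > n_unknown((*pair, *L2_pair), m.name):
                return False
        return True

    pool: list[Haplotype] = list(L2_pair)
    names = {h.name for h in pool}
    for h in library:
        if h.name not in names:
            pool.append(h)
            names.add(h.name)
    library_names = {h.name for h in library}

    def lib_rank(h: Haplotype) -> int:
        # canonical haplotypes come first in a library; on score ties,
        # prefer pairs drawing on earlier (non-mosaic) entries
        for i, entry in enumerate(library):
            if h.name == entry.name or h.same_states(entry, panel, skip_unknown=True):
                return i
        return len(library)

    def sort_key(c):
        pair, score = c
        return (score, lib_rank(pair[0]) + lib_rank(pair[1]))

    candidates = [
        (pair, _pair_score(pair, L2_pair, library_names))
        for pair in combinations_with_replacement(pool, 2)
        if satisfies(pair)
    ]
    if candidates:
        candidates.sort(key=sort_key)
        return LayerDeduction(candidates, contains_unknown=False)

    # synthesize a minimal partner for each known first haplotype
    synthesized: list[tuple[tuple[Haplotype, Haplotype], tuple[int, int]]] = []
    for h1 in pool:
        alleles: dict = {}
        ok = True
        for m in panel:
            want = leaf_sets[m.name]
            if want is None:
                alleles[m.name] = UNKNOWN
                continue
            if concrete(h1, m.name) - want:
                ok = False
                break
            residual = want - l2_sets[m.name] - concrete(h1, m.name)
            if len(residual) == 1:
                alleles[m.name] = residual.pop()
            elif not residual:
                alleles[m.name] = UNKNOWN
            elif len(residual) <= 1 + n_unknown((h1, *L2_pair), m.name):
                alleles[m.name] = UNKNOWN  # split across unresolved states is ambiguous
            else:
                ok = False
                break
        if not ok:
            continue
        h2 = Haplotype(f"{leaf.sample_id}.L1-unknown", alleles)
        n_invented = sum(1 for v in alleles.values() if v is not UNKNOWN)
        pair = (h1, h2)
        synthesized.append((n_invented, pair, _pair_score(pair, L2_pair, library_names)))
    if not synthesized:
        raise ValueError("leaf/L2 inconsistency: no haplotype pair can explain the leaf")
    # invent as little as possible first, then usual parsimony
    synthesized.sort(key=lambda c: (c[0], sort_key((c[1], c[2]))))
    best_key = (synthesized[0][0], synthesized[0][2])
    top = [(pair, score) for n, pair, score in synthesized if (n, score) == best_key]
    return LayerDeduction(top, contains_unknown=True)


def predict_phenotype(model: CloneLayerModel) -> PhenotypePrediction:
    """OIV descriptor 225 berry color of a (possibly chimeric) clone.

    A layer is colored when at least one of its haplotypes carries the
    functional colored allele (dominant).  Colored L1 over white L2 gives
    the grey phenotype; a white L1 over a colored L2 is indistinguishable
    from a fully colored plant in the fruit.
    """
    statuses = {}
    for layer, pair in (("L1", model.L1), ("L2", model.L2)):
        ss = [functional_color_status(h) for h in pair]
        if ColorStatus.UNDETERMINED in ss:
            raise ValueError(f"cannot predict: {layer} haplotype with undetermined color status")
        statuses[layer] = ColorStatus.COLORED if ColorStatus.COLORED in ss else ColorStatus.WHITE
    l1, l2 = statuses["L1"], statuses["L2"]
    if l1 is ColorStatus.COLORED and l2 is ColorStatus.COLORED:
        return PhenotypePrediction(6, "colored alleles in both layers: blue-black")
    if l1 is ColorStatus.COLORED:
        return PhenotypePrediction(4, "colored L1 epidermis over white L2: grey")
    if l2 is ColorStatus.COLORED:
        return PhenotypePrediction(6, "colored L2 under white L1: fruit identical to blue-black")
    return PhenotypePrediction(1, "no functional colored allele in either layer: green-yellow")


def predict_phenotype_from_tissues(
    leaf: SampleGenotype,
    l2,
    panel: MarkerPanel,
    *,
    color_marker: str = "Gret1",
    functional_state: str = "empty",
) -> PhenotypePrediction:
    """OIV 225 berry color from observed tissue states at the color locus.

    Works without fully resolved layer models: the functional colored
    allele shows as the retrotransposon empty site, so its presence in the
    L2 state and/or the leaf pool (which adds L1) fixes the phenotype.
    """
    call = leaf.call(color_marker)
    if call.missing:
        raise ValueError(f"cannot predict: leaf not assayed at {color_marker!r}")
    leaf_colored = functional_state in call.alleles
    if isinstance(l2, SampleGenotype):
        l2_call = l2.call(color_marker)
        if l2_call.missing:
            raise ValueError(f"cannot predict: L2 tissue not assayed at {color_marker!r}")
        l2_colored = functional_state in l2_call.alleles
    else:
        states = [h[color_marker] for h in l2]
        if any(s is UNKNOWN for s in states):
            raise ValueError(f"cannot predict: unresolved L2 state at {color_marker!r}")
        l2_colored = any(s is not NULL and str(s) == functional_state for s in states)
    if l2_colored:
        return PhenotypePrediction(6, "colored allele in L2: blue-black fruit")
    if leaf_colored:
        return PhenotypePrediction(4, "colored allele in leaf pool only (L1): grey")
    return PhenotypePrediction(1, "no colored allele in any layer: green-yellow")


def apply_layer_rearrangement(model: CloneLayerModel, kind: RearrangementKind) -> CloneLayerModel:
    """Homogenize a chimera by cell-layer invasion.

    DISPLACEMENT copies the L2 pair into L1 (inner cells invade the
    epidermis, the common direction); REPLACEMENT copies L1 into L2 (rare
    in angiosperms).  Applying the same kind twice equals applying it once.
    """
    suffix = "+D" if kind is RearrangementKind.DISPLACEMENT else "+R"
    clone_id = model.clone_id if model.clone_id.endswith(suffix) else model.clone_id + suffix
    if kind is RearrangementKind.DISPLACEMENT:
        return CloneLayerModel(clone_id, L1=model.L2, L2=model.L2)
    return CloneLayerModel(clone_id, L1=model.L1, L2=model.L1)
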