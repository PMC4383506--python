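"""Simulation of somatic mutation, chimeric tissues and selfed progenies.

Three layers of the generative process are modeled, at marker-allele
resolution:

* somatic events on a haplotype pair — gene-conversion tracts (internal,
  or running to the chromosome end) in which the recipient haplotype takes
  the donor's alleles, optionally combined with a deletion interval whose
  markers become NULL (never amplify);
* Mendelian self-fertilization — each offspring is the union of two
  independent recombinant gametes of the L2 haplotype pair, with crossover
  probabilities per marker interval derived from a genetic map through a
  mapping function (Haldane by default, making intervals independent, i.e.
  no interference);
* tissue sampling — whole-leaf DNA pools both meristem layers (allele
  union of all four haplotypes), while roots/pith and gametes derive from
  L2 only.

Genotyping noise is a symmetric allele substitution at a configurable
per-call rate, plus a separate dropout rate producing false amplification
failures; both default to 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .mapfun import MappingFunction, cM_to_rf
from .model import (
    NULL,
    UNKNOWN,
    AlleleCall,
    AssayType,
    CloneLayerModel,
    GenotypeTable,
    Haplotype,
    MarkerPanel,
    SampleGenotype,
    Tissue,
)

__all__ = [
    "SomaticEventKind",
    "SomaticEvent",
    "SimulationConfig",
    "apply_somatic_event",
    "simulate_selfed_progeny",
    "simulate_clone_tissues",
    "random_haplotype_pair",
]


class SomaticEventKind(str, enum.Enum):
    CONVERSION_INTERNAL = "CONVERSION_INTERNAL"
    CONVERSION_TO_END = "CONVERSION_TO_END"
    CONVERSION_WITH_DELETION = "CONVERSION_WITH_DELETION"


@dataclass(frozen=True)
class SomaticEvent:
    """A double-strand-break repair event copying donor sequence into the recipient.

    Coordinates are 1-based bp on the panel's chromosome.  For
    CONVERSION_TO_END the tract extends from ``tract_start_bp`` to the
    chromosome end (``tract_end_bp`` is ignored beyond validation).  For
    CONVERSION_WITH_DELETION, markers inside the deletion interval become
    NULL; the deletion may not precede the tract start.
    """

    kind: SomaticEventKind
    recipient: str
    donor: str
    tract_start_bp: int
    tract_end_bp: int
    deletion_start_bp: int | None = None
    deletion_end_bp: int | None = None

    def __post_init__(self) -> None:
        if self.tract_start_bp > self.tract_end_bp:
            raise ValueError("tract_start_bp must be <= tract_end_bp")
        has_del = self.deletion_start_bp is not None
        if has_del != (self.deletion_end_bp is not None):
            raise ValueError("deletion interval needs both start and end")
        if self.kind is SomaticEventKind.CONVERSION_WITH_DELETION and not has_del:
            raise ValueError("CONVERSION_WITH_DELETION requires a deletion interval")
        if has_del:
            if self.deletion_start_bp > self.deletion_end_bp:  # type: ignore[operator]
                raise ValueError("deletion_start_bp must be <= deletion_end_bp")
            if self.deletion_start_bp < self.tract_start_bp:  # type: ignore[operator]
                raise ValueError("deletion interval may not precede the tract start")


@dataclass
class SimulationConfig:
    """Parameters of a selfed-progeny simulation.

    ``genetic_map_cM`` holds one distance per adjacent marker interval of
    the panel; if None, a uniform 5 cM/Mb fixture rate is derived from
    physical spacing.  ``genotyping_error_rate`` is the per-call
    probability of replacing a call by a random other allele of the locus;
    ``dropout_rate`` the per-call probability of a false amplification
    failure.
    """

    n_progeny: int = 24
    genetic_map_cM: list[float] | None = None
    mapping_function: MappingFunction = MappingFunction.HALDANE
    genotyping_error_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self, panel: MarkerPanel) -> None:
        if self.n_progeny <= 0:
            raise ValueError("n_progeny must be > 0")
        if self.genetic_map_cM is not None:
            if len(self.genetic_map_cM) != len(panel) - 1:
                raise ValueError(
                    f"genetic_map_cM needs {len(panel) - 1} interval distances, "
                    f"got {len(self.genetic_map_cM)}"
                )
            if any(d < 0 for d in self.genetic_map_cM):
                raise ValueError("map distances must be >= 0")
        for rate, label in (
            (self.genotyping_error_rate, "genotyping_error_rate"),
            (self.dropout_rate, "dropout_rate"),
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{label} must be in [0, 1)")

    def interval_rfs(self, panel: MarkerPanel) -> np.ndarray:
        if self.genetic_map_cM is None:
            positions = [m.position_bp for m in panel]
            cm = [(b - a) / 1e6 * 5.0 for a, b in zip(positions, positions[1:])]
        else:
            cm = self.genetic_map_cM
        return np.array([cM_to_rf(d, self.mapping_function) for d in cm])


def _find_pair_member(pair: tuple[Haplotype, Haplotype], name: str) -> Haplotype:
    for h in pair:
        if h.name == name:
            return h
    raise ValueError(f"haplotype {name!r} is not a member of the pair "
                     f"({pair[0].name!r}, {pair[1].name!r})")


def apply_somatic_event(
    pair: tuple[Haplotype, Haplotype],
    event: SomaticEvent,
    panel: MarkerPanel,
    *,
    chromosome_length_bp: int | None = None,
    name: str | None = None,
) -> Haplotype:
    """Return the recipient haplotype after a conversion/deletion event.

    Markers with positions inside the tract take the donor's allele;
    markers inside the deletion interval become NULL; all other markers
    keep the recipient's alleles.  A zero-length tract falling between
    markers returns the recipient unchanged (apart from the name).
    """
    recipient = _find_pair_member(pair, event.recipient)
    donor = _find_pair_member(pair, event.donor)
    max_bp = chromosome_length_bp or max(m.position_bp for m in panel)
    if event.tract_start_bp < 1 or event.tract_start_bp > max_bp:
        raise ValueError(
            f"event tract start {event.tract_start_bp} outside chromosome [1, {max_bp}]"
        )
    if event.kind is not SomaticEventKind.CONVERSION_TO_END and event.tract_end_bp > max_bp:
        raise ValueError(
            f"event tract end {event.tract_end_bp} outside chromosome [1, {max_bp}]"
        )
    tract_end = max_bp if event.kind is SomaticEventKind.CONVERSION_TO_END else event.tract_end_bp
    alleles: dict = {}
    for m in panel:
        state = recipient[m.name]
        if event.tract_start_bp <= m.position_bp <= tract_end:
            state = donor[m.name]
        if (
            event.deletion_start_bp is not None
            and event.deletion_start_bp <= m.position_bp <= event.deletion_end_bp  # type: ignore[operator]
        ):
            state = NULL
        alleles[m.name] = state
    return Haplotype(name or f"{recipient.name}*", alleles)


def _require_concrete(h: Haplotype, panel: MarkerPanel) -> None:
    unknown = [m.name for m in panel if h[m.name] is UNKNOWN]
    if unknown:
        raise ValueError(
            f"haplotype {h.name!r} has UNKNOWN states at {unknown}; "
            "simulation needs concrete alleles (see canonical_library(concrete_sc8=True))"
        )


def _locus_universe(panel: MarkerPanel, pair: tuple[Haplotype, Haplotype]) -> list[set[str]]:
    universes = []
    for m in panel:
        u = {h[m.name] for h in pair} - {NULL, UNKNOWN}
        universes.append({str(x) for x in u})
    return universes


def simulate_selfed_progeny(
    L2: tuple[Haplotype, Haplotype],
    config: SimulationConfig,
    panel: MarkerPanel,
    *,
    parent_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Simulate an S1 (selfed) progeny table from an L2 haplotype pair.

    Each offspring is the union of two independent gametes; each gamete is
    a recombinant mosaic of the two haplotypes with per-interval crossover
    probabilities from the mapping function (no interference).  A call
    fails to amplify only when both inherited states are NULL.
    """
    config.validate(panel)
    for h in L2:
        _require_concrete(h, panel)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, n_loci = config.n_progeny, len(panel)
    rfs = config.interval_rfs(panel)

    # gamete phase matrix: 2n gametes x loci, values 0/1 indexing L2
    start = rng.integers(0, 2, size=(2 * n, 1))
    switches = rng.random((2 * n, n_loci - 1)) < rfs
    phase = np.concatenate(
        [start, np.logical_xor(start, np.cumsum(switches, axis=1) % 2 == 1).astype(int)[:, :]],
        axis=1,
    ) if n_loci > 1 else start
    # phase[:, 0] is start; for j>=1, phase flips when an odd number of
    # crossovers occurred in intervals 0..j-1
    states = [[L2[0][m.name], L2[1][m.name]] for m in panel]

    err = config.genotyping_error_rate
    drop = config.dropout_rate
    err_mask = rng.random((n, n_loci)) < err if err > 0 else None
    drop_mask = rng.random((n, n_loci)) < drop if drop > 0 else None
    universes = _locus_universe(panel, L2) if err > 0 else None

    samples = []
    for i in range(n):
        g1, g2 = phase[2 * i], phase[2 * i + 1]
        calls = {}
        for j, m in enumerate(panel):
            inherited = {states[j][g1[j]], states[j][g2[j]]}
            labels = {str(s) for s in inherited if s is not NULL}
            if err_mask is not None and err_mask[i, j]:
                others = sorted(universes[j] - labels)  # type: ignore[operator]
                if others:
                    labels = {others[int(rng.integers(len(others)))]}
            if drop_mask is not None and drop_mask[i, j]:
                labels = set()
            calls[m.name] = AlleleCall.of(*sorted(labels))
        samples.append(SampleGenotype(f"{parent_id}.{i + 1:04d}", Tissue.PROGENY, calls))
    return GenotypeTable(
        panel,
        samples,
        {"parent": parent_id, "seed": str(config.seed), "n_progeny": str(n)},
    )


def random_haplotype_pair(
    panel: MarkerPanel,
    rng: np.random.Generator,
    *,
    p_heterozygous: float = 0.8,
    p_null: float = 0.05,
    n_ssr_alleles: int = 4,
) -> tuple[Haplotype, Haplotype]:
    """A random concrete parent haplotype pair for recovery experiments.

    Each locus is heterozygous with probability ``p_heterozygous`` (SSR
    alleles drawn from a small label pool; insertion pairs from
    empty/full) and the second haplotype carries a null (deleted) state
    with probability ``p_null``.
    """
    ssr_pool = [str(100 + i) for i in range(n_ssr_alleles)]
    h1: dict = {}
    h2: dict = {}
    for m in panel:
        pool = (
            ["empty", "full"]
            if m.assay_type is AssayType.INSERTION_SITE_PAIR
            else ssr_pool
        )
        a = pool[int(rng.integers(len(pool)))]
        b = pool[int(rng.integers(len(pool)))] if rng.random() < p_heterozygous else a
        if rng.random() < p_null:
            b = NULL
        h1[m.name], h2[m.name] = a, b
    return Haplotype("truth.h1", h1), Haplotype("truth.h2", h2)


def simulate_clone_tissues(
    model: CloneLayerModel, panel: MarkerPanel
) -> tuple[SampleGenotype, SampleGenotype]:
    """Leaf (L1 ∪ L2 allele pool) and L2-derived tissue genotypes of a clone."""
    for h in (*model.L1, *model.L2):
        _require_concrete(h, panel)

    def union(haps) -> dict[str, AlleleCall]:
        calls = {}
        for m in panel:
            labels = {str(h[m.name]) for h in haps if h[m.name] is not NULL}
            calls[m.name] = AlleleCall.of(*sorted(labels))
        return calls

    leaf = SampleGenotype(f"{model.clone_id}.leaf", Tissue.LEAF, union([*model.L1, *model.L2]))
    l2 = SampleGenotype(f"{model.clone_id}.l2", Tissue.L2_DERIVED, union(list(model.L2)))
    return leaf, l2
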