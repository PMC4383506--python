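"""Domain types for marker panels, genotypes and haplotypes.

The data model mirrors how clonal-polymorphism studies in grapevine score
molecular markers: codominant SSR loci whose alleles are named by fragment
size in base pairs, and retrotransposon insertion sites scored as two linked
presence/absence PCR assays (empty site / full site) that together form one
logical locus.  Allele labels are opaque strings; no numeric ordering is
assumed beyond output sorting.

Whole-leaf DNA pools the L1 (epidermal) and L2 (subepidermal) meristem cell
layers, so a leaf call may hold up to four allele labels per locus, while
L2-derived tissues (roots, stem pith) and sexual progeny carry at most two.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "NULL",
    "UNKNOWN",
    "AssayType",
    "Tissue",
    "MarkerDef",
    "MarkerPanel",
    "AlleleCall",
    "MISSING_CALL",
    "SampleGenotype",
    "GenotypeTable",
    "Haplotype",
    "CloneLayerModel",
    "validate_panel",
    "genotype_distance",
    "heterozygous_loci",
]


class _Sentinel:
    """Unique haplotype states that are not allele labels."""

    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __deepcopy__(self, memo):  # sentinels stay singletons
        return self

    def __copy__(self):
        return self


#: Physically deleted state: the assay never amplifies from this haplotype.
NULL = _Sentinel("NULL")
#: Phase or state unresolved.
UNKNOWN = _Sentinel("UNKNOWN")

#: State of a haplotype at one logical locus.
HapState = "str | _Sentinel"


class AssayType(str, enum.Enum):
    CODOMINANT_SSR = "CODOMINANT_SSR"
    INSERTION_SITE_PAIR = "INSERTION_SITE_PAIR"


class Tissue(str, enum.Enum):
    LEAF = "LEAF"
    L2_DERIVED = "L2_DERIVED"
    PROGENY = "PROGENY"


#: Semantic allele labels used for insertion-site pair loci.
EMPTY_SITE = "empty"
FULL_SITE = "full"


@dataclass(frozen=True)
class MarkerDef:
    """One logical locus.

    For INSERTION_SITE_PAIR loci, ``paired_assays`` holds the two genotype
    table column labels (empty-site assay first); the in-memory allele
    universe is then ``{"empty", "full"}``.
    """

    name: str
    chromosome: str
    position_bp: int
    assay_type: AssayType = AssayType.CODOMINANT_SSR
    paired_assays: tuple[str, str] | None = None

    @property
    def assay_columns(self) -> tuple[str, ...]:
        if self.assay_type is AssayType.INSERTION_SITE_PAIR:
            assert self.paired_assays is not None
            return self.paired_assays
        return (self.name,)


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[MarkerDef, ...]

    def __init__(self, markers) -> None:
        object.__setattr__(self, "markers", tuple(markers))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel")

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)

    def index(self, name: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise KeyError(f"marker {name!r} not in panel")

    def position(self, name: str) -> int:
        return self[name].position_bp


@dataclass(frozen=True)
class AlleleCall:
    """Observed allele-label set at one logical locus for one sample.

    ``no_amplification`` records an observed negative PCR (empty cell in a
    genotype table); ``missing`` records a locus that was not assayed at all
    ("." in a table) and is excluded from every count.
    """

    alleles: frozenset[str] = frozenset()
    no_amplification: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", frozenset(self.alleles))
        if self.missing and (self.alleles or self.no_amplification):
            raise ValueError("a missing call carries no alleles")
        if self.no_amplification != (not self.alleles and not self.missing):
            raise ValueError("no_amplification must hold exactly when the allele set is empty")

    @classmethod
    def of(cls, *labels: str) -> "AlleleCall":
        labels = tuple(str(x) for x in labels)
        return cls(frozenset(labels), no_amplification=not labels)


MISSING_CALL = AlleleCall(frozenset(), no_amplification=False, missing=True)


@dataclass
class SampleGenotype:
    sample_id: str
    tissue: Tissue
    calls: dict[str, AlleleCall]

    def call(self, marker: str) -> AlleleCall:
        return self.calls.get(marker, MISSING_CALL)


@dataclass
class GenotypeTable:
    panel: MarkerPanel
    samples: list[SampleGenotype]
    metadata: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def sample(self, sample_id: str) -> SampleGenotype:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"sample {sample_id!r} not in table")


@dataclass
class Haplotype:
    """Per-marker allele vector of one chromosome copy.

    Entries are allele labels, ``NULL`` (physically deleted, never
    amplifies) or ``UNKNOWN`` (unresolved).  Insertion-pair loci carry one
    of ``"empty"``/``"full"`` when intact.
    """

    name: str
    alleles: dict[str, "str | _Sentinel"]

    def __getitem__(self, marker: str):
        return self.alleles.get(marker, UNKNOWN)

    def states(self, panel: MarkerPanel) -> tuple:
        return tuple(self[m.name] for m in panel)

    def with_name(self, name: str) -> "Haplotype":
        return Haplotype(name, dict(self.alleles))

    def same_states(self, other: "Haplotype", panel: MarkerPanel, *, skip_unknown: bool = True) -> bool:
        """State equality over the panel, optionally ignoring markers UNKNOWN in either."""
        for m in panel:
            a, b = self[m.name], other[m.name]
            if skip_unknown and (a is UNKNOWN or b is UNKNOWN):
                continue
            if a != b:
                return False
        return True


@dataclass
class CloneLayerModel:
    """A periclinal chimera model: one haplotype pair per meristem cell layer."""

    clone_id: str
    L1: tuple[Haplotype, Haplotype]
    L2: tuple[Haplotype, Haplotype]

    def with_id(self, clone_id: str) -> "CloneLayerModel":
        return replace(self, clone_id=clone_id)


# ---------------------------------------------------------------------------
# elementary genotype algebra


def validate_panel(panel: MarkerPanel) -> list[str]:
    """Return human-readable invariant violations (empty list = valid panel)."""
    violations: list[str] = []
    seen: dict[str, int] = {}
    for m in panel:
        seen[m.name] = seen.get(m.name, 0) + 1
    for name, k in seen.items():
        if k > 1:
            violations.append(f"duplicate marker name {name!r} ({k} occurrences)")
    prev: MarkerDef | None = None
    for m in panel:
        if m.position_bp < 0:
            violations.append(f"marker {m.name!r} has negative position {m.position_bp}")
        if m.assay_type is AssayType.INSERTION_SITE_PAIR and (
            m.paired_assays is None or len(m.paired_assays) != 2
        ):
            violations.append(f"marker {m.name!r} is an insertion pair without two paired assays")
        if prev is not None:
            if (m.chromosome, m.position_bp) < (prev.chromosome, prev.position_bp):
                violations.append(
                    f"markers {prev.name!r} and {m.name!r} out of (chromosome, position) order"
                )
            elif m.chromosome == prev.chromosome and m.position_bp == prev.position_bp:
                violations.append(
                    f"markers {prev.name!r} and {m.name!r} share position {m.position_bp}"
                )
        prev = m
    return violations


def genotype_distance(a: SampleGenotype, b: SampleGenotype, panel: MarkerPanel) -> int:
    """Number of logical loci at which two samples' allele-label sets differ.

    An insertion-site pair counts as one locus.  Loci not assayed ("." /
    missing) in either sample are excluded from the count.
    """
    d = 0
    for m in panel:
        ca, cb = a.call(m.name), b.call(m.name)
        if ca.missing or cb.missing:
            continue
        if ca.alleles != cb.alleles:
            d += 1
    return d


def heterozygous_loci(s: SampleGenotype, panel: MarkerPanel) -> list[str]:
    """Loci at which the sample shows more than one allele label."""
    return [m.name for m in panel if len(s.call(m.name).alleles) > 1]
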