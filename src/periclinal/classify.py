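"""Classification of resolved haplotypes against the canonical references.

A non-canonical haplotype is decomposed marker by marker into composition
segments: runs matching the colored reference (COLORED_BACKBONE), runs
matching the white reference (WHITE_DONOR, the replacement tract copied in
by gene conversion), deleted runs (NULL alleles) and runs matching neither
reference.  Because resolution is bounded by flanking markers, each
segment carries inner bounds (outermost markers showing its state) and
outer bounds (nearest flanking markers showing a different state, or the
chromosome end), giving minimum and maximum physical tract lengths.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .model import NULL, UNKNOWN, Haplotype, MarkerPanel

__all__ = [
    "CHROMOSOME_END",
    "SegmentOrigin",
    "ColorStatus",
    "CompositionSegment",
    "HaplotypeClassification",
    "NOVEL",
    "functional_color_status",
    "infer_composition_segments",
    "tract_length_bounds",
    "match_to_library",
    "classify_haplotype",
    "has_replacement_tract",
]

#: Sentinel outer bound when a segment may extend past the last marker.
CHROMOSOME_END = "CHROMOSOME_END"
NOVEL = "NOVEL"


class SegmentOrigin(str, enum.Enum):
    COLORED_BACKBONE = "COLORED_BACKBONE"
    WHITE_DONOR = "WHITE_DONOR"
    DELETED = "DELETED"
    UNKNOWN = "UNKNOWN"


class ColorStatus(str, enum.Enum):
    COLORED = "COLORED"
    WHITE = "WHITE"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class CompositionSegment:
    origin: SegmentOrigin
    inner_start_marker: str
    inner_end_marker: str
    outer_start_marker: str  # marker name or CHROMOSOME_END
    outer_end_marker: str
    notes: list[str] = field(default_factory=list)


@dataclass
class HaplotypeClassification:
    haplotype: Haplotype
    segments: list[CompositionSegment]
    color_status: ColorStatus
    matched_name: str


def functional_color_status(h: Haplotype, *, color_marker: str = "Gret1") -> ColorStatus:
    """Functional status of the berry-color locus on one haplotype.

    COLORED: the retrotransposon empty site is present and the locus is
    not deleted (the anthocyanin activator is potentially functional).
    WHITE: the insertion (full site) is present, or the locus is deleted.
    UNDETERMINED: the color-locus state is unresolved.
    """
    state = h[color_marker]
    if state is UNKNOWN:
        return ColorStatus.UNDETERMINED
    if state is NULL:
        return ColorStatus.WHITE
    return ColorStatus.COLORED if str(state) == "empty" else ColorStatus.WHITE


def infer_composition_segments(
    h: Haplotype,
    colored_ref: Haplotype,
    white_ref: Haplotype,
    panel: MarkerPanel,
) -> list[CompositionSegment]:
    """Assign each marker to a reference origin and merge maximal runs.

    Markers where the two references share an allele (or where any state
    involved is UNKNOWN) are uninformative: they are absorbed into the
    flanking run when both flanks agree (with a note) and otherwise break
    the tiling into an UNKNOWN segment.  A concrete state matching neither
    reference yields an UNKNOWN-origin segment, not an error.
    """
    if all(
        colored_ref[m.name] == white_ref[m.name]
        or colored_ref[m.name] is UNKNOWN
        or white_ref[m.name] is UNKNOWN
        for m in panel
    ):
        raise ValueError("references must differ at at least one marker")

    UNINFORMATIVE = "uninformative"
    assignments: list[tuple[str, object]] = []
    for m in panel:
        state, c, w = h[m.name], colored_ref[m.name], white_ref[m.name]
        if state is NULL:
            assignments.append((m.name, SegmentOrigin.DELETED))
        elif state is UNKNOWN or c is UNKNOWN or w is UNKNOWN or c == w:
            assignments.append((m.name, UNINFORMATIVE))
        elif state == c:
            assignments.append((m.name, SegmentOrigin.COLORED_BACKBONE))
        elif state == w:
            assignments.append((m.name, SegmentOrigin.WHITE_DONOR))
        else:
            assignments.append((m.name, SegmentOrigin.UNKNOWN))

    # resolve uninformative markers against informative neighbors
    informative = [i for i, (_, o) in enumerate(assignments) if o is not UNINFORMATIVE]
    resolved: list[tuple[str, SegmentOrigin, bool]] = []  # (marker, origin, absorbed)
    for i, (name, origin) in enumerate(assignments):
        if origin is not UNINFORMATIVE:
            resolved.append((name, origin, False))
            continue
        left = max((j for j in informative if j < i), default=None)
        right = min((j for j in informative if j > i), default=None)
        lo = assignments[left][1] if left is not None else None
        ro = assignments[right][1] if right is not None else None
        if lo is not None and (ro is None or ro == lo):
            resolved.append((name, lo, True))
        elif ro is not None and lo is None:
            resolved.append((name, ro, True))
        else:  # disagreeing flanks, or no informative marker at all
            resolved.append((name, SegmentOrigin.UNKNOWN, True))

    segments: list[CompositionSegment] = []
    run: list[tuple[str, SegmentOrigin, bool]] = []

    def flush(run, next_informative_marker: str | None) -> None:
        if not run:
            return
        origin = run[0][1]
        shown = [name for name, _, absorbed in run if not absorbed]
        inner = shown or [name for name, _, _ in run]
        prev_seg = segments[-1] if segments else None
        outer_start = prev_seg.inner_end_marker if prev_seg else CHROMOSOME_END
        outer_end = next_informative_marker or CHROMOSOME_END
        notes = []
        absorbed = [name for name, _, a in run if a]
        if absorbed:
            notes.append(f"uninformative marker(s) absorbed: {', '.join(absorbed)}")
        segments.append(
            CompositionSegment(origin, inner[0], inner[-1], outer_start, outer_end, notes)
        )

    for item in resolved:
        if run and item[1] != run[0][1]:
            # next segment's first shown marker bounds this one
            nxt = item[0]
            flush(run, nxt)
            run = []
        run.append(item)
    flush(run, None)
    # fix outer_end bounds: nearest marker of the following segment showing a state
    for seg, nxt in zip(segments, segments[1:]):
        seg.outer_end_marker = nxt.inner_start_marker
    return segments


def tract_length_bounds(
    segment: CompositionSegment,
    panel: MarkerPanel,
    chromosome_length_bp: int,
) -> tuple[int, int]:
    """Minimum and maximum physical length of a composition segment.

    Minimum: distance between the outermost markers showing the state.
    Maximum: distance between the nearest flanking markers of different
    state, with 0 / chromosome length substituted at chromosome ends.
    Marker point positions are used; sub-marker breakpoint positions are
    beyond the resolution of the design.
    """
    min_len = panel.position(segment.inner_end_marker) - panel.position(segment.inner_start_marker)
    start = 0 if segment.outer_start_marker == CHROMOSOME_END else panel.position(segment.outer_start_marker)
    end = (
        chromosome_length_bp
        if segment.outer_end_marker == CHROMOSOME_END
        else panel.position(segment.outer_end_marker)
    )
    return min_len, end - start


def match_to_library(
    h: Haplotype,
    library: list[Haplotype],
    panel: MarkerPanel,
    *,
    color_status: ColorStatus | None = None,
) -> str:
    """Name a haplotype by exact state match against a library, or NOVEL.

    States are compared at every marker where both entries are known;
    ties go to the earliest library entry.  Unmatched haplotypes get an
    auto-generated name from their color status and their allele at the
    proximal flanking marker, numbered after any same-stem library names.
    """
    if not library:
        raise ValueError("library must be nonempty")
    for entry in library:
        if h.same_states(entry, panel, skip_unknown=True):
            return entry.name
    status = color_status or functional_color_status(h)
    prefix = {"COLORED": "c", "WHITE": "w", "UNDETERMINED": "u"}[status.value]
    first = h[panel.markers[0].name]
    allele = str(first) if first not in (NULL, UNKNOWN) else "x"
    stem = f"{prefix}{allele}"
    taken = sum(1 for e in library if e.name.startswith(f"{stem}-"))
    return f"{stem}-{taken + 1}"


def classify_haplotype(
    h: Haplotype,
    colored_ref: Haplotype,
    white_ref: Haplotype,
    library: list[Haplotype],
    panel: MarkerPanel,
) -> HaplotypeClassification:
    """Full classification: composition segments, color status, library name."""
    status = functional_color_status(h)
    segments = infer_composition_segments(h, colored_ref, white_ref, panel)
    name = match_to_library(h, library, panel, color_status=status)
    return HaplotypeClassification(h, segments, status, name)


def has_replacement_tract(classification: HaplotypeClassification) -> bool:
    """True for mosaic haplotypes carrying a white replacement tract on a
    colored backbone (the signature of a somatic conversion event)."""
    origins = {s.origin for s in classification.segments}
    return (
        SegmentOrigin.WHITE_DONOR in origins and SegmentOrigin.COLORED_BACKBONE in origins
    )
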