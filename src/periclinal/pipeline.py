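"""End-to-end orchestration: segregate → phase → classify → chimera → phenotype.

Runs the full analysis over a set of clones and produces one report per
clone (L2 haplotype names, candidate L1 pairs, chimera call, composition
segments of non-canonical haplotypes, predicted berry color) plus a
summary census of the distinct haplotypes encountered, by color status
and by presence of a replacement tract.  A clone's failure is collected
as an error on its report and does not abort the batch.

Clones with a selfed-progeny table get their L2 pair resolved by
segregation analysis; clones with only an L2-derived tissue genotype
(roots, stem pith) get a subtraction-based deduction; clones with a leaf
genotype alone are reported at genotype level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chimera import (
    ChimeraCall,
    deduce_L1,
    detect_chimera,
    predict_phenotype,
    predict_phenotype_from_tissues,
)
from .classify import (
    ColorStatus,
    CompositionSegment,
    HaplotypeClassification,
    classify_haplotype,
    has_replacement_tract,
)
from .io import read_genotype_table, read_haplotype_library, read_panel
from .model import (
    CloneLayerModel,
    GenotypeTable,
    Haplotype,
    MarkerPanel,
    SampleGenotype,
    heterozygous_loci,
)
from .phasing import deduce_l2_from_tissue, resolve_L2_haplotypes
from .segregation import chi_square_gof

__all__ = [
    "CloneInput",
    "Scenario",
    "CloneReport",
    "HaplotypeCensus",
    "AnalysisSummary",
    "ColorSegregationSummary",
    "progeny_color_summary",
    "run_full_analysis",
    "load_scenario",
    "format_report_tsv",
    "format_summary_text",
]


@dataclass
class CloneInput:
    clone_id: str
    leaf: SampleGenotype | None = None
    progeny: GenotypeTable | None = None
    l2_tissue: SampleGenotype | None = None


@dataclass
class Scenario:
    panel: MarkerPanel
    colored_ref: Haplotype
    white_ref: Haplotype
    library: list[Haplotype]
    clones: list[CloneInput]
    chromosome_length_bp: int


@dataclass
class CloneReport:
    clone_id: str
    l2_names: tuple[str, str] | None = None
    l1_candidate_names: list[tuple[str, str]] = field(default_factory=list)
    chimera: ChimeraCall | None = None
    l2_classifications: list[HaplotypeClassification] = field(default_factory=list)
    segments: dict[str, list[CompositionSegment]] = field(default_factory=dict)
    oiv225: int | None = None
    n_heterozygous_loci: int | None = None
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


@dataclass
class HaplotypeCensus:
    """Distinct haplotypes seen in resolved/deduced L2 pairs, keyed by name."""

    entries: dict[str, tuple[ColorStatus, bool]] = field(default_factory=dict)  # name -> (status, replacement)

    def add(self, classification: HaplotypeClassification) -> None:
        name = classification.matched_name
        self.entries.setdefault(
            name, (classification.color_status, has_replacement_tract(classification))
        )

    @property
    def n_white(self) -> int:
        return sum(1 for s, _ in self.entries.values() if s is ColorStatus.WHITE)

    @property
    def n_replacement_derived(self) -> int:
        return sum(1 for _, r in self.entries.values() if r)


@dataclass
class AnalysisSummary:
    n_clones: int
    n_failed: int
    census: HaplotypeCensus


@dataclass(frozen=True)
class ColorSegregationSummary:
    """Joint color-locus genotype / phenotype segregation of an S1 progeny."""

    n: int
    n_homozygous_empty: int
    n_heterozygous: int
    n_homozygous_full: int
    n_no_amplification: int
    pct_blue_black: float
    pct_green_yellow: float
    chi2_1_2_1_p: float
    chi2_3_1_p: float


def progeny_color_summary(
    progeny: GenotypeTable, *, color_marker: str = "Gret1"
) -> ColorSegregationSummary:
    """Summarize color-locus segregation and the implied berry phenotypes.

    Non-chimeric seedlings carrying the retrotransposon empty site retain
    a functional colored allele and bear blue-black fruit; seedlings
    amplifying only the full (inserted) site are green-yellow.  Goodness
    of fit is reported against the codominant 1:2:1 expectation and the
    dominant 3:1 phenotype expectation.
    """
    hom_empty = het = hom_full = no_amp = 0
    for s in progeny:
        call = s.call(color_marker)
        if call.missing:
            continue
        if call.no_amplification:
            no_amp += 1
        elif call.alleles == frozenset({"empty"}):
            hom_empty += 1
        elif call.alleles == frozenset({"empty", "full"}):
            het += 1
        elif call.alleles == frozenset({"full"}):
            hom_full += 1
    n = hom_empty + het + hom_full
    if n == 0:
        raise ValueError(f"no informative progeny at {color_marker!r}")
    blue = hom_empty + het
    chi_121 = chi_square_gof([hom_empty, het, hom_full], [1, 2, 1])
    chi_31 = chi_square_gof([blue, hom_full], [3, 1])
    return ColorSegregationSummary(
        n=n,
        n_homozygous_empty=hom_empty,
        n_heterozygous=het,
        n_homozygous_full=hom_full,
        n_no_amplification=no_amp,
        pct_blue_black=100.0 * blue / n,
        pct_green_yellow=100.0 * hom_full / n,
        chi2_1_2_1_p=chi_121.p_value,
        chi2_3_1_p=chi_31.p_value,
    )


def _analyze_clone(clone: CloneInput, scenario: Scenario) -> CloneReport:
    report = CloneReport(clone.clone_id)
    panel = scenario.panel
    if clone.leaf is not None:
        report.n_heterozygous_loci = len(heterozygous_loci(clone.leaf, panel))

    l2_pair: tuple[Haplotype, Haplotype] | None = None
    if clone.progeny is not None:
        phased = resolve_L2_haplotypes(clone.progeny, clone.leaf, panel)
        l2_pair = phased.haplotype_pair
        _propagate_null_phase(l2_pair, phased.segregations, scenario.library, panel, report)
        relabeled = _match_pair_to_library(l2_pair, scenario.library, panel)
        if relabeled is not None:
            l2_pair = relabeled
            report.warnings.append(
                "phasing: pair re-identified from allele content against the library "
                "(phase evidence across a weak linkage gap was inconclusive)"
            )
        report.warnings.extend(f"phasing: {c}" for c in phased.conflicts)
        if phased.chimera_signals:
            report.warnings.append(
                "phasing: leaf-only allele(s) at " + ", ".join(phased.chimera_signals)
            )
    elif clone.l2_tissue is not None:
        l2_pair, annotations = deduce_l2_from_tissue(clone.l2_tissue, scenario.library, panel)
        report.warnings.extend(f"l2-deduction: {a}" for a in annotations)
    else:
        report.warnings.append("no progeny or L2 tissue: genotype-level report only")
        return report

    classifications = [
        classify_haplotype(h, scenario.colored_ref, scenario.white_ref, scenario.library, panel)
        for h in l2_pair
    ]
    report.l2_classifications = classifications
    report.l2_names = tuple(sorted(c.matched_name for c in classifications))
    for c in classifications:
        if has_replacement_tract(c) or c.matched_name not in {h.name for h in scenario.library}:
            report.segments[c.matched_name] = c.segments

    l1_pair: tuple[Haplotype, Haplotype] | None = None
    if clone.leaf is not None:
        report.chimera = detect_chimera(clone.leaf, l2_pair, panel)
        deduction = deduce_L1(clone.leaf, l2_pair, scenario.library, panel)
        if deduction.contains_unknown:
            report.warnings.append("L1 deduction required an uncharacterized haplotype")
        for pair, _score in deduction.candidate_L1_pairs:

            def name_of(h: Haplotype) -> str:
                lib = {x.name for x in scenario.library}
                if h.name in lib:
                    return h.name
                return classify_haplotype(
                    h, scenario.colored_ref, scenario.white_ref, scenario.library, panel
                ).matched_name if not _is_unknown_hap(h, panel) else "unknown"

            report.l1_candidate_names.append(tuple(sorted(name_of(h) for h in pair)))
        l1_pair = deduction.candidate_L1_pairs[0][0]
    else:
        l1_pair = l2_pair  # no leaf: treat the plant as homogeneous

    try:
        if clone.leaf is not None:
            # direct observation outranks the deduced layer model
            report.oiv225 = predict_phenotype_from_tissues(clone.leaf, l2_pair, panel).oiv225
        else:
            model = CloneLayerModel(clone.clone_id, l1_pair, l2_pair)
            report.oiv225 = predict_phenotype(model).oiv225
    except ValueError as exc:
        report.warnings.append(f"phenotype: {exc}")
    return report


def _propagate_null_phase(
    pair: tuple[Haplotype, Haplotype],
    segregations,
    library: list[Haplotype],
    panel: MarkerPanel,
    report: CloneReport,
) -> None:
    """Resolve an unphased null allele through library constraints.

    When a locus shows null segregation (one haplotype deleted) but the
    progeny cannot tell which haplotype carries the deletion, the side is
    still determined if one haplotype's library matches all carry the
    amplified allele there: the null must sit on the other haplotype.
    """
    from .model import NULL, UNKNOWN
    from .segregation import SegClass

    h1, h2 = pair
    for m in panel:
        seg = segregations.get(m.name)
        if seg is None or seg.classification is not SegClass.NULL_SEGREGATING:
            continue
        if h1[m.name] is not UNKNOWN or h2[m.name] is not UNKNOWN:
            continue
        allele = seg.alleles[0]

        def determined(h: Haplotype):
            matches = [e for e in library if h.same_states(e, panel, skip_unknown=True)]
            states = {e[m.name] for e in matches if e[m.name] is not UNKNOWN}
            return next(iter(states)) if len(states) == 1 else None

        d1, d2 = determined(h1), determined(h2)
        assign = None
        if d1 == allele and d2 != allele:
            assign = (allele, NULL)
        elif d2 == allele and d1 != allele:
            assign = (NULL, allele)
        elif d1 is NULL and d2 is not NULL:
            assign = (NULL, allele)
        elif d2 is NULL and d1 is not NULL:
            assign = (allele, NULL)
        if assign is not None:
            h1.alleles[m.name], h2.alleles[m.name] = assign
            report.warnings.append(
                f"phasing: null allele at {m.name} placed by library constraint"
            )


def _match_pair_to_library(
    pair: tuple[Haplotype, Haplotype],
    library: list[Haplotype],
    panel: MarkerPanel,
) -> tuple[Haplotype, Haplotype] | None:
    """Re-identify a phased pair by allele content when phase failed.

    Per-locus allele sets from segregation analysis are phase-free and
    reliable; the pairing of alleles across loci is not, with small
    progenies and wide marker gaps.  If the phased haplotypes do not both
    match library entries but exactly one library pair reproduces the
    observed per-locus state sets, that pair is returned.  Genuinely novel
    haplotypes have no such library pair and are left untouched.
    """
    from itertools import combinations_with_replacement

    from .model import UNKNOWN

    h1, h2 = pair

    def in_library(h: Haplotype) -> bool:
        return any(h.same_states(e, panel, skip_unknown=True) for e in library)

    if in_library(h1) and in_library(h2):
        return None

    def set_profile_matches(e1: Haplotype, e2: Haplotype) -> bool:
        for m in panel:
            states = (h1[m.name], h2[m.name], e1[m.name], e2[m.name])
            if any(s is UNKNOWN for s in states):
                continue
            if sorted(map(repr, states[:2])) != sorted(map(repr, states[2:])):
                return False
        return True

    matches = [
        (e1, e2)
        for e1, e2 in combinations_with_replacement(library, 2)
        if set_profile_matches(e1, e2)
    ]
    if len(matches) == 1:
        return matches[0]
    return None


def _is_unknown_hap(h: Haplotype, panel: MarkerPanel) -> bool:
    from .model import UNKNOWN

    n_known = sum(1 for m in panel if h[m.name] is not UNKNOWN)
    return n_known < len(panel) / 2


def run_full_analysis(scenario: Scenario) -> tuple[list[CloneReport], AnalysisSummary]:
    """Analyze every clone of a scenario; failures are per-clone, not fatal."""
    reports: list[CloneReport] = []
    census = HaplotypeCensus()
    n_failed = 0
    for clone in scenario.clones:
        try:
            report = _analyze_clone(clone, scenario)
        except (ValueError, KeyError) as exc:
            report = CloneReport(clone.clone_id, errors=[str(exc)])
            n_failed += 1
        for c in report.l2_classifications:
            census.add(c)
        reports.append(report)
    return reports, AnalysisSummary(len(scenario.clones), n_failed, census)


# ---------------------------------------------------------------------------
# scenario loading and report formatting


def load_scenario(path: str | Path) -> Scenario:
    """Load a YAML scenario bundling panel, references, library and clones.

    Schema::

        panel: panel.tsv
        library: haplotypes.tsv
        references: {colored: c188, white: w216}
        chromosome_length_bp: 18780000
        leaf_table: leaves.tsv           # optional; sample_id = clone id
        l2_table: l2_tissues.tsv         # optional; sample_id = clone id
        clones:
          - id: PN162
            progeny: pn162_s1.tsv        # optional per clone

    All relative paths resolve against the YAML file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    panel = read_panel(resolve(cfg["panel"]))
    library = read_haplotype_library(resolve(cfg["library"]), panel)
    by_name = {h.name: h for h in library}
    refs = cfg["references"]
    colored_ref, white_ref = by_name[refs["colored"]], by_name[refs["white"]]

    leaves = l2s = None
    if cfg.get("leaf_table"):
        leaves = {s.sample_id: s for s in read_genotype_table(resolve(cfg["leaf_table"]), panel)}
    if cfg.get("l2_table"):
        l2s = {s.sample_id: s for s in read_genotype_table(resolve(cfg["l2_table"]), panel)}

    clones = []
    for entry in cfg.get("clones", []):
        cid = str(entry["id"])
        progeny = None
        if entry.get("progeny"):
            progeny = read_genotype_table(resolve(entry["progeny"]), panel)
        clones.append(
            CloneInput(
                clone_id=cid,
                leaf=(leaves or {}).get(cid),
                progeny=progeny,
                l2_tissue=(l2s or {}).get(cid),
            )
        )
    return Scenario(
        panel=panel,
        colored_ref=colored_ref,
        white_ref=white_ref,
        library=library,
        clones=clones,
        chromosome_length_bp=int(cfg.get("chromosome_length_bp", 0))
        or max(m.position_bp for m in panel),
    )


def format_report_tsv(reports: list[CloneReport]) -> str:
    lines = ["clone_id\tl2_haplotypes\tl1_candidates\tchimeric\toiv225\twarnings\terrors"]
    for r in reports:
        l2 = "/".join(r.l2_names) if r.l2_names else "."
        l1 = ";".join("/".join(pair) for pair in r.l1_candidate_names) or "."
        chim = "." if r.chimera is None else ("yes" if r.chimera.is_chimeric else "no")
        oiv = str(r.oiv225) if r.oiv225 is not None else "."
        lines.append(
            f"{r.clone_id}\t{l2}\t{l1}\t{chim}\t{oiv}\t"
            f"{'; '.join(r.warnings) or '.'}\t{'; '.join(r.errors) or '.'}"
        )
    return "\n".join(lines) + "\n"


def format_summary_text(summary: AnalysisSummary) -> str:
    census = summary.census
    lines = [
        f"clones analyzed: {summary.n_clones} ({summary.n_failed} failed)",
        f"distinct L2 haplotypes: {len(census.entries)}",
        f"  white: {census.n_white}",
        f"  colored: {sum(1 for s, _ in census.entries.values() if s is ColorStatus.COLORED)}",
        f"  bearing a replacement tract: {census.n_replacement_derived}",
        "haplotypes:",
    ]
    for name, (status, repl) in sorted(census.entries.items()):
        tag = ", replacement-derived" if repl else ""
        lines.append(f"  {name}: {status.value}{tag}")
    return "\n".join(lines) + "\n"
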