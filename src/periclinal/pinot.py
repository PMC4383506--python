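"""Reference fixtures for the Pinot berry-color region of chromosome 2.

The study system: a 10.07 Mb region on the distal arm of grapevine
chromosome 2 between SSR loci VMC5g7 (8.20 Mb) and VMC7g3 (18.27 Mb),
containing the berry-color locus (the VvMybA gene cluster).  Thirteen loci
heterozygous in Pinot noir are scored: 11 codominant SSRs plus the
empty/full insertion-site assay pairs of the retrotransposons Gret1
(inserted in the VvMybA1 promoter of the non-functional "white" haplotype,
14.24 Mb) and Noble225 (15.85 Mb).

Two canonical haplotypes segregate in Pinot: the "colored" haplotype c188
(Gret1 empty site, functional VvMybA1) and the "white" haplotype w216
(Gret1 insertion).  A second canonical white haplotype, w198, differs from
w216 only by its VMC5g7 allele.  Three non-canonical white haplotypes
(w188-1, w188-2, w188-3) derive from c188 by somatic replacement of
sections by the homologous white sequence — in w188-1 combined with a
deletion spanning the color locus, in w188-3 with loss of the distal
VMC7g3 allele.

Positions known only to 10 kb precision are used as such; loci with no
published position are placed at synthetic positions chosen to be
consistent with the published span statements.  They are
fixture choices of this package, adequate for marker-resolution analyses
but not for kb-precision breakpoint work.
"""

from __future__ import annotations

from .model import (
    NULL,
    UNKNOWN,
    AlleleCall,
    AssayType,
    EMPTY_SITE,
    FULL_SITE,
    CloneLayerModel,
    GenotypeTable,
    Haplotype,
    MISSING_CALL,
    MarkerDef,
    MarkerPanel,
    SampleGenotype,
    Tissue,
)

__all__ = [
    "CHROMOSOME_LENGTH_BP",
    "pinot_panel",
    "build_canonical_haplotypes",
    "canonical_library",
    "clone_models",
    "table1_genotypes",
    "pn162_s1_color_table",
    "default_map_cM",
]

#: Chromosome 2 length per the 12X grapevine genome sequence.
CHROMOSOME_LENGTH_BP = 18_780_000

# (name, position_bp, assay_type); positions 1-based bp.
# VMC5g7, SC8_0146_010, VVNTm1, Gret1, Noble225 and VMC7g3 follow published
# positions; the rest are synthetic fixture positions (see module docstring).
_PANEL_LAYOUT = [
    ("VMC5g7", 8_200_000, AssayType.CODOMINANT_SSR),
    ("SC8_0146_010", 12_670_000, AssayType.CODOMINANT_SSR),
    ("P2-106", 13_200_000, AssayType.CODOMINANT_SSR),
    ("P2-298", 13_500_000, AssayType.CODOMINANT_SSR),
    ("P2-442", 13_903_000, AssayType.CODOMINANT_SSR),
    ("VVNTm1", 14_150_000, AssayType.CODOMINANT_SSR),
    ("VVNTm2", 14_180_890, AssayType.CODOMINANT_SSR),
    ("Gret1", 14_240_000, AssayType.INSERTION_SITE_PAIR),
    ("VVNTm3", 14_288_740, AssayType.CODOMINANT_SSR),
    ("VVNTm5", 14_557_000, AssayType.CODOMINANT_SSR),
    ("Noble225", 15_850_000, AssayType.INSERTION_SITE_PAIR),
    ("VVIu20.1", 16_538_000, AssayType.CODOMINANT_SSR),
    ("VMC7g3", 18_270_000, AssayType.CODOMINANT_SSR),
]


def pinot_panel() -> MarkerPanel:
    """The 13-locus heterozygous panel of the Pinot chromosome 2 region."""
    markers = []
    for name, pos, assay in _PANEL_LAYOUT:
        paired = (f"{name}_empty", f"{name}_full") if assay is AssayType.INSERTION_SITE_PAIR else None
        markers.append(MarkerDef(name, "chr2", pos, assay, paired))
    return MarkerPanel(markers)


# colored / white allele per marker (colored first).  SC8_0146_010 phase is
# not resolvable from any published homozygote: its canonical entries stay
# UNKNOWN; simulation fixtures that need concrete states use
# _SC8_SIM_PHASE below (an arbitrary c=123 / w=128 assignment).
_PHASED_ALLELES = {
    "VMC5g7": ("188", "216"),
    "P2-106": ("222", "262"),
    "P2-298": ("118", "129"),
    "P2-442": ("110", "126"),
    "VVNTm1": ("161", "168"),
    "VVNTm2": ("378", "387"),
    "Gret1": (EMPTY_SITE, FULL_SITE),
    "VVNTm3": ("296", "272"),
    "VVNTm5": ("300", "288"),
    "Noble225": (EMPTY_SITE, FULL_SITE),
    "VVIu20.1": ("386", "363"),
    "VMC7g3": ("132", "116"),
}

# Arbitrary phase used only where a simulation needs concrete SC8 states.
_SC8_SIM_PHASE = ("123", "128")  # (colored, white)


def build_canonical_haplotypes(panel: MarkerPanel) -> tuple[Haplotype, Haplotype]:
    """The canonical colored (c188) and white (w216) haplotypes.

    c188 carries the Gret1 empty site (functional VvMybA1); w216 carries the
    Gret1 insertion.  SC8_0146_010 is UNKNOWN in both (unresolved phase).
    """
    missing = [name for name, _, _ in _PANEL_LAYOUT if name not in panel]
    if missing:
        raise ValueError(f"panel lacks required loci: {missing}")
    colored = {m: c for m, (c, _) in _PHASED_ALLELES.items()}
    white = {m: w for m, (_, w) in _PHASED_ALLELES.items()}
    colored["SC8_0146_010"] = UNKNOWN
    white["SC8_0146_010"] = UNKNOWN
    return Haplotype("c188", colored), Haplotype("w216", white)


def _hap(name: str, *, sc8=None, **overrides) -> Haplotype:
    """Build a haplotype from the colored backbone with white/NULL overrides."""
    alleles: dict = {m: c for m, (c, _) in _PHASED_ALLELES.items()}
    alleles["SC8_0146_010"] = UNKNOWN if sc8 is None else sc8
    alleles.update(overrides)
    return Haplotype(name, alleles)


def _white(marker: str):
    return _PHASED_ALLELES[marker][1]


def canonical_library(*, concrete_sc8: bool = False) -> list[Haplotype]:
    """The six haplotypes resolved in the Pinot group, c188 first.

    With ``concrete_sc8`` the arbitrary simulation phase is filled in at
    SC8_0146_010 so the haplotypes can seed a simulator; by default that
    locus stays UNKNOWN as in the canonical definitions.
    """
    c_sc8, w_sc8 = _SC8_SIM_PHASE if concrete_sc8 else (None, None)
    c188 = _hap("c188", sc8=c_sc8)
    w216 = _hap("w216", sc8=w_sc8, **{m: w for m, (_, w) in _PHASED_ALLELES.items()})
    w198 = w216.with_name("w198")
    w198.alleles["VMC5g7"] = "198"
    # w188-1: white replacement tract at VVNTm1..VVNTm2 plus a deletion
    # spanning the color locus (both Gret1 assays never amplify).
    w188_1 = _hap(
        "w188-1",
        sc8=c_sc8,
        VVNTm1=_white("VVNTm1"),
        VVNTm2=_white("VVNTm2"),
        Gret1=NULL,
    )
    # w188-2: white replacement from P2-442 to the chromosome end.
    tail = ["P2-442", "VVNTm1", "VVNTm2", "Gret1", "VVNTm3", "VVNTm5", "Noble225", "VVIu20.1", "VMC7g3"]
    w188_2 = _hap("w188-2", sc8=c_sc8, **{m: _white(m) for m in tail})
    # w188-3: white replacement from P2-442 through VVIu20.1, distal VMC7g3
    # lost (null allele).
    w188_3 = _hap("w188-3", sc8=c_sc8, **{m: _white(m) for m in tail[:-1]}, VMC7g3=NULL)
    return [c188, w216, w198, w188_1, w188_2, w188_3]


def _lib_map(concrete_sc8: bool) -> dict[str, Haplotype]:
    return {h.name: h for h in canonical_library(concrete_sc8=concrete_sc8)}


def clone_models(*, concrete_sc8: bool = True) -> dict[str, CloneLayerModel]:
    """Layer models of the nine resolved clones plus the bud-sport genotypes.

    The genotype-VI haplotype of the grey bud-sport parents (white
    replacement tract from P2-106 to VVNTm5) and the uncharacterized white
    L1 haplotype of PB3232 (color locus deleted on a colored backbone) are
    included under the names "wVI" and "u188".
    """
    lib = _lib_map(concrete_sc8)
    sc8_c = _SC8_SIM_PHASE[0] if concrete_sc8 else None
    span = ["P2-106", "P2-298", "P2-442", "VVNTm1", "VVNTm2", "Gret1", "VVNTm3", "VVNTm5"]
    wVI = _hap("wVI", sc8=sc8_c, **{m: _white(m) for m in span})
    u188 = _hap("u188", sc8=sc8_c, Gret1=NULL)

    def m(clone_id, l1a, l1b, l2a, l2b):
        extra = {"wVI": wVI, "u188": u188}
        get = lambda n: lib.get(n) or extra[n]
        return CloneLayerModel(clone_id, (get(l1a), get(l1b)), (get(l2a), get(l2b)))

    return {
        "PN162": m("PN162", "c188", "w216", "c188", "w216"),
        "PG52": m("PG52", "c188", "w216", "w216", "w188-1"),
        "PG53": m("PG53", "c188", "w216", "w216", "w188-3"),
        "PG3106": m("PG3106", "c188", "w216", "w198", "w188-1"),
        "PB54": m("PB54", "w198", "w188-1", "w198", "w188-1"),
        "PB55": m("PB55", "w198", "w188-1", "w198", "w188-1"),
        "PB3009": m("PB3009", "w216", "w188-2", "w216", "w188-2"),
        "PB3172": m("PB3172", "w216", "w188-2", "w216", "w188-2"),
        "PB3232": m("PB3232", "w216", "u188", "w198", "w188-1"),
        # grey bud-sport parents: colored L1 over a genotype-VI L2
        "PGMA19": m("PGMA19", "c188", "w216", "w216", "wVI"),
        "BCPG9.S7.1": m("BCPG9.S7.1", "c188", "w216", "w216", "wVI"),
        # their homogenized bud sports
        "PGMA19.S5": m("PGMA19.S5", "w216", "wVI", "w216", "wVI"),
        "PGMA19.S6": m("PGMA19.S6", "c188", "w216", "c188", "w216"),
        "BCPG9.S7.2": m("BCPG9.S7.2", "w216", "wVI", "w216", "wVI"),
    }


# Observed multi-locus genotype classes I..VIII (leaf profiles).  Cells are
# allele-label sets per logical locus.
_TABLE1_ROWS: dict[str, dict[str, tuple[str, ...]]] = {
    "I": {},
    "II": {"VMC5g7": ("188", "198")},
    "III": {"VMC5g7": ("188", "198", "216")},
    "IV": {
        "VMC5g7": ("188", "198"),
        "VVNTm1": ("168",),
        "VVNTm2": ("387",),
        "Gret1": (FULL_SITE,),
    },
    "V": {
        "P2-442": ("126",),
        "VVNTm1": ("168",),
        "VVNTm2": ("387",),
        "Gret1": (FULL_SITE,),
        "VVNTm3": ("272",),
        "VVNTm5": ("288",),
        "Noble225": (FULL_SITE,),
        "VVIu20.1": ("363",),
        "VMC7g3": ("116",),
    },
    "VI": {
        "P2-106": ("262",),
        "P2-298": ("129",),
        "P2-442": ("126",),
        "VVNTm1": ("168",),
        "VVNTm2": ("387",),
        "Gret1": (FULL_SITE,),
        "VVNTm3": ("272",),
        "VVNTm5": ("288",),
    },
    "VII": {"Gret1": (FULL_SITE,)},
    "VIII": {"VMC5g7": ("188", "198", "216"), "Gret1": (FULL_SITE,)},
}

_GENOTYPE_I_BASE: dict[str, tuple[str, ...]] = {
    "VMC5g7": ("188", "216"),
    "SC8_0146_010": ("123", "128"),
    "P2-106": ("222", "262"),
    "P2-298": ("118", "129"),
    "P2-442": ("110", "126"),
    "VVNTm1": ("161", "168"),
    "VVNTm2": ("378", "387"),
    "Gret1": (EMPTY_SITE, FULL_SITE),
    "VVNTm3": ("272", "296"),
    "VVNTm5": ("288", "300"),
    "Noble225": (EMPTY_SITE, FULL_SITE),
    "VVIu20.1": ("363", "386"),
    "VMC7g3": ("116", "132"),
}


def table1_genotypes(panel: MarkerPanel | None = None) -> GenotypeTable:
    """Leaf genotype classes I..VIII of the Pinot collection as a table."""
    panel = panel or pinot_panel()
    samples = []
    for cls, overrides in _TABLE1_ROWS.items():
        calls = {}
        for marker, base in _GENOTYPE_I_BASE.items():
            calls[marker] = AlleleCall.of(*overrides.get(marker, base))
        samples.append(SampleGenotype(f"genotype_{cls}", Tissue.LEAF, calls))
    return GenotypeTable(panel, samples, {"fixture": "table1_genotype_classes"})


def pn162_s1_color_table(panel: MarkerPanel | None = None) -> GenotypeTable:
    """The 51 phenotyped PN162 S1 offspring scored at the Gret1 locus.

    Published class counts: 8 offspring amplified only the Gret1 empty site
    (homozygous colored), 27 amplified both sites (heterozygous), 16 only
    the full site (homozygous for the insertion, green-yellow berried).
    Other loci were not assayed in this subset and are marked missing.
    """
    panel = panel or pinot_panel()
    classes = [
        (8, (EMPTY_SITE,)),
        (27, (EMPTY_SITE, FULL_SITE)),
        (16, (FULL_SITE,)),
    ]
    samples = []
    i = 0
    for count, labels in classes:
        for _ in range(count):
            i += 1
            calls = {m.name: MISSING_CALL for m in panel}
            calls["Gret1"] = AlleleCall.of(*labels)
            samples.append(SampleGenotype(f"PN162.S1.{i:02d}", Tissue.PROGENY, calls))
    return GenotypeTable(panel, samples, {"fixture": "pn162_s1_color_classes"})


def default_map_cM(panel: MarkerPanel, cm_per_mb: float = 5.0) -> list[float]:
    """Per-interval genetic distances from physical spacing.

    A uniform 5 cM/Mb (1 cM per 0.2 Mb) fixture rate giving a ~50 cM region;
    a plausible synthetic choice, not a published map.
    """
    positions = [m.position_bp for m in panel]
    return [(b - a) / 1e6 * cm_per_mb for a, b in zip(positions, positions[1:])]
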