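"""Decompose non-canonical haplotypes into replacement/deletion segments.

Each non-canonical white haplotype is compared marker by marker against
the canonical colored (c188) and white (w216) references, yielding runs of
colored backbone, white donor tract (the gene-conversion replacement) and
deletion.  Physical bounds come from the flanking markers: the minimum
length is the span of markers showing the state, the maximum extends to
the nearest markers showing a different state.
"""

from periclinal import classify_haplotype, tract_length_bounds
from periclinal.pinot import CHROMOSOME_LENGTH_BP, canonical_library, pinot_panel

panel = pinot_panel()
library = canonical_library()
by_name = {h.name: h for h in library}
refs = (by_name["c188"], by_name["w216"])

for name in ("w188-1", "w188-2", "w188-3"):
    cl = classify_haplotype(by_name[name], *refs, library, panel)
    print(f"\n{name}  (functional color status: {cl.color_status.value})")
    for seg in cl.segments:
        lo, hi = tract_length_bounds(seg, panel, CHROMOSOME_LENGTH_BP)
        print(
            f"  {seg.origin.value:17s} {seg.inner_start_marker}..{seg.inner_end_marker}"
            f"  length {lo/1e6:.2f}-{hi/1e6:.2f} Mb"
        )
print("\nWHITE_DONOR on a COLORED_BACKBONE marks a somatic replacement tract;")
print("DELETED runs never amplify and segregate as null alleles in progeny.")
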