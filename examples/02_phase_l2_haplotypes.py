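"""Resolve the L2 haplotypes of a grey (chimeric) clone from its progeny.

The grey clone modeled here is a periclinal chimera: its L1 epidermis
carries the colored haplotype, but its L2 layer pairs the canonical white
w216 with the non-canonical w188-1 — a colored backbone whose VVNTm1-VVNTm2
section was replaced by white sequence and whose color locus is deleted.
Because gametes derive from L2 only, selfed progeny reveal exactly this
pair: the replaced alleles are fixed in every offspring, the deleted Gret1
assays segregate against a null allele, and the leaf-only alleles betray
the chimera.
"""

from periclinal import resolve_L2_haplotypes, SimulationConfig, simulate_selfed_progeny
from periclinal.pinot import clone_models, pinot_panel
from periclinal.simulate import simulate_clone_tissues

panel = pinot_panel()
model = clone_models()["PG52"]

leaf, _pith = simulate_clone_tissues(model, panel)
progeny = simulate_selfed_progeny(model.L2, SimulationConfig(n_progeny=24, seed=7), panel)

result = resolve_L2_haplotypes(progeny, leaf, panel)
h1, h2 = result.haplotype_pair

print(f"anchor locus: {result.anchor_marker}")
print(f"{'marker':14s} {'hap1':8s} {'hap2':8s} support")
for m in panel:
    print(f"{m.name:14s} {str(h1[m.name]):8s} {str(h2[m.name]):8s} "
          f"{result.per_marker_support.get(m.name, 0)}")
print("leaf-only alleles (chimera signal) at:", ", ".join(result.chimera_signals))
print("NULL = deleted (never amplifies); the fixed 168/387 run plus the null")
print("color locus is the signature of the conversion-plus-deletion haplotype.")
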