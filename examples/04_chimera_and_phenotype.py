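"""Detect chimerism, deduce the L1 layer and predict berry color.

A tri-allelic leaf profile cannot come from one diploid genotype: the
extra allele lives in the other meristem layer.  Given the resolved L2
pair, candidate L1 pairs are those whose allele union with L2 reproduces
the leaf pool, ranked by parsimony (one somatic mutation separates the
layers).  Berry color follows OIV descriptor 225: 1 green-yellow, 4 grey
(colored L1 over white L2), 6 blue-black.
"""

from periclinal import (
    RearrangementKind,
    apply_layer_rearrangement,
    deduce_L1,
    detect_chimera,
    predict_phenotype,
)
from periclinal.pinot import canonical_library, clone_models, pinot_panel
from periclinal.simulate import simulate_clone_tissues

panel = pinot_panel()
library = canonical_library()
model = clone_models()["PG3106"]

leaf, _ = simulate_clone_tissues(model, panel)
call = detect_chimera(leaf, model.L2, panel)
print(f"chimeric: {call.is_chimeric}; tri-allelic at: {', '.join(call.triallelic_loci)}")

deduction = deduce_L1(leaf, model.L2, library, panel)
pair, score = deduction.candidate_L1_pairs[0]
print(f"top L1 candidate: {pair[0].name} / {pair[1].name} (parsimony score {score})")

print(f"predicted berry color (OIV 225): {predict_phenotype(model).oiv225}  (4 = grey)")

# displacement: L2 cells invade the epidermis, homogenizing the plant
sport = apply_layer_rearrangement(model, RearrangementKind.DISPLACEMENT)
print(
    f"after L2->L1 displacement: OIV {predict_phenotype(sport).oiv225}  "
    "(1 = green-yellow bud sport)"
)
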