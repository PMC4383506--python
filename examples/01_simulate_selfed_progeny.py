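"""Simulate a selfed progeny of the Pinot noir reference clone.

The L2 cell layer of the reference clone pairs the canonical colored
haplotype c188 (Gret1 empty site, functional VvMybA1) with the canonical
white haplotype w216 (Gret1 insertion).  Selfing it yields offspring whose
color-locus genotypes segregate 1:2:1; offspring carrying the empty site
retain a functional colored allele and bear blue-black fruit.
"""

from periclinal import SimulationConfig, simulate_selfed_progeny
from periclinal.pinot import canonical_library, pinot_panel
from periclinal.pipeline import progeny_color_summary

panel = pinot_panel()
lib = {h.name: h for h in canonical_library(concrete_sc8=True)}

config = SimulationConfig(n_progeny=500, seed=42)
progeny = simulate_selfed_progeny((lib["c188"], lib["w216"]), config, panel)

summary = progeny_color_summary(progeny)
print(f"simulated offspring: {summary.n}")
print(
    f"color-locus classes  empty/empty: {summary.n_homozygous_empty}  "
    f"empty/full: {summary.n_heterozygous}  full/full: {summary.n_homozygous_full}"
)
print(f"predicted blue-black: {summary.pct_blue_black:.1f}%  (Mendelian expectation 75%)")
print(f"predicted green-yellow: {summary.pct_green_yellow:.1f}%  (expectation 25%)")
print(f"1:2:1 chi-square p-value: {summary.chi2_1_2_1_p:.3f}  (> 0.05: Mendelian fit holds)")
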