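# Methods

## The inference problem

A periclinal chimera carries two diploid genotypes, one per meristem cell
layer. Only the L2 layer is transmitted through meiosis, so a selfed
progeny is an S1 family of the L2 genotype alone; whole-leaf DNA is the
allele union of both layers with no dosage information (the assays score
presence/absence of PCR products). The package infers, in order: per-locus
segregation behaviour, the phased L2 haplotype pair, the somatic-event
composition of each haplotype, the L1 pair, and the berry-color phenotype.

Markers are codominant SSRs (alleles named by fragment size in bp) and
retrotransposon insertion sites scored as two linked presence/absence
assays (empty site / full site) treated as one logical locus, which makes
all three genotype classes of an S1 distinguishable. Haplotype states are
allele labels, `NULL` (physically deleted — never amplifies) or `UNKNOWN`.

## Segregation classification

For each locus the progeny calls are reduced to allele-presence counts.
With parental heterozygosity A/B the S1 expectation is 1:2:1
(hom-A : het : hom-B). Classes:

* `SEGREGATING` — both alleles transmitted and the family is not entirely
  heterozygous. An empty homozygote class at n = 18–24 is ordinary
  binomial sampling (P ≈ 0.6% per linked block) and does **not** make a
  locus irregular.
* `FIXED` — a single allele (or an invariant allele pair) shown by all
  offspring within a tolerance of ⌊n·e + 2⌋ discordant calls (e = assumed
  genotyping error rate, default 0). A FIXED locus heterozygous in the
  leaf is the signature of a somatic replacement tract confined to L2.
* `NULL_SEGREGATING` — a single amplified allele plus an
  amplification-failure class larger than ⌊n·d⌋ (d = dropout rate,
  default 0). Under selfing of an A/null parent the null/null class is
  1/4; `detect_null_allele` accepts hemizygosity when an exact binomial
  test does not reject p = 0.25 (α = 0.05, no multiple-testing correction
  across the 13 loci; a Bonferroni switch exists).
* `MONOMORPHIC` / `IRREGULAR` — uninformative or contaminated data.

Pearson goodness-of-fit (`chi_square_gof`) is delegated to
`scipy.stats.chisquare` with expected counts scaled from the ratio.

## Two-point linkage

Recombination fractions are estimated for the S1/F2 design by EM over the
16 ordered gamete-pair configurations compatible with each observable
two-locus class; the double-heterozygote class mixes parental and
recombinant pairs and is handled by posterior expectation of recombinant
gametes. Both phase pairings are evaluated and the higher-likelihood one
kept (S1 data alone do not label the parental haplotypes). Null alleles
enter as a `None` gamete state whose homozygote class is the
amplification failure. Map distances use Kosambi by default for reporting
(the conventional choice of linkage software for this crop) and Haldane
for simulation, where the no-interference assumption makes interval
crossovers independent. Estimator calibration: |bias| < 0.01 at n = 1,000
across rf ∈ {0.05, 0.1, 0.2, 0.4} (measured in the test suite).

## Phasing from selfed progeny

The classical procedure reads internal alleles off offspring that are
homozygous at an anchor locus and non-recombinant in between. The
implementation:

1. anchor = the color-locus insertion pair when it segregates, else the
   segregating locus with most informative offspring (ties: smallest
   position);
2. each locus is phased against the **nearest already-phased codominant
   locus** (chained anchors), because with an 18–24-offspring family and
   a ~50 cM panel the global anchor runs out of non-recombinant
   homozygotes for distal loci;
3. homozygote reads vote for a phase; conflicting votes (recombinants)
   are tallied and the decision is delegated to the full two-point
   likelihood over all progeny classes, which also exploits heterozygous
   and amplification-failure offspring. A single supporting homozygote is
   accepted only when the likelihood agrees; zero support leaves the
   locus `UNKNOWN`;
4. a final consistency sweep re-evaluates each phased locus against its
   nearest phased neighbours (two per side) by summed log-likelihood
   ratios and flips minority orientations. This repairs whole-block flips
   across the panel's widest gap (VMC5g7–SC8, ≈ 22 cM under the fixture
   map), where a single wrong early decision would otherwise propagate.
   Haplotype labels are arbitrary, so mutual consistency is the correct
   target;
5. FIXED/MONOMORPHIC loci put the same allele on both haplotypes;
   NULL_SEGREGATING loci put `NULL` on the haplotype whose co-phased
   offspring class fails to amplify.

Alleles present in the leaf but never transmitted are reported as chimera
signals (they live in L1 only). Phase recovery is exact (zero
mis-assigned segregating loci) in 100/100 error-free simulated families
of n = 200 from random parents — the regime where the procedure is meant
to operate; at the study sizes of 18–24 the residual failure modes are
data-intrinsic (see Limitations).

Without progeny, an L2-derived tissue genotype (roots, stem pith) is
split by subtraction of a consistent library haplotype
(`deduce_l2_from_tissue`); loci where the tissue shows a single allele
are annotated "hemizygosity not excluded", since homozygosity and
hemizygosity are indistinguishable without segregation data.

## Haplotype composition and naming

Against the colored/white references, each marker state is assigned
`COLORED_BACKBONE`, `WHITE_DONOR`, `DELETED` (NULL) or `UNKNOWN`
(matches neither reference); markers where the references share an allele
are uninformative and absorbed into agreeing flanks (noted) or break the
tiling. Maximal runs become segments with inner bounds (outermost markers
showing the state) and outer bounds (nearest markers of different state,
or the chromosome end), giving minimum / maximum physical lengths from
marker point positions — sub-marker breakpoint precision is beyond the
design's resolution, so no kb-exact feature coordinates are asserted.

A haplotype bearing both a colored backbone and a white donor tract is
**replacement-derived** (the product of somatic double-strand-break
repair using the homolog as template). Library matching is exact on all
mutually known states; unmatched haplotypes are auto-named from color
status and the allele at the proximal flanking SSR (`w188-4`, …).

## Chimera analysis and phenotype

`deduce_L1` searches haplotype pairs from library ∪ L2 whose allele union
with L2 reproduces the leaf pool at every assayed marker (an `UNKNOWN`
state may hide one unexplained allele; a concrete allele absent from the
leaf disproves a pair). Ranking is by (haplotypes not shared with L2 as a
multiset, non-library haplotypes), with ties preferring earlier —
canonical, non-mosaic — library entries; when no known pair fits, a
minimal partner is synthesized from the residual alleles (fewest invented
states first) and flagged. Multiset sharing matters: reusing one L2
haplotype twice implies an extra somatic event and must not outrank the
unchanged L2 pair.

Berry color (OIV 225): a layer is colored iff at least one haplotype
carries the functional colored allele (empty insertion site, color locus
not deleted — the green-yellow phenotype is recessive). Colored L1 over
white L2 → 4 (grey); colored L2 under any L1 → 6 (blue-black, the fruit
being indistinguishable from the fully colored plant); all white → 1. In
the pipeline the phenotype is read from observed tissue states at the
color locus when a leaf genotype exists, because a deduced L1 may contain
a synthesized haplotype of undetermined status while the phenotype is
fully observable.

Layer rearrangements: `DISPLACEMENT` copies L2 into L1 (inner cells
invade the epidermis — the common homogenization route producing white
bud sports from grey chimeras), `REPLACEMENT` copies L1 into L2 (rare).
Both are idempotent.

## Pipeline-level constraint propagation

Two repairs run after phasing, both surfaced as warnings on the clone
report, both inert for genuinely novel haplotypes:

* an unphased null allele (NULL_SEGREGATING locus `UNKNOWN` on both
  haplotypes — possible when the only amplification failures are
  anchor-heterozygous, which carry no phase information) is placed on the
  correct haplotype when the other haplotype's library matches force the
  amplified allele onto it;
* when the phased haplotypes do not both match the library but exactly
  one library pair reproduces the per-locus allele **sets** (which are
  phase-free and reliable even when the pairing across loci is not), the
  pair is re-identified by content.

## The simulator and what it does (not) emulate

`simulate_selfed_progeny` draws two independent gametes per offspring as
recombinant mosaics of the L2 pair, with per-interval crossover
probabilities from the map through the inverse mapping function and no
interference. A call fails to amplify only when both inherited states are
`NULL`. Genotyping error is a symmetric substitution by a random other
allele of the locus at a per-call rate; dropout (false amplification
failure) is a separate rate; both default to 0. Identical seeds give
byte-identical tables.

The simulated study (`periclinal.study.build_pinot_scenario`) uses the
study design's sizes: 51 genotyped S1 offspring for the reference
blue-black clone, 18 or 24 for the other eight progenies, plus two
bud-sport pairs contributing leaf and pith genotypes only. The fixture
genetic map assigns a uniform 1 cM per 0.2 Mb (≈ 50 cM over the region) —
a plausible synthetic choice, not a published map; real recombination is
suppressed around the centromere (~11.5 Mb), which would make the wide
VMC5g7–SC8 interval easier to phase than it is here, so the fixture is
conservative. Marker positions without a published coordinate are
synthetic, chosen consistent with the published span statements. The
phase of the SC8_0146_010 alleles (123/128) is not derivable from any
published homozygote: canonical library entries keep it `UNKNOWN`, and
simulation fixtures use an arbitrary, clearly marked assignment.

Not modeled: sequence-level double-strand-break biochemistry (events act
at marker-allele resolution), allele dosage / peak heights, mericlinal
(sector) chimeras, L3, somaclone regeneration, and population-level
phasing of unrelated individuals. Passing tests therefore demonstrate
correctness of the inference chain under presence/absence genotyping with
Mendelian transmission — not robustness to stutter artefacts, allele
dropout biases or segregation distortion in real S1 families.

## Numerical and degenerate-input choices

* EM for rf: init 0.25, tolerance 1e-10, ≤ 500 iterations, estimates
  clipped to [0, 0.5]; classes incompatible with the model (possible only
  with genotyping error) are ignored in the E-step.
* Exactly tied likelihoods (zero phase information) leave a locus
  `UNKNOWN` rather than guessing.
* Empty genotype cells are observed negative PCRs; `.` is
  missing-not-assayed and excluded from every count; a half-missing
  insertion pair is treated as missing for the whole logical locus.
* An all-FIXED/MONOMORPHIC progeny raises "no segregation to phase";
  per-clone failures in the batch pipeline are collected on the report,
  never fatal.
* Determinism: all randomness flows through seeded numpy Generators;
  reports and summaries are sorted; re-running a scenario is
  byte-identical.

## Known limitations

At the study's own progeny sizes, some datasets are intrinsically
uninformative: a family may by chance contain no homozygote for one
haplotype block (P ≈ 1% per clone), or no null/null offspring at a
hemizygous locus, in which case the corresponding state cannot be
recovered by any method and is reported `UNKNOWN` or resolved only
through the library constraints above. The haplotype census of the full
simulated study reproduces the expected six-white / four-replacement
partition across all 151 seeds tested, but individual-locus phase at
n = 18 remains sample-limited by nature.
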