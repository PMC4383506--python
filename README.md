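# periclinal

Cell-layer haplotype resolution for clonally propagated grapevine.

Grapevine clones accumulate somatic mutations during centuries of
vegetative propagation. Most of these mutations do not affect the whole
plant: they fix in a single cell layer of the shoot apical meristem,
producing a **periclinal chimera** whose L1 (epidermal) and L2
(subepidermal) lineages carry different genotypes. Berry-color
polymorphism in the Pinot group is the classic case — grey-berried clones
are colored-L1-over-white-L2 chimeras, white-berried clones arise when
white L2 cells invade the epidermis.

Because gametes (and roots/pith) derive from L2 while whole-leaf DNA
pools both layers, the two layers can be genotyped apart:

* **selfed-progeny segregation** reveals the L2 haplotype pair, including
  runs fixed by somatic replacement (homozygous in L2 though the leaf is
  heterozygous) and **null alleles** — deletions that show up as a ~25%
  amplification-failure class in S1 offspring;
* **leaf − L2 subtraction** then yields the L1 pair (tri-allelic SSR
  profiles are the telltale chimera signal).

`periclinal` implements this entire inference chain for panels of
codominant SSR markers and retrotransposon insertion-site assay pairs
(scored as empty site / full site), together with a simulator of the
generative process, so every stage is testable without external data.

## What it computes

Given a marker panel, leaf genotypes, and per-clone selfed-progeny tables
(or L2-derived tissue genotypes), the pipeline

1. classifies every locus per progeny: `SEGREGATING` (1:2:1 / 3:1),
   `FIXED` (allele shown by all offspring — a replacement-tract signal),
   `NULL_SEGREGATING` (amplified allele + no-amplification class; the
   hemizygosity test is an exact binomial test against the 1/4 null/null
   expectation), with Pearson goodness-of-fit tests;
2. resolves the L2 haplotype pair by reading alleles off
   anchor-homozygous non-recombinant offspring, chained locus to locus,
   with two-point EM likelihoods (F2 design, Kosambi/Haldane map
   functions) deciding ambiguous phase;
3. decomposes each haplotype against the canonical colored (c188) and
   white (w216) references into composition segments — colored backbone,
   white replacement tract (gene conversion), deletion — with min/max
   physical lengths bounded by flanking markers;
4. deduces candidate L1 pairs from the leaf allele pool under a
   parsimony ranking, detects chimerism, and predicts berry color (OIV
   descriptor 225: 1 green-yellow, 4 grey, 6 blue-black; a layer is
   colored iff it carries a functional colored allele, i.e. the Gret1
   empty site with an intact color locus);
5. summarizes the distinct haplotypes by color status and by presence of
   replacement tracts.

The simulator provides the converse direction: somatic
conversion/deletion events applied to haplotype pairs
(`apply_somatic_event`), Mendelian selfing with per-interval
recombination and optional genotyping error (`simulate_selfed_progeny`),
cell-layer tissue sampling (`simulate_clone_tissues`) and layer
rearrangement operators (displacement L2→L1, replacement L1→L2).

## Worked example

```bash
python examples/01_simulate_selfed_progeny.py
```

```
simulated offspring: 500
color-locus classes  empty/empty: 109  empty/full: 261  full/full: 130
predicted blue-black: 74.0%  (Mendelian expectation 75%)
predicted green-yellow: 26.0%  (expectation 25%)
1:2:1 chi-square p-value: 0.255  (> 0.05: Mendelian fit holds)
```

Selfing the blue-black reference clone (L2 = c188/w216) segregates the
color locus 1:2:1; the 74% of offspring amplifying the retrotransposon
empty site keep a functional colored allele and bear blue-black fruit.

```bash
python examples/05_full_study_pipeline.py
```

```
clone        L2 haplotypes      top L1         chimeric OIV
PN162        c188/w216          c188/w216      no       6
PG52         w188-1/w216        c188/w216      yes      4
PB54         w188-1/w198        w188-1/w198    no       1
...
distinct L2 haplotypes: 7
  white: 6
  bearing a replacement tract: 4
```

Across the simulated collection (nine clones with selfed progenies plus
two grey clones and their bud sports), six distinct white haplotypes
account for the loss of berry color; four of them are mosaics carrying a
replacement tract copied from the white homolog — the signature of
somatic double-strand-break repair using the homologous chromosome as
template, in one case combined with a deletion spanning the color locus.

The other examples cover phasing a chimeric clone
(`02_phase_l2_haplotypes.py`), tract decomposition with physical bounds
(`03_classify_conversion_tracts.py`) and chimera/L1/phenotype analysis
with layer-rearrangement operators (`04_chimera_and_phenotype.py`).

A thin CLI mirrors the stages:

```bash
periclinal simulate scenario.yaml -o out/   # progeny + truth haplotypes
periclinal segregate progeny.tsv            # per-locus classes, chi-square, null calls
periclinal phase progeny.tsv --parent-leaf leaf.tsv
periclinal classify haplotypes.tsv          # composition segments + lengths
periclinal chimera leaf.tsv l2_haps.tsv
periclinal evolve model.yaml DISPLACEMENT
periclinal run scenario.yaml -o out/        # full batch analysis
```

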