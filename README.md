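# intronsnp

Quantify how single-nucleotide polymorphism (SNP) density in organellar
protein-coding genes varies with distance from self-splicing intron–exon
boundaries, across a population of resequenced strains.

Self-splicing group I and group II introns in fungal mitochondrial genes
(classically *cox1* and *cob*) often encode homing endonucleases that cleave
intron-free alleles and convert them to intron-containing ones via
homologous-recombination repair. If this invasion–loss cycle is mutagenic,
it should leave an imprint on natural variation: an excess of polymorphism
in exonic sequence immediately flanking the boundaries of *mobile* introns,
absent at immobile introns and at spliceosomal introns. `intronsnp` is a
toolkit for detecting and dissecting exactly that signature, for anyone
working with multi-strain alignments or variant tables of intron-containing
genes.

## The statistic

For every exonic polymorphic site, assign its distance `d` (in nt, the
adjacent base is `d = 1`) to the nearest intron–exon boundary; each site is
counted once, at its nearest boundary only. The **SNP density at distance
`d`** over a window `d ≤ W` (default `W = 70`) is

```
density(d) = snp_count(d) / contrib(d)
```

where `contrib(d)` is the number of contributing units that possess a
nucleotide whose nearest-boundary distance is `d` — per exonic position
("exon_ends" convention, SNPs per site, the default) or per exon ("exons"
convention). Short exons drop out of the denominator at large `d`, so the
denominator is adjusted per distance. Monotone decay of `density(d)` with
`d` is tested with Kendall's τ-b (tie-corrected, two-sided p), stratified
by gene, intron mobility, intron group, and boundary side (5′ exon end vs
3′ exon start). Supporting analyses:

* **union intron-site sets** — distances measured against every insertion
  site observed anywhere in the population (conservative: can only shrink
  distances);
* **mock boundaries** — junctions mapped through a cross-species alignment
  into a constitutively intronless ortholog, as a selection-constraint
  control;
* **selection tests** — synonymous/nonsynonymous classification under NCBI
  genetic codes (yeast mitochondrial `transl_table 3` or standard
  `transl_table 1`), a near/far Fisher exact contingency test, the
  sequence-specific mutational expectation of the nonsynonymous fraction,
  and overlap of SNPs with homing-endonuclease recognition motifs and
  intron–exon base-pairing positions;
* **a seeded population simulator** with a tunable exponential
  boundary-anchored mutation gradient, per-strain intron presence/absence
  and purifying constraint, for end-to-end validation.

## Worked example

Simulate a population of 50 strains over a 20-exon gene (3000 exonic nt, 19
introns of which 13 are mobile) with a 4-fold polymorphism-rate elevation at
mobile-intron boundaries decaying over 15 nt, then fit the full analysis:

```python
from intronsnp import BoundaryGradientModel, SimConfig

model = BoundaryGradientModel.from_simulation(
    SimConfig(seed=5), strata=("all", "mobility"))
results = model.fit()
print(results.summary())
```

```
Boundary SNP-density gradient analysis
======================================================
genes: simgene   window: 70 nt   denominator: exon_ends
exonic SNPs: 202

stratum                  tau         p     n
--------------------------------------------
mobility=mobile       -0.261    0.0022    70
mobility=immobile      0.009    0.9211    70
all                   -0.214    0.0113    70

near/far nonsynonymous Fisher test (cutoff 20 nt):
  near 60/82 nonsyn (73%), far 68/93 nonsyn (73%), OR=1.00, p=1.000
  mutational nonsyn expectation (simgene): 0.766
  cleavage-motif overlap: 44/82 near-boundary SNPs in recognition motifs (54%)
  SNPs on intron-exon pairing positions: 14
```

The mobile stratum shows the planted negative density-vs-distance trend
(τ = −0.26, p = 0.002: SNP density falls as one moves away from
mobile-intron boundaries), the immobile stratum is flat (τ ≈ 0) — the
mobility dissociation the method is designed to expose. With no purifying
suppression configured, the near- and far-boundary nonsynonymous fractions
match (73% vs 73%, Fisher p = 1), close to this sequence's mutational
expectation of 0.77.

Real data enter through `BoundaryGradientModel.from_alignment` (multi-strain
aligned FASTA + a GFF3/JSON gene model with an intron-attribute TSV) or
`from_vcf` (variant calls against a reference). The same pipeline is
scriptable from the shell:

```bash
intronsnp simulate --seed 5 --out-dir sim/
intronsnp profile --fasta sim/alignment.fasta --reference-id REF \
    --gene-model sim/gene_model.json --out-dir out/
intronsnp selection --fasta sim/alignment.fasta --reference-id REF \
    --gene-model sim/gene_model.json --motifs sim/motifs.bed --out-dir out/
```

writing per-distance profile, smoothed-curve and trend TSVs with full
provenance headers. See `docs/methods.md` for the model, conventions and
parameter choices.

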