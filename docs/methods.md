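# Methods

## Coordinates and gene models

All internal coordinates are 0-based, half-open; 1-based coordinates appear
only at the GFF3 and VCF interfaces. A `GeneModel` is an ordered list of
exon intervals on a reference sequence, with intron *k* occupying exactly
the gap between exons *k* and *k+1*; per-intron attributes (group I/II/
spliceosomal, experimentally-determined mobility, encoded ORF activities)
ride on a sidecar TSV because GFF3 has no standard slot for mobility.
Analyses run in gene orientation: minus-strand genes are handled by
reorienting sequences on load (or, in `classify_site`, by complementing
alleles into gene orientation), so "5′ exon end" always means the
donor-adjacent exon terminus.

Intron insertion junctions are stored as **spliced-CDS offsets**. An intron
occupies zero nucleotides of the mature CDS, so every junction — a
reference-annotated intron, an insertion site seen only elsewhere in the
population, or an in-silico mock boundary — is a point in spliced space.
This gives one uniform distance computation and makes the conservativeness
property (adding union sites can only shrink distances) structural rather
than incidental.

## Distance convention

The exonic base immediately adjacent to a boundary is at distance 1.
Each exonic position takes the minimum distance over all junctions; ties
between the two flanking boundaries of an exon break deterministically
toward the 5′ exon end. Terminal exons have a single internal boundary;
positions near the gene's start/stop simply carry large distances and fall
outside the analysis window, with no special-casing. The gene's own start
and stop are not boundaries. An alternative convention would exclude
exon-terminal positions abutting start/stop codons from terminal-exon
profiles; we do not, since the window (70 nt) already excludes almost all
of them in realistic gene architectures.

## Density profile

`density(d) = snp_count(d) / contrib(d)` over `d = 1..W`, `W = 70` nt by
default — wide enough to span the elevated and plateauing region, while
further extension only adds distances to which few exons contribute. Two
denominator conventions are implemented because per-exon and per-site
normalization genuinely differ for internal exons:

* `exon_ends` (default): `contrib(d)` = number of exonic positions whose
  nearest-boundary distance equals `d` (equivalently, (exon, boundary)
  pairs possessing such a position — each pair has at most one). This is a
  true "SNPs per site" density.
* `exons`: `contrib(d)` = number of exons possessing any position at
  nearest-distance `d`.

The convention used is recorded in output metadata. Every site is counted
once, at its nearest boundary; a site's stratum (gene, mobility, group,
side) is that of its *own* nearest boundary, tie-broken as above, and the
denominator of a stratum counts only positions whose nearest boundary
matches, so numerator and denominator stay commensurable.

The smoothed curve is a 10-nt sliding-window mean over defined densities,
moving in 1-nt steps; the first point sits at the center of the first
window (x = 5.5), not at 0. Windows containing no defined density are
omitted.

## Trend test

Kendall's τ-b (tie-corrected) of `density(d)` against `d`, over the
distances with `contrib(d) > 0`; undefined distances are excluded, not
zero-filled, because no observable site can exist there. The two-sided p
uses the tie-corrected normal approximation; for very short profiles
(n ≤ 8 points) an exact permutation enumeration replaces it. A profile
whose defined densities are all identical has no rank trend and is reported
as τ = 0, p = 1 with a degenerate flag. Trend tests require at least 10
defined distances. The test consumes the per-distance densities (one pair
per distance); a per-site indicator variant would be a possible extension
but is not what this implementation computes.

## Variant calling conventions

From an alignment, a column is a polymorphic site when (i) the reference
row is ungapped there (otherwise the column has no reference coordinate),
(ii) at least two distinct bases in {A,C,G,T} are each carried by at least
`min_allele_count` strains (default 1 — a singleton difference between
high-quality assemblies is a SNP), and (iii) the gap+N fraction is at most
`max_missing_frac` (default 0.2). Columns where only missing data varies
are not sites, and a multi-allelic column is a single site. Manual curation
of alignment errors is replaced by explicit, declared strain exclusion
lists — an auditable surrogate with no automatic outlier detection. From a
VCF, SNP records map to 0-based positions (POS−1); indels are skipped with
a logged count; multi-allelic records are one site. These defaults are
recorded in run metadata since reasonable alternatives exist.

## Selection analyses

Sites are classified by substituting each alternative allele into its codon
of the spliced reference CDS (codons spanning exon junctions exist only in
spliced space, where they are handled naturally) and translating under the
model's NCBI code table (3 for yeast-mitochondrial-style data, 1
otherwise). Stop gain/loss counts as nonsynonymous. A site whose alleles
include both silent and protein-changing changes is `mixed` and counts as
nonsynonymous in contingency tables, since it harbors protein-changing
variation; this choice is recorded in output metadata.

The near/far test builds the 2×2 table [distance ≤ 20 nt vs
20 < distance ≤ W] × [nonsynonymous vs synonymous] and applies Fisher's
exact test (two-sided, conditional-MLE odds ratio). The mutational
expectation of the nonsynonymous fraction is computed sequence-specifically
by enumerating all nine single-nucleotide mutants of every codon of the
CDS, uniformly weighted (≈0.77 for a random stop-free CDS under table 3);
an observed nonsynonymous count can be tested against it with an exact
binomial test (`binomial_vs_expectation`). We provide this binomial
construction as our stated surrogate for testing depletion against the
expectation; a Fisher-style test against a fraction is not well defined and
is not claimed.

Motif overlap counts near-boundary sites (≤ 20 nt) inside
cleavage-recognition intervals (BED with a kind column); pairing overlap
returns the sites on intron–exon base-pairing positions with their classes
attached, for manual inspection of base-pair preservation.

## Mock boundaries

Donor junctions are carried column-wise through a two-sequence alignment of
the orthologous coding regions: the target coordinate is the count of
ungapped target characters preceding the junction's column; a junction
landing where the target is gapped resolves deterministically to the next
ungapped target position. The mapped junctions act as an insertion-site set
on an intronless target model, so the identical profile/trend machinery
runs unchanged. Because most introns share a phase, mock-boundary profiles
show 3-nt periodicity; the periodicity tests exploit this deliberately.

## The simulator

`simulate_population` draws, for a population of `n_strains` (default 50)
plus a never-mutated reference row:

* an ancestral gene: a random stop-free CDS under the configured code
  table, cut into exons, with random intron sequences;
* per-site polymorphism: each exonic site becomes polymorphic independently
  with probability `mu0 · (1 + A · exp(−(d−1)/λ))`, `d` being its distance
  to the nearest *gradient-bearing* boundary (`gradient_scope` = all
  introns, mobile introns only, or none). Defaults: `mu0 = 0.05`,
  `A = 3` (4-fold elevation at the boundary), `λ = 15` nt;
* one alternative allele per site (infinite-sites style — the analysis
  consumes only site marginals, so no genealogy is simulated), carried by a
  random nonempty proper subset of strains;
* purifying constraint: a candidate nonsynonymous polymorphism is rejected
  with probability `nonsyn_suppression` and redrawn as synonymous where the
  codon allows (sites with no synonymous option are skipped with a log
  entry);
* intron presence/absence: each strain loses each intron independently
  (default probability 0.05), leaving gap runs in the alignment.

The default gene emulates a pooled organellar exon set at the *cox1*/*cob*
scale: 20 exons of 90–240 nt (3000 exonic nt) separated by 19 introns, 13
of them mobile (about the two-thirds proportion of those genes), so most
exonic positions lie within the 70-nt window of some boundary — the
geometry in which the method is actually used, and the regime where a
λ = 15 nt gradient is statistically visible. `mu0 = 0.05` places ~200
exonic SNPs per population. Everything is deterministic under
(config, seed), and the ground truth (per-site probabilities, realized
sites, presence matrix) is retained; `truth_profile` gives the closed-form
expected density for comparison with measured profiles.

What the simulator does **not** emulate: genealogical correlation between
strains (linkage, shared ancestry), recombination, coconversion tracts,
indels beyond whole-intron presence/absence, alignment error, or
sequencing artifacts. Passing tests therefore demonstrate that the
statistics recover site-marginal structure correctly, not that the pipeline
is robust to misalignment or to the non-independence of real strains.

## Numerical choices and degenerate inputs

* Fisher p-values sum hypergeometric probabilities of all tables at most as
  probable as the observed one; a zero margin yields p = 1 with an
  undefined (NaN) odds ratio and a degenerate flag.
* Simulated per-site rates are clipped at 0.95.
* Empty strata, intronless genes (sites with no distance), and zero-SNP
  inputs are skipped/flagged with logged counts rather than errors.
* Profile TSVs, curve TSVs, and trend TSVs carry header comments with the
  tool version, resolved configuration, and SHA-256 checksums of inputs.

## Validation problem sizes

The test battery uses 20-seed panels for gradient-recovery power (expected
detection in ≥18/20 mobile-stratum runs, ≤3/20 immobile false positives)
and 200-seed panels for null calibration (rejection fraction within
[0.01, 0.12] at α = 0.05) — panel sizes at which the binomial uncertainty
of the checked fractions is small relative to the asserted bounds, while a
full run of suite plus acceptance script stays in the tens of seconds.

## Known limitations

* The per-distance Kendall test treats distances as exchangeable under the
  null; in real data, codon structure and splice-pairing constraints impose
  mild periodicity and local dependence the simulator only partly mimics
  (via codon-structured CDS and the mock-boundary periodicity checks).
* Union-mode insertion sites inherit attributes from whichever strain model
  supplies them; sites with no annotated intron carry unknown
  mobility/group and stratify accordingly.
* VCF mode trusts the caller's choices upstream (no genotype-quality
  filtering beyond what produced the file).
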