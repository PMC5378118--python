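"""Synonymous/nonsynonymous classification and selection tests.

Polymorphisms in the organellar genes are classified against the NCBI
genetic codes (transl_table 3, the yeast mitochondrial code, for
S. cerevisiae / L. kluyveri-like data; transl_table 1 for S. pombe-like
data). The near-vs-far Fisher contingency test asks whether the
nonsynonymous fraction within 20 nt of the intron-exon boundary differs from
the fraction further out -- locally relaxed purifying selection would show up
as a near-boundary excess of protein-changing variants.

``expected_nonsyn_fraction`` gives the sequence-specific mutational
expectation (the fraction of all single-nucleotide changes of the CDS that
alter the protein, roughly 2/3 for a typical coding sequence), against which
an observed nonsynonymous count can be tested with an exact binomial test.

Motif overlap reports how many near-boundary SNPs fall inside annotated
homing-endonuclease recognition motifs, and ``pairing_overlap`` lists SNPs
at exonic positions involved in intron-exon base pairing during
self-splicing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .gene_models import GeneModel, genomic_to_spliced

logger = logging.getLogger("intronsnp")

__all__ = [
    "ContingencyResult",
    "MotifAnnotation",
    "classify_site",
    "classify_all",
    "fisher_2x2",
    "near_far_selection_test",
    "expected_nonsyn_fraction",
    "binomial_vs_expectation",
    "motif_overlap",
    "pairing_overlap",
    "spliced_reference",
]

NEAR_CUTOFF = 20


def _code(table_id: int):
    try:
        return CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table {table_id}") from exc


def translate_codon(codon: str, table_id: int) -> str:
    """One-letter amino acid, '*' for stop."""
    tab = _code(table_id)
    if codon in tab.stop_codons:
        return "*"
    return tab.forward_table[codon]


@dataclass
class ContingencyResult:
    """A 2x2 table with Fisher's exact test and the conditional odds ratio."""

    table: tuple  # ((a, b), (c, d))
    odds_ratio: float  # NaN when undefined (zero margin)
    p_two_sided: float
    row_labels: tuple = ("row1", "row2")
    col_labels: tuple = ("col1", "col2")
    degenerate: bool = False
    near_fraction: float | None = None
    far_fraction: float | None = None


@dataclass(frozen=True)
class MotifAnnotation:
    """Reference intervals of functional motifs.

    ``kind`` is ``cleavage_recognition`` (endonuclease target motifs) or
    ``exon_intron_pairing`` (exonic positions base-pairing with the intron
    during splicing). Intervals are 0-based half-open.
    """

    intervals: tuple  # of (start, end, motif_id, kind)

    @classmethod
    def from_bed(cls, path) -> "MotifAnnotation":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                p = line.split("\t")
                kind = p[4] if len(p) > 4 else "cleavage_recognition"
                rows.append((int(p[1]), int(p[2]),
                             p[3] if len(p) > 3 else ".", kind))
        return cls(intervals=tuple(rows))

    def to_bed(self, path, chrom: str = "gene") -> None:
        with open(path, "w") as fh:
            for s, e, mid, kind in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{mid}\t{kind}\n")

    def of_kind(self, kind: str):
        return [iv for iv in self.intervals if iv[3] == kind]

    def covers(self, pos: int, kind: str) -> bool:
        return any(s <= pos < e for s, e, _, k in self.intervals if k == kind)


# ---------------------------------------------------------------------------
# Classification


def spliced_reference(model: GeneModel, reference_seq: str) -> str:
    """Spliced CDS of the reference sequence (exons concatenated).

    ``reference_seq`` is the ungapped reference the model is annotated on,
    in gene orientation.
    """
    return "".join(reference_seq[s:e] for s, e in model.exons)


def classify_site(site, model: GeneModel, spliced_sequence: str) -> str:
    """Classify one site as synonymous / nonsynonymous / mixed.

    Each alt allele is substituted at the site's position within its codon of
    the spliced CDS and the codon translated under the model's genetic code.
    All alts silent -> synonymous; all protein-changing (stop gain/loss
    included) -> nonsynonymous; both kinds -> mixed; intronic or flanking
    sites -> not_applicable.
    """
    if site.context != "exonic":
        site.sel_class = "not_applicable"
        return site.sel_class
    if len(spliced_sequence) % 3 != 0:
        raise ValueError("spliced CDS length not divisible by 3")
    spliced = genomic_to_spliced(model, site.ref_pos)
    if spliced is None:
        site.sel_class = "not_applicable"
        return site.sel_class
    spliced -= model.cds_phase
    if spliced < 0 or spliced >= len(spliced_sequence):
        raise ValueError(
            f"site at {site.ref_pos}: spliced position {spliced} outside CDS"
        )
    ci = spliced // 3
    codon = spliced_sequence[3 * ci: 3 * ci + 3]
    off = spliced % 3
    # alleles are recorded as read off the annotated reference; on a minus
    # strand gene the CDS runs on the complement
    comp = str.maketrans("ACGT", "TGCA")
    ref_allele = site.ref_allele
    alt_alleles = site.alt_alleles
    if model.strand == "-":
        ref_allele = ref_allele.translate(comp)
        alt_alleles = tuple(a.translate(comp) for a in alt_alleles)
    if codon[off] != ref_allele:
        raise ValueError(
            f"site at {site.ref_pos}: reference allele {ref_allele} "
            f"does not match CDS base {codon[off]}"
        )
    ref_aa = translate_codon(codon, model.code_table)
    kinds = set()
    for alt in alt_alleles:
        alt_codon = codon[:off] + alt + codon[off + 1:]
        alt_aa = translate_codon(alt_codon, model.code_table)
        kinds.add("synonymous" if alt_aa == ref_aa else "nonsynonymous")
    if kinds == {"synonymous"}:
        site.sel_class = "synonymous"
    elif kinds == {"nonsynonymous"}:
        site.sel_class = "nonsynonymous"
    else:
        site.sel_class = "mixed"
    return site.sel_class


def classify_all(sites, model: GeneModel, reference_seq: str):
    """Classify every site against the model's spliced reference CDS."""
    cds = spliced_reference(model, reference_seq)
    for s in sites:
        classify_site(s, model, cds)
    return sites


# ---------------------------------------------------------------------------
# Contingency tests


def fisher_2x2(table, row_labels=("row1", "row2"),
               col_labels=("col1", "col2")) -> ContingencyResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    The p-value sums hypergeometric probabilities (margins fixed) of every
    table at most as probable as the observed one. A zero margin leaves the
    odds ratio undefined (NaN, degenerate flag) with p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return ContingencyResult(
            table=tuple(map(tuple, t)), odds_ratio=float("nan"),
            p_two_sided=1.0, row_labels=row_labels, col_labels=col_labels,
            degenerate=True,
        )
    _, p = stats.fisher_exact(t, alternative="two-sided")
    orat = _odds_ratio(t, kind="conditional").statistic
    return ContingencyResult(
        table=tuple(map(tuple, t)), odds_ratio=float(orat),
        p_two_sided=float(p), row_labels=row_labels, col_labels=col_labels,
    )


def near_far_selection_test(sites, cutoff: int = NEAR_CUTOFF,
                            window: int = 70) -> ContingencyResult:
    """Near/far x nonsynonymous/synonymous Fisher test.

    Near means nearest-boundary distance <= cutoff; far means
    cutoff < distance <= window. Mixed sites (some alleles silent, some not)
    count as nonsynonymous: a site harboring any protein-changing allele
    evidences nonneutral variation. Sites without distance or class are
    ignored.
    """
    cells = np.zeros((2, 2), dtype=int)
    for s in sites:
        if s.distance is None or s.sel_class == "not_applicable":
            continue
        if s.distance <= cutoff:
            i = 0
        elif s.distance <= window:
            i = 1
        else:
            continue
        j = 0 if s.sel_class in {"nonsynonymous", "mixed"} else 1
        cells[i, j] += 1
    res = fisher_2x2(
        cells,
        row_labels=(f"near(<= {cutoff} nt)", f"far({cutoff} < d <= {window})"),
        col_labels=("nonsynonymous", "synonymous"),
    )
    near_n, far_n = cells.sum(axis=1)
    res.near_fraction = cells[0, 0] / near_n if near_n else None
    res.far_fraction = cells[1, 0] / far_n if far_n else None
    if near_n == 0 or far_n == 0:
        res.degenerate = True
    return res


def expected_nonsyn_fraction(spliced_sequence: str, code_table: int) -> float:
    """Fraction of all single-nucleotide changes that alter the protein.

    Enumerates the 9 possible point mutations of every codon of the given
    CDS, uniformly weighted; stop gain/loss counts as nonsynonymous. An
    internal stop codon is still processed, with a warning.
    """
    if len(spliced_sequence) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    n_total = n_nonsyn = 0
    n_codons = len(spliced_sequence) // 3
    for ci in range(n_codons):
        codon = spliced_sequence[3 * ci: 3 * ci + 3]
        aa = translate_codon(codon, code_table)
        if aa == "*" and ci < n_codons - 1:
            logger.warning("internal stop codon at codon %d", ci)
        for off in range(3):
            for b in "ACGT":
                if b == codon[off]:
                    continue
                mut = codon[:off] + b + codon[off + 1:]
                n_total += 1
                if translate_codon(mut, code_table) != aa:
                    n_nonsyn += 1
    return n_nonsyn / n_total


def binomial_vs_expectation(n_nonsyn: int, n_total: int,
                            expected_fraction: float):
    """Exact binomial test of an observed nonsynonymous count.

    The surrogate for testing depletion of protein-changing variants against
    the mutational expectation: two-sided p of ``n_nonsyn`` successes in
    ``n_total`` trials at the expected fraction.
    """
    res = stats.binomtest(n_nonsyn, n_total, expected_fraction)
    return res.pvalue


# ---------------------------------------------------------------------------
# Motif / pairing overlap


def motif_overlap(sites, motifs: MotifAnnotation,
                  near_cutoff: int = NEAR_CUTOFF):
    """(n_near, n_overlapping, fraction) of near-boundary SNPs in motifs.

    Counts exonic sites within ``near_cutoff`` of a boundary whose position
    lies inside any cleavage-recognition interval. Fraction is None when
    there are no near sites.
    """
    near = [
        s for s in sites
        if s.distance is not None and s.distance <= near_cutoff
    ]
    n_over = sum(
        1 for s in near if motifs.covers(s.ref_pos, "cleavage_recognition")
    )
    frac = n_over / len(near) if near else None
    if frac is None:
        logger.info("motif_overlap: no near-boundary sites")
    return len(near), n_over, frac


def pairing_overlap(sites, motifs: MotifAnnotation):
    """Sites falling on intron-exon base-pairing positions, classes attached."""
    return [
        s for s in sites
        if motifs.covers(s.ref_pos, "exon_intron_pairing")
    ]
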