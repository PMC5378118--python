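"""Polymorphic-site identification from multi-strain alignments or VCFs.

Two input routes produce the same :class:`PolymorphicSite` records:

* an aligned FASTA of the gene region across strains (one row defines the
  reference coordinate system), scanned column-wise;
* a pre-computed variant table (VCF), used when per-strain assemblies are not
  available and variant calls against a reference are.

A column is a site when at least two distinct unambiguous bases are each
carried by at least ``min_allele_count`` strains and missingness (gaps + N)
does not exceed ``max_missing_frac``. Columns where the reference row is
gapped have no reference coordinate and are skipped. A multi-allelic column
is one site: every site is counted once downstream, at its distance to the
nearest boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("intronsnp")

BASES = ("A", "C", "G", "T")


@dataclass
class PolymorphicSite:
    """One polymorphic reference position.

    ``distance``/``side``/``sel_class`` start unset and are filled by
    :mod:`intronsnp.boundary_distance` and
    :mod:`intronsnp.selection_analysis`.
    """

    ref_pos: int
    ref_allele: str
    alt_alleles: tuple
    allele_counts: dict
    n_called: int
    gene_id: str | None = None
    context: str = "unknown"  # exonic | intronic | flank
    distance: int | None = None
    side: str | None = None
    boundary_id: str | None = None
    nearest_mobile: bool | None = None
    nearest_group: str | None = None
    sel_class: str = "not_applicable"

    @property
    def alleles(self) -> tuple:
        return (self.ref_allele,) + tuple(self.alt_alleles)


@dataclass(frozen=True)
class StrainAlignment:
    """Equal-length gapped nucleotide rows over {A,C,G,T,N,-} per strain."""

    strain_ids: tuple
    rows: tuple
    reference_id: str

    def __post_init__(self):
        if len(self.strain_ids) != len(self.rows):
            raise ValueError("strain_ids and rows differ in length")
        if len(set(map(len, self.rows))) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_id not in self.strain_ids:
            raise LookupError(
                f"reference row {self.reference_id!r} not in alignment"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def reference_row(self) -> str:
        return self.rows[self.strain_ids.index(self.reference_id)]

    def without_strains(self, exclude) -> "StrainAlignment":
        """Drop listed strains (the declared surrogate for manual curation)."""
        exclude = set(exclude)
        if self.reference_id in exclude:
            raise ValueError("cannot exclude the reference row")
        keep = [i for i, s in enumerate(self.strain_ids) if s not in exclude]
        dropped = self.n_strains - len(keep)
        if dropped:
            logger.info("excluded %d strain(s) from alignment", dropped)
        return StrainAlignment(
            strain_ids=tuple(self.strain_ids[i] for i in keep),
            rows=tuple(self.rows[i] for i in keep),
            reference_id=self.reference_id,
        )

    def matrix(self) -> np.ndarray:
        """(n_strains, n_columns) array of single-byte characters."""
        joined = "".join(self.rows).encode("ascii")
        return np.frombuffer(joined, dtype="S1").reshape(
            self.n_strains, self.n_columns
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(fasta_path, reference_id: str) -> StrainAlignment:
    """Read an aligned FASTA; case-fold to upper and map RNA U to T."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    if len(rows) < 2:
        raise ValueError(f"{fasta_path}: need at least 2 aligned rows")
    return StrainAlignment(
        strain_ids=tuple(ids), rows=tuple(rows), reference_id=reference_id
    )


def find_polymorphic_sites(
    aln: StrainAlignment,
    min_allele_count: int = 1,
    max_missing_frac: float = 0.2,
) -> list:
    """Column scan for polymorphic sites.

    ``ref_pos`` is the count of non-gap reference characters before the
    column, i.e. the position on the ungapped reference sequence. Columns
    where only missing data (gap/N) varies are not sites.
    """
    mat = aln.matrix()
    n, m = mat.shape
    ref = np.frombuffer(aln.reference_row.encode("ascii"), dtype="S1")
    ref_gap = ref == b"-"
    # reference coordinate of each column (valid where reference non-gap)
    ref_pos = np.cumsum(~ref_gap) - 1

    base_counts = np.stack(
        [(mat == b.encode()).sum(axis=0) for b in BASES]
    )  # (4, m)
    missing = n - base_counts.sum(axis=0)
    qualifying = (
        (~ref_gap)
        & ((base_counts >= min_allele_count).sum(axis=0) >= 2)
        & (missing <= max_missing_frac * n)
    )

    sites = []
    for col in np.nonzero(qualifying)[0]:
        counts = {
            b: int(c)
            for b, c in zip(BASES, base_counts[:, col])
            if c >= 1
        }
        ref_base = ref[col].decode()
        if ref_base not in BASES:  # reference N: no usable reference allele
            continue
        alts = tuple(
            b for b in BASES
            if b != ref_base and counts.get(b, 0) >= min_allele_count
        )
        if not alts or (
            counts.get(ref_base, 0) < min_allele_count and len(alts) < 2
        ):
            continue
        sites.append(
            PolymorphicSite(
                ref_pos=int(ref_pos[col]),
                ref_allele=ref_base,
                alt_alleles=alts,
                allele_counts=counts,
                n_called=int(n - missing[col]),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# VCF route


def variants_from_table(vcf_path, region=None) -> list:
    """SNP records from a VCF as :class:`PolymorphicSite`\\ s (POS-1 → 0-based).

    ``region`` is an optional (start, end) half-open span on the reference;
    records outside are dropped. Indels and other non-SNP records are skipped
    with a logged count. Allele counts come from haploid/diploid GT columns
    when samples are present, else from INFO/AC+AN when available.
    """
    import pysam

    skipped = 0
    sites = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()))
            if (
                len(rec.ref) != 1
                or not alts
                or any(len(a) != 1 or a not in BASES for a in alts)
                or rec.ref not in BASES
            ):
                skipped += 1
                continue
            pos = rec.pos - 1
            if region is not None and not region[0] <= pos < region[1]:
                continue
            counts: dict = {}
            n_called = 0
            if rec.samples:
                alleles = (rec.ref,) + alts
                for sample in rec.samples.values():
                    for ai in sample["GT"]:
                        if ai is None:
                            continue
                        counts[alleles[ai]] = counts.get(alleles[ai], 0) + 1
                        n_called += 1
            else:
                info = rec.info
                try:
                    an = info.get("AN")
                    ac = info.get("AC")
                except (KeyError, ValueError):  # fields absent from header
                    an = ac = None
                if ac is not None:
                    ac = tuple(ac) if isinstance(ac, tuple) else (ac,)
                    for a, c in zip(alts, ac):
                        counts[a] = int(c)
                    if an is not None:
                        counts[rec.ref] = int(an) - sum(counts.values())
                        n_called = int(an)
            sites.append(
                PolymorphicSite(
                    ref_pos=pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    allele_counts=counts,
                    n_called=n_called,
                )
            )
    if skipped:
        logger.info("skipped %d non-SNP VCF record(s)", skipped)
    return sites


def write_vcf(sites, path, *, contig: str = "gene", strain_ids=None,
              genotypes=None, contig_length: int | None = None) -> None:
    """Write sites as a minimal plain-text VCFv4.2.

    ``genotypes`` is an optional {ref_pos: list of allele indices per strain
    (None = missing)} mapping; with it, haploid GT sample columns are emitted
    so allele counts survive a round-trip through
    :func:`variants_from_table`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=intronsnp\n")
        if contig_length:
            fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        else:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Called alleles">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if strain_ids is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            cols += ["FORMAT"] + list(strain_ids)
        fh.write("\t".join(cols) + "\n")
        for s in sorted(sites, key=lambda s: s.ref_pos):
            ac = ",".join(
                str(s.allele_counts.get(a, 0)) for a in s.alt_alleles
            )
            row = [
                contig, str(s.ref_pos + 1), ".", s.ref_allele,
                ",".join(s.alt_alleles), ".", "PASS",
                f"AC={ac};AN={s.n_called}",
            ]
            if strain_ids is not None:
                gts = (genotypes or {}).get(s.ref_pos)
                if gts is None:
                    gts = ["."] * len(strain_ids)
                row += ["GT"] + [str(g) if g is not None else "." for g in gts]
            fh.write("\t".join(row) + "\n")
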