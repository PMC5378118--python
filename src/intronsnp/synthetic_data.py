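"""Synthetic multi-strain populations with boundary-anchored SNP gradients.

The generator emulates the statistical structure the analysis is built to
detect, for a population of N strains over one organellar protein-coding
gene with K self-splicing introns:

* each exonic site becomes polymorphic independently with probability
  ``mu0 * (1 + A * exp(-(d - 1) / lam))``, where d is its distance to the
  nearest *gradient-bearing* boundary (all introns, only mobile introns, or
  none, per ``gradient_scope``) -- an exponential decay is the simplest
  monotone form, with flat (A = 0) profiles as a special case;
* a polymorphic site carries one alternative allele on a random nonempty
  proper subset of strains (site-wise, infinite-sites style -- the analysis
  consumes only site marginals, so no genealogy is simulated);
* purifying selection is emulated by rejecting a fraction ``s`` of candidate
  nonsynonymous polymorphisms and redrawing them as synonymous where the
  codon allows;
* each strain loses each intron independently with ``intron_loss_prob``
  (intron presence/absence polymorphism; lost introns appear as gap runs).

Everything is deterministic under (config, seed), and the ground truth
(per-site mutation probabilities, realized sites, presence matrix) is kept
for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .gene_models import GeneModel, Intron, IntronSiteSet, save_gene_model
from .msa_variants import StrainAlignment, write_vcf
from .selection_analysis import MotifAnnotation, translate_codon

logger = logging.getLogger("intronsnp")

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate_population",
            "truth_profile", "DEFAULT_INTRON_ATTRS"]

# the default gene emulates a pooled organellar exon set (cox1/cob scale):
# twenty mostly short exons (3000 exonic nt) separated by nineteen introns,
# about two-thirds of them mobile, so most exonic positions lie within the
# 70-nt analysis window of some boundary and both mobility strata are
# populated
DEFAULT_EXON_LENGTHS = (225, 120, 150, 90, 195, 135, 210, 105, 150, 120,
                        240, 90, 165, 150, 135, 210, 120, 150, 105, 135)
DEFAULT_INTRON_LENGTHS = (60,) * 19
_MOBILE = (True, True, True, False, True, True, True, False, True, True,
           False, False, True, True, True, False, True, True, False)
DEFAULT_INTRON_ATTRS = tuple(
    ("I" if k % 2 == 0 else "II",
     _MOBILE[k],
     ("endonuclease",) if _MOBILE[k] else ("none",))
    for k in range(19)
)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one simulated population.

    ``mu0`` is the baseline per-site polymorphism probability; at a
    gradient-bearing boundary the rate is ``mu0 * (1 + A)`` and decays with
    length scale ``lam`` (nt). The defaults place ~200 SNPs over 3000 exonic
    nt across 50 strains with a 4-fold boundary enrichment confined to
    mobile-intron boundaries.
    """

    n_strains: int = 50
    exon_lengths: tuple = DEFAULT_EXON_LENGTHS
    intron_lengths: tuple = DEFAULT_INTRON_LENGTHS
    intron_attrs: tuple = DEFAULT_INTRON_ATTRS  # (group, mobile, orf) per intron
    mu0: float = 0.05
    gradient_amplitude: float = 3.0  # A
    gradient_decay: float = 15.0  # lam, nt
    gradient_scope: str = "mobile_only"  # mobile_only | all_introns | none
    nonsyn_suppression: float = 0.0  # s
    intron_loss_prob: float = 0.05
    code_table: int = 3
    gene_id: str = "simgene"
    seed: int = 0

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(
                "need len(intron_lengths) == len(exon_lengths) - 1"
            )
        if len(self.intron_attrs) != len(self.intron_lengths):
            raise ValueError("intron_attrs must match intron_lengths")
        for p, name in [(self.mu0, "mu0"),
                        (self.nonsyn_suppression, "nonsyn_suppression"),
                        (self.intron_loss_prob, "intron_loss_prob")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.gradient_decay <= 0:
            raise ValueError("gradient_decay must be positive")
        if self.gradient_amplitude < 0:
            raise ValueError("gradient_amplitude must be >= 0")
        if self.gradient_scope not in {"mobile_only", "all_introns", "none"}:
            raise ValueError(f"bad gradient_scope {self.gradient_scope!r}")
        if self.n_strains < 3:
            raise ValueError("need at least 3 strains")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intron_attrs"] = [
            [g, m, list(o)] for g, m, o in self.intron_attrs
        ]
        return d


@dataclass
class SimTruth:
    """Generator ground truth for recovery tests."""

    config: SimConfig
    mu: np.ndarray  # per exonic spliced position, true polymorphism prob
    realized_ref_positions: list  # reference positions that became sites
    skipped_positions: list  # candidates dropped (no synonymous option)
    presence: np.ndarray  # (n_strains, n_introns) bool intron presence
    spliced_to_ref: np.ndarray  # reference position of each spliced offset

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "mu": [round(float(v), 10) for v in self.mu],
            "realized_ref_positions": list(map(int, self.realized_ref_positions)),
            "skipped_positions": list(map(int, self.skipped_positions)),
            "presence": self.presence.astype(int).tolist(),
        }


@dataclass
class SimResult:
    """Everything one simulation produced, with plain-text writers."""

    config: SimConfig
    model: GeneModel
    alignment: StrainAlignment
    genotypes: dict  # ref_pos -> allele index per strain row
    motifs: MotifAnnotation
    truth: SimTruth

    def strain_models(self):
        """Per-strain gene models reflecting intron presence/absence.

        Strains are modeled on the shared reference coordinate system; a
        strain that lost an intron still shares the exon content, so all
        models carry the same junction offsets except for lost introns.
        """
        out = {"REF": self.model}
        exon_lengths = self.model.exon_lengths
        for si, sid in enumerate(self.alignment.strain_ids[1:]):
            present = self.truth.presence[si]
            if present.all():
                out[sid] = self.model
                continue
            # rebuild on the strain's own (ungapped) coordinates: exon
            # lengths are shared, lost introns merge their flanking exons
            exons = []
            introns = []
            pos = 0
            cur_start = 0
            for k, el in enumerate(exon_lengths):
                pos += el
                if k == len(exon_lengths) - 1:
                    exons.append((cur_start, pos))
                elif present[k]:
                    exons.append((cur_start, pos))
                    intr = self.model.introns[k]
                    il = intr.end - intr.start
                    introns.append(dataclasses.replace(
                        intr, start=pos, end=pos + il))
                    pos += il
                    cur_start = pos
                # lost intron: keep accumulating into the merged exon
            out[sid] = GeneModel(
                gene_id=self.model.gene_id,
                strand="+",
                exons=tuple(exons),
                introns=tuple(introns),
                code_table=self.model.code_table,
            )
        return out

    def write(self, outdir) -> dict:
        """Write FASTA, GFF3 + attribute TSV, JSON model, VCF, BED, truth."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {k: os.path.join(outdir, v) for k, v in {
            "fasta": "alignment.fasta",
            "gff3": "gene_model.gff3",
            "attrs": "intron_attrs.tsv",
            "model_json": "gene_model.json",
            "vcf": "variants.vcf",
            "bed": "motifs.bed",
            "truth": "truth.json",
        }.items()}
        with open(paths["fasta"], "w") as fh:
            for sid, row in zip(self.alignment.strain_ids,
                                self.alignment.rows):
                fh.write(f">{sid}\n{row}\n")
        self._write_gff3(paths["gff3"])
        self._write_attr_tsv(paths["attrs"])
        save_gene_model(self.model, paths["model_json"])
        sites = self._vcf_sites()
        write_vcf(
            sites, paths["vcf"], contig=self.config.gene_id,
            strain_ids=self.alignment.strain_ids,
            genotypes=self.genotypes,
            contig_length=self.model.span[1],
        )
        self.motifs.to_bed(paths["bed"], chrom=self.config.gene_id)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth.to_dict(), fh)
            fh.write("\n")
        return paths

    def _write_gff3(self, path) -> None:
        gid = self.config.gene_id
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"# seed={self.config.seed}\n")
            lo, hi = self.model.span
            fh.write(
                f"{gid}\tintronsnp\tgene\t{lo + 1}\t{hi}\t.\t+\t.\tID={gid}\n"
            )
            for k, (s, e) in enumerate(self.model.exons, 1):
                fh.write(
                    f"{gid}\tintronsnp\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={gid}-e{k};Parent={gid}\n"
                )
            for intr in self.model.introns:
                fh.write(
                    f"{gid}\tintronsnp\tintron\t{intr.start + 1}\t{intr.end}"
                    f"\t.\t+\t.\tID={intr.intron_id};Parent={gid}\n"
                )

    def _write_attr_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("intron_id\tgroup\tmobile\torf_content\n")
            for intr in self.model.introns:
                mob = {True: "true", False: "false", None: "unknown"}[intr.mobile]
                fh.write(
                    f"{intr.intron_id}\t{intr.group}\t{mob}\t"
                    f"{','.join(sorted(intr.orf_content))}\n"
                )

    def _vcf_sites(self):
        from .msa_variants import find_polymorphic_sites

        return find_polymorphic_sites(self.alignment, min_allele_count=1,
                                      max_missing_frac=1.0)


def _build_model(config: SimConfig) -> GeneModel:
    exons, introns = [], []
    pos = 0
    for k, el in enumerate(config.exon_lengths):
        exons.append((pos, pos + el))
        pos += el
        if k < len(config.intron_lengths):
            il = config.intron_lengths[k]
            group, mobile, orf = config.intron_attrs[k]
            introns.append(Intron(
                intron_id=f"{config.gene_id}-i{k + 1}",
                start=pos, end=pos + il,
                group=group, mobile=mobile,
                orf_content=frozenset(orf),
            ))
            pos += il
    return GeneModel(
        gene_id=config.gene_id, strand="+",
        exons=tuple(exons), introns=tuple(introns),
        code_table=config.code_table,
        complete_cds=sum(config.exon_lengths) % 3 == 0,
    )


def _scope_junctions(model: GeneModel, scope: str):
    offs = model.junction_offsets()
    if scope == "all_introns":
        return list(offs)
    if scope == "mobile_only":
        return [j for j, i in zip(offs, model.introns) if i.mobile]
    return []


def _nearest_scope_distance(n: int, junctions) -> np.ndarray:
    """Distance of each spliced position to its nearest listed junction."""
    if not junctions:
        return np.full(n, np.inf)
    pos = np.arange(n)
    junc = np.asarray(junctions)
    d = np.where(
        pos[:, None] < junc[None, :],
        junc[None, :] - pos[:, None],
        pos[:, None] - junc[None, :] + 1,
    )
    return d.min(axis=1)


def _random_cds(rng: np.random.Generator, n_codons: int,
                code_table: int) -> str:
    """Random CDS without internal stop codons."""
    bases = "ACGT"
    codons = ["".join(bases[i] for i in rng.integers(0, 4, 3))
              for _ in range(n_codons)]
    out = []
    for c in codons:
        while translate_codon(c, code_table) == "*":
            c = "".join(bases[i] for i in rng.integers(0, 4, 3))
        out.append(c)
    return "".join(out)


def site_rate(config: SimConfig, d) -> np.ndarray:
    """Per-site polymorphism probability at scope-distance d (vectorized)."""
    d = np.asarray(d, dtype=float)
    rate = config.mu0 * (
        1.0 + config.gradient_amplitude
        * np.exp(-(d - 1.0) / config.gradient_decay)
    )
    rate = np.where(np.isfinite(d), rate, config.mu0)
    return np.minimum(rate, 0.95)


def simulate_population(config: SimConfig) -> SimResult:
    """Draw one population under the configured gradient model."""
    rng = np.random.default_rng(config.seed)
    model = _build_model(config)
    L_spliced = model.spliced_length
    n = config.n_strains

    cds = _random_cds(rng, L_spliced // 3, config.code_table) \
        if L_spliced % 3 == 0 else "".join(
            "ACGT"[i] for i in rng.integers(0, 4, L_spliced))
    # reference coordinates of each spliced offset
    spliced_to_ref = np.concatenate(
        [np.arange(s, e) for s, e in model.exons]
    )
    gene_len = model.span[1]
    ancestral = np.full(gene_len, b"N", dtype="S1")
    ancestral[spliced_to_ref] = np.frombuffer(cds.encode(), dtype="S1")
    for intr in model.introns:
        il = intr.end - intr.start
        ancestral[intr.start:intr.end] = np.frombuffer(
            "".join("ACGT"[i] for i in rng.integers(0, 4, il)).encode(),
            dtype="S1",
        )

    scope_j = _scope_junctions(model, config.gradient_scope)
    d_scope = _nearest_scope_distance(L_spliced, scope_j)
    mu = site_rate(config, d_scope)
    polymorphic = rng.random(L_spliced) < mu

    bases = "ACGT"
    realized, skipped = [], []
    site_alts = {}  # spliced pos -> alt base
    for sp in np.nonzero(polymorphic)[0]:
        ref_base = cds[sp]
        ci, off = divmod(sp, 3)
        codon = cds[3 * ci: 3 * ci + 3]
        ref_aa = translate_codon(codon, config.code_table)
        alts = [b for b in bases if b != ref_base]
        alt = alts[rng.integers(0, 3)]
        alt_aa = translate_codon(
            codon[:off] + alt + codon[off + 1:], config.code_table
        )
        if alt_aa != ref_aa and rng.random() < config.nonsyn_suppression:
            syn = [
                b for b in alts
                if translate_codon(codon[:off] + b + codon[off + 1:],
                                   config.code_table) == ref_aa
            ]
            if not syn:
                skipped.append(int(spliced_to_ref[sp]))
                continue
            alt = syn[int(rng.integers(0, len(syn)))]
        site_alts[int(sp)] = alt
        realized.append(int(spliced_to_ref[sp]))

    # strain rows: REF + n strains
    mat = np.tile(ancestral, (n + 1, 1))
    genotypes = {}
    for sp, alt in site_alts.items():
        k = int(rng.integers(1, n))  # nonempty proper subset size
        carriers = rng.choice(n, size=k, replace=False)
        rp = int(spliced_to_ref[sp])
        mat[carriers + 1, rp] = alt.encode()
        gts = [0] * (n + 1)
        for c in carriers:
            gts[c + 1] = 1
        genotypes[rp] = gts

    presence = rng.random((n, len(model.introns))) >= config.intron_loss_prob
    for si in range(n):
        for k, intr in enumerate(model.introns):
            if not presence[si, k]:
                mat[si + 1, intr.start:intr.end] = b"-"

    strain_ids = ("REF",) + tuple(f"S{j:03d}" for j in range(1, n + 1))
    rows = tuple(mat[i].tobytes().decode() for i in range(n + 1))
    alignment = StrainAlignment(
        strain_ids=strain_ids, rows=rows, reference_id="REF"
    )

    motifs = _default_motifs(model)
    truth = SimTruth(
        config=config, mu=mu,
        realized_ref_positions=sorted(realized),
        skipped_positions=sorted(skipped),
        presence=presence, spliced_to_ref=spliced_to_ref,
    )
    if skipped:
        logger.info("simulate_population: %d candidate site(s) skipped "
                    "(no synonymous option)", len(skipped))
    return SimResult(
        config=config, model=model, alignment=alignment,
        genotypes=genotypes, motifs=motifs, truth=truth,
    )


def _default_motifs(model: GeneModel, flank: int = 12,
                    pairing: int = 6) -> MotifAnnotation:
    """Motif fixture: homing-site halves flanking each mobile junction.

    A homing endonuclease recognition site spans the insertion point; on the
    intron-containing reference it is split into the terminal ``flank`` nt of
    the upstream exon and the initial ``flank`` nt of the downstream exon.
    The terminal ``pairing`` nt of each upstream exon stand in for the
    intron-exon base-pairing positions of the splicing structure.
    """
    rows = []
    for k, intr in enumerate(model.introns):
        up = model.exons[k]
        down = model.exons[k + 1]
        if intr.mobile:
            rows.append((max(up[0], intr.start - flank), intr.start,
                         f"{intr.intron_id}_HEG_5p", "cleavage_recognition"))
            rows.append((intr.end, min(down[1], intr.end + flank),
                         f"{intr.intron_id}_HEG_3p", "cleavage_recognition"))
        rows.append((max(up[0], intr.start - pairing), intr.start,
                     f"{intr.intron_id}_IBS", "exon_intron_pairing"))
    return MotifAnnotation(intervals=tuple(rows))


def truth_profile(truth: SimTruth, window: int = 70) -> np.ndarray:
    """Analytic expected density at distances 1..window.

    This is the expected per-site polymorphism probability at distance d
    from a gradient-bearing boundary (for ``gradient_scope="none"`` or
    A = 0 it is flat at mu0), directly comparable to the measured
    ``exon_ends``-convention density over the gradient stratum.
    """
    c = truth.config
    d = np.arange(1, window + 1, dtype=float)
    if c.gradient_scope == "none":
        return np.full(window, c.mu0)
    return site_rate(c, d)
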