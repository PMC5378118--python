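import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from intronsnp.boundary_distance import annotate_distances
from intronsnp.gene_models import GeneModel, Intron
from intronsnp.msa_variants import PolymorphicSite
from intronsnp.selection_analysis import (
    MotifAnnotation,
    classify_all,
    classify_site,
    expected_nonsyn_fraction,
    fisher_2x2,
    motif_overlap,
    near_far_selection_test,
    pairing_overlap,
    spliced_reference,
    translate_codon,
)

BASES = "ACGT"


def site_at(pos, ref, alts, distance=None, context="exonic",
            sel_class="not_applicable"):
    s = PolymorphicSite(ref_pos=pos, ref_allele=ref,
                        alt_alleles=tuple(alts), allele_counts={},
                        n_called=0, context=context)
    s.distance = distance
    s.sel_class = sel_class
    return s


def single_exon_model(cds, code_table=3):
    return GeneModel(gene_id="g", exons=((0, len(cds)),),
                     code_table=code_table, complete_cds=True)


def enumeration_fisher_p(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestClassification:
    def test_cac_cat_synonymous_under_mito_code(self):
        """CAC<->CAT is a silent histidine change under transl_table 3."""
        cds = "ATGCACTTA"  # ATG CAC TTA
        model = single_exon_model(cds, code_table=3)
        s = site_at(5, "C", ["T"])  # CAC -> CAT, His in both
        assert classify_site(s, model, cds) == "synonymous"

    def test_ata_differs_between_tables(self):
        cds = "ATAGCTGCT"
        s = site_at(2, "A", ["G"])  # ATA -> ATG
        m3 = single_exon_model(cds, code_table=3)
        assert classify_site(s, m3, cds) == "synonymous"  # Met -> Met
        m1 = single_exon_model(cds, code_table=1)
        s1 = site_at(2, "A", ["G"])
        assert classify_site(s1, m1, cds) == "nonsynonymous"  # Ile -> Met

    def test_mixed_requires_both_kinds(self):
        cds = "TTAGCTGCT"  # TTA Leu under table 1
        m = single_exon_model(cds, code_table=1)
        # TTA->TTG silent (Leu), TTA->TCA nonsyn (Ser): site at pos 2 alts G
        s = site_at(2, "A", ["G"])
        assert classify_site(s, m, cds) == "synonymous"
        s2 = site_at(1, "T", ["C"])
        assert classify_site(s2, m, cds) == "nonsynonymous"
        # pos 2 with alts {G (silent), T (TTT Phe, nonsyn)} -> mixed
        s3 = site_at(2, "A", ["G", "T"])
        assert classify_site(s3, m, cds) == "mixed"

    def test_stop_gain_is_nonsynonymous(self):
        cds = "TACGCTGCT"  # TAC Tyr; TAC->TAA stop under table 1
        m = single_exon_model(cds, code_table=1)
        s = site_at(2, "C", ["A"])
        assert classify_site(s, m, cds) == "nonsynonymous"

    def test_intronic_site_not_applicable(self, three_exon_model):
        s = site_at(50, "A", ["G"], context="intronic")
        assert classify_site(s, three_exon_model, "ATG" * 37) == \
            "not_applicable"

    def test_reference_mismatch_rejected(self):
        cds = "ATGGCTGCT"
        m = single_exon_model(cds, code_table=1)
        s = site_at(0, "C", ["G"])  # CDS has A at 0
        with pytest.raises(ValueError):
            classify_site(s, m, cds)

    def test_codon_spanning_exon_junction(self):
        """Codons split by an intron are classified in spliced space."""
        # exons (0,4) and (10,15): spliced CDS length 9; the junction falls
        # inside codon 2 (spliced positions 3,4,5 = ref 3, 10, 11)
        gm = GeneModel(gene_id="g", exons=((0, 4), (10, 15)), code_table=1)
        ref = "ATGG" + "NNNNNN" + "CTGCT"
        cds = spliced_reference(gm, ref)
        assert cds == "ATGGCTGCT"
        s = site_at(10, "C", ["G"])  # spliced pos 4: GCT -> GGT Ala->Gly
        assert classify_site(s, gm, cds) == "nonsynonymous"

    def test_strand_consistency(self):
        """Reverse-complementing the locus leaves classes unchanged."""
        from Bio.Seq import Seq

        rng = np.random.default_rng(4)
        cds = "ATG" + "".join(
            rng.choice(list("ACGT"), 1)[0] for _ in range(30)
        )
        cds = cds[:33 - 33 % 3]
        m_fwd = single_exon_model(cds, code_table=3)
        L = len(cds)
        rc = str(Seq(cds).reverse_complement())
        m_rev = GeneModel(gene_id="g", strand="-", exons=((0, L),),
                          code_table=3, complete_cds=True)
        comp = dict(zip("ACGT", "TGCA"))
        for pos in range(L):
            ref = cds[pos]
            alts = [b for b in BASES if b != ref][:2]
            s_f = site_at(pos, ref, alts)
            c_f = classify_site(s_f, m_fwd, cds)
            # mirrored site on the reverse-complemented locus
            s_r = site_at(L - 1 - pos, comp[ref], [comp[a] for a in alts])
            c_r = classify_site(s_r, m_rev, cds)
            assert c_f == c_r

    def test_tables_1_and_3_differ_only_at_divergent_codons(self):
        """Exhaustive 64 x 9 check of where the two codes disagree."""
        divergent = {
            c for c in map("".join, itertools.product(BASES, repeat=3))
            if translate_codon(c, 1) != translate_codon(c, 3)
        }
        assert divergent == {"CTT", "CTC", "CTA", "CTG", "ATA", "TGA"}
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            for off in range(3):
                for b in BASES:
                    if b == codon[off]:
                        continue
                    mut = codon[:off] + b + codon[off + 1:]
                    syn1 = translate_codon(codon, 1) == translate_codon(mut, 1)
                    syn3 = translate_codon(codon, 3) == translate_codon(mut, 3)
                    if syn1 != syn3:
                        assert codon in divergent or mut in divergent


class TestFisher:
    def test_reference_cox1_near_far_table(self):
        res = fisher_2x2([[15, 29], [5, 14]])
        assert round(res.p_two_sided, 2) == 0.77

    def test_identical_rows_give_p_one(self):
        res = fisher_2x2([[5, 5], [5, 5]])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        res = fisher_2x2([[0, 0], [3, 4]])
        assert res.degenerate and res.p_two_sided == 1.0
        assert math.isnan(res.odds_ratio)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(55)
        for _ in range(100):
            t = rng.integers(0, 16, size=(2, 2))
            if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
                continue
            res = fisher_2x2(t)
            assert res.p_two_sided == pytest.approx(
                enumeration_fisher_p(t.tolist()), abs=1e-9)

    def test_invariance_under_transpose_and_swaps(self):
        rng = np.random.default_rng(66)
        for _ in range(20):
            t = rng.integers(1, 12, size=(2, 2))
            p = fisher_2x2(t).p_two_sided
            assert fisher_2x2(t.T).p_two_sided == pytest.approx(p)
            swapped = t[::-1, ::-1]
            assert fisher_2x2(swapped).p_two_sided == pytest.approx(p)


class TestNearFar:
    def test_reference_fraction_example(self):
        """44 near sites with 15 nonsyn, 19 far with 5 -> 34% vs 26%."""
        sites = (
            [site_at(i, "A", ["G"], distance=5, sel_class="nonsynonymous")
             for i in range(15)]
            + [site_at(100 + i, "A", ["G"], distance=10,
                       sel_class="synonymous") for i in range(29)]
            + [site_at(200 + i, "A", ["G"], distance=40,
                       sel_class="nonsynonymous") for i in range(5)]
            + [site_at(300 + i, "A", ["G"], distance=50,
                       sel_class="synonymous") for i in range(14)]
        )
        res = near_far_selection_test(sites, cutoff=20, window=70)
        assert res.table == ((15, 29), (5, 14))
        assert res.near_fraction == pytest.approx(15 / 44)
        assert res.far_fraction == pytest.approx(5 / 19)
        assert round(res.near_fraction, 2) == 0.34
        assert round(res.far_fraction, 2) == 0.26
        assert round(res.p_two_sided, 2) == 0.77

    def test_all_synonymous(self):
        sites = [site_at(i, "A", ["G"], distance=d, sel_class="synonymous")
                 for i, d in enumerate([5, 10, 30, 40])]
        res = near_far_selection_test(sites)
        assert res.near_fraction == 0 and res.far_fraction == 0
        assert res.p_two_sided == 1.0

    def test_mixed_counts_as_nonsynonymous(self):
        sites = [site_at(0, "A", ["G", "T"], distance=3, sel_class="mixed"),
                 site_at(1, "A", ["G"], distance=30,
                         sel_class="synonymous")]
        res = near_far_selection_test(sites)
        assert res.table[0] == (1, 0)

    def test_type_one_error_calibrated(self):
        """Equal near/far nonsyn rates: rejection frequency <= 0.08."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_runs = 200
        for _ in range(n_runs):
            sites = []
            for i in range(60):
                d = int(rng.integers(1, 71))
                cls = ("nonsynonymous" if rng.random() < 0.3
                       else "synonymous")
                sites.append(site_at(i, "A", ["G"], distance=d,
                                     sel_class=cls))
            res = near_far_selection_test(sites)
            if not res.degenerate and res.p_two_sided < 0.05:
                rejections += 1
        assert rejections / n_runs <= 0.08


class TestExpectedNonsyn:
    def test_single_codon_tta_matches_enumeration(self):
        """TTA under the mito code: list its nine mutants by hand."""
        aa = translate_codon("TTA", 3)
        mutants = []
        for off in range(3):
            for b in BASES:
                if b != "TTA"[off]:
                    mutants.append("TTA"[:off] + b + "TTA"[off + 1:])
        expected = sum(
            translate_codon(m, 3) != aa for m in mutants
        ) / 9
        assert expected_nonsyn_fraction("TTA", 3) == pytest.approx(expected)

    def test_codon_shuffle_invariance(self):
        rng = np.random.default_rng(10)
        cds = "".join(rng.choice(list(BASES), 60))
        codons = [cds[i:i + 3] for i in range(0, 60, 3)]
        rng.shuffle(codons)
        shuffled = "".join(codons)
        assert expected_nonsyn_fraction(cds, 3) == pytest.approx(
            expected_nonsyn_fraction(shuffled, 3))

    def test_matches_brute_force_positionwise(self):
        rng = np.random.default_rng(20)
        cds = "".join(rng.choice(list(BASES), 30))
        n = nn = 0
        for pos in range(30):
            ci, off = divmod(pos, 3)
            codon = cds[3 * ci: 3 * ci + 3]
            for b in BASES:
                if b == cds[pos]:
                    continue
                mut = codon[:off] + b + codon[off + 1:]
                n += 1
                nn += translate_codon(mut, 3) != translate_codon(codon, 3)
        frac = expected_nonsyn_fraction(cds, 3)
        assert 0.0 <= frac <= 1.0
        assert frac == pytest.approx(nn / n)

    def test_roughly_two_thirds_for_random_cds(self):
        rng = np.random.default_rng(30)
        cds = "".join(rng.choice(list(BASES), 900))
        assert 0.6 < expected_nonsyn_fraction(cds, 3) < 0.85


class TestMotifs:
    def test_tally_mirroring_near_boundary_overlap(self):
        """24 near-boundary SNPs, 17 inside motifs -> fraction ~ 0.708."""
        motifs = MotifAnnotation(intervals=(
            (0, 17, "m1", "cleavage_recognition"),
        ))
        sites = [site_at(i, "A", ["G"], distance=5) for i in range(24)]
        n_near, n_over, frac = motif_overlap(sites, motifs)
        assert (n_near, n_over) == (24, 17)
        assert frac == pytest.approx(17 / 24)
        assert round(frac, 2) == 0.71

    def test_empty_motifs(self):
        sites = [site_at(1, "A", ["G"], distance=2)]
        assert motif_overlap(sites, MotifAnnotation(intervals=()))[1] == 0

    def test_full_coverage(self):
        motifs = MotifAnnotation(intervals=(
            (0, 1000, "all", "cleavage_recognition"),))
        sites = [site_at(i, "A", ["G"], distance=3) for i in range(5)]
        assert motif_overlap(sites, motifs)[2] == 1.0

    def test_no_near_sites_flagged(self):
        motifs = MotifAnnotation(intervals=())
        n_near, n_over, frac = motif_overlap([], motifs)
        assert n_near == 0 and frac is None

    def test_pairing_overlap_is_set_intersection(self):
        rng = np.random.default_rng(40)
        for _ in range(20):
            pos = rng.integers(0, 200, size=15)
            ivs = []
            for _ in range(4):
                s = int(rng.integers(0, 190))
                ivs.append((s, s + int(rng.integers(1, 10)), "p",
                            "exon_intron_pairing"))
            motifs = MotifAnnotation(intervals=tuple(ivs))
            sites = [site_at(int(p), "A", ["G"]) for p in pos]
            got = {s.ref_pos for s in pairing_overlap(sites, motifs)}
            brute = {
                int(p) for p in pos
                if any(s <= p < e for s, e, _, k in ivs)
            }
            assert got == brute

    def test_pairing_disjoint_and_singleton(self):
        motifs = MotifAnnotation(intervals=(
            (10, 16, "p1", "exon_intron_pairing"),))
        assert pairing_overlap([site_at(50, "A", ["G"])], motifs) == []
        hit = site_at(12, "A", ["G"], sel_class="synonymous")
        out = pairing_overlap([hit], motifs)
        assert out == [hit] and out[0].sel_class == "synonymous"

    def test_bed_round_trip(self, tmp_path):
        motifs = MotifAnnotation(intervals=(
            (5, 25, "m1", "cleavage_recognition"),
            (30, 36, "p1", "exon_intron_pairing"),
        ))
        p = tmp_path / "motifs.bed"
        motifs.to_bed(p)
        again = MotifAnnotation.from_bed(p)
        assert again == motifs
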