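"""Model/Results interface over the boundary-gradient analysis.

:class:`BoundaryGradientModel` bundles the data (polymorphic sites, gene
models, intron site sets) with the analysis settings; :meth:`fit` runs the
full pipeline -- distance annotation, density profiles, smoothing, stratified
Kendall trend tests and (when a reference CDS is available) the
synonymous/nonsynonymous selection battery -- and returns a
:class:`BoundaryGradientResults` carrying estimates, p-values and a
``summary()`` table.

Construct from data with :meth:`from_alignment` (multi-strain aligned FASTA),
:meth:`from_vcf` (variant table against a reference), or
:meth:`from_simulation` (a :class:`~intronsnp.synthetic_data.SimConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boundary_distance, density_stats, msa_variants, selection_analysis
from .gene_models import GeneModel, IntronSiteSet

__all__ = ["BoundaryGradientModel", "BoundaryGradientResults"]


class BoundaryGradientModel:
    """SNP-density-vs-boundary-distance analysis of one or more genes.

    Parameters
    ----------
    sites
        Polymorphic sites (annotated or not; distances are recomputed).
    gene_models
        One :class:`GeneModel` or a list.
    intron_sites
        Optional :class:`IntronSiteSet` (or dict keyed by gene id); defaults
        to reference mode.
    window
        Profile window W in nt (default 70).
    convention
        Denominator convention, ``exon_ends`` (per-site) or ``exons``.
    strata
        Stratification keys for the trend tests, drawn from
        {"all", "gene", "mobility", "group", "side"}.
    reference_seqs
        Optional {gene_id: ungapped reference sequence} enabling the
        selection analysis.
    near_cutoff
        Near-boundary cutoff in nt for the selection contingency test.
    """

    def __init__(self, sites, gene_models, intron_sites=None, *,
                 window: int = density_stats.DEFAULT_WINDOW,
                 convention: str = "exon_ends",
                 strata=("all", "mobility"),
                 reference_seqs: dict | None = None,
                 motifs=None,
                 near_cutoff: int = selection_analysis.NEAR_CUTOFF,
                 min_trend_points: int = 10):
        if isinstance(gene_models, GeneModel):
            gene_models = [gene_models]
        self.sites = list(sites)
        self.gene_models = list(gene_models)
        self.intron_sites = intron_sites
        self.window = window
        self.convention = convention
        self.strata = tuple(strata)
        self.reference_seqs = reference_seqs or {}
        self.motifs = motifs
        self.near_cutoff = near_cutoff
        self.min_trend_points = min_trend_points

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_alignment(cls, fasta_path, gene_model, reference_id: str,
                       *, min_allele_count: int = 1,
                       max_missing_frac: float = 0.2,
                       exclude_strains=(), **kw) -> "BoundaryGradientModel":
        aln = msa_variants.read_alignment(fasta_path, reference_id)
        if exclude_strains:
            aln = aln.without_strains(exclude_strains)
        sites = msa_variants.find_polymorphic_sites(
            aln, min_allele_count=min_allele_count,
            max_missing_frac=max_missing_frac,
        )
        ref_seq = aln.reference_row.replace("-", "")
        kw.setdefault("reference_seqs", {gene_model.gene_id: ref_seq})
        return cls(sites, gene_model, **kw)

    @classmethod
    def from_vcf(cls, vcf_path, gene_model, *, reference_seq=None,
                 **kw) -> "BoundaryGradientModel":
        sites = msa_variants.variants_from_table(
            vcf_path, region=gene_model.span
        )
        if reference_seq is not None:
            kw.setdefault("reference_seqs",
                          {gene_model.gene_id: reference_seq})
        return cls(sites, gene_model, **kw)

    @classmethod
    def from_simulation(cls, config, *, union_mode: bool = False,
                        **kw) -> "BoundaryGradientModel":
        from .synthetic_data import simulate_population

        sim = simulate_population(config)
        sites = msa_variants.find_polymorphic_sites(
            sim.alignment, min_allele_count=1, max_missing_frac=1.0
        )
        intron_sites = None
        if union_mode:
            intron_sites = boundary_distance.union_insertion_sites(
                sim.strain_models().values()
            )
        ref_seq = sim.alignment.reference_row.replace("-", "")
        kw.setdefault("reference_seqs", {sim.model.gene_id: ref_seq})
        kw.setdefault("motifs", sim.motifs)
        m = cls(sites, sim.model, intron_sites, **kw)
        m.simulation = sim
        return m

    # -- fitting ------------------------------------------------------------

    def _site_sets(self) -> dict:
        out = {}
        for gm in self.gene_models:
            if isinstance(self.intron_sites, dict):
                ss = self.intron_sites.get(gm.gene_id)
            elif isinstance(self.intron_sites, IntronSiteSet):
                ss = self.intron_sites
            else:
                ss = None
            out[gm.gene_id] = ss or IntronSiteSet.from_model(gm)
        return out

    def fit(self) -> "BoundaryGradientResults":
        site_sets = self._site_sets()
        by_gene = {gm.gene_id: gm for gm in self.gene_models}
        if len(by_gene) == 1:
            only = next(iter(by_gene))
            for s in self.sites:
                if s.gene_id is None:
                    s.gene_id = only
        for gid, gm in by_gene.items():
            gene_sites = [s for s in self.sites
                          if (s.gene_id or gid) == gid]
            boundary_distance.annotate_distances(
                gene_sites, gm, site_sets[gid]
            )
            ref = self.reference_seqs.get(gid)
            if ref is not None:
                selection_analysis.classify_all(gene_sites, gm, ref)

        trends, profiles = density_stats.stratified_trends(
            self.sites, self.gene_models, site_sets,
            strata_spec=self.strata, window=self.window,
            convention=self.convention, min_points=self.min_trend_points,
        )
        curves = {}
        for prof in profiles:
            try:
                curves[prof.stratum] = density_stats.smooth(prof)
            except ValueError:
                pass

        selection = None
        expected_fraction = {}
        motif_result = None
        pairing_sites = None
        if self.reference_seqs:
            classed = [s for s in self.sites
                       if s.sel_class != "not_applicable"
                       and s.distance is not None]
            if classed:
                selection = selection_analysis.near_far_selection_test(
                    classed, cutoff=self.near_cutoff, window=self.window
                )
            for gid, ref in self.reference_seqs.items():
                gm = by_gene.get(gid)
                if gm is not None:
                    cds = selection_analysis.spliced_reference(gm, ref)
                    expected_fraction[gid] = (
                        selection_analysis.expected_nonsyn_fraction(
                            cds, gm.code_table
                        )
                    )
        if self.motifs is not None:
            motif_result = selection_analysis.motif_overlap(
                [s for s in self.sites if s.distance is not None],
                self.motifs, near_cutoff=self.near_cutoff,
            )
            pairing_sites = selection_analysis.pairing_overlap(
                self.sites, self.motifs
            )

        return BoundaryGradientResults(
            model=self,
            trends=trends,
            profiles={p.stratum: p for p in profiles},
            curves=curves,
            selection=selection,
            expected_nonsyn=expected_fraction,
            motif_overlap=motif_result,
            pairing_sites=pairing_sites,
        )


@dataclass
class BoundaryGradientResults:
    """Fitted boundary-gradient analysis.

    ``trends`` holds one :class:`~intronsnp.density_stats.TrendTestResult`
    per stratum (including the combined "all" stratum); ``profiles`` and
    ``curves`` are keyed by stratum label. ``selection`` is the near/far
    Fisher contingency result when a reference CDS allowed classification.
    """

    model: BoundaryGradientModel
    trends: list
    profiles: dict
    curves: dict
    selection: object = None
    expected_nonsyn: dict = field(default_factory=dict)
    motif_overlap: tuple | None = None
    pairing_sites: list | None = None

    def trend(self, stratum: str = "all"):
        for t in self.trends:
            if t.stratum == stratum:
                return t
        raise KeyError(f"no trend result for stratum {stratum!r}")

    @property
    def n_sites(self) -> int:
        return sum(1 for s in self.model.sites if s.context == "exonic")

    def trends_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stratum": t.stratum, "tau": t.tau, "p": t.p_two_sided,
                 "n_points": t.n_points, "degenerate": t.degenerate}
                for t in self.trends
            ]
        )

    def profile_frame(self) -> pd.DataFrame:
        return pd.concat(
            [p.to_frame() for p in self.profiles.values()],
            ignore_index=True,
        )

    def summary(self) -> str:
        lines = []
        w = self.model.window
        lines.append("Boundary SNP-density gradient analysis")
        lines.append("=" * 54)
        genes = ", ".join(g.gene_id for g in self.model.gene_models)
        lines.append(f"genes: {genes}   window: {w} nt   "
                     f"denominator: {self.model.convention}")
        lines.append(f"exonic SNPs: {self.n_sites}")
        lines.append("")
        lines.append(f"{'stratum':<20}{'tau':>8}{'p':>10}{'n':>6}")
        lines.append("-" * 44)
        for t in self.trends:
            flag = " (degenerate)" if t.degenerate else ""
            lines.append(
                f"{t.stratum:<20}{t.tau:>8.3f}{t.p_two_sided:>10.4f}"
                f"{t.n_points:>6d}{flag}"
            )
        if self.selection is not None:
            s = self.selection
            lines.append("")
            lines.append(
                f"near/far nonsynonymous Fisher test "
                f"(cutoff {self.model.near_cutoff} nt):"
            )
            (a, b), (c, d) = s.table
            nf = f"{s.near_fraction:.0%}" if s.near_fraction is not None else "NA"
            ff = f"{s.far_fraction:.0%}" if s.far_fraction is not None else "NA"
            lines.append(
                f"  near {a}/{a + b} nonsyn ({nf}), "
                f"far {c}/{c + d} nonsyn ({ff}), "
                f"OR={s.odds_ratio:.2f}, p={s.p_two_sided:.3f}"
            )
        for gid, frac in self.expected_nonsyn.items():
            lines.append(
                f"  mutational nonsyn expectation ({gid}): {frac:.3f}"
            )
        if self.motif_overlap is not None:
            n_near, n_over, frac = self.motif_overlap
            fs = f"{frac:.0%}" if frac is not None else "NA"
            lines.append(
                f"  cleavage-motif overlap: {n_over}/{n_near} near-boundary "
                f"SNPs in recognition motifs ({fs})"
            )
        if self.pairing_sites is not None:
            lines.append(
                f"  SNPs on intron-exon pairing positions: "
                f"{len(self.pairing_sites)}"
            )
        return "\n".join(lines)

    def plot_profile(self, stratum: str = "all", ax=None):
        """Density dots plus the smoothed curve (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.profiles[stratum]
        ok = prof.defined()
        ax.plot(prof.distances[ok], prof.density[ok], ".", color="0.5",
                label="per-distance density")
        curve = self.curves.get(stratum)
        if curve is not None:
            ax.plot(curve.x, curve.y, "-", label="10-nt smoothed")
        ax.set_xlabel("distance from intron-exon boundary (nt)")
        ax.set_ylabel("SNPs per site")
        ax.set_title(f"stratum: {stratum}")
        ax.legend()
        return ax
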