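"""Distances from exonic positions to the nearest intron-exon boundary.

Distance is counted in exonic nucleotides, 1-based from the junction: the
exonic base immediately adjacent to a boundary is at distance 1. Because
intron junctions are points in spliced-CDS space, the nearest boundary of an
exonic position is simply the nearest junction offset, and adding
population-wide insertion sites (union mode) can only shrink distances --
the conservativeness property the reference-only convention relies on.

Ties between the two flanking boundaries of an exon break toward the 5' exon
end (the boundary at the exon terminus upstream of an intron), which is
deterministic and recorded per site.

Also here: mapping mock boundaries into an intronless ortholog through a
two-sequence alignment (the selection-constraint control), and the
first-variant-distance helper used for cleavage-site scans such as the HO
site of the yeast MAT locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gene_models import (
    FIVE_PRIME,
    THREE_PRIME,
    GeneModel,
    IntronSiteSet,
    genomic_to_spliced,
)

logger = logging.getLogger("intronsnp")

__all__ = [
    "nearest_boundary",
    "union_insertion_sites",
    "annotate_distances",
    "CrossSpeciesMap",
    "map_mock_boundaries",
    "first_variant_distance",
    "distance_array",
]


def _nearest_from_spliced(spliced: int, sites: IntronSiteSet):
    """(distance, side, junction, intron) for a spliced offset, or None."""
    best = None
    for j, intr in zip(sites.junctions, sites.attrs):
        if spliced < j:
            cand = (j - spliced, FIVE_PRIME, j, intr)
        else:
            cand = (spliced - j + 1, THREE_PRIME, j, intr)
        if (
            best is None
            or cand[0] < best[0]
            # tie: prefer the 5' exon end boundary
            or (cand[0] == best[0] and cand[1] == FIVE_PRIME
                and best[1] != FIVE_PRIME)
        ):
            best = cand
    return best


def nearest_boundary(site_pos: int, model: GeneModel,
                     sites: IntronSiteSet | None = None):
    """Distance/side/boundary_id of the boundary nearest to an exonic position.

    Returns ``(distance, side, boundary_id, intron)`` or ``None`` when the
    site set is empty (intronless gene in reference mode). Raises
    ``ValueError`` for intronic positions.
    """
    if sites is None:
        sites = IntronSiteSet.from_model(model)
    spliced = genomic_to_spliced(model, site_pos)
    if spliced is None:
        raise ValueError(
            f"position {site_pos} is intronic in {model.gene_id}"
        )
    if not sites.junctions:
        return None
    d, side, j, intr = _nearest_from_spliced(spliced, sites)
    name = intr.intron_id if intr is not None else f"ins{j}"
    return d, side, f"{name}:{side}", intr


def distance_array(model: GeneModel, sites: IntronSiteSet | None = None):
    """Vectorized nearest-boundary assignment for every spliced position.

    Returns ``(dist, side5, junc_idx)`` arrays of length ``spliced_length``:
    distance, whether the nearest boundary is a 5' exon end, and the index of
    the nearest junction within ``sites.junctions`` -- the workhorse behind
    denominator counting and simulation.
    """
    if sites is None:
        sites = IntronSiteSet.from_model(model)
    n = model.spliced_length
    if not sites.junctions:
        return None
    pos = np.arange(n)
    junc = np.asarray(sites.junctions)
    # candidate distance to each junction; side depends on relative order
    d = np.where(
        pos[:, None] < junc[None, :],
        junc[None, :] - pos[:, None],          # 5' exon end side
        pos[:, None] - junc[None, :] + 1,      # 3' exon start side
    )
    is5 = pos[:, None] < junc[None, :]
    # tie-break toward the 5' side: subtract epsilon-rank by preferring 5'
    order = np.lexsort((~is5, d), axis=1)  # sort by d, then 5' first
    best = order[:, 0]
    rows = np.arange(n)
    return d[rows, best], is5[rows, best], best


def annotate_distances(sites_list, model: GeneModel,
                       intron_sites: IntronSiteSet | None = None):
    """Fill context/distance/side and nearest-boundary attributes in place.

    Positions outside the gene span get context ``flank``; intronic positions
    ``intronic`` (distance stays None for both). Returns the list.
    """
    if intron_sites is None:
        intron_sites = IntronSiteSet.from_model(model)
    lo, hi = model.span
    for s in sites_list:
        s.gene_id = model.gene_id
        if not lo <= s.ref_pos < hi:
            s.context = "flank"
            continue
        spliced = genomic_to_spliced(model, s.ref_pos)
        if spliced is None:
            s.context = "intronic"
            continue
        s.context = "exonic"
        if not intron_sites.junctions:
            continue
        d, side, j, intr = _nearest_from_spliced(spliced, intron_sites)
        s.distance = int(d)
        s.side = side
        name = intr.intron_id if intr is not None else f"ins{j}"
        s.boundary_id = f"{name}:{side}"
        s.nearest_mobile = intr.mobile if intr is not None else None
        s.nearest_group = intr.group if intr is not None else None
    return sites_list


def union_insertion_sites(models) -> IntronSiteSet:
    """All intron insertion junctions observed across strain gene models.

    Each strain's model is on its own coordinates but shares the exon content
    of the gene, so junctions are compared as spliced offsets (which is where
    an insertion site lives). The union is the conservative site set: a
    position inferred exon-internal from the reference alone may in fact sit
    next to an intron present elsewhere in the population.
    """
    models = list(models)
    if not models:
        raise ValueError("no models given")
    gene_ids = {m.gene_id.split("|")[0] for m in models}
    if len(gene_ids) > 1:
        raise ValueError(f"models describe different genes: {sorted(gene_ids)}")
    lengths = {m.spliced_length for m in models}
    if len(lengths) > 1:
        raise ValueError(
            "models differ in spliced length; not one coordinate system"
        )
    merged: dict = {}
    for m in models:
        for j, intr in zip(m.junction_offsets(), m.introns):
            if j not in merged or merged[j] is None:
                merged[j] = intr
    ref = IntronSiteSet.from_model(models[0])
    return ref.with_extra_sites(merged.keys(), attrs=merged)


# ---------------------------------------------------------------------------
# Mock boundaries through a cross-species alignment


@dataclass(frozen=True)
class CrossSpeciesMap:
    """Pairwise gapped alignment of orthologous coding regions."""

    donor_id: str
    target_id: str
    donor_row: str
    target_row: str

    def __post_init__(self):
        if len(self.donor_row) != len(self.target_row):
            raise ValueError("alignment rows have unequal lengths")
        if not self.donor_row or not self.target_row:
            raise ValueError("empty alignment row")

    @classmethod
    def from_fasta(cls, path, donor_id: str, target_id: str):
        from Bio import SeqIO

        rows = {r.id: str(r.seq).upper().replace("U", "T")
                for r in SeqIO.parse(str(path), "fasta")}
        try:
            return cls(donor_id, target_id, rows[donor_id], rows[target_id])
        except KeyError as exc:
            raise LookupError(f"row {exc} not in {path}") from exc


def map_mock_boundaries(cmap: CrossSpeciesMap, donor_model: GeneModel):
    """Carry donor intron junctions to target coordinates column-wise.

    The donor row covers the donor's coding region, so junctions are the
    donor model's spliced offsets. Each junction is walked to its alignment
    column and the target coordinate is the count of non-gap target
    characters preceding that column; a junction landing where the target is
    gapped resolves to the nearest following non-gap target position. The
    result serves as insertion sites for an intronless target model.
    """
    donor = np.frombuffer(cmap.donor_row.encode(), dtype="S1")
    target = np.frombuffer(cmap.target_row.encode(), dtype="S1")
    donor_nongap = donor != b"-"
    target_nongap = target != b"-"
    n_donor = int(donor_nongap.sum())
    n_target = int(target_nongap.sum())
    # column index of each donor coordinate
    donor_cols = np.nonzero(donor_nongap)[0]
    target_before = np.cumsum(target_nongap) - target_nongap  # count before col

    out = []
    for j in donor_model.junction_offsets():
        if not 0 < j <= n_donor:
            raise ValueError(
                f"junction {j} outside aligned donor region (0, {n_donor}]"
            )
        # column of the first donor base after the junction; a junction at
        # the donor's very end maps past the last donor column
        col = donor_cols[j] if j < n_donor else len(donor)
        if col >= len(target):
            t = n_target
        else:
            t = int(target_before[col])
            if not target_nongap[col]:
                # target gapped at the junction column: next non-gap position
                pass  # target_before already names the following position
        out.append(int(t))
    return out


def first_variant_distance(anchor_pos: int, sites, direction: str):
    """Distance to the closest site strictly down/upstream of an anchor.

    Mirrors scans like "how far from the endonuclease cutting site is the
    first SNP"; returns None when no site lies in that direction.
    """
    if direction not in {"downstream", "upstream"}:
        raise ValueError(f"bad direction {direction!r}")
    if direction == "downstream":
        ds = [s.ref_pos - anchor_pos for s in sites if s.ref_pos > anchor_pos]
    else:
        ds = [anchor_pos - s.ref_pos for s in sites if s.ref_pos < anchor_pos]
    return min(ds) if ds else None
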