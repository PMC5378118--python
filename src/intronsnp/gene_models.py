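"""Gene architecture: exons, introns, and coordinate arithmetic.

A :class:`GeneModel` describes one protein-coding gene as an ordered list of
exon intervals separated by introns, on a 0-based half-open reference
coordinate system. Self-splicing (group I / group II) introns carry the
attributes that matter for the downstream analysis: their group, whether they
are experimentally mobile (i.e. able to home into intron-free alleles via an
intron-encoded endonuclease), and which ORF activities they encode.

Three coordinate spaces are in play:

* **reference** -- positions on the genomic sequence the gene model is
  annotated on (introns included);
* **spliced** -- positions on the mature CDS (introns excised), the frame in
  which codons exist;
* **alignment column** -- handled in :mod:`intronsnp.msa_variants`.

Intron insertion *junctions* are naturally points in spliced space (an intron
occupies zero spliced nucleotides). :class:`IntronSiteSet` therefore stores
junctions as spliced offsets, which unifies reference-annotated introns,
population-wide ("union") insertion sites and in-silico mock boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "Intron",
    "GeneModel",
    "IntronSiteSet",
    "GeneStructureError",
    "load_gene_model",
    "save_gene_model",
    "genomic_to_spliced",
    "spliced_to_genomic",
    "boundary_positions",
    "Boundary",
]

FIVE_PRIME = "5prime"  # exon terminus upstream of an intron (donor-adjacent)
THREE_PRIME = "3prime"  # exon terminus downstream of an intron

VALID_GROUPS = frozenset({"I", "II", "spliceosomal", "unknown"})
VALID_ORF = frozenset({"endonuclease", "maturase", "RT", "none"})


class GeneStructureError(ValueError):
    """An exon/intron layout violates a structural invariant."""


@dataclass(frozen=True)
class Intron:
    """One intron: reference interval plus mobility/group attributes.

    ``mobile`` is ``True``/``False`` when known experimentally and ``None``
    when unknown; group and mobility are independent (both group I and group
    II introns can be mobile).
    """

    intron_id: str
    start: int
    end: int
    group: str = "unknown"
    mobile: bool | None = None
    orf_content: frozenset = frozenset({"none"})

    def __post_init__(self):
        if self.end <= self.start:
            raise GeneStructureError(
                f"intron {self.intron_id} has non-positive length "
                f"({self.start}, {self.end})"
            )
        if self.group not in VALID_GROUPS:
            raise GeneStructureError(
                f"intron {self.intron_id}: unknown group {self.group!r}"
            )
        bad = set(self.orf_content) - VALID_ORF
        if bad:
            raise GeneStructureError(
                f"intron {self.intron_id}: unknown ORF content {sorted(bad)}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one gene on reference coordinates.

    Parameters
    ----------
    exons
        Sorted, non-overlapping 0-based half-open intervals. Intron k occupies
        exactly the gap between exon k and exon k+1.
    code_table
        NCBI genetic code id used for synonymous/nonsynonymous classification
        (3 = yeast mitochondrial, 1 = standard).
    cds_phase
        Offset of the first exonic base within its codon (0, 1 or 2).
    complete_cds
        When True the spliced length must be divisible by 3.
    """

    gene_id: str
    strand: str = "+"
    exons: tuple = ()
    introns: tuple = ()
    code_table: int = 1
    cds_phase: int = 0
    complete_cds: bool = False

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise GeneStructureError(f"bad strand {self.strand!r}")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise GeneStructureError(f"gene {self.gene_id}: no exons")
        for s, e in exons:
            if e <= s:
                raise GeneStructureError(
                    f"gene {self.gene_id}: empty exon ({s}, {e})"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise GeneStructureError(
                    f"gene {self.gene_id}: exons ({s1}, {e1}) and ({s2}, {e2}) "
                    "overlap or are unsorted"
                )
            if s2 == e1:
                raise GeneStructureError(
                    f"gene {self.gene_id}: exons ({s1}, {e1}) and ({s2}, {e2}) "
                    "abut with no intervening intron"
                )
        introns = tuple(self.introns) or tuple(
            Intron(intron_id=f"{self.gene_id}-i{k + 1}", start=e1, end=s2)
            for k, ((_, e1), (s2, _)) in enumerate(zip(exons, exons[1:]))
        )
        object.__setattr__(self, "introns", introns)
        if len(introns) != len(exons) - 1:
            raise GeneStructureError(
                f"gene {self.gene_id}: {len(exons)} exons require "
                f"{len(exons) - 1} introns, got {len(introns)}"
            )
        for k, intr in enumerate(introns):
            gap = (exons[k][1], exons[k + 1][0])
            if intr.interval != gap:
                raise GeneStructureError(
                    f"gene {self.gene_id}: intron {intr.intron_id} interval "
                    f"{intr.interval} does not fill exon gap {gap}"
                )
        if self.complete_cds and self.spliced_length % 3 != 0:
            raise GeneStructureError(
                f"gene {self.gene_id}: complete CDS but spliced length "
                f"{self.spliced_length} is not a multiple of 3"
            )
        if self.cds_phase not in {0, 1, 2}:
            raise GeneStructureError(f"bad cds_phase {self.cds_phase}")

    # -- derived geometry ---------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_lengths(self) -> tuple:
        return tuple(e - s for s, e in self.exons)

    def junction_offsets(self) -> tuple:
        """Spliced offsets of the intron junctions (one per intron)."""
        offs, acc = [], 0
        for length in self.exon_lengths[:-1]:
            acc += length
            offs.append(acc)
        return tuple(offs)

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def reverse_complemented(self, seq_length: int) -> "GeneModel":
        """The same model on the reverse-complemented reference.

        Used to put minus-strand genes into gene orientation: position p maps
        to ``seq_length - 1 - p`` and intervals flip accordingly.
        """
        flip = lambda s, e: (seq_length - e, seq_length - s)  # noqa: E731
        exons = tuple(sorted(flip(s, e) for s, e in self.exons))
        introns = tuple(
            replace(i, start=seq_length - i.end, end=seq_length - i.start)
            for i in reversed(self.introns)
        )
        return replace(
            self,
            strand="+" if self.strand == "-" else "-",
            exons=exons,
            introns=introns,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "introns": [
                {
                    "intron_id": i.intron_id,
                    "start": i.start,
                    "end": i.end,
                    "group": i.group,
                    "mobile": i.mobile,
                    "orf_content": sorted(i.orf_content),
                }
                for i in self.introns
            ],
            "code_table": self.code_table,
            "cds_phase": self.cds_phase,
            "complete_cds": self.complete_cds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        introns = tuple(
            Intron(
                intron_id=i["intron_id"],
                start=i["start"],
                end=i["end"],
                group=i.get("group", "unknown"),
                mobile=i.get("mobile"),
                orf_content=frozenset(i.get("orf_content", ["none"])),
            )
            for i in d.get("introns", [])
        )
        return cls(
            gene_id=d["gene_id"],
            strand=d.get("strand", "+"),
            exons=tuple(tuple(e) for e in d["exons"]),
            introns=introns,
            code_table=d.get("code_table", 1),
            cds_phase=d.get("cds_phase", 0),
            complete_cds=d.get("complete_cds", False),
        )


# ---------------------------------------------------------------------------
# Intron site sets


@dataclass(frozen=True)
class IntronSiteSet:
    """The set of intron insertion junctions used for distance assignment.

    ``reference`` mode uses exactly the junctions of the reference
    :class:`GeneModel`. ``union`` mode adds every insertion site observed
    anywhere in the population (junctions where any strain carries an intron),
    which is the conservative choice: it can only shrink distances.

    Junctions are spliced-CDS offsets, with per-junction attribute lookup
    (the representative :class:`Intron`, or ``None`` for a site with no
    annotated intron, e.g. a mock boundary).
    """

    mode: str  # "reference" | "union"
    junctions: tuple  # sorted spliced offsets
    attrs: tuple = ()  # parallel tuple of Intron | None

    def __post_init__(self):
        if self.mode not in {"reference", "union"}:
            raise ValueError(f"bad IntronSiteSet mode {self.mode!r}")
        junc = tuple(sorted(int(j) for j in self.junctions))
        if len(set(junc)) != len(junc):
            raise ValueError("duplicate junction offsets")
        attrs = tuple(self.attrs) if self.attrs else (None,) * len(junc)
        if len(attrs) != len(junc):
            raise ValueError("attrs must parallel junctions")
        if tuple(self.junctions) != junc:
            order = sorted(range(len(self.junctions)),
                           key=lambda k: self.junctions[k])
            attrs = tuple(attrs[k] for k in order)
        object.__setattr__(self, "junctions", junc)
        object.__setattr__(self, "attrs", attrs)

    @classmethod
    def from_model(cls, model: GeneModel) -> "IntronSiteSet":
        return cls(
            mode="reference",
            junctions=model.junction_offsets(),
            attrs=tuple(model.introns),
        )

    def intron_at(self, junction: int):
        try:
            return self.attrs[self.junctions.index(junction)]
        except ValueError:
            raise KeyError(f"no junction at spliced offset {junction}")

    def with_extra_sites(self, extra, attrs=None) -> "IntronSiteSet":
        """Union-mode copy including additional spliced junction offsets."""
        attrs = dict(attrs or {})
        merged = {j: a for j, a in zip(self.junctions, self.attrs)}
        for j in extra:
            j = int(j)
            if j not in merged or merged[j] is None:
                merged[j] = attrs.get(j)
        junc = tuple(sorted(merged))
        return IntronSiteSet(
            mode="union",
            junctions=junc,
            attrs=tuple(merged[j] for j in junc),
        )


@dataclass(frozen=True)
class Boundary:
    """One intron-exon boundary in reference coordinates."""

    pos: int  # reference coordinate of the junction point
    side: str  # FIVE_PRIME (end of upstream exon) | THREE_PRIME
    junction: int  # spliced offset of the junction
    intron: Intron | None = None

    @property
    def boundary_id(self) -> str:
        name = self.intron.intron_id if self.intron else f"ins{self.junction}"
        return f"{name}:{self.side}"


def boundary_positions(model: GeneModel, sites: IntronSiteSet | None = None):
    """All intron-exon boundaries of ``model`` under a site set.

    Each junction yields two boundaries: the 5' exon end (the last base of
    the upstream exon abuts it) and the 3' exon start. For a reference intron
    the two sit at ``intron.start`` and ``intron.end``; for a population
    insertion site inside a reference exon both sit at the insertion point.
    The gene's own start and stop are not boundaries, so an intronless model
    in reference mode yields an empty list.
    """
    if sites is None:
        sites = IntronSiteSet.from_model(model)
    ref_junc = {
        j: intr for j, intr in zip(model.junction_offsets(), model.introns)
    }
    out = []
    for j, attr in zip(sites.junctions, sites.attrs):
        if j in ref_junc:
            intr = ref_junc[j]
            out.append(Boundary(intr.start, FIVE_PRIME, j, intr))
            out.append(Boundary(intr.end, THREE_PRIME, j, intr))
        else:
            pos = spliced_to_genomic(model, j)
            out.append(Boundary(pos, FIVE_PRIME, j, attr))
            out.append(Boundary(pos, THREE_PRIME, j, attr))
    return out


# ---------------------------------------------------------------------------
# Coordinate arithmetic


def genomic_to_spliced(model: GeneModel, pos: int):
    """Spliced-CDS offset of reference position ``pos``, or None if intronic.

    On the minus strand the spliced coordinate runs right-to-left (the caller
    is responsible for complementing bases before translation). Raises
    ``ValueError`` outside the gene span.
    """
    lo, hi = model.span
    if not lo <= pos < hi:
        raise ValueError(
            f"position {pos} outside gene span [{lo}, {hi}) of {model.gene_id}"
        )
    acc = 0
    for s, e in model.exons:
        if s <= pos < e:
            fwd = acc + (pos - s)
            if model.strand == "-":
                return model.spliced_length - 1 - fwd
            return fwd
        acc += e - s
    return None


def spliced_to_genomic(model: GeneModel, offset: int) -> int:
    """Reference position of spliced offset; inverse of genomic_to_spliced.

    ``offset == spliced_length`` is accepted on the plus strand and returns
    the end of the last exon (the 3' junction point convention).
    """
    n = model.spliced_length
    if model.strand == "-":
        if not 0 <= offset < n:
            raise ValueError(f"spliced offset {offset} outside [0, {n})")
        offset = n - 1 - offset
    if not 0 <= offset <= n:
        raise ValueError(f"spliced offset {offset} outside [0, {n}]")
    acc = 0
    for s, e in model.exons:
        if offset < acc + (e - s):
            return s + (offset - acc)
        acc += e - s
    return model.exons[-1][1]


# ---------------------------------------------------------------------------
# Loading / saving


def save_gene_model(model: GeneModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def _parse_bool(s: str):
    s = s.strip().lower()
    if s in {"true", "yes", "1", "mobile"}:
        return True
    if s in {"false", "no", "0", "immobile"}:
        return False
    return None


def _read_attr_tsv(path) -> dict:
    """Sidecar intron attributes: intron_id, group, mobile, orf_content."""
    attrs = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None and parts[0] == "intron_id":
                header = parts
                continue
            d = dict(zip(["intron_id", "group", "mobile", "orf_content"], parts))
            orf = d.get("orf_content", "none") or "none"
            attrs[d["intron_id"]] = {
                "group": d.get("group", "unknown") or "unknown",
                "mobile": _parse_bool(d.get("mobile", "")),
                "orf_content": frozenset(orf.split(",")),
            }
    return attrs


def _gff_attr(field9: str) -> dict:
    out = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_gene_model(annotation_path, gene_id: str, *, attr_path=None,
                    code_table: int = 1, complete_cds: bool = False,
                    cds_phase: int = 0) -> GeneModel:
    """Load a gene model from GFF3, a BED-like exon TSV, or JSON.

    GFF3: exon rows (columns 4/5 1-based inclusive) whose ``Parent`` or
    ``gene_id`` attribute matches ``gene_id``; intron rows are optional and
    otherwise inferred as the gaps between consecutive exons. A sidecar TSV
    (``attr_path``) supplies per-intron group/mobility/ORF attributes keyed by
    intron_id; inferred introns are named ``<gene_id>-i<k>`` (1-based).

    BED-like TSV dialect: lines ``gene_id<TAB>start<TAB>end`` (0-based
    half-open exon intervals), selected when the file does not look like GFF3.
    JSON files produced by :func:`save_gene_model` round-trip exactly.
    """
    path = str(annotation_path)
    with open(path) as fh:
        head = fh.read(1)
    if head == "{":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("gene_id") != gene_id:
            raise LookupError(f"gene {gene_id!r} not in {path}")
        return GeneModel.from_dict(d)

    exons, explicit_introns, strand = [], [], "+"
    is_gff = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##gff-version"):
                    is_gff = True
                continue
            parts = line.split("\t")
            if len(parts) >= 9:
                is_gff = True
                ftype = parts[2].lower()
                attrs = _gff_attr(parts[8])
                owner = attrs.get("Parent", attrs.get("gene_id", attrs.get("ID")))
                if owner != gene_id:
                    continue
                try:
                    start, end = int(parts[3]) - 1, int(parts[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                strand = parts[6] if parts[6] in "+-" else "+"
                if ftype == "exon":
                    exons.append((start, end))
                elif ftype == "intron":
                    explicit_introns.append(
                        (start, end, attrs.get("ID", ""))
                    )
            elif len(parts) >= 3 and not is_gff:
                if parts[0] != gene_id:
                    continue
                try:
                    exons.append((int(parts[1]), int(parts[2])))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
    if not exons:
        raise LookupError(f"gene {gene_id!r} not found in {path}")
    exons.sort()

    attr_map = _read_attr_tsv(attr_path) if attr_path else {}
    introns = []
    gaps = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    explicit = {(s, e): iid for s, e, iid in explicit_introns}
    for k, (gs, ge) in enumerate(gaps):
        iid = explicit.get((gs, ge)) or f"{gene_id}-i{k + 1}"
        a = attr_map.get(iid, {})
        introns.append(
            Intron(
                intron_id=iid,
                start=gs,
                end=ge,
                group=a.get("group", "unknown"),
                mobile=a.get("mobile"),
                orf_content=a.get("orf_content", frozenset({"none"})),
            )
        )
    return GeneModel(
        gene_id=gene_id,
        strand=strand,
        exons=tuple(exons),
        introns=tuple(introns),
        code_table=code_table,
        cds_phase=cds_phase,
        complete_cds=complete_cds,
    )
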