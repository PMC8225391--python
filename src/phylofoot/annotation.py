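"""Gene models, regulatory compartments and motif-hit assignment.

Each protein-coding gene is reduced to the compartments used by the
footprinting features: an upstream interval (the intergenic stretch 5' of
the transcription start, bounded by the nearer of a neighboring gene body
or a configured maximum distance), introns (gaps in the exon union across
transcripts), exons, and a downstream interval defined symmetrically to the
upstream one.  Hits are assigned to every (gene, compartment) they fall in;
exonic and downstream assignments are annotated but flagged non-scoring.

All coordinates are 0-based half-open internally; GFF3 input (1-based
inclusive) is converted on load.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

from .motifs import RawHit

SCORING_COMPARTMENTS = ("upstream", "intron")


class AnnotationError(ValueError):
    """Raised for inconsistent FASTA/GFF3 input."""


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and disjoint."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass
class GeneModel:
    """A protein-coding gene with derived regulatory compartments.

    ``tss`` is the 0-based coordinate of the transcription start base (the
    most 5' transcript start over all transcripts).  ``span`` covers the
    exon union; ``introns`` are its internal gaps.  ``upstream_interval``
    and ``downstream_interval`` are filled by
    :func:`compute_upstream_intervals`.
    """

    gene_id: str
    species: str
    sequence_id: str
    strand: str
    tss: int
    span: tuple[int, int]
    exons: list[tuple[int, int]]
    upstream_interval: tuple[int, int] | None = None
    downstream_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.exons = merge_intervals(list(self.exons))
        s, e = self.span
        if not self.exons or self.exons[0][0] < s or self.exons[-1][1] > e:
            raise AnnotationError(f"gene {self.gene_id}: exons outside span")

    @property
    def introns(self) -> list[tuple[int, int]]:
        gaps = []
        for (_, prev_end), (nxt_start, _) in zip(self.exons, self.exons[1:]):
            if nxt_start > prev_end:
                gaps.append((prev_end, nxt_start))
        return gaps


@dataclass(frozen=True)
class AssignedMatch:
    """A motif hit labeled with a gene, compartment and TSS distance.

    ``distance_to_tss`` is the bp gap between the hit and the TSS for
    upstream/downstream hits (>= 0), and the transcription-direction offset
    of the hit's 5'-most base from the TSS for gene-body hits (>= 0,
    increasing downstream).  ``scoring`` marks upstream/intron assignments,
    the only compartments consulted by the ranking features.
    """

    hit: RawHit
    gene_id: str
    species: str
    compartment: str
    distance_to_tss: int

    @property
    def scoring(self) -> bool:
        return self.compartment in SCORING_COMPARTMENTS


def load_genome(fasta: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of sequence id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}


def _is_coding(feature: gffutils.Feature) -> bool:
    for key in ("gene_biotype", "biotype", "gene_type"):
        if key in feature.attributes:
            return feature.attributes[key][0] == "protein_coding"
    return True


def load_annotation(
    fasta: str | Path, gff: str | Path, species: str
) -> list[GeneModel]:
    """Load protein-coding gene models from a FASTA + GFF3 pair.

    Multi-transcript genes use the exon union to define introns and the most
    5' transcript start as the TSS.  Upstream/downstream intervals are not
    set here; see :func:`compute_upstream_intervals`.
    """
    seq_lengths = {
        rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
    }
    try:
        db = gffutils.create_db(
            str(gff),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        raise AnnotationError(f"{species}: zero features parsed from {gff}") from None
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in seq_lengths:
            raise AnnotationError(
                f"{species}: GFF feature {gene.id} references unknown sequence "
                f"{gene.seqid!r}"
            )
        if not _is_coding(gene):
            continue
        exons = [
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        ]
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        exons = merge_intervals(exons)
        span = (exons[0][0], exons[-1][1])
        if transcripts:
            if gene.strand == "+":
                tss = min(t.start for t in transcripts) - 1
            else:
                tss = max(t.end for t in transcripts) - 1
        else:
            tss = span[0] if gene.strand == "+" else span[1] - 1
        genes.append(
            GeneModel(
                gene_id=gene.id,
                species=species,
                sequence_id=gene.seqid,
                strand=gene.strand,
                tss=tss,
                span=span,
                exons=exons,
            )
        )
    if not genes:
        raise AnnotationError(f"{species}: zero protein-coding genes parsed from {gff}")
    return genes


def compute_upstream_intervals(
    genes: list[GeneModel],
    seq_lengths: dict[str, int],
    max_distance: int | None = None,
) -> list[GeneModel]:
    """Fill upstream (and downstream) intergenic intervals in place.

    The upstream interval extends 5' from the TSS to the nearer of the
    closest gene-body boundary and ``max_distance`` (``None`` = the full
    intergenic stretch), clipped to the sequence.  Two divergently
    transcribed genes both receive the full shared intergenic interval.
    Empty intervals (a neighbor abutting or covering the TSS) are allowed
    and stored as ``None``.
    """
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.sequence_id, []).append(g)

    for seq_id, group in by_seq.items():
        length = seq_lengths[seq_id]
        order = sorted(range(len(group)), key=lambda i: group[i].span[0])
        starts = [group[i].span[0] for i in order]
        ends = [group[i].span[1] for i in order]
        prefix_max_end = []
        running = 0
        for e in ends:
            running = max(running, e)
            prefix_max_end.append(running)
        suffix_min_start = [0] * len(order)
        running = length
        for k in range(len(order) - 1, -1, -1):
            running = min(running, starts[k])
            suffix_min_start[k] = running

        def left_boundary(pos: int) -> int:
            """Largest gene-body end at or left of pos (genes starting < pos)."""
            j = bisect.bisect_left(starts, pos)
            if j == 0:
                return 0
            return min(prefix_max_end[j - 1], pos)

        def right_boundary(pos: int) -> int:
            """Smallest gene-body start at or right of pos; pos if covered."""
            j = bisect.bisect_left(starts, pos)
            if j > 0 and prefix_max_end[j - 1] > pos:
                return pos  # a gene body covers pos
            if j == len(starts):
                return length
            return suffix_min_start[j]

        for g in group:
            if g.strand == "+":
                up_b, up_a = g.tss, left_boundary(g.tss)
                dn_a = g.span[1]
                dn_b = right_boundary(dn_a)
                if max_distance is not None:
                    up_a = max(up_a, up_b - max_distance)
                    dn_b = min(dn_b, dn_a + max_distance)
            else:
                up_a = g.span[1]
                up_b = right_boundary(up_a)
                dn_b = g.span[0]
                dn_a = left_boundary(dn_b)
                if max_distance is not None:
                    up_b = min(up_b, up_a + max_distance)
                    dn_a = max(dn_a, dn_b - max_distance)
            up_a, up_b = max(0, up_a), min(length, up_b)
            dn_a, dn_b = max(0, dn_a), min(length, dn_b)
            g.upstream_interval = (up_a, up_b) if up_b > up_a else None
            g.downstream_interval = (dn_a, dn_b) if dn_b > dn_a else None
    return genes


def assign_hits(
    hits: list[RawHit], genes: list[GeneModel]
) -> list[AssignedMatch]:
    """Label each hit with every (gene, compartment) it falls in.

    Per gene the precedence is exon > intron inside the gene body (a hit
    overlapping any exon base is exonic); upstream/downstream require full
    containment in the respective interval.  A hit in the shared intergenic
    region of a divergent pair is upstream of both genes.  Hits outside all
    compartments are dropped.
    """
    body_trees: dict[str, IntervalTree] = {}
    up_trees: dict[str, IntervalTree] = {}
    dn_trees: dict[str, IntervalTree] = {}
    for g in genes:
        body_trees.setdefault(g.sequence_id, IntervalTree()).addi(
            g.span[0], g.span[1], g
        )
        if g.upstream_interval is not None:
            a, b = g.upstream_interval
            up_trees.setdefault(g.sequence_id, IntervalTree()).addi(a, b, g)
        if g.downstream_interval is not None:
            a, b = g.downstream_interval
            dn_trees.setdefault(g.sequence_id, IntervalTree()).addi(a, b, g)

    out: list[AssignedMatch] = []
    for hit in hits:
        assigned: list[tuple[GeneModel, str]] = []
        for iv in body_trees.get(hit.sequence_id, IntervalTree()).overlap(
            hit.start, hit.end
        ):
            g: GeneModel = iv.data
            if any(hit.start < e and hit.end > s for s, e in g.exons):
                assigned.append((g, "exon"))
            elif any(s <= hit.start and hit.end <= e for s, e in g.introns):
                assigned.append((g, "intron"))
            else:
                assigned.append((g, "exon"))  # boundary-straddling fallback
        for tree, label in ((up_trees, "upstream"), (dn_trees, "downstream")):
            for iv in tree.get(hit.sequence_id, IntervalTree()).overlap(
                hit.start, hit.end
            ):
                g = iv.data
                if iv.begin <= hit.start and hit.end <= iv.end:
                    assigned.append((g, label))
        for g, compartment in assigned:
            out.append(
                AssignedMatch(
                    hit=hit,
                    gene_id=g.gene_id,
                    species=g.species,
                    compartment=compartment,
                    distance_to_tss=_tss_distance(hit, g, compartment),
                )
            )
    out.sort(key=lambda m: (m.hit.start, m.gene_id, m.compartment))
    return out


def _tss_distance(hit: RawHit, gene: GeneModel, compartment: str) -> int:
    if compartment == "upstream":
        if gene.strand == "+":
            return max(0, gene.tss - hit.end)
        return max(0, hit.start - gene.tss - 1)
    if compartment == "downstream":
        if gene.strand == "+":
            return max(0, hit.start - gene.span[1])
        return max(0, gene.span[0] - hit.end)
    # gene body: transcription-direction offset of the hit's 5'-most base
    if gene.strand == "+":
        return max(0, hit.start - gene.tss)
    return max(0, gene.tss - (hit.end - 1))
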