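"""Gene models, compartment intervals and hit assignment."""

import numpy as np
import pytest

import phylofoot as pf
from phylofoot.annotation import AnnotationError
from phylofoot.motifs import RawHit


def hit(seq_id, start, end, strand="+"):
    return RawHit(seq_id, start, end, strand, 5.0, 1e-5, "A" * (end - start))


def gene(gid, strand, span, exons, seq_id="chr1", species="sp"):
    tss = span[0] if strand == "+" else span[1] - 1
    return pf.GeneModel(
        gene_id=gid,
        species=species,
        sequence_id=seq_id,
        strand=strand,
        tss=tss,
        span=span,
        exons=exons,
    )


GFF_TWO_TRANSCRIPTS = """\
##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=gA;gene_biotype=protein_coding
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=gA.t2;Parent=gA
chr1\tsrc\texon\t101\t250\t.\t+\t.\tID=gA.t2.e1;Parent=gA.t2
chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=gA.t2.e2;Parent=gA.t2
"""


class TestLoadAnnotation:
    def write_pair(self, tmp_path, gff_text, seq_len=600):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + "A" * seq_len + "\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(gff_text)
        return fasta, gff

    def test_transcript_union_defines_introns(self, tmp_path):
        fasta, gff = self.write_pair(tmp_path, GFF_TWO_TRANSCRIPTS)
        (g,) = pf.load_annotation(fasta, gff, "sp")
        assert g.exons == [(100, 250), (300, 400)]
        assert g.introns == [(250, 300)]
        assert g.tss == 100 and g.span == (100, 400)

    def test_missing_sequence_raises(self, tmp_path):
        text = GFF_TWO_TRANSCRIPTS.replace("chr1", "chrX")
        fasta, gff = self.write_pair(tmp_path, text)
        with pytest.raises(AnnotationError, match="chrX"):
            pf.load_annotation(fasta, gff, "sp")

    def test_zero_genes_raises(self, tmp_path):
        fasta, gff = self.write_pair(tmp_path, "##gff-version 3\n")
        with pytest.raises(AnnotationError, match="zero"):
            pf.load_annotation(fasta, gff, "sp")

    def test_noncoding_genes_skipped(self, tmp_path):
        text = GFF_TWO_TRANSCRIPTS + (
            "chr1\tsrc\tgene\t450\t500\t.\t+\t.\tID=nc1;gene_biotype=ncRNA\n"
        )
        fasta, gff = self.write_pair(tmp_path, text)
        genes = pf.load_annotation(fasta, gff, "sp")
        assert [g.gene_id for g in genes] == ["gA"]


class TestGeneModel:
    def test_single_exon_no_introns(self):
        g = gene("g1", "+", (100, 200), [(100, 200)])
        assert g.introns == []

    def test_two_exon_intron(self):
        g = gene("g1", "+", (100, 400), [(100, 200), (300, 400)])
        assert g.introns == [(200, 300)]


class TestUpstreamIntervals:
    def test_full_intergenic(self):
        up = gene("up", "+", (200, 400), [(200, 400)])
        g = gene("g", "+", (1000, 1200), [(1000, 1200)])
        pf.compute_upstream_intervals([up, g], {"chr1": 2000}, None)
        assert g.upstream_interval == (400, 1000)

    def test_max_distance_clips(self):
        up = gene("up", "+", (200, 400), [(200, 400)])
        g = gene("g", "+", (1000, 1200), [(1000, 1200)])
        pf.compute_upstream_intervals([up, g], {"chr1": 2000}, 300)
        assert g.upstream_interval == (700, 1000)

    def test_divergent_pair_shares_interval(self):
        left = gene("L", "-", (100, 400), [(100, 400)])
        right = gene("R", "+", (1000, 1300), [(1000, 1300)])
        pf.compute_upstream_intervals([left, right], {"chr1": 2000}, None)
        assert left.upstream_interval == (400, 1000)
        assert right.upstream_interval == (400, 1000)

    def test_clipped_to_sequence_ends(self):
        g = gene("g", "+", (50, 150), [(50, 150)])
        pf.compute_upstream_intervals([g], {"chr1": 200}, None)
        assert g.upstream_interval == (0, 50)
        assert g.downstream_interval == (150, 200)

    def test_abutting_neighbor_empty_interval(self):
        a = gene("a", "+", (0, 100), [(0, 100)])
        b = gene("b", "+", (100, 200), [(100, 200)])
        pf.compute_upstream_intervals([a, b], {"chr1": 300}, None)
        assert b.upstream_interval is None

    def test_compartment_partition_disjoint(self, small_world):
        """Upstream, introns, exons and downstream never overlap per gene."""
        for sp in small_world.species:
            genes = small_world.genes[sp]
            lengths = {k: len(v) for k, v in small_world.sequences[sp].items()}
            pf.compute_upstream_intervals(genes, lengths, None)
            for g in genes:
                parts = list(g.exons) + list(g.introns)
                if g.upstream_interval:
                    parts.append(g.upstream_interval)
                if g.downstream_interval:
                    parts.append(g.downstream_interval)
                parts.sort()
                for (a0, a1), (b0, b1) in zip(parts, parts[1:]):
                    assert a1 <= b0
                assert parts[0][0] >= 0 and parts[-1][1] <= lengths[g.sequence_id]


class TestAssignHits:
    def setup_method(self):
        self.gene = gene("g", "+", (1000, 1600), [(1000, 1200), (1400, 1600)])
        self.up = gene("up", "-", (100, 400), [(100, 400)])
        pf.compute_upstream_intervals([self.up, self.gene], {"chr1": 3000}, None)

    def test_intronic_hit(self):
        (m,) = [
            a
            for a in pf.assign_hits([hit("chr1", 1250, 1260)], [self.up, self.gene])
            if a.gene_id == "g"
        ]
        assert m.compartment == "intron" and m.scoring

    def test_divergent_intergenic_hit_assigned_to_both(self):
        matches = pf.assign_hits([hit("chr1", 600, 610)], [self.up, self.gene])
        by_gene = {m.gene_id: m.compartment for m in matches}
        assert by_gene == {"g": "upstream", "up": "upstream"}

    def test_exon_intron_boundary_hit_is_exonic(self):
        matches = [
            a
            for a in pf.assign_hits([hit("chr1", 1195, 1205)], [self.up, self.gene])
            if a.gene_id == "g"
        ]
        assert [m.compartment for m in matches] == ["exon"]
        assert not matches[0].scoring

    def test_unassignable_hit_dropped(self):
        g = gene("x", "+", (100, 200), [(100, 200)])
        pf.compute_upstream_intervals([g], {"chr1": 150_000}, 50)
        assert pf.assign_hits([hit("chr1", 100_000, 100_010)], [g]) == []

    def test_distance_to_tss_upstream(self):
        (m,) = [
            a
            for a in pf.assign_hits([hit("chr1", 980, 990)], [self.up, self.gene])
            if a.gene_id == "g"
        ]
        assert m.compartment == "upstream" and m.distance_to_tss == 10

    def test_hit_conservation_rule(self, small_world, small_scan):
        """Each hit appears <= 1x per flanking gene upstream and <= 1x per
        gene body; never both upstream and intron of the same gene."""
        for sp in small_world.species:
            seen = {}
            for m in small_scan.assigned_by_species[sp]:
                key = (m.hit.sequence_id, m.hit.start, m.hit.strand, m.gene_id)
                seen.setdefault(key, []).append(m.compartment)
            for comps in seen.values():
                assert len(comps) == len(set(comps))
                assert not {"upstream", "intron"} <= set(comps)
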