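"""Ingest, normalization, conserved-gene selection and flat-file output."""

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from mitoirg4.genome_io import (
    Feature,
    FeatureSet,
    canonical_gene_name,
    conserved_completeness,
    conserved_exon_set,
    read_features,
    read_genome,
    write_bed,
    write_gff3,
)


class TestReadGenome:
    def test_minimal_fasta(self, fasta_file):
        g = read_genome(fasta_file("ACGT"), "fasta")
        assert g.id == "x" and g.length == 4 and not g.circular

    def test_lowercase_and_ambiguity_normalized(self, fasta_file):
        g = read_genome(fasta_file("acgn"), "fasta")
        assert g.sequence == "ACGN"
        g2 = read_genome(fasta_file("acgryk", path_name="g2.fa"), "fasta")
        assert g2.sequence == "ACGNNN"  # non-ACGTN codes -> N, not an error

    def test_multi_record_rejected(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="exactly one"):
            read_genome(p, "fasta")

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_genome(p, "fasta")

    def test_genbank_topology_honored(self, tmp_path):
        rec = SeqRecord(Seq("ACGT" * 30), id="gb1", annotations={
            "molecule_type": "DNA", "topology": "circular"})
        p = tmp_path / "g.gb"
        SeqIO.write([rec], p, "genbank")
        g = read_genome(p, "genbank")
        assert g.circular and g.length == 120


class TestReadFeatures:
    def test_gff3_coordinate_convention(self, tmp_path, fasta_file):
        gff = tmp_path / "a.gff3"
        gff.write_text("##gff-version 3\ng1\tsrc\tgene\t1\t10\t.\t+\t.\tName=cox1;gene=cox1\n")
        fs = read_features(gff, "gff3")
        assert fs.features[0].interval == (0, 10)

    def test_empty_gff3(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("##gff-version 3\n")
        assert len(read_features(gff, "gff3")) == 0

    def test_genbank_join_yields_exons_and_intron(self, tmp_path):
        loc = CompoundLocation([FeatureLocation(0, 30, 1), FeatureLocation(60, 90, 1)])
        rec = SeqRecord(Seq("A" * 100), id="g", annotations={"molecule_type": "DNA"})
        rec.features = [SeqFeature(loc, type="CDS", qualifiers={"gene": ["cox1"]})]
        p = tmp_path / "j.gb"
        SeqIO.write([rec], p, "genbank")
        fs = read_features(p, "genbank")
        exons = [f for f in fs if f.kind == "exon"]
        introns = [f for f in fs if f.kind == "intron"]
        assert [f.interval for f in exons] == [(0, 30), (60, 90)]
        assert [f.interval for f in introns] == [(30, 60)]
        # exon + intron lengths tile the full CDS span
        total = sum(f.end - f.start for f in exons + introns)
        assert total == 90 - 0

    def test_wrapping_feature_split_on_circular(self, tmp_path, fasta_file):
        genome = read_genome(fasta_file("ACGT" * 25), "fasta", circular=True)
        gff = tmp_path / "w.gff3"
        gff.write_text("##gff-version 3\nx\tsrc\tgene\t91\t110\t.\t+\t.\tName=nad1\n")
        fs = read_features(gff, "gff3", genome=genome)
        assert len(fs) == 2
        (a, b) = fs.features
        assert a.interval == (90, 100) and b.interval == (0, 10)
        assert a.group == b.group is not None

    def test_wrapping_feature_rejected_on_linear(self, tmp_path, fasta_file):
        genome = read_genome(fasta_file("ACGT" * 25), "fasta")
        gff = tmp_path / "w.gff3"
        gff.write_text("##gff-version 3\nx\tsrc\tgene\t91\t110\t.\t+\t.\tName=nad1\n")
        with pytest.raises(ValueError, match="exceeds"):
            read_features(gff, "gff3", genome=genome)


class TestConservedSet:
    def _fs(self, *features):
        return FeatureSet(genome_id="g", features=list(features))

    def test_nonconserved_genes_dropped(self):
        fs = self._fs(
            Feature("exon", "cox1.e1", 0, 100, "+", gene="cox1"),
            Feature("exon", "orf255.e1", 200, 300, "+", gene="orf255"),
        )
        out = conserved_exon_set(fs)
        assert [f.gene for f in out] == ["cox1"]

    def test_empty_input(self):
        assert len(conserved_exon_set(self._fs())) == 0

    def test_alias_table_maps_cytb_to_cob(self):
        fs = self._fs(Feature("exon", "CytB.e1", 0, 50, "+", gene="CytB"))
        assert len(conserved_exon_set(fs)) == 1
        assert canonical_gene_name("CytB") == "cob"

    def test_rrna_full_spans_included(self):
        fs = self._fs(Feature("rRNA", "rnl", 0, 2000, "+", gene="rnl"))
        assert len(conserved_exon_set(fs)) == 1

    def test_nad4L_toggle(self):
        fs = self._fs(Feature("exon", "nad4L.e1", 0, 100, "+", gene="nad4L"))
        assert len(conserved_exon_set(fs, include_nad4L=True)) == 1
        assert len(conserved_exon_set(fs, include_nad4L=False)) == 0

    def test_completeness_report(self):
        fs = self._fs(Feature("exon", "cox1.e1", 0, 100, "+", gene="cox1"))
        rep = conserved_completeness(fs)
        assert rep["cox1"] and not rep["cob"]


class TestOutput:
    def test_bed_line_format(self, tmp_path):
        from mitoirg4.g4scan import G4Motif

        out = tmp_path / "m.bed"
        write_bed([G4Motif(10, 35, 2.2)], out, chrom="g1")
        lines = out.read_text().splitlines()
        assert lines[1].split("\t") == ["g1", "10", "35", "G4_1", "2200", "+"]
        sidecar = (tmp_path / "m.bed.tsv").read_text().splitlines()
        assert "2.2" in sidecar[1]

    def test_bed_negative_strand_and_empty(self, tmp_path):
        from mitoirg4.g4scan import G4Motif

        out = tmp_path / "m.bed"
        write_bed([G4Motif(5, 30, -3.0)], out)
        assert out.read_text().splitlines()[1].endswith("-")
        write_bed([], tmp_path / "e.bed")
        assert (tmp_path / "e.bed").read_text().startswith("track")

    def test_gff3_round_trip(self, tmp_path):
        fs = FeatureSet(
            genome_id="g",
            features=[
                Feature("gene", "cox1", 10, 500, "+", gene="cox1"),
                Feature("exon", "cox1.e1", 10, 200, "+", gene="cox1"),
                Feature("intron", "cox1.i1", 200, 300, "+", gene="cox1"),
                Feature("rRNA", "rnl", 600, 900, "-", gene="rnl"),
            ],
        )
        p = tmp_path / "rt.gff3"
        write_gff3(fs, p)
        back = read_features(p, "gff3")
        assert [(f.kind, f.interval, f.strand) for f in back] == [
            (f.kind, f.interval, f.strand) for f in fs
        ]
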