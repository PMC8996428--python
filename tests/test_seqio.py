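import pytest

from vqsurvey.seqio import (
    GeneModel,
    GenomeBundle,
    extract_promoter,
    gene_span_sequence,
    load_genome,
    read_fasta,
    read_gff3,
    write_fasta,
)
from vqsurvey._util import revcomp


def test_read_fasta_uppercases_and_preserves_order(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">g1 description here\nacgt\n>g2\nTTaa\n")
    seqs = read_fasta(p)
    assert list(seqs) == ["g1", "g2"]
    assert seqs["g1"] == "ACGT"
    assert seqs["g2"] == "TTAA"


def test_read_fasta_duplicate_id_errors(tmp_path):
    p = tmp_path / "d.fasta"
    p.write_text(">g1\nAC\n>g1\nGT\n")
    with pytest.raises(ValueError, match="g1"):
        read_fasta(p)


def test_fasta_round_trip(tmp_path):
    seqs = {"a": "ACGT" * 40, "b": "N" * 5}
    f1 = tmp_path / "x.fasta"
    write_fasta(seqs, f1)
    assert read_fasta(f1) == seqs


GFF = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=geneA.1;Parent=geneA
chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=e2;Parent=geneA.1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=e1;Parent=geneA.1
chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=c1;Parent=geneA.1
chr1\tsrc\tCDS\t301\t400\t.\t+\t0\tID=c2;Parent=geneA.1
"""


def test_read_gff3_sorts_exons(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(GFF)
    genes = read_gff3(p)
    assert len(genes) == 1
    g = genes[0]
    assert g.exons == [(101, 200), (301, 400)]
    assert g.intron_count == 1
    assert g.strand == "+"


def test_exon_outside_gene_span_errors():
    with pytest.raises(ValueError, match="outside gene span"):
        GeneModel("g", "chr1", "+", 10, 20, exons=[(5, 20)])


def test_unknown_strand_errors():
    with pytest.raises(ValueError, match="strand"):
        GeneModel("g", "chr1", "?", 1, 10, exons=[(1, 10)])


def test_cds_not_divisible_by_three_errors(tmp_path):
    gff = (
        "##gff-version 3\n"
        "chr1\ts\tgene\t1\t10\t.\t+\t.\tID=g\n"
        "chr1\ts\tmRNA\t1\t10\t.\t+\t.\tID=g.1;Parent=g\n"
        "chr1\ts\texon\t1\t10\t.\t+\t.\tID=e;Parent=g.1\n"
        "chr1\ts\tCDS\t1\t10\t.\t+\t0\tID=c;Parent=g.1\n"
    )
    fa = tmp_path / "g.fasta"
    fa.write_text(">chr1\n" + "ACGTACGTACGTACGT" + "\n")
    gf = tmp_path / "g.gff3"
    gf.write_text(gff)
    with pytest.raises(ValueError, match="divisible by 3"):
        load_genome(fa, gf)


def _mini_bundle():
    # + strand gene: CDS starts at 2001; - strand mirror on chr2
    chrom = ["N"] * 4000
    promoter = "TTGACCAAAA" * 15  # 150 bp of recognizable sequence
    chrom1 = "A" * (2000 - 150) + promoter + "ATGAAATGA" + "C" * (4000 - 2009)
    chrom2 = revcomp(chrom1)
    g1 = GeneModel(
        "plus", "chr1", "+", 2001, 2009,
        exons=[(2001, 2009)], cds_intervals=[(2001, 2009)],
    )
    # mirrored coordinates on the reverse-complemented chromosome
    s = len(chrom1) - 2009 + 1
    e = len(chrom1) - 2001 + 1
    g2 = GeneModel(
        "minus", "chr2", "-", s, e, exons=[(s, e)], cds_intervals=[(s, e)],
    )
    return GenomeBundle({"chr1": chrom1, "chr2": chrom2}, [g1, g2])


def test_promoter_plus_strand_coordinates():
    b = _mini_bundle()
    prom = extract_promoter(b, "plus", 1500)
    assert len(prom) == 1500
    # positions 501..2000 of chr1
    assert prom == b.chromosomes["chr1"][500:2000]


def test_promoter_strand_symmetry():
    b = _mini_bundle()
    assert extract_promoter(b, "plus", 1500) == extract_promoter(b, "minus", 1500)
    assert extract_promoter(b, "plus", 150) == extract_promoter(b, "minus", 150)


def test_promoter_truncated_at_chromosome_edge():
    g = GeneModel(
        "g", "c", "+", 100, 108, exons=[(100, 108)], cds_intervals=[(100, 108)]
    )
    b = GenomeBundle({"c": "A" * 200}, [g])
    assert len(extract_promoter(b, "g", 1500)) == 99


def test_promoter_never_overlaps_cds():
    b = _mini_bundle()
    for gid in ("plus", "minus"):
        g = b.gene(gid)
        length = 500
        prom_len = len(extract_promoter(b, gid, length))
        anchor = g.cds_start
        if g.strand == "+":
            window = range(anchor - prom_len, anchor)  # 1-based, exclusive of anchor
        else:
            window = range(anchor + 1, anchor + prom_len + 1)
        cds_positions = set()
        for s, e in g.cds_intervals:
            cds_positions.update(range(s, e + 1))
        assert cds_positions.isdisjoint(window)


def test_unknown_gene_errors():
    b = _mini_bundle()
    with pytest.raises(KeyError, match="nope"):
        extract_promoter(b, "nope")


def test_derived_sequences_match_generator_fasta(manifest, bundle):
    """Splicing + translation from genome/GFF reproduces the generator's CDS
    and protein FASTA byte for byte, on both strands."""
    cds = read_fasta(manifest.files["cds"])
    prot = read_fasta(manifest.files["proteins"])
    for g in bundle.genes:
        assert g.cds_seq == cds[g.gene_id]
        assert g.protein_seq == prot[g.gene_id]
        assert g.has_stop_codon


def test_gene_span_sequence_length(bundle):
    g = bundle.genes[0]
    assert len(gene_span_sequence(bundle, g.gene_id)) == g.end - g.start + 1
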