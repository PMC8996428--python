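"""Sequence and annotation IO: FASTA, GFF3, and per-gene sequence derivation.

Coordinates are 1-based inclusive throughout (the GFF3 dialect). Promoters are
anchored at the translation start: the window immediately 5' of the first CDS
base, following the convention of surveying the 1.5 kb upstream of the coding
sequence rather than of the transcript.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp

__all__ = [
    "GeneModel",
    "GenomeBundle",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "load_genome",
    "attach_sequences",
    "extract_promoter",
    "gene_span_sequence",
]


@dataclass
class GeneModel:
    """One annotated gene (representative transcript only).

    ``exons`` and ``cds_intervals`` are sorted ascending, non-overlapping,
    1-based inclusive. ``cds_seq``/``protein_seq`` are filled in by
    :func:`attach_sequences`. ``has_stop_codon`` records whether the CDS ends
    in a stop (protein length = cds/3 - 1) or not (protein length = cds/3).
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str | None = None
    protein_seq: str | None = None
    has_stop_codon: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        self.cds_intervals = sorted(self.cds_intervals)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon start > end")
            if s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            prev_end = e

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def cds_start(self) -> int:
        """First base of the CDS in transcription order (1-based genomic)."""
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id}: no CDS intervals")
        return self.cds_intervals[0][0] if self.strand == "+" else self.cds_intervals[-1][1]


@dataclass
class GenomeBundle:
    """A genome (chromosome name -> uppercase sequence) plus its gene models."""

    chromosomes: dict[str, str]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            if g.chromosome not in self.chromosomes:
                raise ValueError(
                    f"gene {g.gene_id} references unknown chromosome {g.chromosome!r}"
                )
            if g.end > len(self.chromosomes[g.chromosome]):
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")
            self._by_id[g.gene_id] = g

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase sequence mapping.

    Ids are the first whitespace-delimited token of each header. A duplicate
    id raises ValueError naming the id; an empty file yields an empty mapping.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _representative_mrna(db: gffutils.FeatureDB, gene) -> object | None:
    """The mRNA with the longest total CDS (ties by id), or None."""
    best = None
    best_key = None
    for mrna in db.children(gene, featuretype="mRNA"):
        cds_len = sum(
            c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS")
        )
        key = (-cds_len, mrna.id)
        if best_key is None or key < best_key:
            best, best_key = mrna, key
    return best


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels (one per gene feature).

    Exons and CDS intervals come from the representative mRNA (the one with
    the longest CDS); genes with direct exon/CDS children and no mRNA are also
    accepted.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        parent = _representative_mrna(db, gene) or gene
        exons = [
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        ]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        if not exons:
            exons = list(cds) or [(gene.start, gene.end)]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                cds_intervals=cds,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "vqsurvey") -> None:
    """Write gene/mRNA/exon/CDS features for each GeneModel."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chromosome}\t{source}"
            fh.write(
                f"{base}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{base}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.cds_intervals, 1):
                fh.write(
                    f"{base}\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def attach_sequences(bundle: GenomeBundle, translate: bool = True) -> GenomeBundle:
    """Splice each gene's CDS from the genome and (optionally) translate it.

    CDS length must be divisible by 3 when translation is requested; an
    internal stop codon is an error. A trailing stop is recorded via
    ``has_stop_codon`` and trimmed from the protein.
    """
    for g in bundle.genes:
        if not g.cds_intervals:
            continue
        chrom = bundle.chromosomes[g.chromosome]
        cds = "".join(chrom[s - 1 : e] for s, e in g.cds_intervals)
        if g.strand == "-":
            cds = revcomp(cds)
        g.cds_seq = cds
        if translate:
            if len(cds) % 3 != 0:
                raise ValueError(
                    f"gene {g.gene_id}: CDS length {len(cds)} not divisible by 3"
                )
            aa = str(Seq(cds).translate())
            g.has_stop_codon = aa.endswith("*")
            if g.has_stop_codon:
                aa = aa[:-1]
            if "*" in aa:
                raise ValueError(f"gene {g.gene_id}: internal stop codon in CDS")
            g.protein_seq = aa
    return bundle


def load_genome(genome_fasta: str | Path, gff3: str | Path, translate: bool = True) -> GenomeBundle:
    """Read genome + annotation and derive CDS/protein sequences."""
    bundle = GenomeBundle(read_fasta(genome_fasta), read_gff3(gff3))
    return attach_sequences(bundle, translate=translate)


def extract_promoter(bundle: GenomeBundle, gene_id: str, length: int = 1500) -> str:
    """The `length` bp immediately 5' of the translation start.

    Plus strand: genomic positions [cds_start-length, cds_start-1]. Minus
    strand: reverse complement of [cds_end+1, cds_end+length]. Truncated at the
    chromosome boundary, so fewer than `length` bp may be returned.
    """
    if length <= 0:
        raise ValueError("promoter length must be positive")
    g = bundle.gene(gene_id)
    chrom = bundle.chromosomes[g.chromosome]
    anchor = g.cds_start
    if g.strand == "+":
        lo = max(1, anchor - length)
        return chrom[lo - 1 : anchor - 1]
    hi = min(len(chrom), anchor + length)
    return revcomp(chrom[anchor : hi])


def gene_span_sequence(bundle: GenomeBundle, gene_id: str) -> str:
    """Genomic sequence of the gene span (forward orientation, introns included)."""
    g = bundle.gene(gene_id)
    return bundle.chromosomes[g.chromosome][g.start - 1 : g.end]
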