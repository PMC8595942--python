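"""Genome/annotation input and strand-aware promoter extraction.

A *promoter* here is the fixed-length window (default 200 bp) immediately
upstream of a CDS start codon, reported 5'->3' on the gene's coding strand so
that its last base abuts the first base of the start codon.  Genes close to a
contig edge yield a truncated (possibly empty) promoter rather than an error.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED output
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: identifier plus uppercase DNA sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: non-DNA characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """One CDS: locus tag, contig, 1-based inclusive coordinates, strand."""

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream window of a gene, oriented 5'->3' on the coding strand.

    ``sequence`` ends immediately before the start codon; ``truncated`` is True
    iff the contig edge cut the window short of the requested length.  The
    genomic interval is 1-based inclusive; an empty promoter has
    ``genomic_end = genomic_start - 1``.
    """

    locus_tag: str
    contig_id: str
    sequence: str
    genomic_start: int
    genomic_end: int
    strand: str
    truncated: bool

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T.  Duplicate contig ids,
    empty files and non-DNA characters (other than N) are hard errors.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(contig_id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _gff3_genes(path: str | Path) -> list[GeneModel]:
    # Collect CDS segments per locus tag; a multi-segment CDS keeps the
    # segment carrying the start codon (lowest start on +, highest end on -).
    segments: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end ({start} > {end})")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            tag = None
            for item in attrs.split(";"):
                if "=" in item:
                    key, value = item.split("=", 1)
                    if key.strip() == "locus_tag":
                        tag = value.strip()
            if tag is None:
                raise ValueError(f"{path}:{lineno}: CDS without locus_tag attribute")
            if tag not in segments:
                order.append(tag)
            segments.setdefault(tag, []).append((seqid, start, end, strand))
    genes = []
    for tag in order:
        segs = segments[tag]
        strand = segs[0][3]
        if strand == "+":
            seqid, start, end, strand = min(segs, key=lambda s: s[1])
        else:
            seqid, start, end, strand = max(segs, key=lambda s: s[2])
        genes.append(GeneModel(tag, seqid, start, end, strand))
    return genes


def _gene_table_genes(path: str | Path) -> list[GeneModel]:
    required = ["locus_tag", "contig", "start", "end", "strand"]
    genes = []
    with open(path) as fh:
        header_line = fh.readline()
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}:1: missing columns {missing}")
        idx = {c: header.index(c) for c in required}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                start = int(fields[idx["start"]])
                end = int(fields[idx["end"]])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = fields[idx["strand"]].strip()
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end ({start} > {end})")
            tag = fields[idx["locus_tag"]].strip()
            if not tag:
                raise ValueError(f"{path}:{lineno}: empty locus_tag")
            genes.append(GeneModel(tag, fields[idx["contig"]].strip(), start, end, strand))
    return genes


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read CDS gene models from GFF3 or a plain five-column gene table.

    Parameters
    ----------
    path
        Annotation file.
    dialect
        ``"gff3"`` (CDS features with a ``locus_tag`` attribute) or
        ``"gene_table"`` (TSV with columns locus_tag, contig, start, end,
        strand).
    """
    if dialect == "gff3":
        genes = _gff3_genes(path)
    elif dialect == "gene_table":
        genes = _gene_table_genes(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    tags = [g.locus_tag for g in genes]
    if len(tags) != len(set(tags)):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise ValueError(f"{path}: duplicate locus tags {dup[:5]}")
    return genes


def extract_promoter(
    gene: GeneModel, genome: GenomeRecord, promoter_length: int = 200
) -> PromoterRegion:
    """Extract the promoter window upstream of ``gene`` on its coding strand.

    For a + strand gene the window is ``genome[start-L .. start-1]``; for a -
    strand gene it is the reverse complement of ``genome[end+1 .. end+L]``,
    with ``L`` truncated at the contig edge.  A gene starting at the contig
    edge yields an empty, truncated promoter.
    """
    if gene.contig_id != genome.contig_id:
        raise ValueError(
            f"{gene.locus_tag}: contig {gene.contig_id!r} != {genome.contig_id!r}"
        )
    contig_len = len(genome)
    if gene.end > contig_len:
        raise ValueError(f"{gene.locus_tag}: gene extends past contig end")
    seq = genome.sequence
    if gene.strand == "+":
        length = min(promoter_length, gene.start - 1)
        gstart, gend = gene.start - length, gene.start - 1
        prom = seq[gstart - 1 : gend]
        codon = seq[gene.start - 1 : gene.start + 2]
    else:
        length = min(promoter_length, contig_len - gene.end)
        gstart, gend = gene.end + 1, gene.end + length
        prom = reverse_complement(seq[gstart - 1 : gend])
        codon = reverse_complement(seq[gene.end - 3 : gene.end])
    if len(codon) == 3 and codon not in START_CODONS:
        logger.warning("%s: first codon %s is not ATG/GTG/TTG", gene.locus_tag, codon)
    return PromoterRegion(
        locus_tag=gene.locus_tag,
        contig_id=gene.contig_id,
        sequence=prom,
        genomic_start=gstart,
        genomic_end=gend,
        strand=gene.strand,
        truncated=length < promoter_length,
    )


def extract_promoters(
    genes: Iterable[GeneModel],
    genomes: Sequence[GenomeRecord] | GenomeRecord,
    promoter_length: int = 200,
) -> list[PromoterRegion]:
    """Extract promoters for many genes across one or more contigs."""
    if isinstance(genomes, GenomeRecord):
        genomes = [genomes]
    by_id = {g.contig_id: g for g in genomes}
    out = []
    for gene in genes:
        if gene.contig_id not in by_id:
            raise ValueError(f"{gene.locus_tag}: unknown contig {gene.contig_id!r}")
        out.append(extract_promoter(gene, by_id[gene.contig_id], promoter_length))
    return out


def write_promoters_fasta(promoters: Iterable[PromoterRegion], path: str | Path) -> None:
    """Write promoters as FASTA (header = locus tag). Empty promoters are skipped."""
    with open(path, "w") as fh:
        for p in promoters:
            if p.sequence:
                fh.write(f">{p.locus_tag}\n{p.sequence}\n")


def write_promoters_bed(promoters: Iterable[PromoterRegion], path: str | Path) -> None:
    """Write promoter genomic intervals as BED6 (0-based half-open, score 0)."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f"{p.contig_id}\t{p.genomic_start - 1}\t{p.genomic_end}\t"
                f"{p.locus_tag}\t0\t{p.strand}\n"
            )
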