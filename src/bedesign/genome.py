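"""Genome access: FASTA sequences, GFF3 gene annotation, strand-aware
sub-sequence fetch, transcript/codon coordinate mapping, and genic vs
intergenic interval classification.

All coordinates at this surface are 1-based inclusive, the GFF3/Ensembl
convention; half-open arithmetic stays internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

from .registry import reverse_complement, translate_codon

__all__ = [
    "CoordinateError",
    "ValidationError",
    "TranscriptModel",
    "GenomeBundle",
    "load_genome",
    "fetch_sequence",
    "codon_genomic_location",
    "classify_region",
]


class CoordinateError(ValueError):
    """A genomic coordinate fell outside the genome's bounds."""


class ValidationError(ValueError):
    """A request refers to an entity or state the genome does not support."""


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript as an ordered run of CDS exons.

    ``cds_exons`` lists genomic (start, end) intervals, 1-based inclusive,
    in translation order: ascending starts for ``+`` transcripts, descending
    for ``-``.  The concatenated CDS (including the stop codon) must be a
    multiple of 3.
    """

    transcript_id: str
    chromosome: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not self.cds_exons:
            raise ValidationError(f"{self.transcript_id}: no CDS exons")
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )
        starts = [s for s, _ in self.cds_exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if not ordered:
            raise ValidationError(f"{self.transcript_id}: exons out of translation order")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def n_residues(self) -> int:
        """Codon count including the stop codon."""
        return self.cds_length // 3

    def genomic_positions(self) -> list[int]:
        """All CDS genomic positions in translation (5'->3' transcript) order."""
        out: list[int] = []
        for s, e in self.cds_exons:
            if self.strand == "+":
                out.extend(range(s, e + 1))
            else:
                out.extend(range(e, s - 1, -1))
        return out


@dataclass
class GenomeBundle:
    """In-memory genome: sequences, gene intervals, and transcript models."""

    sequences: dict[str, str]
    gene_intervals: dict[str, list[tuple[int, int, str, str]]] = field(default_factory=dict)
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for chrom, genes in self.gene_intervals.items():
            if chrom not in self.sequences:
                raise CoordinateError(f"gene annotation on unknown chromosome {chrom!r}")
            clen = len(self.sequences[chrom])
            for start, end, _, gid in genes:
                if not (1 <= start <= end <= clen):
                    raise CoordinateError(
                        f"gene {gid}: interval {start}..{end} outside {chrom} (1..{clen})"
                    )
        self._trees = {
            chrom: IntervalTree.from_tuples(
                (start, end + 1, gid) for start, end, _, gid in genes
            )
            for chrom, genes in self.gene_intervals.items()
            if genes
        }

    def chromosome_length(self, chromosome: str) -> int:
        try:
            return len(self.sequences[chromosome])
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chromosome!r}")

    def copy_with_sequences(self, sequences: dict[str, str]) -> "GenomeBundle":
        return GenomeBundle(sequences, dict(self.gene_intervals), dict(self.transcripts))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fetch_sequence(
    genome: GenomeBundle, chromosome: str, start: int, end: int, strand: str = "+"
) -> str:
    """Fetch the 1-based inclusive interval; reverse-complement when ``-``."""
    clen = genome.chromosome_length(chromosome)
    if not (1 <= start <= end <= clen):
        raise CoordinateError(
            f"{chromosome}:{start}-{end} outside valid range 1..{clen}"
        )
    seq = genome.sequences[chromosome][start - 1 : end]
    if strand == "-":
        return reverse_complement(seq)
    if strand != "+":
        raise CoordinateError(f"invalid strand {strand!r}")
    return seq


def codon_genomic_location(
    tx: TranscriptModel, residue_position: int
) -> list[tuple[str, int, str]]:
    """Genomic (chromosome, position, strand) of a codon's three bases.

    Returned in translation order, so for ``-`` strand transcripts the
    positions descend.
    """
    if not (1 <= residue_position <= tx.n_residues):
        raise ValidationError(
            f"{tx.transcript_id}: residue {residue_position} beyond CDS "
            f"({tx.n_residues} codons)"
        )
    pos = tx.genomic_positions()
    i = (residue_position - 1) * 3
    return [(tx.chromosome, p, tx.strand) for p in pos[i : i + 3]]


def codon_sequence(genome: GenomeBundle, tx: TranscriptModel, residue_position: int) -> str:
    """The codon for a residue, read on the transcript strand."""
    bases = []
    for chrom, p, strand in codon_genomic_location(tx, residue_position):
        b = fetch_sequence(genome, chrom, p, p, "+")
        bases.append(b if strand == "+" else reverse_complement(b))
    return "".join(bases)


def spliced_cds(genome: GenomeBundle, tx: TranscriptModel) -> str:
    parts = [
        fetch_sequence(genome, tx.chromosome, min(s, e), max(s, e), tx.strand)
        for s, e in tx.cds_exons
    ]
    return "".join(parts)


def translate_cds(genome: GenomeBundle, tx: TranscriptModel) -> str:
    cds = spliced_cds(genome, tx)
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def classify_region(
    genome: GenomeBundle, chromosome: str, start: int, end: int
) -> str:
    """``genic`` iff the interval overlaps any annotated gene by >= 1 bp."""
    clen = genome.chromosome_length(chromosome)
    if not (1 <= start <= end <= clen):
        raise CoordinateError(f"{chromosome}:{start}-{end} outside 1..{clen}")
    tree = genome._trees.get(chromosome)
    if tree is not None and tree.overlap(start, end + 1):
        return "genic"
    return "intergenic"


# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------

def load_genome(fasta_path: str | Path, gff_path: str | Path | None = None) -> GenomeBundle:
    """Read a FASTA genome and (optionally) a GFF3 annotation.

    Gene features of type ``gene`` define genic intervals; transcripts are
    assembled from ``CDS`` features grouped by their ``Parent`` mRNA.
    """
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not sequences:
        raise ValidationError(f"no sequences in {fasta_path}")
    gene_intervals: dict[str, list[tuple[int, int, str, str]]] = {c: [] for c in sequences}
    transcripts: dict[str, TranscriptModel] = {}

    if gff_path is not None:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        for gene in db.features_of_type("gene"):
            gene_intervals.setdefault(gene.seqid, []).append(
                (gene.start, gene.end, gene.strand, gene.id)
            )
        for mrna in db.features_of_type("mRNA"):
            exons = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            if not exons:
                continue
            exons.sort(key=lambda se: se[0], reverse=(mrna.strand == "-"))
            transcripts[mrna.id] = TranscriptModel(
                mrna.id, mrna.seqid, mrna.strand, tuple(exons)
            )
    return GenomeBundle(sequences, gene_intervals, transcripts)
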