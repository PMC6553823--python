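"""Deterministic synthetic test data: genomes with annotated single-exon
genes, random mutation tables in both input dialects, and planted off-target
sites with known coordinates.

Everything is reproducible bit-for-bit from (recipe, seed); the seed is
recorded in output headers and the manifest.  Fixtures aim for correctness
testing, not compositional realism — no repeats, isochores or introns unless
a test builds them by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBundle, TranscriptModel
from .registry import reverse_complement, translate_codon

__all__ = [
    "RecipeError",
    "PlacementError",
    "FixtureRecipe",
    "generate_genome",
    "write_genome",
    "generate_mutations",
    "write_mutations",
    "write_manifest",
    "plant_offtarget_sites",
]

_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in _STOP_CODONS
)
AA20 = "ACDEFGHIKLMNPQRSTVWY"


class RecipeError(ValueError):
    """A fixture recipe is internally infeasible."""


class PlacementError(ValueError):
    """A planted site collides with protected sequence."""


@dataclass(frozen=True)
class FixtureRecipe:
    """Parameters of one synthetic data set.

    Defaults mirror the reference study conditions scaled to a desk-size
    genome: 1000 randomly assigned mutations over an annotated genome, in
    either mutation format and either mutagenesis mode.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 20_000
    n_genes: int = 20
    gene_length: int = 300
    n_mutations: int = 1000
    mutation_format: str = "nucleotide"
    mode: str = "model"
    gc_content: float = 0.40

    def __post_init__(self):
        if self.gene_length % 3 != 0 or self.gene_length < 9:
            raise RecipeError("gene_length must be a multiple of 3 and >= 9")
        if not (0.0 <= self.gc_content <= 1.0):
            raise RecipeError("gc_content must lie in [0, 1]")
        if self.mutation_format not in ("nucleotide", "amino_acid"):
            raise RecipeError(f"bad mutation_format {self.mutation_format!r}")
        if self.mode not in ("model", "correct"):
            raise RecipeError(f"bad mode {self.mode!r}")
        per_chrom = -(-self.n_genes // self.n_chromosomes) if self.n_chromosomes else 0
        if self.n_genes and per_chrom * (self.gene_length + 2) > self.chromosome_length:
            raise RecipeError("genes do not fit within chromosomes without overlap")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + sense codons + stop; never an internal stop codon."""
    n_mid = length // 3 - 2
    mid = rng.choice(len(_SENSE_CODONS), size=n_mid)
    stop = _STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in mid) + stop


def generate_genome(recipe: FixtureRecipe) -> GenomeBundle:
    """A seeded random genome with non-overlapping single-exon genes.

    Gene g occupies a slot of its chromosome; its CDS (ATG ... stop, length
    ``gene_length``) is written onto a uniformly chosen strand.  The gene
    interval in the annotation equals the CDS interval.
    """
    rng = np.random.default_rng(recipe.seed)
    gc = recipe.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    sequences: dict[str, str] = {}
    gene_intervals: dict[str, list] = {}
    transcripts: dict[str, TranscriptModel] = {}

    chrom_names = [f"chr{i + 1}" for i in range(recipe.n_chromosomes)]
    genes_per_chrom = [0] * recipe.n_chromosomes
    for g in range(recipe.n_genes):
        genes_per_chrom[g % recipe.n_chromosomes] += 1

    gene_no = 0
    for ci, chrom in enumerate(chrom_names):
        seq = rng.choice(np.array(list("ACGT")), size=recipe.chromosome_length, p=probs)
        seq = list("".join(seq))
        gene_intervals[chrom] = []
        k = genes_per_chrom[ci]
        if k:
            slot = recipe.chromosome_length // k
            if slot < recipe.gene_length + 2:
                raise RecipeError("genes do not fit within chromosomes without overlap")
            for s in range(k):
                gene_no += 1
                offset = int(rng.integers(0, slot - recipe.gene_length + 1))
                start = s * slot + offset + 1  # 1-based
                end = start + recipe.gene_length - 1
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                cds = _random_cds(rng, recipe.gene_length)
                plus = cds if strand == "+" else reverse_complement(cds)
                seq[start - 1 : end] = list(plus)
                gid = f"gene{gene_no:04d}"
                tid = f"{gid}.t1"
                gene_intervals[chrom].append((start, end, strand, gid))
                transcripts[tid] = TranscriptModel(tid, chrom, strand, ((start, end),))
        sequences[chrom] = "".join(seq)
    return GenomeBundle(sequences, gene_intervals, transcripts)


def write_genome(
    bundle: GenomeBundle, fasta_path: str | Path, gff_path: str | Path, seed: int | None = None
) -> None:
    """Write the bundle as wrapped FASTA + GFF3 (gene/mRNA/CDS features)."""
    with open(fasta_path, "w") as fh:
        for chrom in bundle.sequences:
            fh.write(f">{chrom}\n")
            s = bundle.sequences[chrom]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"#seed={seed}\n")
        for chrom, seq in bundle.sequences.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for chrom in bundle.sequences:
            for start, end, strand, gid in bundle.gene_intervals.get(chrom, []):
                fh.write(
                    f"{chrom}\tbedesign\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
                )
                for tid, tx in bundle.transcripts.items():
                    if not tid.startswith(gid + "."):
                        continue
                    lo = min(min(s, e) for s, e in tx.cds_exons)
                    hi = max(max(s, e) for s, e in tx.cds_exons)
                    fh.write(
                        f"{chrom}\tbedesign\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\t"
                        f"ID={tid};Parent={gid}\n"
                    )
                    phase = 0
                    for s, e in tx.cds_exons:
                        lo_e, hi_e = min(s, e), max(s, e)
                        fh.write(
                            f"{chrom}\tbedesign\tCDS\t{lo_e}\t{hi_e}\t.\t{strand}\t{phase}\t"
                            f"ID={tid}.cds;Parent={tid}\n"
                        )
                        phase = (3 - ((hi_e - lo_e + 1 - phase) % 3)) % 3


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def generate_mutations(genome: GenomeBundle, recipe: FixtureRecipe) -> pd.DataFrame:
    """Randomly assigned mutations in the recipe's format, verified against
    the genome (reference alleles are read from it, never invented)."""
    rng = np.random.default_rng(recipe.seed + 1_000_003)
    rows = []
    if recipe.mutation_format == "nucleotide":
        chroms = sorted(genome.sequences)
        lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
        p = lengths / lengths.sum()
        for i in range(recipe.n_mutations):
            chrom = chroms[int(rng.choice(len(chroms), p=p))]
            pos = int(rng.integers(1, len(genome.sequences[chrom]) + 1))
            ref = genome.sequences[chrom][pos - 1]
            if ref == "N":
                continue
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            rows.append(
                {
                    "request_id": f"m{i + 1:05d}",
                    "chromosome": chrom,
                    "position": pos,
                    "ref_base": ref,
                    "alt_base": alt,
                }
            )
        cols = ["request_id", "chromosome", "position", "ref_base", "alt_base"]
    else:
        tids = sorted(genome.transcripts)
        if not tids:
            raise RecipeError("amino_acid mutations need a genome with transcripts")
        from .genome import codon_sequence

        for i in range(recipe.n_mutations):
            tid = tids[int(rng.integers(0, len(tids)))]
            tx = genome.transcripts[tid]
            # residues 2 .. n-1: skip the start codon and the stop codon
            residue = int(rng.integers(2, tx.n_residues))
            ref = translate_codon(codon_sequence(genome, tx, residue))
            alt = AA20.replace(ref, "")[rng.integers(0, len(AA20) - (ref in AA20))]
            rows.append(
                {
                    "request_id": f"m{i + 1:05d}",
                    "transcript_id": tid,
                    "residue_position": residue,
                    "ref_residue": ref,
                    "alt_residue": alt,
                }
            )
        cols = ["request_id", "transcript_id", "residue_position", "ref_residue", "alt_residue"]
    return pd.DataFrame(rows, columns=cols)


def write_mutations(df: pd.DataFrame, path: str | Path, recipe: FixtureRecipe) -> None:
    with open(path, "w") as fh:
        fh.write(f"#seed={recipe.seed} format={recipe.mutation_format} mode={recipe.mode}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# planted off-target sites
# ---------------------------------------------------------------------------

def plant_offtarget_sites(
    genome: GenomeBundle,
    spacer: str,
    pam_observed: str,
    pam_side: str,
    placements: list[tuple[str, int, str, int]],
    seed: int = 0,
    protect_cds: bool = False,
) -> tuple[GenomeBundle, list[dict]]:
    """Overwrite the genome with near-copies of spacer+PAM at known sites.

    Each placement (chromosome, protospacer_start, strand, n_mismatches)
    receives the spacer mutated at exactly ``n_mismatches`` seeded-random
    positions (never in the PAM) plus the concrete PAM.  Returns the modified
    bundle and the planted records (coordinates, strand, mismatch offsets in
    PAM-distal 1-based convention) for oracle comparison.
    """
    rng = np.random.default_rng(seed)
    L = len(spacer)
    pl = len(pam_observed)
    seqs = {c: list(s) for c, s in genome.sequences.items()}
    cds_spans: dict[str, list[tuple[int, int]]] = {}
    for tx in genome.transcripts.values():
        for s, e in tx.cds_exons:
            cds_spans.setdefault(tx.chromosome, []).append((min(s, e), max(s, e)))
    planted = []
    for chrom, start, strand, n_mm in placements:
        if n_mm > L:
            raise PlacementError(f"n_mismatches {n_mm} exceeds spacer length {L}")
        clen = len(seqs[chrom])
        site_lo = start - (0 if (pam_side == "three_prime") == (strand == "+") else pl)
        site_hi = start + L - 1 + (pl if (pam_side == "three_prime") == (strand == "+") else 0)
        if site_lo < 1 or site_hi > clen:
            raise PlacementError(f"placement {chrom}:{start} out of bounds")
        if protect_cds:
            for lo, hi in cds_spans.get(chrom, []):
                if site_lo <= hi and lo <= site_hi:
                    raise PlacementError(
                        f"placement {chrom}:{start} collides with a CDS"
                    )
        # choose mismatch positions in PAM-distal offsets, mutate the spacer
        offsets = sorted(rng.choice(L, size=n_mm, replace=False).tolist())
        site = list(spacer)
        distal_offsets = []
        for i5 in offsets:
            orig = site[i5]
            site[i5] = "ACGT".replace(orig, "")[rng.integers(0, 3)]
            distal_offsets.append(i5 + 1 if pam_side == "three_prime" else L - i5)
        site_spacer = "".join(site)
        full = (
            site_spacer + pam_observed
            if pam_side == "three_prime"
            else pam_observed + site_spacer
        )
        plus = full if strand == "+" else reverse_complement(full)
        seqs[chrom][site_lo - 1 : site_hi] = list(plus)
        planted.append(
            {
                "chromosome": chrom,
                "start": start,
                "end": start + L - 1,
                "strand": strand,
                "n_mismatches": n_mm,
                "mismatch_offsets": sorted(distal_offsets),
            }
        )
    new = genome.copy_with_sequences({c: "".join(s) for c, s in seqs.items()})
    return new, planted


def write_manifest(path: str | Path, recipe: FixtureRecipe, planted: list[dict] | None = None):
    doc = {"seed": recipe.seed, "recipe": recipe.__dict__, "planted_sites": planted or []}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
        fh.write("\n")
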