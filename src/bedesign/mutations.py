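"""Mutation-request parsing, validation, codon-level edit planning, and
substitution filters.

Two tab-separated input dialects are accepted.  Nucleotide format::

    request_id  chromosome  position  ref_base  alt_base

Amino-acid format::

    request_id  transcript_id  residue_position  ref_residue  alt_residue

Lines starting with ``#`` are comments.  In ``model`` mode the genome carries
``ref`` and the design goal is ref -> alt; in ``correct`` mode the edited
background carries ``alt`` and the goal is alt -> ref.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from .genome import GenomeBundle, ValidationError, codon_sequence, fetch_sequence
from .registry import (
    BaseEditorSpec,
    ConfigError,
    ContractViolation,
    RunConfig,
    complement_base,
    translate_codon,
)

__all__ = [
    "MutationRequest",
    "CodonEditPlan",
    "parse_mutation_table",
    "validate_request",
    "aa_edit_candidates",
    "apply_filters",
    "minimal_hamming_codon",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY*")

NUCLEOTIDE_COLUMNS = ["request_id", "chromosome", "position", "ref_base", "alt_base"]
AMINO_ACID_COLUMNS = [
    "request_id",
    "transcript_id",
    "residue_position",
    "ref_residue",
    "alt_residue",
]

_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


@dataclass(frozen=True)
class MutationRequest:
    """One desired edit, in nucleotide or amino-acid form."""

    request_id: str
    format: str
    mode: str
    chromosome: str | None = None
    position: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None
    transcript_id: str | None = None
    residue_position: int | None = None
    ref_residue: str | None = None
    alt_residue: str | None = None

    def __post_init__(self):
        nuc = (self.chromosome, self.position, self.ref_base, self.alt_base)
        aa = (self.transcript_id, self.residue_position, self.ref_residue, self.alt_residue)
        if self.format == "nucleotide":
            if any(v is None for v in nuc) or any(v is not None for v in aa):
                raise ContractViolation(
                    f"request {self.request_id}: nucleotide fields incomplete or mixed"
                )
            if self.ref_base == self.alt_base:
                raise ContractViolation(f"request {self.request_id}: no-op substitution")
        elif self.format == "amino_acid":
            if any(v is None for v in aa) or any(v is not None for v in nuc):
                raise ContractViolation(
                    f"request {self.request_id}: amino-acid fields incomplete or mixed"
                )
            if self.ref_residue == self.alt_residue:
                raise ContractViolation(f"request {self.request_id}: no-op substitution")
        else:
            raise ContractViolation(f"request {self.request_id}: bad format {self.format!r}")

    @property
    def substitution(self) -> tuple[str, str]:
        """(from_symbol, to_symbol) of the requested change."""
        if self.format == "nucleotide":
            return (self.ref_base, self.alt_base)
        return (self.ref_residue, self.alt_residue)


@dataclass(frozen=True)
class CodonEditPlan:
    """One way to turn a codon into a target residue with a base editor.

    ``codon_positions`` are the edited positions (1..3, translation order);
    ``strand_of_edit`` is the strand, relative to the codon's reading strand,
    on which the editor's source base is read (``-`` means the editor acts on
    the antisense presentation, e.g. a C->T editor performing G->A on the
    sense strand).
    """

    request_id: str
    codon_positions: tuple[int, ...]
    strand_of_edit: str
    original_codon: str
    edited_codon: str
    resulting_residue: str

    def __post_init__(self):
        if translate_codon(self.edited_codon) != self.resulting_residue:
            raise ContractViolation("edited codon does not translate to stated residue")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_mutation_table(
    path: str | Path, cfg: RunConfig
) -> tuple[list[MutationRequest], pd.DataFrame]:
    """Read a mutation TSV; malformed rows go to a rejects table, not /dev/null.

    Returns (requests, rejects); rejects has columns row, request_id, reason.
    """
    columns = NUCLEOTIDE_COLUMNS if cfg.mutation_format == "nucleotide" else AMINO_ACID_COLUMNS
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"mutation table {path} is empty")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"mutation table missing column(s): {', '.join(missing)}")

    requests: list[MutationRequest] = []
    rejects: list[dict] = []

    def reject(i, rid, reason):
        rejects.append({"row": i, "request_id": rid, "reason": reason})

    for i, row in enumerate(df.itertuples(index=False), start=1):
        rid = getattr(row, "request_id") or f"row{i}"
        try:
            if cfg.mutation_format == "nucleotide":
                ref, alt = row.ref_base.upper(), row.alt_base.upper()
                if ref not in "ACGT" or alt not in "ACGT":
                    reject(i, rid, "invalid base")
                    continue
                if ref == alt:
                    reject(i, rid, "no-op substitution")
                    continue
                requests.append(
                    MutationRequest(
                        rid,
                        "nucleotide",
                        cfg.mode,
                        chromosome=row.chromosome,
                        position=int(row.position),
                        ref_base=ref,
                        alt_base=alt,
                    )
                )
            else:
                ref, alt = row.ref_residue.upper(), row.alt_residue.upper()
                if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
                    reject(i, rid, "invalid residue")
                    continue
                if ref == alt:
                    reject(i, rid, "no-op substitution")
                    continue
                requests.append(
                    MutationRequest(
                        rid,
                        "amino_acid",
                        cfg.mode,
                        transcript_id=row.transcript_id,
                        residue_position=int(row.residue_position),
                        ref_residue=ref,
                        alt_residue=alt,
                    )
                )
        except (ValueError, ContractViolation) as exc:
            reject(i, rid, str(exc))
    return requests, pd.DataFrame(rejects, columns=["row", "request_id", "reason"])


def validate_request(req: MutationRequest, genome: GenomeBundle) -> MutationRequest:
    """Check the request against the genome; raises ValidationError on mismatch."""
    if req.format == "nucleotide":
        observed = fetch_sequence(genome, req.chromosome, req.position, req.position, "+")
        if observed != req.ref_base:
            raise ValidationError(
                f"request {req.request_id}: expected {req.ref_base} at "
                f"{req.chromosome}:{req.position}, observed {observed}"
            )
    else:
        tx = genome.transcripts.get(req.transcript_id)
        if tx is None:
            raise ValidationError(
                f"request {req.request_id}: transcript {req.transcript_id} not found"
            )
        codon = codon_sequence(genome, tx, req.residue_position)
        observed = translate_codon(codon)
        if observed != req.ref_residue:
            raise ValidationError(
                f"request {req.request_id}: expected residue {req.ref_residue} at "
                f"{req.transcript_id}:{req.residue_position}, observed {observed}"
            )
    return req


# ---------------------------------------------------------------------------
# codon edit planning
# ---------------------------------------------------------------------------

def aa_edit_candidates(
    codon: str, target_residue: str, editor: BaseEditorSpec, request_id: str = ""
) -> list[CodonEditPlan]:
    """Every single-strand editable-subset conversion of ``codon`` that yields
    ``target_residue``.

    On the ``+`` (codon) strand the editor converts source->target directly;
    on ``-`` it acts on the complementary presentation, i.e. a C->T editor
    performs G->A on the sense codon.  Each plan converts one nonempty subset
    of eligible positions, all on one strand.
    """
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ContractViolation(f"not an unambiguous codon: {codon!r}")
    if target_residue not in AMINO_ACIDS:
        raise ContractViolation(f"invalid residue {target_residue!r}")
    plans: list[CodonEditPlan] = []
    for strand in "+-":
        if strand == "+":
            src, tgt = editor.source_base, editor.target_base
        else:
            src = complement_base(editor.source_base)
            tgt = complement_base(editor.target_base)
        eligible = [i for i in range(3) if codon[i] == src]
        for r in range(1, len(eligible) + 1):
            for subset in combinations(eligible, r):
                edited = "".join(
                    tgt if i in subset else codon[i] for i in range(3)
                )
                if translate_codon(edited) == target_residue:
                    plans.append(
                        CodonEditPlan(
                            request_id,
                            tuple(i + 1 for i in subset),
                            strand,
                            codon,
                            edited,
                            target_residue,
                        )
                    )
    plans.sort(key=lambda p: (len(p.codon_positions), p.codon_positions, p.strand_of_edit))
    return plans


def apply_filters(
    plans: list[CodonEditPlan],
    matrix: list[tuple[str, str]] | None,
    mutation_class: str,
) -> list[CodonEditPlan]:
    """Keep plans allowed by the substitution matrix and mutation class.

    The class compares the original codon's residue with the plan's resulting
    residue (synonymous <=> identical).
    """
    if matrix is not None:
        for a, b in matrix:
            if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
                raise ConfigError(f"substitution matrix entry ({a},{b}) invalid")
        allowed = {(a, b) for a, b in matrix}
    out = []
    for p in plans:
        ref = translate_codon(p.original_codon)
        if matrix is not None and (ref, p.resulting_residue) not in allowed:
            continue
        syn = ref == p.resulting_residue
        if mutation_class == "synonymous" and not syn:
            continue
        if mutation_class == "nonsynonymous" and syn:
            continue
        out.append(p)
    return out


def minimal_hamming_codon(target_residue: str, reference_codon: str) -> str:
    """The codon for ``target_residue`` closest (Hamming) to ``reference_codon``.

    Ties break lexicographically.  Used to reconstruct the mutant background
    in ``correct`` mode for amino-acid requests.
    """
    if target_residue not in AMINO_ACIDS:
        raise ContractViolation(f"invalid residue {target_residue!r}")
    candidates = [c for c in _ALL_CODONS if translate_codon(c) == target_residue]
    return min(
        candidates,
        key=lambda c: (sum(a != b for a, b in zip(c, reference_codon)), c),
    )
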