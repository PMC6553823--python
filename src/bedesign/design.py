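"""Guide (spacer) enumeration for validated mutation requests.

A candidate guide is any placement of a ``guide_length`` spacer over the
genome such that (a) every intended edited base sits inside the spacer,
(b) an adjacent PAM matches on the same strand, and (c) the strand presents
the editor's source base at every intended position.  Placements whose
editable base falls outside the editor's activity window are emitted and
flagged, not suppressed — the window penalty in the scoring stage exists
precisely to down-weight them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    GenomeBundle,
    ValidationError,
    codon_genomic_location,
    codon_sequence,
    fetch_sequence,
)
from .mutations import (
    CodonEditPlan,
    MutationRequest,
    aa_edit_candidates,
    apply_filters,
    minimal_hamming_codon,
)
from .registry import (
    BaseEditorSpec,
    PamSpec,
    RunConfig,
    complement_base,
    pam_matches,
    reverse_complement,
    translate_codon,
)

__all__ = [
    "GuideCandidate",
    "DesignContext",
    "UnreachableRequest",
    "annotate_polyT",
    "build_design_context",
    "scan_protospacers",
    "design_guides_for_request",
    "design_positive_controls",
    "design_negative_controls",
]


@dataclass(frozen=True)
class GuideCandidate:
    """A designed spacer+PAM with genomic placement and edit annotations.

    ``edited_offset`` and every other spacer position are 1-based from the
    PAM-distal end.  ``edits`` are the plus-strand genomic substitutions the
    guide is predicted to install: (position, from_base, to_base).
    """

    guide_id: str
    request_id: str
    editor_name: str
    pam_name: str
    spacer: str
    pam_observed: str
    strand: str
    chromosome: str
    protospacer_start: int
    protospacer_end: int
    edited_offset: int
    in_window: bool
    bystander_offsets: tuple[int, ...]
    polyT_length: int
    edits: tuple[tuple[int, str, str], ...]
    intended_offsets: tuple[int, ...] = ()
    resulting_residue: str | None = None
    guide_score: float | None = None


@dataclass(frozen=True)
class UnreachableRequest:
    request_id: str
    reason: str


@dataclass
class DesignContext:
    """A plus-strand genomic window hosting the intended edit(s).

    ``seq`` already reflects the background being edited (in ``correct``
    mode the alternative allele is substituted in).  ``edits`` are
    (offset-in-seq 0-based, from_base, to_base) on the plus strand;
    the first entry is the primary target.
    """

    chromosome: str
    genomic_start: int  # genomic 1-based position of seq[0]
    seq: str
    edits: tuple[tuple[int, str, str], ...]
    resulting_residue: str | None = None

    @property
    def target_offset(self) -> int:
        return self.edits[0][0]


def annotate_polyT(spacer: str) -> int:
    """Length of the longest run of consecutive T in the spacer.

    Runs of >= 4 T can act as RNA-polymerase-III terminators; the length is
    reported so users can filter, never auto-filtered.
    """
    runs = re.findall(r"T+", spacer)
    return max((len(r) for r in runs), default=0)


# ---------------------------------------------------------------------------
# placement enumeration
# ---------------------------------------------------------------------------

def _chemistry_strand_ok(editor: BaseEditorSpec, from_base: str, to_base: str, strand: str) -> bool:
    """Can the editor install plus-strand change from->to acting on ``strand``?"""
    if strand == "+":
        return editor.source_base == from_base and editor.target_base == to_base
    return editor.source_base == complement_base(from_base) and (
        editor.target_base == complement_base(to_base)
    )


def _distal_offset(i5: int, guide_length: int, pam_side: str) -> int:
    """PAM-distal 1-based offset from a 0-based 5'-end spacer index."""
    return i5 + 1 if pam_side == "three_prime" else guide_length - i5


def _i5_from_distal(offset: int, guide_length: int, pam_side: str) -> int:
    return offset - 1 if pam_side == "three_prime" else guide_length - offset


def scan_protospacers(
    context: DesignContext,
    editor: BaseEditorSpec,
    pam: PamSpec,
    guide_length: int,
) -> list[GuideCandidate]:
    """Enumerate every spacer placement achieving the context's edits.

    Both strands are scanned; a C->T request presented as G->A on the minus
    strand yields minus-strand candidates.  Out-of-window placements are
    returned with ``in_window=False``.
    """
    seq = context.seq
    L = guide_length
    pl = len(pam)
    out: list[GuideCandidate] = []

    for strand in "+-":
        if not all(_chemistry_strand_ok(editor, f, t, strand) for _, f, t in context.edits):
            continue
        # context consistency: the stated from-base must be present
        if any(seq[o] != f for o, f, t in context.edits):
            raise ValidationError("design context does not carry the stated source allele")
        offsets = [o for o, _, _ in context.edits]
        lo, hi = min(offsets), max(offsets)
        if hi - lo >= L:
            continue  # edits cannot share one protospacer
        for ws in range(max(0, hi - L + 1), lo + 1):
            we = ws + L  # exclusive
            if we > len(seq):
                continue
            # PAM genomic window on the plus strand
            pam_right = (pam.side == "three_prime") == (strand == "+")
            if pam_right:
                ps, pe = we, we + pl
            else:
                ps, pe = ws - pl, ws
            if ps < 0 or pe > len(seq):
                continue
            spacer_plus = seq[ws:we]
            pam_plus = seq[ps:pe]
            if "N" in spacer_plus or "N" in pam_plus:
                continue
            spacer = spacer_plus if strand == "+" else reverse_complement(spacer_plus)
            pam_obs = pam_plus if strand == "+" else reverse_complement(pam_plus)
            if not pam_matches(pam.pattern, pam_obs):
                continue
            i5 = lambda o: (o - ws) if strand == "+" else (we - 1 - o)
            distal = [_distal_offset(i5(o), L, pam.side) for o in offsets]
            in_window = all(editor.window_start <= d <= editor.window_end for d in distal)
            intended = set(distal)
            bystanders = tuple(
                sorted(
                    d
                    for d in range(editor.window_start, editor.window_end + 1)
                    if d not in intended
                    and spacer[_i5_from_distal(d, L, pam.side)] == editor.source_base
                )
            )
            g_start = context.genomic_start + ws
            g_end = context.genomic_start + we - 1
            edits = tuple(
                (context.genomic_start + o, f, t) for o, f, t in context.edits
            )
            out.append(
                GuideCandidate(
                    guide_id="",
                    request_id="",
                    editor_name=editor.name,
                    pam_name=pam.name,
                    spacer=spacer,
                    pam_observed=pam_obs,
                    strand=strand,
                    chromosome=context.chromosome,
                    protospacer_start=g_start,
                    protospacer_end=g_end,
                    edited_offset=distal[0],
                    in_window=in_window,
                    bystander_offsets=bystanders,
                    polyT_length=annotate_polyT(spacer),
                    edits=edits,
                    intended_offsets=tuple(sorted(intended)),
                    resulting_residue=context.resulting_residue,
                )
            )
    return out


# ---------------------------------------------------------------------------
# context construction
# ---------------------------------------------------------------------------

def _flank(cfg: RunConfig) -> int:
    return cfg.guide_length + max((len(p) for p in cfg.pams), default=0)


def _fetch_context(
    genome: GenomeBundle, chromosome: str, lo: int, hi: int, flank: int
) -> tuple[int, str]:
    """Plus-strand slice [lo-flank, hi+flank] clipped to the chromosome."""
    clen = genome.chromosome_length(chromosome)
    start = max(1, lo - flank)
    end = min(clen, hi + flank)
    return start, fetch_sequence(genome, chromosome, start, end, "+")


def build_design_context(
    req: MutationRequest, genome: GenomeBundle, cfg: RunConfig
) -> list[DesignContext] | UnreachableRequest:
    """Design contexts for a validated request, one per achievable edit plan.

    ``model`` mode edits the reference background ref->alt; ``correct`` mode
    first substitutes the alternative allele into the context and designs the
    reverting alt->ref edit.  Returns an UnreachableRequest when no configured
    editor chemistry can perform the required conversion.
    """
    flank = _flank(cfg)
    if req.format == "nucleotide":
        if req.mode == "model":
            from_b, to_b = req.ref_base, req.alt_base
        else:
            from_b, to_b = req.alt_base, req.ref_base
        reachable = any(
            _chemistry_strand_ok(e, from_b, to_b, s) for e in cfg.editors for s in "+-"
        )
        if not reachable:
            return UnreachableRequest(
                req.request_id, "conversion not offered by any configured editor"
            )
        start, seq = _fetch_context(genome, req.chromosome, req.position, req.position, flank)
        off = req.position - start
        if req.mode == "correct":
            seq = seq[:off] + req.alt_base + seq[off + 1 :]
        return [DesignContext(req.chromosome, start, seq, ((off, from_b, to_b),))]

    # amino-acid request: one context per codon edit plan per editor chemistry
    tx = genome.transcripts[req.transcript_id]
    triplet = codon_genomic_location(tx, req.residue_position)
    ref_codon = codon_sequence(genome, tx, req.residue_position)
    if req.mode == "model":
        base_codon, target_residue = ref_codon, req.alt_residue
    else:
        base_codon = minimal_hamming_codon(req.alt_residue, ref_codon)
        target_residue = req.ref_residue

    seen_chemistries = set()
    plans: list[tuple[BaseEditorSpec, CodonEditPlan]] = []
    for editor in cfg.editors:
        eplans = aa_edit_candidates(base_codon, target_residue, editor, req.request_id)
        eplans = apply_filters(eplans, cfg.substitution_matrix, cfg.mutation_class)
        for p in eplans:
            plans.append((editor, p))
        seen_chemistries.add((editor.source_base, editor.target_base))
    if not plans:
        return UnreachableRequest(
            req.request_id, "conversion not offered by any configured editor"
        )

    positions = [p for _, p, _ in triplet]
    lo, hi = min(positions), max(positions)
    contexts: list[DesignContext] = []
    for editor, plan in plans:
        start, seq = _fetch_context(genome, tx.chromosome, lo, hi, flank)
        seq_list = list(seq)
        # install the edited background (correct mode) codon base by base
        for k in range(3):
            _, gpos, strand = triplet[k]
            b = base_codon[k] if strand == "+" else complement_base(base_codon[k])
            seq_list[gpos - start] = b
        seq = "".join(seq_list)
        edits = []
        for k in plan.codon_positions:  # 1..3 translation order
            _, gpos, strand = triplet[k - 1]
            f = base_codon[k - 1]
            t = plan.edited_codon[k - 1]
            if strand == "-":
                f, t = complement_base(f), complement_base(t)
            edits.append((gpos - start, f, t))
        edits.sort(key=lambda e: e[0])
        offs = [o for o, _, _ in edits]
        if max(offs) - min(offs) >= cfg.guide_length:
            continue  # codon split too wide for one contiguous protospacer
        contexts.append(
            DesignContext(
                tx.chromosome,
                start,
                seq,
                tuple(edits),
                resulting_residue=plan.resulting_residue,
            )
        )
    if not contexts:
        return UnreachableRequest(
            req.request_id, "edited bases cannot share one contiguous protospacer"
        )
    return contexts


def design_guides_for_request(
    req: MutationRequest, genome: GenomeBundle, cfg: RunConfig
) -> list[GuideCandidate] | UnreachableRequest:
    """All candidates for one request across every (editor, PAM) combination."""
    contexts = build_design_context(req, genome, cfg)
    if isinstance(contexts, UnreachableRequest):
        return contexts
    out: list[GuideCandidate] = []
    seen = set()
    for ctx in contexts:
        for editor in cfg.editors:
            for pam in cfg.pams:
                for cand in scan_protospacers(ctx, editor, pam, cfg.guide_length):
                    key = (
                        cand.editor_name,
                        cand.pam_name,
                        cand.chromosome,
                        cand.protospacer_start,
                        cand.strand,
                        cand.edits,
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    gid = (
                        f"{req.request_id}|{cand.editor_name}|{cand.pam_name}|"
                        f"{cand.chromosome}:{cand.protospacer_start}:{cand.strand}"
                        f":{cand.edited_offset}"
                    )
                    out.append(
                        _with(cand, guide_id=gid, request_id=req.request_id)
                    )
    if not out:
        return UnreachableRequest(
            req.request_id, "no protospacer placement with a matching PAM"
        )
    return out


def _with(cand: GuideCandidate, **kw) -> GuideCandidate:
    from dataclasses import replace

    return replace(cand, **kw)


# ---------------------------------------------------------------------------
# control guides
# ---------------------------------------------------------------------------

def design_positive_controls(
    tx, genome: GenomeBundle, editor: BaseEditorSpec, pam: PamSpec, cfg: RunConfig, n: int
) -> list[GuideCandidate]:
    """Up to ``n`` guides whose in-window edit creates a premature stop codon.

    Codons are visited in ascending residue order; only in-window candidates
    qualify (a nonsense control must actually edit).
    """
    out: list[GuideCandidate] = []
    flank = _flank(cfg)
    for residue in range(2, tx.n_residues):  # skip start codon and stop
        if len(out) >= n:
            break
        codon = codon_sequence(genome, tx, residue)
        triplet = codon_genomic_location(tx, residue)
        for plan in aa_edit_candidates(codon, "*", editor):
            positions = [p for _, p, _ in triplet]
            start, seq = _fetch_context(genome, tx.chromosome, min(positions), max(positions), flank)
            edits = []
            for k in plan.codon_positions:
                _, gpos, strand = triplet[k - 1]
                f, t = codon[k - 1], plan.edited_codon[k - 1]
                if strand == "-":
                    f, t = complement_base(f), complement_base(t)
                edits.append((gpos - start, f, t))
            edits.sort(key=lambda e: e[0])
            if max(o for o, _, _ in edits) - min(o for o, _, _ in edits) >= cfg.guide_length:
                continue
            ctx = DesignContext(tx.chromosome, start, seq, tuple(edits), "*")
            for cand in scan_protospacers(ctx, editor, pam, cfg.guide_length):
                if not cand.in_window:
                    continue
                gid = (
                    f"posctrl|{tx.transcript_id}:{residue}|{editor.name}|{pam.name}|"
                    f"{cand.chromosome}:{cand.protospacer_start}:{cand.strand}"
                )
                out.append(
                    _with(cand, guide_id=gid, request_id=f"posctrl:{tx.transcript_id}:{residue}")
                )
                if len(out) >= n:
                    break
            if len(out) >= n:
                break
    return out[:n]


def design_negative_controls(
    genome: GenomeBundle,
    editor: BaseEditorSpec,
    pam: PamSpec,
    cfg: RunConfig,
    n: int,
    seed: int,
) -> list[GuideCandidate]:
    """``n`` guides with valid PAMs but zero editable bases in the window.

    Sites are collected by a deterministic genome scan and sampled with a
    seeded generator; if fewer than ``n`` exist, all found are returned.
    """
    L = cfg.guide_length
    pl = len(pam)
    sites: list[GuideCandidate] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        for strand in "+-":
            for ws in range(0, len(seq) - L + 1):
                pam_right = (pam.side == "three_prime") == (strand == "+")
                ps, pe = (ws + L, ws + L + pl) if pam_right else (ws - pl, ws)
                if ps < 0 or pe > len(seq):
                    continue
                spacer_plus = seq[ws : ws + L]
                pam_plus = seq[ps:pe]
                if "N" in spacer_plus or "N" in pam_plus:
                    continue
                spacer = spacer_plus if strand == "+" else reverse_complement(spacer_plus)
                pam_obs = pam_plus if strand == "+" else reverse_complement(pam_plus)
                if not pam_matches(pam.pattern, pam_obs):
                    continue
                window = [
                    spacer[_i5_from_distal(d, L, pam.side)]
                    for d in range(editor.window_start, editor.window_end + 1)
                ]
                if editor.source_base in window:
                    continue
                sites.append(
                    GuideCandidate(
                        guide_id=f"negctrl|{editor.name}|{pam.name}|{chrom}:{ws + 1}:{strand}",
                        request_id="negctrl",
                        editor_name=editor.name,
                        pam_name=pam.name,
                        spacer=spacer,
                        pam_observed=pam_obs,
                        strand=strand,
                        chromosome=chrom,
                        protospacer_start=ws + 1,
                        protospacer_end=ws + L,
                        edited_offset=0,
                        in_window=False,
                        bystander_offsets=(),
                        polyT_length=annotate_polyT(spacer),
                        edits=(),
                    )
                )
    rng = np.random.default_rng(seed)
    if len(sites) <= n:
        if len(sites) < n:
            warnings.warn(
                f"only {len(sites)} negative-control sites exist for "
                f"{editor.name}/{pam.name}; requested {n}",
                stacklevel=2,
            )
        return sites
    idx = sorted(rng.choice(len(sites), size=n, replace=False).tolist())
    return [sites[i] for i in idx]
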