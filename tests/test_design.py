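"""Guide enumeration: placements, windows, strands, controls, replay."""

import pytest

from bedesign.design import (
    DesignContext,
    UnreachableRequest,
    annotate_polyT,
    build_design_context,
    design_guides_for_request,
    design_negative_controls,
    design_positive_controls,
    scan_protospacers,
)
from bedesign.genome import GenomeBundle, codon_sequence, fetch_sequence
from bedesign.mutations import MutationRequest, aa_edit_candidates
from bedesign.registry import (
    BaseEditorSpec,
    PamSpec,
    RunConfig,
    builtin_editors,
    reverse_complement,
    translate_codon,
)

TARGET_AID = BaseEditorSpec("Target-AID", "C", "T", 2, 4)
ABE = BaseEditorSpec("ABE7.10", "A", "G", 4, 7)
NGG = PamSpec("NGG", "NGG", "three_prime")


@pytest.mark.parametrize(
    "spacer,expected",
    [("GTTTTGACGTACGTACGTAC", 4), ("ACGACGACGACGACGACGAC", 0), ("T" * 20, 20)],
)
def test_annotate_polyT(spacer, expected):
    assert annotate_polyT(spacer) == expected


def _context_with_planted_site():
    """60-nt context: target C at spacer window position 3 of Target-AID,
    i.e. 2 nt from the spacer's 5' end, with an AGG PAM 3' of the spacer."""
    spacer = "GACTGACTGACTGACTGACT".replace("C", "G")  # no stray C
    spacer = "GATTGATTGATTGATTGATT"
    spacer = spacer[:2] + "C" + spacer[3:]  # C at position 3
    left = "ATATATATATATATATATAT"
    right = "AGG" + "ATATATATATATATATA"
    seq = left + spacer + right
    target_off = len(left) + 2
    return seq, target_off, spacer


def test_hand_built_context_yields_exact_candidate():
    seq, target_off, spacer = _context_with_planted_site()
    ctx = DesignContext("c1", 1001, seq, ((target_off, "C", "T"),))
    cands = scan_protospacers(ctx, TARGET_AID, NGG, 20)
    in_window = [c for c in cands if c.in_window]
    assert len(in_window) == 1
    c = in_window[0]
    assert c.spacer == spacer
    assert c.strand == "+"
    assert c.edited_offset == 3
    assert c.pam_observed == "AGG"
    assert c.protospacer_start == 1001 + len("ATATATATATATATATATAT")
    # spacer recorded equals the strand-aware genome fetch of its interval
    assert seq[c.protospacer_start - 1001 : c.protospacer_end - 1000] == c.spacer


def test_pam_ablated_context_yields_nothing():
    seq, target_off, _ = _context_with_planted_site()
    seq = seq.replace("AGG", "ATT")
    ctx = DesignContext("c1", 1001, seq, ((target_off, "C", "T"),))
    assert [c for c in scan_protospacers(ctx, TARGET_AID, NGG, 20) if c.in_window] == []


def test_a_to_g_with_t_on_plus_designs_minus_strand_only():
    # plus strand shows T at the target: ABE must act on the minus strand.
    # The only PAM is the CCA at plus 11..13, i.e. TGG on the minus strand
    # adjacent to the minus spacer spanning plus 14..33.
    seq = "GAGAGAGAGA" + "CCA" + "GAGAGAGAGAG" + "T" + "GAGAGAGA" + "GAGAGAGAGA"
    off = 24
    assert seq[off] == "T"
    ctx = DesignContext("c1", 500, seq, ((off, "T", "C"),))
    cands = scan_protospacers(ctx, ABE, NGG, 20)
    assert cands and all(c.strand == "-" for c in cands)
    assert all(c.pam_observed == "TGG" for c in cands)


def test_out_of_window_candidates_emitted_and_flagged():
    seq, target_off, _ = _context_with_planted_site()
    ctx = DesignContext("c1", 1001, seq, ((target_off, "C", "T"),))
    cands = scan_protospacers(ctx, TARGET_AID, NGG, 20)
    flags = {c.in_window for c in cands}
    assert flags == {True, False} or flags == {True}
    for c in cands:
        assert c.in_window == (TARGET_AID.window_start <= c.edited_offset <= TARGET_AID.window_end)


def test_bystander_annotation():
    # two C's inside the window; targeting one annotates the other
    spacer = "GACGATTGATTGATTGATTG"  # C at positions 3 (target) and... build explicitly
    spacer = "GTCCATTGATTGATTGATTG"  # C at 3 and 4
    seq = "ATATATATATATATATATAT" + spacer + "AGG" + "ATATATATATATATATA"
    off = 20 + 2  # the C at spacer position 3
    ctx = DesignContext("c1", 1, seq, ((off, "C", "T"),))
    cands = [c for c in scan_protospacers(ctx, TARGET_AID, NGG, 20) if c.in_window]
    exact = [c for c in cands if c.edited_offset == 3]
    assert exact and exact[0].bystander_offsets == (4,)


def _nuc_cfg(**kw):
    kw.setdefault("editors", builtin_editors())
    return RunConfig(**kw)


class TestDesignContext:
    def test_model_mode_uses_reference(self, small_genome):
        seq = small_genome.sequences["chr1"]
        pos = seq.index("C", 100) + 1
        req = MutationRequest("r", "nucleotide", "model", chromosome="chr1",
                              position=pos, ref_base="C", alt_base="T")
        ctxs = build_design_context(req, small_genome, _nuc_cfg())
        assert not isinstance(ctxs, UnreachableRequest)
        ctx = ctxs[0]
        assert ctx.seq[ctx.target_offset] == "C"
        assert ctx.edits[0][1:] == ("C", "T")

    def test_correct_mode_substitutes_alt(self, small_genome):
        seq = small_genome.sequences["chr1"]
        pos = seq.index("G", 200) + 1
        req = MutationRequest("r", "nucleotide", "correct", chromosome="chr1",
                              position=pos, ref_base="G", alt_base="A")
        ctxs = build_design_context(req, small_genome, _nuc_cfg(mode="correct"))
        ctx = ctxs[0]
        assert ctx.seq[ctx.target_offset] == "A"  # mutant background installed
        assert ctx.edits[0][1:] == ("A", "G")  # design reverts alt -> ref

    def test_chemistry_mismatch_unreachable(self, small_genome):
        seq = small_genome.sequences["chr1"]
        pos = seq.index("C", 100) + 1
        cbe_only = [BaseEditorSpec("cbe", "C", "T", 2, 4)]
        # correcting ref C / alt T needs T->C: no CBE chemistry offers it
        req = MutationRequest("r", "nucleotide", "correct", chromosome="chr1",
                              position=pos, ref_base="C", alt_base="T")
        out = build_design_context(req, small_genome, _nuc_cfg(mode="correct", editors=cbe_only))
        assert isinstance(out, UnreachableRequest)
        assert "not offered" in out.reason


def test_predicted_edit_replay_on_genome(small_genome, small_recipe):
    """Substituting each guide's predicted edits into the genome yields the
    requested base at the target."""
    from bedesign.fixtures import generate_mutations

    df = generate_mutations(small_genome, small_recipe).head(12)
    cfg = _nuc_cfg()
    n_checked = 0
    for row in df.itertuples(index=False):
        req = MutationRequest(row.request_id, "nucleotide", "model",
                              chromosome=row.chromosome, position=int(row.position),
                              ref_base=row.ref_base, alt_base=row.alt_base)
        designed = design_guides_for_request(req, small_genome, cfg)
        if isinstance(designed, UnreachableRequest):
            continue
        for g in designed:
            seqs = {c: list(s) for c, s in small_genome.sequences.items()}
            for pos, f, t in g.edits:
                assert seqs[g.chromosome][pos - 1] == f
                seqs[g.chromosome][pos - 1] = t
            assert seqs[row.chromosome][int(row.position) - 1] == row.alt_base
            n_checked += 1
    assert n_checked > 0


def test_strand_symmetry_under_genome_reversal():
    """Designing against the reverse-complemented genome yields the mirrored
    candidate set."""
    seq = ("ATGCTAGCTAGGATCCTTGACCATGGTACCAATCGTTAGCATGCCTAGGATCGATCGTAGCTAACG"
           "GTTACCGGATCCATGGCAATTGCAGGCTAGCTAGCAT")
    n = len(seq)
    pos = seq.index("C", 40) + 1
    g1 = GenomeBundle({"c": seq})
    g2 = GenomeBundle({"c": reverse_complement(seq)})
    cfg = _nuc_cfg()
    req1 = MutationRequest("r", "nucleotide", "model", chromosome="c", position=pos,
                           ref_base="C", alt_base="T")
    req2 = MutationRequest("r", "nucleotide", "model", chromosome="c", position=n - pos + 1,
                           ref_base="G", alt_base="A")
    d1 = design_guides_for_request(req1, g1, cfg)
    d2 = design_guides_for_request(req2, g2, cfg)
    if isinstance(d1, UnreachableRequest):
        assert isinstance(d2, UnreachableRequest)
        return
    key1 = sorted((c.editor_name, c.pam_name, c.spacer, c.pam_observed,
                   n - c.protospacer_end + 1, "-" if c.strand == "+" else "+",
                   c.edited_offset) for c in d1)
    key2 = sorted((c.editor_name, c.pam_name, c.spacer, c.pam_observed,
                   c.protospacer_start, c.strand, c.edited_offset) for c in d2)
    assert key1 == key2


class TestControls:
    def test_positive_controls_create_stop_on_replay(self, small_genome):
        cfg = _nuc_cfg()
        pam = cfg.pams[0]
        editor = cfg.editors[0]  # Target-AID
        found = 0
        for tx in small_genome.transcripts.values():
            controls = design_positive_controls(tx, small_genome, editor, pam, cfg, n=3)
            for g in controls:
                assert g.in_window
                seqs = {c: list(s) for c, s in small_genome.sequences.items()}
                for pos, f, t in g.edits:
                    assert seqs[g.chromosome][pos - 1] == f
                    seqs[g.chromosome][pos - 1] = t
                edited = small_genome.copy_with_sequences(
                    {c: "".join(s) for c, s in seqs.items()}
                )
                residue = int(g.request_id.rsplit(":", 1)[1])
                assert translate_codon(codon_sequence(edited, tx, residue)) == "*"
                found += 1
        assert found > 0

    def test_positive_controls_zero_n(self, small_genome):
        cfg = _nuc_cfg()
        tx = next(iter(small_genome.transcripts.values()))
        assert design_positive_controls(tx, small_genome, cfg.editors[0], cfg.pams[0], cfg, 0) == []

    def test_abe_cannot_create_stop_from_sense_codons(self):
        """Single-strand A->G subsets never turn a sense codon into a stop."""
        abe = ABE
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    codon = a + b + c
                    if translate_codon(codon) == "*":
                        continue
                    assert aa_edit_candidates(codon, "*", abe) == []

    def test_negative_controls_lack_editable_window_bases(self, small_genome):
        cfg = _nuc_cfg()
        editor, pam = cfg.editors[0], cfg.pams[0]
        controls = design_negative_controls(small_genome, editor, pam, cfg, n=8, seed=3)
        assert controls
        for g in controls:
            window = [
                g.spacer[d - 1] if pam.side == "three_prime" else g.spacer[len(g.spacer) - d]
                for d in range(editor.window_start, editor.window_end + 1)
            ]
            assert editor.source_base not in window
            # spacer really is the genomic sequence at its coordinates
            assert fetch_sequence(
                small_genome, g.chromosome, g.protospacer_start, g.protospacer_end, g.strand
            ) == g.spacer

    def test_negative_controls_deterministic(self, small_genome):
        cfg = _nuc_cfg()
        editor, pam = cfg.editors[0], cfg.pams[0]
        a = design_negative_controls(small_genome, editor, pam, cfg, n=5, seed=9)
        b = design_negative_controls(small_genome, editor, pam, cfg, n=5, seed=9)
        assert [g.guide_id for g in a] == [g.guide_id for g in b]

    def test_negative_controls_impossible_genome(self):
        # with the window widened to the full spacer, a CG-repeat genome
        # presents an editable C in every window on both strands
        g = GenomeBundle({"c": "CG" * 100})
        editor = BaseEditorSpec("cbe", "C", "T", 1, 20)
        cfg = RunConfig(editors=[editor], pams=[PamSpec("NG", "NG")])
        with pytest.warns(UserWarning):
            out = design_negative_controls(g, editor, cfg.pams[0], cfg, n=3, seed=1)
        assert out == []
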