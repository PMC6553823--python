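"""Mutation parsing/validation and codon-level edit planning."""

import numpy as np
import pytest

from conftest import brute_force_codon_edits

from bedesign.genome import ValidationError
from bedesign.mutations import (
    aa_edit_candidates,
    apply_filters,
    minimal_hamming_codon,
    parse_mutation_table,
    validate_request,
    MutationRequest,
)
from bedesign.registry import BaseEditorSpec, ConfigError, RunConfig, translate_codon

CBE = BaseEditorSpec("cbe", "C", "T", 2, 4)
ABE = BaseEditorSpec("abe", "A", "G", 4, 7)


def _cfg(**kw):
    return RunConfig(**kw)


class TestParsing:
    def test_valid_nucleotide_rows(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "# comment\nrequest_id\tchromosome\tposition\tref_base\talt_base\n"
            "r1\tchr1\t100\tC\tT\nr2\tchr1\t200\tA\tG\nr3\tchr2\t50\tG\tA\n"
        )
        reqs, rejects = parse_mutation_table(p, _cfg())
        assert len(reqs) == 3 and rejects.empty
        assert reqs[0].substitution == ("C", "T")

    def test_noop_row_rejected_with_reason(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "request_id\tchromosome\tposition\tref_base\talt_base\nr1\tchr1\t100\tC\tC\n"
        )
        reqs, rejects = parse_mutation_table(p, _cfg())
        assert reqs == []
        assert rejects.iloc[0]["reason"] == "no-op substitution"

    def test_invalid_residue_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "request_id\ttranscript_id\tresidue_position\tref_residue\talt_residue\n"
            "r1\ttx1\t5\tB\tQ\n"
        )
        reqs, rejects = parse_mutation_table(p, _cfg(mutation_format="amino_acid"))
        assert reqs == []
        assert rejects.iloc[0]["reason"] == "invalid residue"

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("request_id\tchromosome\tposition\tref_base\nr1\tchr1\t1\tC\n")
        with pytest.raises(ValidationError, match="alt_base"):
            parse_mutation_table(p, _cfg())

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("")
        with pytest.raises(ValidationError):
            parse_mutation_table(p, _cfg())


class TestValidation:
    def test_fixture_mutations_validate(self, small_genome, small_recipe):
        from bedesign.fixtures import generate_mutations

        df = generate_mutations(small_genome, small_recipe)
        for row in df.head(10).itertuples(index=False):
            req = MutationRequest(
                row.request_id, "nucleotide", "model",
                chromosome=row.chromosome, position=int(row.position),
                ref_base=row.ref_base, alt_base=row.alt_base,
            )
            assert validate_request(req, small_genome) is req

    def test_reference_mismatch_reported(self, small_genome):
        pos = 50
        observed = small_genome.sequences["chr1"][pos - 1]
        wrong = "ACGT".replace(observed, "")[0]
        req = MutationRequest(
            "r", "nucleotide", "model", chromosome="chr1", position=pos,
            ref_base=wrong, alt_base=observed,
        )
        with pytest.raises(ValidationError, match=f"expected {wrong} .*observed {observed}"):
            validate_request(req, small_genome)

    def test_unknown_transcript(self, small_genome):
        req = MutationRequest(
            "r", "amino_acid", "model", transcript_id="nope", residue_position=2,
            ref_residue="Q", alt_residue="L",
        )
        with pytest.raises(ValidationError, match="not found"):
            validate_request(req, small_genome)


class TestEditPlanning:
    def test_caa_to_stop_single_plan(self):
        plans = aa_edit_candidates("CAA", "*", CBE)
        assert len(plans) == 1
        p = plans[0]
        assert p.codon_positions == (1,) and p.edited_codon == "TAA" and p.strand_of_edit == "+"

    def test_aaa_to_glu_via_abe(self):
        plans = aa_edit_candidates("AAA", "E", ABE)
        assert any(
            p.edited_codon == "GAA" and p.codon_positions == (1,) and p.strand_of_edit == "+"
            for p in plans
        )

    def test_ttt_to_gly_unreachable(self):
        assert aa_edit_candidates("TTT", "G", CBE) == []

    def test_minus_strand_presentation(self):
        # C->T editor acts as G->A on the sense codon: GAA -> AAA (E -> K)
        plans = aa_edit_candidates("GAA", "K", CBE)
        assert any(p.strand_of_edit == "-" and p.edited_codon == "AAA" for p in plans)

    @pytest.mark.parametrize("editor", [CBE, ABE])
    def test_agrees_with_brute_force_oracle(self, editor):
        rng = np.random.default_rng(42)
        codons = ["".join("ACGT"[i] for i in rng.integers(0, 4, 3)) for _ in range(40)]
        residues = list("ACDEFGHIKLMNPQRSTVWY*")
        for codon in codons:
            for target in residues:
                got = {
                    (p.strand_of_edit, p.edited_codon)
                    for p in aa_edit_candidates(codon, target, editor)
                }
                want = brute_force_codon_edits(
                    codon, target, editor.source_base, editor.target_base
                )
                assert got == want, (codon, target)

    def test_plan_replay_reconstructs_edited_codon(self):
        from bedesign.registry import complement_base

        for codon in ("CCA", "ACA", "CAC", "GGG"):
            for target in "ACDEFGHIKLMNPQRSTVWY*":
                for p in aa_edit_candidates(codon, target, CBE):
                    src = CBE.source_base if p.strand_of_edit == "+" else complement_base(CBE.source_base)
                    tgt = CBE.target_base if p.strand_of_edit == "+" else complement_base(CBE.target_base)
                    replay = list(p.original_codon)
                    for k in p.codon_positions:
                        assert replay[k - 1] == src
                        replay[k - 1] = tgt
                    assert "".join(replay) == p.edited_codon


class TestFilters:
    def test_synonymous_excludes_stop_gain(self):
        plans = aa_edit_candidates("CAA", "*", CBE)
        assert apply_filters(plans, None, "synonymous") == []

    def test_matrix_allows_pair(self):
        plans = aa_edit_candidates("CAA", "*", CBE)
        assert apply_filters(plans, [("Q", "*")], "any") == plans
        assert apply_filters(plans, [("Q", "L")], "any") == []

    def test_no_filters_is_identity(self):
        plans = aa_edit_candidates("CAA", "*", CBE)
        assert apply_filters(plans, None, "any") == plans

    def test_invalid_matrix_residue(self):
        with pytest.raises(ConfigError):
            apply_filters([], [("Q", "Z")], "any")


class TestMinimalHammingCodon:
    def test_prefers_closest_codon(self):
        # from CAA (Q), a Lys codon at distance 1 is AAA
        assert minimal_hamming_codon("K", "CAA") == "AAA"

    def test_lexicographic_tie_break(self):
        # Leu codons at distance 1 from CAA: CTA; distance-1 unique
        assert minimal_hamming_codon("L", "CAA") == "CTA"
        # stop codons from TAT: TAA and TAG both distance 1 -> TAA wins
        assert minimal_hamming_codon("*", "TAT") == "TAA"

    def test_result_codes_residue(self):
        for res in "ACDEFGHIKLMNPQRSTVWY*":
            assert translate_codon(minimal_hamming_codon(res, "ATG")) == res
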