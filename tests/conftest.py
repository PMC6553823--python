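"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force (per-position
scans, exhaustive enumeration) so they share no algorithmic structure with
the implementations they check.
"""

from __future__ import annotations

from itertools import product

import pytest

from bedesign.fixtures import FixtureRecipe, generate_genome
from bedesign.genome import GenomeBundle, TranscriptModel
from bedesign.registry import PamSpec, pam_matches, reverse_complement


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def naive_offtarget_scan(
    bundle: GenomeBundle, spacer: str, pam: PamSpec, max_mismatches: int
) -> set[tuple]:
    """Position-by-position scan of both strands; the off-target oracle.

    Returns {(chromosome, start, end, strand, mismatch_offsets)} with offsets
    in the PAM-distal 1-based convention.
    """
    L, pl = len(spacer), len(pam.pattern)
    hits = set()
    for chrom, seq in bundle.sequences.items():
        n = len(seq)
        for strand in "+-":
            for start in range(1, n - L + 2):
                if (pam.side == "three_prime") == (strand == "+"):
                    ps, pe = start + L, start + L + pl - 1
                else:
                    ps, pe = start - pl, start - 1
                if ps < 1 or pe > n:
                    continue
                pobs = seq[ps - 1 : pe]
                site = seq[start - 1 : start - 1 + L]
                if strand == "-":
                    pobs = reverse_complement(pobs)
                    site = reverse_complement(site)
                if not pam_matches(pam.pattern, pobs):
                    continue
                mm = [i for i in range(L) if site[i] != spacer[i]]
                if len(mm) > max_mismatches:
                    continue
                offs = tuple(
                    sorted((i + 1) if pam.side == "three_prime" else (L - i) for i in mm)
                )
                hits.add((chrom, start, start + L - 1, strand, offs))
    return hits


def brute_force_codon_edits(codon: str, target_residue: str, source: str, target: str):
    """Exhaustive oracle for codon-edit planning.

    Enumerates, via per-position choice vectors rather than subsets, every
    single-strand conversion of source->target bases yielding the target
    residue.  Returns {(strand, edited_codon)}.
    """
    from bedesign.registry import complement_base, translate_codon

    out = set()
    for strand in "+-":
        s = source if strand == "+" else complement_base(source)
        t = target if strand == "+" else complement_base(target)
        choices = [(c, t) if c == s else (c,) for c in codon]
        for combo in product(*choices):
            edited = "".join(combo)
            if edited != codon and translate_codon(edited) == target_residue:
                out.add((strand, edited))
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_recipe() -> FixtureRecipe:
    return FixtureRecipe(
        seed=7,
        n_chromosomes=2,
        chromosome_length=6000,
        n_genes=6,
        gene_length=300,
        n_mutations=30,
    )


@pytest.fixture(scope="session")
def small_genome(small_recipe) -> GenomeBundle:
    return generate_genome(small_recipe)


@pytest.fixture()
def toy_plus_transcript() -> tuple[GenomeBundle, TranscriptModel]:
    """A hand-built 60-nt chromosome with one 9-codon + strand CDS at 11..37.

    CDS: ATG CAA CCC AAA GGG TTT CAC TAC TAA  (M Q P K G F H Y *)
    """
    cds = "ATGCAACCCAAAGGGTTTCACTACTAA"
    seq = "GGATTACGTA" + cds + "GTACGTACGTACGTACGTACGTA"
    tx = TranscriptModel("txA.t1", "c1", "+", ((11, 11 + len(cds) - 1),))
    bundle = GenomeBundle(
        {"c1": seq}, {"c1": [(11, 11 + len(cds) - 1, "+", "txA")]}, {"txA.t1": tx}
    )
    return bundle, tx


@pytest.fixture()
def toy_minus_transcript() -> tuple[GenomeBundle, TranscriptModel]:
    """Same CDS on the minus strand."""
    cds = "ATGCAACCCAAAGGGTTTCACTACTAA"
    plus = reverse_complement(cds)
    seq = "GGATTACGTA" + plus + "GTACGTACGTACGTACGTACGTA"
    tx = TranscriptModel("txB.t1", "c1", "-", ((11, 11 + len(cds) - 1),))
    bundle = GenomeBundle(
        {"c1": seq}, {"c1": [(11, 11 + len(cds) - 1, "-", "txB")]}, {"txB.t1": tx}
    )
    return bundle, tx
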