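# bedesign

Design libraries of CRISPR **base-editing** guide RNAs (gRNAs) against an
annotated genome, and score every guide *a priori* with a multiplicative
off-target penalty system.

Base editors (BEs) — deaminases fused to a nuclease-dead Cas9 — convert one
base into another without a double-strand break: cytosine base editors (CBEs,
e.g. Target-AID, BE3) perform C•G→T•A, adenine base editors (ABEs, e.g.
ABE7.10) perform A•T→G•C. Each editor acts efficiently only inside an
*activity window*, a short range of spacer positions, and requires a PAM
(e.g. NGG) adjacent to the protospacer. Designing a library of guides for
hundreds of targeted substitutions — while tracking strands, windows, PAMs,
bystander bases and off-target sites — is the bookkeeping problem this
package solves, for arbitrary editor chemistries, arbitrary IUPAC PAMs on
either side of the spacer, and arbitrary guide lengths.

## What it does

* **Inputs**: a genome (FASTA) + annotation (GFF3), and a tab-separated
  mutation table in either *nucleotide* form (chromosome, position, ref,
  alt) or *amino-acid* form (transcript id, residue position, ref, alt).
  Either table can be processed in **model** mode (install the mutation on
  the reference background) or **correct** mode (revert an alternative
  allele back to the reference).
* **Design**: every placement of a spacer hosting the editable base, on both
  strands (a C→T edit on + is a G→A presentation on −), under every
  configured (editor, PAM) combination. Out-of-window placements are
  emitted and flagged — the score, not the enumerator, penalises them.
  In-window bystander source bases and poly-T stretches (Pol III
  terminators) are annotated, never silently filtered.
* **Controls**: positive controls that create premature stop codons in a
  coding region of interest, and negative controls whose activity window
  contains no editable base.
* **Off-targets**: a genome-wide search for every alignment of spacer+PAM
  with at most `max_mismatches` (default 2) spacer mismatches and an exact
  (IUPAC-degenerate) PAM match, on both strands.
* **Score**: for a guide with *n* off-target alignments,

      B = ( ∏_{a=1..n}  P_a · G_a ) · A,        0 < B ≤ 1

  where `P_a = ∏_{i=1..M_max} P_i` multiplies position-dependent mismatch
  penalties over the `M_max` mismatches of alignment *a* (`P_i` runs from
  `P_min` for PAM-proximal mismatches to `P_max` for PAM-distal ones, via a
  third-degree polynomial fitted to a position-tolerance table; for 5′ PAMs
  the position-penalty vector is reversed, and non-20-nt spacers are
  interpolated on the fitted curve), `G_a` is `G_g` for genic and `G_ig`
  for intergenic off-target sites (genic is worse, so `G_g ≤ G_ig`), and
  `A` is 1 if the editable base lies inside the activity window, `A_out`
  otherwise. An optimal guide — in-window, no off-targets — scores exactly
  **1**; every suboptimal feature multiplies the score down.

## Worked example

Generate a seeded synthetic genome with annotated genes plus 25 random
nucleotide mutations, then design and score a library:

```sh
bedesign fixtures --recipe recipe.yml --out fix     # genome.fa, genome.gff3, mutations.tsv
bedesign design --cfg params.yml --out out
```

with `recipe.yml` setting `seed: 11`, one 12 kb chromosome, 8 genes, 25
mutations, and `params.yml` pointing at the three generated files. The run
prints:

```
library: out/library.tsv
requests=25 editable=7 editability=28.0% guides_per_mutation=7.14
```

i.e. 7 of the 25 random substitutions are reachable by the default editors
(Target-AID, BE3, ABE7.10 — only C→T/G→A and A→G/T→C chemistries), and on
average 7.1 candidate placements (including flagged out-of-window ones) were
emitted per editable mutation. The library itself is a TSV, one guide per
row:

```
guide_id                          request_id editor  pam chromosome ... in_window ... n_offtargets guide_score
m00002|ABE7.10|NG|chr1:3527:+:6   m00002     ABE7.10 NG  chr1       ... True      ... 0            1.0
m00002|ABE7.10|NG|chr1:3513:+:20  m00002     ABE7.10 NG  chr1       ... False     ... 0            0.5
```

The first guide edits its A at spacer position 6 — inside ABE7.10's 4–7
window — and has no off-target alignment, so it scores the optimum 1.0; the
second hosts the same A at position 20, outside the window, and is halved by
the window penalty (`A_out = 0.5`). `out/summary.tsv` holds the
per-substitution editability table (the numbers behind a substitution-map
heat map), e.g. `A→G 3/3 edited (100%, + strand)`, `C→G 0/5 (0%)`.

`bedesign score` rescoring an existing library, `--stop-after` for partial
runs, and YAML-configurable editors, PAMs and penalties are described in
`bedesign --help` and `docs/methods.md`.

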