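# Methods

## Scope and model

`bedesign` designs candidate gRNA spacers for base-editing experiments and
assigns each a multiplicative *a priori* quality score. The procedure is
deterministic given (inputs, configuration, seed):

1. **Parse & validate.** Mutation tables are checked row by row; malformed
   rows land in a rejects report with a reason, and requests whose stated
   reference allele or residue disagrees with the genome land in the
   unreachable report. Nothing is silently dropped: every input request
   ends in exactly one of {library, unreachable report}.
2. **Plan the edit.** Nucleotide requests need one substitution. For
   amino-acid requests, every single-strand conversion of a nonempty subset
   of the codon's editable positions is enumerated (on the sense strand the
   editor converts source→target; on the antisense presentation a C→T
   editor acts as G→A), and plans whose edited codon translates to the
   requested residue are kept, subject to the optional substitution-matrix
   and synonymous/nonsynonymous filters. In *correct* mode the mutant
   background is first reconstructed; for amino-acid input the mutant codon
   is the minimal-Hamming-distance codon encoding the alternative residue,
   ties broken lexicographically — the paperwork rule we adopted because
   the input format names only the residue, not the codon.
3. **Enumerate placements.** Every spacer window hosting all intended
   edited bases, with an adjacent IUPAC-matching PAM on the same strand, on
   either strand, is emitted. Out-of-window placements are emitted with
   `in_window=False` rather than suppressed: the window penalty exists
   precisely to score them, and suppressing them would hide usable (if
   weaker) guides. Bystander source bases inside the window are annotated
   (`bystander_offsets`), and the longest poly-T run is reported (a run of
   ≥ 4 T can terminate Pol III transcription of the guide) — reported, not
   auto-filtered.
4. **Off-target search.** A vectorised rolling-Hamming scan over every
   chromosome and both strands reports all placements with an exact
   degenerate PAM match and spacer Hamming distance ≤ `max_mismatches`
   (default 2). PAM positions never consume the mismatch budget: a
   mismatched PAM abolishes recognition rather than weakening binding. The
   search's contract is exact set-equivalence with a naive per-position
   scan, which the test suite enforces on dozens of random genomes.
5. **Score** (below) and **summarise** (% editability per substitution
   pair, strand coverage, guides per editable mutation).

## Coordinate conventions

Genomic coordinates are 1-based inclusive (GFF3/Ensembl). Spacer positions
— activity windows, edited offsets, mismatch offsets — are 1-based counted
from the **PAM-distal** end, so for a 3′ PAM position 1 is the spacer's 5′
terminus. Mismatch *distance from the PAM* is `L − offset + 1` for 3′ PAMs
and equals the offset for 5′ PAMs; the 5′-PAM case is the reversal of the
position-penalty vector. BED output converts to half-open 0-based.

## The score

For a guide with `n` scored alignments, `B = (∏ P_a · G_a) · A`:

* `P_i`, the penalty for a mismatch at distance `i` from the PAM, is read
  from a third-degree polynomial least-squares fit to a
  (distance, tolerance) table, clamped into `[P_min, P_max]`. All factors
  are **multipliers in (0, 1]**: PAM-proximal mismatches are poorly
  tolerated and get the small multiplier `P_min`; PAM-distal mismatches
  retain activity and approach `P_max`. For spacer lengths other than the
  20-nt reference, the distance is rescaled by `20 / L` before evaluating
  the curve, so the fitted shape spans any spacer.
* `P_a = ∏ P_i` over the alignment's mismatches; an exact-match off-target
  has the empty product `P_a = 1` but still penalises through `G_a`.
* `G_a` is `G_g` (genic) or `G_ig` (intergenic). An interval is *genic*
  iff it overlaps any annotated `gene` feature by ≥ 1 bp — a deliberately
  binary rule; finer feature types are not consulted. Off-target edits in
  genic regions confound phenotypes more, hence `G_g ≤ G_ig`.
* `A` is `A_in` (default 1) when the editable base lies inside the activity
  window, `A_out` otherwise.
* The guide's **own intended site is excluded** from the product. It is
  identified by coordinates and strand, not by requiring a perfect match:
  in correct mode the guide is complementary to the *edited* background,
  so its own site shows the intended edits as mismatches against the
  reference. Without this exclusion no guide could reach the optimum
  B = 1, every guide being penalised by its own genic on-target site.

### Default numeric values

| parameter | default | meaning |
|---|---|---|
| `P_min` | 0.01 | multiplier for a PAM-adjacent mismatch |
| `P_max` | 1.0 | multiplier for the most PAM-distal mismatch |
| `G_g` / `G_ig` | 0.5 / 0.9 | genic / intergenic off-target multiplier |
| `A_in` / `A_out` | 1.0 / 0.5 | in-window / out-of-window multiplier |
| `max_mismatches` | 2 | off-target search budget |
| `guide_length` | 20 nt | spacer length |

The bundled position-tolerance table is a monotone synthetic stand-in
(quadratic rise from `P_min` at distance 1 to `P_max` at distance 20) with
the qualitative shape of empirical Cas9 mismatch-tolerance profiles; no
public base-editing dataset at library scale exists to fit it from, so all
of these numbers express requirement importance, are declared in the
configuration, and can be replaced wholesale (table or explicit cubic
coefficients) via the `penalty_model` config block.

Built-in editors — Target-AID (C→T, window 2–4), BE3 (C→T, 4–8), ABE7.10
(A→G, 4–7) — and PAMs (NGG, NG, both 3′) are literature-based defaults,
overridable and freely combinable; `compatible_pams` is advisory only.

## Synthetic data generator

`bedesign.fixtures` emulates the study conditions the package is validated
under: a random genome (default two 20 kb chromosomes, GC 0.40, twenty
single-exon genes of 300 nt with valid ATG…stop CDSs and no internal
stops) and 1000 randomly assigned mutations in either format and mode, all
reproducible bit-for-bit from a seed recorded in the output headers.
`plant_offtarget_sites` writes near-copies of a spacer+PAM at known
coordinates with an exact number of seeded mismatches (never in the PAM),
giving the off-target search a planted ground truth. Acceptance-style
checks scale the genome down (8–100 kb, 15–500 mutations per scenario) to
keep each scenario's runtime in seconds while exercising every stage;
these sizes are the package's own validation choices.

What the fixtures deliberately do **not** model: repeats and segmental
duplications (which dominate real off-target counts), introns/UTRs (genes
are bare single-exon CDSs; multi-exon transcripts are supported by the
coordinate mapper and covered by hand-built cases), ambiguous bases, and
realistic codon usage. Passing tests therefore demonstrate correctness of
the bookkeeping — coordinates, strands, windows, mismatch accounting,
score arithmetic — not predictive accuracy on real genomes.

## Numerical and design choices

* The cubic fit uses ordinary least squares (`numpy.polyfit`); evaluation
  clamps into `[P_min, P_max]`, which also enforces the (0, 1] score
  bound. A constant table yields a constant curve; fewer than four
  distinct distances is a configuration error.
* Candidate order is deterministic: request id, then descending score,
  then genomic coordinate, `+` before `-`.
* Multi-base codon plans (several editable positions converted on one
  strand) are designed only when all edited bases fit one contiguous
  protospacer; `in_window` then requires *every* intended offset inside
  the window. Codons split across exon junctions are mapped correctly,
  but placements whose edited bases cannot share a contiguous protospacer
  are reported unreachable with a reason code.
* Genome `N`s: a spacer or PAM containing `N` is never designed, and an
  observed `N` satisfies no PAM class; in the off-target scan an `N`
  simply counts as a mismatch.
* Negative-control sites are collected by a deterministic full scan and
  sampled with a seeded generator; if fewer than requested exist, all are
  returned with a warning.
* Determinism extends to bytes: reruns with identical inputs, config and
  seed write identical files (the provenance header records seed and a
  hash of the design parameters; input file *locations* are excluded from
  the hash so the same run in a different directory compares equal).

## Limitations

* Off-target search is ungapped (no bulges) and applies zero tolerance at
  the PAM; alternate off-target PAM recognition is not modelled.
* No on-target efficiency model (e.g. sequence-context rules) and no
  empirical fit of the penalties; the score ranks guides by design-rule
  conformity, not by measured editing rates.
* Editor efficiency inside the window is binary (in/out); bystander edits
  are annotated, not probability-weighted.
* Ensembl/remote genome retrieval is out of scope; inputs are local files.
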