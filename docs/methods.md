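# Methods

## Problem and model

`mcraprof` profiles a methanogen community from pooled, MID-tagged amplicon
reads of the *mcrA*/*mrtA* marker gene. The analysis model is deliberately
the classic one: reads are units of evidence; identical reads are combined
and their multiplicity is carried as a weight; each distinct sequence is
labelled with the species of its best local-alignment hit in an annotated
reference; and community structure and metabolic potential are
count-weighted rollups of those labels. No OTU clustering below 100 %
identity, no lowest-common-ancestor logic, and no abundance correction for
copy number or primer bias is attempted — primer bias is instead surfaced
by reporting each primer set's community separately alongside the pooled
view.

## Stages and their parameters

### Demultiplexing and length filtering

Reads are uppercased and U→T normalized on ingest. A read is binned by
exact prefix match of its MID tag (mismatch budget configurable,
default 0); with a nonzero budget, a read matching two tags equally well is
ambiguous and rejected. Tags must be pairwise distinct; the simulator
generates them with pairwise Hamming distance ≥ 3 so that no single error
can cross-assign a read. After tag removal, primer sequences are retained
in the read by default.

The length filter keeps reads **strictly longer** than 100 bp (a 100 bp
read is discarded). Sub-cutoff reads are overwhelmingly primer-dimer
artifacts; the cutoff is a flag (`--min-len`) so the inclusive convention
is also reachable.

### Dereplication

Identity is exact full-length string equality. Representatives are sorted
by descending count with lexicographic tie-break on the sequence, making
names of the form `<PRIMER>_<rank 04d>_<count>` deterministic across runs.
The delimiter and component order of the name are an artifact convention;
the three components (primer code, ordinal, combined-read count) are the
contract.

### Local alignment and E-values

The search is a full affine-gap Smith–Waterman dynamic program (numba-jitted)
with the default scheme **+1 match, −2 mismatch, gap open −5, gap
extend −2**; a gap of length L costs `gap_open + L·gap_extend`. IUPAC
ambiguity codes in reference sequences count as identities when the query
base is in their allowed set. Both query strands are searched; the database
is stored in one orientation. Ties among maximal-scoring alignments are
broken deterministically (lowest query start, then subject start; traceback
prefers diagonal moves, then gaps in the subject direction being closed
first).

Expectation values use ungapped Karlin–Altschul statistics,
`E = K·m·n·e^(−λS)`, with `m` = query length and `n` = total database
residues. λ is the positive root of `Σᵢⱼ pᵢpⱼ e^(λ sᵢⱼ) = 1` found by
bracketed Brent root-finding (residual < 10⁻⁹); under uniform base
composition and the default scheme λ ≈ 1.3327. K defaults to 0.621, the
published ungapped constant for this scheme, and is configurable. Two
simplifications relative to NCBI BLAST are intentional and documented: no
effective-length (edge) correction, and no gapped-statistics fitting.
Internal scores only need to be monotone-consistent for top-hit selection,
and the downstream E-value threshold (10⁻⁶) is conservative at desk-scale
database sizes. Users wanting exact BLASTn numbers can run BLASTn and feed
the tabular output in via `parse_blast_tabular`.

### Filtering and assignment

Defaults: alignment length ≥ 50 bp (inclusive), E-value < 10⁻⁶ (strict),
percent identity ≥ 97 (inclusive), and removal of subjects whose
description or annotation matches any exclude keyword
(default `uncultured`) or whose annotation carries the uncultured flag.
Two of these deserve comment:

* The 97 % identity floor is enforced as a filter even though in the
  motivating use case it was an observed property of the surviving hits;
  enforcing it makes the output satisfy that property by construction.
  Inclusive ≥ 97 was chosen where "greater than" and "at least" readings
  both circulate; set `--min-identity 0` to disable.
* Keyword exclusion exists because environmental-clone records carry no
  physiology and would otherwise absorb top hits; an empty keyword list
  disables all description-based exclusion (including the uncultured flag),
  which is what the decoy-immunity test exercises.

Assignment is strict top hit: maximal score, ties by lower E-value, higher
identity, then lexicographically smallest accession. Queries with no
surviving hit form the class "No significant similarity found".

### Profiling

Genus is derived as the first whitespace token of the species label. Order
and genus fractions use assigned reads as denominator and sum to 1;
pathway percentages classify assigned reads by their species'
capability flags and may overlap (a species coded acetoclastic +
hydrogenotrophic + methylotrophic counts fully in all three); the
formate-capable share is also reported relative to the hydrogenotrophic
subset; the unassigned percentage uses assigned + unassigned as
denominator. Pathway codes are parsed with `2*` (hydrogenotrophic, formate
as alternate electron donor) as a single token refining `2`, so
formate-capable ⇒ hydrogenotrophic always holds. Percentages are kept at
full precision internally and rounded to integers only where a report
prints integers.

## Synthetic data: what it emulates and what it does not

The generator builds mock reference templates containing one amplicon block
per primer set — a concrete realization of the degenerate forward primer,
random filler, and the reverse complement of a realization of the reverse
primer — sized exactly to the primer set's expected amplicon length
(470/500/760 bp for the bundled ML/MCR/ME). Reads are `tag + amplicon` with
templates drawn from configured relative abundances; a configured fraction
are primer-dimer junk (tag plus random DNA, total length uniform in
[20, 100)); substitution errors are i.i.d. per base downstream of the tag
(tags are emitted intact by default, since exact-prefix demultiplexing
would otherwise only shrink every bin uniformly; a `tag_error` flag applies
errors to tags too). An optional indel rate and reverse-strand fraction
exist for stress tests but default to 0.

Degenerate primer positions are resolved from the template by default, so
an error-free run from k templates dereplicates to exactly k
representatives per primer and every amplicon is an exact substring of its
template; `resolve="random"` instead draws each degenerate position
uniformly from its allowed set, modelling a heterogeneous primer pool at
the cost of inflating the dereplicated sequence count.

What passing synthetic tests shows: the plumbing is conservative (no read
duplicated or lost), assignments recover the generating template exactly at
0–1 % substitution error, and abundance recovery is binomially consistent.
What they do not show: robustness to 454 homopolymer indel error profiles,
chimeras, real primer-binding bias, or reference databases with closely
related species whose amplicons are not separable at the marker — mock
templates share only their short primer sites, which is deliberately easier
than real *mcrA* space.

## Default study conditions used by the checks

The end-to-end checks run 3 primer sets over 4 mock templates at
read depths 60/60/30 (ML/MCR/ME), abundances 4:2:1:1, dimer fraction 0.1
where dimers are exercised, and 1 % substitution error for the noisy case —
small enough to run the full dynamic program everywhere while leaving
expected per-template counts (≥ 15 reads) comfortably testable under
3σ binomial bounds. The digester tally profile uses the bundled 35-row,
1,896-read table directly; its percentages are deterministic arithmetic.

## Numerical and degenerate-input choices

* λ root-finding brackets [10⁻¹², hi] with hi doubled until the objective
  is positive; a non-negative expected pair score is a configuration error
  (no λ exists).
* A query/subject pair with no positive-scoring local alignment yields
  score 0 with empty spans; such alignments never become hits.
* Empty bins dereplicate to empty lists; an empty tally is an error for
  rollups and pathway breakdowns (there is no community to describe).
* Zero-read or all-rejected runs still produce a consistent report; the
  conservation identities are asserted, not merely printed.

## Known limitations

* Internal E-values are not NCBI-BLAST-comparable in absolute terms (no
  edge correction, ungapped λ/K with gapped alignments); rank order of
  scores is what assignment consumes.
* Exact-match dereplication means every sequencing error creates a new
  representative; at high error rates the search stage dominates runtime.
* The uncultured-record heuristics are keyword-based; annotation quality of
  the user-supplied reference determines assignment quality.
* `per_primer_report` flags taxa detected by a single primer set but does
  not model primer-binding energetics; it reports, not explains, primer
  bias.
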