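# Methods

## Scope and model

`ple-scout` annotates the structural anatomy of *Penelope*-like
retroelements (PLEs): terminal pseudo-LTR (pLTR) arrangements, target-site
duplications (TSDs), tails, palindromes and promoter motifs, ORF defects
and asparagine-rich inserts, pLTR-framed gene-capture events with
empty-site verification, family classification, and small-RNA polarity
profiles. Because curated PLE loci are scarce and the published examples
are described by a handful of printed structural parameters, the package
pairs every detector with a seeded generator (`locus_forge`) that emits
loci built to those parameters together with exact ground truth; the test
suite and the acceptance script exercise the detectors end-to-end against
that truth.

Coordinates are 0-based half-open everywhere in memory; GFF3 output is
1-based inclusive. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); there is no global random state.

## The synthetic locus generator

A default (Pen2a-type) locus is, left to right: flank, TSD copy, the
reverse-complemented 31-bp tail, a 181-bp inverted pLTR, a 218-bp direct
pLTR whose last 36 bases are the first 12 ORF codons, the ORF body
(842 aa + stop), a second direct pLTR, the tail, the second TSD copy, and
flank. The inverted unit is the full unit truncated by 37 bp and overlaps
the direct unit by 15 bp. Other arrangements (`DD_only`,
`inverted_pair`, `solo`, `tandem_partial`) rearrange the same parts; a
`tandem_partial` second copy is reduced to a short ORF remnant plus the
terminal unit so that the remnant stays below the repeat detector's
minimum unit length and does not masquerade as an extra repeat pair.

Three constructions deserve comment:

- **The overlap mirror.** For the inverted unit to overlap the direct one,
  the shared bases must read as the unit start in one orientation and as
  part of the truncated inverted copy in the other; the generator
  therefore writes the reverse complement of the unit's first
  `overlap` bases at the truncation point. This partial mirror symmetry is
  exactly what would let a maximal inverted-repeat alignment run straight
  past the truncation point, so the five positions after the mirror region
  are constrained to mismatch their alignment partners: the inverted
  alignment stops at the annotated boundary on every seed, not merely most.
- **Maximal ground truth.** Planted boundaries are made maximal: the base
  entering each flank differs from the base that would extend the
  repeat/tail/TSD match, promoter motifs are rejection-sampled to be
  unique within the unit, and flanks are re-checked for accidental longer
  flank duplications. Without this, "the TSD is 9 bp" would only be true
  with probability ~3/4 per boundary.
- **N-rich inserts.** Insert residues are asparagine with the target
  fraction, stratified per 10-aa block (exact count per block, random
  placement within it; Asn codons split evenly between AAT and AAC,
  non-Asn positions drawn from the 59 other sense codons). Stratification
  models the *uniformly* N-rich composition of the real inserts; pure
  Bernoulli placement produces local dips below any windowed detection
  threshold and would fragment a segment that is biologically one insert.

Backgrounds and flanks are i.i.d. uniform ACGT by default — this avoids
spurious repeats that would confound detector tests — with an optional
AT-rich mode (`at_rich_flanks`) for the AT-rich-target scenario. The base
composition of real pLTRs and flanks is not modelled. Allelic pairs
diverge by per-site substitutions only (raw p-distance semantics, no
indels); the junction motif of an empty-site allele is protected from
mutation, mirroring the observed empty sites where the would-be TSD is
still intact. Small-RNA libraries draw read lengths uniformly from
25–32 nt, place a configurable fraction on the antisense strand, and
position a configurable fraction so the 5′ base is U — the piRNA-like
signature — by rejection sampling of start positions.

What the generator does *not* emulate: sequencing error, assembly gaps or
collapse of near-identical copies, nested insertions of unrelated TEs,
genuine phylogenetic decay (copies diverge by uniform substitution, not by
lineage), and indel divergence between alleles. Passing tests therefore
demonstrate correctness of the detectors' logic and exact boundary
arithmetic, not robustness to every artifact of real assemblies.

## Detectors and numerical choices

**Seed-and-extend.** All similarity searches (repeat pairs, library hits,
flank anchoring) share one primitive: exact 12-mer seeds, merged per
diagonal, extended ungapped in both directions. Extension tolerates
isolated mismatches but aborts at 5 consecutive mismatches, and the
reported boundary is trimmed back to the end of the last run of ≥8
consecutive matches. The commit rule is what makes boundaries of
high-identity repeats exact: a chance match just past a true boundary,
following a mismatch, is never committed (a chance *contiguous* match is
— which is why the generator constrains first-out-of-boundary bases).
Gapped extension is deliberately omitted at these scales; diverged copies
fragment into multiple pairs instead.

**Arrangement resolution.** Direct pairs define the full unit length;
inverted hits whose partner extends beyond an anchored direct unit are
clipped by the overhang (the overhang is tail evidence). Arrangement
labels follow the unit pattern: ≥2 direct + ≥1 inverted →
`DD_plus_inverted5p`; exactly 2 direct → `DD_only`; ≥3 direct →
`tandem_partial`; 1 direct + 1 inverted → `inverted_pair`; a single unit
(possible only with a pLTR-library scan) → `solo`; nested units → `none`
with warnings. Orientation is relative to the ORF strand; with no direct
pair, the 3′-most unit is taken as direct.

**Tails and TSDs** are exact longest-common-extension quantities: the
tail is the longest shared prefix of the sequences running off two units'
3′ ends (each read in its own orientation); a TSD is the longest suffix of
the left flank matching a prefix of the right flank, length 4–25 bp, 0
mismatches by default (published TSDs are 8–10 bp exact; a mismatch budget
exists for diverged insertions). Anchoring at the element boundary makes
the TSD candidate unique per length, so no tie-breaking is required.

**Palindromes.** An interval qualifies if for some central spacer ≤4 of
matching parity the left arm equals the reverse complement of the right
arm up to 2 mismatched pairs, with the outermost pair exact; only
intervals not strictly contained in another qualifying interval are
reported. Implementation is centre expansion; the test oracle enumerates
all intervals. A palindrome starting within 5 bp of the unit start is
flagged terminal.

**ORF defects.** Three forward-frame translations are tiled onto the
family reference protein by exact 8-aa seeds with mismatch-tolerant
ungapped extension. Frame switches between chained blocks are frameshifts;
stops inside or between matched blocks are premature stops (the in-block
scan matters: extension runs straight through an isolated stop); missing
reference prefix/suffix ≥30 aa are truncations. Deletions are analysed at
the DNA level: the left block's diagonal is scanned rightwards and the
right block's leftwards, and the overlap of the two exact extents is the
junction ambiguity, i.e. the breakpoint microhomology (≥2 bp →
microhomology-mediated deletion). This needs the reference DNA, which the
pipeline threads through; with only a reference protein the call degrades
to a plain indel. Intactness = no defects, length within ±5% of the
reference, and (for EN+ families) a GIY-YIG hit (literal GIY …8–12 aa…
YIG); RT identification beyond the placeholder motif is out of scope.

**N-rich segments** are the union of 50-aa windows with Asn fraction
≥0.25, merged as intervals and filtered to ≥100 aa (published inserts are
460–554 aa at 25–30%); each segment reports its exact composition.

**Anchored p-distance.** Unique shared 12-mers, chained by longest
increasing subsequence, same-diagonal runs merged; inter-anchor gaps
contribute per-column mismatches and length differences count as
mismatched columns. If anchors cover <20% of the shorter sequence the
pair is reported unanchorable (distance 1.0, flagged, in matrices): with
k=12 the estimator is reliable to roughly 15% divergence, which covers
the allelic (2–5%) and subfamily (~10%) regimes; more diverged pairs are
only ever compared against the coarse group cut. Symmetry is guaranteed
by canonicalising the argument order.

**Families and trees.** Copies covering ≥1/3 of the reference coding
sequence (closed threshold, integer arithmetic) enter classification.
Single-linkage clustering at distance cuts 0.10 / 0.25 / 0.45 yields
nested subfamily/family/group partitions (copies 90% identical share a
subfamily; the cuts are closed); cluster names are assigned by each
cluster's lexicographically smallest member, making output invariant to
input order. Neighbor joining is delegated to scikit-bio with taxa
canonicalised to sorted label order (deterministic tie-breaks) and
negative branch lengths clamped to zero and logged; on additive matrices
the tree reproduces the input distances exactly. Likelihood phylogenetics
and bootstrap support are non-goals.

**Small RNAs.** Reads map to both strands with ≤1 mismatch by default;
every occurrence is reported and multi-mappers carry fractional weight
1/n — repeats are the subject, and discarding multi-mappers would zero
out young copies. Windows are keyed by the read's 5′ position (lengths
vary 25–32 nt); the polarity index is (sense − antisense)/(sense +
antisense) on weighted counts, undefined (NaN) for empty windows. A
polarity switch requires a sign flip sustained for ≥3 covered windows on
each side — undefined windows are skipped, not run-breaking — which is
the signature of circularly permuted copies. Transcription is summarised
as counts per kb.

## Problem sizes

The routine validation uses desk-scale inputs: loci of ~3.5–4.5 kb,
brute-force oracle equivalence on 200 random instances per detector at
20–400 bp, 50-locus end-to-end round-trips, 10-replicate compositional
means, and 10⁴-read small-RNA libraries. These sizes put every binomial
tolerance in the test suite at or below the corresponding planted effect.

## Known limitations

- Boundary exactness holds for high-identity copies; diverged copies
  (identity ~0.9) are recovered with boundary slack of a few bp (the
  report flags differences beyond `forge.boundary_slack_bp`, default
  ±2 bp, rather than suppressing them).
- The anchored distance saturates above ~15% divergence by design;
  between-group distances are effectively "unanchorable" rather than
  numeric.
- `classify_defects` assumes the copy is collinear with the reference on
  the forward strand; inversions within a copy are not modelled.
- The empty-site verifier anchors flanks on the forward strand of the
  candidate allele; a reverse-complemented allele should be oriented
  first.
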