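# Methods

## The question the pipeline answers

Two bacterial strains share most of their gene content, yet a handful of
point mutations, truncations and deletions can flip a whole phenotype.
The pipeline takes a reference strain's annotated proteome (restricted to
a candidate gene list), asks for each protein whether the target genome
still encodes it, and — when it does not match exactly — characterizes how
it differs. The target side is deliberately *not* taken from annotation
by default: the target genome is translated in all six frames into every
potential ORF, so the comparison is robust to annotation gaps and to
start-codon misprediction in the target.

## Alignment model

Global (Needleman–Wunsch) alignment over the 20-letter amino-acid
alphabet plus `X` (unknown; translated from N-containing codons).
The scoring scheme is identity-based: `match = +1`, `mismatch = −1`,
`gap = −1` (linear). The published procedure this reimplements pins only
the calibration "an exact match scores the query protein's length"; the
penalties are the smallest integers that turn that calibration into a true
biconditional — `score(q,t) = |q|·match ⟺ t = q` — so the exact-match
existence test cannot be fooled by an alignment that trades a mismatch
against a gap pair. Proof sketch: with these values
`score = 2·matches − columns ≤ 2·min(|q|,|t|) − max(|q|,|t|) ≤ |q|`,
with equality forcing `t = q` column by column. All three values are
configurable; an affine-gap (Gotoh, open/extend) mode exists for
exploration but is off by default because nothing in the reconstructed
procedure motivates particular affine parameters. Scores are integers and
no floating point enters the DP. `X` never scores as a match, even
against `X` — conservatism of the existence test.

Traceback tie-break: diagonal over query-gap over target-gap, applied
end-to-start. This makes column lists, CIGARs, and therefore reports
byte-reproducible.

Two implementations exist side by side: the production DP (numba-jitted
two-row kernel for scores, full matrix + traceback for the reported best
alignment) and `brute_force_align`, an explicit recursion over every
global alignment, guarded to `|q|+|t| ≤ 16` and used purely as a test
oracle. They are compared on hundreds of seeded pairs in the test suite
and in the acceptance script.

## ORF enumeration

"Potential ORF" is defined as: start codons {ATG, GTG, TTG}, stop codons
{TAA, TAG, TGA}, minimum length 30 residues, both strands, three frames.
For each stop, the maximal ORF from the most upstream in-frame start since
the previous stop is emitted, plus (default on) one ORF per internal start
codon. Nested starts matter twice: a maximal ORF may begin upstream of
the true gene start whenever the upstream region happens to lack an
in-frame stop, and the ORF beginning at the *true* start is then the one
that aligns perfectly; and an N-terminally truncated protein is only
findable through an internal start. Codons containing N never match start
or stop sets. Initial ATG/GTG/TTG translate as Met (bacterial
convention, table 11). Minus-strand ORFs are reported on forward
coordinates with `start < end`, `strand = −1`. Circular genomes are
scanned with an origin overhang and deduplicated. There is deliberately
no gene-prediction scoring (no RBS models, no codon-usage likelihoods):
the ORF set is a search space, not a gene call.

## Best hit and classification

For each query the ORF with the maximal similarity score wins; ties go to
the smallest (start, strand). Two exact accelerations keep the scan
tractable without changing any result: (i) an upper bound
`min(|q|,|t|)·match + ||q|−|t||·gap` (valid whenever gap scores are
non-positive) lets the scan skip ORFs that provably cannot beat the
running best — a tie with a later ORF would lose the tie-break anyway;
(ii) an amino-acid 6-mer index optionally *orders* candidates so a
high-scoring ORF is found early and the bound bites sooner. The index
never excludes anything, which is why prefilter on/off reports are
byte-identical (a tested invariant).

Classification precedence is **identical → truncated → missing →
substituted**:

* *identical* iff `best_score = |q|·match` (exact by the biconditional);
* *truncated* if the target carries a premature stop codon in the
  reference reading frame. The check is codon-by-codon against a
  genome-anchored, frame-aligned region: the first aligned column of the
  best alignment fixes where reference codon 1 sits on the target's coding
  strand, and the region then spans the full reference frame. Anchoring
  to the genome rather than to the best ORF's own CDS matters because a
  stop near the middle of a gene splits it into a prefix ORF and a
  (post-stop) suffix ORF whose scores can tie or even favor the suffix —
  in which case the premature stop lies upstream of the best ORF and would
  be invisible in its CDS. Guards: the translated prefix before the stop
  must match the reference at ≥ 0.9 identity over ≥ 10 codons (establishes
  the frame; random hits of missing genes never pass), and the stop must
  remove ≥ 5 residues (an in-frame deletion near the C terminus shifts the
  *natural* stop a codon early, which is an indel, not a nonsense
  mutation). Truncation is tested before the missing cutoff because an
  early stop leaves a score far below it (e.g. codon 141 of 250 scores
  140 − 110 = 30 < 125); a truncated gene with additional upstream
  missense stays *truncated*, with the exchanges still listed.
* *missing* if `best_score < 0.5 · |q| · match` (`missing_frac = 0.5`,
  configurable). The published analysis never defines "missing"; 0.5 sits
  far below plausible allelic divergence between strains of one species
  and far above random-alignment noise under this scheme, but it is a
  stand-in, and how the original authors separated "missing" from "highly
  diverged" is unknown.
* *substituted* otherwise: one exchange per mismatch column, positions in
  reference coordinates, 1-based (`R51L` style). Gap columns are reported
  as indel annotations (`Q95del`, `85insV`) and excluded from the exchange
  count by default — the headline "n amino-acid exchanges" counts missense
  only, with single-residue indels noted separately; a flag
  (`count_indels_as_exchanges`) flips this, since published totals do not
  always say which convention they use.

An annotated-CDS target mode (one pseudo-ORF per annotated CDS) exists
for annotated targets; in that mode a CDS is kept at its full annotated
extent even when translation stops early, precisely so truncation
detection can see past the premature stop.

## Synthetic strain pairs

The generator emulates what the comparison procedure actually consumes: a
genome of clean protein-coding genes and a derivative carrying the five
event classes the classifier must distinguish. Ancestor genes are random
codon sequences (uniform over the 61 sense codons of table 11 — codon-
usage bias is irrelevant to classifier correctness and would add untested
parameters), ATG-initiated, internally stop-free, on random strands,
separated by uniform-random intergenic spacers. Mutations are planted on
the coding strand with one event per codon at most, never on the start
codon, and the protein-level consequence of every event is computed from
the genetic code at planting time and written to the truth table — the
scan is graded against that ledger, not against re-derived expectations.

Placement constraints keep expectations unambiguous rather than making
the task easier: random nonsense stops land at codon ≥ 31 (the orphaned
prefix must clear the 30-residue ORF floor to be discoverable at all) and
≤ L−6 (so the stop is unambiguously premature under the 5-residue-lost
guard); single-codon deletions/insertions are placed so the affected
residue differs from both neighbors (otherwise the optimal gap placement
is genuinely ambiguous and no unique expected token exists); missense
counts per gene are capped (12, and ≤ L/5) so a substituted gene cannot
drift below the missing threshold.

Default shapes shipped: a **flagship** pair (86 genes of 150–450 residues,
42 genes carrying 78 missense total, 5 whole-gene deletions, and one
pinned CAG→TAG amber nonsense at codon 141 of a 250-residue gene — the
shape of the strain comparison this package reimplements), a
**silent-only** pair (the scan must see nothing), and a small **smoke**
pair exercising every event class. The expected flagship summary is
(86 queries, 38 identical, 42 substituted, 78 exchanges, 1 truncated,
5 missing) for *any* seed.

What the synthetic pairs do **not** emulate: codon-usage and GC bias, real
intergenic structure (promoters, RBSs, terminators), overlapping genes,
paralogous families, repeats, prophages/IS elements, rearrangements, and
neutral interstrain drift. Passing the planted-mutation tests therefore
shows the *procedure* is correct (detection, coordinates, notation,
counts), not that the thresholds are optimal for any particular pair of
real genomes — on real data, paralogy and high divergence are exactly
where the 0.5 missing threshold and the best-hit tie-break deserve
scrutiny.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive (GenBank convention) everywhere
user-facing. Genetic code fixed to table 11 (overridable); ambiguity
characters other than N are rejected, never guessed. Empty query and
empty target align to score 0; a non-empty query against an empty target
scores `|q|·gap`. Identity is match-columns over query length; coverage
is aligned (non-gap) query residues over query length. An empty ORF list
yields a missing call with a note rather than an error; unresolvable
candidates (absent, ambiguous would raise, frame violations, internal
stops) are reported in an "unresolved" section, never silently fixed.
Report floats are fixed to four decimals so reruns are byte-identical.

## Problem sizes

The shipped fixtures were sized so the whole suite runs comfortably on a
single CPU: the flagship pair is an ~87 kb genome with 86 genes, scanned
against ~2,800 ORFs in a few seconds; oracle suites use hundreds of pairs
with `|q|+|t| ≤ 16` (the enumeration oracle's tractable regime). A
full-scale two-strain comparison (~4.6 Mb genomes, 86 candidates,
hundreds of thousands of ORFs) runs through the same code path in
minutes-to-hours depending on the prefilter setting and is not part of
the test suite; its exact counts additionally depend on candidate-list
reconstruction and on the reconstructed penalties, as noted above.
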