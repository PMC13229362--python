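# Methods

This note records the model, the conventions, and the design decisions
behind `seedpolish`, at the level a maintainer or reviewer needs to
judge what the package does and does not show.

## Spaced seeds and the seed designer

A spaced seed is a binary mask of span `k`; a window matches a
high-confidence k-mer when every *care* (1) position agrees, regardless
of the *don't care* (0) positions. A set of three seeds per `k` is the
default: more seeds widen the family of tolerated error patterns but
each one costs a Bloom filter and per-window queries.

Seed sets come from a small genetic algorithm (tournament selection of
size 2, uniform crossover, per-bit interior mutation, elitism of one;
population 50, 200 generations by default). The objective is the number
of distinct mismatch bitmasks whose mismatches fall entirely on
don't-care positions of at least one seed, restricted to a span of
`w = 5` bases (the classifier's window), minus `0.1` per don't-care
position. Two structural constraints close degeneracies the raw
objective allows:

* **Minimum weight** (default `ceil(2k/3)`): without it, the optimum is
  a mask that is almost entirely don't-care, which matches everything
  and carries no signal. This keeps seeds specific, the role the weight
  penalty alone cannot play because the pattern count grows much faster
  than linearly with clustered don't-care positions.
* First and last positions are care positions (anchored ends), the
  standard convention that removes trivially shifted duplicates.

Under these constraints the optimum places don't-care positions in
contiguous blocks at varying offsets. That is also good for
identification, not just detection: sliding windows that cover only a
suffix or prefix of an error cluster expose its interior structure.

## Confidence index

Canonical k-mers (lexicographic min of k-mer and reverse complement)
are counted exactly in memory; this package targets desk-scale inputs,
so no streaming cardinality estimation is used. The high-confidence
threshold is the first interior local minimum of the 3-bin-smoothed
multiplicity histogram (fallback 2 when no interior minimum exists,
e.g. for error-free reads). Bloom filters are sized with
`m = -n ln(fpr) / (ln 2)^2` bits and `h = round(m/n ln 2)` keyed
blake2b double hashes; default `fpr = 0.001` per filter. Seed filters
hold the care-position projections of each high-confidence k-mer in
both orientations, so either read orientation matches regardless of
mask asymmetry. Windows containing non-ACGT characters never match.

## Region scanning

A window of the draft is unsupported when its canonical k-mer misses
the filter. Maximal unsupported runs separated by fewer than `k`
supported positions are merged (they share affected k-mers, and at high
Bloom FPR the false "supported" positions inside a genuine run would
otherwise fragment it). The suspect interval of a run spanning `s`
window starts is the intersection of its windows when `s < k` (an
isolated error lands exactly on the erroneous base) and the union
interior otherwise (a dense cluster maps to the erroneous span).
Regions longer than `4k` are split back at supported anchors or
dropped. Each region carries `k-1` bases of flank plus a few extra
right-context bases so the classifier always sees a full-width context
window — during development, truncated contexts measurably flipped the
predicted indel direction, because every training sample has the full
width.

## Error-pattern label space

A label is a mismatch bitmask over a window of `w = 5` draft bases plus
at most one indel of length `<= w` anchored at the region start:
`2^w * (2w + 1) = 352` labels; label 0 is no-edit. Convention: the
indel applies first, then the mask marks the first `w` *retained* draft
bases at the anchor. With the alternative convention (mask over
pre-indel coordinates) each insertion of length `d` makes `2^d` labels
produce identical corruptions, which structurally caps classification
accuracy; the chosen convention keeps every label's corruption
signature distinct.

## Context encoding

`S` is the seed-structure tensor `(k, n_seeds)`. `X` has one row per
seed placement (window start) in the region's context and
`1 + n_seeds (w + 1)` columns: a homopolymer flag, then for each seed
and gap size `g in [0, w]` the membership of that placement after a
gap of `g` bases is hypothesised at the region start. The gap is
two-sided: `g` wildcard bases inserted at the anchor re-align a draft
that is *missing* `g` bases (a wildcard on a care position fails the
match; on a don't-care it is tolerated), while `g` draft bases removed
at the anchor re-align a draft carrying `g` *surplus* bases. A column
is set when either hypothesis matches. One-sided variants were tested
and leave the opposite indel direction nearly unclassifiable (top-1
accuracy below 10% for that half of the label space).

The encoding is content-agnostic: relabeling the alphabet consistently
(preserving complement pairing) leaves the membership columns
unchanged, which is what lets one model generalize across genomes and
platforms.

## Training

Training data is synthesized under ideal conditions: a truth substring
is corrupted by a known label and memberships are computed against the
exact set of the truth's projections (no Bloom filter). Sampling is
class-balanced. Defaults: 40 training seed sets at the target `k`
(minimum weight cycled through roughly 0.63k-0.74k for structural
diversity), two held-out validation seed sets, 20,000 samples, AdamW
with learning rate 0.001 and cosine decay to 10%, batch size 8,
cross-entropy, 30 epochs, GRU hidden size 32, orthogonal recurrent
initialization with the update-gate bias at -1. Held-out validation is
across *seed sets*, not substrings — the generalization the polisher
actually needs — and the checkpoint with the best validation accuracy
is kept. Batches are drawn within one seed set and the seed order is
randomly permuted per batch (tensor columns move together), exposing
the task's permutation symmetry; this was the single largest
generalization gain in development. Training is reproducible under a
fixed seed.

What the ideal training data does not contain: Bloom false positives,
coverage gaps, repeats sharing projections, and scanner-induced anchor
uncertainty. The corrector is therefore built to be robust to imperfect
predictions rather than to trust them (below).

## Correction

Candidates for a region are the top `T = 3` predicted patterns, with
the classifier consulted at anchor shifts {0, -1, +1} and the best
confidence per pattern kept; because indel type and length are
predicted much more reliably than individual mask bits, an
all-ones-mask variant of each distinct indel near the top of the
ranking is appended as a fallback (evaluated only when the primary
candidates fail). Applying a pattern deletes marked bases and turns
insertion sites and masked positions into placeholders; all four bases
are allowed at a substitution placeholder (keeping the draft base is a
no-op), so an over-marked mask can still resolve to the exact repair.

Placeholder resolution is a beam search: placeholders are assigned
left to right, each k-mer window is scored as soon as its last
placeholder is fixed, and the 16 best partial assignments (by miss
count, ties by assignment string, so results are deterministic and
lexicographically first among equal-support optima) survive each step.
The beam shape matters under a noisy filter: a false positive can make
a wrong base tie the true one on the single window an intermediate
placeholder decides, and depth-first or limited-discrepancy search
then spends its whole budget inside a wrong early branch before the
bulk of the windows (decided at the last placeholder) delivers the
verdict. The true assignment's prefixes have zero genuine misses — the
filter has no false negatives — so they provably survive any beam wide
enough to hold the occasional false-positive tie; width 16 covers an
effective per-bit false-positive rate well above the 0.1 stress case.
A window-evaluation budget of 8,000 bounds the worst case, and at most
10 placeholders are permuted per candidate.

Acceptance requires support `>= p` (default 0.5) *and* strictly greater
support than the unedited region, so no-op assignments and the no-edit
label can never be "applied". Anchor jitter of up to two bases is also
searched at application time. Later acceptable candidates (up to 4)
are reported as potentially heterozygous VCF records rather than
applied. N-gap regions of length `<= w` are resolved by the same
machinery with every N a free placeholder, also trying shrunken fills
since drafted gap lengths are estimates.

The sparse post-pass re-scans the polished assembly with the same
k-mer filter and repairs any remaining unsupported run that has a
*unique* single-base fix making all covering k-mers supported;
candidate fixes with identical net effect (homopolymer indels at
shifted offsets) are deduplicated on a fixed evaluation window before
the uniqueness test. Post-pass edits are mapped back to input-draft
coordinates for the VCF; an edit falling inside a model-stage
replacement is applied but logged as unrepresentable.

## Synthetic data and evaluation

The generator draws i.i.d. genomes at a given GC (optionally with
duplicated segments as repeats), corrupts drafts at per-base mismatch
and indel rates with a configurable fraction of errors grouped into
dense clusters (2-3 errors within a 5-base span, hence within one
k-mer span), and samples uniform-start, both-strand reads with
substitution-only errors. Error sites are kept >= 150 bp apart so each
produces its own region; real assemblies can violate this, and the
region merger handles it, but recovery statistics quoted by the tests
are for separated sites. Draft error profiles follow the short-read
polishing regime (defaults 0.5% mismatches, 0.05% indels of 1-3 bp for
stress tests; 0.1%/0.01% is the light profile) and indels stay within
`w` so that every injected error is inside the model's signature
family. Residual errors are measured by banded global alignment
(edlib) per contig: substituted columns count individually, each
maximal gap run counts as one indel event, normalized per 100 kbp of
truth. Equal-cost alignment ambiguities (e.g. a clustered mismatch
pair re-expressed as paired gaps) can shift a few counts between the
two categories.

Problem sizes used by the tests and the acceptance script — 500 kb
genomes, 40x reads, 20,000 training samples, 30 epochs — are the
package's desk-scale defaults; they exercise every stage of the method
end to end while keeping a full run in the minutes range on one CPU.

## Known limitations

* Exact in-memory counting and pure-Python Bloom queries target
  desk-scale data (tens of Mb of reads), not whole human genomes.
* The classifier's held-out-seed-set label accuracy is modest (about
  half of the 352 labels exactly at top-1 in internal measurements);
  the pipeline compensates with anchor-shifted prediction, relaxed-mask
  fallbacks, and support gating, which is why end-to-end recovery is
  high even where exact label identification is not. Regions whose
  true edit is outside the label family (indels > w, very wide
  clusters) are left to the post-pass or filtered.
* Repeats that share seed projections can mask the local signal, the
  known failure mode of small-context k-mer methods; the support gate
  then leaves the region unedited rather than guessing.
* Read errors are substitution-only in the simulator; platform error
  models (homopolymer-length biases, quality strings) are out of scope.
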