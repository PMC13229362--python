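# seedpolish

Alignment-free polishing of draft genome assemblies with spaced seeds,
Bloom-filter k-mer support, and a small recurrent error-pattern
classifier.

## The problem

Draft assemblies — especially from long reads — carry base-level errors
(mismatches and indels, typically under 5 bp). Alignment-based polishers
are accurate but slow; classical k-mer polishers are fast but blind in
regions with *dense* errors, where several errors inside one k-mer span
leave no exact k-mer match to work from. `seedpolish` keeps the
alignment-free speed while recovering the dense-error signal through
*spaced seeds*: binary masks over a k-mer that mark "care" positions
(must match) and "don't care" positions (ignored), so a read k-mer still
matches a corrupted assembly window when the errors fall on tolerated
positions.

## How it works

1. **Confidence index.** Canonical k-mers of the reads are counted
   exactly; the count threshold is the first local minimum of the
   (smoothed) multiplicity histogram, separating erroneous from genomic
   k-mers. K-mers at or above the threshold go into a Bloom filter, and
   their care-position projections (both orientations) into one Bloom
   filter per spaced seed. Bloom filters guarantee no false negatives
   at a configurable false-positive rate (default 0.001).
2. **Region scan.** Maximal runs of consecutive draft windows absent
   from the k-mer filter become suspect regions (point-like errors are
   localized to the intersection of the missing windows); runs of N are
   collected as gap regions.
3. **Error-pattern classification.** Each region is encoded as two
   binary tensors: `S` (k x n_seeds), the seed structure, with
   `S[i,j] = 1` when base `i` of seed `j` is a care position; and `X`,
   per window position, a homopolymer flag plus the membership of every
   seed after hypothesising a gap of `g in [0,w]` bases at the region
   start. Two GRU encoders (hidden size 32) read `S` and `X`; their
   final hidden states feed one linear layer over the space of edit
   signatures — a mismatch bitmask over a `w = 5` window plus at most
   one indel of length `<= w` (352 labels). The model never sees raw
   sequence, only match/mismatch structure, so one trained model serves
   any genome and platform.
4. **Correction.** The top `T = 3` patterns (plus relaxed-mask
   fallbacks) are applied as candidate edits: deletions remove bases,
   insertions and masked positions become placeholders, and a
   branch-and-bound search assigns bases to placeholders to maximize
   the *support ratio* — the fraction of the region's k-mers found in
   the high-confidence filter. An edit is accepted only if its support
   reaches `p = 0.5` and strictly improves on the unedited region;
   runner-up candidates are reported as potentially heterozygous.
   Short N-gaps are filled the same way.
5. **Sparse post-pass.** A final sweep over the polished assembly,
   reusing the same k-mer filter, fixes isolated single-base errors
   that have a unique fully-supported repair.

Outputs are a polished FASTA and a VCF (v4.2, on input-draft
coordinates) with PASS/lowsupport records, heterozygous alternates
(`HET=1`), and per-stage provenance (`STAGE=model|post`).

Spaced-seed sets are designed by a genetic algorithm whose fitness is
the number of distinct mismatch signatures the set can detect, with a
minimum-weight constraint for specificity.

## Worked example

```sh
# Simulate a 100 kb genome, an erroneous draft, and 40x reads
seedpolish simulate --length 100000 --depth 40 --read-length 250 \
    --mismatch-rate 0.005 --indel-rate 0.0005 --seed 1 --out-prefix sim

# Train the classifier (writes sim.model.json and a seed set)
seedpolish train --reference sim.truth.fa --k 35 --samples 20000 \
    --epochs 30 --seed 0 --out sim.model.json --seeds-out sim.seeds.txt

# Polish the draft
seedpolish polish --draft sim.draft.fa --reads sim.reads.fq -k 35 \
    --model sim.model.json --seeds sim.seeds.txt --out-prefix polished
```

The polish run logs a summary such as

```
regions=478 edited=477 filtered=1 gaps=0 post=0
```

meaning 478 suspect regions were located, 477 received an accepted edit
and one stayed below the support threshold (recorded as `lowsupport` in
`polished.vcf`). On this simulation the draft starts at 464 mismatches
and 117 indels per 100 kbp and the polished assembly, evaluated against
`sim.truth.fa` by banded global alignment
(`seedpolish.evaluate_errors`), comes out at 1.0 and 1.0 — a ~99%
error-rate reduction.

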