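# Methods

## The model

`targetpolish` assumes base errors in a draft assembly are concentrated in
*identifiable* regions — soft-masked runs left by gap-filling with raw read
sequence, or intervals the user names in a BED file — and that the rest of
the assembly is accurate enough to serve as anchoring context. Under that
assumption, polishing reduces to a local consensus problem per region: does
the read evidence mapped *to this region* support the draft's k-mers, and
if not, what single edit restores support?

The evidence structure is a set of Bloom filters, one per (target, k-mer
size): a probabilistic set with no false negatives and a configurable
false-positive rate. Membership of a canonical k-mer (lexicographic
minimum of the k-mer and its reverse complement, so strand never matters)
stands in for "the reads contain this sequence". Filters deliberately carry
no counts; all coverage reasoning happens once, at construction, through
the solid-k-mer rule below.

## Stage contracts

**Targeting.** Maximal lowercase runs (`a/c/g/t/n`; uppercase `N` is a gap,
not a mask) or BED intervals, extended by `flank_len` (default 64 bp,
giving the engine ≥ 2k of anchoring context at the default largest k),
clamped to the contig, merged when extensions overlap or touch. Names
encode provenance: `{contig}.{index}.{start}-{end}`, 0-based half-open,
parsed rightmost-first so contig names containing `.` or `-` survive.
When a BED file is supplied it is authoritative and mask scanning is
skipped; flanks apply to BED targets too (the polisher needs the context
either way).

**Liftover.** A PAF block is intersected with the disjoint targets of its
contig; one record is emitted per overlapped target. Query coordinates are
clipped proportionally to the clipped target fraction (colinearity
assumption — PAF may carry no CIGAR, and the engine uses reads only as
k-mer bags, so base-exact clipping would buy nothing). Minus-strand blocks
clip from the opposite query end. `n_matches`/`block_len` scale by the
retained fraction, floored, floors of zero raised to one. Reads touching
no target are discarded and counted.

**Filter construction.** Per target and per k, the canonical k-mers of the
lifted read substrings are counted exactly (numpy `unique`; targets are
small), and only k-mers seen ≥ `min_count` (default 2) are inserted into a
filter sized by the standard formulae m = ⌈−n·ln p/(ln 2)²⌉,
h = max(1, round((m/n)·ln 2)) for the solid-k-mer count n at
`bloom_fpr` p (default 0.01). The solidity rule is load-bearing: long-read
errors are mostly unreplicated, so a singleton k-mer is overwhelmingly an
artefact. Admitting singletons has two measurable failure modes: a read
error coinciding with a draft error makes the erroneous draft k-mers
"present" and masks the site, and a read error at a candidate edit site
gives a *wrong* base full support (one read's error replicates across all
k of its k-mers), tying correct and wrong candidates at support 1.0. At
the coverages targeted polishing assumes (tens of reads per region) a true
k-mer is essentially never lost to `min_count=2`; at very low coverage set
`--min-kmer-count 1`.

Hashing is double hashing, index_i = (h1 + i·h2) mod m, over two seeded
splitmix64 finalizations of the 2-bit-packed canonical k-mer (k ≤ 32 packs
into one 64-bit word). The bulk (numpy) and scalar query paths compute
identical hashes; this is asserted in the test suite.

## The edit engine

The scan runs at each k in `k_values` (default 32, 28, 24, 20, largest
first: long k-mers are specific, shorter k recovers sensitivity where
coverage thins). Within a pass, the per-position presence profile is
computed vectorized; each *maximal absent run* is attacked at its start —
the k-mer one past the last supported one, whose final base is the suspect
— plus up to `backtrack` = 2 earlier anchors (a single false-positive
k-mer at the true run start would otherwise shift the suspect) and the run
end (for an isolated error the last absent k-mer starts exactly at the
error, however much of the run's left side is masked).

Candidates at a suspect base: the three substitutions; deletions of
1..`max_indel` (default 5) bases; insertions of 1..`max_indel` bases grown
greedily base-by-base. Support of a candidate is the fraction of the next
`verify_window` = j k-mers (default 4) present in the filter after the
edit. Insertions are *scored for acceptance* at the first window that
crosses the insertion back into pre-existing downstream sequence;
left-anchored windows only guide the greedy growth. Without that
junction anchoring the greedy search can "rebuild" read sequence
indefinitely, each inserted base self-confirming — in development this
produced net damage (hundreds of spurious insertions) on the synthetic
conditions.

Acceptance requires support strictly above both the unedited support and a
threshold: `accept_fraction` = 0.45 for substitutions (2 of 4 windows — a
correct edit passes whenever ≥ 2 clean bases follow it, while a wrong edit
needs two simultaneous Bloom false positives), and
`indel_accept_fraction` = 0.7 for indels (3 of 4 — a wrong indel shifts
the frame of every downstream k-mer and invites compensating-edit
cascades, so it must clear a higher bar). Ties break by edit type
(substitution > deletion > insertion), then lexicographically; the type
priority is what resolves the genuine ambiguity of a perfect tandem
repeat, where deleting one repeat unit is exactly as supported as the
correct substitution.

Two structural rules close the remaining failure modes:

* **Progress rule.** An accepted edit must strictly reduce the target's
  absent-k-mer count, else it is reverted and the site skipped for the
  pass. Membership filters cannot measure repeat copy number, so a
  microsatellite can otherwise absorb an unbounded run of "supported"
  repeat-unit insertions that never resolve the triggering absent run.
* **Re-anchoring.** After an accepted edit the scan resumes k−1 bases
  before the edit (never past the start of the edited run), so junction
  k-mers created by the edit are themselves verified, and the left member
  of a close error pair is revisited once its right neighbour is fixed.

Why j = 4 rather than the full k windows covering the edit: a window of j
k-mers spans k+j−1 bases, and with gap g to the next (still-uncorrected)
error a correct edit scores min(g, j)/j. In the error densities this tool
exists for (a few percent per base, mean spacing ~40 bp) a k-wide window
almost always overlaps the next error, capping correct-edit support far
below any safe threshold; j must be small relative to the expected error
spacing. With j = 4 the engine corrects isolated errors and all cluster
pairs ≥ 2 bp apart; adjacent (1 bp) pairs are the main principled residual.

Targets shorter than the smallest k are returned unchanged; k values
longer than a target are skipped. Positions whose window contains a
non-ACGT character are never "present", so an `N` inside a target can only
be removed by an edit whose verification eliminates it. The engine is
entirely deterministic; targets are independent, and the process-pool
parallel path collects results in target order, so output is identical to
serial execution byte for byte.

**Edits in flanks** are permitted: flanks come from already-polished
assembly, their k-mers are read-supported, and restricting edits would
require threading coordinate offsets through every prior edit. The
per-edit log (`--edit-log`) records positions so flank edits are
auditable.

**Reinsertion** applies replacements per contig in descending start order
(so earlier coordinates stay valid despite length changes) and uppercases
polished slices — lowercase means unpolished in the drafts this tool
serves; `--keep-case` disables that for round-trip checks.

## The synthetic data generator

`fixtures` emulates the input state the tool is designed for, not real
sequencing chemistry. The truth genome is uniform-random ACGT except that
each planned target window has `paralogs_per_window` (default 1) diverged
copies (substitution divergence 1 − `paralog_identity`, default 2%)
planted elsewhere — the segmental-duplication-like structure that makes
read locality matter at all. Without it, a whole-assembly filter and
per-target filters are statistically indistinguishable on these problem
sizes, because uniform-random 200 kb genomes contain no sequence that
could mislead a global filter; with it, the paralog's solid k-mers sit in
the global filter and can mask window errors or support paralog-allele
edits, which is precisely the argument for targeting.

The draft equals the truth outside the windows; inside, substitutions
(rate 2%/bp) and indels (0.5%/bp, lengths 1–3, short-biased) are injected
and the window is lowercased. The ledger records every injected event and
can replay them, which the tests assert reproduces the draft byte for
byte. Reads are sampled from the truth (lognormal lengths around 10 kb,
random strand) with independent per-base errors (default 1%; ¾
substitutions, ⅛ insertions, ⅛ deletions), and the generator emits the PAF
of true read origins projected onto draft coordinates, so the pipeline
runs with no mapper and read *assignment* is exact. Consequences for
interpretation: passing tests demonstrate the correction mechanics under
concentrated error, clean read assignment, and idealized error models —
they do not show robustness to mapper misassignment, chimeric reads,
homopolymer-biased ONT errors, or real repeat landscapes beyond the
planted paralogs. All randomness flows from one explicit PCG64 generator
per stage, seeded from the config; a fixed seed reproduces every byte on
any platform.

The truth-aware evaluator aligns each polished contig globally against its
truth contig (edlib; alignment is used nowhere in the polisher, keeping
the check independent) and classifies each difference event by truth
position: inside a window extended by the flank (residual target error) or
outside (off-target change — the pipeline must introduce none). Reductions
are reported against the injected event counts. Minimum-cost alignment may
merge a handful of adjacent events, so event counts can differ from ledger
size by a small margin; the tests allow 2%.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `flank_len` | 64 | bp | anchoring context added per target side |
| `k_values` | 32, 28, 24, 20 | bp | filter/edit k-mer schedule, descending |
| `bloom_fpr` | 0.01 | — | per-query false-positive rate each filter is sized for |
| `min_kmer_count` | 2 | reads | solidity threshold for filter admission |
| `verify_window` (j) | 4 | k-mers | support windows scored per candidate |
| `accept_fraction` | 0.45 | — | substitution acceptance threshold |
| `indel_accept_fraction` | 0.7 | — | indel acceptance threshold |
| `max_indel` | 5 | bp | longest single-site indel attempted |
| `backtrack` | 2 | positions | extra anchors before each absent-run start |
| `min_overlap` | 1 | bp | minimum lifted-block overlap kept |

## Problem sizes

The default synthetic conditions are a 200 kb genome in two contigs, ten
2 kb windows, 30× coverage — sizes at which the full pipeline runs in
seconds and the complete verification (`scripts/acceptance.py`, including
three replicate targeted-vs-global comparisons) in about a minute on one
CPU, while every mechanism the method relies on is still exercised.

## Known limitations

* A perfect tandem repeat admits copy-number-changing edits with full
  k-mer support; the type-priority tie-break and the progress rule contain
  the damage but cannot recover copy number without counts.
* Adjacent error pairs (1 bp apart) and errors whose every covering k-mer
  is replicated by ≥ `min_count` identical read errors are not
  correctable under the membership model.
* Proportional query clipping assumes colinear alignments; severely
  clipped or split alignments should be filtered upstream or via
  `--min-overlap`.
* The engine corrects; it does not fill scaffold gaps, phase haplotypes,
  or emit quality scores.
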