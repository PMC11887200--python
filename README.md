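# targetpolish

Targeted long-read polishing of draft genome assemblies.

Long-read assemblers and scaffolders routinely leave *localized* pockets of
low-quality sequence in otherwise accurate assemblies — most prominently,
scaffold gaps that were filled with raw, unpolished read sequence and
flagged by soft-masking (lowercase bases). Re-polishing the whole assembly
to fix a few percent of it is wasteful and can even degrade the accurate
majority. `targetpolish` polishes *only* the flagged regions: it excises
soft-masked runs (or user-supplied BED intervals) with flanking context,
restricts the read evidence to alignments overlapping each region, corrects
substitutions and indels with a per-region Bloom-filter k-mer edit engine,
and splices the corrected sequence back into the assembly.

## Method

The pipeline has five stages; stage 1 (read mapping) is delegated to an
external mapper (ntLink-style `pair` output or `minimap2`), consumed as PAF.

1. **Map** long reads to the draft assembly → PAF.
2. **Extract** target regions: maximal soft-masked runs per contig (or BED
   intervals), each extended by an *f* = 64 bp flank, overlapping or
   touching extensions merged. Each target is named
   `{contig}.{index}.{start}-{end}` (0-based, half-open), so its provenance
   travels in the FASTA header.
3. **Lift** each PAF record onto the targets it overlaps: target
   coordinates rebased to the excised sequence, query intervals clipped
   proportionally, reads touching no target discarded.
4. **Polish** each target independently. For every k in a descending
   schedule (default k ∈ {32, 28, 24, 20}) a Bloom filter is populated
   with the *solid* canonical k-mers (count ≥ 2) of the reads lifted to
   that target. The engine scans the target; at each maximal run of absent
   k-mers the base one past the last supported k-mer is the suspect, and
   candidate edits — 3 substitutions, deletions of 1..5 bp, insertions of
   1..5 bp grown greedily — are scored by the fraction of the following
   *j* = 4 k-mers present after the edit. A candidate is accepted when its
   support exceeds both the unedited support and an acceptance threshold
   (0.45 for substitutions, 0.7 for indels), and an accepted edit must
   strictly reduce the target's absent-k-mer count. After an edit the scan
   rewinds k−1 bases so the new junction k-mers are themselves verified.
5. **Reinsert** polished targets at their provenance coordinates
   (length changes handled by descending-coordinate splicing); polished
   slices are emitted uppercase.

Because each target's filters see only locally mapped reads, sequence from
elsewhere in the genome — paralogs, repeats, other regions' read errors —
can neither mask a local error nor support a wrong edit. That locality is
the point of targeted polishing, and the package ships an experiment
demonstrating it against a single whole-assembly filter
(`scripts/acceptance.py`).

There is no randomness anywhere in the pipeline: identical inputs give
byte-identical outputs, regardless of `--threads`.

## Worked example

The built-in simulator generates a truth genome, a draft whose soft-masked
windows carry concentrated errors, long reads sampled from the truth, and
the read-origin PAF — so the full pipeline runs without an external mapper:

```bash
$ targetpolish simulate --genome-len 50000 --n-contigs 1 --n-windows 4 --seed 7 -o fly
50000 bp truth, 206 injected errors, 155 reads -> fly.*

$ targetpolish polish --assembly fly.draft.fa --reads fly.reads.fq --paf fly.map.paf -o run
4 targets, 152 subs / 15 ins / 27 del, output: run.polished.fa

$ targetpolish evaluate --polished run.polished.fa --truth fly.truth.fa --ledger fly.ledger.tsv
errors_after    15
errors_after_indel      6
errors_after_sub        9
errors_before   206
offtarget_changes       0
pct_reduction_indel     83.33333333333333
pct_reduction_sub       94.70588235294117
pct_reduction_total     92.71844660194175
```

Reading the numbers: the draft carried 206 injected errors confined to four
soft-masked windows; polishing applied 194 edits and left 15 residual
errors — a 92.7% total reduction (94.7% of substitutions, 83.3% of
indels) — while changing nothing outside the windows
(`offtarget_changes 0`).

Each stage is also independently runnable (`extract`, `lift`, `reinsert`)
for debugging, and `--edit-log` writes a per-edit TSV
(target, position, type, ref, alt, support, k) for auditing.

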