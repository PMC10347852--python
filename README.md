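# linklocal

Local assembly of target loci from linked-read sequencing data.

Linked-read technologies (10x Genomics Chromium, stLFR, TELL-Seq, Haplotagging)
tag every short read with the barcode of the long DNA molecule (~30–70 Kb) it
was sequenced from. `linklocal` exploits that long-range signal to assemble a
*target* — the unknown sequence between two known flanking coordinates on a
reference or draft assembly — without a whole-genome assembly and without
trusting the reference across the target. Typical uses: filling intra- and
inter-scaffold gaps, reconstructing the alternative allele of structural
variants (insertion sequences, deletion breakpoints), and recovering regions
that short-read mapping cannot resolve.

## Method

For each target, defined by a GFA 2.0 gap (G line) between two flank segments:

1. **Barcode subsampling** — barcodes observed at least `-occ` times (default 2)
   among reads mapped within `-flank` bp (default 10 Kb) of the gap are
   selected; *all* reads of those barcodes, genome-wide and including unmapped
   mates, form the assembly input. Molecules spanning the gap necessarily reach
   a flank, so their reads are recruited; the rest of the genome stays out.
2. **Anchored de Bruijn graph assembly** — the subsample is k-merized into a
   solid-k-mer graph (canonical k-mers with abundance ≥ a). START/STOP anchor
   k-mers are taken by majority vote from the reads aligned at the anchor
   coordinates, and a bounded breadth-first traversal enumerates every
   START→STOP path; near-identical paths are reduced to representatives that
   pairwise differ by more than 10%.
3. **Extension gate and iteration** — anchors sit `--ext` bp (default 500)
   inside the flanks, so a correct assembly reproduces known flank sequence on
   both sides. A candidate is returned only if each assembled extension aligns
   to its flank with >90% identity over >90% of its length; otherwise the
   assembly is retried down a ladder of decreasing (k, a), by default
   k ∈ {61, 51, 41, 31, 21} with a ∈ {3, 2} within each k. If several mutually
   divergent candidates pass, none is returned by default (`--report-multiple`
   overrides).

A bundled simulator (`linklocal.simulate`) generates barcoded reads from long
molecules with full ground truth (read → molecule → barcode → interval), so
every stage is testable without external data. See `docs/methods.md` for the
model, parameter rationale and limitations.

## Worked example

Simulate a 120 Kb genome at 40x, define one target, and assemble it:

```sh
linklocal simulate --ref-len 120000 --coverage 40 --seed 7 --out sim/
printf 'ref1\t30000\t45000\tref1\t46000\t61000\n' > pairs.bed
linklocal targets --bed pairs.bed --ref sim/reference.fa -o targets.gfa
linklocal run --gfa targets.gfa --bam sim/reads.bam --reads sim/reads.fq \
    --ref sim/reference.fa --out out/
```

which prints

```
24000 read pairs, 24 molecules -> sim/
1 targets -> targets.gfa
1 targets: 1 solved, 0 multiple-solutions, 0 no-assembly, 0 errors
```

`out/assembled_targets.fasta` then holds one record,

```
>target_0.assembled k=61 a=3 len=1000
```

the 1,000 bp gap sequence (flank extensions already trimmed), assembled at the
first parameter rung (k=61, a=3). `out/report.tsv` records per-target status,
the (k, a) used, barcode and read counts, and the per-side extension identities
and coverages (here 1.0000 on both sides); `out/targets_filled.gfa` complements
the input GFA, replacing the solved G line with the assembled segment and two
edges recording its overlap with the flanks. With a heterozygous, divergent
locus the status column reads `multiple_solutions` and no sequence is emitted
unless `--report-multiple` is given.

Library use mirrors the CLI: `subsample.select_barcodes` /
`subsample_reads`, `dbg.assemble_target`, `evaluate.iterative_assemble`,
`pipeline.run_pipeline`, and `benchmarks.random_locus_benchmark` for
truth-aware evaluation.

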