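# Methods

## Problem and model

Linked-read protocols (10x Chromium, stLFR, TELL-Seq, Haplotagging) partition long
DNA molecules (roughly 30–70 Kb) into barcoded short-read libraries: every read
carries the barcode of the molecule it came from. `linklocal` reconstructs a
*target* — the unknown sequence between two known flanking coordinates on a
reference or draft assembly — in three stages, each target processed
independently:

1. **Barcode subsampling.** Reads aligned within a window of `flank_size` bp on
   each side of the gap vote for their barcodes; barcodes observed at least
   `min_occurrences` times (pooled over both windows) are selected, and *all*
   reads of those barcodes — genome-wide, mapped or not — form the assembly
   input. A molecule spanning the gap necessarily reaches into a flank, so its
   barcode is selected and its gap-interior reads are recruited even if they map
   nowhere or elsewhere. Everything else stays out, which is what makes a
   whole-genome read set usable for a single-locus assembly.
2. **Anchored de Bruijn graph assembly.** The subsample is k-merized into a
   solid-k-mer graph (canonical k-mers with abundance ≥ `a`). START and STOP
   anchor k-mers are taken from the *reads* aligned at the anchor coordinates
   (majority vote, ties to the lexicographically smallest), not from the
   reference, so anchors reflect the sequenced individual and are guaranteed
   graph nodes when coverage allows. A breadth-first frontier expansion
   enumerates all START→STOP path sequences under exploration caps, and a greedy
   reduction keeps representatives that pairwise differ by more than 10%.
3. **Extension gate and parameter descent.** Anchors are placed `ext` bp inside
   the flanks, so a correct assembly reproduces `ext` bp of known flank on each
   side. Each candidate's extensions are aligned to the true flank sequence; a
   candidate passes only if *each* side shows more than 90% identity over more
   than 90% of the extension (per-side, the stricter reading of the rule).
   Failing targets are retried down a ladder of decreasing (k, a). One passing
   candidate is reported; several mutually divergent passing candidates mean the
   right one cannot be chosen, and nothing is returned unless `--report-multiple`
   is set.

In benchmark mode, where the true target sequence is known (planted loci), a
returned sequence with more than 90% identity and coverage against the truth is
*successful*, any other returned sequence is *erroneous*, and no returned
sequence is *no assembly*; success rate is successful/targets and accuracy is
successful/(successful + erroneous).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `flank_size` | 10,000 bp | barcode-harvest window per side; performance is flat across 5–15 Kb, the middle value is used |
| `min_occurrences` | 2 | occurrences (pooled over both windows) for a barcode to be selected; >1 suppresses barcode-collision noise |
| `k` ladder | 61, 51, 41, 31, 21 | k-mer sizes tried in decreasing order |
| `a` ladder | 3, 2 | solid-k-mer abundance thresholds; `a` descends within each `k` before `k` drops, matching usual solid-k-mer practice at 20–50x depth |
| `ext` | 500 bp | flank extension included in the assembly for the quality gate; large enough for a meaningful 90/90 alignment at every k, small against the flanks |
| `min_identity`, `min_coverage` | 0.90, 0.90 | per-side extension gate and benchmark thresholds |
| `max_path_length` | gap estimate + 2·ext + 10 Kb (50 Kb when unknown) | cap on assembled length, bounded by molecule reach |
| `max_active_branches` | 100 | BFS frontier cap; truncation is deterministic (lexicographic) and flagged |
| `max_nodes_explored` | 10⁷ | global traversal budget |

## Numerical and algorithmic choices

- **Coordinates** are 0-based half-open everywhere inside the package;
  conversions live at the I/O boundary.
- **Canonical k-mers** (lexicographic minimum of k-mer and reverse complement)
  with odd `k` enforced, so membership is strand-symmetric and no k-mer is its
  own reverse complement. Assembling the reverse-complemented problem yields
  exactly the reverse-complemented candidates.
- **Cycles.** A path may traverse an oriented k-mer at most twice. Pure simple
  paths would forbid any tandem repeat; unlimited revisits would not terminate.
  Two visits admit one extra copy of a tandem unit; longer arrays are truncated
  and surface as erroneous/multiple rather than hanging.
- **Paths end at the first STOP occurrence**; candidates are ordered by
  (length, sequence) for determinism. The traversal is validated against an
  independent exhaustive depth-first enumerator on small random graphs.
- **Extension-gate alignment** uses a local pairwise alignment (match +1,
  mismatch −1, gap open −2, gap extend −1); identity is matching columns over
  alignment columns, coverage is the aligned reference span over the extension
  length. The paper's pipeline delegated this to Nucmer; any sensible scheme
  satisfying the gate's monotonicity works, one is fixed for reproducibility.
  With these affine costs a local alignment may decline to bridge a long
  deletion inside a candidate (bridging n bp costs ~n+1 against n gained), so
  coverage of badly broken candidates is reported conservatively low.
- **Representative reduction** measures identity by global (Needleman–Wunsch)
  alignment via edlib, matching columns over alignment columns; greedy in
  candidate order, keeping a candidate iff it is ≤90% identical to every kept
  one. The exact clustering of the original tool is unpublished; this is a
  declared choice, not a reconstruction.
- **Anchor failure** (no read spanning an anchor coordinate) is reported
  distinctly from assembly failure and, like an empty traversal, advances the
  ladder.
- **Solved-gap GFA encoding.** The assembled segment is written with its full
  extended sequence, and two E lines record its ext + k bp overlaps with the
  flank segments; unsolved gaps keep their G lines. The original tool's output
  encoding is unspecified, so this one is fixed and documented.
- **Degenerate inputs.** Empty barcode selections, zero-read subsamples and
  candidates shorter than 2·ext + k all fail softly into "no assembly" with a
  recorded reason; per-target exceptions are caught into the run report and
  never abort a batch.

## The simulator

`linklocal.simulate` generates the data the method assumes: a (random or
supplied) reference; molecules with truncated-lognormal lengths (mean 50 Kb,
bounds 5–150 Kb) placed uniformly over one or two haplotypes at ~10x molecule
coverage; one barcode per molecule by default (`molecules_per_barcode` > 1
models collisions); paired 100 bp reads allocated to molecules in proportion to
length until the configured read coverage (default 40x) is met; substitution
errors at 0.5%. The BAM is written from the *true* placements: reads lying in a
reference-colinear block of their haplotype map with a full-match CIGAR, reads
crossing variant breakpoints or inside novel insertions are emitted unmapped
with their barcode. Truth tables record read → molecule → (barcode, haplotype,
interval).

What the simulator does **not** model: mapping errors and multi-mapping (the
BAM is ideal; a placement-jitter option is not implemented), PCR/optical
duplicates, GC-coverage bias, indel sequencing errors (substitutions only by
default), chimeric molecules, and quality-score profiles. Passing tests
therefore demonstrate the algorithm's correctness under the linked-read data
model, not robustness to aligner artifacts or library chemistry; on real data
the subsampling step additionally competes with mapping noise that is absent
here.

Benchmark problem sizes were chosen to exercise the claims at desk scale: a
500 Kb genome for locus recovery (20×1 Kb + 10×5 Kb targets), 3 Mb for the
enrichment measurement (on small genomes the enrichment ratio is bounded above
by genome size over the molecule neighbourhood, so a larger genome is needed
for the ratio to be informative), 420 Kb carrying ten 1–5 Kb deletions, and
120–150 Kb genomes for single-case behaviors.

## Known limitations

- Diploid targets are not phased: two sufficiently divergent alleles are
  reported as multiple solutions (none returned by default), by design.
  A heterozygous allele sees half the read depth, so at 40x its k-mer
  coverage (~10x at k=61) sits close to the a=3 solid threshold: whether
  both alleles survive the ladder's first rung, or only one (then returned
  as the unique passing candidate), depends on the local coverage draw.
- Tandem arrays beyond two unit copies cannot be spelled (visit cap) and
  repeat units longer than the largest k leave the copy number ambiguous;
  such targets end as multiple solutions or no assembly rather than a
  confidently wrong sequence.
- The exact k-mer hash tables are sized for barcode-subsampled read sets
  (10⁴–10⁶ reads), not whole-genome k-mer counting.
- Barcode error correction / whitelisting is out of scope; malformed barcodes
  are treated as distinct.
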