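"""Barcode-based read subsampling.

The recruitment step that makes local assembly from whole-genome
linked-reads tractable: barcodes observed in the windows flanking the gap
identify the long molecules spanning the locus, and *all* reads of those
barcodes — genome-wide, including unmapped mates — become the assembly
input.  Reads mapped far away but sharing a spanning molecule's barcode
carry the sequence the gap needs; everything else is noise the subsample
excludes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from linklocal.io_formats import (
    BarcodedRead,
    BarcodeIndex,
    Region,
    TargetLocus,
    fetch_reads_by_barcodes,
)

logger = logging.getLogger(__name__)

DEFAULT_FLANK_SIZE = 10_000
DEFAULT_MIN_OCCURRENCES = 2


@dataclass
class BarcodeSelection:
    """Barcodes retained for one target and the occurrence evidence."""

    target: str
    flank_size: int
    min_occurrences: int
    barcodes: tuple[str, ...]
    occurrence_table: dict[str, int] = field(default_factory=dict)


@dataclass
class ReadSubsample:
    target: str
    reads: list[BarcodedRead]
    n_barcodes: int

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def flank_windows(target: TargetLocus, flank_size: int = DEFAULT_FLANK_SIZE,
                  sequence_lengths=None) -> tuple[Region, Region]:
    """Barcode-harvest windows of up to ``flank_size`` bp on each side of the gap.

    Windows sit immediately against the gap on each flank's contig,
    extending away from the gap, truncated at contig boundaries (they may
    extend past the flank segment itself, which is deliberate: any read
    mapped near the gap is evidence for a spanning molecule).
    """
    if flank_size <= 0:
        raise ValueError("flank_size must be positive")

    def clamp(name: str, start: int, end: int) -> tuple[int, int]:
        start = max(0, start)
        if sequence_lengths is not None:
            length = sequence_lengths[name] if isinstance(sequence_lengths, dict) \
                else sequence_lengths.get_reference_length(name)
            end = min(end, length)
        if start >= end:
            raise ValueError(f"empty flank window on {name} at {start}-{end}")
        return start, end

    lf, rf = target.left_flank, target.right_flank
    if lf.strand == "+":
        s, e = clamp(lf.sequence_id, lf.end - flank_size, lf.end)
    else:
        s, e = clamp(lf.sequence_id, lf.start, lf.start + flank_size)
    left = Region(lf.sequence_id, s, e, lf.strand)
    if rf.strand == "+":
        s, e = clamp(rf.sequence_id, rf.start, rf.start + flank_size)
    else:
        s, e = clamp(rf.sequence_id, rf.end - flank_size, rf.end)
    right = Region(rf.sequence_id, s, e, rf.strand)
    return left, right


def _alignment_barcode(aln: pysam.AlignedSegment) -> str | None:
    if aln.has_tag("BX"):
        return aln.get_tag("BX")
    name = aln.query_name or ""
    if "#" in name:
        barcode = name.rpartition("#")[2]
        return barcode or None
    return None


def _window_barcode_counts(bam: pysam.AlignmentFile, windows,
                           seen: set) -> dict[str, int]:
    counts: dict[str, int] = {}
    for w in windows:
        if bam.get_tid(w.sequence_id) < 0:
            raise ValueError(f"sequence {w.sequence_id!r} absent from BAM header")
        for aln in bam.fetch(w.sequence_id, w.start, w.end):
            if (aln.is_secondary or aln.is_supplementary or aln.is_unmapped
                    or aln.is_duplicate or aln.mapping_quality == 0):
                continue
            key = (aln.query_name, aln.is_read1, aln.reference_start)
            if key in seen:  # same read overlapping both windows counts once
                continue
            seen.add(key)
            barcode = _alignment_barcode(aln)
            if barcode is not None:
                counts[barcode] = counts.get(barcode, 0) + 1
    return counts


def collect_flank_barcodes(bam, windows: tuple[Region, Region],
                           per_side: bool = False):
    """Count read alignments per barcode over the union of both windows.

    Secondary/supplementary/duplicate and MAPQ-0 alignments are ignored so
    each sequenced read contributes at most one count per window union.
    With ``per_side`` a pair of per-window tables is returned instead
    (used by the strict both-sides selection mode).
    """
    own = isinstance(bam, (str, bytes)) or hasattr(bam, "__fspath__")
    bamfile = pysam.AlignmentFile(str(bam), "rb") if own else bam
    try:
        if per_side:
            return (_window_barcode_counts(bamfile, [windows[0]], set()),
                    _window_barcode_counts(bamfile, [windows[1]], set()))
        return _window_barcode_counts(bamfile, list(windows), set())
    finally:
        if own:
            bamfile.close()


def select_barcodes(table: dict[str, int], min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
                    target: str = "", flank_size: int = DEFAULT_FLANK_SIZE,
                    per_side_tables=None) -> BarcodeSelection:
    """Retain barcodes observed at least ``min_occurrences`` times.

    Occurrences are pooled over both windows (union semantics).  When
    ``per_side_tables`` is given, a barcode must additionally appear at
    least once in each window — the stricter variant useful for
    inter-scaffold gaps.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    kept = [b for b, n in table.items() if n >= min_occurrences]
    if per_side_tables is not None:
        left, right = per_side_tables
        kept = [b for b in kept if b in left and b in right]
    return BarcodeSelection(
        target=target, flank_size=flank_size, min_occurrences=min_occurrences,
        barcodes=tuple(sorted(kept)), occurrence_table=dict(table))


def subsample_reads(selection: BarcodeSelection,
                    index: BarcodeIndex) -> ReadSubsample:
    """All reads (both mates, genome-wide) of the selected barcodes."""
    if not selection.barcodes:
        logger.warning("target %s: empty barcode selection, empty subsample",
                       selection.target)
        return ReadSubsample(target=selection.target, reads=[], n_barcodes=0)
    reads = fetch_reads_by_barcodes(index, selection.barcodes)
    return ReadSubsample(target=selection.target, reads=reads,
                         n_barcodes=len(selection.barcodes))


def count_shared_barcodes(bam, region_a: Region, region_b: Region,
                          min_occurrences: int = DEFAULT_MIN_OCCURRENCES) -> int:
    """Number of barcodes selected in both regions (scaffold-ordering signal).

    Two scaffold ends bridged by long molecules share many barcodes; distant
    ends share essentially none, so this count orders scaffolds.
    """
    own = isinstance(bam, (str, bytes)) or hasattr(bam, "__fspath__")
    bamfile = pysam.AlignmentFile(str(bam), "rb") if own else bam
    try:
        table_a = _window_barcode_counts(bamfile, [region_a], set())
        table_b = _window_barcode_counts(bamfile, [region_b], set())
    finally:
        if own:
            bamfile.close()
    sel_a = {b for b, n in table_a.items() if n >= min_occurrences}
    sel_b = {b for b, n in table_b.items() if n >= min_occurrences}
    return len(sel_a & sel_b)
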