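"""Flank windows, barcode selection and read recruitment."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linklocal.io_formats import Region, TargetLocus, build_barcode_index
from linklocal.subsample import (
    collect_flank_barcodes,
    count_shared_barcodes,
    flank_windows,
    select_barcodes,
    subsample_reads,
)

from conftest import make_bam


def _target(gap_start=10_000, gap_end=12_000, contig="chr1", flank=5_000):
    return TargetLocus(
        label="t", gap_length_estimate=gap_end - gap_start,
        left_flank=Region(contig, gap_start - flank, gap_start),
        right_flank=Region(contig, gap_end, gap_end + flank))


def test_flank_windows_arithmetic():
    left, right = flank_windows(_target(), 5000, {"chr1": 100_000})
    assert (left.start, left.end) == (5000, 10_000)
    assert (right.start, right.end) == (12_000, 17_000)


def test_flank_windows_truncate_at_boundaries():
    t = _target(gap_start=2000, gap_end=4000, flank=2000)
    left, right = flank_windows(t, 5000, {"chr1": 5000})
    assert (left.start, left.end) == (0, 2000)
    assert (right.start, right.end) == (4000, 5000)


def test_flank_windows_reverse_strand_point_away_from_gap():
    # '-' left flank abuts the gap at its genomic start
    t = TargetLocus(label="t",
                    left_flank=Region("chr1", 30_000, 40_000, "-"),
                    right_flank=Region("chr1", 50_000, 60_000))
    left, _ = flank_windows(t, 5000, {"chr1": 100_000})
    assert (left.start, left.end) == (30_000, 35_000)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(gap_start=st.integers(6_000, 90_000), flank=st.integers(1, 20_000))
def test_flank_window_lengths_exhaustive(gap_start, flank):
    """Windows have length min(flank, space to the contig end)."""
    t = TargetLocus(label="t",
                    left_flank=Region("chr1", max(0, gap_start - 5000), gap_start),
                    right_flank=Region("chr1", gap_start + 100, gap_start + 5100))
    left, right = flank_windows(t, flank, {"chr1": 100_000})
    assert len(left) == min(flank, gap_start)
    assert len(right) == min(flank, 100_000 - (gap_start + 100))


# ---------------------------------------------------------------------------
# barcode counting on a hand-built BAM
# ---------------------------------------------------------------------------

@pytest.fixture()
def counting_bam(tmp_path):
    ref = {"chr1": "A" * 30_000}
    seq = "ACGT" * 25
    records = [
        # barcode X: three alignments in the left window, one in the right
        {"name": "x1", "contig": "chr1", "pos": 5_100, "seq": seq, "tags": {"BX": "X"}},
        {"name": "x2", "contig": "chr1", "pos": 6_000, "seq": seq, "tags": {"BX": "X"}},
        {"name": "x3", "contig": "chr1", "pos": 9_950, "seq": seq, "tags": {"BX": "X"}},
        {"name": "x4", "contig": "chr1", "pos": 12_500, "seq": seq, "tags": {"BX": "X"}},
        # barcode Y once; plus ignored records: secondary, MAPQ 0, outside
        {"name": "y1", "contig": "chr1", "pos": 7_000, "seq": seq, "tags": {"BX": "Y"}},
        {"name": "y2", "contig": "chr1", "pos": 7_100, "seq": seq, "tags": {"BX": "Y"},
         "flag": 0x100},
        {"name": "z1", "contig": "chr1", "pos": 7_200, "seq": seq, "tags": {"BX": "Z"},
         "mapq": 0},
        {"name": "x5", "contig": "chr1", "pos": 20_000, "seq": seq, "tags": {"BX": "X"}},
    ]
    return make_bam(tmp_path / "counting.bam", ref, records)


def test_collect_flank_barcodes_union_semantics(counting_bam):
    windows = flank_windows(_target(), 5000, {"chr1": 30_000})
    table = collect_flank_barcodes(counting_bam, windows)
    assert table == {"X": 4, "Y": 1}


def test_collect_flank_barcodes_missing_contig(counting_bam):
    windows = (Region("chrX", 0, 100), Region("chrX", 200, 300))
    with pytest.raises(ValueError, match="chrX"):
        collect_flank_barcodes(counting_bam, windows)


def test_collect_flank_barcodes_empty_windows(counting_bam):
    windows = (Region("chr1", 25_000, 25_100), Region("chr1", 26_000, 26_100))
    assert collect_flank_barcodes(counting_bam, windows) == {}


def test_collect_matches_linear_scan_oracle(small_sim):
    """Window counts equal a brute-force scan over all alignments."""
    sim, design, _ = small_sim
    t = design.targets[0].target
    windows = flank_windows(t, 10_000, {"ref1": 120_000})
    table = collect_flank_barcodes(sim.bam, windows)

    expected: dict[str, int] = {}
    with pysam.AlignmentFile(sim.bam) as bam:
        for aln in bam.fetch():
            if (aln.is_secondary or aln.is_supplementary or aln.is_unmapped
                    or aln.is_duplicate or aln.mapping_quality == 0):
                continue
            s, e = aln.reference_start, aln.reference_end
            if any(s < w.end and e > w.start for w in windows):
                barcode = aln.get_tag("BX")
                expected[barcode] = expected.get(barcode, 0) + 1
    assert table == expected


def test_select_barcodes_threshold_and_determinism():
    table = {"X": 4, "Y": 1}
    assert select_barcodes(table, 2).barcodes == ("X",)
    assert select_barcodes(table, 1).barcodes == ("X", "Y")
    with pytest.raises(ValueError):
        select_barcodes(table, 0)


def test_select_barcodes_both_sides_mode():
    table = {"X": 4, "Y": 3}
    per_side = ({"X": 2, "Y": 3}, {"X": 2})
    sel = select_barcodes(table, 2, per_side_tables=per_side)
    assert sel.barcodes == ("X",)  # Y never seen on the right side


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.dictionaries(st.text("ACGT", min_size=4, max_size=6),
                       st.integers(1, 20), max_size=30),
       st.integers(1, 10))
def test_occurrence_monotonicity(table, min_occ):
    """Raising the occurrence threshold never grows the barcode set."""
    lower = set(select_barcodes(table, min_occ).barcodes)
    higher = set(select_barcodes(table, min_occ + 1).barcodes)
    assert higher <= lower


def test_subsample_reads_composition(tmp_path):
    lines = []
    for i, barcode in enumerate(["X", "X", "Y", "X", "Y", "X"]):
        lines.append(f"@p{i // 2}/{i % 2 + 1} BX:Z:{barcode}\nACGTACGT\n+\nIIIIIIII\n")
    fq = tmp_path / "six.fq"
    fq.write_text("".join(lines))
    index = build_barcode_index(str(fq))
    sel = select_barcodes({"X": 4, "Y": 1}, 2, target="t")
    sub = subsample_reads(sel, index)
    assert sub.n_reads == 4 and sub.n_barcodes == 1
    assert all(r.barcode == "X" for r in sub.reads)
    empty = subsample_reads(select_barcodes({}, 2, target="t"), index)
    assert empty.n_reads == 0


def test_recruitment_covers_spanning_molecules(small_sim):
    """Reads of molecules spanning a flank window are recruited (>=95%)."""
    sim, design, _ = small_sim
    t = design.targets[0].target
    windows = flank_windows(t, 10_000, {"ref1": 120_000})
    table = collect_flank_barcodes(sim.bam, windows)
    sel = select_barcodes(table, 2, target=t.label)
    index = build_barcode_index(sim.fastq)
    sub = subsample_reads(sel, index)
    recruited_ids = {r.read_id for r in sub.reads}

    spanning_mols = {
        m.mol_id for m in sim.truth.molecules.values()
        if any(m.start <= w.start and m.end >= w.end for w in windows)}
    spanning_reads = [rid for rid, mid in sim.truth.read_to_molecule.items()
                      if mid in spanning_mols]
    assert spanning_reads
    hit = sum(rid in recruited_ids for rid in spanning_reads)
    assert hit / len(spanning_reads) >= 0.95


def test_count_shared_barcodes(counting_bam, small_sim):
    # disjoint barcode neighbourhoods share nothing; a region shares all
    # its own selected barcodes with itself
    near = Region("chr1", 5_000, 10_000)
    far = Region("chr1", 19_000, 24_000)
    assert count_shared_barcodes(counting_bam, near, far, 1) == 1  # X on both
    assert count_shared_barcodes(counting_bam, near, far, 2) == 0
    assert count_shared_barcodes(counting_bam, near, near, 1) == 2  # X and Y

    # simulated scaffold ends: close ends bridged by molecules share
    # barcodes, distant ends effectively none
    sim, _, _ = small_sim
    a = Region("ref1", 20_000, 30_000)
    b = Region("ref1", 35_000, 45_000)
    c = Region("ref1", 110_000, 120_000)
    assert count_shared_barcodes(sim.bam, a, b, 2) >= 1
    assert count_shared_barcodes(sim.bam, a, c, 2) <= \
        count_shared_barcodes(sim.bam, a, b, 2) / 5
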