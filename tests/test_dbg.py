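"""K-mer graph construction, anchoring, traversal and path reduction."""

import numpy as np
import pytest

from linklocal.dbg import (
    AnchorKmers,
    AnchoringError,
    AssemblyParams,
    DeBruijnGraph,
    build_graph,
    count_kmers,
    exhaustive_paths,
    pairwise_identity,
    pick_anchor_kmers,
    representative_subset,
    traverse,
)
from linklocal.dna import canonical, revcomp
from linklocal.io_formats import Region, TargetLocus

from conftest import make_bam, mutate, random_dna


def _params(k, a=1, **kw):
    return AssemblyParams(k=k, a=a, **kw)


def _linear_anchors(seq, k):
    return AnchorKmers(start_kmer=seq[:k], stop_kmer=seq[-k:],
                       start_support=1, stop_support=1)


def _brute_force_kmer_counts(seqs, k):
    """Independent oracle: count canonical k-mers the slow, obvious way."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" in km:
                continue
            km = min(km, revcomp(km))
            counts[km] = counts.get(km, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def test_count_kmers_hand_enumeration():
    counts = count_kmers(["ACGTACGT"], 4)
    assert counts == _brute_force_kmer_counts(["ACGTACGT"], 4)
    assert sum(counts.values()) == 5  # five k-mer occurrences in an 8-mer


def test_count_kmers_matches_oracle_on_random_reads():
    rng = np.random.default_rng(1)
    reads = [random_dna(rng, int(rng.integers(30, 120))) for _ in range(50)]
    reads[0] = reads[0][:10] + "N" + reads[0][11:]
    for k in (5, 21):
        assert count_kmers(reads, k) == _brute_force_kmer_counts(reads, k)


def test_solid_threshold_filters_singletons():
    g = build_graph(["ACGTAGGCTA"], k=5, a=2)
    assert g.n_kmers == 0
    g1 = build_graph(["ACGTAGGCTA"], k=5, a=1)
    assert g1.n_kmers == 6


def test_build_graph_errors():
    with pytest.raises(ValueError):
        build_graph([], 5, 1)
    with pytest.raises(ValueError):
        build_graph(["ACG"], 5, 1)


def test_graph_membership_is_strand_symmetric():
    rng = np.random.default_rng(2)
    seq = random_dna(rng, 200)
    g = build_graph([seq], k=21, a=1)
    for i in range(0, 180, 13):
        km = seq[i:i + 21]
        assert km in g and revcomp(km) in g
        assert g.abundance(km) == g.abundance(revcomp(km))


def test_simulated_subsample_contains_truth_kmers(small_sim):
    """At 40x the solid graph holds nearly all k-mers of a true locus."""
    sim, design, _ = small_sim
    planted = design.targets[0]
    reads = [r.sequence for r in _all_reads(sim)]
    g = build_graph(reads, k=61, a=3)
    truth_kmers = {canonical(planted.truth[i:i + 61])
                   for i in range(len(planted.truth) - 60)}
    present = sum(km in g.counts for km in truth_kmers)
    assert present / len(truth_kmers) >= 0.99


def _all_reads(sim):
    from linklocal.io_formats import iter_fastq
    return list(iter_fastq(sim.fastq))


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _anchor_fixture(tmp_path, reads_with_snp=0, n_clean=5):
    rng = np.random.default_rng(3)
    ref = {"chr1": random_dna(rng, 4000)}
    # gap at 2000-2500; ext 100, k 21 -> left anchor window 1879-1900
    target = TargetLocus(label="t",
                         left_flank=Region("chr1", 0, 2000),
                         right_flank=Region("chr1", 2500, 4000),
                         gap_length_estimate=500)
    records = []
    for i in range(n_clean):
        records.append({"name": f"c{i}", "contig": "chr1", "pos": 1850,
                        "seq": ref["chr1"][1850:1950]})
    snp_seq = list(ref["chr1"][1850:1950])
    pos_in_read = 1890 - 1850
    snp_seq[pos_in_read] = "A" if snp_seq[pos_in_read] != "A" else "C"
    for i in range(reads_with_snp):
        records.append({"name": f"s{i}", "contig": "chr1", "pos": 1850,
                        "seq": "".join(snp_seq)})
    for i in range(3):  # right anchor support
        records.append({"name": f"r{i}", "contig": "chr1", "pos": 2580,
                        "seq": ref["chr1"][2580:2680]})
    bam = make_bam(tmp_path / "anchor.bam", ref, records)
    return ref, target, bam, "".join(snp_seq)


def test_anchor_equals_reference_kmer_with_clean_reads(tmp_path):
    ref, target, bam, _ = _anchor_fixture(tmp_path)
    anchors = pick_anchor_kmers(bam, target, k=21, ext=100)
    assert anchors.start_kmer == ref["chr1"][1879:1900]
    assert anchors.stop_kmer == ref["chr1"][2600:2621]
    assert anchors.start_support == 5


def test_anchor_majority_vote_carries_the_snp(tmp_path):
    ref, target, bam, snp_read = _anchor_fixture(tmp_path, reads_with_snp=7)
    anchors = pick_anchor_kmers(bam, target, k=21, ext=100)
    assert anchors.start_kmer == snp_read[1879 - 1850:1900 - 1850]
    assert anchors.start_kmer != ref["chr1"][1879:1900]


def test_anchoring_failure_is_reported(tmp_path):
    rng = np.random.default_rng(4)
    ref = {"chr1": random_dna(rng, 4000)}
    target = TargetLocus(label="t",
                         left_flank=Region("chr1", 0, 2000),
                         right_flank=Region("chr1", 2500, 4000))
    bam = make_bam(tmp_path / "empty.bam", ref, [
        {"name": "far", "contig": "chr1", "pos": 100,
         "seq": ref["chr1"][100:200]}])
    with pytest.raises(AnchoringError, match="left"):
        pick_anchor_kmers(bam, target, k=21, ext=100)


def test_anchors_on_reverse_strand_flank(tmp_path):
    """A '-' oriented flank yields the reverse-complemented anchor."""
    rng = np.random.default_rng(5)
    ref = {"chr1": random_dna(rng, 4000)}
    fwd_target = TargetLocus(label="f",
                             left_flank=Region("chr1", 0, 2000),
                             right_flank=Region("chr1", 2500, 4000))
    # same gap, but the right flank supplied in reverse orientation:
    # its 5' end (gap side) is then the genomic end of the region
    rev_target = TargetLocus(label="r",
                             left_flank=Region("chr1", 0, 2000),
                             right_flank=Region("chr1", 1000, 2000, "-"))
    records = [{"name": f"a{i}", "contig": "chr1", "pos": p,
                "seq": ref["chr1"][p:p + 100]}
               for i, p in enumerate([1850, 1860, 2600, 2610, 1870])]
    bam = make_bam(tmp_path / "rev.bam", ref, records)
    rev = pick_anchor_kmers(bam, rev_target, k=21, ext=100)
    # right flank '-': stop anchor is revcomp of the window ending at 1900
    assert rev.stop_kmer == revcomp(ref["chr1"][1879:1900])
    fwd = pick_anchor_kmers(bam, fwd_target, k=21, ext=100)
    assert fwd.start_kmer == ref["chr1"][1879:1900]


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------

def test_linear_graph_spells_its_sequence():
    seq = "ACGTACGTTTGCAGGCATTAC"
    k = 7
    g = build_graph([seq], k=k, a=1)
    res = traverse(g, _linear_anchors(seq, k), _params(k))
    assert [c.sequence for c in res.candidates] == [seq]
    assert not res.limit_reached


def test_start_equals_stop_degenerate():
    k = 7
    g = build_graph(["ACGTACGTT"], k=k, a=1)
    anchors = AnchorKmers("ACGTACG", "ACGTACG", 1, 1)
    res = traverse(g, anchors, _params(k))
    assert [c.sequence for c in res.candidates] == ["ACGTACG"]


def test_bubble_yields_two_candidates():
    rng = np.random.default_rng(6)
    k = 11
    left, right = random_dna(rng, 40), random_dna(rng, 40)
    mid = random_dna(rng, 30)
    alt = list(mid)
    alt[15] = "ACGT"[("ACGT".index(alt[15]) + 1) % 4]
    h1, h2 = left + mid + right, left + "".join(alt) + right
    g = build_graph([h1, h2], k=k, a=1)
    res = traverse(g, _linear_anchors(h1, k), _params(k))
    assert sorted(c.sequence for c in res.candidates) == sorted([h1, h2])
    assert [c.sequence for c in res.candidates] == exhaustive_paths(g, h1[:k], h1[-k:])


def test_unreachable_stop_gives_empty_list():
    g = build_graph(["ACGTACGTTTGCA"], k=7, a=1)
    anchors = AnchorKmers("ACGTACG", "AAAAAAA", 1, 1)
    assert traverse(g, anchors, _params(7)).candidates == []


def test_tandem_repeat_double_visit():
    """A node may be traversed twice: one extra repeat copy is assembled."""
    rng = np.random.default_rng(7)
    k = 11
    unit = random_dna(rng, 40)
    seq = random_dna(rng, 50) + unit + unit + random_dna(rng, 50)
    g = build_graph([seq], k=k, a=1)
    res = traverse(g, _linear_anchors(seq, k), _params(k))
    spelled = {c.sequence for c in res.candidates}
    assert seq in spelled  # the two-copy (true) path is recoverable
    assert spelled == set(exhaustive_paths(g, seq[:k], seq[-k:]))


def test_traversal_matches_exhaustive_dfs_on_random_graphs():
    """Frontier BFS and recursive DFS enumerate identical path sets."""
    rng = np.random.default_rng(8)
    for trial in range(40):
        k = int(rng.choice([15, 21]))
        backbone = random_dna(rng, int(rng.integers(100, 400)))
        reads = [backbone]
        for _ in range(int(rng.integers(0, 3))):  # mutated copies -> bubbles
            reads.append(mutate(rng, backbone, 0.005))
        if rng.random() < 0.4:  # a planted repeat -> cycles
            pos = int(rng.integers(20, len(backbone) - 60))
            reads.append(backbone[:pos] + backbone[pos:pos + 40] * 2
                         + backbone[pos + 40:])
        g = build_graph(reads, k=k, a=1)
        res = traverse(g, _linear_anchors(backbone, k),
                       _params(k, max_active_branches=10_000,
                               max_path_length=5_000))
        dfs = exhaustive_paths(g, backbone[:k], backbone[-k:],
                               max_path_length=5_000)
        assert [c.sequence for c in res.candidates] == dfs, f"trial {trial}"


def test_candidate_soundness_and_order():
    """Candidates spell only solid k-mers, anchored at both ends,
    ordered by (length, sequence)."""
    rng = np.random.default_rng(9)
    k = 11
    backbone = random_dna(rng, 300)
    reads = [backbone, mutate(rng, backbone, 0.02)]
    g = build_graph(reads, k=k, a=1)
    res = traverse(g, _linear_anchors(backbone, k),
                   _params(k, max_active_branches=10_000))
    assert res.candidates
    keys = [(len(c.sequence), c.sequence) for c in res.candidates]
    assert keys == sorted(keys)
    for c in res.candidates:
        assert c.sequence[:k] == backbone[:k]
        assert c.sequence[-k:] == backbone[-k:]
        assert all(c.sequence[i:i + k] in g
                   for i in range(len(c.sequence) - k + 1))


def test_strand_symmetry_of_assembly():
    """The reverse-complemented problem yields reverse-complemented paths."""
    rng = np.random.default_rng(10)
    k = 11
    backbone = random_dna(rng, 250)
    reads = [backbone, mutate(rng, backbone, 0.02)]
    g = build_graph(reads, k=k, a=1)
    fwd = traverse(g, _linear_anchors(backbone, k),
                   _params(k, max_active_branches=10_000))
    rc = revcomp(backbone)
    rev = traverse(g, _linear_anchors(rc, k),
                   _params(k, max_active_branches=10_000))
    assert {c.sequence for c in fwd.candidates} == \
        {revcomp(c.sequence) for c in rev.candidates}


def test_monotonicity_in_abundance():
    """Paths at (k, a+1) use only k-mers solid at (k, a)."""
    rng = np.random.default_rng(11)
    k = 11
    for _ in range(20):
        backbone = random_dna(rng, 200)
        reads = [backbone] + [mutate(rng, backbone, 0.005) for _ in range(3)]
        counts = count_kmers(reads, k)
        lower = DeBruijnGraph(k, counts, 2)
        higher = DeBruijnGraph(k, counts, 3)
        assert set(higher.counts) <= set(lower.counts)
        anchors = _linear_anchors(backbone, k)
        strict = traverse(higher, anchors, _params(k, max_active_branches=10_000))
        for c in strict.candidates:
            assert all(c.sequence[i:i + k] in lower
                       for i in range(len(c.sequence) - k + 1))


def test_exploration_limits_flagged():
    seq = "ACGTACGTTTGCAGGCATTACGGATC"
    g = build_graph([seq], k=7, a=1)
    res = traverse(g, _linear_anchors(seq, 7), _params(7, max_path_length=10))
    assert res.candidates == [] and res.limit_reached


# ---------------------------------------------------------------------------
# representative subset
# ---------------------------------------------------------------------------

def _cand(seq, k=11):
    from linklocal.dbg import AssemblyCandidate
    return AssemblyCandidate(sequence=seq, params=_params(k))


def test_identical_and_near_identical_collapse():
    rng = np.random.default_rng(12)
    seq = random_dna(rng, 1000)
    assert len(representative_subset([_cand(seq), _cand(seq)])) == 1
    near = seq[:500] + ("A" if seq[500] != "A" else "C") + seq[501:]
    assert len(representative_subset([_cand(seq), _cand(near)])) == 1


def test_divergent_sequences_all_kept():
    rng = np.random.default_rng(13)
    cands = [_cand(random_dna(rng, 500)) for _ in range(5)]
    kept = representative_subset(cands)
    assert len(kept) == 5
    for i, a in enumerate(kept):  # verified with the aligner itself
        for b in kept[i + 1:]:
            assert pairwise_identity(a.sequence, b.sequence) <= 0.90


def test_pairwise_identity_values():
    rng = np.random.default_rng(14)
    seq = random_dna(rng, 1000)
    near = seq[:400] + ("A" if seq[400] != "A" else "C") + seq[401:]
    assert pairwise_identity(seq, seq) == 1.0
    assert pairwise_identity(seq, near) == pytest.approx(0.999)


def test_params_validation():
    with pytest.raises(ValueError):
        AssemblyParams(k=20, a=1)  # even k
    with pytest.raises(ValueError):
        AssemblyParams(k=21, a=0)
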