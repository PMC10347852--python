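"""Anchored de Bruijn graph assembly of one target locus.

The recruited reads are k-merized into a solid-k-mer graph (canonical
k-mers with abundance >= a).  Assembly is the set of graph paths from a
START k-mer (taken from reads at the left anchor coordinate, pointing into
the gap) to a STOP k-mer (right anchor), found by a bounded breadth-first
frontier expansion.  Paths may revisit a node once (two traversals total),
which admits a single extra copy of a tandem repeat while guaranteeing
termination.  Near-identical paths are reduced to representatives that
pairwise differ by more than 10%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import pysam

from linklocal.dna import canonical, revcomp
from linklocal.io_formats import TargetLocus

logger = logging.getLogger(__name__)

DEFAULT_MAX_ACTIVE_BRANCHES = 100
DEFAULT_MAX_NODES_EXPLORED = 10_000_000
REPRESENTATIVE_MAX_IDENTITY = 0.90


class AnchoringError(RuntimeError):
    """No read spans an anchor coordinate; distinct from assembly failure."""


@dataclass(frozen=True)
class AssemblyParams:
    """De Bruijn graph parameters for one assembly attempt.

    k must be odd (canonical hashing is then strand-unambiguous);
    ``a`` is the solid-k-mer abundance threshold.  ``max_path_length``
    caps assembled sequence length, ``max_active_branches`` the BFS
    frontier width, ``max_nodes_explored`` the global exploration budget.
    """

    k: int
    a: int = 2
    max_path_length: int = 50_000
    max_active_branches: int = DEFAULT_MAX_ACTIVE_BRANCHES
    max_nodes_explored: int = DEFAULT_MAX_NODES_EXPLORED

    def __post_init__(self):
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if self.a < 1:
            raise ValueError("abundance threshold a must be >= 1")
        if min(self.max_path_length, self.max_active_branches,
               self.max_nodes_explored) <= 0:
            raise ValueError("exploration caps must be positive")


class DeBruijnGraph:
    """Solid canonical k-mer set with abundances for a fixed (k, a)."""

    def __init__(self, k: int, counts: dict[str, int], a: int):
        self.k = k
        self.a = a
        self.counts = {km: c for km, c in counts.items() if c >= a}

    @property
    def n_kmers(self) -> int:
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def abundance(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def successors(self, kmer: str) -> list[str]:
        suffix = kmer[1:]
        return [suffix + b for b in "ACGT" if suffix + b in self]


def count_kmers(sequences, k: int) -> dict[str, int]:
    """Canonical k-mer abundances over reads; k-mers containing N skipped."""
    counts: dict[str, int] = {}
    get = counts.get
    for item in sequences:
        seq = item if isinstance(item, str) else item.sequence
        n = len(seq)
        if n < k:
            continue
        rc = revcomp(seq)
        if "N" in seq:
            for i in range(n - k + 1):
                km = seq[i:i + k]
                if "N" in km:
                    continue
                km2 = rc[n - k - i:n - i]
                cano = km if km <= km2 else km2
                counts[cano] = get(cano, 0) + 1
        else:
            for i in range(n - k + 1):
                km = seq[i:i + k]
                km2 = rc[n - k - i:n - i]
                cano = km if km <= km2 else km2
                counts[cano] = get(cano, 0) + 1
    return counts


def build_graph(reads, k: int, a: int = 2) -> DeBruijnGraph:
    """Solid-k-mer graph of a read set (reads shorter than k are skipped)."""
    reads = list(reads)
    if not reads:
        raise ValueError("cannot build a graph from zero reads")
    lengths = [len(r if isinstance(r, str) else r.sequence) for r in reads]
    if max(lengths) < k:
        raise ValueError(f"all reads shorter than k={k}")
    return DeBruijnGraph(k, count_kmers(reads, k), a)


# ---------------------------------------------------------------------------
# anchor k-mers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorKmers:
    start_kmer: str
    stop_kmer: str
    start_support: int
    stop_support: int


def _anchor_window(target: TargetLocus, side: str, k: int, ext: int):
    """Reference window holding one anchor k-mer, plus orientation.

    Anchors sit ``ext`` bp inside the flanks so the assembled sequence
    overlaps ``ext`` bp of known flank on each side (the extended target).
    Returns (contig, window_start, window_end, needs_revcomp, anchor_at_end).
    ``anchor_at_end`` marks whether reads must be sampled at the window's
    right (True) or left (False) boundary coordinate.
    """
    if side == "left":
        f = target.left_flank
        if f.strand == "+":
            w0 = f.end - ext - k
            return f.sequence_id, w0, w0 + k, False, True
        w0 = f.start + ext
        return f.sequence_id, w0, w0 + k, True, False
    f = target.right_flank
    if f.strand == "+":
        w0 = f.start + ext
        return f.sequence_id, w0, w0 + k, False, False
    w0 = f.end - ext - k
    return f.sequence_id, w0, w0 + k, True, True


def _read_kmers_at(bam: pysam.AlignmentFile, contig: str, w0: int, w1: int,
                   k: int, at_end: bool) -> dict[str, int]:
    """Length-k read substrings anchored at one window boundary coordinate."""
    counts: dict[str, int] = {}
    for aln in bam.fetch(contig, w0, w1):
        if (aln.is_secondary or aln.is_supplementary or aln.is_unmapped
                or aln.is_duplicate):
            continue
        query = aln.query_sequence
        if query is None:
            continue
        qpos = None
        anchor_ref = w1 - 1 if at_end else w0
        for q, r in aln.get_aligned_pairs(matches_only=True):
            if r == anchor_ref:
                qpos = q
                break
        if qpos is None:
            continue
        if at_end:
            lo, hi = qpos - k + 1, qpos + 1
        else:
            lo, hi = qpos, qpos + k
        if lo < 0 or hi > len(query):
            continue
        km = query[lo:hi].upper()
        if len(km) == k and "N" not in km:
            counts[km] = counts.get(km, 0) + 1
    return counts


def pick_anchor_kmers(bam, target: TargetLocus, k: int, ext: int) -> AnchorKmers:
    """Most represented read k-mer at each anchor coordinate.

    Reads rather than the reference supply the anchors, so the anchors
    reflect the re-sequenced individual and are guaranteed to be graph
    nodes when coverage suffices.  Ties break to the lexicographically
    smallest k-mer; both anchors are oriented in assembly direction
    (START pointing into the gap).
    """
    own = isinstance(bam, (str, bytes)) or hasattr(bam, "__fspath__")
    bamfile = pysam.AlignmentFile(str(bam), "rb") if own else bam
    try:
        picked = {}
        for side in ("left", "right"):
            contig, w0, w1, need_rc, at_end = _anchor_window(target, side, k, ext)
            if w0 < 0:
                raise AnchoringError(
                    f"target {target.label}: {side} anchor window extends past "
                    f"the start of {contig} (flank shorter than ext + k)")
            counts = _read_kmers_at(bamfile, contig, w0, w1, k, at_end)
            if need_rc:
                counts = {revcomp(km): c for km, c in counts.items()}
            if not counts:
                raise AnchoringError(
                    f"target {target.label}: no read spans the {side} anchor "
                    f"coordinate on {contig}:{w0}-{w1}")
            best = max(counts, key=lambda km: (counts[km], _lex_key(km)))
            picked[side] = (best, counts[best])
    finally:
        if own:
            bamfile.close()
    return AnchorKmers(start_kmer=picked["left"][0], stop_kmer=picked["right"][0],
                       start_support=picked["left"][1], stop_support=picked["right"][1])


def _lex_key(km: str):
    # max() keeps the lexicographically smallest on count ties
    return tuple(-ord(c) for c in km)


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyCandidate:
    """One START->STOP path: sequence spelled through both anchors."""

    sequence: str
    params: AssemblyParams
    branches_encountered: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TraversalResult:
    candidates: list[AssemblyCandidate]
    limit_reached: bool = False
    nodes_explored: int = 0


def traverse(graph: DeBruijnGraph, anchors: AnchorKmers,
             params: AssemblyParams) -> TraversalResult:
    """All START->STOP path sequences under the exploration budget.

    Breadth-first frontier expansion; a path terminates at its first STOP
    occurrence and may visit any oriented k-mer at most twice.  Candidates
    are returned sorted by (length, sequence).  ``limit_reached`` flags any
    truncation by the caps, which drives the parameter-ladder descent.
    """
    k = graph.k
    start, stop = anchors.start_kmer, anchors.stop_kmer
    if len(start) != k or len(stop) != k:
        raise ValueError("anchor length does not match graph k")
    result = TraversalResult(candidates=[])
    if start not in graph:
        return result
    if start == stop:
        result.candidates = [AssemblyCandidate(sequence=start, params=params)]
        return result

    found: list[str] = []
    frontier: list[tuple[str, dict[str, int]]] = [(start, {start: 1})]
    nodes = 0
    branches = 0
    out_of_budget = False
    while frontier and not out_of_budget:
        new_frontier: list[tuple[str, dict[str, int]]] = []
        for seq, visits in frontier:
            cur = seq[-k:]
            suffix = cur[1:]
            exts = [suffix + b for b in "ACGT" if suffix + b in graph]
            if len(exts) > 1:
                branches += 1
            for nxt in exts:
                nodes += 1
                if nodes > params.max_nodes_explored:
                    result.limit_reached = True
                    out_of_budget = True
                    break
                if visits.get(nxt, 0) >= 2:
                    continue
                if nxt == stop:
                    found.append(seq + nxt[-1])
                    continue
                if len(seq) + 1 >= params.max_path_length:
                    result.limit_reached = True
                    continue
                nv = dict(visits)
                nv[nxt] = nv.get(nxt, 0) + 1
                new_frontier.append((seq + nxt[-1], nv))
            if out_of_budget:
                break
        if len(new_frontier) > params.max_active_branches:
            result.limit_reached = True
            new_frontier.sort(key=lambda sv: sv[0])
            new_frontier = new_frontier[:params.max_active_branches]
        frontier = new_frontier
    result.nodes_explored = nodes
    seqs = sorted(set(found), key=lambda s: (len(s), s))
    result.candidates = [
        AssemblyCandidate(sequence=s, params=params, branches_encountered=branches)
        for s in seqs]
    return result


def exhaustive_paths(graph: DeBruijnGraph, start: str, stop: str,
                     max_path_length: int = 1_000_000) -> list[str]:
    """Reference enumerator: depth-first search with the same path rules.

    Independent of :func:`traverse` (recursion instead of frontier
    expansion, no branch/node budgets); used to validate the traversal on
    small graphs.
    """
    if start not in graph:
        return []
    if start == stop:
        return [start]
    out: list[str] = []
    visits = {start: 1}

    def recurse(seq: str) -> None:
        cur = seq[-len(start):]
        for nxt in graph.successors(cur):
            if visits.get(nxt, 0) >= 2:
                continue
            if nxt == stop:
                out.append(seq + nxt[-1])
                continue
            if len(seq) + 1 >= max_path_length:
                continue
            visits[nxt] = visits.get(nxt, 0) + 1
            recurse(seq + nxt[-1])
            visits[nxt] -= 1

    recurse(start)
    return sorted(set(out), key=lambda s: (len(s), s))


# ---------------------------------------------------------------------------
# representative paths
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global alignment identity: matching columns / alignment columns."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="path", mode="NW")
    cigar = res["cigar"]
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches / columns if columns else 0.0


def representative_subset(candidates: list[AssemblyCandidate],
                          max_identity: float = REPRESENTATIVE_MAX_IDENTITY
                          ) -> list[AssemblyCandidate]:
    """Greedy reduction to candidates that pairwise differ by more than 10%.

    Walking candidates in their given (length, sequence) order, a candidate
    is kept iff its identity to every already-kept candidate is at most
    ``max_identity``; the output is pairwise-divergent by construction.
    """
    kept: list[AssemblyCandidate] = []
    for cand in candidates:
        if all(pairwise_identity(cand.sequence, other.sequence) <= max_identity
               for other in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# one assembly attempt
# ---------------------------------------------------------------------------

@dataclass
class TargetAssembly:
    """Outcome of one (k, a) attempt on one target."""

    candidates: list[AssemblyCandidate] = field(default_factory=list)
    anchors: AnchorKmers | None = None
    limit_reached: bool = False
    failure: str | None = None  # 'no_reads' | 'anchoring' | 'no_path'


def assemble_target(subsample, target: TargetLocus, params: AssemblyParams,
                    bam, ext: int, graph: DeBruijnGraph | None = None,
                    anchors: AnchorKmers | None = None) -> TargetAssembly:
    """Graph build, anchoring, traversal and representative reduction.

    ``graph``/``anchors`` may be injected by the iterative driver to reuse
    k-mer counts across abundance thresholds at the same k.
    """
    reads = subsample.reads if hasattr(subsample, "reads") else list(subsample)
    if not reads:
        return TargetAssembly(failure="no_reads")
    if graph is None:
        try:
            graph = build_graph(reads, params.k, params.a)
        except ValueError:
            return TargetAssembly(failure="no_reads")
    if anchors is None:
        try:
            anchors = pick_anchor_kmers(bam, target, params.k, ext)
        except AnchoringError as exc:
            logger.info("%s", exc)
            return TargetAssembly(failure="anchoring")
    trav = traverse(graph, anchors, params)
    if not trav.candidates:
        return TargetAssembly(anchors=anchors, limit_reached=trav.limit_reached,
                              failure="no_path")
    return TargetAssembly(candidates=representative_subset(trav.candidates),
                          anchors=anchors, limit_reached=trav.limit_reached)
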