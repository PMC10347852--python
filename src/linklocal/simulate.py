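"""Synthetic linked-read data with ground truth.

Emulates the generative structure of linked-read sequencing: long DNA
molecules (lognormal lengths, ~50 Kb mean) are drawn from one or two
haplotypes, each molecule carries a barcode, and paired short reads with
substitution errors are sampled from the molecules.  A coordinate-sorted
BAM is written from the true placements (no mapper involved): reads lying
entirely within a reference-colinear block of their haplotype are mapped
there, reads crossing variant breakpoints or inside inserted sequence are
emitted unmapped with their barcode preserved.  Truth tables record the
read -> molecule -> (barcode, haplotype, interval) chain for every read.
"""

from __future__ import annotations

import bisect
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from linklocal.dna import revcomp
from linklocal.io_formats import Region, TargetLocus, targets_to_gfa, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults reflect a typical linked-read experiment: 40x read coverage of
    100 bp pairs, molecules averaging 50 Kb (truncated lognormal within
    5-150 Kb) covering the genome ~10x in molecule bases, one molecule per
    barcode, and a 0.5% substitution error rate.
    """

    reference_length: int = 500_000
    coverage: float = 40.0
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 40.0
    error_rate: float = 0.005
    molecule_mean: float = 50_000.0
    molecule_sigma: float = 0.35  # lognormal shape on the log scale
    molecule_min: int = 5_000
    molecule_max: int = 150_000
    molecule_coverage: float = 10.0  # genome coverage in molecule bases
    molecules_per_barcode: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if min(self.reference_length, self.read_length, self.molecule_min,
               self.molecules_per_barcode) <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.coverage <= 0 or self.molecule_coverage <= 0:
            raise ValueError("coverages must be positive")


@dataclass
class Haplotype:
    """One haplotype of one contig, with reference-colinear blocks.

    ``blocks`` are (hap_start, hap_end, ref_start) triples mapping
    haplotype intervals onto the like-named reference contig; haplotype
    positions outside every block (inserted sequence) have no reference
    placement.
    """

    sequence: str
    blocks: list[tuple[int, int, int]]

    @classmethod
    def identity(cls, sequence: str) -> "Haplotype":
        return cls(sequence=sequence, blocks=[(0, len(sequence), 0)])

    def liftover(self, start: int, end: int) -> int | None:
        """Reference start of a haplotype interval fully inside one block."""
        i = bisect.bisect_right([b[0] for b in self.blocks], start) - 1
        if i < 0:
            return None
        hs, he, rs = self.blocks[i]
        if start >= hs and end <= he:
            return rs + (start - hs)
        return None


def build_haplotype(ref_seq: str, variants) -> Haplotype:
    """Apply non-overlapping, sorted variants to a reference contig.

    Variants are ("del", start, end) or ("ins", site, sequence) in
    reference coordinates.
    """
    pieces: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    ref_pos = 0
    hap_pos = 0

    def emit(ref_from: int, ref_to: int):
        nonlocal hap_pos
        if ref_to > ref_from:
            pieces.append(ref_seq[ref_from:ref_to])
            blocks.append((hap_pos, hap_pos + (ref_to - ref_from), ref_from))
            hap_pos += ref_to - ref_from

    for var in sorted(variants, key=lambda v: v[1]):
        kind = var[0]
        if kind == "del":
            _, start, end = var
            if start < ref_pos:
                raise ValueError("overlapping variants")
            emit(ref_pos, start)
            ref_pos = end
        elif kind == "ins":
            _, site, seq = var
            if site < ref_pos:
                raise ValueError("overlapping variants")
            emit(ref_pos, site)
            pieces.append(seq.upper())
            hap_pos += len(seq)
            ref_pos = site
        else:
            raise ValueError(f"unknown variant kind {kind!r}")
    emit(ref_pos, len(ref_seq))
    return Haplotype(sequence="".join(pieces), blocks=blocks)


@dataclass
class MoleculeRecord:
    mol_id: int
    barcode: str
    haplotype: int
    contig: str
    start: int  # on the haplotype sequence
    end: int


@dataclass
class MoleculeTruth:
    """Ground truth linking reads to molecules to barcodes and intervals."""

    molecules: dict[int, MoleculeRecord] = field(default_factory=dict)
    read_to_molecule: dict[str, int] = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        with open(directory / "molecules.tsv", "w") as out:
            out.write("mol_id\tbarcode\thaplotype\tcontig\tstart\tend\n")
            for m in self.molecules.values():
                out.write(f"{m.mol_id}\t{m.barcode}\t{m.haplotype}\t{m.contig}"
                          f"\t{m.start}\t{m.end}\n")
        with open(directory / "reads.tsv", "w") as out:
            out.write("read_id\tmol_id\n")
            for rid, mid in self.read_to_molecule.items():
                out.write(f"{rid}\t{mid}\n")

    @classmethod
    def load(cls, directory) -> "MoleculeTruth":
        directory = Path(directory)
        truth = cls()
        with open(directory / "molecules.tsv") as fh:
            next(fh)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rec = MoleculeRecord(int(f[0]), f[1], int(f[2]), f[3],
                                     int(f[4]), int(f[5]))
                truth.molecules[rec.mol_id] = rec
        with open(directory / "reads.tsv") as fh:
            next(fh)
            for line in fh:
                rid, mid = line.rstrip("\n").split("\t")
                truth.read_to_molecule[rid] = int(mid)
        return truth


@dataclass
class _PairRecord:
    read_id: str
    mol_id: int
    hap: int
    contig: str
    r1_start: int  # haplotype coordinates of the forward fragment ends
    r2_start: int
    r1_seq: str    # forward-strand sequences (errors included)
    r2_seq: str


@dataclass
class SimResult:
    reference: dict[str, str]
    ref_fasta: str
    fastq: str
    bam: str
    truth: MoleculeTruth
    config: SimConfig
    n_pairs: int = 0


def random_reference(length: int, seed_or_rng, name: str = "ref1") -> dict[str, str]:
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    arr = rng.integers(0, 4, size=length)
    return {name: _BASES[arr].tobytes().decode()}


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct 16-mer barcodes in 10x style (ACGT16-1)."""
    seen: set[int] = set()
    out: list[str] = []
    while len(out) < n:
        for code in rng.integers(0, 4 ** 16, size=n - len(out)):
            code = int(code)
            if code in seen:
                continue
            seen.add(code)
            chars = []
            for _ in range(16):
                chars.append("ACGT"[code & 3])
                code >>= 2
            out.append("".join(chars) + "-1")
    return out


def _inject_errors(seq: str, rng: np.random.Generator, n_err: int) -> str:
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=min(n_err, len(seq)), replace=False)
    arr = bytearray(seq, "ascii")
    for pos in positions:
        cur = arr[pos]
        choices = [b for b in b"ACGT" if b != cur]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return arr.decode()


def simulate(config: SimConfig, out_dir, reference: dict[str, str] | None = None,
             haplotypes: list[dict[str, Haplotype]] | None = None) -> SimResult:
    """Generate reference FASTA, barcoded FASTQ, truth BAM and truth tables.

    ``haplotypes`` is a list of haplotype sets (contig -> Haplotype), one
    per haplotype; molecules are drawn uniformly across haplotypes, so two
    haplotypes each receive half the read depth.  Identical configs and
    seeds produce identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if reference is None:
        reference = random_reference(config.reference_length, rng)
    if haplotypes is None:
        haplotypes = [{name: Haplotype.identity(seq)
                       for name, seq in reference.items()}]

    genome_size = sum(len(s) for s in reference.values())
    rl = config.read_length

    # --- molecules ---------------------------------------------------------
    n_mol = max(1, round(config.molecule_coverage * genome_size
                         / config.molecule_mean))
    mu = math.log(config.molecule_mean) - config.molecule_sigma ** 2 / 2
    lengths = np.clip(rng.lognormal(mu, config.molecule_sigma, size=n_mol),
                      config.molecule_min, config.molecule_max).astype(np.int64)
    hap_idx = rng.integers(0, len(haplotypes), size=n_mol)
    contigs = list(reference)
    contig_weights = np.array([len(reference[c]) for c in contigs], dtype=float)
    contig_idx = rng.choice(len(contigs), size=n_mol,
                            p=contig_weights / contig_weights.sum())

    n_barcodes = math.ceil(n_mol / config.molecules_per_barcode)
    barcodes = _random_barcodes(rng, n_barcodes)
    order = rng.permutation(n_mol)
    barcode_of = [""] * n_mol
    for rank, mol in enumerate(order):
        barcode_of[mol] = barcodes[rank // config.molecules_per_barcode]

    truth = MoleculeTruth()
    mol_span = []
    for m in range(n_mol):
        contig = contigs[contig_idx[m]]
        hap = haplotypes[hap_idx[m]][contig]
        length = int(min(lengths[m], len(hap.sequence)))
        start = int(rng.integers(0, len(hap.sequence) - length + 1))
        mol_span.append((contig, start, start + length))
        truth.molecules[m] = MoleculeRecord(
            mol_id=m, barcode=barcode_of[m], haplotype=int(hap_idx[m]),
            contig=contig, start=start, end=start + length)

    # --- read pairs --------------------------------------------------------
    total_pairs = max(1, round(config.coverage * genome_size / (2 * rl)))
    span_lengths = np.array([e - s for _, s, e in mol_span], dtype=float)
    alloc = rng.multinomial(total_pairs, span_lengths / span_lengths.sum())

    inserts = np.clip(rng.normal(config.insert_mean, config.insert_sd,
                                 size=total_pairs), rl, None).astype(np.int64)
    offset_u = rng.random(size=total_pairs)
    err_counts = rng.binomial(rl, config.error_rate, size=2 * total_pairs)

    pairs: list[_PairRecord] = []
    pair_i = 0
    for m in range(n_mol):
        contig, mstart, mend = mol_span[m]
        mol_len = mend - mstart
        hap = haplotypes[hap_idx[m]][contig]
        for _ in range(alloc[m]):
            insert = int(min(inserts[pair_i], mol_len))
            frag = mstart + int(offset_u[pair_i] * (mol_len - insert + 1))
            r1s, r2s = frag, frag + insert - rl
            r1 = _inject_errors(hap.sequence[r1s:r1s + rl], rng,
                                int(err_counts[2 * pair_i]))
            r2 = _inject_errors(hap.sequence[r2s:r2s + rl], rng,
                                int(err_counts[2 * pair_i + 1]))
            rid = f"r{pair_i:07d}"
            pairs.append(_PairRecord(rid, m, int(hap_idx[m]), contig,
                                     r1s, r2s, r1, r2))
            truth.read_to_molecule[rid] = m
            pair_i += 1

    # --- outputs -----------------------------------------------------------
    ref_fasta = str(out_dir / "reference.fa")
    write_fasta(reference, ref_fasta)
    fastq = str(out_dir / "reads.fq")
    qual = "I" * rl
    with open(fastq, "w") as out:
        for p in pairs:
            barcode = truth.molecules[p.mol_id].barcode
            out.write(f"@{p.read_id}/1 BX:Z:{barcode}\n{p.r1_seq}\n+\n{qual}\n")
            out.write(f"@{p.read_id}/2 BX:Z:{barcode}\n"
                      f"{revcomp(p.r2_seq)}\n+\n{qual}\n")
    truth.save(out_dir)
    bam = write_truth_bam(pairs, truth, reference, haplotypes,
                          str(out_dir / "reads.bam"), rl)
    return SimResult(reference=reference, ref_fasta=ref_fasta, fastq=fastq,
                     bam=bam, truth=truth, config=config, n_pairs=len(pairs))


def write_truth_bam(pairs, truth: MoleculeTruth, reference: dict[str, str],
                    haplotypes, out_bam: str, read_length: int) -> str:
    """Coordinate-sorted, indexed BAM of the true read placements.

    R1 is forward, R2 reverse (FR orientation).  A read whose haplotype
    interval lies inside a reference-colinear block maps with a full-match
    CIGAR; reads crossing variant breakpoints or inside insertions are
    written unmapped, keeping the barcode tag.
    """
    rl = read_length
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": name, "LN": len(seq)}
                     for name, seq in reference.items()]}
    unsorted = out_bam + ".unsorted"
    quals = pysam.qualitystring_to_array("I" * rl)
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for p in pairs:
            hap = haplotypes[p.hap][p.contig]
            barcode = truth.molecules[p.mol_id].barcode
            pos1 = hap.liftover(p.r1_start, p.r1_start + rl)
            pos2 = hap.liftover(p.r2_start, p.r2_start + rl)
            for mate, (pos, mpos, seq, rev) in enumerate(
                    [(pos1, pos2, p.r1_seq, False),
                     (pos2, pos1, p.r2_seq, True)], start=1):
                aln = pysam.AlignedSegment()
                aln.query_name = p.read_id
                aln.query_sequence = seq
                aln.query_qualities = quals
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if pos is None:
                    flag |= 0x4
                    if mpos is not None:
                        aln.reference_id = out.get_tid(p.contig)
                        aln.reference_start = mpos
                else:
                    aln.reference_id = out.get_tid(p.contig)
                    aln.reference_start = pos
                    aln.mapping_quality = 60
                    aln.cigarstring = f"{rl}M"
                    if rev:
                        flag |= 0x10
                if mpos is None:
                    flag |= 0x8
                else:
                    aln.next_reference_id = out.get_tid(p.contig)
                    aln.next_reference_start = mpos
                    if not rev:
                        flag |= 0x20  # mate (R2) on reverse strand
                if pos is not None and mpos is not None:
                    flag |= 0x2
                    tlen = (mpos + rl) - pos if not rev else -((pos + rl) - mpos)
                    aln.template_length = tlen
                aln.flag = flag
                aln.set_tag("BX", barcode)
                out.write(aln)
    pysam.sort("-o", out_bam, unsorted)
    os.unlink(unsorted)
    pysam.index(out_bam)
    return out_bam


# ---------------------------------------------------------------------------
# planted targets
# ---------------------------------------------------------------------------

@dataclass
class PlantedTarget:
    """One target with its known truth sequence (and donor haplotypes)."""

    target: TargetLocus
    truth: str  # expected assembled target (extensions excluded)
    truth_alt: str | None = None  # second allele for heterozygous variants


@dataclass
class PlantedDesign:
    targets: list[PlantedTarget]
    haplotypes: list[dict[str, Haplotype]] | None  # None: reads from reference

    @property
    def gfa(self) -> str:
        return targets_to_gfa([p.target for p in self.targets])

    def truth_of(self, label: str) -> str:
        for p in self.targets:
            if p.target.label == label:
                return p.truth
        raise KeyError(label)


def plant_random_loci(reference: dict[str, str], contig: str, sizes,
                      seed_or_rng, flank_len: int = 15_000,
                      margin: int = 2_000) -> PlantedDesign:
    """Targets whose true sequence is a uniformly sampled reference locus.

    The reads still come from the whole (unmodified) genome; the truth is
    simply known because the target already sits in the reference.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    length = len(reference[contig])
    planted = []
    for i, size in enumerate(sizes):
        lo = margin + flank_len
        hi = length - size - margin - flank_len
        if hi <= lo:
            raise ValueError(f"reference too short for a {size} bp locus")
        start = int(rng.integers(lo, hi))
        target = TargetLocus(
            label=f"locus_{i}_{size}bp",
            left_flank=Region(contig, start - flank_len, start),
            right_flank=Region(contig, start + size, start + size + flank_len),
            gap_length_estimate=size)
        planted.append(PlantedTarget(target=target,
                                     truth=reference[contig][start:start + size]))
    return PlantedDesign(targets=planted, haplotypes=None)


def plant_deletions(reference: dict[str, str], contig: str, deletions,
                    pad: int = 50, flank_len: int = 15_000,
                    heterozygous: bool = False) -> PlantedDesign:
    """Donor genome carrying deletions; targets are the segments +/- pad.

    Each truth is the novel breakpoint adjacency of length 2*pad.
    ``deletions`` is a list of (start, end) reference intervals, sorted
    and non-overlapping.
    """
    seq = reference[contig]
    variants = [("del", s, e) for s, e in deletions]
    hap = build_haplotype(seq, variants)
    hapset = {c: (Haplotype.identity(s) if c != contig else hap)
              for c, s in reference.items()}
    identity = {c: Haplotype.identity(s) for c, s in reference.items()}
    planted = []
    for i, (ds, de) in enumerate(deletions):
        target = TargetLocus(
            label=f"del_{i}_{ds}_{de}",
            left_flank=Region(contig, ds - pad - flank_len, ds - pad),
            right_flank=Region(contig, de + pad, de + pad + flank_len),
            gap_length_estimate=2 * pad)
        truth = seq[ds - pad:ds] + seq[de:de + pad]
        truth_alt = seq[ds - pad:de + pad] if heterozygous else None
        planted.append(PlantedTarget(target=target, truth=truth,
                                     truth_alt=truth_alt))
    haplotypes = [hapset, identity] if heterozygous else [hapset]
    return PlantedDesign(targets=planted, haplotypes=haplotypes)


def plant_insertion(reference: dict[str, str], contig: str, site: int,
                    insertion: str, pad: int = 50, flank_len: int = 15_000,
                    heterozygous: bool = False) -> PlantedDesign:
    """Donor genome carrying an insertion; target is the site +/- pad.

    The expected assembly length is unknown a priori (the inserted
    sequence is novel), so the gap length estimate is left unknown.  For a
    heterozygous insertion the alternative allele (reference adjacency,
    length 2*pad) is recorded as ``truth_alt``.
    """
    seq = reference[contig]
    hap = build_haplotype(seq, [("ins", site, insertion)])
    hapset = {c: (Haplotype.identity(s) if c != contig else hap)
              for c, s in reference.items()}
    identity = {c: Haplotype.identity(s) for c, s in reference.items()}
    target = TargetLocus(
        label=f"ins_{site}",
        left_flank=Region(contig, site - pad - flank_len, site - pad),
        right_flank=Region(contig, site + pad, site + pad + flank_len),
        gap_length_estimate=None)
    truth = seq[site - pad:site] + insertion.upper() + seq[site:site + pad]
    truth_alt = seq[site - pad:site + pad] if heterozygous else None
    planted = PlantedTarget(target=target, truth=truth, truth_alt=truth_alt)
    haplotypes = [hapset, identity] if heterozygous else [hapset]
    return PlantedDesign(targets=[planted], haplotypes=haplotypes)
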