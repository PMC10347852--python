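"""Benchmark-mode harnesses on synthetic data.

Implements the evaluation protocol used to measure the method: targets are
planted at loci whose true sequence is known (randomly sampled loci,
deletion breakpoints, insertion alleles), the full pipeline runs blind to
the truth, and results are classified successful / erroneous / no-assembly
with the 90/90 rule.  Also provides the subsampling-enrichment measurement
and the traversal-vs-exhaustive-enumeration validation harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from linklocal.dbg import build_graph, exhaustive_paths, traverse, AnchorKmers, AssemblyParams
from linklocal.evaluate import benchmark_classify, summarize_benchmark
from linklocal.io_formats import build_barcode_index
from linklocal.pipeline import RunConfig, run_pipeline
from linklocal.simulate import (
    PlantedDesign,
    SimConfig,
    plant_deletions,
    plant_insertion,
    plant_random_loci,
    random_reference,
    simulate,
)
from linklocal.subsample import collect_flank_barcodes, flank_windows, select_barcodes, subsample_reads


@dataclass
class BenchmarkRun:
    sim: object
    design: PlantedDesign
    report: object
    labels: dict[str, object] = field(default_factory=dict)

    def summary(self) -> dict:
        return summarize_benchmark(self.labels.values())


def run_design(out_dir, sim, design, **config_kw) -> object:
    """Run the full pipeline on a simulated dataset and planted design."""
    return _run(out_dir, sim, design, **config_kw)


def _run(out_dir, sim, design, **config_kw) -> object:
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    gfa_path = Path(out_dir) / "targets.gfa"
    gfa_path.write_text(design.gfa)
    config = RunConfig(gfa=str(gfa_path), bam=sim.bam, reads=sim.fastq,
                       reference=sim.ref_fasta,
                       out_dir=str(Path(out_dir) / "run"), **config_kw)
    return run_pipeline(config)


def random_locus_benchmark(out_dir, seed: int, ref_len: int = 500_000,
                           sizes=(1000,) * 20 + (5000,) * 10,
                           coverage: float = 40.0,
                           **config_kw) -> BenchmarkRun:
    """Plant loci of known sequence, assemble them blind, classify vs truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = random_reference(ref_len, seed)
    design = plant_random_loci(ref, "ref1", sizes, seed + 1,
                               flank_len=15_000, margin=2_000)
    sim = simulate(SimConfig(reference_length=ref_len, coverage=coverage,
                             seed=seed), out_dir, reference=ref)
    report = _run(out_dir, sim, design, **config_kw)
    labels = {row.label: benchmark_classify(row.sequence,
                                            design.truth_of(row.label))
              for row in report.rows}
    return BenchmarkRun(sim=sim, design=design, report=report, labels=labels)


def deletion_benchmark(out_dir, seed: int, n_deletions: int = 10,
                       ref_len: int = 420_000, pad: int = 50) -> BenchmarkRun:
    """Homozygous deletions of 1-5 Kb; targets are the segments +/- pad."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ref = random_reference(ref_len, rng)
    spacing = (ref_len - 60_000) // n_deletions
    deletions = []
    for i in range(n_deletions):
        size = int(rng.integers(1_000, 5_001))
        start = 30_000 + i * spacing + int(rng.integers(0, spacing - 5_200))
        deletions.append((start, start + size))
    design = plant_deletions(ref, "ref1", deletions, pad=pad, flank_len=15_000)
    sim = simulate(SimConfig(reference_length=ref_len, seed=seed), out_dir,
                   reference=ref, haplotypes=design.haplotypes)
    report = _run(out_dir, sim, design)
    labels = {row.label: benchmark_classify(row.sequence,
                                            design.truth_of(row.label))
              for row in report.rows}
    return BenchmarkRun(sim=sim, design=design, report=report, labels=labels)


def het_insertion_case(out_dir, seed: int, insertion_len: int = 1_000,
                       ref_len: int = 150_000,
                       report_multiple: bool = False) -> BenchmarkRun:
    """A heterozygous insertion whose alleles diverge by far more than 10%."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ref = random_reference(ref_len, rng)
    insertion = "".join("ACGT"[i] for i in rng.integers(0, 4, size=insertion_len))
    design = plant_insertion(ref, "ref1", ref_len // 2, insertion,
                             flank_len=15_000, heterozygous=True)
    sim = simulate(SimConfig(reference_length=ref_len, seed=seed), out_dir,
                   reference=ref, haplotypes=design.haplotypes)
    report = _run(out_dir, sim, design, report_multiple=report_multiple)
    return BenchmarkRun(sim=sim, design=design, report=report)


def repeat_ladder_case(out_dir, seed: int, unit_len: int = 300,
                       ref_len: int = 150_000) -> BenchmarkRun:
    """One easy unique-sequence target and one spanning an exact tandem
    repeat pair (two adjacent copies of a unit), assembled with the
    default ladder."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = random_reference(ref_len, rng)["ref1"]
    unit = "".join("ACGT"[i] for i in rng.integers(0, 4, size=unit_len))
    repeat_at = ref_len // 3
    ref_seq = base[:repeat_at] + unit + unit + base[repeat_at:]
    ref = {"ref1": ref_seq}
    flank = 15_000
    # repeat target: 1 Kb window centred on the tandem pair
    pre = (1_000 - 2 * unit_len) // 2
    r_start = repeat_at - pre
    r_end = r_start + 1_000
    from linklocal.io_formats import Region, TargetLocus
    from linklocal.simulate import PlantedTarget
    repeat_target = PlantedTarget(
        target=TargetLocus(label="repeat_target",
                           left_flank=Region("ref1", r_start - flank, r_start),
                           right_flank=Region("ref1", r_end, r_end + flank),
                           gap_length_estimate=1_000),
        truth=ref_seq[r_start:r_end])
    easy_start = 2 * ref_len // 3
    easy_target = PlantedTarget(
        target=TargetLocus(label="easy_target",
                           left_flank=Region("ref1", easy_start - flank, easy_start),
                           right_flank=Region("ref1", easy_start + 1_000,
                                              easy_start + 1_000 + flank),
                           gap_length_estimate=1_000),
        truth=ref_seq[easy_start:easy_start + 1_000])
    design = PlantedDesign(targets=[easy_target, repeat_target], haplotypes=None)
    sim = simulate(SimConfig(reference_length=len(ref_seq), seed=seed),
                   out_dir, reference=ref)
    report = _run(out_dir, sim, design)
    labels = {row.label: benchmark_classify(row.sequence,
                                            design.truth_of(row.label))
              for row in report.rows}
    return BenchmarkRun(sim=sim, design=design, report=report, labels=labels)


# ---------------------------------------------------------------------------
# subsampling enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentMetrics:
    enrichment_fold: float
    recruited_fraction: float
    near_fraction_recruited: float
    near_fraction_genome: float


def subsampling_enrichment(sim, design: PlantedDesign, target_index: int = 0,
                           flank_size: int = 10_000, min_occ: int = 2,
                           reach: int = 50_000, index=None) -> EnrichmentMetrics:
    """How strongly barcode recruitment concentrates reads near the target.

    Compares the fraction of recruited reads whose truth molecule overlaps
    [gap - reach, gap + reach] with the same fraction over all reads.
    """
    t = design.targets[target_index].target
    lengths = {name: len(seq) for name, seq in sim.reference.items()}
    windows = flank_windows(t, flank_size, lengths)
    table = collect_flank_barcodes(sim.bam, windows)
    selection = select_barcodes(table, min_occ, target=t.label)
    if index is None:
        index = build_barcode_index(sim.fastq)
    sub = subsample_reads(selection, index)

    lo = t.gap_abuts_left - reach
    hi = t.gap_abuts_right + reach
    truth = sim.truth

    def near(read_id: str) -> bool:
        mol = truth.molecules[truth.read_to_molecule[read_id]]
        return mol.contig == t.left_flank.sequence_id and \
            mol.start < hi and mol.end > lo

    n_total = 2 * sim.n_pairs
    n_near_genome = sum(near(rid) for rid in truth.read_to_molecule)
    recruited = [r.read_id for r in sub.reads]
    n_near_recruited = sum(near(rid) for rid in recruited)
    near_rec = n_near_recruited / len(recruited) if recruited else 0.0
    near_gen = n_near_genome / len(truth.read_to_molecule)
    return EnrichmentMetrics(
        enrichment_fold=near_rec / near_gen if near_gen else float("inf"),
        recruited_fraction=len(recruited) / n_total,
        near_fraction_recruited=near_rec,
        near_fraction_genome=near_gen)


# ---------------------------------------------------------------------------
# traversal-vs-oracle validation
# ---------------------------------------------------------------------------

def traversal_oracle_trials(n_trials: int, seed: int) -> tuple[int, int]:
    """Random small graphs: count trials where the frontier traversal and
    the exhaustive DFS enumerator return identical path sets."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        k = int(rng.choice([15, 21]))
        backbone = "".join("ACGT"[i] for i in
                           rng.integers(0, 4, size=int(rng.integers(100, 400))))
        reads = [backbone]
        for _ in range(int(rng.integers(0, 3))):
            arr = list(backbone)
            for pos in rng.choice(len(arr), size=max(1, len(arr) // 200),
                                  replace=False):
                arr[pos] = "ACGT"[("ACGT".index(arr[pos]) + 1
                                   + int(rng.integers(0, 3))) % 4]
            reads.append("".join(arr))
        if rng.random() < 0.4:
            pos = int(rng.integers(20, len(backbone) - 60))
            reads.append(backbone[:pos] + backbone[pos:pos + 40] * 2
                         + backbone[pos + 40:])
        graph = build_graph(reads, k=k, a=1)
        anchors = AnchorKmers(backbone[:k], backbone[-k:], 1, 1)
        params = AssemblyParams(k=k, a=1, max_path_length=5_000,
                                max_active_branches=100_000)
        got = [c.sequence for c in traverse(graph, anchors, params).candidates]
        expected = exhaustive_paths(graph, backbone[:k], backbone[-k:],
                                    max_path_length=5_000)
        if got == expected and got:
            agree += 1
    return agree, n_trials
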