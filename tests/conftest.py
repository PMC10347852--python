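"""Shared fixtures: tiny hand-built files and one small simulated dataset."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from linklocal.io_formats import write_fasta
from linklocal.pipeline import RunConfig
from linklocal.simulate import SimConfig, plant_random_loci, random_reference, simulate


def make_bam(path, reference: dict[str, str], records) -> str:
    """Write a small coordinate-sorted indexed BAM from record dicts.

    Each record: name, contig, pos, seq, and optional flag/mapq/cigar/tags.
    """
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": n, "LN": len(s)} for n, s in reference.items()]}
    tmp = str(path) + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for rec in records:
            aln = pysam.AlignedSegment()
            aln.query_name = rec["name"]
            aln.query_sequence = rec["seq"]
            aln.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
            aln.reference_id = out.get_tid(rec["contig"])
            aln.reference_start = rec["pos"]
            aln.mapping_quality = rec.get("mapq", 60)
            aln.cigarstring = rec.get("cigar", f"{len(rec['seq'])}M")
            aln.flag = rec.get("flag", 0)
            for tag, value in rec.get("tags", {}).items():
                aln.set_tag(tag, value)
            out.write(aln)
    pysam.sort("-o", str(path), tmp)
    pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """120 Kb haploid dataset at 40x with three solvable planted loci.

    Shared read-only across tests; returns (SimResult, PlantedDesign,
    gfa path).
    """
    out = tmp_path_factory.mktemp("small_sim")
    ref = random_reference(120_000, 7)
    design = plant_random_loci(ref, "ref1", [1000, 1000, 2000], 7,
                               flank_len=12_000, margin=2_000)
    sim = simulate(SimConfig(reference_length=120_000, seed=7), out,
                   reference=ref)
    gfa_path = out / "targets.gfa"
    gfa_path.write_text(design.gfa)
    return sim, design, str(gfa_path)


@pytest.fixture()
def small_run_config(small_sim, tmp_path):
    sim, design, gfa_path = small_sim
    return RunConfig(gfa=gfa_path, bam=sim.bam, reads=sim.fastq,
                     reference=sim.ref_fasta, out_dir=str(tmp_path / "out"))


@pytest.fixture()
def tiny_reference(tmp_path):
    """One 30 Kb contig, written to FASTA, plus the in-memory dict."""
    ref = random_reference(30_000, 3)
    path = tmp_path / "ref.fa"
    write_fasta(ref, path)
    return ref, str(path)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)
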