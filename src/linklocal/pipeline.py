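"""End-to-end orchestration over many targets.

Each target is processed independently (subsample -> iterative assembly ->
quality gate), optionally in parallel worker processes; per-target failures
are recorded in the run report and never abort the batch.  Outputs are an
assembled-targets FASTA, a GFA complementing the input (solved gaps become
segments linked to their flanks by edges, unsolved gaps keep their G
lines), and a per-target TSV report.  Output bytes are independent of the
worker count.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, fields
from pathlib import Path

import pyfaidx
import pysam

from linklocal import io_formats, subsample as subsample_mod
from linklocal.evaluate import (
    STATUS_MULTIPLE,
    STATUS_NO_ASSEMBLY,
    STATUS_SOLVED,
    ParameterLadder,
    iterative_assemble,
)
from linklocal.io_formats import (
    BarcodeIndex,
    Region,
    TargetLocus,
    build_barcode_index,
    parse_gfa,
    read_gfa_targets,
    write_fastq,
)
from linklocal.subsample import (
    collect_flank_barcodes,
    flank_windows,
    select_barcodes,
    subsample_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips through a key=value file."""

    gfa: str = ""
    bam: str = ""
    reads: str = ""
    reference: str = ""
    out_dir: str = "linklocal_out"
    flank_size: int = 10_000
    min_occurrences: int = 2
    barcode_dialect: str = "auto"
    ext: int = 500
    kmer_ladder: tuple[int, ...] = (61, 51, 41, 31, 21)
    abundance_ladder: tuple[int, ...] = (3, 2)
    min_identity: float = 0.90
    min_coverage: float = 0.90
    report_multiple: bool = False
    max_active_branches: int = 100
    max_nodes_explored: int = 10_000_000
    threads: int = 1
    resume: bool = False

    def save(self, path) -> None:
        with open(path, "w") as out:
            for f in fields(self):
                value = getattr(self, f.name)
                if isinstance(value, tuple):
                    value = ",".join(map(str, value))
                out.write(f"{f.name}={value}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                if key not in types:
                    raise KeyError(f"unknown config key {key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, tuple):
                    kwargs[key] = tuple(int(x) for x in raw.split(",") if x)
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    def ladder(self) -> ParameterLadder:
        return ParameterLadder.default(self.kmer_ladder, self.abundance_ladder)


@dataclass
class TargetRow:
    label: str
    status: str
    k: int | None = None
    a: int | None = None
    n_barcodes: int = 0
    n_reads: int = 0
    left_identity: float = 0.0
    left_coverage: float = 0.0
    right_identity: float = 0.0
    right_coverage: float = 0.0
    length: int = 0
    sequence: str | None = None
    full_sequence: str | None = None
    alternatives: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunReport:
    rows: list[TargetRow]

    @property
    def counts(self) -> dict[str, int]:
        out = {STATUS_SOLVED: 0, STATUS_MULTIPLE: 0, STATUS_NO_ASSEMBLY: 0,
               "error": 0}
        for row in self.rows:
            out[row.status if row.error is None else "error"] += 1
        return out


def ensure_index(config: RunConfig) -> BarcodeIndex:
    """Load the on-disk barcode index or build and persist it."""
    index_path = BarcodeIndex.default_path(config.reads)
    if os.path.exists(index_path):
        return BarcodeIndex.load(index_path, reads_path=config.reads)
    index = build_barcode_index(config.reads, dialect=config.barcode_dialect)
    index.save(index_path)
    return index


def process_target(target: TargetLocus, config: RunConfig,
                   index: BarcodeIndex, reference, work_dir) -> TargetRow:
    """Subsample, assemble and gate one target; never raises for data issues."""
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    sub_fq = work_dir / f"{target.label}.subsample.fq"
    barcode_tsv = work_dir / f"{target.label}.barcodes.tsv"
    row = TargetRow(label=target.label, status=STATUS_NO_ASSEMBLY)
    try:
        with pysam.AlignmentFile(config.bam, "rb") as bam:
            lengths = {name: bam.get_reference_length(name)
                       for name in bam.references}
            if config.resume and sub_fq.exists():
                logger.info("%s: resume, reusing %s", target.label, sub_fq)
                reads = list(io_formats.iter_fastq(sub_fq))
                sub = subsample_mod.ReadSubsample(
                    target=target.label, reads=reads,
                    n_barcodes=len({r.barcode for r in reads if r.barcode}))
            else:
                windows = flank_windows(target, config.flank_size, lengths)
                table = collect_flank_barcodes(bam, windows)
                selection = select_barcodes(table, config.min_occurrences,
                                            target.label, config.flank_size)
                sub = subsample_reads(selection, index)
                write_fastq(sub.reads, sub_fq)
                with open(barcode_tsv, "w") as out:
                    out.write("barcode\toccurrences\n")
                    for barcode in selection.barcodes:
                        out.write(f"{barcode}\t{selection.occurrence_table[barcode]}\n")
            row.n_barcodes = sub.n_barcodes
            row.n_reads = sub.n_reads
            result = iterative_assemble(
                target, sub, bam, reference,
                ladder=config.ladder(), ext=config.ext,
                min_identity=config.min_identity,
                min_coverage=config.min_coverage,
                report_multiple=config.report_multiple,
                max_active_branches=config.max_active_branches,
                max_nodes_explored=config.max_nodes_explored)
        row.status = result.status
        row.k, row.a = result.k, result.a
        row.alternatives = result.alternatives
        if result.status == STATUS_SOLVED:
            row.sequence = result.sequence
            row.full_sequence = result.full_sequence
            row.length = len(result.sequence or "")
            v = result.verdict
            row.left_identity, row.left_coverage = v.left_identity, v.left_coverage
            row.right_identity, row.right_coverage = v.right_identity, v.right_coverage
    except Exception as exc:  # keep the batch alive; report the failure
        logger.exception("target %s failed", target.label)
        row.error = f"{type(exc).__name__}: {exc}"
    return row


def _worker(args) -> TargetRow:
    target, config = args
    reference = pyfaidx.Fasta(config.reference)
    index = BarcodeIndex.load(BarcodeIndex.default_path(config.reads),
                              reads_path=config.reads)
    return process_target(target, config, index, reference,
                          Path(config.out_dir) / "work")


def run_pipeline(config: RunConfig) -> RunReport:
    """Process every G line of the input GFA; write FASTA, GFA and report."""
    out_dir = Path(config.out_dir)
    (out_dir / "work").mkdir(parents=True, exist_ok=True)
    reference = pyfaidx.Fasta(config.reference)
    targets = read_gfa_targets(config.gfa, reference)
    labels = [t.label for t in targets]
    if len(set(labels)) != len(labels):
        raise ValueError("target labels are not unique")
    ensure_index(config)  # built once; workers reopen it read-only

    if config.threads > 1 and len(targets) > 1:
        with ProcessPoolExecutor(max_workers=config.threads) as pool:
            rows = list(pool.map(_worker, [(t, config) for t in targets]))
    else:
        index = BarcodeIndex.load(BarcodeIndex.default_path(config.reads),
                                  reads_path=config.reads)
        rows = [process_target(t, config, index, reference, out_dir / "work")
                for t in targets]

    report = RunReport(rows=rows)
    _write_outputs(config, targets, report)
    return report


def _write_outputs(config: RunConfig, targets, report: RunReport) -> None:
    out_dir = Path(config.out_dir)
    rows = {row.label: row for row in report.rows}
    with open(out_dir / "assembled_targets.fasta", "w") as out:
        for t in targets:
            row = rows[t.label]
            if row.sequence is not None:
                out.write(f">{t.label}.assembled k={row.k} a={row.a} "
                          f"len={row.length}\n{row.sequence}\n")
            for j, alt in enumerate(row.alternatives):
                out.write(f">{t.label}.alt{j} k={row.k} a={row.a} "
                          f"len={len(alt)}\n{alt}\n")
    _write_filled_gfa(config, targets, rows, out_dir / "targets_filled.gfa")
    with open(out_dir / "report.tsv", "w") as out:
        cols = ["label", "status", "k", "a", "n_barcodes", "n_reads",
                "left_identity", "left_coverage", "right_identity",
                "right_coverage", "length", "error"]
        out.write("\t".join(cols) + "\n")
        for t in targets:
            row = rows[t.label]
            values = [getattr(row, c) for c in cols]
            out.write("\t".join("" if v is None else
                                (f"{v:.4f}" if isinstance(v, float) else str(v))
                                for v in values) + "\n")


def _write_filled_gfa(config: RunConfig, targets, rows, path) -> None:
    """Complement the input GFA: solved gaps become segments plus edges.

    The assembled segment is the full extended sequence (anchors and
    flank extensions included), so it overlaps each flank segment by
    ext + k bp; the two E lines record those overlaps.  Unsolved targets
    keep their G lines.
    """
    segments, gaps, other = parse_gfa(config.gfa)
    lines = other or ["H\tVN:Z:2.0"]
    lines += [seg.to_line() for seg in segments.values()]
    label_of = {t.label: t for t in targets}
    gap_by_label = {}
    for i, gap in enumerate(gaps):
        label = gap.gid if gap.gid != "*" else f"{gap.sid1}_{gap.sid2}_{i}"
        gap_by_label[label] = gap
    for t in targets:
        row = rows[t.label]
        gap = gap_by_label[t.label]
        if row.full_sequence is None:
            lines.append(gap.to_line())
            continue
        sid = f"{t.label}.assembled"
        seq = row.full_sequence
        overlap = config.ext + (row.k or 0)
        lines.append(f"S\t{sid}\t{len(seq)}\t{seq}")
        left_len = segments[gap.sid1].length or len(t.left_flank)
        right_len = segments[gap.sid2].length or len(t.right_flank)
        lines.append(f"E\t{t.label}.e1\t{gap.sid1}{gap.orient1}\t{sid}+\t"
                     f"{max(0, left_len - overlap)}\t{left_len}$\t0\t{overlap}\t*")
        lines.append(f"E\t{t.label}.e2\t{sid}+\t{gap.sid2}{gap.orient2}\t"
                     f"{max(0, len(seq) - overlap)}\t{len(seq)}$\t0\t{overlap}\t*")
    with open(path, "w") as out:
        out.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SV targets from VCF
# ---------------------------------------------------------------------------

def sv_targets_from_vcf(vcf, reference, mode: str, pad: int = 50,
                        flank_len: int = 10_000) -> tuple[str, list[TargetLocus]]:
    """Targets for SV allele reconstruction from VCF calls.

    Deletion mode spans the deleted segment +/- pad bp, so the expected
    assembly is the 2*pad bp breakpoint adjacency; insertion mode targets
    the insertion site +/- pad bp with unknown expected length (the
    inserted sequence is novel).  Records without resolvable coordinates
    are skipped with a warning.
    """
    if mode not in ("deletion", "insertion"):
        raise ValueError("mode must be 'deletion' or 'insertion'")
    targets = []
    with pysam.VariantFile(str(vcf)) as vf:
        for i, rec in enumerate(vf):
            svtype = rec.info.get("SVTYPE")
            if svtype is None and rec.alts:
                alt = rec.alts[0]
                if alt.startswith("<") and alt.endswith(">"):
                    svtype = alt[1:-1]
                elif rec.ref and len(rec.ref) > len(alt):
                    svtype = "DEL"
                elif rec.ref and len(alt) > len(rec.ref):
                    svtype = "INS"
            wanted = "DEL" if mode == "deletion" else "INS"
            if svtype != wanted:
                continue
            contig = rec.chrom
            if not io_formats.ref_has(reference, contig):
                logger.warning("skipping %s:%s: contig not in reference",
                               rec.chrom, rec.pos)
                continue
            start = rec.start  # 0-based
            end = rec.stop
            length = io_formats.ref_length(reference, contig)
            if mode == "deletion":
                gap_start, gap_end = start - pad, end + pad
                estimate = 2 * pad
            else:
                gap_start, gap_end = start - pad, start + pad
                estimate = None
            if gap_start - flank_len < 0 or gap_end + flank_len > length:
                logger.warning("skipping %s:%s: too close to contig end",
                               rec.chrom, rec.pos)
                continue
            targets.append(TargetLocus(
                label=f"{mode}_{i}_{contig}_{start}",
                left_flank=Region(contig, gap_start - flank_len, gap_start),
                right_flank=Region(contig, gap_end, gap_end + flank_len),
                gap_length_estimate=estimate))
    return io_formats.targets_to_gfa(targets), targets
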