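"""Readers and writers for the formats the tool consumes and produces.

FASTA access goes through :mod:`pyfaidx` (or an in-memory mapping of
name -> sequence), barcoded FASTQ is parsed record-wise with byte offsets
so that the barcode index can seek straight back to any read, and targets
are exchanged as GFA 2.0 with flanks as S lines and gaps as G lines.

All coordinates inside the package are 0-based half-open; conversion to
1-based conventions (BAM text forms, GFA display) happens only at the
edges of this module.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from linklocal.dna import revcomp

logger = logging.getLogger(__name__)

UNKNOWN = None  # gap length estimate sentinel


class GfaError(ValueError):
    """Malformed GFA content."""


class SegmentResolutionError(GfaError):
    """A gap references a segment that cannot be placed on the reference."""


# ---------------------------------------------------------------------------
# reference access (pyfaidx Fasta or plain mapping name -> sequence)
# ---------------------------------------------------------------------------

def ref_length(reference, name: str) -> int:
    if isinstance(reference, Mapping):
        return len(reference[name])
    return len(reference[name])  # pyfaidx FastaRecord also supports len()


def ref_has(reference, name: str) -> bool:
    if isinstance(reference, Mapping):
        return name in reference
    try:
        reference[name]
        return True
    except KeyError:
        return False


def ref_fetch(reference, name: str, start: int | None = None,
              end: int | None = None) -> str:
    """Forward-strand subsequence of a reference contig, upper-cased."""
    if start is None:
        start, end = 0, ref_length(reference, name)
    if isinstance(reference, Mapping):
        return reference[name][start:end].upper()
    return str(reference[name][start:end]).upper()


def ref_names(reference) -> list[str]:
    if isinstance(reference, Mapping):
        return list(reference)
    return list(reference.keys())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """An oriented interval on a reference contig, 0-based half-open."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid region {self.sequence_id}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def fetch(self, reference) -> str:
        """Oriented sequence: reverse-complemented when strand is '-'."""
        seq = ref_fetch(reference, self.sequence_id, self.start, self.end)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class TargetLocus:
    """A gap between two oriented flanks, to be reconstructed.

    Flanks are oriented in assembly direction: the left flank's 3' end and
    the right flank's 5' end abut the gap.  ``gap_length_estimate`` is the
    expected length of the assembled target in bp, or ``None`` when unknown
    (e.g. inter-scaffold gaps, insertion sites).
    """

    label: str
    left_flank: Region
    right_flank: Region
    gap_length_estimate: int | None = UNKNOWN

    def left_sequence(self, reference) -> str:
        return self.left_flank.fetch(reference)

    def right_sequence(self, reference) -> str:
        return self.right_flank.fetch(reference)

    @property
    def gap_abuts_left(self) -> int:
        """Reference coordinate where the gap meets the left flank."""
        return self.left_flank.end if self.left_flank.strand == "+" \
            else self.left_flank.start

    @property
    def gap_abuts_right(self) -> int:
        """Reference coordinate where the gap meets the right flank."""
        return self.right_flank.start if self.right_flank.strand == "+" \
            else self.right_flank.end


@dataclass(frozen=True)
class BarcodedRead:
    """One read with its molecular barcode (or None when untagged)."""

    read_id: str
    mate: int
    sequence: str
    qualities: str
    barcode: str | None = None

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")
        if self.barcode is not None and (not self.barcode or
                                         any(c.isspace() for c in self.barcode)):
            raise ValueError(f"{self.read_id}: malformed barcode {self.barcode!r}")


# ---------------------------------------------------------------------------
# barcoded FASTQ
# ---------------------------------------------------------------------------

def _split_read_name(name: str) -> tuple[str, int]:
    """Strip a /1 or /2 mate suffix; mate 0 means unknown."""
    if name.endswith("/1"):
        return name[:-2], 1
    if name.endswith("/2"):
        return name[:-2], 2
    return name, 0


def parse_barcode(name: str, comment: str, dialect: str = "auto") -> tuple[str, str | None]:
    """Extract (bare read name, barcode) from a FASTQ header.

    Dialects:
      * ``bx``      -- a ``BX:Z:<barcode>`` field in the comment (10x style);
      * ``suffix``  -- a trailing ``#<barcode>`` on the read name (stLFR style);
      * ``auto``    -- try ``bx`` then ``suffix``.
    """
    barcode = None
    if dialect in ("bx", "auto"):
        for tok in comment.split():
            if tok.startswith("BX:Z:"):
                barcode = tok[5:] or None
                break
    if barcode is None and dialect in ("suffix", "auto"):
        if "#" in name:
            name, _, suffix = name.rpartition("#")
            barcode = suffix or None
    return name, barcode


def _open_maybe_gzip(path, mode="rb"):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path, dialect: str = "auto",
               tag_map: Mapping[str, str] | None = None,
               with_offsets: bool = False) -> Iterator:
    """Iterate FASTQ records as BarcodedRead, optionally with byte offsets.

    Offsets refer to the uncompressed byte stream, which is what the
    barcode index stores.  ``tag_map`` (read name -> barcode) overrides any
    in-header barcode, supporting sidecar barcode tables.
    """
    fh = _open_maybe_gzip(path)
    try:
        offset = 0
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise GfaError(f"{path}: truncated FASTQ record at offset {offset}")
            record_len = len(header) + len(seq) + len(plus) + len(qual)
            h = header.decode().rstrip("\n")
            if not h.startswith("@"):
                raise ValueError(f"{path}: bad FASTQ header at offset {offset}: {h[:40]!r}")
            name, _, comment = h[1:].partition(" ")
            name, barcode = parse_barcode(name, comment, dialect)
            name, mate = _split_read_name(name)
            if tag_map is not None:
                barcode = tag_map.get(name, barcode)
            read = BarcodedRead(
                read_id=name, mate=mate,
                sequence=seq.decode().rstrip("\n").upper(),
                qualities=qual.decode().rstrip("\n"),
                barcode=barcode,
            )
            yield (offset, read) if with_offsets else read
            offset += record_len
    finally:
        fh.close()


def load_tag_file(path) -> dict[str, str]:
    """Two-column sidecar table: read name <tab> barcode."""
    table = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, barcode = line.split()[:2]
                table[_split_read_name(name)[0]] = barcode
    return table


def write_fastq(reads: Iterable[BarcodedRead], path) -> None:
    """Write reads with the barcode restated as a BX:Z: comment."""
    with open(path, "w") as out:
        for r in reads:
            mate = f"/{r.mate}" if r.mate else ""
            bx = f" BX:Z:{r.barcode}" if r.barcode else ""
            out.write(f"@{r.read_id}{mate}{bx}\n{r.sequence}\n+\n{r.qualities}\n")


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path,
                width: int = 80) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as out:
        for name, seq in items:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# barcode index
# ---------------------------------------------------------------------------

@dataclass
class BarcodeIndex:
    """Persistent map barcode -> byte offsets of reads in a FASTQ file.

    Offsets address the uncompressed stream; for plain files retrieval
    seeks directly, for gzip input it falls back to a filtered scan.
    Re-runs with new assembly parameters reuse the on-disk index instead
    of re-reading the whole read file.
    """

    reads_path: str
    entries: dict[str, list[int]] = field(default_factory=dict)
    n_records: int = 0

    def barcodes(self) -> list[str]:
        return sorted(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def default_path(reads_path) -> str:
        return str(reads_path) + ".bci"

    def save(self, path=None) -> str:
        path = path or self.default_path(self.reads_path)
        with open(path, "w") as out:
            out.write(f"#linklocal-barcode-index\t{os.path.basename(str(self.reads_path))}"
                      f"\t{self.n_records}\n")
            for barcode in sorted(self.entries):
                offsets = ",".join(map(str, self.entries[barcode]))
                out.write(f"{barcode}\t{offsets}\n")
        return path

    @classmethod
    def load(cls, path, reads_path=None) -> "BarcodeIndex":
        entries: dict[str, list[int]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            n_records = int(header[2]) if len(header) > 2 else 0
            for line in fh:
                barcode, offsets = line.rstrip("\n").split("\t")
                entries[barcode] = [int(x) for x in offsets.split(",")]
        if reads_path is None:
            reads_path = str(path)[:-4] if str(path).endswith(".bci") else str(path)
        return cls(reads_path=str(reads_path), entries=entries, n_records=n_records)


def build_barcode_index(reads_path, dialect: str = "auto",
                        tag_file=None) -> BarcodeIndex:
    """Index every barcoded read of a FASTQ file by its barcode."""
    tag_map = load_tag_file(tag_file) if tag_file else None
    entries: dict[str, list[int]] = {}
    n = 0
    for offset, read in iter_fastq(reads_path, dialect, tag_map, with_offsets=True):
        n += 1
        if read.barcode is not None:
            entries.setdefault(read.barcode, []).append(offset)
    if not entries and n:
        logger.warning("no barcoded read found in %s", reads_path)
    return BarcodeIndex(reads_path=str(reads_path), entries=entries, n_records=n)


def fetch_reads_by_barcodes(index: BarcodeIndex, barcodes: Iterable[str],
                            dialect: str = "auto") -> list[BarcodedRead]:
    """All reads whose barcode is in ``barcodes``, in file order."""
    wanted = sorted({off for b in barcodes for off in index.entries.get(b, ())})
    if not wanted:
        return []
    fh = _open_maybe_gzip(index.reads_path)
    is_gzip = isinstance(fh, gzip.GzipFile)
    reads = []
    try:
        if is_gzip:
            fh.close()
            wanted_set = set(wanted)
            for offset, read in iter_fastq(index.reads_path, dialect,
                                           with_offsets=True):
                if offset in wanted_set:
                    reads.append(read)
        else:
            for offset in wanted:
                fh.seek(offset)
                lines = [fh.readline() for _ in range(4)]
                h = lines[0].decode().rstrip("\n")
                name, _, comment = h[1:].partition(" ")
                name, barcode = parse_barcode(name, comment, dialect)
                name, mate = _split_read_name(name)
                reads.append(BarcodedRead(
                    read_id=name, mate=mate,
                    sequence=lines[1].decode().rstrip("\n").upper(),
                    qualities=lines[3].decode().rstrip("\n"),
                    barcode=barcode))
    finally:
        if not fh.closed:
            fh.close()
    return reads


# ---------------------------------------------------------------------------
# GFA 2.0 (S and G lines)
# ---------------------------------------------------------------------------

@dataclass
class GfaSegment:
    sid: str
    length: int | None = None
    sequence: str | None = None
    region: Region | None = None  # from SN/SO/SE tags

    def to_line(self) -> str:
        length = self.length if self.length is not None else (
            len(self.sequence) if self.sequence else 0)
        seq = self.sequence or "*"
        tags = ""
        if self.region is not None:
            r = self.region
            tags = f"\tSN:Z:{r.sequence_id}\tSO:i:{r.start}\tSE:i:{r.end}"
        return f"S\t{self.sid}\t{length}\t{seq}{tags}"


@dataclass
class GfaGap:
    gid: str
    sid1: str
    orient1: str
    sid2: str
    orient2: str
    dist: int | None  # None encoded as '*': unknown gap length

    def to_line(self) -> str:
        dist = "*" if self.dist is None else str(self.dist)
        return f"G\t{self.gid}\t{self.sid1}{self.orient1}\t{self.sid2}{self.orient2}\t{dist}\t*"


def parse_gfa(text_or_path) -> tuple[dict[str, GfaSegment], list[GfaGap], list[str]]:
    """Parse S/G/other lines of a GFA 2.0 document (text or file path)."""
    if isinstance(text_or_path, str) and "\n" in text_or_path:
        lines = text_or_path.splitlines()
    else:
        with open(text_or_path) as fh:
            lines = fh.read().splitlines()
    segments: dict[str, GfaSegment] = {}
    gaps: list[GfaGap] = []
    other: list[str] = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "S":
            if len(fields) < 4:
                raise GfaError(f"line {lineno}: S line needs sid, slen, sequence: {line!r}")
            sid, slen, seq = fields[1], fields[2], fields[3]
            tags = {f.split(":", 2)[0]: f.split(":", 2)[2] for f in fields[4:] if f.count(":") >= 2}
            region = None
            if {"SN", "SO", "SE"} <= tags.keys():
                region = Region(tags["SN"], int(tags["SO"]), int(tags["SE"]))
            segments[sid] = GfaSegment(
                sid=sid,
                length=None if slen == "*" else int(slen),
                sequence=None if seq == "*" else seq.upper(),
                region=region)
        elif kind == "G":
            if len(fields) < 5:
                raise GfaError(f"line {lineno}: malformed G line: {line!r}")
            gid = fields[1]
            refs = []
            for f in fields[2:4]:
                if len(f) < 2 or f[-1] not in "+-":
                    raise GfaError(f"line {lineno}: bad oriented segment {f!r} in G line")
                refs.append((f[:-1], f[-1]))
            dist = None if fields[4] == "*" else int(fields[4])
            gaps.append(GfaGap(gid, refs[0][0], refs[0][1], refs[1][0], refs[1][1], dist))
        else:
            other.append(line)
    return segments, gaps, other


def _parse_coord_sid(sid: str) -> tuple[str, int, int] | None:
    """Recognize 'name:start-end' segment names."""
    if ":" not in sid:
        return None
    name, _, span = sid.rpartition(":")
    if "-" not in span:
        return None
    a, _, b = span.partition("-")
    try:
        return name, int(a), int(b)
    except ValueError:
        return None


def _resolve_segment(seg: GfaSegment, reference, orient: str) -> Region:
    """Place a segment on the reference, applying the G-line orientation."""
    if seg.region is not None:
        base = seg.region
    elif reference is not None and ref_has(reference, seg.sid):
        base = Region(seg.sid, 0, ref_length(reference, seg.sid))
    else:
        coords = _parse_coord_sid(seg.sid)
        if coords and reference is not None and ref_has(reference, coords[0]):
            base = Region(coords[0], coords[1], coords[2])
        else:
            raise SegmentResolutionError(
                f"segment {seg.sid!r} has no SN/SO/SE coordinate tags and does not "
                f"name a reference sequence; cannot place it on the reference")
    strand = "+" if orient == "+" else "-"
    return Region(base.sequence_id, base.start, base.end, strand)


def read_gfa_targets(gfa, reference) -> list[TargetLocus]:
    """One TargetLocus per G line of a GFA 2.0 file.

    The G-line orientations are applied so both flank Regions are expressed
    on the strand pointing into the gap (assembly direction is
    oriented(left) + gap + oriented(right)).
    """
    segments, gaps, _ = parse_gfa(gfa)
    targets = []
    for i, gap in enumerate(gaps):
        for sid in (gap.sid1, gap.sid2):
            if sid not in segments:
                raise GfaError(f"G line {gap.gid!r} references unknown segment {sid!r}")
        left = _resolve_segment(segments[gap.sid1], reference, gap.orient1)
        right = _resolve_segment(segments[gap.sid2], reference, gap.orient2)
        label = gap.gid if gap.gid != "*" else f"{gap.sid1}_{gap.sid2}_{i}"
        targets.append(TargetLocus(
            label=label, left_flank=left, right_flank=right,
            gap_length_estimate=gap.dist))
    return targets


def targets_to_gfa(targets: Iterable[TargetLocus]) -> str:
    """Serialize targets back to GFA 2.0 (round-trips through read_gfa_targets)."""
    lines = ["H\tVN:Z:2.0"]
    seen: dict[str, GfaSegment] = {}
    gap_lines = []
    for t in targets:
        sids = []
        for region in (t.left_flank, t.right_flank):
            sid = f"{region.sequence_id}:{region.start}-{region.end}"
            sids.append((sid, region.strand))
            if sid not in seen:
                seen[sid] = GfaSegment(
                    sid=sid, length=len(region),
                    region=Region(region.sequence_id, region.start, region.end))
        gap_lines.append(GfaGap(t.label, sids[0][0], sids[0][1],
                                sids[1][0], sids[1][1],
                                t.gap_length_estimate).to_line())
    lines += [seg.to_line() for seg in seen.values()]
    lines += gap_lines
    return "\n".join(lines) + "\n"


def bed_pair_to_gfa(left: Region, right: Region, reference,
                    label: str = "target_0") -> str:
    """GFA 2.0 text for one gap between two coordinate-defined flanks.

    On the same contig the left flank must strictly precede the right flank
    and the implied gap length is ``right.start - left.end``; flanks on two
    different contigs define an inter-scaffold gap of unknown length.
    """
    for region in (left, right):
        if not ref_has(reference, region.sequence_id):
            raise SegmentResolutionError(f"{region.sequence_id!r} not in reference")
        if region.end > ref_length(reference, region.sequence_id):
            raise ValueError(f"region {region} exceeds reference length")
    if left.sequence_id == right.sequence_id:
        if right.start < left.end:
            raise ValueError("right flank starts before left flank ends "
                             "(overlapping or inverted coordinates)")
        estimate = right.start - left.end
    else:
        estimate = UNKNOWN
    target = TargetLocus(label=label, left_flank=left, right_flank=right,
                         gap_length_estimate=estimate)
    return targets_to_gfa([target])
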