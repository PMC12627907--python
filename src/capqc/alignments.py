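"""Read streaming, per-read target classification and per-sample tallies.

Every mapped read is assigned exactly one class against the comparable
partition: reads on a mitochondrial contig are ``mito``; otherwise a read
overlapping a comparable target by at least ``min_overlap`` bp (default 1)
is ``on_comparable``; otherwise the same rule against noncomparable targets
gives ``on_noncomparable``; everything else is ``off_target``. The class
counts obey the conservation identity
``on_comparable + on_noncomparable + off_target + mito == total_mapped``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import pysam
from intervaltree import IntervalTree

from .panels import ComparablePartition, TargetInterval


class AlignmentError(ValueError):
    pass


class ReadClass(Enum):
    UNMAPPED = "unmapped"
    MITO = "mito"
    ON_COMPARABLE = "on_comparable"
    ON_NONCOMPARABLE = "on_noncomparable"
    OFF_TARGET = "off_target"


@dataclass(frozen=True)
class ReadRecord:
    """Minimal alignment record (0-based half-open span on the reference).

    ``sequence`` is stored in reference (plus-strand) orientation, as in SAM;
    for a minus-strand read the sequenced 5' end is therefore at ``end - 1``.
    """

    name: str
    mapped: bool
    chrom: str | None = None
    start: int = 0
    end: int = 0
    sequence: str = ""
    qualities: tuple[int, ...] | None = None
    mapq: int = 0
    duplicate: bool = False
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.mapped and (self.chrom is None or self.start >= self.end):
            raise AlignmentError(f"read {self.name}: mapped but span invalid")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "ReadRecord":
        if aln.is_unmapped:
            return cls(aln.query_name, mapped=False,
                       sequence=aln.query_sequence or "",
                       duplicate=aln.is_duplicate)
        return cls(
            name=aln.query_name,
            mapped=True,
            chrom=aln.reference_name,
            start=aln.reference_start,
            end=aln.reference_end,
            sequence=aln.query_sequence or "",
            qualities=tuple(aln.query_qualities) if aln.query_qualities is not None else None,
            mapq=aln.mapping_quality,
            duplicate=aln.is_duplicate,
            strand="-" if aln.is_reverse else "+",
        )


def read_sam(path, region=None) -> Iterator[ReadRecord]:
    """Stream a SAM/BAM file as ReadRecords (secondary/supplementary skipped)."""
    save = pysam.set_verbosity(0)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        pysam.set_verbosity(save)
        it = fh.fetch(region=region) if region else fh
        for aln in it:
            if aln.is_secondary or aln.is_supplementary:
                continue
            yield ReadRecord.from_pysam(aln)


class PartitionIndex:
    """Interval index over a comparable partition for per-read overlap queries."""

    def __init__(self, partition: ComparablePartition, min_overlap: int = 1) -> None:
        if min_overlap < 1:
            raise AlignmentError("min_overlap must be >= 1")
        self.min_overlap = min_overlap
        self._comparable = self._build(partition.comparable)
        self._noncomparable = self._build(partition.noncomparable)

    @staticmethod
    def _build(intervals: Sequence[TargetInterval]) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.snp_id)
        return trees

    def _overlaps(self, trees: dict[str, IntervalTree], read: ReadRecord) -> bool:
        tree = trees.get(read.chrom)
        if tree is None:
            return False
        for hit in tree.overlap(read.start, read.end):
            if min(hit.end, read.end) - max(hit.begin, read.start) >= self.min_overlap:
                return True
        return False

    def overlaps_comparable(self, read: ReadRecord) -> bool:
        return self._overlaps(self._comparable, read)

    def overlaps_noncomparable(self, read: ReadRecord) -> bool:
        return self._overlaps(self._noncomparable, read)


def classify_read(
    read: ReadRecord,
    index: PartitionIndex,
    mito_names: Sequence[str] = ("chrM",),
    known_contigs: Sequence[str] | None = None,
) -> ReadClass:
    """Assign the single class of a read (precedence: mito > comparable >
    noncomparable > off-target; mito contigs carry no panel targets)."""
    if not read.mapped:
        return ReadClass.UNMAPPED
    if known_contigs is not None and read.chrom not in known_contigs:
        raise AlignmentError(f"read {read.name} on unknown contig {read.chrom!r}")
    if read.chrom in mito_names:
        return ReadClass.MITO
    if index.overlaps_comparable(read):
        return ReadClass.ON_COMPARABLE
    if index.overlaps_noncomparable(read):
        return ReadClass.ON_NONCOMPARABLE
    return ReadClass.OFF_TARGET


@dataclass
class SampleCounts:
    """Per-sample read-classification tallies feeding the ratio metrics."""

    total_raw: int = 0
    total_mapped: int = 0
    mapped_dedup: int = 0
    on_comparable: int = 0
    on_comparable_dedup: int = 0
    on_noncomparable: int = 0
    on_noncomparable_dedup: int = 0
    off_target: int = 0
    mito: int = 0
    per_panel_on_target: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        vals = [self.total_raw, self.total_mapped, self.mapped_dedup,
                self.on_comparable, self.on_comparable_dedup,
                self.on_noncomparable, self.off_target, self.mito]
        if any(v < 0 for v in vals):
            raise AlignmentError("negative count")
        if self.total_raw < self.total_mapped:
            raise AlignmentError(
                f"total_raw ({self.total_raw}) < total_mapped ({self.total_mapped})")
        if self.mapped_dedup > self.total_mapped:
            raise AlignmentError("mapped_dedup exceeds total_mapped")
        s = self.on_comparable + self.on_noncomparable + self.off_target + self.mito
        if s != self.total_mapped:
            raise AlignmentError(
                f"class counts sum to {s}, expected total_mapped={self.total_mapped}")


def mark_duplicates(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Flag coordinate duplicates: among mapped reads sharing
    (chrom, start, end, strand), exactly one stays non-duplicate."""
    out = []
    seen: set[tuple] = set()
    for read in reads:
        if not read.mapped:
            out.append(read)
            continue
        key = (read.chrom, read.start, read.end, read.strand)
        if key in seen:
            out.append(replace(read, duplicate=True))
        else:
            seen.add(key)
            out.append(replace(read, duplicate=False))
    return out


def tally_sample(
    reads: Iterable[ReadRecord],
    partition: ComparablePartition,
    mito_names: Sequence[str] = ("chrM",),
    total_raw: int | None = None,
    min_overlap: int = 1,
    use_flags: bool = True,
) -> SampleCounts:
    """Classify every read and return SampleCounts.

    ``total_raw`` must include unmapped/exogenous reads (it cannot be
    recovered from a mapped-only alignment file); if omitted, it is taken
    as the number of records streamed. Duplicate status comes from SAM
    flags when ``use_flags`` (default); otherwise reads are re-marked by
    identical alignment coordinates + strand.
    """
    reads = list(reads)
    if not use_flags:
        reads = mark_duplicates(reads)
    index = PartitionIndex(partition, min_overlap=min_overlap)
    c = SampleCounts()
    n_streamed = 0
    for read in reads:
        n_streamed += 1
        cls = classify_read(read, index, mito_names)
        if cls is ReadClass.UNMAPPED:
            continue
        c.total_mapped += 1
        if not read.duplicate:
            c.mapped_dedup += 1
        if cls is ReadClass.MITO:
            c.mito += 1
        elif cls is ReadClass.ON_COMPARABLE:
            c.on_comparable += 1
            if not read.duplicate:
                c.on_comparable_dedup += 1
        elif cls is ReadClass.ON_NONCOMPARABLE:
            c.on_noncomparable += 1
            if not read.duplicate:
                c.on_noncomparable_dedup += 1
        else:
            c.off_target += 1
    c.total_raw = n_streamed if total_raw is None else total_raw
    c.validate()
    return c


def tally_single_panel(
    reads: Iterable[ReadRecord],
    intervals: Sequence[TargetInterval],
    mito_names: Sequence[str] = ("chrM",),
    total_raw: int | None = None,
    min_overlap: int = 1,
) -> SampleCounts:
    """Tally against one panel's own footprints (empty noncomparable set),
    used for the per-original-panel efficiency variants."""
    partition = ComparablePartition(list(intervals), [], [])
    return tally_sample(reads, partition, mito_names, total_raw, min_overlap)


def trim_read_ends(read: ReadRecord, n_bases: int = 5) -> ReadRecord | None:
    """Trim n bases off both ends of a mapped read (pre-genotyping step).

    Reads with length <= 2n are dropped (None). The damage profile must be
    computed on *untrimmed* reads.
    """
    if n_bases == 0:
        return read
    if not read.mapped or read.length <= 2 * n_bases:
        return None
    return replace(
        read,
        start=read.start + n_bases,
        end=read.end - n_bases,
        sequence=read.sequence[n_bases:-n_bases] if read.sequence else "",
        qualities=read.qualities[n_bases:-n_bases] if read.qualities else None,
    )
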