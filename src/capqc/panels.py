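"""SNP panels, probe geometries and the comparable-target partition.

A capture panel is a set of SNP sites, each covered by a probe *footprint*:
the total reference span tiled by the probes targeting that SNP (e.g. four
60 bp probes covering 121 bp, or a single 80 bp probe covering 80 bp).
Cross-kit comparisons are made on "comparable targets": the geometric
intersection of the two designs' footprints at SNPs shared by both panels.
Intervals use BED conventions (0-based half-open); SNP positions are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Malformed panel input (parse or validation failure)."""


@dataclass(frozen=True)
class SNPSite:
    """A biallelic SNP targeted by a capture panel (1-based position)."""

    chrom: str
    pos: int
    allele1: str
    allele2: str
    snp_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.allele1 not in _BASES or self.allele2 not in _BASES:
            raise PanelError(
                f"{self.snp_id}: alleles must be in A/C/G/T, got "
                f"{self.allele1}/{self.allele2}"
            )
        if self.allele1 == self.allele2:
            raise PanelError(f"{self.snp_id}: alleles must differ, got {self.allele1}")


@dataclass(frozen=True)
class ProbeDesign:
    """Probe geometry of one capture kit.

    Parameters
    ----------
    probe_length
        Length of a single probe in bp.
    footprint_length
        Total reference span covered per SNP by all probes of the design.
    tiling
        Number of probes per SNP.
    snp_offset
        1-based position of the SNP within the footprint.
    """

    name: str
    probe_length: int
    footprint_length: int
    tiling: int = 1
    snp_offset: int = 0

    def __post_init__(self) -> None:
        if self.footprint_length < self.probe_length:
            raise PanelError("footprint_length must be >= probe_length")
        if self.tiling < 1:
            raise PanelError("tiling must be >= 1")
        offset = self.snp_offset or (self.footprint_length + 1) // 2
        object.__setattr__(self, "snp_offset", offset)
        if not 1 <= self.snp_offset <= self.footprint_length:
            raise PanelError("snp_offset must lie within the footprint")


# Geometries of the two commercial designs compared in the toolkit's tests:
# four 60 bp ssRNA probes spanning 121 bp (SNP centered), and a single 80 bp
# dsDNA probe spanning 80 bp (even length forces a one-off-center SNP).
MYBAITS_LIKE = ProbeDesign("mybaits-like", probe_length=60, footprint_length=121,
                           tiling=4, snp_offset=61)
TWIST_LIKE = ProbeDesign("twist-like", probe_length=80, footprint_length=80,
                         tiling=1, snp_offset=41)


@dataclass(frozen=True)
class TargetInterval:
    """A probe footprint on the reference, 0-based half-open."""

    chrom: str
    start: int
    end: int
    snp_id: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise PanelError(
                f"{self.snp_id}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def intersect(self, other: "TargetInterval") -> "TargetInterval | None":
        if self.chrom != other.chrom:
            return None
        start, end = max(self.start, other.start), min(self.end, other.end)
        if start >= end:
            return None
        return TargetInterval(self.chrom, start, end, self.snp_id)


@dataclass
class ProbePanel:
    """A panel: SNP sites plus the target intervals their probes cover."""

    name: str
    design: ProbeDesign
    sites: list[SNPSite]
    intervals: list[TargetInterval]

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.intervals):
            raise PanelError("one interval per site required")
        ids = [iv.snp_id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate snp_id among intervals")
        self.intervals.sort(key=lambda iv: (iv.chrom, iv.start))

    @property
    def site_by_id(self) -> dict[str, SNPSite]:
        return {s.snp_id: s for s in self.sites}

    @property
    def interval_by_id(self) -> dict[str, TargetInterval]:
        return {iv.snp_id: iv for iv in self.intervals}


@dataclass
class ComparablePartition:
    """Intersection/complement split of two panels' footprints.

    ``comparable`` holds, for every SNP shared by both panels, the geometric
    intersection of the two footprints; targets unique to one panel go to
    that panel's noncomparable list and are excluded from cross-kit metrics.
    """

    comparable: list[TargetInterval]
    noncomparable_a: list[TargetInterval] = field(default_factory=list)
    noncomparable_b: list[TargetInterval] = field(default_factory=list)

    @property
    def noncomparable(self) -> list[TargetInterval]:
        return self.noncomparable_a + self.noncomparable_b


def load_snp_sites(path) -> list[SNPSite]:
    """Read SNP sites from a TSV (chrom, pos1based, allele1, allele2, snp_id).

    Lines starting with '#' are skipped. Sites are validated and returned
    sorted by (chrom, pos); duplicated chrom+pos is an error.
    """
    sites: list[SNPSite] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 5:
                raise PanelError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            chrom, pos_s, a1, a2, snp_id = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            try:
                site = SNPSite(chrom, pos, a1.upper(), a2.upper(), snp_id)
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
            if (chrom, pos) in seen:
                raise PanelError(f"{path}:{lineno}: duplicate site {chrom}:{pos}")
            seen.add((chrom, pos))
            sites.append(site)
    if not sites:
        logger.warning("no SNP sites parsed from %s", path)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def write_snp_sites(sites: Iterable[SNPSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tallele1\tallele2\tsnp_id\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.allele1}\t{s.allele2}\t{s.snp_id}\n")


def derive_target_intervals(
    sites: Sequence[SNPSite],
    design: ProbeDesign,
    panel_name: str | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> ProbePanel:
    """Place each design footprint around its SNP.

    A SNP at 1-based position ``p`` with footprint ``F`` and snp_offset ``k``
    yields the 0-based half-open interval ``[p-k, p-k+F)``. Footprints
    running past a contig boundary are clipped and flagged.
    """
    intervals = []
    for s in sites:
        start = s.pos - design.snp_offset
        end = start + design.footprint_length
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if contig_lengths is not None:
            limit = contig_lengths.get(s.chrom)
            if limit is not None and end > limit:
                end, clipped = limit, True
        if clipped:
            logger.warning("footprint for %s clipped to [%d,%d)", s.snp_id, start, end)
        intervals.append(TargetInterval(s.chrom, start, end, s.snp_id, clipped=clipped))
    return ProbePanel(panel_name or design.name, design, list(sites), intervals)


def comparable_partition(panel_a: ProbePanel, panel_b: ProbePanel) -> ComparablePartition:
    """Split two panels into comparable (intersected) and unique targets."""
    sites_a, sites_b = panel_a.site_by_id, panel_b.site_by_id
    iv_a, iv_b = panel_a.interval_by_id, panel_b.interval_by_id
    shared = set(sites_a) & set(sites_b)
    for snp_id in shared:
        sa, sb = sites_a[snp_id], sites_b[snp_id]
        if (sa.chrom, sa.pos) != (sb.chrom, sb.pos):
            raise PanelError(
                f"snp_id {snp_id} maps to {sa.chrom}:{sa.pos} in {panel_a.name} "
                f"but {sb.chrom}:{sb.pos} in {panel_b.name}"
            )
    comparable = []
    for snp_id in shared:
        inter = iv_a[snp_id].intersect(iv_b[snp_id])
        if inter is None:  # cannot happen for same-SNP footprints, guard anyway
            raise PanelError(f"footprints for shared SNP {snp_id} do not overlap")
        comparable.append(inter)
    comparable.sort(key=lambda iv: (iv.chrom, iv.start))
    nc_a = sorted((iv_a[i] for i in set(sites_a) - shared),
                  key=lambda iv: (iv.chrom, iv.start))
    nc_b = sorted((iv_b[i] for i in set(sites_b) - shared),
                  key=lambda iv: (iv.chrom, iv.start))
    return ComparablePartition(comparable, nc_a, nc_b)


def panel_gc_content(panel_or_intervals, reference) -> tuple[dict[str, float], float]:
    """GC fraction per target interval and the panel mean, as percentages.

    N bases are ignored in the per-interval fraction; all-N intervals are
    excluded from the mean (and reported as NaN).
    """
    intervals = (panel_or_intervals.intervals
                 if isinstance(panel_or_intervals, ProbePanel) else panel_or_intervals)
    fasta = Fasta(str(reference)) if isinstance(reference, (str, Path)) else reference
    per_interval: dict[str, float] = {}
    means = []
    for iv in intervals:
        seq = str(fasta[iv.chrom][iv.start:iv.end]).upper()
        gc = sum(seq.count(b) for b in "GC")
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            per_interval[iv.snp_id] = float("nan")
            continue
        pct = 100.0 * gc / acgt
        per_interval[iv.snp_id] = pct
        means.append(pct)
    mean = sum(means) / len(means) if means else float("nan")
    return per_interval, mean


def write_bed(intervals: Iterable[TargetInterval], path, panel_name: str = ".") -> None:
    """Write intervals as 6-column BED (chrom, start, end, snp_id, panel, strand)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.snp_id}\t{panel_name}\t.\n")


def read_bed(path) -> list[TargetInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            snp_id = fields[3] if len(fields) > 3 else f"iv{lineno}"
            intervals.append(TargetInterval(chrom, start, end, snp_id))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return intervals
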