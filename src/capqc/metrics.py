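"""Ratio metrics for capture QC: on-target rate, target efficiency, fold
enrichment, expected coverage, SNP coverage and evenness.

Conventions follow the field's usage for comparing enrichment kits:

* on-target rate = 100 x on_comparable / (total_raw - on_noncomparable):
  on-target reads (including duplicates) over all sequenced reads, with
  reads on targets unique to one kit excluded from the denominator.
* target efficiency = 100 x on_comparable / (total_mapped - on_noncomparable):
  same numerator over endogenous (mapped) reads only.
* fold enrichment = target efficiency after capture / target efficiency of
  shotgun sequencing of the same library.

Undefined ratios (zero denominators) are returned as None and written as
missing, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignments import SampleCounts

#: Genome length used to convert informative sequence content to coverage
#: (hooded crow nuclear genome, bp).
DEFAULT_GENOME_LENGTH = 1.12e9


class MetricError(ValueError):
    pass


def on_target_rate(counts: SampleCounts) -> float | None:
    denom = counts.total_raw - counts.on_noncomparable
    if denom <= 0:
        return None
    return 100.0 * counts.on_comparable / denom


def target_efficiency(counts: SampleCounts, dedup: bool = False) -> float | None:
    """Percentage of mapped reads on comparable targets.

    With ``dedup`` both numerator and denominator use duplicate-removed
    counts.
    """
    if dedup:
        num = counts.on_comparable_dedup
        denom = counts.mapped_dedup - counts.on_noncomparable_dedup
    else:
        num = counts.on_comparable
        denom = counts.total_mapped - counts.on_noncomparable
    if denom <= 0:
        return None
    return 100.0 * num / denom


def fold_enrichment(te_captured: float | None, te_shotgun: float | None) -> float | None:
    if te_captured is None or te_shotgun is None or te_shotgun == 0:
        return None
    return te_captured / te_shotgun


def scenario_adjusted_efficiency(
    counts: SampleCounts,
    off_target_scale: float = 1.0,
    on_target_multiplier: float = 1.0,
) -> float | None:
    """Target efficiency under a counterfactual rescaling of the read pools
    (e.g. doubling on-target reads to mimic denser probe tiling, or scaling
    off-target reads to mimic a smaller panel's off-target load)."""
    if off_target_scale <= 0 or on_target_multiplier <= 0:
        raise MetricError("scaling factors must be > 0")
    on = counts.on_comparable * on_target_multiplier
    off = (counts.total_mapped - counts.on_noncomparable - counts.on_comparable) \
        * off_target_scale
    denom = on + off
    if denom <= 0:
        return None
    return 100.0 * on / denom


def expected_coverage(
    qpcr_mol: float,
    mapped_reads: float,
    total_reads: float,
    mean_read_length: float,
    genome_length: float = DEFAULT_GENOME_LENGTH,
    volume_fraction: float = 1.0,
) -> float:
    """Expected genomic coverage of a library from qPCR molecule counts.

    Informative sequence content = qPCR molecules x endogenous fraction
    (mapped/total reads) x mean mapped read length; dividing by the genome
    length gives expected coverage, scaled by the fraction of the library
    volume actually used in the capture reaction.
    """
    if total_reads <= 0 or qpcr_mol <= 0 or mean_read_length <= 0 or genome_length <= 0:
        raise MetricError("qpcr_mol, total_reads, mean_read_length, genome_length must be > 0")
    if not 0 < volume_fraction <= 1:
        raise MetricError("volume_fraction must be in (0, 1]")
    if mapped_reads < 0:
        raise MetricError("mapped_reads must be >= 0")
    return (qpcr_mol * (mapped_reads / total_reads) * mean_read_length
            / genome_length * volume_fraction)


def snp_site_coverage(depths: Sequence[float] | np.ndarray) -> float:
    """Mean read depth at the exact SNP base across all panel sites
    (uncovered sites enter as 0)."""
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        return float("nan")
    return float(arr.mean())


@dataclass
class EvennessRow:
    """Coverage evenness: % of SNPs at or above each depth threshold."""

    sample: str
    pct_ge: dict[int, float]
    flag_80pct: dict[int, bool]


def evenness(
    depths: Sequence[float] | np.ndarray,
    thresholds: Sequence[int] = (1, 2, 3, 4, 5),
    sample_flag_cut: float = 80.0,
    sample: str = "",
) -> EvennessRow:
    """Per-threshold percentage of SNPs with depth >= t, plus a flag for
    whether the sample clears ``sample_flag_cut`` percent at that t."""
    if any(t < 1 for t in thresholds):
        raise MetricError("thresholds must be positive integers")
    arr = np.asarray(depths, dtype=float)
    pct = {int(t): (100.0 * float((arr >= t).mean()) if arr.size else float("nan"))
           for t in thresholds}
    flags = {t: (p >= sample_flag_cut) for t, p in pct.items()}
    return EvennessRow(sample=sample, pct_ge=pct, flag_80pct=flags)


def mito_fraction(counts: SampleCounts) -> float | None:
    if counts.total_mapped <= 0:
        return None
    return 100.0 * counts.mito / counts.total_mapped


@dataclass
class MetricsRow:
    """One sample's headline capture metrics (percent / fold units)."""

    sample: str
    on_target_rate: float | None = None
    target_efficiency: float | None = None
    target_efficiency_dedup: float | None = None
    fold_enrichment: float | None = None
    mito_fraction: float | None = None
    expected_coverage: float | None = None
    mean_snp_coverage: float | None = None
    mean_snp_coverage_dedup: float | None = None
    per_panel_efficiency: dict[str, float] = field(default_factory=dict)


def compute_metrics_row(
    sample: str,
    counts: SampleCounts,
    depths: Sequence[float] | None = None,
    depths_dedup: Sequence[float] | None = None,
    shotgun_counts: SampleCounts | None = None,
    library_meta: Mapping[str, float] | None = None,
) -> MetricsRow:
    """Assemble the full metrics row for one sample.

    ``library_meta`` may carry qpcr_mol, total_reads, mean_read_length and
    volume_fraction for the expected-coverage estimate.
    """
    row = MetricsRow(sample=sample)
    row.on_target_rate = on_target_rate(counts)
    row.target_efficiency = target_efficiency(counts)
    row.target_efficiency_dedup = target_efficiency(counts, dedup=True)
    row.mito_fraction = mito_fraction(counts)
    if shotgun_counts is not None:
        row.fold_enrichment = fold_enrichment(
            row.target_efficiency, target_efficiency(shotgun_counts))
    if depths is not None:
        row.mean_snp_coverage = snp_site_coverage(depths)
    if depths_dedup is not None:
        row.mean_snp_coverage_dedup = snp_site_coverage(depths_dedup)
    if library_meta is not None and "qpcr_mol" in library_meta:
        row.expected_coverage = expected_coverage(
            qpcr_mol=library_meta["qpcr_mol"],
            mapped_reads=counts.total_mapped,
            total_reads=library_meta.get("total_reads", counts.total_raw),
            mean_read_length=library_meta["mean_read_length"],
            genome_length=library_meta.get("genome_length", DEFAULT_GENOME_LENGTH),
            volume_fraction=library_meta.get("volume_fraction", 1.0),
        )
    return row
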