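"""Pipeline orchestration: run every QC stage for a set of samples and
write a combined report directory plus a two-kit comparison table.

Exchange format is TSV (UTF-8, header row, "." for missing values); the
JSON summary mirrors the TSV values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignments, damage, gc_bias, genotyping, metrics
from .panels import ComparablePartition, ProbePanel, SNPSite, read_bed, load_snp_sites

logger = logging.getLogger(__name__)

MISSING = "."


class ReportError(ValueError):
    pass


@dataclass
class SampleSpec:
    """One library to run through the pipeline."""

    sample: str
    bam: str
    total_raw: int | None = None
    qpcr_mol: float | None = None
    volume_fraction: float = 1.0
    kit: str = ""
    shotgun_bam: str | None = None
    shotgun_total_raw: int | None = None


@dataclass
class RunConfig:
    samples: list[SampleSpec]
    reference: str
    partition_bed: str | None = None
    noncomparable_bed: str | None = None
    sites_tsv: str | None = None
    mito_names: tuple[str, ...] = ("chrM",)
    min_overlap: int = 1
    trim_bases: int = 5
    evenness_thresholds: tuple[int, ...] = (1, 2, 3, 4, 5)

    def validate(self) -> None:
        for s in self.samples:
            if not Path(s.bam).exists():
                raise ReportError(f"sample {s.sample}: BAM not found: {s.bam}")
            if s.shotgun_bam and not Path(s.shotgun_bam).exists():
                raise ReportError(
                    f"sample {s.sample}: shotgun BAM not found: {s.shotgun_bam}")
        if not Path(self.reference).exists():
            raise ReportError(f"reference not found: {self.reference}")
        for s in self.samples:
            if not 0 < s.volume_fraction <= 1:
                raise ReportError(f"sample {s.sample}: volume_fraction out of (0,1]")


def _summary_value(v):
    if v == MISSING:
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        return v


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return MISSING
    return f"{v:.6g}" if isinstance(v, float) else str(v)


def site_depths(
    reads: list[alignments.ReadRecord],
    sites: list[SNPSite],
    trim_bases: int = 5,
    dedup: bool = False,
    min_mapq: int = 0,
    min_baseq: int = 0,
) -> np.ndarray:
    """Read depth at the exact SNP base per panel site (0 where uncovered)."""
    trimmed = []
    for r in reads:
        t = alignments.trim_read_ends(r, trim_bases)
        if t is not None:
            trimmed.append(t)
    counts = genotyping.pileup_allele_counts(
        trimmed, sites, min_mapq=min_mapq, min_baseq=min_baseq,
        exclude_duplicates=dedup)
    return np.array([counts[s.snp_id].total_depth for s in sites], dtype=float)


def run_sample(
    spec: SampleSpec,
    partition: ComparablePartition,
    config: RunConfig,
    sites: list[SNPSite] | None = None,
) -> dict:
    """All per-sample stages: tally, metrics, evenness, GC bias, damage."""
    reads = list(alignments.read_sam(spec.bam))
    counts = alignments.tally_sample(
        reads, partition, config.mito_names, total_raw=spec.total_raw,
        min_overlap=config.min_overlap)
    length_stats = damage.read_length_stats(reads)
    meta = None
    if spec.qpcr_mol is not None:
        meta = {"qpcr_mol": spec.qpcr_mol, "volume_fraction": spec.volume_fraction,
                "mean_read_length": length_stats["mean"],
                "total_reads": counts.total_raw}
    shotgun_counts = None
    if spec.shotgun_bam:
        shotgun_counts = alignments.tally_sample(
            list(alignments.read_sam(spec.shotgun_bam)), partition,
            config.mito_names, total_raw=spec.shotgun_total_raw,
            min_overlap=config.min_overlap)
    depths = depths_dedup = None
    ev = None
    if sites:
        depths = site_depths(reads, sites, config.trim_bases, dedup=False)
        depths_dedup = site_depths(reads, sites, config.trim_bases, dedup=True)
        ev = metrics.evenness(depths, config.evenness_thresholds, sample=spec.sample)
    row = metrics.compute_metrics_row(
        spec.sample, counts, depths, depths_dedup, shotgun_counts, meta)
    windows, _ = gc_bias.window_gc_bins(partition.comparable, config.reference)
    table = gc_bias.gc_bin_read_counts(reads, windows)
    profile = damage.ct_profile(reads, config.reference)
    return {
        "counts": counts, "metrics": row, "evenness": ev, "gc_table": table,
        "at_dropout": gc_bias.at_dropout(table),
        "gc_dropout": gc_bias.gc_dropout(table),
        "damage": profile, "length_stats": length_stats,
    }


def run_all(config: RunConfig, out_dir) -> Path:
    """Run every stage for every sample and write the report directory
    (metrics.tsv, evenness.tsv, gc.tsv, damage.tsv, allele_bias.tsv,
    summary.json)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.partition_bed is None:
        raise ReportError("partition_bed is required")
    comparable = read_bed(config.partition_bed)
    noncomp = read_bed(config.noncomparable_bed) if config.noncomparable_bed else []
    partition = ComparablePartition(comparable, noncomp, [])
    sites = load_snp_sites(config.sites_tsv) if config.sites_tsv else None

    metric_rows, even_rows, gc_rows, dmg_rows, bias_rows = [], [], [], [], []
    summary: dict = {"samples": {}}
    for spec in config.samples:
        res = run_sample(spec, partition, config, sites)
        r = res["metrics"]
        metric_rows.append({
            "sample": spec.sample, "kit": spec.kit,
            "on_target_rate": _fmt(r.on_target_rate),
            "target_efficiency": _fmt(r.target_efficiency),
            "target_efficiency_dedup": _fmt(r.target_efficiency_dedup),
            "fold_enrichment": _fmt(r.fold_enrichment),
            "mito_fraction": _fmt(r.mito_fraction),
            "expected_coverage": _fmt(r.expected_coverage),
            "mean_snp_coverage": _fmt(r.mean_snp_coverage),
            "mean_snp_coverage_dedup": _fmt(r.mean_snp_coverage_dedup),
            "at_dropout": _fmt(res["at_dropout"]),
            "gc_dropout": _fmt(res["gc_dropout"]),
            "ct_rate_pos1": _fmt(res["damage"].first_base_rate),
            "mean_read_length": _fmt(res["length_stats"]["mean"]),
        })
        if res["evenness"] is not None:
            row = {"sample": spec.sample}
            for t, p in res["evenness"].pct_ge.items():
                row[f"pct_ge_{t}x"] = _fmt(p)
                row[f"flag80_{t}x"] = str(res["evenness"].flag_80pct[t]).lower()
            even_rows.append(row)
        gdf = res["gc_table"].table.copy()
        gdf.insert(0, "sample", spec.sample)
        gc_rows.append(gdf)
        ddf = res["damage"].to_frame()
        ddf.insert(0, "sample", spec.sample)
        dmg_rows.append(ddf)
        summary["samples"][spec.sample] = {
            k: _summary_value(v) for k, v in metric_rows[-1].items()
            if k != "sample"}

    pd.DataFrame(metric_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    pd.DataFrame(even_rows).to_csv(out / "evenness.tsv", sep="\t", index=False)
    pd.concat(gc_rows).to_csv(out / "gc.tsv", sep="\t", index=False, na_rep=MISSING)
    pd.concat(dmg_rows).to_csv(out / "damage.tsv", sep="\t", index=False,
                               na_rep=MISSING)
    pd.DataFrame(bias_rows, columns=["sample", "class", "n", "est_ad_ratio",
                                     "p", "sig_raw", "sig_bonferroni"]).to_csv(
        out / "allele_bias.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return out


def write_bias_table(results_by_sample: dict[str, list], path) -> pd.DataFrame:
    """Table-style output of allelic-bias tests: one row per sample x class."""
    rows = []
    for sample, results in results_by_sample.items():
        for r in results:
            rows.append({
                "sample": sample, "class": r.variant_class, "n": r.n_sites,
                "est_ad_ratio": round(r.est_ad_ratio, 6),
                "p": r.p_value,
                "sig_raw": bool(r.significant_raw),
                "sig_bonferroni": bool(r.significant_bonferroni),
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def compare_kits(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame) -> pd.DataFrame:
    """Per-sample deltas and ratios between two kits' metric tables.

    Both tables must share the same sample ids; numeric columns common to
    both are compared, with column means appended as a final row.
    """
    a = metrics_a.set_index("sample")
    b = metrics_b.set_index("sample")
    if set(a.index) != set(b.index):
        raise ReportError(
            f"sample mismatch: {sorted(set(a.index) ^ set(b.index))}")
    b = b.loc[a.index]
    rows = []
    num_cols = [c for c in a.columns
                if c in b.columns and
                pd.to_numeric(a[c], errors="coerce").notna().any()]
    an = a[num_cols].apply(pd.to_numeric, errors="coerce")
    bn = b[num_cols].apply(pd.to_numeric, errors="coerce")
    for sample in a.index:
        row = {"sample": sample}
        for c in num_cols:
            va, vb = an.loc[sample, c], bn.loc[sample, c]
            row[f"{c}_a"], row[f"{c}_b"] = va, vb
            row[f"{c}_delta"] = va - vb
            row[f"{c}_ratio"] = va / vb if vb not in (0,) and pd.notna(vb) else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"sample": "MEAN"}
    for c in df.columns:
        if c != "sample":
            mean_row[c] = df[c].mean()
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
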