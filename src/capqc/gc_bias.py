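"""GC-bias summary over target regions: per-GC-bin window counts, read
counts, normalized coverage and AT/GC dropout.

Target intervals are tiled end-to-end with fixed-size windows (default
80 bp; partial trailing windows are dropped). Each window is assigned an
integer GC bin = round(100 x GC fraction). Each on-target read is credited
to the bin of the window containing its 5' alignment start (strand-aware;
a ``midpoint`` crediting rule is available). Per bin:

* pct_windows: percentage of all windows in that bin,
* pct_reads:   percentage of all credited reads in that bin,
* normalized_coverage: (reads/windows in bin) / (total reads/total windows),
  so 1.0 is the mean and the window-weighted mean is exactly 1.

AT dropout sums max(0, pct_windows - pct_reads) over bins 0..50, GC dropout
over bins 50..100; bin 50 belongs to both sums by default (``split_bin_50``
assigns it to the AT side only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .alignments import ReadRecord
from .panels import TargetInterval

DEFAULT_WINDOW = 80


class GCBiasError(ValueError):
    pass


@dataclass(frozen=True)
class GCWindow:
    chrom: str
    start: int
    end: int
    bin: int  # GC percent, 0..100


def window_gc_bins(
    intervals: Sequence[TargetInterval],
    reference,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[GCWindow], int]:
    """Tile target intervals with fixed windows and assign GC bins.

    Returns (windows, n_excluded) where n_excluded counts all-N windows.
    GC fraction ignores N bases. ``reference`` may be a FASTA path, a
    pyfaidx.Fasta, or any mapping supporting ``ref[chrom][start:end]``.
    """
    fasta = Fasta(str(reference)) if isinstance(reference, (str, Path)) else reference
    windows: list[GCWindow] = []
    n_excluded = 0
    for iv in intervals:
        for ws in range(iv.start, iv.end - window + 1, window):
            seq = str(fasta[iv.chrom][ws:ws + window]).upper()
            gc = seq.count("G") + seq.count("C")
            acgt = gc + seq.count("A") + seq.count("T")
            if acgt == 0:
                n_excluded += 1
                continue
            windows.append(GCWindow(iv.chrom, ws, ws + window, round(100.0 * gc / acgt)))
    return windows, n_excluded


class WindowIndex:
    """Point lookup: genomic position -> GC bin of the containing window."""

    def __init__(self, windows: Sequence[GCWindow]) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._bins: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GCWindow]] = {}
        for w in windows:
            by_chrom.setdefault(w.chrom, []).append(w)
        for chrom, ws in by_chrom.items():
            ws.sort(key=lambda w: w.start)
            self._starts[chrom] = np.array([w.start for w in ws])
            self._ends[chrom] = np.array([w.end for w in ws])
            self._bins[chrom] = np.array([w.bin for w in ws])

    def bin_at(self, chrom: str, pos: int) -> int | None:
        starts = self._starts.get(chrom)
        if starts is None:
            return None
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self._ends[chrom][i]:
            return None
        return int(self._bins[chrom][i])


def _credit_position(read: ReadRecord, rule: str) -> int:
    if rule == "start":
        # 5' end of the sequenced molecule: alignment start on plus-strand
        # reads, last aligned base on minus-strand reads.
        return read.start if read.strand == "+" else read.end - 1
    if rule == "midpoint":
        return (read.start + read.end) // 2
    raise GCBiasError(f"unknown crediting rule {rule!r}")


@dataclass
class GCBinTable:
    """Per-GC-bin window and read summary (bins 0..100)."""

    table: pd.DataFrame  # columns: bin, n_windows, read_count, pct_windows,
    #                      pct_reads, normalized_coverage
    n_reads_outside: int = 0
    empty: bool = False

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep=".")


def gc_bin_read_counts(
    reads: Iterable[ReadRecord],
    windows: Sequence[GCWindow],
    credit: str = "start",
) -> GCBinTable:
    """Count windows and credited reads per GC bin and derive the
    percentage and normalized-coverage columns."""
    index = WindowIndex(windows)
    n_windows = np.zeros(101, dtype=np.int64)
    for w in windows:
        n_windows[w.bin] += 1
    read_count = np.zeros(101, dtype=np.int64)
    outside = 0
    for read in reads:
        if not read.mapped:
            continue
        b = index.bin_at(read.chrom, _credit_position(read, credit))
        if b is None:
            outside += 1
        else:
            read_count[b] += 1
    total_w, total_r = int(n_windows.sum()), int(read_count.sum())
    df = pd.DataFrame({"bin": np.arange(101), "n_windows": n_windows,
                       "read_count": read_count})
    if total_w == 0:
        raise GCBiasError("no windows; cannot build GC table")
    df["pct_windows"] = 100.0 * df["n_windows"] / total_w
    empty = total_r == 0
    df["pct_reads"] = (100.0 * df["read_count"] / total_r) if not empty else np.nan
    mean_cov = total_r / total_w
    with np.errstate(divide="ignore", invalid="ignore"):
        per_bin = df["read_count"].to_numpy() / df["n_windows"].to_numpy()
    df["normalized_coverage"] = (per_bin / mean_cov) if not empty else np.nan
    df.loc[df["n_windows"] == 0, "normalized_coverage"] = np.nan
    return GCBinTable(df, n_reads_outside=outside, empty=empty)


def _dropout(table: GCBinTable, lo: int, hi: int) -> float:
    if table.empty:
        return float("nan")
    df = table.table
    sel = (df["bin"] >= lo) & (df["bin"] <= hi)
    diff = df.loc[sel, "pct_windows"] - df.loc[sel, "pct_reads"]
    return float(diff.clip(lower=0.0).sum())


def at_dropout(table: GCBinTable, split_bin_50: bool = False) -> float:
    """Summed positive shortfall of read% vs window% over low-GC bins 0..50."""
    return _dropout(table, 0, 50)


def gc_dropout(table: GCBinTable, split_bin_50: bool = False) -> float:
    """Summed positive shortfall of read% vs window% over high-GC bins
    50..100 (51..100 when ``split_bin_50``)."""
    return _dropout(table, 51 if split_bin_50 else 50, 100)


def gc_bias_summary(table: GCBinTable, sample: str = "",
                    split_bin_50: bool = False) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample": sample,
        "at_dropout": at_dropout(table, split_bin_50),
        "gc_dropout": gc_dropout(table, split_bin_50),
    }])
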