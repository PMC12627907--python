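"""GC windows, normalized coverage and AT/GC dropout."""

import numpy as np
import pandas as pd
import pytest

from capqc.alignments import ReadRecord
from capqc.gc_bias import (GCBinTable, at_dropout, gc_bin_read_counts,
                           gc_dropout, window_gc_bins)
from capqc.panels import TargetInterval
from tests import oracle


def _ref(tmp_path, seq, name="chr1"):
    path = tmp_path / "ref.fa"
    path.write_text(f">{name}\n{seq}\n")
    return path


def _read(start, end=None, strand="+", chrom="chr1"):
    end = end if end is not None else start + 40
    return ReadRecord("r", True, chrom, start, end, "A" * (end - start),
                      strand=strand)


class TestWindows:
    def test_bin_assignment(self, tmp_path):
        seq = "GC" * 20 + "AT" * 20 + "A" * 80  # window0: 50% GC, window1: 0%
        ref = _ref(tmp_path, seq)
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 160, "s")], ref)
        assert [w.bin for w in windows] == [50, 0]

    def test_partial_trailing_window_dropped(self, tmp_path):
        ref = _ref(tmp_path, "A" * 121)
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 121, "s")], ref)
        assert len(windows) == 1 and (windows[0].start, windows[0].end) == (0, 80)

    def test_all_n_window_excluded(self, tmp_path):
        ref = _ref(tmp_path, "N" * 80 + "G" * 80)
        windows, n_excl = window_gc_bins([TargetInterval("chr1", 0, 160, "s")], ref)
        assert n_excl == 1 and [w.bin for w in windows] == [100]

    def test_bimodal_gc_blocks_recovered(self):
        """Window-bin histogram over a two-block genome peaks near 30 and 70."""
        from capqc.simulate import SimConfig, make_genome, make_panels, _GenomeAdapter
        cfg = SimConfig(seed=5, genome_length=400_000,
                        gc_blocks=[(200_000, 0.30), (200_000, 0.70)],
                        n_snps_a=200, n_snps_b=400)
        genome = make_genome(cfg)
        _, panel_b = make_panels(cfg, genome)
        windows, _ = window_gc_bins(panel_b.intervals, _GenomeAdapter(genome))
        bins = np.array([w.bin for w in windows])
        low, high = bins[bins < 50], bins[bins >= 50]
        assert abs(low.mean() - 30) < 2 and abs(high.mean() - 70) < 2


class TestReadCrediting:
    def test_reads_credited_to_start_window(self, tmp_path):
        ref = _ref(tmp_path, ("GC" * 20 + "AT" * 20) + "A" * 80)
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 160, "s")], ref)
        reads = [_read(10) for _ in range(10)]
        table = gc_bin_read_counts(reads, windows)
        assert table.table.loc[50, "read_count"] == 10
        assert table.table["read_count"].sum() == 10

    def test_minus_strand_uses_five_prime_end(self, tmp_path):
        ref = _ref(tmp_path, ("GC" * 40) + "A" * 80)
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 160, "s")], ref)
        # alignment spans both windows; 5' end of a minus read is its last base
        table = gc_bin_read_counts([_read(60, 100, strand="-")], windows)
        assert table.table.loc[0, "read_count"] == 1
        assert table.table.loc[100, "read_count"] == 0

    def test_read_outside_windows_tallied(self, tmp_path):
        ref = _ref(tmp_path, "G" * 300)
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 80, "s")], ref)
        table = gc_bin_read_counts([_read(200)], windows)
        assert table.n_reads_outside == 1

    def test_no_reads_flags_table(self, tmp_path):
        ref = _ref(tmp_path, "G" * 80)
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 80, "s")], ref)
        table = gc_bin_read_counts([], windows)
        assert table.empty and np.isnan(at_dropout(table))


class TestNormalizedCoverage:
    def _table(self, spec):
        """spec: {bin: (n_windows, read_count)} -> GCBinTable"""
        nw = np.zeros(101, dtype=int)
        rc = np.zeros(101, dtype=int)
        for b, (w, r) in spec.items():
            nw[b], rc[b] = w, r
        df = pd.DataFrame({"bin": np.arange(101), "n_windows": nw, "read_count": rc})
        df["pct_windows"] = 100.0 * nw / nw.sum()
        df["pct_reads"] = 100.0 * rc / rc.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            df["normalized_coverage"] = (rc / nw) / (rc.sum() / nw.sum())
        return GCBinTable(df)

    def test_worked_example(self, tmp_path):
        ref = _ref(tmp_path, "GCGC" * 20 + "GCAT" * 20)  # bins 100 and 50
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 160, "s")], ref)
        reads = [_read(i % 80) for i in range(30)] + [_read(80 + i % 80) for i in range(10)]
        table = gc_bin_read_counts(reads, windows)
        assert table.table.loc[100, "normalized_coverage"] == pytest.approx(1.5)
        assert table.table.loc[50, "normalized_coverage"] == pytest.approx(0.5)

    def test_uniform_coverage_gives_unity(self, tmp_path):
        ref = _ref(tmp_path, "GCGC" * 20 + "GCAT" * 20 + "ATAT" * 20)
        windows, _ = window_gc_bins([TargetInterval("chr1", 0, 240, "s")], ref)
        reads = [_read(w.start + 3) for w in windows for _ in range(7)]
        table = gc_bin_read_counts(reads, windows)
        nc = table.table["normalized_coverage"].dropna()
        assert np.allclose(nc, 1.0)

    def test_window_weighted_mean_is_one(self, small_sim, small_sam_reads):
        part = small_sim["partition"]
        windows, _ = window_gc_bins(part.comparable,
                                    small_sim["dir"] / "genome.fa")
        table = gc_bin_read_counts(small_sam_reads, windows)
        df = table.table
        wmean = (df["normalized_coverage"].fillna(0) * df["n_windows"]).sum() \
            / df["n_windows"].sum()
        assert wmean == pytest.approx(1.0, abs=1e-9)


class TestDropout:
    def _table_from_pcts(self, pw, pr):
        df = pd.DataFrame({"bin": np.arange(101),
                           "n_windows": np.ones(101, dtype=int),
                           "read_count": np.ones(101, dtype=int)})
        df["pct_windows"] = [pw.get(b, 0.0) for b in range(101)]
        df["pct_reads"] = [pr.get(b, 0.0) for b in range(101)]
        df["normalized_coverage"] = 1.0
        return GCBinTable(df)

    def test_worked_example(self):
        t = self._table_from_pcts({40: 50.0, 60: 50.0}, {40: 30.0, 60: 70.0})
        assert at_dropout(t) == pytest.approx(20.0)
        assert gc_dropout(t) == pytest.approx(0.0)

    def test_identical_distributions_give_zero(self):
        pw = {40: 50.0, 60: 50.0}
        t = self._table_from_pcts(pw, dict(pw))
        assert at_dropout(t) == 0.0 and gc_dropout(t) == 0.0

    def test_bin_50_in_both_sums_by_default(self):
        t = self._table_from_pcts({50: 60.0, 60: 40.0}, {50: 40.0, 60: 60.0})
        assert at_dropout(t) == pytest.approx(20.0)
        assert gc_dropout(t) == pytest.approx(20.0)
        assert gc_dropout(t, split_bin_50=True) == 0.0

    def test_random_tables_match_bruteforce(self, rng):
        """Vectorized dropout equals an explicit loop on random tables."""
        for _ in range(100):
            nw = rng.integers(0, 50, size=101)
            rc = rng.integers(0, 500, size=101)
            if nw.sum() == 0 or rc.sum() == 0:
                continue
            df = pd.DataFrame({"bin": np.arange(101), "n_windows": nw,
                               "read_count": rc})
            df["pct_windows"] = 100.0 * nw / nw.sum()
            df["pct_reads"] = 100.0 * rc / rc.sum()
            df["normalized_coverage"] = 1.0
            t = GCBinTable(df)
            at, gc = oracle.recount_dropout(df["pct_windows"].tolist(),
                                            df["pct_reads"].tolist())
            assert at_dropout(t) == pytest.approx(at, abs=1e-12)
            assert gc_dropout(t) == pytest.approx(gc, abs=1e-12)
            assert 0 <= at <= 100 and 0 <= gc <= 100
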