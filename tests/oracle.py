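"""Independent brute-force recount of simulator truth tables.

These functions re-derive every pipeline quantity (sample tallies, GC-bin
tables, damage profiles, pileups) directly from the per-read truth TSV and
the genome string, using plain-Python bookkeeping that shares no code with
the capqc implementation. They are the oracle side of the
pipeline-vs-truth equivalence tests.
"""

from __future__ import annotations

from bisect import bisect_right

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def load_truth(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append({
                "read": f["read"],
                "endogenous": f["endogenous"] == "1",
                "chrom": None if f["chrom"] == "." else f["chrom"],
                "start": int(f["start"]),
                "end": int(f["end"]),
                "strand": f["strand"],
                "duplicate": f["duplicate"] == "1",
                "deam": [] if f["deam_offsets"] == "." else
                        [int(x) for x in f["deam_offsets"].split(",")],
                "mito": f["mito"] == "1",
            })
    return rows


class _IntervalLookup:
    """Sorted-starts + bisect overlap query (intervals non-overlapping)."""

    def __init__(self, intervals):
        self.by_chrom = {}
        for iv in intervals:
            self.by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for lst in self.by_chrom.values():
            lst.sort()

    def overlaps(self, chrom, start, end) -> bool:
        lst = self.by_chrom.get(chrom)
        if not lst:
            return False
        i = bisect_right(lst, (start, float("inf"))) - 1
        if i >= 0 and lst[i][1] > start:
            return True
        return i + 1 < len(lst) and lst[i + 1][0] < end


def recount_sample_counts(truth, comparable, noncomparable, mito_names=("chrM",)):
    """Re-derive every SampleCounts field by looping over truth rows."""
    comp = _IntervalLookup(comparable)
    noncomp = _IntervalLookup(noncomparable)
    c = dict(total_raw=0, total_mapped=0, mapped_dedup=0, on_comparable=0,
             on_comparable_dedup=0, on_noncomparable=0, on_noncomparable_dedup=0,
             off_target=0, mito=0)
    for r in truth:
        c["total_raw"] += 1
        if r["chrom"] is None:
            continue
        c["total_mapped"] += 1
        if not r["duplicate"]:
            c["mapped_dedup"] += 1
        if r["chrom"] in mito_names:
            c["mito"] += 1
        elif comp.overlaps(r["chrom"], r["start"], r["end"]):
            c["on_comparable"] += 1
            if not r["duplicate"]:
                c["on_comparable_dedup"] += 1
        elif noncomp.overlaps(r["chrom"], r["start"], r["end"]):
            c["on_noncomparable"] += 1
            if not r["duplicate"]:
                c["on_noncomparable_dedup"] += 1
        else:
            c["off_target"] += 1
    return c


def read_sequence(row, seqs) -> str:
    """Rebuild the as-sequenced read from genome + truth deamination."""
    frag = seqs[row["chrom"]][row["start"]:row["end"]]
    if row["strand"] == "-":
        frag = revcomp(frag)
    bases = list(frag)
    for i in row["deam"]:
        bases[i] = "T"
    return "".join(bases)


def tile_windows(intervals, seqs, window=80):
    """(chrom, start, end, gc_bin) per full window tiling each interval."""
    out = []
    for iv in intervals:
        pos = iv.start
        while pos + window <= iv.end:
            seq = seqs[iv.chrom][pos:pos + window].upper()
            gc = sum(1 for b in seq if b in "GC")
            acgt = sum(1 for b in seq if b in "ACGT")
            if acgt:
                out.append((iv.chrom, pos, pos + window, round(100.0 * gc / acgt)))
            pos += window
    return out


def recount_gc_table(truth, windows):
    """Per-bin window counts, credited-read counts and derived columns."""
    by_chrom = {}
    for chrom, start, end, b in windows:
        by_chrom.setdefault(chrom, []).append((start, end, b))
    for lst in by_chrom.values():
        lst.sort()
    n_windows = [0] * 101
    for _, _, _, b in windows:
        n_windows[b] += 1
    read_count = [0] * 101
    outside = 0
    for r in truth:
        if r["chrom"] is None:
            continue
        pos = r["start"] if r["strand"] == "+" else r["end"] - 1
        lst = by_chrom.get(r["chrom"], [])
        i = bisect_right(lst, (pos, float("inf"), 101)) - 1
        if i >= 0 and lst[i][0] <= pos < lst[i][1]:
            read_count[lst[i][2]] += 1
        else:
            outside += 1
    total_w = sum(n_windows)
    total_r = sum(read_count)
    pct_windows = [100.0 * n / total_w for n in n_windows]
    pct_reads = [100.0 * n / total_r for n in read_count] if total_r else None
    mean_cov = total_r / total_w
    norm = [(read_count[b] / n_windows[b]) / mean_cov if n_windows[b] else None
            for b in range(101)]
    return {"n_windows": n_windows, "read_count": read_count,
            "pct_windows": pct_windows, "pct_reads": pct_reads,
            "normalized": norm, "outside": outside}


def recount_dropout(pct_windows, pct_reads):
    at = sum(max(0.0, pct_windows[b] - pct_reads[b]) for b in range(0, 51))
    gc = sum(max(0.0, pct_windows[b] - pct_reads[b]) for b in range(50, 101))
    return at, gc


def recount_damage(truth, seqs, max_pos=25):
    """5' C->T counts per position from truth rows (duplicates included)."""
    n_ref_c = [0] * max_pos
    n_ct = [0] * max_pos
    for r in truth:
        if r["chrom"] is None:
            continue
        qry = read_sequence(r, seqs)
        ref = seqs[r["chrom"]][r["start"]:r["end"]]
        if r["strand"] == "-":
            ref = revcomp(ref)
        for i in range(min(max_pos, len(qry))):
            if ref[i] == "C":
                n_ref_c[i] += 1
                if qry[i] == "T":
                    n_ct[i] += 1
    return n_ref_c, n_ct


def recount_pileup(truth, seqs, sites, trim=5):
    """Per-site base depths after end trimming, duplicates excluded."""
    counts = {s.snp_id: {b: 0 for b in "ACGT"} for s in sites}
    by_chrom = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append((s.pos - 1, s.snp_id))
    for r in truth:
        if r["chrom"] is None or r["duplicate"]:
            continue
        length = r["end"] - r["start"]
        if length <= 2 * trim:
            continue
        lo, hi = r["start"] + trim, r["end"] - trim
        plus_seq = read_sequence(r, seqs)
        if r["strand"] == "-":
            plus_seq = revcomp(plus_seq)
        for pos0, snp_id in by_chrom.get(r["chrom"], []):
            if lo <= pos0 < hi:
                base = plus_seq[pos0 - r["start"]]
                if base in "ACGT":
                    counts[snp_id][base] += 1
    return counts
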