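"""Post-mortem damage profiling: positional C->T substitution rates at
fragment ends and read-length summaries.

Cytosine deamination in degraded DNA produces uracils that sequence as
thymine, concentrated at fragment termini. For non-UDG single-stranded
libraries the signal appears as C->T at both ends in the read's own
orientation; the 5' profile is the headline statistic here, with the 3'
profile available on request.

Substitutions are identified against the reference sequence directly (no
MD-tag dependence); reads are oriented before counting, so a minus-strand
alignment contributes plus-strand G->A sites as C->T observations.
Profiling must run on untrimmed reads (before any end-trimming step).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .alignments import ReadRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class DamageProfile:
    """Positional C->T rates from the 5' (or 3') end.

    ``ct_rate[i]`` is NaN where no reference C was observed at offset i+1.
    """

    position: np.ndarray      # 1-based distance from the read end
    n_ref_c: np.ndarray       # reads with reference C at that offset
    n_ct: np.ndarray          # of those, reads showing T
    end: str = "5p"

    @property
    def ct_rate(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n_ref_c > 0, self.n_ct / self.n_ref_c, np.nan)

    @property
    def first_base_rate(self) -> float:
        return float(self.ct_rate[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.position, "n_ref_C": self.n_ref_c,
                             "n_CtoT": self.n_ct, "rate": self.ct_rate})


def ct_profile(
    reads: Iterable[ReadRecord],
    reference,
    max_pos: int = 25,
    end: str = "5p",
) -> DamageProfile:
    """Positional C->T substitution rates over the first ``max_pos`` bases.

    For each read, the reference segment under the alignment is oriented to
    the read's own 5'->3' direction and compared base-by-base with the read
    sequence (stored plus-strand in SAM, re-oriented the same way). Only
    ungapped alignments are profiled; reads whose query length differs from
    the alignment span are skipped.
    """
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    fasta = Fasta(str(reference)) if isinstance(reference, (str, Path)) else reference
    n_ref_c = np.zeros(max_pos, dtype=np.int64)
    n_ct = np.zeros(max_pos, dtype=np.int64)
    for read in reads:
        if not read.mapped or not read.sequence:
            continue
        if len(read.sequence) != read.length:
            continue  # gapped alignment: positional bookkeeping undefined here
        ref = str(fasta[read.chrom][read.start:read.end]).upper()
        qry = read.sequence.upper()
        if read.strand == "-":
            ref, qry = _revcomp(ref), _revcomp(qry)
        if end == "3p":
            ref, qry = ref[::-1], qry[::-1]
        span = min(max_pos, len(qry))
        for i in range(span):
            if ref[i] == "C":
                n_ref_c[i] += 1
                if qry[i] == "T":
                    n_ct[i] += 1
    return DamageProfile(np.arange(1, max_pos + 1), n_ref_c, n_ct, end=end)


def fit_exponential_decay(profile: DamageProfile) -> tuple[float, float]:
    """Least-squares fit of d(i) = d0 * exp(-lam * (i-1)) to the rate curve
    on the log scale (positions with defined, positive rates only)."""
    rate = profile.ct_rate
    ok = np.isfinite(rate) & (rate > 0)
    x = (profile.position[ok] - 1).astype(float)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive rates to fit a decay")
    slope, intercept = np.polyfit(x, np.log(rate[ok]), 1)
    return float(np.exp(intercept)), float(-slope)


def read_length_stats(reads: Iterable[ReadRecord]) -> dict:
    """Mean/median/histogram of aligned read lengths (mapped reads only)."""
    lengths = np.array([r.length for r in reads if r.mapped], dtype=np.int64)
    if lengths.size == 0:
        return {"n": 0, "mean": float("nan"), "median": float("nan"), "histogram": {}}
    vals, counts = np.unique(lengths, return_counts=True)
    return {
        "n": int(lengths.size),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "histogram": {int(v): int(c) for v, c in zip(vals, counts)},
    }
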