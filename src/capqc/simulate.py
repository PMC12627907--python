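"""Synthetic aDNA capture experiment generator.

Emulates the data-generating chain of a hybridization-capture experiment on
a degraded-DNA library: a small reference genome with programmable GC
blocks plus a mitochondrial contig; two nested SNP panels with different
probe footprints; short fragments with 5' C->T deamination; an endogenous
fraction; on-/off-target capture retention with a per-design enrichment
factor, GC-dependent capture efficiency and a saturation regime; PCR
duplicates. Reads are emitted pre-aligned (true coordinates in SAM), plus
FASTQ and per-read truth tables, so the whole QC pipeline is testable with
no external aligner or data.

Capture model: every pre-capture molecule i gets a retention weight
``w_i = 1`` off-target and ``w_i = enrichment_factor * gc_mult(bin_i)``
on-target (bin_i from the 80 bp target window containing the fragment's 5'
start). If the implied post-capture target efficiency would exceed
``saturation_cap``, on-target weights are scaled down so the expected
efficiency equals the cap — the simplest mechanism producing an
efficiency/fold-enrichment plateau independent of endogenous content.
Weights are converted to retention probabilities by dividing by the
maximum weight. Each retained molecule is re-emitted k-1 extra times with
k-1 ~ Geometric(duplication_rate), so the expected duplicate fraction
among emitted reads equals the duplication rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam

from .gc_bias import WindowIndex, window_gc_bins
from .panels import (MYBAITS_LIKE, TWIST_LIKE, ProbeDesign, ProbePanel, SNPSite,
                     TargetInterval, derive_target_intervals, write_bed,
                     write_snp_sites)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic capture experiment.

    Defaults describe a desk-scale non-UDG single-stranded aDNA library:
    short lognormal fragments around 45 bp, 30% first-base C->T deamination
    decaying along the read, a quarter endogenous DNA, a small mitochondrial
    compartment, and moderate PCR duplication.
    """

    seed: int = 0
    genome_length: int = 400_000
    gc_blocks: list[tuple[int, float]] | None = None  # (length bp, GC fraction)
    mito_length: int = 4_000
    mito_gc: float = 0.45
    autosome_name: str = "chr1"
    mito_name: str = "chrM"

    n_snps_a: int = 100
    n_snps_b: int = 220
    design_a: ProbeDesign = field(default_factory=lambda: MYBAITS_LIKE)
    design_b: ProbeDesign = field(default_factory=lambda: TWIST_LIKE)
    ts_tv_ratio: float = 2.0

    n_reads: int = 100_000  # pre-capture molecules sampled
    endogenous_fraction: float = 0.25
    fragment_family: str = "lognormal"   # or "constant", "uniform"
    fragment_mean: float = 45.0
    fragment_sigma: float = 0.25         # sigma of log length (lognormal)
    fragment_min: int = 20
    fragment_max: int = 150
    deamination_d0: float = 0.30
    deamination_lambda: float = 0.3
    deaminate_3p: bool = False
    enrichment_factor: dict[str, float] = field(
        default_factory=lambda: {"a": 8.0, "b": 8.0})
    saturation_cap: float | None = None  # max achievable target efficiency (fraction)
    gc_capture_curve: list[tuple[int, int, float]] = field(default_factory=list)
    #   (min_bin, max_bin, multiplier) ranges; bins not covered multiply by 1
    duplication_rate: float = 0.0        # expected duplicate fraction of emitted reads
    mito_fraction: float = 0.0           # endogenous molecules drawn from mito

    def __post_init__(self) -> None:
        if self.gc_blocks is None:
            self.gc_blocks = [(self.genome_length, 0.42)]
        if sum(l for l, _ in self.gc_blocks) != self.genome_length:
            raise SimulationError("gc_blocks lengths must sum to genome_length")
        for _, gc in self.gc_blocks:
            if not 0 <= gc <= 1:
                raise SimulationError("GC fractions must be in [0,1]")
        if not 0 < self.endogenous_fraction <= 1:
            raise SimulationError("endogenous_fraction must be in (0,1]")
        if not 0 <= self.duplication_rate < 1:
            raise SimulationError("duplication_rate must be in [0,1)")
        if not 0 <= self.mito_fraction < 1:
            raise SimulationError("mito_fraction must be in [0,1)")
        for f in self.enrichment_factor.values():
            if f < 1:
                raise SimulationError("enrichment_factor must be >= 1")
        if self.saturation_cap is not None and not 0 < self.saturation_cap < 1:
            raise SimulationError("saturation_cap must be in (0,1)")

    def gc_multiplier(self, gc_bin: int) -> float:
        for lo, hi, mult in self.gc_capture_curve:
            if lo <= gc_bin <= hi:
                return mult
        return 1.0


@dataclass
class SimGenome:
    sequences: dict[str, str]
    autosome_name: str
    mito_name: str

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def _random_block(rng: np.random.Generator, length: int, gc: float) -> str:
    is_gc = rng.random(length) < gc
    second = rng.random(length) < 0.5
    # GC bases: G or C; AT bases: A or T
    codes = np.where(is_gc, np.where(second, ord("G"), ord("C")),
                     np.where(second, ord("A"), ord("T")))
    return codes.astype(np.uint8).tobytes().decode("ascii")


def make_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """Build the autosome-like contig from the configured GC blocks plus a
    mitochondrial contig."""
    rng = rng or np.random.default_rng([config.seed, 1])
    autosome = "".join(_random_block(rng, l, gc) for l, gc in config.gc_blocks)
    mito = _random_block(rng, config.mito_length, config.mito_gc)
    return SimGenome({config.autosome_name: autosome, config.mito_name: mito},
                     config.autosome_name, config.mito_name)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def make_panels(
    config: SimConfig, genome: SimGenome, rng: np.random.Generator | None = None,
) -> tuple[ProbePanel, ProbePanel]:
    """Place two nested SNP panels (panel A's sites are a subset of B's).

    SNP positions are drawn on a slot grid wide enough that footprints never
    collide; alternative alleles follow the configured transition:transversion
    ratio; the reference base is always one of the two alleles.
    """
    rng = rng or np.random.default_rng([config.seed, 2])
    if config.n_snps_a > config.n_snps_b:
        raise SimulationError("panel A must be nested within panel B")
    margin = max(config.design_a.footprint_length, config.design_b.footprint_length)
    slot = 2 * margin + 2
    autosome = genome.sequences[genome.autosome_name]
    n_slots = len(autosome) // slot
    if n_slots < config.n_snps_b:
        raise SimulationError(
            f"genome too small for {config.n_snps_b} SNPs (fits {n_slots})")
    slots = np.sort(rng.choice(n_slots, size=config.n_snps_b, replace=False))
    offsets = rng.integers(margin, slot - margin, size=config.n_snps_b)
    positions0 = slots * slot + offsets  # 0-based
    ts_prob = config.ts_tv_ratio / (config.ts_tv_ratio + 1.0)

    sites_b: list[SNPSite] = []
    for i, pos0 in enumerate(positions0):
        ref = autosome[pos0]
        if ref not in "ACGT":  # defensive; generator never emits N
            ref = "A"
        if rng.random() < ts_prob:
            alt = _TRANSITION[ref]
        else:
            choices = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
            alt = choices[int(rng.integers(2))]
        sites_b.append(SNPSite(genome.autosome_name, int(pos0) + 1, ref, alt,
                               f"s{i:06d}"))
    subset = np.sort(rng.choice(config.n_snps_b, size=config.n_snps_a, replace=False))
    sites_a = [sites_b[i] for i in subset]
    lengths = genome.contig_lengths
    panel_a = derive_target_intervals(sites_a, config.design_a, "panel_a", lengths)
    panel_b = derive_target_intervals(sites_b, config.design_b, "panel_b", lengths)
    return panel_a, panel_b


@dataclass
class SimRead:
    """Ground truth for one emitted read."""

    name: str
    endogenous: bool
    chrom: str | None
    start: int
    end: int
    strand: str
    sequence: str           # read orientation (as sequenced)
    deam_offsets: tuple[int, ...]  # 0-based 5'->3' offsets flipped C->T
    duplicate: bool
    on_target_a: bool
    on_target_b: bool
    mito: bool


@dataclass
class SimReadSet:
    reads: list[SimRead]
    captured_panel: str | None  # "a", "b" or None (shotgun)
    config: SimConfig

    @property
    def total_raw(self) -> int:
        return len(self.reads)

    def write_sam(self, path, genome: SimGenome) -> None:
        header = {"HD": {"VN": "1.6", "SO": "unsorted"},
                  "SQ": [{"SN": n, "LN": l} for n, l in genome.contig_lengths.items()]}
        tid = {n: i for i, n in enumerate(genome.contig_lengths)}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for r in self.reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.name
                if r.chrom is None:
                    a.is_unmapped = True
                    a.query_sequence = r.sequence
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
                else:
                    a.reference_id = tid[r.chrom]
                    a.reference_start = r.start
                    a.mapping_quality = 37
                    a.cigartuples = [(0, r.end - r.start)]
                    a.is_reverse = r.strand == "-"
                    seq = r.sequence if r.strand == "+" else _revcomp(r.sequence)
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                a.is_duplicate = r.duplicate
                out.write(a)

    def to_read_records(self):
        """In-memory ReadRecords equivalent to the SAM output (sequences in
        plus-strand orientation), for running the pipeline without files."""
        from .alignments import ReadRecord
        recs = []
        for r in self.reads:
            if r.chrom is None:
                recs.append(ReadRecord(r.name, False, sequence=r.sequence,
                                       duplicate=r.duplicate))
            else:
                seq = r.sequence if r.strand == "+" else _revcomp(r.sequence)
                recs.append(ReadRecord(
                    r.name, True, r.chrom, r.start, r.end, seq,
                    qualities=tuple([40] * len(seq)), mapq=37,
                    duplicate=r.duplicate, strand=r.strand))
        return recs

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read\tendogenous\tchrom\tstart\tend\tstrand\tduplicate\t"
                     "deam_offsets\ton_target_a\ton_target_b\tmito\n")
            for r in self.reads:
                fh.write("\t".join([
                    r.name, str(int(r.endogenous)), r.chrom or ".",
                    str(r.start), str(r.end), r.strand, str(int(r.duplicate)),
                    ",".join(map(str, r.deam_offsets)) or ".",
                    str(int(r.on_target_a)), str(int(r.on_target_b)),
                    str(int(r.mito)),
                ]) + "\n")


def _fragment_lengths(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.fragment_family == "constant":
        lengths = np.full(n, int(config.fragment_mean))
    elif config.fragment_family == "uniform":
        lengths = rng.integers(config.fragment_min, config.fragment_max + 1, size=n)
    elif config.fragment_family == "lognormal":
        mu = np.log(config.fragment_mean) - config.fragment_sigma ** 2 / 2
        lengths = np.rint(rng.lognormal(mu, config.fragment_sigma, size=n)).astype(int)
    else:
        raise SimulationError(f"unknown fragment_family {config.fragment_family!r}")
    return np.clip(lengths, config.fragment_min, config.fragment_max)


def _overlaps_any(starts: np.ndarray, ends: np.ndarray,
                  intervals: list[TargetInterval]) -> np.ndarray:
    """Vectorized >=1 bp overlap of read spans with non-overlapping sorted
    intervals on one contig."""
    if not intervals:
        return np.zeros(starts.shape, dtype=bool)
    iv_starts = np.array([iv.start for iv in intervals])
    iv_ends = np.array([iv.end for iv in intervals])
    idx = np.searchsorted(iv_starts, starts, side="right") - 1
    prev_ok = (idx >= 0) & (starts < iv_ends[np.clip(idx, 0, None)])
    nxt = idx + 1
    nxt_ok = (nxt < len(intervals)) & (ends > iv_starts[np.clip(nxt, None, len(intervals) - 1)])
    return prev_ok | nxt_ok


def _deaminate(seq: str, config: SimConfig, rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    if config.deamination_d0 <= 0:
        return seq, ()
    bases = list(seq)
    n = len(bases)
    offsets = []
    probs5 = config.deamination_d0 * np.exp(
        -config.deamination_lambda * np.arange(n))
    u = rng.random(n)
    for i in range(n):
        if bases[i] == "C" and u[i] < probs5[i]:
            bases[i] = "T"
            offsets.append(i)
    if config.deaminate_3p:
        u3 = rng.random(n)
        for i in range(n):
            j = n - 1 - i  # offset i from the 3' end
            if bases[j] == "C" and u3[i] < probs5[i] and j not in offsets:
                bases[j] = "T"
                offsets.append(j)
    return "".join(bases), tuple(sorted(offsets))


def simulate_reads(
    config: SimConfig,
    genome: SimGenome,
    panels: tuple[ProbePanel, ProbePanel],
    captured_panel: str | None = "a",
    rng: np.random.Generator | None = None,
) -> SimReadSet:
    """Run the per-molecule pipeline and emit reads with ground truth.

    ``captured_panel`` selects which design's footprints drive retention
    ("a" or "b"); None simulates shotgun sequencing of the same library
    (every molecule retained).
    """
    stream = {"a": 3, "b": 4, None: 5}[captured_panel]
    rng = rng or np.random.default_rng([config.seed, stream])
    panel_a, panel_b = panels
    autosome = genome.sequences[genome.autosome_name]
    mito = genome.sequences[genome.mito_name]
    n = config.n_reads

    endo = rng.random(n) < config.endogenous_fraction
    on_mito = endo & (rng.random(n) < config.mito_fraction)
    lengths = _fragment_lengths(config, rng, n)
    auto_starts = rng.integers(0, max(len(autosome) - config.fragment_max, 1), size=n)
    mito_starts = rng.integers(0, max(len(mito) - config.fragment_max, 1), size=n)
    starts = np.where(on_mito, mito_starts, auto_starts)
    ends = starts + lengths
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    ivs_a = [iv for iv in panel_a.intervals]
    ivs_b = [iv for iv in panel_b.intervals]
    on_a = _overlaps_any(starts, ends, ivs_a) & endo & ~on_mito
    on_b = _overlaps_any(starts, ends, ivs_b) & endo & ~on_mito

    # retention weights
    weights = np.ones(n)
    if captured_panel is not None:
        cap_panel = panel_a if captured_panel == "a" else panel_b
        on_cap = on_a if captured_panel == "a" else on_b
        factor = config.enrichment_factor[captured_panel]
        windows, _ = window_gc_bins(cap_panel.intervals, _GenomeAdapter(genome))
        index = WindowIndex(windows)
        five_prime = np.where(strands == "+", starts, ends - 1)
        mult = np.ones(n)
        for i in np.nonzero(on_cap)[0]:
            b = index.bin_at(genome.autosome_name, int(five_prime[i]))
            if b is not None:
                mult[i] = config.gc_multiplier(b)
        weights = np.where(on_cap, factor * mult, 1.0)
        if config.saturation_cap is not None:
            mapped = endo  # all endogenous molecules are mappable
            w_on = weights[on_cap & mapped].sum()
            w_off = weights[~on_cap & mapped].sum()
            if w_on + w_off > 0:
                te = w_on / (w_on + w_off)
                cap = config.saturation_cap
                if te > cap:
                    scale = cap * w_off / ((1 - cap) * w_on)
                    weights = np.where(on_cap, weights * scale, weights)
    retain_p = weights / weights.max()
    retained = rng.random(n) < retain_p

    if config.duplication_rate > 0:
        extras = rng.geometric(1.0 - config.duplication_rate, size=n) - 1
    else:
        extras = np.zeros(n, dtype=int)

    reads: list[SimRead] = []
    for i in np.nonzero(retained)[0]:
        name = f"r{i:07d}"
        if endo[i]:
            chrom = genome.mito_name if on_mito[i] else genome.autosome_name
            src = mito if on_mito[i] else autosome
            frag = src[starts[i]:ends[i]]
            oriented = frag if strands[i] == "+" else _revcomp(frag)
            seq, offsets = _deaminate(oriented, config, rng)
            base = SimRead(name, True, chrom, int(starts[i]), int(ends[i]),
                           str(strands[i]), seq, offsets, False,
                           bool(on_a[i]), bool(on_b[i]), bool(on_mito[i]))
        else:
            codes = rng.integers(0, 4, size=int(lengths[i]))
            seq = "".join("ACGT"[c] for c in codes)
            base = SimRead(name, False, None, 0, 0, "+", seq, (), False,
                           False, False, False)
        reads.append(base)
        for j in range(int(extras[i])):
            dup = SimRead(f"{name}_d{j + 1}", base.endogenous, base.chrom,
                          base.start, base.end, base.strand, base.sequence,
                          base.deam_offsets, True, base.on_target_a,
                          base.on_target_b, base.mito)
            reads.append(dup)
    return SimReadSet(reads, captured_panel, config)


class _GenomeAdapter:
    """Duck-typed pyfaidx.Fasta facade over an in-memory SimGenome."""

    def __init__(self, genome: SimGenome) -> None:
        self._seqs = genome.sequences

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]


def simulate_allele_counts(
    sites: list[SNPSite],
    rng: np.random.Generator,
    mean_depth: float = 12.0,
    min_depth_draw: int = 1,
    ad_ratio: float = 0.5,
    het_fraction: float = 1.0,
    damage_leakage: float = 0.0,
    genotypes=None,
):
    """Per-site allele-count tables for bias testing.

    Each site is heterozygous with probability ``het_fraction`` (else
    homozygous for allele1). Depths are Poisson(``mean_depth``) clipped
    below at ``min_depth_draw``; at het sites the first-allele depth is
    Binomial(depth, r) where r is ``ad_ratio`` reflected so it applies to
    the alphabetically first allele. ``damage_leakage`` flips reads of
    hom-CC (or GG) sites to T (A) with the given probability, creating the
    spurious heterozygous-transition signal of damaged libraries.
    Passing ``genotypes`` (snp_id -> allele frozenset) reuses an existing
    truth instead of drawing new genotypes, so several datasets (e.g. a
    shotgun baseline and two enriched libraries) share the same individual.

    Returns ({snp_id: AlleleCounts}, {snp_id: true allele frozenset}).
    """
    from .genotyping import AlleleCounts

    out: dict[str, AlleleCounts] = {}
    truth: dict[str, frozenset[str]] = {}
    for site in sites:
        depth = max(int(rng.poisson(mean_depth)), min_depth_draw)
        ac = AlleleCounts(site)
        if genotypes is not None:
            is_het = len(genotypes[site.snp_id]) == 2
        else:
            is_het = rng.random() < het_fraction
        if is_het:
            first, second = sorted((site.allele1, site.allele2))
            k = int(rng.binomial(depth, ad_ratio))
            ac.depth[first] += k
            ac.depth[second] += depth - k
            truth[site.snp_id] = frozenset((first, second))
        else:
            hom = site.allele1
            n_flip = 0
            if damage_leakage > 0 and hom in ("C", "G"):
                n_flip = int(rng.binomial(depth, damage_leakage))
            ac.depth[hom] += depth - n_flip
            if n_flip:
                ac.depth["T" if hom == "C" else "A"] += n_flip
            truth[site.snp_id] = frozenset((hom,))
        out[site.snp_id] = ac
    return out, truth


def write_config(config: SimConfig, path) -> None:
    d = asdict(config)
    d["design_a"] = asdict(config.design_a)
    d["design_b"] = asdict(config.design_b)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def run_simulation(config: SimConfig, out_dir, captured_panels=("a", "b", None)):
    """Generate genome, panels and one read set per requested capture mode,
    writing FASTA/BED/TSV/SAM/FASTQ outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(config)
    genome.write_fasta(out / "genome.fa")
    panels = make_panels(config, genome)
    for panel, tag in zip(panels, ("a", "b")):
        write_bed(panel.intervals, out / f"panel_{tag}.bed", panel.name)
        write_snp_sites(panel.sites, out / f"sites_{tag}.tsv")
    write_config(config, out / "config.json")
    results = {}
    for mode in captured_panels:
        tag = mode or "shotgun"
        rs = simulate_reads(config, genome, panels, captured_panel=mode)
        rs.write_sam(out / f"reads_{tag}.sam", genome)
        rs.write_fastq(out / f"reads_{tag}.fastq")
        rs.write_truth(out / f"truth_{tag}.tsv")
        results[tag] = rs
    return genome, panels, results
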