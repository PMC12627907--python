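# Methods

## Panel geometry and the comparable partition

A panel is a list of biallelic SNP sites (1-based positions) plus, per SNP,
one probe *footprint*: the contiguous reference span the design's probes
cover. Two built-in geometries mirror the common commercial designs: a
tiled ssRNA design (four 60 bp probes, 121 bp footprint, SNP centred at
offset 61) and a single-probe dsDNA design (one 80 bp probe, 80 bp
footprint, SNP at offset 41 — an even footprint length forces the
one-off-centre placement). Vendors do not publish exact probe boundaries;
any consistent placement convention gives the same comparable partition,
because cross-kit metrics use only the geometric intersection of the two
footprints at shared SNPs. Intervals are BED-style 0-based half-open;
footprints running off a contig are clipped and flagged. Footprints of
nearby SNPs are deliberately *not* merged: per-read classification must be
single-valued, and overlap queries treat the interval list as a set.

## Read classification and tallies

Each mapped read receives exactly one class, with precedence
mito > comparable > noncomparable > off-target. The on-target criterion is
overlap ≥ 1 bp (exposed as `min_overlap`); neither a minimum-overlap nor a
midpoint rule is standard in the field's reports, so the most inclusive
rule is the default and the parameter exists for sensitivity analysis.
`total_raw` (all sequenced reads, including unmapped) must be supplied by
the caller — it cannot be recovered from a mapped-only BAM, and it is the
denominator of the on-target rate. Duplicate status is taken from SAM
flags when present; otherwise reads sharing (chrom, start, end, strand)
are re-marked with exactly one survivor per group. The tallies satisfy the
conservation identity comp + noncomp + off + mito = mapped exactly, and
`SampleCounts.validate()` enforces it.

End trimming (default 5 bp per end) is applied before genotyping pileups
to strip the damage-enriched termini; it is *never* applied before damage
profiling, which needs those termini. Reads shorter than 2·n after
trimming are dropped.

## Capture metrics

The ratio metrics are plain count ratios (see README for formulas).
Undefined ratios (zero denominators) propagate as missing values — never
as 0 — and are written as "." in TSV output. The expected-coverage
estimate converts qPCR molecule counts into genomic coverage via the
informative-sequence-content argument; the genome-length default is
1.12 Gbp (a corvid-sized nuclear genome) and the volume fraction defaults
to 1 (callers pass e.g. 7/50 when only 7 of 50 µL of a library went into
the capture reaction). The scenario-adjustment operation recomputes target
efficiency under counterfactual rescalings of the on- and off-target read
pools (e.g. 2× on-target to mimic denser tiling); it is an arithmetic
identity on counts, not a model.

## GC bias

Target intervals are tiled end-to-end with non-overlapping 80 bp windows;
partial trailing windows are dropped, matching the fixed-window convention
of the standard GC-bias tooling. Window GC bins are round(100·GC) ignoring
N; all-N windows are excluded with a tally. Reads are credited to the
window containing their 5′ alignment start (strand-aware: the 5′ end of a
minus-strand alignment is its last reference base); a midpoint rule is
available. Normalized coverage is defined so its window-weighted mean is
exactly 1, which the tests assert to 1e-9. Bin 50 belongs to both the AT
(0–50) and GC (50–100) dropout sums by default — that is how the ranges
are conventionally written — with an exclusive split behind a flag.

## Damage profiling

C→T rates are computed against the reference sequence directly (no MD
tags), after orienting both read and reference to the read's own 5′→3′
direction, so minus-strand alignments contribute plus-strand G→A sites.
Rates are conditional on reference C at the offset; offsets with no
reference C are missing, not 0. Only ungapped alignments are profiled
(query length must equal the alignment span); gapped reads are skipped
rather than approximated. The single-stranded-library convention reports
the 5′ profile as the headline, with the 3′ profile on request. A
least-squares log-linear helper fits d(i) = d0·exp(−λ(i−1)) for parameter
recovery; it is a summary device, not a damage-model MLE.

## Genotyping and the allelic-bias test

The genotyper is an explicit simplification: a counting caller with
min depth 3, min 2 reads and ≥ 20% fraction per allele, truncating to the
top two bases. It is *not* equivalent to a genotype-likelihood caller and
is documented as such; the concordance rule and the bias test are
independent of the caller choice. Concordance uses the lenient rule
appropriate for a low-coverage baseline: a match requires at least one
enriched allele present in the baseline call.

The allelic-bias test pools heterozygous sites within one variant class
(labels canonically sorted, first allele = alphabetically first base) and
fits an intercept-only quasibinomial model: p̂ = Σk/Σn, Pearson dispersion
φ̂ = Σ(kᵢ − nᵢp̂)²/(nᵢp̂(1−p̂)) / (m−1), and a two-sided Wald t-test of
logit(p̂) against logit(0.5) with variance φ̂/(N·p̂(1−p̂)) and m−1 degrees
of freedom — the behaviour of R's `glm(cbind(k, n−k) ~ 1,
family=quasibinomial)`. With m < 2 the dispersion is fixed at 1 and
flagged; at the boundary (p̂ ∈ {0,1}) a continuity-corrected estimate
(Σk+0.5)/(Σn+1) is used and flagged. Bonferroni correction is applied
within sample, default 18 tests (6 classes × 3 datasets). Calibration is
verified by simulation: type-I error 0.05 ± 0.01 at m=100 sites with
depths 3–30, and power > 0.9 at a true ratio of 0.6 with nᵢ=20, m=100 at
the Bonferroni threshold.

## The simulator

The generator emulates the statistical structure the pipeline assumes,
per read: endogenous origin with probability e; uniform placement on an
autosome-like contig built from programmable GC blocks (or, with
probability `mito_fraction`, on a small mitochondrial contig); lognormal
fragment lengths (mean 45 bp, σ_log 0.25, clamped to 20–150 bp — typical
of degraded non-UDG single-stranded libraries); 5′ C→T deamination with
d(i) = d0·e^(−λ(i−1)), defaults d0 = 0.30, λ = 0.3 (a strongly damaged
library; symmetric 3′ damage optional); capture retention with weight
`enrichment_factor × gc_multiplier(bin)` on-target and 1 off-target, the
GC multiplier keyed to the 80 bp target window containing the fragment's
5′ start (the same geometry the GC-bias module measures); an optional
saturation cap that rescales on-target weights so the expected
post-capture target efficiency cannot exceed the cap — the simplest
mechanism that produces the efficiency/fold-enrichment plateau observed
when a capture chemistry saturates, and deliberately a modelling choice,
since no quantitative saturation mechanism is established; and PCR
duplication, each retained molecule re-emitted k−1 extra times with
k−1 ~ Geometric(ρ), so the expected duplicate share of emitted reads is
exactly ρ. Duplicates copy their template's damage, as PCR copies do.
Exogenous reads are unalignable random sequence and are emitted unmapped.

Reads are emitted pre-aligned with true coordinates (SAM), alongside FASTQ
and a per-read truth table, so tests never need an external aligner and
every pipeline quantity can be recounted from truth by an independent
brute-force script — the equivalence is asserted exactly in the test
suite. Identical config + seed gives byte-identical output files.

What the simulator does **not** model: sequencing error profiles, indels,
paired-end mechanics, reference bias, environmental genomes with alignable
sequence, probe-specific thermodynamics. Passing tests therefore
demonstrate the correctness of the *measurement* code and the internal
consistency of the capture model, not the field realism of any particular
parameter value.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale experiments:
genomes of 0.12–0.8 Mbp, panels of 100–220 SNPs (nested, as custom panel
pairs typically are), 20k–600k library molecules giving roughly 10⁴–10⁵
emitted reads — sizes chosen so every stochastic check sits several
standard errors inside its tolerance while a full run stays in minutes.
Statistical calibration uses 2000 null replicates. Tolerances on
stochastic recoveries are stated per test (3σ binomial for the on-target
rate; ±10% for fold enrichment and duplication; ±0.02 for d0; ±0.1 for
the GC multiplier). Float comparisons against the independent GLM
implementation allow 1e-4 relative slack for IRLS convergence; exact
recounts are compared exactly (integers) or to 1e-9 (derived
percentages).

## Known limitations

* The counting genotyper under-calls heterozygotes at depth 3–4 compared
  with likelihood-based callers; concordance numbers from it are
  illustrative of the rule, not of a production caller.
* Fold enrichment measured on small toy genomes is visibly below the
  programmed retention ratio whenever the panel footprint is a
  non-negligible fraction of the genome (efficiency is a bounded share);
  recovery tests use sparse panels where the two nearly coincide.
* The quasibinomial test assumes sites within a class are exchangeable;
  site-level covariates (depth, GC, mappability) are out of scope.
* The saturation cap is phenomenological; it reproduces a plateau, not
  the kinetics that cause one.
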