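"""Allele counting at panel SNPs, a threshold genotyper, genotype
concordance, and the quasibinomial allelic-bias test.

The genotyper is a deliberately simple counting caller (depth and
allele-fraction thresholds), not a genotype-likelihood model; concordance
and the bias test are independent of the caller choice.

The allelic-bias test treats per-site counts of the canonically first
allele (alphabetical order) at heterozygous sites of one variant class as
binomial outcomes with null probability 0.5. An intercept-only
quasibinomial GLM is fitted: the pooled estimate p-hat = sum(k)/sum(n),
Pearson overdispersion phi-hat, and a two-sided Wald t-test of
logit(p-hat) against logit(0.5) with the variance inflated by phi-hat
(df = m - 1), matching the behaviour of R's ``glm(..., family=quasibinomial)``.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .alignments import ReadRecord
from .panels import SNPSite

_BASES = ("A", "C", "G", "T")
TRANSITIONS = {"AG", "CT"}


class GenotypingError(ValueError):
    pass


@dataclass
class AlleleCounts:
    """Read depth per base at one SNP site (after quality filters)."""

    site: SNPSite
    depth: dict[str, int] = field(default_factory=lambda: {b: 0 for b in _BASES})

    @property
    def total_depth(self) -> int:
        return sum(self.depth.values())


def pileup_allele_counts(
    reads: Iterable[ReadRecord],
    sites: Sequence[SNPSite],
    min_mapq: int = 20,
    min_baseq: int = 20,
    exclude_duplicates: bool = True,
) -> dict[str, AlleleCounts]:
    """Per-base depths at the exact SNP coordinates.

    Reads should already be end-trimmed. Reads failing the mapping-quality
    filter, duplicate-flagged reads, and bases failing the base-quality
    filter are excluded. Uncovered sites are present with zero counts.
    Only ungapped alignments (query length == alignment span) contribute.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append((s.pos - 1, s.snp_id))
    for lst in by_chrom.values():
        lst.sort()
    positions = {c: [p for p, _ in lst] for c, lst in by_chrom.items()}
    counts = {s.snp_id: AlleleCounts(s) for s in sites}

    for read in reads:
        if not read.mapped or read.mapq < min_mapq:
            continue
        if exclude_duplicates and read.duplicate:
            continue
        if not read.sequence or len(read.sequence) != read.length:
            continue
        pos_list = positions.get(read.chrom)
        if not pos_list:
            continue
        lo = bisect_left(pos_list, read.start)
        hi = bisect_right(pos_list, read.end - 1)
        for idx in range(lo, hi):
            pos0, snp_id = by_chrom[read.chrom][idx]
            offset = pos0 - read.start
            base = read.sequence[offset].upper()
            if base not in _BASES:
                continue
            if read.qualities is not None and read.qualities[offset] < min_baseq:
                continue
            counts[snp_id].depth[base] += 1
    return counts


@dataclass
class GenotypeCall:
    site: SNPSite
    alleles: frozenset[str]
    depth: int
    multiallelic: bool = False


def call_genotype(
    counts: AlleleCounts,
    min_depth: int = 3,
    min_allele_reads: int = 2,
    min_allele_frac: float = 0.2,
) -> GenotypeCall | None:
    """Threshold genotyper: no call below ``min_depth``; alleles are bases
    clearing both the absolute-read and fraction thresholds, truncated to
    the top two by depth (ties broken alphabetically)."""
    total = counts.total_depth
    if total < min_depth:
        return None
    qualifying = [
        b for b in _BASES
        if counts.depth[b] >= min_allele_reads and counts.depth[b] / total >= min_allele_frac
    ]
    if not qualifying:
        return None
    multi = len(qualifying) > 2
    qualifying.sort(key=lambda b: (-counts.depth[b], b))
    return GenotypeCall(counts.site, frozenset(qualifying[:2]), total, multiallelic=multi)


def concordance(
    baseline_calls: Mapping[str, GenotypeCall],
    enriched_calls: Mapping[str, GenotypeCall],
) -> tuple[float | None, int]:
    """Genotype match rate between an enriched dataset and its baseline.

    Restricted to sites called in both; a match requires that at least one
    allele of the enriched call is present in the baseline call (lenient
    rule: a low-coverage baseline may miss one allele of a true het).
    Returns (percent matched or None if no overlap, n overlapping sites).
    """
    shared = set(baseline_calls) & set(enriched_calls)
    if not shared:
        return None, 0
    matched = sum(
        1 for sid in shared
        if enriched_calls[sid].alleles & baseline_calls[sid].alleles
    )
    return 100.0 * matched / len(shared), len(shared)


@dataclass(frozen=True)
class VariantClass:
    """Canonical biallelic class: letters sorted, e.g. (G,A) -> AG."""

    label: str

    @property
    def first_allele(self) -> str:
        return self.label[0]

    @property
    def is_transition(self) -> bool:
        return self.label in TRANSITIONS


def classify_variant(allele1: str, allele2: str) -> VariantClass:
    a, b = allele1.upper(), allele2.upper()
    if a == b:
        raise GenotypingError(f"identical alleles {a}")
    if a not in _BASES or b not in _BASES:
        raise GenotypingError(f"non-ACGT alleles {a}/{b}")
    return VariantClass("".join(sorted((a, b))))


ALL_CLASSES = tuple(VariantClass(lbl) for lbl in ("AC", "AG", "AT", "CG", "CT", "GT"))


@dataclass
class BiasTestResult:
    """Quasibinomial test of allele-depth balance within one variant class."""

    variant_class: str
    n_sites: int
    est_ad_ratio: float
    dispersion: float
    p_value: float
    boundary: bool = False
    significant_raw: bool | None = None
    significant_bonferroni: bool | None = None


def quasibinomial_bias_test(
    k: Sequence[int],
    n: Sequence[int],
    p0: float = 0.5,
    variant_class: str = "",
) -> BiasTestResult:
    """Test whether the pooled allele-depth ratio deviates from ``p0``.

    k[i] is the first-allele depth and n[i] the total depth at site i.
    Overdispersion phi-hat is the Pearson statistic / (m - 1); with fewer
    than two sites phi-hat is fixed at 1. At the boundary (p-hat 0 or 1)
    a continuity-corrected estimate (sum k + 0.5)/(sum n + 1) is used and
    the result flagged.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.shape != n.shape or k.ndim != 1 or k.size == 0:
        raise GenotypingError("k and n must be equal-length non-empty vectors")
    if np.any(k < 0) or np.any(n <= 0) or np.any(k > n):
        raise GenotypingError("require 0 <= k_i <= n_i and n_i > 0")
    m = k.size
    K, N = k.sum(), n.sum()
    p_hat = K / N
    boundary = p_hat in (0.0, 1.0)
    if boundary:
        p_hat = (K + 0.5) / (N + 1.0)
    if m >= 2:
        pearson = np.sum((k - n * p_hat) ** 2 / (n * p_hat * (1 - p_hat)))
        phi = float(pearson / (m - 1))
    else:
        phi = 1.0
    # Wald test on the logit scale: Var(beta) = phi / (N * p(1-p))
    beta = math.log(p_hat / (1 - p_hat)) - math.log(p0 / (1 - p0))
    se = math.sqrt(phi / (N * p_hat * (1 - p_hat)))
    # phi (hence se) can be exactly 0 when all residuals vanish; the test
    # statistic is then 0 under no effect and infinite otherwise
    t = beta / se if se > 0 else (0.0 if beta == 0 else math.copysign(math.inf, beta))
    df = max(m - 1, 1)
    p_value = float(2.0 * stats.t.sf(abs(t), df))
    return BiasTestResult(
        variant_class=variant_class,
        n_sites=int(m),
        est_ad_ratio=float(K / N) if not boundary else float(p_hat),
        dispersion=phi,
        p_value=p_value,
        boundary=boundary,
    )


def bonferroni_adjust(
    results: Sequence[BiasTestResult],
    alpha: float = 0.05,
    n_tests: int = 18,
) -> float:
    """Within-sample Bonferroni correction.

    Default n_tests = 18 (6 variant classes x 3 datasets). Sets the
    significance flags on each result in place and returns the adjusted
    threshold alpha / n_tests.
    """
    if n_tests < 1:
        raise GenotypingError("n_tests must be >= 1")
    threshold = alpha / n_tests
    for r in results:
        r.significant_raw = r.p_value < alpha
        r.significant_bonferroni = r.p_value < threshold
    return threshold


def bias_test_by_class(
    allele_counts: Iterable[AlleleCounts],
    het_sites: Mapping[str, frozenset[str]] | None = None,
    min_depth: int = 3,
    alpha: float = 0.05,
    n_tests: int = 18,
) -> list[BiasTestResult]:
    """Run the bias test per variant class over heterozygous panel sites.

    ``het_sites`` maps snp_id -> allele pair for sites established as
    heterozygous (e.g. from a shotgun baseline); if None, each site's own
    panel alleles are used. Sites below ``min_depth`` (counting the two
    class alleles) are excluded. The first allele of a class is the
    alphabetically first base.
    """
    per_class: dict[str, tuple[list[int], list[int]]] = {}
    for ac in allele_counts:
        if het_sites is not None:
            if ac.site.snp_id not in het_sites:
                continue
            alleles = sorted(het_sites[ac.site.snp_id])
        else:
            alleles = sorted((ac.site.allele1, ac.site.allele2))
        vc = classify_variant(*alleles)
        d1, d2 = ac.depth[alleles[0]], ac.depth[alleles[1]]
        if d1 + d2 < min_depth:
            continue
        ks, ns = per_class.setdefault(vc.label, ([], []))
        ks.append(d1)
        ns.append(d1 + d2)
    results = [
        quasibinomial_bias_test(ks, ns, variant_class=label)
        for label, (ks, ns) in sorted(per_class.items())
    ]
    bonferroni_adjust(results, alpha=alpha, n_tests=n_tests)
    return results
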