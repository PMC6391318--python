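"""Association and equilibrium statistics used in the case-control arm.

Implements allele counting from genotype classes, Hardy-Weinberg tests
(chi-square goodness of fit and an exact conditional test), the Pearson
chi-square on 2x2 allele tables, Fisher's exact test on haplotype
presence counts, and the linkage-disequilibrium risk statistic

    delta = (Fd - Fc) / (1 - Fc)

where Fd and Fc are the haplotype (or allele) frequencies on disease
and control chromosomes.  delta is the population attributable risk
under complete association and is reported signed; no continuity
corrections are applied anywhere, and the two-sided Fisher p-value uses
the "sum of tables at most as probable as observed" convention, so all
results are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from scipy import stats as sps

__all__ = [
    "GenotypeCounts",
    "AlleleCounts",
    "TestResult",
    "DeltaResult",
    "StatsError",
    "allele_counts",
    "hwe_chi_square",
    "hwe_exact",
    "hwe_test",
    "allele_chi_square",
    "fisher_haplotype_test",
    "delta_statistic",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype-class counts for one SNP in one group."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    group: str = ""
    rs_id: str = ""
    ref_allele: str = ""
    alt_allele: str = ""
    printed: Optional[Dict[str, str]] = None  # published annotations, if any

    def __post_init__(self):
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise StatsError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


@dataclass(frozen=True)
class AlleleCounts:
    ref: int
    alt: int
    freq_ref: float
    freq_alt: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: Optional[int]
    method: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise StatsError(f"p-value {self.p_value} out of range")


@dataclass(frozen=True)
class DeltaResult:
    f_disease: float
    f_control: float
    delta: float


def allele_counts(g: GenotypeCounts) -> AlleleCounts:
    """Allele counts and frequencies from genotype classes (2n alleles)."""
    if g.n == 0:
        raise StatsError("all genotype counts are zero")
    ref = 2 * g.n_hom_ref + g.n_het
    alt = 2 * g.n_hom_alt + g.n_het
    total = 2 * g.n
    return AlleleCounts(ref, alt, ref / total, alt / total)


def hwe_chi_square(g: GenotypeCounts) -> TestResult:
    """Chi-square goodness of fit to p^2 : 2pq : q^2 proportions (df = 1)."""
    ac = allele_counts(g)
    n = g.n
    p, q = ac.freq_ref, ac.freq_alt
    if p == 0.0 or q == 0.0:
        # monomorphic: the fit is exact by construction
        return TestResult(0.0, 1.0, 1, "chi_square_gof")
    expected = (n * p * p, n * 2 * p * q, n * q * q)
    observed = (g.n_hom_ref, g.n_het, g.n_hom_alt)
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return TestResult(stat, float(sps.chi2.sf(stat, 1)), 1, "chi_square_gof")


def _log_hwe_het_prob(n_het: int, n_rare: int, n: int) -> float:
    """Log of P(heterozygote count | allele counts) under HWE.

    Conditional distribution of the number of heterozygotes given the
    minor-allele count ``n_rare`` among ``n`` diploids:

        P(het) = n! / (n_aa! n_ab! n_bb!) * 2^het * n_rare! n_common! / (2n)!
    """
    n_common = 2 * n - n_rare
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    return (
        math.lgamma(n + 1)
        - math.lgamma(n_hom_rare + 1)
        - math.lgamma(n_het + 1)
        - math.lgamma(n_hom_common + 1)
        + n_het * math.log(2.0)
        + math.lgamma(n_rare + 1)
        + math.lgamma(n_common + 1)
        - math.lgamma(2 * n + 1)
    )


def hwe_exact(g: GenotypeCounts) -> TestResult:
    """Exact conditional HWE test.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of configurations no more
    probable than the observed one (the standard two-sided convention).
    The statistic reported is the probability of the observed table.
    """
    if g.n == 0:
        raise StatsError("all genotype counts are zero")
    n = g.n
    n_ref = 2 * g.n_hom_ref + g.n_het
    n_alt = 2 * g.n_hom_alt + g.n_het
    n_rare = min(n_ref, n_alt)
    if n_rare == 0:
        # monomorphic: only one configuration exists
        return TestResult(1.0, 1.0, None, "hwe_exact")
    hets = range(n_rare % 2, n_rare + 1, 2)
    logps = {h: _log_hwe_het_prob(h, n_rare, n) for h in hets}
    log_obs = logps[g.n_het]
    # relative tolerance guards against ties lost to rounding
    p = sum(math.exp(lp) for lp in logps.values() if lp <= log_obs + 1e-9)
    return TestResult(math.exp(log_obs), min(p, 1.0), None, "hwe_exact")


def hwe_test(g: GenotypeCounts, method: str = "exact") -> TestResult:
    """Hardy-Weinberg test; ``method`` is "exact" or "chi_square_gof".

    The exact test is the default: with genotype classes as small as a
    handful of rare homozygotes the chi-square approximation is poor.
    """
    if method == "exact":
        return hwe_exact(g)
    if method == "chi_square_gof":
        return hwe_chi_square(g)
    raise StatsError(f"unknown HWE method {method!r}")


def allele_chi_square(
    case: Tuple[int, int], control: Tuple[int, int]
) -> TestResult:
    """Pearson chi-square (no continuity correction) on a 2x2 allele table."""
    a, b = case
    c, d = control
    if min(a, b, c, d) < 0:
        raise StatsError("negative allele count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise StatsError("a margin of the 2x2 table is zero")
    total = a + b + c + d
    stat = total * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return TestResult(stat, float(sps.chi2.sf(stat, 1)), 1, "chi_square_2x2")


def fisher_haplotype_test(
    case_counts: Tuple[int, int], control_counts: Tuple[int, int]
) -> TestResult:
    """Two-sided Fisher exact test on haplotype presence/absence counts.

    ``case_counts`` = (with haplotype, without) among disease
    chromosomes, likewise for controls.
    """
    a, b = case_counts
    c, d = control_counts
    if min(a, b, c, d) < 0:
        raise StatsError("negative count")
    if a + b == 0 or c + d == 0:
        raise StatsError("empty margin (degenerate table)")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(odds) if math.isfinite(odds) else float("inf"),
                      float(p), None, "fisher_exact")


def delta_statistic(f_disease: float, f_control: float) -> DeltaResult:
    """delta = (Fd - Fc)/(1 - Fc); signed, exact, requires Fc < 1."""
    if not (0.0 <= f_disease <= 1.0):
        raise StatsError(f"Fd = {f_disease} outside [0, 1]")
    if not (0.0 <= f_control < 1.0):
        raise StatsError(f"Fc = {f_control} must lie in [0, 1)")
    return DeltaResult(
        f_disease, f_control, (f_disease - f_control) / (1.0 - f_control)
    )
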