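"""Per-locus summary statistics and randomization tests for reference adults.

Observed heterozygosity is the heterozygote fraction; expected
heterozygosity uses Nei's small-sample correction ``(2n/(2n-1))(1 - sum p_i^2)``.
Hardy-Weinberg is tested with a plain Monte-Carlo exact test (random
re-pairing of the observed allele multiset) rather than a Markov chain:
the null distribution targeted is identical and convergence is trivial.
Linkage disequilibrium is tested at the genotypic level with a permutation
G-test, since gametic phase is unknown.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2_contingency

from .genotype_model import Genotype

__all__ = [
    "PopgenLocusSummary",
    "TestResult",
    "summarize_locus",
    "hwe_test",
    "ld_test",
    "bonferroni",
]

_LN2 = float(np.log(2.0))


@dataclass
class PopgenLocusSummary:
    locus: str
    n: int
    Na: int
    Ho: float
    He: float
    p_hwe: float | None = None


@dataclass
class TestResult:
    statistic: float
    p: float
    df: int = 0
    n_permutations: int = 0
    flag: str = ""


def _clean(genotypes: Sequence[Genotype]) -> list[Genotype]:
    return [g for g in genotypes if not g.missing]


def summarize_locus(locus: str, genotypes: Sequence[Genotype]) -> PopgenLocusSummary:
    """Allele count, observed and unbiased expected heterozygosity."""
    gts = _clean(genotypes)
    n = len(gts)
    if n < 2:
        raise ValueError(f"locus {locus}: need >=2 non-missing genotypes, got {n}")
    alleles = Counter(a for g in gts for a in g.alleles)
    total = 2 * n
    ho = sum(1 for g in gts if g.is_heterozygous) / n
    # summed in sorted allele order so the estimate is exactly invariant to
    # individual ordering
    sum_p2 = sum((c / total) ** 2 for _, c in sorted(alleles.items()))
    he = (total / (total - 1)) * (1.0 - sum_p2)
    return PopgenLocusSummary(locus=locus, n=n, Na=len(alleles), Ho=ho, He=he)


def _log_table_prob(genotype_counts: Counter, allele_counts: Counter, n: int) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Levene's formula: P = n! * prod(a_i!) * 2^h / [(2n)! / ... ] — written in
    log space via gammaln.
    """
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    logp = gammaln(n + 1) + h * _LN2 - gammaln(2 * n + 1)
    for c in allele_counts.values():
        logp += gammaln(c + 1)
    for c in genotype_counts.values():
        logp -= gammaln(c + 1)
    return float(logp)


def hwe_test(
    genotypes: Sequence[Genotype], n_reps: int = 10_000, seed: int | None = None
) -> TestResult:
    """Monte-Carlo exact test of Hardy-Weinberg proportions.

    The statistic is the conditional probability of the observed genotype
    table given the allele counts; the p-value is the fraction of random
    pairings of the observed allele multiset with probability <= observed,
    with the (n_reps + 1)-denominator convention.
    """
    gts = _clean(genotypes)
    n = len(gts)
    if n < 5:
        raise ValueError(f"HWE test needs n >= 5, got {n}")
    allele_counts = Counter(a for g in gts for a in g.alleles)
    if len(allele_counts) < 2:
        return TestResult(statistic=1.0, p=1.0, flag="monomorphic")

    obs_counts = Counter(g.alleles for g in gts)
    log_obs = _log_table_prob(obs_counts, allele_counts, n)

    rng = np.random.default_rng(seed)
    pool = np.array([a for g in gts for a in g.alleles])
    hits = 0
    tol = 1e-12
    for _ in range(n_reps):
        rng.shuffle(pool)
        pairs = pool.reshape(n, 2)
        pairs = np.sort(pairs, axis=1)
        table = Counter(map(tuple, pairs))
        if _log_table_prob(table, allele_counts, n) <= log_obs + tol:
            hits += 1
    p = (hits + 1) / (n_reps + 1)
    return TestResult(statistic=float(np.exp(log_obs)), p=p, n_permutations=n_reps)


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood-ratio G on the contingency table of two category vectors."""
    xi, x_inv = np.unique(x, return_inverse=True)
    yi, y_inv = np.unique(y, return_inverse=True)
    if len(xi) < 2 or len(yi) < 2:
        return 0.0
    table = np.zeros((len(xi), len(yi)))
    np.add.at(table, (x_inv, y_inv), 1)
    g, _, _, _ = chi2_contingency(table, lambda_="log-likelihood", correction=False)
    return float(g)


def ld_test(
    genotypes_a: Sequence[Genotype],
    genotypes_b: Sequence[Genotype],
    n_reps: int = 2_000,
    seed: int | None = None,
) -> TestResult:
    """Permutation G-test of genotypic association between two loci.

    Individuals missing at either locus are dropped; the null is generated
    by shuffling one locus' genotypes across individuals.
    """
    pairs = [
        (ga.alleles, gb.alleles)
        for ga, gb in zip(genotypes_a, genotypes_b)
        if not ga.missing and not gb.missing
    ]
    if len(pairs) < 5:
        return TestResult(statistic=0.0, p=1.0, flag="insufficient_data")
    xa = np.array([hash(a) for a, _ in pairs])
    xb = np.array([hash(b) for _, b in pairs])
    if len(np.unique(xa)) < 2 or len(np.unique(xb)) < 2:
        return TestResult(statistic=0.0, p=1.0, flag="insufficient_variation")
    g_obs = _g_statistic(xa, xb)
    rng = np.random.default_rng(seed)
    hits = 0
    xb_perm = xb.copy()
    for _ in range(n_reps):
        rng.shuffle(xb_perm)
        if _g_statistic(xa, xb_perm) >= g_obs - 1e-12:
            hits += 1
    return TestResult(statistic=g_obs, p=(hits + 1) / (n_reps + 1), n_permutations=n_reps)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Significance flags under the Bonferroni-adjusted threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = len(p_values)
    if m == 0:
        return []
    threshold = alpha / m
    return [p <= threshold for p in p_values]


def summarize_panel(
    individuals, loci, n_reps: int = 10_000, seed: int | None = None
) -> list[PopgenLocusSummary]:
    """Summary + HWE p per locus over a set of individuals (skips thin loci)."""
    out = []
    for loc in loci:
        gts = [ind.genotype_at(loc.name) for ind in individuals]
        gts = [g for g in gts if not g.missing]
        if len(gts) < 5:
            warnings.warn(f"locus {loc.name}: <5 genotypes, skipped")
            continue
        summ = summarize_locus(loc.name, gts)
        summ.p_hwe = hwe_test(gts, n_reps=n_reps, seed=seed).p if summ.Na >= 2 else 1.0
        out.append(summ)
    return out
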