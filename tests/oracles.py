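"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written naively and separately from the package code:
exhaustive enumeration over father genotypes and assignments, explicit
minimum hitting sets, and full probability-weighted enumeration of
simulated detection.  Slow by design; only run at tiny sizes.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

from litterkin.genotype_model import AlleleFrequencies, Genotype, Litter

FALLBACK = 1e-3


def naive_transmission(mother: tuple[int, int], father: tuple[int, int],
                       embryo: tuple[int, int]) -> float:
    p = 0.0
    for a in mother:
        for b in father:
            if tuple(sorted((a, b))) == tuple(sorted(embryo)):
                p += 0.25
    return p


def naive_prior(pair: tuple[int, int], freqs: dict[int, float]) -> float:
    fx = freqs.get(pair[0], FALLBACK)
    fy = freqs.get(pair[1], FALLBACK)
    return fx * fx if pair[0] == pair[1] else 2 * fx * fy


def naive_paternal_pool(mother: tuple[int, int], embryos: list[tuple[int, int]],
                        alleles: list[int]) -> set[int]:
    """Alleles that could be the paternal contribution of >=1 embryo."""
    pool = set()
    for e in embryos:
        for a in alleles:
            for b in mother:
                if tuple(sorted((b, a))) == tuple(sorted(e)):
                    pool.add(a)
    return pool


def naive_min_paternal_count(mother: tuple[int, int],
                             embryos: list[tuple[int, int]]) -> int:
    """Smallest allele set providing one paternal allele per embryo."""
    alleles = sorted({a for e in embryos for a in e} | set(mother))

    def possible_paternal(e):
        return {
            x for x in alleles
            if any(tuple(sorted((b, x))) == tuple(sorted(e)) for b in mother)
        }

    usable = [e for e in embryos if possible_paternal(e)]
    if not usable:
        return 0
    for size in range(1, len(alleles) + 1):
        for subset in itertools.combinations(alleles, size):
            ok = True
            for e in usable:
                if not any(
                    tuple(sorted((b, x))) == tuple(sorted(e))
                    for x in subset for b in mother
                ):
                    ok = False
                    break
            if ok:
                return size
    return len(alleles)


def _restricted_growth_assignments(n: int, k: int):
    """All assignments of n items to exactly k groups, first-occurrence order."""
    def rec(i, used, cur):
        if n - i < k - used:
            return
        if i == n:
            if used == k:
                yield tuple(cur)
            return
        for g in range(min(used + 1, k)):
            cur.append(g)
            yield from rec(i + 1, used + (1 if g == used else 0), cur)
            cur.pop()

    yield from rec(0, 0, [])


def brute_force_min_sires(litter: Litter, freqs: AlleleFrequencies,
                          loci: list[str], max_k: int = 4):
    """Exhaustive search over father genotype tuples and embryo assignments.

    Returns (k, solutions) with solutions a dict keyed by the canonical
    (fathers, assignment) structure, valued by normalized probability.
    """
    mother = {l: litter.mother.genotype_at(l).alleles for l in loci}
    embryos = [{l: e.genotype_at(l).alleles for l in loci} for e in litter.embryos]
    n = len(embryos)
    pools = {}
    for l in loci:
        alleles = sorted({a for e in embryos for a in e[l]} | set(mother[l])
                         | set(freqs.freqs.get(l, {})))
        pool = naive_paternal_pool(mother[l], [e[l] for e in embryos], alleles)
        wild = max(sorted(freqs.freqs.get(l, {0: 1.0})),
                   key=lambda a: freqs.freqs.get(l, {0: 1.0})[a])
        pools[l] = sorted(pool | {wild})

    for k in range(1, max_k + 1):
        found = {}
        total = 0.0
        for assign in _restricted_growth_assignments(n, k):
            cells = {}
            feasible = True
            for g in range(k):
                members = [i for i in range(n) if assign[i] == g]
                for l in loci:
                    opts = []
                    for pair in itertools.combinations_with_replacement(pools[l], 2):
                        if all(naive_transmission(mother[l], pair, embryos[i][l]) > 0
                               for i in members):
                            w = naive_prior(pair, freqs.freqs.get(l, {}))
                            for i in members:
                                w *= naive_transmission(mother[l], pair, embryos[i][l])
                            opts.append((pair, w))
                    if not opts:
                        feasible = False
                        break
                    cells[(g, l)] = opts
                if not feasible:
                    break
            if not feasible:
                continue
            keys = sorted(cells)
            for combo in itertools.product(*(cells[key] for key in keys)):
                weight = math.prod(w for _, w in combo)
                fathers = [tuple() for _ in range(k)]
                per_father = defaultdict(dict)
                for (g, l), (pair, _) in zip(keys, combo):
                    per_father[g][l] = pair
                genos = [tuple(sorted(per_father[g].items())) for g in range(k)]
                order = sorted(range(k), key=lambda g: genos[g])
                remap = {old: new for new, old in enumerate(order)}
                key = (
                    tuple(genos[g] for g in order),
                    tuple(remap[assign[i]] for i in range(n)),
                )
                found[key] = found.get(key, 0.0) + weight
                total += weight
        if found:
            return k, {key: w / total for key, w in found.items()}
    return None, {}


def exact_prdm(freqs: dict[int, float], n_sires: int, skew: list[float],
               litter_size: int) -> float:
    """Exact detection probability for a single locus by full enumeration."""
    alleles = sorted(freqs)

    def geno_draws():
        for pair in itertools.product(alleles, repeat=2):
            yield tuple(sorted(pair)), freqs[pair[0]] * freqs[pair[1]]

    detect_cache: dict = {}

    def detected(mother, embryo_genos) -> bool:
        key = (mother, tuple(sorted(embryo_genos)))
        if key not in detect_cache:
            detect_cache[key] = naive_min_paternal_count(mother, list(embryo_genos)) >= 3
        return detect_cache[key]

    total = 0.0
    parents = [geno_draws] * (1 + n_sires)
    for mother, pm in geno_draws():
        for dads in itertools.product(*(list(geno_draws()) for _ in range(n_sires))):
            pd = pm * math.prod(w for _, w in dads)
            dad_genos = [g for g, _ in dads]
            # enumerate per-embryo outcome distribution, embryos iid given parents
            outcome_probs: dict[tuple[int, int], float] = defaultdict(float)
            for s in range(n_sires):
                for mi in range(2):
                    for fi in range(2):
                        g = tuple(sorted((mother[mi], dad_genos[s][fi])))
                        outcome_probs[g] += skew[s] * 0.25
            genos = list(outcome_probs)
            for combo in itertools.product(genos, repeat=litter_size):
                pe = math.prod(outcome_probs[g] for g in combo)
                if detected(mother, combo):
                    total += pd * pe
    return total


def naive_multinomial_skew_p(counts: list[int]) -> float:
    """Exact equal-probability multinomial test by full enumeration."""
    k, n = len(counts), sum(counts)

    def pmf(table):
        p = math.factorial(n)
        for c in table:
            p //= math.factorial(c)
        return p * (1.0 / k) ** n

    p_obs = pmf(counts)
    total = 0.0
    for combo in itertools.product(range(n + 1), repeat=k - 1):
        if sum(combo) > n:
            continue
        table = list(combo) + [n - sum(combo)]
        pm = pmf(table)
        if pm <= p_obs * (1 + 1e-12):
            total += pm
    return min(total, 1.0)
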