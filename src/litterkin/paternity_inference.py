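"""Minimum-sire reconstruction from mother-litter microsatellite genotypes.

The maternal contribution is subtracted from each embryo genotype to obtain
per-locus paternal candidate alleles.  A litter with three or more paternal
alleles at any locus (under the conservative minimum resolution of
ambiguous embryos) is flagged polyandrous.  The minimum number of sires is
found by exhaustive search over embryo-to-father partitions; all father
multilocus genotypes consistent with the best (smallest) father count are
enumerated and ranked by a relative probability combining Hardy-Weinberg
priors on father genotypes with Mendelian transmission probabilities.

Candidate-set structure
-----------------------
Given a genotyped mother, an embryo's paternal candidate set at a locus is
either a single allele (the embryo carries an allele the mother lacks, or
is homozygous) or exactly the mother's heterozygous allele pair (the
embryo shares both alleles with her).  The minimum number of distinct
paternal alleles therefore has the closed form::

    |obligate| + 1  if ambiguous embryos exist and no obligate allele is maternal
    |obligate|      otherwise

which is the minimum hitting set over the candidate sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binomtest, chi2 as chi2_dist, multinomial

from .genotype_model import AlleleFrequencies, Genotype, Individual, Litter, LocusDef

__all__ = [
    "PaternalAlleleSummary",
    "LocusPaternalSummary",
    "SireSolution",
    "SireReconstruction",
    "SkewTestResult",
    "FisherCombined",
    "UnresolvedPaternityError",
    "paternal_candidates",
    "deduce_paternal_alleles",
    "flag_polyandry",
    "min_sires",
    "reconstruct_litter",
    "mendelian_segregation_test",
    "fisher_combine",
    "skew_test",
    "unassigned_embryos",
    "litter_report",
]

#: HWE-prior frequency used for alleles absent from the reference sample
FALLBACK_FREQ = 1e-3


class UnresolvedPaternityError(RuntimeError):
    """No Mendel-consistent father set found within ``max_k``."""


# ---------------------------------------------------------------------------
# paternal allele deduction
# ---------------------------------------------------------------------------


def paternal_candidates(mother: Genotype, embryo: Genotype) -> frozenset[int] | None:
    """Possible paternal alleles for one embryo at one locus.

    Returns ``None`` when neither embryo allele could be maternal
    (mother-embryo incompatibility).  Both genotypes must be non-missing.
    """
    m = set(mother.alleles)
    e1, e2 = embryo.alleles
    in1, in2 = e1 in m, e2 in m
    if e1 == e2:
        return frozenset((e1,)) if in1 else None
    if in1 and in2:
        return frozenset((e1, e2))  # ambiguous: equals the mother's pair
    if in1:
        return frozenset((e2,))
    if in2:
        return frozenset((e1,))
    return None


@dataclass
class LocusPaternalSummary:
    locus: str
    obligate: frozenset[int]
    n_ambiguous: int
    min_count: int
    incompatible: tuple[str, ...] = ()


@dataclass
class PaternalAlleleSummary:
    litter_id: str
    per_locus: dict[str, LocusPaternalSummary]
    maternal_mismatch: tuple[str, ...] = ()

    @property
    def min_counts(self) -> dict[str, int]:
        return {loc: s.min_count for loc, s in self.per_locus.items()}


def _min_count(obligate: frozenset[int], n_amb: int, mother_alleles: frozenset[int]) -> int:
    if n_amb > 0 and not (obligate & mother_alleles):
        return len(obligate) + 1
    return len(obligate)


def deduce_paternal_alleles(
    litter: Litter, loci: Sequence[LocusDef]
) -> PaternalAlleleSummary:
    """Subtract the maternal contribution and count paternal alleles per locus.

    Embryos incompatible with the mother at two or more loci are flagged
    ``maternal_mismatch`` and excluded entirely; a single-locus
    incompatibility excludes only that embryo-locus.
    """
    mother = litter.mother
    usable = [
        loc.name for loc in loci if not mother.genotype_at(loc.name).missing
    ]
    if not usable:
        raise ValueError(f"mother {mother.id} has no genotyped loci in the panel")

    incompat_count: dict[str, int] = {}
    cands: dict[tuple[str, str], frozenset[int] | None] = {}
    for emb in litter.embryos:
        for locus in usable:
            egt = emb.genotype_at(locus)
            if egt.missing:
                continue
            c = paternal_candidates(mother.genotype_at(locus), egt)
            cands[(emb.id, locus)] = c
            if c is None:
                incompat_count[emb.id] = incompat_count.get(emb.id, 0) + 1
    mismatched = tuple(sorted(e for e, c in incompat_count.items() if c >= 2))

    per_locus: dict[str, LocusPaternalSummary] = {}
    for locus in usable:
        mset = frozenset(mother.genotype_at(locus).alleles)
        obligate: set[int] = set()
        n_amb = 0
        bad: list[str] = []
        for emb in litter.embryos:
            if emb.id in mismatched:
                continue
            c = cands.get((emb.id, locus))
            if c is None:
                if (emb.id, locus) in cands:
                    bad.append(emb.id)
                continue
            if len(c) == 1:
                obligate.update(c)
            else:
                n_amb += 1
        ob = frozenset(obligate)
        per_locus[locus] = LocusPaternalSummary(
            locus=locus,
            obligate=ob,
            n_ambiguous=n_amb,
            min_count=_min_count(ob, n_amb, mset),
            incompatible=tuple(bad),
        )
    return PaternalAlleleSummary(litter.mother.id, per_locus, mismatched)


def flag_polyandry(summary: PaternalAlleleSummary) -> bool:
    """True iff >=3 minimal paternal alleles at one or more loci."""
    return any(s.min_count >= 3 for s in summary.per_locus.values())


# ---------------------------------------------------------------------------
# minimum-sire exhaustive search
# ---------------------------------------------------------------------------


@dataclass
class SireSolution:
    k: int
    fathers: list[dict[str, Genotype]]
    assignment: dict[str, int]
    relative_probability: float
    skew: list[int] = field(default_factory=list)

    def sort_key(self) -> tuple:
        return tuple(
            tuple(sorted((loc, g.alleles) for loc, g in f.items())) for f in self.fathers
        )


@dataclass
class SireReconstruction:
    litter_id: str
    k: int
    solutions: list[SireSolution]
    excluded_embryos: tuple[str, ...] = ()
    truncated: bool = False
    n_partitions: int = 0
    unresolved_at: int | None = None

    @property
    def best(self) -> SireSolution:
        return self.solutions[0]


def _transmission(mother: Genotype, father: tuple[int, int], embryo: Genotype) -> float:
    """P(embryo genotype | mother, father) under Mendelian segregation."""
    target = embryo.alleles
    p = 0.0
    for a in mother.alleles:
        for b in father:
            if (a, b) == target or (b, a) == target:
                p += 0.25
    return p


def _hwe_prior(pair: tuple[int, int], freqs: Mapping[int, float]) -> float:
    fx = freqs.get(pair[0], FALLBACK_FREQ)
    fy = freqs.get(pair[1], FALLBACK_FREQ)
    return fx * fx if pair[0] == pair[1] else 2.0 * fx * fy


def _enumerate_partitions(
    cand: list[list[frozenset[int] | None]],
    mother_sets: list[frozenset[int]],
    k: int,
    cap: int,
) -> tuple[list[list[int]], bool]:
    """All embryo->group partitions into exactly k feasible father groups.

    Restricted-growth DFS with incremental per-group, per-locus feasibility
    (a group is infeasible once no two-allele genotype can serve all its
    embryos at some locus).  Returns (partitions, hit_cap).
    """
    n, L = len(cand), len(mother_sets)
    empty_state = tuple((frozenset(), False) for _ in range(L))
    partitions: list[list[int]] = []
    assign = [0] * n
    hit_cap = False

    def try_add(state, i):
        new = []
        for l in range(L):
            O, amb = state[l]
            c = cand[i][l]
            if c is None:
                new.append((O, amb))
                continue
            if len(c) == 1:
                O = O | c
            else:
                amb = True
            if len(O) > 2:
                return None
            if len(O) == 2 and amb and not (O & mother_sets[l]):
                return None
            new.append((O, amb))
        return tuple(new)

    def rec(i: int, used: int, states: list):
        nonlocal hit_cap
        if hit_cap or len(partitions) >= cap:
            hit_cap = len(partitions) >= cap
            return
        if n - i < k - used:
            return
        if i == n:
            if used == k:
                partitions.append(assign.copy())
            return
        top = min(used + 1, k)
        for g in range(top):
            state = states[g] if g < used else empty_state
            new = try_add(state, i)
            if new is None:
                continue
            assign[i] = g
            if g < used:
                old = states[g]
                states[g] = new
                rec(i + 1, used, states)
                states[g] = old
            else:
                states.append(new)
                rec(i + 1, used + 1, states)
                states.pop()

    rec(0, 0, [])
    return partitions, hit_cap


def _cell_options(
    O: frozenset[int],
    amb: bool,
    mother_set: frozenset[int],
    pool: frozenset[int],
    wild: int,
    freqs: Mapping[int, float],
) -> list[tuple[tuple[int, int], float]]:
    """Consistent father genotypes for one (father, locus) cell with priors."""
    universe = sorted(pool | {wild})
    pairs: set[tuple[int, int]] = set()
    if len(O) == 2:
        pairs.add(tuple(sorted(O)))
    elif len(O) == 1:
        (a,) = O
        for y in universe:
            if amb and not ({a, y} & mother_set):
                continue
            pairs.add(tuple(sorted((a, y))))
    elif amb:
        for x, y in itertools.combinations_with_replacement(universe, 2):
            if {x, y} & mother_set:
                pairs.add((x, y))
    else:  # no constraints at this locus: homozygous completion at the wildcard
        pairs.add((wild, wild))
    return [(p, _hwe_prior(p, freqs)) for p in sorted(pairs)]


def reconstruct_litter(
    litter: Litter,
    freqs: AlleleFrequencies,
    loci: Sequence[LocusDef],
    max_k: int = 4,
    partition_cap: int = 20_000,
    combo_cap: int = 2_000,
) -> SireReconstruction:
    """Exhaustive minimum-sire search with likelihood-ranked solutions.

    Finds the smallest ``k <= max_k`` admitting a Mendel-consistent
    assignment of embryos to ``k`` fathers, then enumerates all father
    genotype solutions at that ``k`` (father alleles restricted to the
    litter's paternal candidates plus a most-frequent-allele wildcard).
    Relative probabilities are HWE priors times transmission probabilities,
    normalized over the full solution space (computed in factorized form,
    so normalization is exact even when the returned list is truncated).
    """
    summary = deduce_paternal_alleles(litter, loci)
    mother = litter.mother
    embryos = [e for e in litter.embryos if e.id not in summary.maternal_mismatch]
    if not embryos:
        raise ValueError(f"litter {mother.id}: no embryos usable for reconstruction")

    used_loci = [
        loc.name
        for loc in loci
        if loc.name in summary.per_locus
        and any(not e.genotype_at(loc.name).missing for e in embryos)
    ]
    if not used_loci:
        raise ValueError(f"litter {mother.id}: no informative loci")

    mother_sets = [frozenset(mother.genotype_at(l).alleles) for l in used_loci]
    cand: list[list[frozenset[int] | None]] = []
    for e in embryos:
        row: list[frozenset[int] | None] = []
        for l in used_loci:
            egt = e.genotype_at(l)
            # missing and single-locus-incompatible embryo-loci impose no
            # constraint on the father search (both map to None)
            row.append(None if egt.missing else paternal_candidates(mother.genotype_at(l), egt))
        cand.append(row)

    # order embryos most-constrained-first for DFS pruning
    order = sorted(
        range(len(embryos)),
        key=lambda i: -sum(1 for c in cand[i] if c is not None and len(c) == 1),
    )
    cand_ord = [cand[i] for i in order]
    ids_ord = [embryos[i].id for i in order]

    pools = [
        frozenset(a for row in cand_ord for c in (row[l],) if c for a in c)
        for l in range(len(used_loci))
    ]
    wilds = [freqs.most_common_allele(l) if l in freqs.freqs else min(mother_sets[i])
             for i, l in enumerate(used_loci)]
    locus_freqs = [freqs.freqs.get(l, {}) for l in used_loci]

    k_lower = max(
        1, max(math.ceil(s.min_count / 2) for s in summary.per_locus.values())
    )
    for k in range(k_lower, min(max_k, len(embryos)) + 1):
        partitions, hit_cap = _enumerate_partitions(cand_ord, mother_sets, k, partition_cap)
        if not partitions:
            continue
        solutions, z_total, truncated = _build_solutions(
            partitions, cand_ord, ids_ord, mother, embryos, order,
            used_loci, mother_sets, pools, wilds, locus_freqs, k, combo_cap,
        )
        for s in solutions:
            s.relative_probability /= z_total
        solutions.sort(key=lambda s: (-s.relative_probability, s.sort_key()))
        return SireReconstruction(
            litter_id=mother.id,
            k=k,
            solutions=solutions,
            excluded_embryos=summary.maternal_mismatch,
            truncated=truncated or hit_cap,
            n_partitions=len(partitions),
        )
    return SireReconstruction(
        litter_id=mother.id,
        k=0,
        solutions=[],
        excluded_embryos=summary.maternal_mismatch,
        unresolved_at=max_k,
    )


def _build_solutions(
    partitions, cand_ord, ids_ord, mother, embryos, order,
    used_loci, mother_sets, pools, wilds, locus_freqs, k, combo_cap,
):
    """Enumerate (partition x father-genotype) solutions with exact total mass."""
    emb_by_id = {e.id: e for e in embryos}
    solutions: list[SireSolution] = []
    z_total = 0.0
    truncated = False
    for part in partitions:
        # per (group, locus) weighted genotype options
        cells: list[list[list[tuple[tuple[int, int], float]]]] = []
        feasible = True
        for g in range(k):
            members = [i for i in range(len(part)) if part[i] == g]
            grow = []
            for l, locus in enumerate(used_loci):
                O: set[int] = set()
                amb = False
                for i in members:
                    c = cand_ord[i][l]
                    if c is None:
                        continue
                    if len(c) == 1:
                        O.update(c)
                    else:
                        amb = True
                opts = _cell_options(
                    frozenset(O), amb, mother_sets[l], pools[l], wilds[l], locus_freqs[l]
                )
                # fold embryo transmission probabilities into the option weight
                mgt = mother.genotype_at(locus)
                weighted = []
                for pair, prior in opts:
                    w = prior
                    for i in members:
                        egt = emb_by_id[ids_ord[i]].genotype_at(locus)
                        if egt.missing:
                            continue
                        w *= _transmission(mgt, pair, egt)
                    if w > 0.0:
                        weighted.append((pair, w))
                if not weighted:
                    feasible = False
                    break
                grow.append(weighted)
            if not feasible:
                break
            cells.append(grow)
        if not feasible:
            continue

        flat = [cell for grow in cells for cell in grow]
        z_part = 1.0
        for cell in flat:
            z_part *= sum(w for _, w in cell)
        z_total += z_part

        n_combos = 1
        for cell in flat:
            n_combos *= len(cell)
        assignment = {ids_ord[i]: part[i] for i in range(len(part))}
        skew = [part.count(g) for g in range(k)]

        def make_solution(choice: tuple[tuple[tuple[int, int], float], ...]) -> SireSolution:
            weight = 1.0
            fathers: list[dict[str, Genotype]] = []
            idx = 0
            for g in range(k):
                fg: dict[str, Genotype] = {}
                for l, locus in enumerate(used_loci):
                    pair, w = choice[idx]
                    idx += 1
                    fg[locus] = Genotype.of(*pair)
                    weight *= w
                fathers.append(fg)
            sol = SireSolution(
                k=k, fathers=fathers, assignment=dict(assignment),
                relative_probability=weight, skew=list(skew),
            )
            _canonicalize(sol)
            return sol

        if n_combos <= combo_cap:
            for choice in itertools.product(*flat):
                solutions.append(make_solution(choice))
        else:
            truncated = True
            best = tuple(max(cell, key=lambda pw: pw[1]) for cell in flat)
            solutions.append(make_solution(best))
    return solutions, z_total, truncated


def _canonicalize(sol: SireSolution) -> None:
    """Order fathers deterministically by genotype; remap assignment/skew."""
    keyed = sorted(
        range(sol.k),
        key=lambda g: tuple(sorted((loc, gt.alleles) for loc, gt in sol.fathers[g].items())),
    )
    remap = {old: new for new, old in enumerate(keyed)}
    sol.fathers = [sol.fathers[g] for g in keyed]
    sol.assignment = {e: remap[g] for e, g in sol.assignment.items()}
    sol.skew = [sol.skew[g] for g in keyed]


def min_sires(
    litter: Litter,
    freqs: AlleleFrequencies,
    loci: Sequence[LocusDef],
    max_k: int = 4,
) -> list[SireSolution]:
    """Best-first list of minimum-sire solutions (see :func:`reconstruct_litter`)."""
    recon = reconstruct_litter(litter, freqs, loci, max_k=max_k)
    if recon.unresolved_at is not None:
        raise UnresolvedPaternityError(
            f"litter {litter.mother.id}: unresolved with k <= {max_k}"
        )
    return recon.solutions


# ---------------------------------------------------------------------------
# Mendelian segregation of paternal alleles (monandrous litters)
# ---------------------------------------------------------------------------


@dataclass
class LocusSegregation:
    locus: str
    count1: int
    count2: int
    chi2: float
    p: float


@dataclass
class FisherCombined:
    chi2: float
    df: int
    p: float
    per_locus: list[LocusSegregation] = field(default_factory=list)


def fisher_combine(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: -2 sum(ln p), chi-square with 2m df."""
    if not p_values:
        raise ValueError("no p-values to combine")
    stat = -2.0 * sum(math.log(p) for p in p_values)
    df = 2 * len(p_values)
    return stat, df, float(chi2_dist.sf(stat, df))


def mendelian_segregation_test(
    litter: Litter, solution: SireSolution
) -> FisherCombined | None:
    """Per-locus 1:1 chi-square on paternal alleles, combined by Fisher's method.

    Applies to single-father solutions only.  Loci where the inferred father
    is homozygous are uninformative and skipped, as are embryos whose
    paternal allele cannot be resolved between the father's two alleles.
    Returns ``None`` when no locus is informative.
    """
    if solution.k != 1:
        raise ValueError("segregation test applies to single-father solutions")
    father = solution.fathers[0]
    per_locus: list[LocusSegregation] = []
    for locus, fgt in father.items():
        if not fgt.is_heterozygous:
            continue
        mgt = litter.mother.genotype_at(locus)
        if mgt.missing:
            continue
        x, y = fgt.alleles
        n1 = n2 = 0
        for emb in litter.embryos:
            egt = emb.genotype_at(locus)
            if egt.missing:
                continue
            c = paternal_candidates(mgt, egt)
            if c is None:
                continue
            resolved = c & {x, y}
            if len(resolved) != 1:
                continue
            if x in resolved:
                n1 += 1
            else:
                n2 += 1
        if n1 + n2 == 0:
            continue
        stat = (n1 - n2) ** 2 / (n1 + n2)
        per_locus.append(
            LocusSegregation(locus, n1, n2, stat, float(chi2_dist.sf(stat, 1)))
        )
    if not per_locus:
        return None
    stat, df, p = fisher_combine([s.p for s in per_locus])
    return FisherCombined(chi2=stat, df=df, p=p, per_locus=per_locus)


# ---------------------------------------------------------------------------
# paternity skew
# ---------------------------------------------------------------------------


@dataclass
class SkewTestResult:
    counts: list[int]
    statistic: float
    p: float
    test_name: str


def skew_test(
    counts: Sequence[int], n_reps: int = 100_000, seed: int | None = None
) -> SkewTestResult:
    """Exact test of equal paternal contributions.

    Two sires: two-sided exact binomial against 1/2.  Three or more: exact
    multinomial against equal proportions (full enumeration for n <= 30,
    Monte Carlo beyond), summing the probability of all tables at most as
    probable as the observed one.
    """
    counts = [int(c) for c in counts]
    k, n = len(counts), sum(counts)
    if k < 2 or n == 0:
        raise ValueError("skew test needs >=2 sires with >=1 embryo")
    if k == 2:
        res = binomtest(counts[0], n, 0.5)
        return SkewTestResult(counts, float(counts[0]), float(res.pvalue), "exact binomial")
    probs = np.full(k, 1.0 / k)
    p_obs = float(multinomial.pmf(counts, n, probs))
    tol = 1e-12
    if n <= 30:
        total = 0.0
        for combo in itertools.combinations(range(n + k - 1), k - 1):
            cuts = (-1,) + combo + (n + k - 1,)
            table = [cuts[i + 1] - cuts[i] - 1 for i in range(k)]
            pm = float(multinomial.pmf(table, n, probs))
            if pm <= p_obs + tol:
                total += pm
        return SkewTestResult(counts, p_obs, min(total, 1.0), "exact multinomial")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_reps)
    pms = multinomial.pmf(draws, n, probs)
    p = (np.sum(pms <= p_obs + tol) + 1) / (n_reps + 1)
    return SkewTestResult(counts, p_obs, float(p), "monte carlo multinomial")


# ---------------------------------------------------------------------------
# per-litter reporting
# ---------------------------------------------------------------------------


def unassigned_embryos(solutions: Sequence[SireSolution], rel_tol: float = 1e-9) -> set[str]:
    """Embryos whose father index differs across equally-best solutions."""
    if not solutions:
        return set()
    best = solutions[0].relative_probability
    tied = [s for s in solutions if s.relative_probability >= best * (1.0 - rel_tol)]
    out: set[str] = set()
    ref = tied[0].assignment
    for s in tied[1:]:
        for emb, g in s.assignment.items():
            if ref.get(emb) != g:
                out.add(emb)
    return out


def litter_report(
    litter: Litter,
    species: str,
    recon: SireReconstruction,
    skew_result: SkewTestResult | None,
    segregation: FisherCombined | None,
    polyandrous: bool,
) -> dict:
    """One summary row per litter (study-report shape)."""
    row: dict = {
        "litter": litter.mother.id,
        "species": species,
        "tl_mm": litter.mother.tl_mm,
        "n_embryos": litter.size,
        "n_excluded": len(recon.excluded_embryos),
        "polyandrous": polyandrous,
        "n_sires": recon.k if recon.solutions else None,
    }
    if recon.solutions:
        best = recon.best
        unassigned = unassigned_embryos(recon.solutions)
        counts = [0] * best.k
        for emb, g in best.assignment.items():
            if emb not in unassigned:
                counts[g] += 1
        row["skew"] = ":".join(str(c) for c in counts) if best.k > 1 else str(sum(counts))
        row["n_unassigned"] = len(unassigned)
        row["best_probability"] = best.relative_probability
    else:
        row["skew"] = ""
        row["n_unassigned"] = 0
        row["best_probability"] = None
    row["skew_p"] = skew_result.p if skew_result else None
    row["segregation_p"] = segregation.p if segregation else None
    return row
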