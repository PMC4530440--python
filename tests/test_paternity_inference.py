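from __future__ import annotations

import numpy as np
import pytest

from litterkin.genotype_model import AlleleFrequencies, Genotype, LocusDef
from litterkin import paternity_inference as pi

from conftest import make_litter
from oracles import (
    brute_force_min_sires,
    naive_min_paternal_count,
    naive_multinomial_skew_p,
)

LOCI3 = [LocusDef("L1"), LocusDef("L2"), LocusDef("L3")]


def flat_freqs(loci, alleles):
    return AlleleFrequencies(
        {l.name: {a: 1.0 / len(alleles) for a in alleles} for l in loci},
        {l.name: 0 for l in loci},
    )


class TestPaternalCandidates:
    def test_obligate_by_exclusion(self):
        c = pi.paternal_candidates(Genotype.of(155, 157), Genotype.of(157, 161))
        assert c == frozenset({161})

    def test_ambiguous_mother_sharing(self):
        c = pi.paternal_candidates(Genotype.of(155, 157), Genotype.of(155, 157))
        assert c == frozenset({155, 157})

    def test_homozygous_embryo_is_obligate(self):
        c = pi.paternal_candidates(Genotype.of(155, 157), Genotype.of(155, 155))
        assert c == frozenset({155})

    def test_incompatible(self):
        assert pi.paternal_candidates(Genotype.of(155, 157), Genotype.of(161, 163)) is None


class TestDeduce:
    def test_three_obligate_alleles(self):
        litter = make_litter(
            {"L1": (155, 157)},
            [{"L1": (157, 161)}, {"L1": (157, 163)}, {"L1": (155, 165)}],
        )
        s = pi.deduce_paternal_alleles(litter, [LocusDef("L1")])
        locus = s.per_locus["L1"]
        assert locus.obligate == frozenset({161, 163, 165})
        assert locus.min_count == 3

    def test_ambiguous_only_min_one(self):
        litter = make_litter({"L1": (155, 157)}, [{"L1": (155, 157)}] * 4)
        s = pi.deduce_paternal_alleles(litter, [LocusDef("L1")])
        assert s.per_locus["L1"].min_count == 1
        assert s.per_locus["L1"].n_ambiguous == 4

    def test_maternal_mismatch_excluded(self):
        litter = make_litter(
            {"L1": (155, 157), "L2": (200, 202)},
            [
                {"L1": (161, 163), "L2": (210, 212)},  # incompatible at both
                {"L1": (155, 161), "L2": (200, 204)},
            ],
        )
        s = pi.deduce_paternal_alleles(litter, LOCI3[:2])
        assert s.maternal_mismatch == ("E1",)
        assert s.per_locus["L1"].obligate == frozenset({161})

    def test_min_count_matches_naive_hitting_set(self, rng):
        alleles = [100, 102, 104, 106]
        for _ in range(200):
            mother = tuple(sorted(rng.choice(alleles, size=2)))
            embryos = []
            for _ in range(rng.integers(2, 6)):
                a = int(rng.choice(mother))
                b = int(rng.choice(alleles))
                embryos.append(tuple(sorted((a, b))))
            litter = make_litter(
                {"L1": mother}, [{"L1": e} for e in embryos]
            )
            s = pi.deduce_paternal_alleles(litter, [LocusDef("L1")])
            assert s.per_locus["L1"].min_count == naive_min_paternal_count(
                mother, embryos
            )


class TestFlagPolyandry:
    def test_two_alleles_everywhere_not_flagged(self):
        litter = make_litter(
            {"L1": (100, 102)}, [{"L1": (100, 104)}, {"L1": (102, 106)}]
        )
        s = pi.deduce_paternal_alleles(litter, [LocusDef("L1")])
        assert not pi.flag_polyandry(s)

    def test_three_obligate_flags(self):
        litter = make_litter(
            {"L1": (100, 102)},
            [{"L1": (100, 104)}, {"L1": (100, 106)}, {"L1": (100, 108)}],
        )
        assert pi.flag_polyandry(pi.deduce_paternal_alleles(litter, [LocusDef("L1")]))

    def test_ambiguity_resolved_conservatively(self):
        # obligate {102, 104} (102 maternal) + mother-sharing embryo: the
        # ambiguous embryo resolves to 102, so the minimum stays 2
        litter = make_litter(
            {"L1": (100, 102)},
            [{"L1": (102, 102)}, {"L1": (100, 104)}, {"L1": (100, 102)}],
        )
        s = pi.deduce_paternal_alleles(litter, [LocusDef("L1")])
        assert s.per_locus["L1"].min_count == 2
        assert not pi.flag_polyandry(s)

    def test_non_maternal_obligate_plus_ambiguous_needs_third(self):
        # ambiguous candidates are the mother's alleles; when no obligate
        # allele is maternal a third paternal allele is unavoidable
        litter = make_litter(
            {"L1": (100, 102)},
            [{"L1": (100, 104)}, {"L1": (100, 106)}, {"L1": (100, 102)}],
        )
        s = pi.deduce_paternal_alleles(litter, [LocusDef("L1")])
        assert s.per_locus["L1"].min_count == 3
        assert pi.flag_polyandry(s)


class TestMinSires:
    def test_single_father_consistent(self):
        litter = make_litter(
            {"L1": (100, 102), "L2": (200, 202)},
            [
                {"L1": (100, 104), "L2": (200, 210)},
                {"L1": (102, 104), "L2": (202, 210)},
            ],
        )
        freqs = flat_freqs(LOCI3[:2], [100, 102, 104, 200, 202, 210])
        recon = pi.reconstruct_litter(litter, freqs, LOCI3[:2])
        assert recon.k == 1
        assert sum(s.relative_probability for s in recon.solutions) == pytest.approx(1.0)

    def test_pigeonhole_five_obligate(self):
        embryos = [{"L1": (100, a)} for a in (104, 106, 108, 110, 112)]
        litter = make_litter({"L1": (100, 102)}, embryos)
        freqs = flat_freqs([LocusDef("L1")], [100, 102, 104, 106, 108, 110, 112])
        recon = pi.reconstruct_litter(litter, freqs, [LocusDef("L1")])
        assert recon.k == 3

    def test_unresolved_flagged(self):
        embryos = [{"L1": (100, a)} for a in (104, 106, 108, 110, 112)]
        litter = make_litter({"L1": (100, 102)}, embryos)
        freqs = flat_freqs([LocusDef("L1")], [100, 102, 104, 106, 108, 110, 112])
        recon = pi.reconstruct_litter(litter, freqs, [LocusDef("L1")], max_k=2)
        assert recon.unresolved_at == 2 and not recon.solutions
        with pytest.raises(pi.UnresolvedPaternityError):
            pi.min_sires(litter, freqs, [LocusDef("L1")], max_k=2)

    def test_lower_bound_and_upper_bound(self, rng):
        freqs = flat_freqs(LOCI3, [100, 102, 104, 106])
        for _ in range(30):
            litter = _random_litter(rng, n_loci=3, n_embryos=int(rng.integers(2, 6)))
            recon = pi.reconstruct_litter(litter, freqs, LOCI3)
            if not recon.solutions:
                continue
            s = pi.deduce_paternal_alleles(litter, LOCI3)
            lower = max(-(-c // 2) for c in s.min_counts.values())
            assert max(1, lower) <= recon.k <= litter.size

    def test_two_sire_toy_matches_brute_force(self):
        # loci engineered to conflict under any single father
        litter = make_litter(
            {"L1": (100, 102), "L2": (200, 202), "L3": (300, 302)},
            [
                {"L1": (100, 104), "L2": (200, 210), "L3": (300, 304)},
                {"L1": (100, 106), "L2": (200, 212), "L3": (300, 304)},
                {"L1": (102, 108), "L2": (202, 210), "L3": (302, 306)},
                {"L1": (100, 104), "L2": (200, 212), "L3": (300, 306)},
            ],
        )
        freqs = AlleleFrequencies(
            {
                "L1": {100: 0.3, 102: 0.2, 104: 0.2, 106: 0.2, 108: 0.1},
                "L2": {200: 0.4, 202: 0.2, 210: 0.2, 212: 0.2},
                "L3": {300: 0.35, 302: 0.25, 304: 0.25, 306: 0.15},
            },
            {"L1": 0, "L2": 0, "L3": 0},
        )
        recon = pi.reconstruct_litter(litter, freqs, LOCI3)
        k_oracle, oracle_sols = brute_force_min_sires(
            litter, freqs, ["L1", "L2", "L3"]
        )
        assert recon.k == k_oracle == 2
        impl = _impl_solution_dict(litter, recon)
        orc = _oracle_solution_dict(litter, oracle_sols)
        assert set(impl) == set(orc)
        for key in impl:
            assert impl[key] == pytest.approx(orc[key], abs=1e-9)

    def test_oracle_equivalence_random_small_litters(self, rng):
        freqs = flat_freqs(LOCI3[:2], [100, 102, 104, 106])
        loci = LOCI3[:2]
        checked = 0
        for _ in range(40):
            litter = _random_litter(rng, n_loci=2, n_embryos=int(rng.integers(2, 5)))
            recon = pi.reconstruct_litter(litter, freqs, loci)
            k_oracle, oracle_sols = brute_force_min_sires(
                litter, freqs, [l.name for l in loci]
            )
            assert recon.k == (k_oracle or 0)
            if not recon.solutions:
                continue
            impl = _impl_solution_dict(litter, recon)
            orc = _oracle_solution_dict(litter, oracle_sols)
            assert set(impl) == set(orc)
            for key in impl:
                assert impl[key] == pytest.approx(orc[key], abs=1e-9)
            checked += 1
        assert checked >= 30


def _random_litter(rng, n_loci: int, n_embryos: int):
    """Random Mendelian litter from 1-3 true fathers over a 4-allele panel."""
    alleles = [100, 102, 104, 106]
    k_true = int(rng.integers(1, 4))
    mother = {f"L{i+1}": tuple(sorted(rng.choice(alleles, 2))) for i in range(n_loci)}
    fathers = [
        {f"L{i+1}": tuple(sorted(rng.choice(alleles, 2))) for i in range(n_loci)}
        for _ in range(k_true)
    ]
    embryos = []
    for _ in range(n_embryos):
        f = fathers[int(rng.integers(k_true))]
        g = {}
        for loc in mother:
            a = mother[loc][int(rng.integers(2))]
            b = f[loc][int(rng.integers(2))]
            g[loc] = tuple(sorted((int(a), int(b))))
        embryos.append(g)
    # shift allele values per locus so loci are distinguishable
    shifted_m = {loc: tuple(a + 100 * i for a in g)
                 for i, (loc, g) in enumerate(sorted(mother.items()))}
    shifted_e = [
        {loc: tuple(a + 100 * i for a in g)
         for i, (loc, g) in enumerate(sorted(e.items()))}
        for e in embryos
    ]
    return make_litter(shifted_m, shifted_e)


def _impl_solution_dict(litter, recon):
    out = {}
    for sol in recon.solutions:
        key = tuple(
            sorted(
                (
                    tuple(sorted((loc, gt.alleles) for loc, gt in father.items())),
                    tuple(sorted(e for e, g in sol.assignment.items() if g == gi)),
                )
                for gi, father in enumerate(sol.fathers)
            )
        )
        out[key] = out.get(key, 0.0) + sol.relative_probability
    return out


def _oracle_solution_dict(litter, oracle_sols):
    ids = [e.id for e in litter.embryos]
    out = {}
    for (genos, assign), p in oracle_sols.items():
        key = tuple(
            sorted(
                (
                    genos[g],
                    tuple(sorted(ids[i] for i in range(len(ids)) if assign[i] == g)),
                )
                for g in range(len(genos))
            )
        )
        out[key] = out.get(key, 0.0) + p
    return out


class TestMendelianSegregation:
    def test_fisher_seven_half_pvalues(self):
        stat, df, p = pi.fisher_combine([0.5] * 7)
        assert stat == pytest.approx(-14 * np.log(0.5), abs=1e-9)
        assert df == 14
        assert p == pytest.approx(0.7835, abs=5e-4)

    def test_balanced_counts_give_p1(self):
        litter = make_litter(
            {"L1": (100, 102)},
            [{"L1": (100, 104)}] * 5 + [{"L1": (100, 106)}] * 5,
        )
        freqs = flat_freqs([LocusDef("L1")], [100, 102, 104, 106])
        recon = pi.reconstruct_litter(litter, freqs, [LocusDef("L1")])
        assert recon.k == 1
        res = pi.mendelian_segregation_test(litter, recon.best)
        (loc,) = res.per_locus
        assert {loc.count1, loc.count2} == {5}
        assert loc.chi2 == 0.0 and loc.p == 1.0

    def test_df_is_twice_informative_loci(self, rng):
        loci = [LocusDef(f"L{i+1}") for i in range(7)]
        base = 100
        mother_gts, embryo_template = {}, []
        father = {}
        for i, loc in enumerate(loci):
            lo = base + 100 * i
            mother_gts[loc.name] = (lo, lo)  # homozygous mother
            father[loc.name] = (lo + 4, lo + 6)  # heterozygous father
        embryos = []
        for j in range(10):
            g = {}
            for i, loc in enumerate(loci):
                lo = base + 100 * i
                g[loc.name] = tuple(sorted((lo, father[loc.name][j % 2])))
            embryos.append(g)
        litter = make_litter(mother_gts, embryos)
        freqs = AlleleFrequencies(
            {loc.name: {base + 100 * i + d: 0.25 for d in (0, 2, 4, 6)}
             for i, loc in enumerate(loci)},
            {loc.name: 0 for loc in loci},
        )
        recon = pi.reconstruct_litter(litter, freqs, loci)
        assert recon.k == 1
        res = pi.mendelian_segregation_test(litter, recon.best)
        assert res.df == 14

    def test_no_informative_locus_returns_none(self):
        litter = make_litter({"L1": (100, 102)}, [{"L1": (100, 104)}] * 4)
        freqs = flat_freqs([LocusDef("L1")], [100, 102, 104])
        recon = pi.reconstruct_litter(litter, freqs, [LocusDef("L1")])
        best_homo = [s for s in recon.solutions if not s.fathers[0]["L1"].is_heterozygous]
        assert pi.mendelian_segregation_test(litter, best_homo[0]) is None


class TestSkewTest:
    def test_symmetric_three_three(self):
        assert pi.skew_test([3, 3]).p == 1.0

    def test_seventeen_one_binomial_tail(self):
        res = pi.skew_test([17, 1])
        assert res.p == pytest.approx(2 * 19 / 2**18, rel=1e-9)
        assert res.test_name == "exact binomial"

    def test_multinomial_enumeration_matches_oracle(self):
        res = pi.skew_test([4, 3, 2])
        assert res.test_name == "exact multinomial"
        assert res.p == pytest.approx(naive_multinomial_skew_p([4, 3, 2]), abs=1e-9)
        assert res.p > 0.5

    def test_multinomial_extreme(self):
        res = pi.skew_test([12, 1, 1])
        assert res.p == pytest.approx(naive_multinomial_skew_p([12, 1, 1]), abs=1e-9)
        assert res.p < 0.01

    def test_monte_carlo_branch(self):
        res = pi.skew_test([20, 10, 10], n_reps=20_000, seed=9)
        assert res.test_name == "monte carlo multinomial"
        assert 0 < res.p <= 1

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            pi.skew_test([5])


class TestLitterReport:
    def test_monandrous_row(self):
        litter = make_litter({"L1": (100, 102)}, [{"L1": (100, 104)}] * 3)
        freqs = flat_freqs([LocusDef("L1")], [100, 102, 104])
        recon = pi.reconstruct_litter(litter, freqs, [LocusDef("L1")])
        row = pi.litter_report(litter, "A", recon, None, None, False)
        assert row["n_sires"] == 1 and row["skew"] == "3"
        assert row["polyandrous"] is False

    def test_bookkeeping_on_simulated_study(self, rng):
        from litterkin.synthetic_data import (
            SimulationConfig,
            SpeciesSimConfig,
            default_allele_frequencies,
            default_loci,
            simulate_study,
        )
        from litterkin.genotype_model import build_litters

        cfg = SimulationConfig(
            seed=77,
            species={"A": SpeciesSimConfig(n_adults=5, n_litters=10,
                                           litter_size_range=(3, 8))},
        )
        inds, truth = simulate_study(cfg)
        litters = build_litters(inds)
        freqs = default_allele_frequencies("A")
        loci = default_loci("A")
        rows = []
        for litter in litters:
            s = pi.deduce_paternal_alleles(litter, loci)
            recon = pi.reconstruct_litter(litter, freqs, loci)
            rows.append(pi.litter_report(litter, "A", recon, None, None,
                                         pi.flag_polyandry(s)))
        assert len(rows) == 10
        assert sum(r["n_embryos"] for r in rows) == sum(
            t["n_embryos"] for t in truth["litters"].values()
        )
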