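"""Monte-Carlo power to detect multiple paternity (PrDM-style).

Each replicate draws a mother and the scenario's sires from Hardy-Weinberg
proportions at the panel allele frequencies, produces a litter by Mendelian
transmission with sires sampled according to the skew, and applies the same
detection rule used on real data: three or more minimal paternal alleles at
one or more loci.  Detection is therefore impossible on loci with fewer
than three alleles, and an all-diallelic panel gives exactly zero power.

The per-locus minimal paternal allele count has a closed form (see
``paternity_inference``), which lets the whole simulation run vectorized on
allele bitmasks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_model import AlleleFrequencies, Genotype

__all__ = ["PowerScenario", "PowerEstimate", "prdm", "power_table", "DEFAULT_SCENARIOS"]

#: the four canonical sire-number/skew scenarios
DEFAULT_SCENARIOS: tuple[tuple[str, int, tuple[float, ...]], ...] = (
    ("2 males (50:50)", 2, (0.5, 0.5)),
    ("2 males (66.7:33.3)", 2, (0.667, 0.333)),
    ("3 males (33.3:33.3:33.3)", 3, (1 / 3, 1 / 3, 1 / 3)),
    ("3 males (57:28.5:14.5)", 3, (0.57, 0.285, 0.145)),
)


@dataclass
class PowerScenario:
    n_sires: int
    skew: tuple[float, ...]
    litter_size: int
    freqs: AlleleFrequencies
    mother: Mapping[str, Genotype] | None = None  # fixed mother genotype, optional

    def __post_init__(self) -> None:
        if self.n_sires < 2:
            raise ValueError("power scenarios need >=2 sires")
        if len(self.skew) != self.n_sires:
            raise ValueError("skew length must equal n_sires")
        if abs(sum(self.skew) - 1.0) > 1e-6 or any(not 0 < s < 1 for s in self.skew):
            raise ValueError("skew proportions must lie in (0,1) and sum to 1")
        if self.litter_size < 1:
            raise ValueError("litter_size must be >= 1")


@dataclass
class PowerEstimate:
    p_detect: float
    mc_se: float
    n_reps: int
    seed: int | None
    flag: str = ""


def _popcount(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x)


def _draw_alleles(rng, probs: np.ndarray, shape) -> np.ndarray:
    return rng.choice(len(probs), size=shape, p=probs)


def prdm(
    scenario: PowerScenario, n_reps: int = 10_000, seed: int | None = None
) -> PowerEstimate:
    """Probability of detecting multiple paternity under a mating scenario.

    When ``scenario.mother`` is set, that multilocus genotype is held fixed
    across replicates (per-litter detection power conditional on the
    observed mother); otherwise mothers are drawn from HWE like the sires.
    """
    rng = np.random.default_rng(seed)
    loci = [l for l in scenario.freqs.loci if len(scenario.freqs.for_locus(l)) >= 3]
    flag = ""
    if not loci:
        warnings.warn("no locus with >=3 alleles: detection power is exactly 0")
        return PowerEstimate(0.0, 0.0, n_reps, seed, flag="no_informative_locus")

    L = scenario.litter_size
    skew = np.asarray(scenario.skew, dtype=float)
    skew = skew / skew.sum()
    # embryo -> sire assignment is shared across loci within a replicate
    sire_idx = rng.choice(scenario.n_sires, size=(n_reps, L), p=skew)
    detected = np.zeros(n_reps, dtype=bool)

    for locus in loci:
        todo = ~detected  # short-circuit replicates already detected
        m = int(todo.sum())
        if m == 0:
            break
        fdict = scenario.freqs.for_locus(locus)
        alleles = np.array(sorted(fdict))
        probs = np.array([fdict[a] for a in sorted(fdict)])
        probs = probs / probs.sum()
        n_all = len(alleles)
        if n_all > 30:
            raise ValueError(f"locus {locus}: too many alleles for bitmask simulation")
        bit = (np.uint64(1) << np.arange(n_all, dtype=np.uint64))

        if scenario.mother is not None:
            mgt = scenario.mother.get(locus)
            if mgt is None or mgt.missing:
                continue
            idx = {a: i for i, a in enumerate(alleles)}
            if mgt.allele1 not in idx or mgt.allele2 not in idx:
                # maternal allele unseen in the reference: extend the code space
                extra = [a for a in mgt.alleles if a not in idx]
                for a in sorted(set(extra)):
                    idx[a] = len(idx)
                if len(idx) > 60:
                    raise ValueError(f"locus {locus}: allele space too large")
                bit = (np.uint64(1) << np.arange(len(idx), dtype=np.uint64))
            mom = np.tile(np.array([[idx[mgt.allele1], idx[mgt.allele2]]]), (m, 1))
        else:
            mom = _draw_alleles(rng, probs, (m, 2))

        dads = _draw_alleles(rng, probs, (m, scenario.n_sires, 2))
        mat_pick = rng.integers(0, 2, size=(m, L))
        pat_pick = rng.integers(0, 2, size=(m, L))
        e_mat = np.take_along_axis(mom, mat_pick, axis=1)  # (m, L)
        rows = np.arange(m)[:, None]
        sires = sire_idx[todo]
        e_pat = dads[rows, sires, pat_pick]  # (m, L)

        mom_mask = bit[mom[:, 0]] | bit[mom[:, 1]]  # (m,)
        pat_in_mom = (bit[e_pat] & mom_mask[:, None]) != 0
        same = e_mat == e_pat
        # obligate paternal allele: paternal allele not carried by the mother,
        # or embryo homozygous; otherwise the embryo is ambiguous
        obligate = np.where(
            ~pat_in_mom | same, bit[e_pat], np.uint64(0)
        )
        amb = pat_in_mom & ~same
        O = np.bitwise_or.reduce(obligate, axis=1)
        count = _popcount(O) + ((amb.any(axis=1)) & ((O & mom_mask) == 0))
        detected[todo] |= count >= 3

    p = float(detected.mean())
    return PowerEstimate(
        p_detect=p,
        mc_se=float(np.sqrt(p * (1.0 - p) / n_reps)),
        n_reps=n_reps,
        seed=seed,
        flag=flag,
    )


def power_table(
    freqs: AlleleFrequencies,
    litter_sizes: Sequence[int],
    scenarios: Sequence[tuple[str, int, tuple[float, ...]]] = DEFAULT_SCENARIOS,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Scenario x litter-size matrix of detection percentages."""
    rows = {}
    for si, (name, n_sires, skew) in enumerate(scenarios):
        row = {}
        for li, size in enumerate(litter_sizes):
            est = prdm(
                PowerScenario(n_sires, tuple(skew), size, freqs),
                n_reps=n_reps,
                seed=None if seed is None else seed + 1000 * si + li,
            )
            row[size] = 100.0 * est.p_detect
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
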