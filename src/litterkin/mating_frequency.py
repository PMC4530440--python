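"""Bayesian estimation of the population frequency of multiple mating.

Observed per-litter detection outcomes are corrected for per-litter
detection power ``d_i`` (the probability that a truly multiply-sired litter
of that size, under that mother's genotype, would have been flagged).  With
multiple-mating frequency ``f`` the likelihood of litter ``i`` is
``f * d_i`` when detected and ``1 - f * d_i`` when not; the posterior is
evaluated on a fixed grid with a uniform prior by default, so the mode is
essentially a maximum-likelihood estimate.  The 95% interval is central
(equal-tailed), not HPD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .detection_power import PowerScenario, prdm
from .genotype_model import AlleleFrequencies, Genotype, Litter

__all__ = ["FMMResult", "litter_detection_power", "fmm_estimate"]


@dataclass
class FMMResult:
    grid: np.ndarray
    posterior: np.ndarray
    mode: float
    ci95: tuple[float, float]
    per_litter_power: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = float(self.posterior.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior sums to {total}, not 1")
        if self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 low > high")


def litter_detection_power(
    litter: Litter | None,
    freqs: AlleleFrequencies,
    n_sires: int = 2,
    skew: Sequence[float] | None = None,
    litter_size: int | None = None,
    mother_genotypes: Mapping[str, Genotype] | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Detection power ``d_i`` conditional on the observed mother genotype.

    The alternative being powered against defaults to two sires with equal
    contribution (the modal observed pattern); fathers are drawn from HWE at
    the reference frequencies while the mother stays fixed.
    """
    if litter is not None:
        mother_genotypes = litter.mother.genotypes
        litter_size = litter.size
    if litter_size is None or mother_genotypes is None:
        raise ValueError("need either a litter or explicit mother genotypes + size")
    skew = tuple(skew) if skew is not None else tuple([1.0 / n_sires] * n_sires)
    scenario = PowerScenario(
        n_sires=n_sires,
        skew=skew,
        litter_size=litter_size,
        freqs=freqs,
        mother=mother_genotypes,
    )
    return prdm(scenario, n_reps=n_reps, seed=seed).p_detect


def fmm_estimate(
    detections: Sequence[bool],
    powers: Sequence[float],
    prior: Callable[[np.ndarray], np.ndarray] | None = None,
    grid_step: float = 0.001,
) -> FMMResult:
    """Grid posterior over the frequency of multiple mating.

    ``detections[i]`` is whether litter ``i`` was flagged polyandrous and
    ``powers[i]`` its detection power ``d_i``.  A detected litter with
    ``d_i = 0`` is inconsistent input and raises.
    """
    detections = [bool(d) for d in detections]
    powers = [float(p) for p in powers]
    if len(detections) != len(powers):
        raise ValueError("detections and powers must have the same length")
    for i, (det, d) in enumerate(zip(detections, powers)):
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"power d_{i} = {d} outside [0, 1]")
        if det and d == 0.0:
            raise ValueError(f"litter {i} detected but has detection power 0")

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    with np.errstate(divide="ignore"):
        loglik = np.zeros_like(grid)
        for det, d in zip(detections, powers):
            if det:
                loglik += np.log(grid * d)
            else:
                loglik += np.log1p(-grid * d)
    logpost = loglik + (np.log(prior(grid)) if prior is not None else 0.0)
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()

    mode = float(grid[int(np.argmax(post))])
    cum = np.cumsum(post)
    low = float(grid[int(np.searchsorted(cum, 0.025))])
    high = float(grid[int(np.searchsorted(cum, 0.975))])
    return FMMResult(grid=grid, posterior=post, mode=mode, ci95=(low, high),
                     per_litter_power=powers)
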