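"""Forward simulation of two-species microsatellite studies.

Generates adult reference panels, mothers and multi-sire litters with
configurable polyandry frequency, sire counts and paternal skew, plus
optional F1-hybrid embryos, under an error-free Mendelian model (no
mutation or genotyping error by default).  The default locus panel mirrors
the shapes seen in real smooth-hound data: a 6-locus diagnostic panel with
two fixed loci, and 7 polymorphic loci per species (5 shared, 2 private to
each species) with allele counts from 2 to 13 and heterozygosities from
~0.02 to ~0.85.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .genotype_model import (
    AlleleFrequencies,
    Genotype,
    Individual,
    Litter,
    LocusDef,
    write_genotype_table,
)
from .reference import load_default_panel

__all__ = [
    "SpeciesSimConfig",
    "SimulationConfig",
    "default_allele_frequencies",
    "default_loci",
    "simulate_adults",
    "simulate_litter",
    "simulate_study",
]

# ---------------------------------------------------------------------------
# default panel: allele frequencies per species
# ---------------------------------------------------------------------------

# polymorphic loci; values are allele_bp -> frequency
_POLY_A: dict[str, dict[int, float]] = {
    "MaD2X": {150: 0.50, 154: 0.20, 158: 0.15, 162: 0.10, 166: 0.05},
    "McaB5": {121: 0.30, 125: 0.20, 129: 0.12, 133: 0.10, 137: 0.08,
              141: 0.07, 145: 0.05, 149: 0.05, 153: 0.03},
    "McaB35": {200: 0.30, 204: 0.15, 208: 0.10, 212: 0.08, 216: 0.07,
               220: 0.06, 224: 0.05, 228: 0.05, 232: 0.04, 236: 0.04,
               240: 0.03, 244: 0.02, 248: 0.01},
    "Mh9": {173: 0.55, 175: 0.30, 177: 0.15},
    "Mh25": {140: 0.88, 142: 0.05, 144: 0.03, 146: 0.02, 148: 0.01, 150: 0.01},
    "Gg22": {88: 0.35, 92: 0.15, 96: 0.10, 100: 0.08, 104: 0.07, 108: 0.06,
             112: 0.05, 116: 0.04, 120: 0.04, 124: 0.03, 128: 0.02, 132: 0.01},
    "MaFYP": {230: 0.62, 234: 0.20, 238: 0.10, 242: 0.05, 246: 0.03},
}
_POLY_B: dict[str, dict[int, float]] = {
    "MaD2X": {150: 0.62, 154: 0.24, 158: 0.14},
    "McaB5": {121: 0.9915, 125: 0.0085},
    "McaB35": {200: 0.82, 204: 0.12, 208: 0.06},
    "Mh9": {173: 0.62, 175: 0.25, 177: 0.13},
    "Mh25": {140: 0.48, 142: 0.27, 144: 0.15, 146: 0.10},
    "MaND5": {310: 0.47, 314: 0.24, 318: 0.15, 322: 0.09, 326: 0.05},
    "Mh29": {188: 0.52, 190: 0.25, 192: 0.15, 194: 0.08},
}
# diagnostic loci drawn within each species' own allele set
_DIAG_A: dict[str, dict[int, float]] = {
    "Gg4": {198: 1.0},
    "Gg20": {280: 1.0},
    "MaTJ5": {159: 1.0},
    "Mca33": {194: 0.5, 200: 0.5},
    "McaB26": {224: 0.5, 229: 0.5},
    "Mh1": {203: 1.0},
}
_DIAG_B: dict[str, dict[int, float]] = {
    "Gg4": {199: 1.0},
    "Gg20": {281: 0.7, 282: 0.3},
    "MaTJ5": {157: 1.0},
    "Mca33": {197: 1.0},
    "McaB26": {224: 1.0},
    "Mh1": {201: 0.9, 205: 0.1},
}

_PRIVATE = {"Gg22": "A", "MaFYP": "A", "MaND5": "B", "Mh29": "B"}


def default_allele_frequencies(species: str, include_diagnostic: bool = True) -> AlleleFrequencies:
    """Generating allele frequencies for one species of the default panel."""
    if species == "A":
        freqs = dict(_POLY_A)
        diag = _DIAG_A
    elif species == "B":
        freqs = dict(_POLY_B)
        diag = _DIAG_B
    else:
        raise ValueError(f"unknown species {species!r}")
    if include_diagnostic:
        freqs = {**freqs, **diag}
    return AlleleFrequencies(
        {k: dict(v) for k, v in freqs.items()}, {k: 0 for k in freqs}
    )


def default_loci(species: str | None = None) -> list[LocusDef]:
    """Locus definitions for the default panel (union of both species)."""
    names = list(_DIAG_A) + sorted(set(_POLY_A) | set(_POLY_B))
    out = []
    for name in names:
        scope = "both"
        if name in _PRIVATE:
            scope = "species_A_only" if _PRIVATE[name] == "A" else "species_B_only"
        out.append(LocusDef(name=name, repeat_size=2, amplifies_in=scope))
    if species == "A":
        out = [l for l in out if l.amplifies_in != "species_B_only"]
    elif species == "B":
        out = [l for l in out if l.amplifies_in != "species_A_only"]
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SpeciesSimConfig:
    n_adults: int = 60
    n_litters: int = 10
    polyandry_freq: float = 0.5
    tl_range: tuple[float, float] = (1210.0, 1630.0)
    litter_size_range: tuple[int, int] = (3, 18)
    sire_count_probs: dict[int, float] = field(default_factory=lambda: {2: 0.9, 3: 0.1})
    skew: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: {2: (0.5, 0.5), 3: (1 / 3, 1 / 3, 1 / 3)}
    )
    size_follows_tl: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.polyandry_freq <= 1.0:
            raise ValueError("polyandry_freq must be in [0, 1]")
        total = sum(self.sire_count_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("sire_count_probs must sum to 1")


@dataclass
class SimulationConfig:
    seed: int = 0
    species: dict[str, SpeciesSimConfig] = field(
        default_factory=lambda: {
            "A": SpeciesSimConfig(),
            "B": SpeciesSimConfig(
                tl_range=(1100.0, 1410.0), litter_size_range=(9, 35)
            ),
        }
    )
    #: list of (species, litter_index, n_hybrid_embryos)
    hybrid_litters: list[tuple[str, int, int]] = field(default_factory=list)
    error_rate: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        species = {}
        for label, sub in (raw.get("species") or {}).items():
            sub = dict(sub)
            for key in ("tl_range", "litter_size_range"):
                if key in sub:
                    sub[key] = tuple(sub[key])
            if "sire_count_probs" in sub:
                sub["sire_count_probs"] = {int(k): float(v) for k, v in sub["sire_count_probs"].items()}
            if "skew" in sub:
                sub["skew"] = {int(k): tuple(v) for k, v in sub["skew"].items()}
            species[str(label)] = SpeciesSimConfig(**sub)
        cfg = cls(seed=int(raw.get("seed", 0)))
        if species:
            cfg.species = species
        cfg.hybrid_litters = [tuple(h) for h in raw.get("hybrid_litters", [])]
        cfg.error_rate = float(raw.get("error_rate", 0.0))
        return cfg


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def _draw_genotypes(rng: np.random.Generator, freqs: AlleleFrequencies) -> dict[str, Genotype]:
    out = {}
    for locus in freqs.loci:
        f = freqs.for_locus(locus)
        alleles = sorted(f)
        p = np.array([f[a] for a in alleles])
        p = p / p.sum()
        a, b = rng.choice(alleles, size=2, p=p)
        out[locus] = Genotype.of(int(a), int(b))
    return out


def simulate_adults(
    rng: np.random.Generator,
    species: str,
    n: int,
    freqs: AlleleFrequencies | None = None,
    id_prefix: str = "",
    role: str = "adult",
) -> list[Individual]:
    """Adults drawn locus-by-locus from HWE at the configured frequencies."""
    freqs = freqs or default_allele_frequencies(species)
    prefix = id_prefix or f"{species}AD"
    return [
        Individual(
            id=f"{prefix}{i + 1}",
            role=role,
            species_hint=species,
            genotypes=_draw_genotypes(rng, freqs),
        )
        for i in range(n)
    ]


def simulate_litter(
    rng: np.random.Generator,
    mother: Individual,
    fathers: Sequence[Mapping[str, Genotype]],
    skew: Sequence[float],
    n: int,
    id_prefix: str | None = None,
) -> tuple[Litter, list[int]]:
    """Mendelian litter: each embryo samples a father by skew, then one
    allele from each parent per locus.  Returns the litter and the true
    per-embryo father indices."""
    skew = np.asarray(skew, dtype=float)
    if abs(skew.sum() - 1.0) > 1e-9:
        raise ValueError("skew must sum to 1")
    prefix = id_prefix or f"{mother.id}_e"
    sires = rng.choice(len(fathers), size=n, p=skew)
    embryos = []
    for j in range(n):
        father = fathers[sires[j]]
        genotypes = {}
        for locus, mgt in mother.genotypes.items():
            fgt = father.get(locus)
            if mgt.missing or fgt is None or fgt.missing:
                continue
            a = mgt.alleles[rng.integers(0, 2)]
            b = fgt.alleles[rng.integers(0, 2)]
            genotypes[locus] = Genotype.of(a, b)
        embryos.append(
            Individual(
                id=f"{prefix}{j + 1}",
                role="embryo",
                mother_id=mother.id,
                genotypes=genotypes,
            )
        )
    return Litter(mother, embryos), [int(s) for s in sires]


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[Individual], dict]:
    """Simulate a full two-species study with ground-truth sidecar.

    Returns all individuals (adults + mothers + embryos) and a truth dict
    with per-litter true sire counts, per-embryo sire assignments, hybrid
    embryo ids and the generating polyandry frequencies.  When ``out_dir``
    is given, writes ``genotypes.tsv`` and ``truth.json`` there.
    """
    rng = np.random.default_rng(config.seed)
    individuals: list[Individual] = []
    truth: dict = {"seed": config.seed, "species": {}, "litters": {}, "hybrids": []}
    hybrid_spec = {(sp, idx): nh for sp, idx, nh in config.hybrid_litters}

    for sp, sim in config.species.items():
        freqs = default_allele_frequencies(sp)
        other = "B" if sp == "A" else "A"
        other_freqs = default_allele_frequencies(other)
        individuals.extend(simulate_adults(rng, sp, sim.n_adults))
        truth["species"][sp] = {
            "polyandry_freq": sim.polyandry_freq,
            "n_litters": sim.n_litters,
        }
        lo_tl, hi_tl = sim.tl_range
        lo_sz, hi_sz = sim.litter_size_range
        for li in range(sim.n_litters):
            tl = float(rng.uniform(lo_tl, hi_tl))
            if sim.size_follows_tl and hi_tl > lo_tl:
                frac = (tl - lo_tl) / (hi_tl - lo_tl)
                mean_size = lo_sz + frac * (hi_sz - lo_sz)
                size = int(np.clip(round(mean_size + rng.normal(0, 0.1 * (hi_sz - lo_sz + 1))), lo_sz, hi_sz))
            else:
                size = int(rng.integers(lo_sz, hi_sz + 1))
            mother = Individual(
                id=f"{sp}M{li + 1}",
                role="mother",
                species_hint=sp,
                tl_mm=tl,
                genotypes=_draw_genotypes(rng, freqs),
            )
            polyandrous = bool(rng.random() < sim.polyandry_freq)
            if polyandrous:
                ks = sorted(sim.sire_count_probs)
                k = int(rng.choice(ks, p=[sim.sire_count_probs[x] for x in ks]))
            else:
                k = 1
            fathers = [_draw_genotypes(rng, freqs) for _ in range(k)]
            skew = sim.skew.get(k, tuple([1.0 / k] * k)) if k > 1 else (1.0,)
            litter, sires = simulate_litter(rng, mother, fathers, skew, size)

            n_hyb = hybrid_spec.get((sp, li), 0)
            if n_hyb:
                hyb_father = _draw_genotypes(rng, other_freqs)
                hyb_ids = []
                for emb in litter.embryos[:n_hyb]:
                    genotypes = {}
                    for locus, mgt in mother.genotypes.items():
                        fgt = hyb_father.get(locus)
                        if fgt is None or fgt.missing:
                            continue
                        a = mgt.alleles[rng.integers(0, 2)]
                        b = fgt.alleles[rng.integers(0, 2)]
                        genotypes[locus] = Genotype.of(a, b)
                    emb.genotypes = genotypes
                    hyb_ids.append(emb.id)
                truth["hybrids"].extend(hyb_ids)

            individuals.append(mother)
            individuals.extend(litter.embryos)
            truth["litters"][mother.id] = {
                "species": sp,
                "tl_mm": tl,
                "n_embryos": size,
                "true_sires": k,
                "polyandrous": polyandrous,
                "sire_of": {e.id: s for e, s in zip(litter.embryos, sires)},
            }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotype_table(individuals, default_loci(), out / "genotypes.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return individuals, truth
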