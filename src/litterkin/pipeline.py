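"""End-to-end study pipeline: identify -> popgen -> paternity -> power -> fmm.

Species are analysed separately after diagnosis.  Hybrid and
mother-incompatible embryos are excluded from paternity inference but kept
in the calls table.  Per-species allele frequencies are estimated from
classified adults only.  All randomness flows from one root seed, split
per stage via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import fecundity_and_summary as fs
from . import mating_frequency as mf
from . import paternity_inference as pi
from . import popgen_stats as pg
from .detection_power import power_table
from .genotype_model import (
    AlleleFrequencies,
    Individual,
    LocusDef,
    build_litters,
    estimate_allele_frequencies,
)
from .species_diagnosis import (
    DiagnosticRule,
    FamilyFlag,
    SpeciesCall,
    check_family_consistency,
    classify_all,
)

log = logging.getLogger("litterkin")

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    max_k: int = 4
    power_reps: int = 2_000
    fmm_power_reps: int = 2_000
    hwe_reps: int = 2_000
    run_popgen: bool = True
    run_power: bool = False
    power_litter_sizes: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"A": (3, 9, 15, 18), "B": (9, 18, 27, 35)}
    )


@dataclass
class StudyReport:
    calls: pd.DataFrame
    family_flags: list[FamilyFlag]
    popgen: dict[str, pd.DataFrame]
    litters: pd.DataFrame
    species_summaries: dict[str, fs.SpeciesSummary]
    fmm: dict[str, mf.FMMResult]
    power: dict[str, pd.DataFrame]
    ancova: dict[str, fs.AncovaResult]
    freqs: dict[str, AlleleFrequencies]
    reconstructions: dict[str, pi.SireReconstruction]
    seed: int = 0

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.calls.to_csv(out / "species_calls.tsv", sep="\t", index=False)
        self.litters.to_csv(out / "litter_report.tsv", sep="\t", index=False)
        for sp, df in self.popgen.items():
            df.to_csv(out / f"popgen_{sp}.tsv", sep="\t", index=False)
        for sp, df in self.power.items():
            df.to_csv(out / f"power_{sp}.tsv", sep="\t")
        summary = {
            "seed": self.seed,
            "species": {
                sp: vars(s) for sp, s in self.species_summaries.items()
            },
            "fmm": {
                sp: {
                    "mode": r.mode,
                    "ci95": list(r.ci95),
                    "per_litter_power": r.per_litter_power,
                }
                for sp, r in self.fmm.items()
            },
            "ancova": {
                sp: {"F": a.F, "p": a.p, "df": {k: list(v) for k, v in a.df.items()}, "n": a.n}
                for sp, a in self.ancova.items()
            },
            "family_flags": [vars(f) for f in self.family_flags],
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))


def _calls_frame(calls: dict[str, SpeciesCall], individuals: Sequence[Individual]) -> pd.DataFrame:
    roles = {i.id: i.role for i in individuals}
    return pd.DataFrame(
        {
            "sample_id": [c.individual_id for c in calls.values()],
            "role": [roles[c.individual_id] for c in calls.values()],
            "label": [c.label for c in calls.values()],
            "n_informative": [c.n_informative for c in calls.values()],
            "hint_conflict": [c.hint_conflict for c in calls.values()],
        }
    )


def run_pipeline(
    individuals: Sequence[Individual],
    panel: Sequence[DiagnosticRule],
    loci: Sequence[LocusDef],
    config: PipelineConfig | None = None,
) -> StudyReport:
    """Run the full analysis on a set of individuals.

    ``loci`` is the paternity panel (polymorphic loci); species-private loci
    are selected per species via their ``amplifies_in`` scope.
    """
    config = config or PipelineConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0]) for s in seeds]

    log.info("stage 1: species identification (%d individuals)", len(individuals))
    calls = classify_all(individuals, panel)
    litters = build_litters(individuals)
    flags: list[FamilyFlag] = []
    for litter in litters:
        flags.extend(check_family_consistency(litter, calls))
    hybrid_ids = {f.embryo_id for f in flags if f.kind == "hybrid_offspring"}
    conflict_ids = {f.embryo_id for f in flags if f.kind == "identity_conflict"}

    by_species_loci = {
        "A": [l for l in loci if l.amplifies_in in ("both", "species_A_only")],
        "B": [l for l in loci if l.amplifies_in in ("both", "species_B_only")],
    }
    adults = {
        sp: [
            i for i in individuals
            if i.role == "adult" and calls[i.id].label == sp
        ]
        for sp in ("A", "B")
    }
    freqs: dict[str, AlleleFrequencies] = {}
    popgen: dict[str, pd.DataFrame] = {}
    for sp in ("A", "B"):
        if not adults[sp]:
            continue
        freqs[sp] = estimate_allele_frequencies(adults[sp], by_species_loci[sp])
        if config.run_popgen:
            log.info("stage 2: popgen summaries, species %s (n=%d)", sp, len(adults[sp]))
            summaries = pg.summarize_panel(
                adults[sp], by_species_loci[sp],
                n_reps=config.hwe_reps, seed=stage_seed[0],
            )
            popgen[sp] = pd.DataFrame([vars(s) for s in summaries])

    log.info("stage 3: paternity inference (%d litters)", len(litters))
    rows = []
    recons: dict[str, pi.SireReconstruction] = {}
    detections: dict[str, list[bool]] = {"A": [], "B": []}
    powers: dict[str, list[float]] = {"A": [], "B": []}
    fmm_rng = np.random.default_rng(stage_seed[1])
    for litter in litters:
        sp = calls[litter.mother.id].label
        if sp not in freqs:
            log.warning("litter %s: mother label %s has no reference adults, skipped",
                        litter.mother.id, sp)
            continue
        keep = [
            e for e in litter.embryos
            if e.id not in hybrid_ids and e.id not in conflict_ids
        ]
        if not keep:
            continue
        if len(keep) < litter.size:
            log.info("litter %s: %d embryo(s) excluded after species check",
                     litter.mother.id, litter.size - len(keep))
        sub = type(litter)(litter.mother, keep)
        sp_loci = by_species_loci[sp]
        summary = pi.deduce_paternal_alleles(sub, sp_loci)
        polyandrous = pi.flag_polyandry(summary)
        recon = pi.reconstruct_litter(sub, freqs[sp], sp_loci, max_k=config.max_k)
        recons[litter.mother.id] = recon
        skew_res = seg_res = None
        if recon.solutions:
            if recon.k >= 2:
                best = recon.best
                unassigned = pi.unassigned_embryos(recon.solutions)
                counts = [0] * best.k
                for emb, g in best.assignment.items():
                    if emb not in unassigned:
                        counts[g] += 1
                if all(c > 0 for c in counts):
                    skew_res = pi.skew_test(counts, seed=stage_seed[2])
            else:
                seg_res = pi.mendelian_segregation_test(sub, recon.best)
        rows.append(pi.litter_report(sub, sp, recon, skew_res, seg_res, polyandrous))
        detections[sp].append(polyandrous)
        powers[sp].append(
            mf.litter_detection_power(
                sub, freqs[sp], n_reps=config.fmm_power_reps,
                seed=int(fmm_rng.integers(2**31)),
            )
        )
    litter_df = pd.DataFrame(rows)

    log.info("stage 4: study summaries")
    species_summaries: dict[str, fs.SpeciesSummary] = {}
    ancova: dict[str, fs.AncovaResult] = {}
    fmm_results: dict[str, mf.FMMResult] = {}
    for sp in ("A", "B"):
        sub = litter_df[litter_df["species"] == sp] if len(litter_df) else litter_df
        if len(sub) == 0:
            continue
        species_summaries[sp] = fs.summarize_species(sub, species=sp)
        try:
            ancova[sp] = fs.fecundity_ancova(sub)
        except ValueError:
            pass
        det, pw = detections[sp], powers[sp]
        if det:
            try:
                fmm_results[sp] = mf.fmm_estimate(det, pw)
            except ValueError as exc:
                log.warning("fmm skipped for species %s: %s", sp, exc)

    power: dict[str, pd.DataFrame] = {}
    if config.run_power:
        log.info("stage 5: detection power tables")
        for sp, f in freqs.items():
            sizes = config.power_litter_sizes.get(sp, (3, 9, 15, 18))
            power[sp] = power_table(
                f, sizes, n_reps=config.power_reps, seed=stage_seed[3]
            )

    return StudyReport(
        calls=_calls_frame(calls, individuals),
        family_flags=flags,
        popgen=popgen,
        litters=litter_df,
        species_summaries=species_summaries,
        fmm=fmm_results,
        power=power,
        ancova=ancova,
        freqs=freqs,
        reconstructions=recons,
        seed=config.seed,
    )
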