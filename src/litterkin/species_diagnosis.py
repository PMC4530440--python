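"""Species and F1-hybrid calls from a panel of diagnostic microsatellite loci.

Each diagnostic locus carries species-specific allele sets.  Loci are
``fixed`` (one allele per species), ``non_overlapping`` (disjoint allele
sets) or ``overlapping`` (shared alleles).  A pure call requires all
informative per-locus votes to agree; an F1 hybrid call requires a mixed
(one-allele-per-species) genotype at BOTH fixed loci and no non-overlapping
locus voting pure.  Overlapping loci vote for a species only through their
private alleles and never participate in hybrid calls.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genotype_model import Individual, Litter

__all__ = [
    "DiagnosticRule",
    "SpeciesCall",
    "FamilyFlag",
    "classify_individual",
    "classify_all",
    "check_family_consistency",
    "read_panel_file",
    "write_calls_table",
]

STATUSES = ("fixed", "non_overlapping", "overlapping")


@dataclass(frozen=True)
class DiagnosticRule:
    """Species-specific allele sets at one diagnostic locus."""

    locus: str
    alleles_A: frozenset[int]
    alleles_B: frozenset[int]
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}")
        overlap = self.alleles_A & self.alleles_B
        if self.status == "fixed" and not (
            len(self.alleles_A) == len(self.alleles_B) == 1 and not overlap
        ):
            raise ValueError(f"{self.locus}: fixed locus needs one private allele per species")
        if self.status == "non_overlapping" and overlap:
            raise ValueError(f"{self.locus}: non_overlapping locus has shared alleles {overlap}")
        if self.status == "overlapping" and not overlap:
            raise ValueError(f"{self.locus}: overlapping status but allele sets are disjoint")

    @property
    def private_A(self) -> frozenset[int]:
        return self.alleles_A - self.alleles_B

    @property
    def private_B(self) -> frozenset[int]:
        return self.alleles_B - self.alleles_A


@dataclass
class SpeciesCall:
    """Classification outcome for one individual."""

    individual_id: str
    label: str  # A | B | hybrid | ambiguous
    per_locus_votes: dict[str, str] = field(default_factory=dict)
    n_informative: int = 0
    hint_conflict: bool = False


def _vote(rule: DiagnosticRule, a1: int, a2: int) -> str:
    """Per-locus vote: A, B, mixed, or uninformative."""
    if rule.status == "overlapping":
        # private alleles may still support a pure call; shared alleles say
        # nothing, and an overlapping locus never votes "mixed"
        has_a = a1 in rule.private_A or a2 in rule.private_A
        has_b = a1 in rule.private_B or a2 in rule.private_B
        if has_a and not has_b:
            return "A"
        if has_b and not has_a:
            return "B"
        return "uninformative"
    in_a1, in_a2 = a1 in rule.alleles_A, a2 in rule.alleles_A
    in_b1, in_b2 = a1 in rule.alleles_B, a2 in rule.alleles_B
    if in_a1 and in_a2:
        return "A"
    if in_b1 and in_b2:
        return "B"
    if (in_a1 and in_b2) or (in_b1 and in_a2):
        return "mixed"
    return "uninformative"  # allele unknown to the panel


def classify_individual(ind: Individual, panel: Sequence[DiagnosticRule]) -> SpeciesCall:
    """Classify one individual from its diagnostic-locus genotypes."""
    votes: dict[str, str] = {}
    for rule in panel:
        gt = ind.genotype_at(rule.locus)
        if gt.missing:
            votes[rule.locus] = "missing"
        else:
            votes[rule.locus] = _vote(rule, gt.allele1, gt.allele2)

    informative = {loc: v for loc, v in votes.items() if v in ("A", "B", "mixed")}
    n_inf = len(informative)
    fixed_loci = [r.locus for r in panel if r.status == "fixed"]
    non_overlap = [r.locus for r in panel if r.status in ("fixed", "non_overlapping")]

    label = "ambiguous"
    if n_inf >= 1:
        vals = set(informative.values())
        if vals == {"A"}:
            label = "A"
        elif vals == {"B"}:
            label = "B"
        elif (
            fixed_loci
            and all(votes.get(loc) == "mixed" for loc in fixed_loci)
            and not any(votes.get(loc) in ("A", "B") for loc in non_overlap)
        ):
            label = "hybrid"

    hint_conflict = bool(
        ind.species_hint and label in ("A", "B") and ind.species_hint != label
    )
    return SpeciesCall(ind.id, label, votes, n_inf, hint_conflict)


def classify_all(
    individuals: Iterable[Individual], panel: Sequence[DiagnosticRule]
) -> dict[str, SpeciesCall]:
    return {ind.id: classify_individual(ind, panel) for ind in individuals}


@dataclass(frozen=True)
class FamilyFlag:
    embryo_id: str
    mother_id: str
    kind: str  # hybrid_offspring | identity_conflict
    detail: str = ""


def check_family_consistency(
    litter: Litter, calls: dict[str, SpeciesCall]
) -> list[FamilyFlag]:
    """Flag embryos whose species call conflicts with the mother's.

    A hybrid embryo under a pure mother is the expected cross-species mating
    signature (``hybrid_offspring``); two different pure labels are a hard
    inconsistency (``identity_conflict``).
    """
    flags: list[FamilyFlag] = []
    mcall = calls[litter.mother.id]
    if mcall.label not in ("A", "B"):
        return flags
    for emb in litter.embryos:
        ecall = calls[emb.id]
        if ecall.label == "hybrid":
            flags.append(
                FamilyFlag(emb.id, litter.mother.id, "hybrid_offspring",
                           f"hybrid embryo under pure-{mcall.label} mother")
            )
        elif ecall.label in ("A", "B") and ecall.label != mcall.label:
            flags.append(
                FamilyFlag(emb.id, litter.mother.id, "identity_conflict",
                           f"embryo called {ecall.label}, mother {mcall.label}")
            )
    return flags


# ---------------------------------------------------------------------------
# panel file IO
# ---------------------------------------------------------------------------


def read_panel_file(path: str | Path) -> list[DiagnosticRule]:
    """Read a diagnostic panel TSV: locus, A alleles (;-sep), B alleles, status."""
    rules = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rules.append(
                DiagnosticRule(
                    locus=row["locus"],
                    alleles_A=frozenset(int(a) for a in row["species_A_alleles"].split(";")),
                    alleles_B=frozenset(int(a) for a in row["species_B_alleles"].split(";")),
                    status=row["status"],
                )
            )
    return rules


def write_calls_table(calls: dict[str, SpeciesCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tlabel\tn_informative\thint_conflict\tvotes\n")
        for call in calls.values():
            votestr = ";".join(f"{k}={v}" for k, v in call.per_locus_votes.items())
            fh.write(
                f"{call.individual_id}\t{call.label}\t{call.n_informative}"
                f"\t{int(call.hint_conflict)}\t{votestr}\n"
            )
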