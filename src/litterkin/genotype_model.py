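"""Core data types for microsatellite genotypes, individuals and litters.

Alleles are pre-binned integer fragment sizes in base pairs; 0 encodes a
missing allele.  Genotypes are diploid and unordered — they are stored in
canonical order ``allele1 <= allele2``.  A locus that does not amplify in a
species is simply missing for every member of that species and is excluded
from that species' computations (it is never treated as a null allele).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LocusDef",
    "Genotype",
    "MISSING",
    "Individual",
    "Litter",
    "AlleleFrequencies",
    "GenotypeTableError",
    "read_genotype_table",
    "write_genotype_table",
    "build_litters",
    "estimate_allele_frequencies",
    "write_genepop",
    "read_genepop",
]

#: amplification scopes for a locus
AMPLIFIES = ("both", "species_A_only", "species_B_only")


class GenotypeTableError(ValueError):
    """Raised on malformed genotype tables or inconsistent family links."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: name, repeat unit size, amplification scope."""

    name: str
    repeat_size: int = 2
    amplifies_in: str = "both"

    def __post_init__(self) -> None:
        if self.repeat_size < 1:
            raise ValueError(f"repeat_size must be >= 1, got {self.repeat_size}")
        if self.amplifies_in not in AMPLIFIES:
            raise ValueError(f"amplifies_in must be one of {AMPLIFIES}")


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype in canonical allele order (``allele1 <= allele2``)."""

    allele1: int
    allele2: int

    @classmethod
    def of(cls, a: int, b: int) -> "Genotype":
        a, b = int(a), int(b)
        if (a == 0) != (b == 0):
            raise ValueError(f"half-missing genotype {a}/{b} not allowed")
        if a < 0 or b < 0:
            raise ValueError(f"negative allele in {a}/{b}")
        if a > b:
            a, b = b, a
        return cls(a, b)

    @property
    def missing(self) -> bool:
        return self.allele1 == 0

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele1, self.allele2)

    @property
    def is_heterozygous(self) -> bool:
        return not self.missing and self.allele1 != self.allele2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.allele1}/{self.allele2}"


MISSING = Genotype(0, 0)

ROLES = ("mother", "embryo", "adult")


@dataclass
class Individual:
    """One sampled animal with its multilocus genotype.

    ``species_hint`` is an optional externally supplied species label (it
    stands in for an independent mtDNA assay call); the nuclear classifier
    never lets it override the multilocus call.
    """

    id: str
    role: str
    mother_id: str | None = None
    species_hint: str | None = None
    tl_mm: float | None = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "embryo" and not self.mother_id:
            raise ValueError(f"embryo {self.id!r} lacks a mother_id")
        if self.tl_mm is not None and not (100 <= self.tl_mm <= 3000):
            raise ValueError(f"tl_mm {self.tl_mm} outside plausible range 100-3000")

    def genotype_at(self, locus: str) -> Genotype:
        return self.genotypes.get(locus, MISSING)


@dataclass
class Litter:
    """A mother and her embryos."""

    mother: Individual
    embryos: list[Individual]

    def __post_init__(self) -> None:
        if not self.embryos:
            raise ValueError(f"litter of {self.mother.id} has no embryos")
        bad = [e.id for e in self.embryos if e.mother_id != self.mother.id]
        if bad:
            raise ValueError(f"embryos {bad} do not reference mother {self.mother.id}")

    @property
    def size(self) -> int:
        return len(self.embryos)


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequency estimates with per-locus sample sizes."""

    freqs: dict[str, dict[int, float]]
    sample_size: dict[str, int]

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")
            if any(p <= 0 for p in f.values()):
                raise ValueError(f"non-positive frequency at {locus}")

    def for_locus(self, locus: str) -> dict[int, float]:
        return self.freqs[locus]

    def most_common_allele(self, locus: str) -> int:
        f = self.freqs[locus]
        return max(sorted(f), key=lambda a: f[a])

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)


# ---------------------------------------------------------------------------
# genotype table IO
# ---------------------------------------------------------------------------

_META_COLUMNS = ("sample_id", "role", "mother_id", "species_hint", "tl_mm", "site", "date")


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_genotype_table(path: str | Path, panel: Sequence[LocusDef]) -> list[Individual]:
    """Read a rectangular genotype table into :class:`Individual` records.

    The table has columns ``sample_id, role, mother_id, species_hint, tl_mm,
    site, date`` followed by two allele columns ``<LOCUS>_1, <LOCUS>_2`` per
    locus; 0 or blank encodes a missing allele.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeTableError(f"genotype table not found: {path}")
    known = {loc.name for loc in panel}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        header = reader.fieldnames or []
        locus_cols: dict[str, tuple[str, str]] = {}
        for col in header:
            if col in _META_COLUMNS:
                continue
            if col.endswith("_1") or col.endswith("_2"):
                stem = col[:-2]
                if stem not in known:
                    raise GenotypeTableError(
                        f"column {col!r} refers to locus {stem!r} not in the panel"
                    )
                locus_cols.setdefault(stem, ("", ""))
            else:
                raise GenotypeTableError(f"unrecognized column {col!r}")
        for stem in locus_cols:
            if f"{stem}_1" not in header or f"{stem}_2" not in header:
                raise GenotypeTableError(f"locus {stem!r} lacks paired _1/_2 columns")

        individuals: list[Individual] = []
        for row in reader:
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                continue
            genotypes: dict[str, Genotype] = {}
            for stem in locus_cols:
                raw1 = (row.get(f"{stem}_1") or "").strip() or "0"
                raw2 = (row.get(f"{stem}_2") or "").strip() or "0"
                try:
                    a, b = int(raw1), int(raw2)
                except ValueError as exc:
                    raise GenotypeTableError(
                        f"non-integer allele {raw1!r}/{raw2!r} at locus {stem} "
                        f"for sample {sid}"
                    ) from exc
                gt = Genotype.of(a, b)
                if not gt.missing:
                    genotypes[stem] = gt
            tl_raw = (row.get("tl_mm") or "").strip()
            meta = {k: (row.get(k) or "").strip() for k in ("site", "date") if row.get(k)}
            individuals.append(
                Individual(
                    id=sid,
                    role=(row.get("role") or "").strip(),
                    mother_id=(row.get("mother_id") or "").strip() or None,
                    species_hint=(row.get("species_hint") or "").strip() or None,
                    tl_mm=float(tl_raw) if tl_raw else None,
                    genotypes=genotypes,
                    metadata=meta,
                )
            )
    return individuals


def write_genotype_table(
    individuals: Iterable[Individual], panel: Sequence[LocusDef], path: str | Path
) -> None:
    """Write individuals to the standard table format (inverse of the reader)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    loci = [loc.name for loc in panel]
    header = list(_META_COLUMNS) + [f"{n}_{i}" for n in loci for i in (1, 2)]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(header)
        for ind in individuals:
            row = [
                ind.id,
                ind.role,
                ind.mother_id or "",
                ind.species_hint or "",
                "" if ind.tl_mm is None else f"{ind.tl_mm:g}",
                ind.metadata.get("site", ""),
                ind.metadata.get("date", ""),
            ]
            for name in loci:
                gt = ind.genotype_at(name)
                row.extend([gt.allele1, gt.allele2])
            writer.writerow(row)


def build_litters(individuals: Sequence[Individual]) -> list[Litter]:
    """Group embryos under their mothers; one litter per mother with embryos.

    Raises on embryos whose ``mother_id`` does not resolve to a mother-role
    individual.
    """
    mothers = {ind.id: ind for ind in individuals if ind.role == "mother"}
    by_role = {ind.id: ind.role for ind in individuals}
    orphans: list[str] = []
    members: dict[str, list[Individual]] = {}
    for ind in individuals:
        if ind.role != "embryo":
            continue
        mid = ind.mother_id
        if mid not in by_role:
            orphans.append(f"{ind.id} -> {mid}")
            continue
        if mid not in mothers:
            raise GenotypeTableError(
                f"embryo {ind.id} points to {mid!r}, whose role is {by_role[mid]!r}, "
                "not 'mother'"
            )
        members.setdefault(mid, []).append(ind)
    if orphans:
        raise GenotypeTableError(f"embryos with unknown mother_id: {orphans}")
    return [Litter(mothers[mid], embs) for mid, embs in members.items()]


def estimate_allele_frequencies(
    adults: Sequence[Individual], loci: Sequence[LocusDef]
) -> AlleleFrequencies:
    """Allele frequencies by direct count over non-missing genotypes.

    frequency = allele count / (2 x non-missing individuals) per locus.
    Loci with no data are dropped with a warning.
    """
    freqs: dict[str, dict[int, float]] = {}
    sizes: dict[str, int] = {}
    for loc in loci:
        counts: dict[int, int] = {}
        n = 0
        for ind in adults:
            gt = ind.genotype_at(loc.name)
            if gt.missing:
                continue
            n += 1
            for a in gt.alleles:
                counts[a] = counts.get(a, 0) + 1
        if n == 0:
            warnings.warn(f"locus {loc.name}: no genotyped individuals, excluded")
            continue
        freqs[loc.name] = {a: c / (2 * n) for a, c in sorted(counts.items())}
        sizes[loc.name] = n
    return AlleleFrequencies(freqs, sizes)


# ---------------------------------------------------------------------------
# GenePop export / import
# ---------------------------------------------------------------------------


def write_genepop(
    individuals: Sequence[Individual],
    loci: Sequence[LocusDef],
    path: str | Path,
    group_by: str = "species_hint",
) -> dict[str, dict[int, int]]:
    """Write a GenePop 4.x text file with 3-digit allele codes.

    Alleles are recoded per locus to 001..999 in ascending size order; the
    allele->code map is returned and also written next to the file as
    ``<path>.alleles.tsv``.  One ``Pop`` block per distinct group label.
    """
    path = Path(path)
    code_map: dict[str, dict[int, int]] = {}
    for loc in loci:
        alleles = sorted(
            {
                a
                for ind in individuals
                for a in ind.genotype_at(loc.name).alleles
                if a > 0
            }
        )
        if len(alleles) > 999:
            raise GenotypeTableError(f"locus {loc.name}: >999 distinct alleles")
        code_map[loc.name] = {a: i + 1 for i, a in enumerate(alleles)}

    groups: dict[str, list[Individual]] = {}
    for ind in individuals:
        key = getattr(ind, group_by, None) or ind.species_hint or "all"
        groups.setdefault(str(key), []).append(ind)

    with path.open("w") as fh:
        fh.write("litterkin genepop export\n")
        for loc in loci:
            fh.write(f"{loc.name}\n")
        for label in sorted(groups):
            fh.write("Pop\n")
            for ind in groups[label]:
                codes = []
                for loc in loci:
                    gt = ind.genotype_at(loc.name)
                    if gt.missing:
                        codes.append("000000")
                    else:
                        c1 = code_map[loc.name][gt.allele1]
                        c2 = code_map[loc.name][gt.allele2]
                        codes.append(f"{c1:03d}{c2:03d}")
                fh.write(f"{ind.id} ,  " + " ".join(codes) + "\n")

    with Path(str(path) + ".alleles.tsv").open("w") as fh:
        fh.write("locus\tallele_bp\tcode\n")
        for loc in loci:
            for a, c in code_map[loc.name].items():
                fh.write(f"{loc.name}\t{a}\t{c:03d}\n")
    return code_map


def read_genepop(path: str | Path, code_map: Mapping[str, Mapping[int, int]]) -> list[Individual]:
    """Parse a GenePop file written by :func:`write_genepop` (round-trip aid)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    decode = {
        locus: {c: a for a, c in mapping.items()} for locus, mapping in code_map.items()
    }
    individuals: list[Individual] = []
    pop_idx = -1
    for line in lines[i:]:
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            continue
        name, rest = line.split(",", 1)
        fields = rest.split()
        genotypes: dict[str, Genotype] = {}
        for locus, fieldv in zip(loci, fields):
            c1, c2 = int(fieldv[:3]), int(fieldv[3:])
            if c1 == 0 or c2 == 0:
                continue
            genotypes[locus] = Genotype.of(decode[locus][c1], decode[locus][c2])
        individuals.append(Individual(id=name.strip(), role="adult", genotypes=genotypes))
    return individuals
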