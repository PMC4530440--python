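from __future__ import annotations

import numpy as np
import pytest

from litterkin.genotype_model import Genotype, Individual, Litter, LocusDef
from litterkin.reference import load_default_panel


def make_ind(
    ident: str,
    role: str = "adult",
    gts: dict[str, tuple[int, int]] | None = None,
    mother_id: str | None = None,
    **kw,
) -> Individual:
    genotypes = {loc: Genotype.of(a, b) for loc, (a, b) in (gts or {}).items()}
    return Individual(id=ident, role=role, mother_id=mother_id, genotypes=genotypes, **kw)


def make_litter(
    mother_gts: dict[str, tuple[int, int]],
    embryo_gts: list[dict[str, tuple[int, int]]],
    mother_id: str = "M1",
) -> Litter:
    mother = make_ind(mother_id, "mother", mother_gts)
    embryos = [
        make_ind(f"E{i + 1}", "embryo", g, mother_id=mother_id)
        for i, g in enumerate(embryo_gts)
    ]
    return Litter(mother, embryos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def diag_panel():
    return load_default_panel()


@pytest.fixture
def toy_loci():
    return [LocusDef(f"L{i + 1}", repeat_size=2) for i in range(3)]
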