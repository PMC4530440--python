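"""Study-level statistics: fecundity ANCOVA and per-species paternity summaries."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["AncovaResult", "SpeciesSummary", "fecundity_ancova", "summarize_species"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class AncovaResult:
    terms: list[str]
    F: dict[str, float]
    p: dict[str, float]
    df: dict[str, tuple[float, float]]
    n: int


@dataclass
class SpeciesSummary:
    species: str
    n_litters: int
    n_polyandrous: int
    polyandry_pct: int
    mean_sires: float | None
    mean_top_share_pct: int | None
    sd_top_share_pct: int | None
    max_sires: int | None


def fecundity_ancova(litters: pd.DataFrame) -> AncovaResult:
    """Type-II ANCOVA of litter size on female length and mating system.

    ``litters`` needs columns ``tl_mm``, ``n_embryos`` and boolean
    ``polyandrous``.  With a single mating-system level present, falls back
    to the covariate-only model with a warning.
    """
    df = litters.dropna(subset=["tl_mm", "n_embryos"]).copy()
    if len(df) < 5:
        raise ValueError(f"need >=5 litters for the ANCOVA, got {len(df)}")
    df["polyandrous"] = df["polyandrous"].astype(bool)
    levels = df["polyandrous"].nunique()
    if levels < 2:
        warnings.warn("single mating-system level: fitting covariate-only model")
        model = smf.ols("n_embryos ~ tl_mm", data=df).fit()
    else:
        model = smf.ols("n_embryos ~ tl_mm + C(polyandrous)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    terms, F, p, dfs = [], {}, {}, {}
    for term in table.index:
        if term == "Residual":
            continue
        name = "mating_system" if term.startswith("C(polyandrous") else "female_size"
        terms.append(name)
        F[name] = float(table.loc[term, "F"])
        p[name] = float(table.loc[term, "PR(>F)"])
        dfs[name] = (float(table.loc[term, "df"]), resid_df)
    return AncovaResult(terms=terms, F=F, p=p, df=dfs, n=len(df))


def summarize_species(rows: pd.DataFrame, species: str = "") -> SpeciesSummary:
    """Per-species paternity summary from litter-report rows.

    Expects one row per litter with ``n_sires`` (1 for monandrous) and, for
    polyandrous litters, a ``skew`` string of per-sire embryo counts
    (``"8:2"``).  Top-sire shares use assigned-embryo denominators (the sum
    of the skew counts, not the full litter size) and each litter's share is
    rounded to a whole percent before averaging, matching how such study
    tables are conventionally reported.
    """
    if len(rows) == 0:
        raise ValueError("no litters to summarize")
    n_litters = len(rows)
    poly = rows[rows["n_sires"] >= 2]
    n_poly = len(poly)
    if n_poly == 0:
        return SpeciesSummary(species, n_litters, 0, 0, None, None, None,
                              int(rows["n_sires"].max()) if n_litters else None)
    mean_sires = _round_half_up(10.0 * float(poly["n_sires"].mean())) / 10.0
    shares = []
    for skew in poly["skew"]:
        counts = [int(c) for c in str(skew).split(":")]
        shares.append(_round_half_up(100.0 * max(counts) / sum(counts)))
    mean_share = _round_half_up(float(np.mean(shares)))
    sd_share = _round_half_up(float(np.std(shares, ddof=1))) if len(shares) > 1 else None
    return SpeciesSummary(
        species=species,
        n_litters=n_litters,
        n_polyandrous=n_poly,
        polyandry_pct=_round_half_up(100.0 * n_poly / n_litters),
        mean_sires=mean_sires,
        mean_top_share_pct=mean_share,
        sd_top_share_pct=sd_share,
        max_sires=int(rows["n_sires"].max()),
    )
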