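"""Loaders for the bundled reference dataset.

The package ships two small transcribed summary tables from the original
smooth-hound study this pipeline mirrors — the 32 sampled litters (maternal
total length and litter size) and the 16 polyandrous litters (minimum sire
number and paternal skew) — plus the default 6-locus diagnostic panel.
Species labels are ``A`` (*M. mustelus*) and ``B`` (*M. punctulatus*).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .species_diagnosis import DiagnosticRule, read_panel_file

__all__ = [
    "load_default_panel",
    "load_study_litters",
    "load_polyandrous_litters",
    "parse_skew",
]


def _data_path(name: str):
    return resources.files("litterkin.data").joinpath(name)


def load_default_panel() -> list[DiagnosticRule]:
    """The default diagnostic panel (6 loci, 2 fixed between species)."""
    with resources.as_file(_data_path("diagnostic_panel.tsv")) as p:
        return read_panel_file(p)


def load_study_litters() -> pd.DataFrame:
    """All 32 sampled litters: species, mother id, TL (mm), litter size."""
    with resources.as_file(_data_path("study_litters.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_polyandrous_litters() -> pd.DataFrame:
    """The 16 polyandrous litters with minimum sire count and skew string."""
    with resources.as_file(_data_path("polyandrous_litters.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def parse_skew(skew: str) -> list[int]:
    """Parse a per-sire embryo-count string like ``'8:2'`` or ``'4:3:2'``."""
    counts = [int(x) for x in str(skew).split(":")]
    if any(c < 0 for c in counts) or not counts:
        raise ValueError(f"bad skew string {skew!r}")
    return counts
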