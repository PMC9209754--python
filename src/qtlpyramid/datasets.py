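"""Loaders for the packaged rice stigma-exsertion fixtures.

The genotype matrix (11 SER QTLs x 31 pyramiding lines plus the HJX74
control) and the published group-level summaries are transcribed from the
study's main text; per-line raw phenotypes were never deposited, so the
per-locus single-QTL effects shipped here are a synthetic reconstruction
(see the file header of ``synthetic_single_effects.csv``).
"""

from __future__ import annotations

from collections import OrderedDict
from importlib import resources

import pandas as pd

from .genotype_data import GenotypePanel, read_genotype_table, read_qtl_metadata

__all__ = [
    "load_table1_panel",
    "load_qtl_metadata",
    "load_synthetic_single_effects",
    "load_group_summaries",
    "load_group_epistasis",
    "load_focal_summaries",
]

_DATA = resources.files("qtlpyramid") / "data"


def _path(name: str):
    return _DATA / name


def load_qtl_metadata() -> dict:
    """The 11 SER QTLs with donor species and linked-segment annotations."""
    with resources.as_file(_path("qtl_metadata.tsv")) as p:
        return read_qtl_metadata(p)


def load_table1_panel() -> GenotypePanel:
    """The published line x QTL matrix: control + 31 lines (29 pyramids and
    two 2-QTL single-segment lines, A35 and A88)."""
    meta = load_qtl_metadata()
    with resources.as_file(_path("table1_genotypes.csv")) as p:
        return read_genotype_table(p, metadata=meta)


def load_synthetic_single_effects() -> "OrderedDict[str, float]":
    """Reconstructed (synthetic) per-locus additive effects, %.

    Solved to match every published aggregate (grand mean 18.9, level means
    16.2/20.8/26.4, donor means 16.6/17.1/24.3); not measured values.
    """
    df = pd.read_csv(_path("synthetic_single_effects.csv"), comment="#")
    return OrderedDict(zip(df["locus"], df["additive_effect"].astype(float)))


def load_group_summaries() -> pd.DataFrame:
    """Published group mean SER (%, with ranges): control, 1QL..6QL."""
    return pd.read_csv(_path("group_summaries.csv"), comment="#")


def load_group_epistasis() -> pd.DataFrame:
    """Published per-group mean epistasis (%, with ranges and stars)."""
    return pd.read_csv(_path("group_epistasis.csv"), comment="#")


def load_focal_summaries() -> pd.DataFrame:
    """Published with/without qSER3a-sat subgroup means (i and SER) for the
    2-4 QTL groups."""
    return pd.read_csv(_path("focal_qser3a_summaries.csv"), comment="#")
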