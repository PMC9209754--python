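"""With/without contrasts for a focal QTL and focal epistasis attribution.

Within a pyramid group (say the 3-QTL lines), lines either carry the focal
locus or not.  Comparing the two subgroups' mean epistasis isolates how
much of a pyramid's interaction deficit travels with the focal locus; the
focal-free subgroup's per-QTL epistasis stands in for the non-focal loci,
so the focal locus is credited with

    i_focal = mean_i(with) - (n - 1) * mean_i(without) / n

for a group of n-QTL pyramids.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genotype_data import GenotypePanel, split_by_focal_locus
from .effect_estimation import EpistasisEstimate

__all__ = ["FocalContrast", "focal_contrast", "attribute_focal_epistasis", "focal_contrast_table"]


@dataclass
class FocalContrast:
    """Subgroup summary for one pyramid group split on a focal locus."""

    group: str
    focal: str
    with_n: int
    without_n: int
    with_mean_i: float
    without_mean_i: float
    with_mean_ser: float
    without_mean_ser: float
    t: float = float("nan")  # Welch t on line-level i values
    p: float = float("nan")
    attribution_possible: bool = True

    @property
    def group_mean_i(self) -> float:
        """Count-weighted reconstruction of the whole group's mean i."""
        return (
            self.with_n * self.with_mean_i + self.without_n * self.without_mean_i
        ) / (self.with_n + self.without_n)

    @property
    def group_mean_ser(self) -> float:
        return (
            self.with_n * self.with_mean_ser + self.without_n * self.without_mean_ser
        ) / (self.with_n + self.without_n)


def focal_contrast(
    panel: GenotypePanel,
    estimates: Sequence[EpistasisEstimate],
    records,
    focal: str,
    group: str,
) -> FocalContrast:
    """Contrast lines with vs without ``focal`` inside one pyramid group.

    Uses line-level epistasis estimates and line-level SER means; subgroup
    difference in i is tested with a Welch two-sample t when both subgroups
    have >= 2 lines.  An empty subgroup yields a contrast flagged as not
    supporting attribution.
    """
    from .phenotype_summary import season_means

    with_lines, without_lines = split_by_focal_locus(panel, focal, [group])[group]
    est_by_id = {e.line_id: e for e in estimates}
    wide = season_means(records)

    def subgroup(lines):
        ids = [ln.line_id for ln in lines]
        ivals = np.array([est_by_id[i].i for i in ids if i in est_by_id])
        ser = np.array([wide.loc[i].mean() for i in ids if i in wide.index])
        return ivals, ser

    wi, wser = subgroup(with_lines)
    oi, oser = subgroup(without_lines)
    t = p = float("nan")
    if wi.size >= 2 and oi.size >= 2:
        t, p = stats.ttest_ind(wi, oi, equal_var=False)
        t, p = float(t), float(p)
    return FocalContrast(
        group=group,
        focal=focal,
        with_n=int(wi.size),
        without_n=int(oi.size),
        with_mean_i=float(wi.mean()) if wi.size else float("nan"),
        without_mean_i=float(oi.mean()) if oi.size else float("nan"),
        with_mean_ser=float(wser.mean()) if wser.size else float("nan"),
        without_mean_ser=float(oser.mean()) if oser.size else float("nan"),
        t=t,
        p=p,
        attribution_possible=bool(wi.size and oi.size),
    )


def attribute_focal_epistasis(contrast: FocalContrast, n: int) -> float:
    """Epistatic effect credited to the focal locus within an n-QTL group.

    The focal-carrying subgroup's mean epistasis minus (n-1) shares of the
    focal-free subgroup's per-QTL epistasis.  Requires both subgroups
    non-empty and n >= 2.
    """
    if n < 2:
        raise ValueError("attribution needs pyramids of >= 2 QTLs")
    if not contrast.attribution_possible or contrast.with_n == 0 or contrast.without_n == 0:
        raise ValueError(
            f"{contrast.group}/{contrast.focal}: attribution needs both "
            "subgroups non-empty"
        )
    return contrast.with_mean_i - (n - 1) * (contrast.without_mean_i / n)


def contrast_from_summaries(
    group: str,
    focal: str,
    with_mean_i: float,
    with_n: int,
    without_mean_i: float,
    without_n: int,
    with_mean_ser: float = float("nan"),
    without_mean_ser: float = float("nan"),
) -> FocalContrast:
    """Build a contrast from pre-aggregated subgroup summaries (no test)."""
    return FocalContrast(
        group=group,
        focal=focal,
        with_n=with_n,
        without_n=without_n,
        with_mean_i=with_mean_i,
        without_mean_i=without_mean_i,
        with_mean_ser=with_mean_ser,
        without_mean_ser=without_mean_ser,
        attribution_possible=with_n > 0 and without_n > 0,
    )


def focal_contrast_table(
    panel: GenotypePanel,
    estimates: Sequence[EpistasisEstimate],
    records,
    focal: str,
    groups: Sequence[str] = ("2QL", "3QL", "4QL"),
) -> "OrderedDict[str, dict]":
    """Per-group contrast rows mirroring a with/without focal-QTL report."""
    out: "OrderedDict[str, dict]" = OrderedDict()
    for group in groups:
        c = focal_contrast(panel, estimates, records, focal, group)
        n = int(group.rstrip("QL"))
        row = {
            "with_n": c.with_n,
            "without_n": c.without_n,
            "with_mean_i": c.with_mean_i,
            "without_mean_i": c.without_mean_i,
            "with_mean_ser": c.with_mean_ser,
            "without_mean_ser": c.without_mean_ser,
            "t": c.t,
            "p": c.p,
        }
        if c.attribution_possible:
            row["focal_i"] = attribute_focal_epistasis(c, n)
            row["nonfocal_per_qtl_i"] = c.without_mean_i / n
        else:
            row["focal_i"] = float("nan")
            row["nonfocal_per_qtl_i"] = float("nan")
            row["flag"] = "empty subgroup"
        out[group] = row
    return out
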