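"""Report assembly: published-aggregate reproduction and CSV emission.

The study's raw per-line phenotypes are unavailable, so the package offers
two reporting modes: *raw-records* mode runs the full estimator chain on
season-level data, while *group-summary* mode re-derives every downstream
aggregate (combination effects, per-QTL epistasis, epistasis fractions,
focal-QTL attributions, weighted-mean identities) from pre-aggregated group
summaries such as the packaged fixture.
"""

from __future__ import annotations

import hashlib
import json
from collections import OrderedDict
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import __version__, datasets
from .effect_estimation import epistasis_fraction, per_qtl_epistasis
from .focal_qtl_analysis import attribute_focal_epistasis, contrast_from_summaries
from .phenotype_summary import group_mean_from_subgroups

__all__ = ["round_half_up", "reproduce_published_aggregates", "provenance_header"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Presentation rounding (half away from zero), as printed tables use."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def reproduce_published_aggregates(
    group_summaries: pd.DataFrame | None = None,
    group_epistasis: pd.DataFrame | None = None,
    focal_summaries: pd.DataFrame | None = None,
    *,
    focal_locus: str = "qSER3a-sat",
) -> dict:
    """Re-derive the study's downstream aggregates from group summaries.

    Combination effects are group mean minus control; per-QTL epistasis is
    group mean i over n; epistasis fractions divide the presentation-
    rounded per-QTL value by the mean single-QTL effect (the two-stage
    rounding the printed percentages imply); focal attributions follow the
    with/without decomposition.  Returns a nested dict of unrounded values
    (round at presentation only).
    """
    gs = group_summaries if group_summaries is not None else datasets.load_group_summaries()
    ge = group_epistasis if group_epistasis is not None else datasets.load_group_epistasis()
    fs = focal_summaries if focal_summaries is not None else datasets.load_focal_summaries()

    means = dict(zip(gs["subject"], gs["mean"].astype(float)))
    control = means["HJX74"] if "HJX74" in means else means["control"]
    mean_single = means["1QL"] - control

    combination = OrderedDict(
        (subj, means[subj] - control)
        for subj in gs["subject"]
        if subj.endswith("QL")
    )

    per_qtl = OrderedDict()
    fractions = OrderedDict()
    group_i = OrderedDict()
    for _, row in ge.iterrows():
        n = int(str(row["group"]).rstrip("QL"))
        group_i[row["group"]] = float(row["mean_i"])
        pq = per_qtl_epistasis(float(row["mean_i"]), n)
        per_qtl[row["group"]] = pq
        fractions[row["group"]] = epistasis_fraction(round_half_up(pq, 1), mean_single)

    focal = OrderedDict()
    for group, sub in fs.groupby("group", sort=True):
        n = int(str(group).rstrip("QL"))
        w = sub[sub["subgroup"] == "with"].iloc[0]
        o = sub[sub["subgroup"] == "without"].iloc[0]
        contrast = contrast_from_summaries(
            group,
            focal_locus,
            float(w["mean_i"]),
            int(w["n"]),
            float(o["mean_i"]),
            int(o["n"]),
            float(w["mean_ser"]),
            float(o["mean_ser"]),
        )
        focal[group] = {
            "with_n": contrast.with_n,
            "without_n": contrast.without_n,
            "with_mean_i": contrast.with_mean_i,
            "without_mean_i": contrast.without_mean_i,
            "with_mean_ser": contrast.with_mean_ser,
            "without_mean_ser": contrast.without_mean_ser,
            "focal_i": attribute_focal_epistasis(contrast, n),
            "nonfocal_per_qtl_i": contrast.without_mean_i / n,
            "group_mean_ser_reconstructed": group_mean_from_subgroups(
                [(contrast.with_mean_ser, contrast.with_n), (contrast.without_mean_ser, contrast.without_n)]
            ),
            "group_mean_i_reconstructed": group_mean_from_subgroups(
                [(contrast.with_mean_i, contrast.with_n), (contrast.without_mean_i, contrast.without_n)]
            ),
        }

    return {
        "control_mean": control,
        "mean_single_additive": mean_single,
        "combination_effects": combination,
        "group_epistasis": group_i,
        "per_qtl_epistasis": per_qtl,
        "epistasis_fractions": fractions,
        "focal": focal,
    }


def provenance_header(config: dict) -> str:
    """Comment lines embedding the package version and a config hash, so
    reruns with identical inputs are byte-identical."""
    blob = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return f"# qtlpyramid {__version__}\n# config_sha256 {digest}\n"
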