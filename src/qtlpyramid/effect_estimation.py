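"""Additive and additive-by-additive epistatic effect estimation.

All lines are homozygous substitutions in one recipient background, so a
single-QTL additive effect is simply the SSSL-minus-control difference in
trait means, and the n-QTL combination effect is the pyramid-minus-control
difference.  Epistasis is the deviation of a pyramid's combination effect
from the sum of its constituent single-QTL effects:

    i = (Pn - P0) - sum(a_j)        (additive x additive interaction)

which, because each a_j = (SSSL_j - P0), is the exactly equivalent linear
contrast

    i = Pn + (k - 1) * P0 - sum(SSSL_j)

over k contributing single-segment lines.  The contrast is evaluated per
cropping season (seasons as blocks, which absorbs the shared control term's
covariance) and tested with a one-sample Student's t across seasons under
H0: i = 0.  Because the null is defined in raw percentage points, the
epistasis t-test defaults to the raw scale; the variance-stabilising
arcsine square-root scale (used for group comparisons) is available as an
option, at the cost of a transform-induced offset under the raw-scale null.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .genotype_data import GenotypePanel, PyramidLine
from .phenotype_summary import TraitSummary, arcsine_sqrt, season_means

__all__ = [
    "EpistasisEstimate",
    "EffectClassification",
    "additive_single",
    "combination_effect",
    "epistasis_from_seasons",
    "estimate_single_effects",
    "estimate_epistasis",
    "per_qtl_epistasis",
    "epistasis_fraction",
    "classify_effect_levels",
    "aggregate_by_donor",
]

TestScale = Literal["raw_percent", "arcsine_sqrt"]


def additive_single(ssl_summary: TraitSummary, control_summary: TraitSummary) -> float:
    """Single-QTL additive effect: SSSL mean minus control mean (signed, %)."""
    if ssl_summary.scale != control_summary.scale:
        raise ValueError(
            f"scale mismatch: {ssl_summary.scale} vs {control_summary.scale}"
        )
    return ssl_summary.mean - control_summary.mean


def combination_effect(pyramid_summary: TraitSummary, control_summary: TraitSummary) -> float:
    """n-QTL combination effect: pyramid mean minus control mean (signed, %)."""
    return additive_single(pyramid_summary, control_summary)


@dataclass
class EpistasisEstimate:
    """Epistasis for one pyramiding line, with its season-blocked t-test.

    ``n`` is the number of stacked QTLs; ``additive_singles`` maps each
    contributing single-segment term to its additive effect (a linked pair
    contributes one joint term but two QTLs).
    """

    line_id: str
    n: int
    p0: float
    pn: float
    additive_singles: "OrderedDict[str, float]"
    i: float
    se_i: float
    t: float
    p: float
    df: int
    test_scale: TestScale = "raw_percent"

    @property
    def combination_effect(self) -> float:
        return self.pn - self.p0

    @property
    def additive_sum(self) -> float:
        return sum(self.additive_singles.values())

    @property
    def per_qtl_i(self) -> float:
        return per_qtl_epistasis(self.i, self.n)

    @property
    def stars(self) -> str:
        if math.isnan(self.p):
            return ""
        return "***" if self.p <= 0.001 else "**" if self.p <= 0.01 else "*" if self.p <= 0.05 else "ns"


def _one_sample_t(values: np.ndarray) -> tuple[float, float, int]:
    """t, p, df for H0 mean = 0; zero-spread inputs map to t=0 (all-zero)
    or +/-inf (constant nonzero) rather than NaN."""
    values = np.asarray(values, dtype=float)
    s = values.std(ddof=1)
    df = values.size - 1
    if s == 0.0:
        m = values.mean()
        if m == 0.0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, m), 0.0, df
    t = values.mean() / (s / math.sqrt(values.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def epistasis_from_seasons(
    line_id: str,
    pn_seasons: Sequence[float],
    p0_seasons: Sequence[float],
    contributor_seasons: Mapping[str, Sequence[float]],
    *,
    n_qtl: int | None = None,
    test_scale: TestScale = "raw_percent",
) -> EpistasisEstimate:
    """Estimate epistasis from season-level means of the pyramid, the
    control, and each contributing single-segment line.

    The point estimate and SE are on the raw percentage scale; the t-test
    runs on ``test_scale`` (raw by default, where H0 i=0 lives; the arcsine
    square-root option stabilises variance but shifts the null).
    """
    pn = np.asarray(pn_seasons, dtype=float)
    p0 = np.asarray(p0_seasons, dtype=float)
    contribs = OrderedDict((k, np.asarray(v, dtype=float)) for k, v in contributor_seasons.items())
    k = len(contribs)
    if k < 1:
        raise ValueError(f"{line_id}: no contributing single-segment lines")
    n = n_qtl if n_qtl is not None else k
    if n < 2:
        raise ValueError(f"{line_id}: epistasis undefined for fewer than 2 QTLs")
    S = pn.size
    if S < 2:
        raise ValueError(f"{line_id}: need >= 2 seasons for the blocked t-test")
    for name, arr in list(contribs.items()) + [("control", p0)]:
        if arr.size != S:
            raise ValueError(f"{line_id}: season count mismatch for {name}")

    def contrast(x_pn, x_p0, x_contribs):
        return x_pn + (k - 1) * x_p0 - sum(x_contribs.values())

    i_seasons = contrast(pn, p0, contribs)
    i_hat = float(i_seasons.mean())
    se_i = float(i_seasons.std(ddof=1) / math.sqrt(S))

    if test_scale == "arcsine_sqrt":
        tf = {name: arcsine_sqrt(arr) for name, arr in contribs.items()}
        t, p, df = _one_sample_t(contrast(arcsine_sqrt(pn), arcsine_sqrt(p0), tf))
    elif test_scale == "raw_percent":
        t, p, df = _one_sample_t(i_seasons)
    else:
        raise ValueError(f"unknown test scale {test_scale!r}")

    singles = OrderedDict(
        (name, float(arr.mean() - p0.mean())) for name, arr in contribs.items()
    )
    return EpistasisEstimate(
        line_id=line_id,
        n=n,
        p0=float(p0.mean()),
        pn=float(pn.mean()),
        additive_singles=singles,
        i=i_hat,
        se_i=se_i,
        t=t,
        p=p,
        df=df,
        test_scale=test_scale,
    )


def _variance_propagation(est: EpistasisEstimate, wide, line_map) -> EpistasisEstimate:
    """Alternative SE treating line means as independent (no season blocking)."""
    terms = [(line_map["pyramid"], 1.0), (line_map["control"], len(line_map["contribs"]) - 1.0)]
    terms += [(lid, -1.0) for lid in line_map["contribs"]]
    var = 0.0
    dfs_num, dfs_den = 0.0, 0.0
    for lid, coef in terms:
        x = wide.loc[lid].dropna().to_numpy()
        v = coef**2 * x.var(ddof=1) / x.size
        var += v
        dfs_num += v
        dfs_den += v**2 / (x.size - 1)
    se = math.sqrt(var)
    df = max(1, int(round(dfs_num**2 / dfs_den))) if dfs_den > 0 else 1
    t = est.i / se if se > 0 else (0.0 if est.i == 0 else math.copysign(math.inf, est.i))
    p = 2.0 * stats.t.sf(abs(t), df) if math.isfinite(t) else (1.0 if t == 0 else 0.0)
    est.se_i, est.t, est.p, est.df = se, float(t), float(p), df
    return est


def _resolve_contributors(
    line: PyramidLine, panel: GenotypePanel, singles: Mapping[str, list[PyramidLine]]
) -> "OrderedDict[str, str]":
    """Map contributing term label -> line_id for each locus a pyramid carries.

    Loci with their own single-QTL line use it; a locus without one may be
    covered jointly by a 2-QTL line matching its linked pair, in which case
    the pair contributes one joint term (still counting 2 toward n).
    """
    out: "OrderedDict[str, str]" = OrderedDict()
    covered: set[str] = set()
    two_ql = [ln for ln in panel.lines if ln.qtl_count == 2]
    for locus in line.loci_present:
        if locus in covered:
            continue
        if locus in singles:
            out[locus] = singles[locus][0].line_id
            covered.add(locus)
            continue
        meta = panel.locus(locus)
        partner = None
        if meta.linked_group is not None:
            partners = [
                l.name
                for l in panel.loci
                if l.linked_group == meta.linked_group and l.name != locus
            ]
            partner = next((p for p in partners if line.has(p)), None)
        if partner is not None:
            joint = next(
                (ln for ln in two_ql if set(ln.loci_present) == {locus, partner}), None
            )
            if joint is not None:
                out[f"{locus}+{partner}"] = joint.line_id
                covered.update({locus, partner})
                continue
        raise ValueError(
            f"line {line.line_id!r}: no single-QTL line (or linked joint line) "
            f"provides an additive effect for locus {locus!r}"
        )
    return out


def estimate_single_effects(
    panel: GenotypePanel,
    records,
    *,
    control_id: str = "HJX74",
) -> "OrderedDict[str, float]":
    """Per-locus additive effects from the panel's 1-QTL lines.

    When several single-QTL lines carry the same locus their line means are
    averaged before subtracting the control mean.
    """
    wide = season_means(records)
    if control_id not in wide.index:
        raise ValueError(f"control line {control_id!r} has no phenotype records")
    p0 = wide.loc[control_id].mean()
    out: "OrderedDict[str, float]" = OrderedDict()
    singles = panel.single_qtl_lines()
    for locus in panel.locus_names:
        if locus not in singles:
            continue
        ids = [ln.line_id for ln in singles[locus] if ln.line_id in wide.index]
        if not ids:
            continue
        out[locus] = float(wide.loc[ids].mean(axis=1).mean() - p0)
    return out


def estimate_epistasis(
    panel: GenotypePanel,
    records,
    *,
    control_id: str = "HJX74",
    test_scale: TestScale = "raw_percent",
    method: Literal["season_blocks", "propagation"] = "season_blocks",
) -> list[EpistasisEstimate]:
    """Epistasis estimates for every pyramiding line (>= 2 QTLs) in a panel.

    Requires season-level phenotype data for the control, each pyramid, and
    a single-QTL line per carried locus (or a linked-pair joint line).
    """
    wide = season_means(records)
    if control_id not in wide.index:
        raise ValueError(f"control line {control_id!r} has no phenotype records")
    seasons = wide.columns
    singles = panel.single_qtl_lines()
    out = []
    for line in panel.non_control_lines:
        if line.qtl_count < 2 or line.line_id not in wide.index:
            continue
        contribs = _resolve_contributors(line, panel, singles)
        missing = [lid for lid in contribs.values() if lid not in wide.index]
        if missing:
            raise ValueError(
                f"line {line.line_id!r}: contributing lines lack phenotypes: {missing}"
            )
        est = epistasis_from_seasons(
            line.line_id,
            wide.loc[line.line_id, seasons].to_numpy(),
            wide.loc[control_id, seasons].to_numpy(),
            OrderedDict((k, wide.loc[lid, seasons].to_numpy()) for k, lid in contribs.items()),
            n_qtl=line.qtl_count,
            test_scale=test_scale,
        )
        if method == "propagation":
            est = _variance_propagation(
                est, wide,
                {"pyramid": line.line_id, "control": control_id, "contribs": list(contribs.values())},
            )
        elif method != "season_blocks":
            raise ValueError(f"unknown method {method!r}")
        out.append(est)
    return out


def per_qtl_epistasis(i: float, n: int) -> float:
    """Average epistatic effect per stacked QTL: i / n."""
    if n < 1:
        raise ValueError("QTL count must be >= 1")
    return i / n


def epistasis_fraction(per_qtl_i: float, mean_single_additive: float) -> float:
    """Percentage of the per-QTL genetic effect attributable to epistasis:
    100 * |per-QTL i| / mean single-QTL additive effect."""
    if mean_single_additive <= 0:
        raise ValueError("mean single-QTL additive effect must be positive")
    return 100.0 * abs(per_qtl_i) / mean_single_additive


@dataclass
class EffectClassification:
    """Loci partitioned into ordered magnitude levels (low < ... < high)."""

    levels: list[str]  # level name per ascending mean, e.g. ["low","moderate","high"]
    assignment: dict[str, str]  # locus -> level name
    level_means: dict[str, float]
    members: dict[str, list[str]] = field(default_factory=dict)


_LEVEL_NAMES = {3: ["low", "moderate", "high"]}


def classify_effect_levels(effects: Mapping[str, float], k: int = 3) -> EffectClassification:
    """Partition loci into ``k`` effect levels by exact 1-D least squares.

    Dynamic programming over contiguous partitions of the sorted effects
    minimises total within-level sum of squares; ties prefer a smaller top
    level.  Level means must come out strictly increasing (they cannot when
    there are fewer than k distinct values), otherwise a ValueError asks
    for a smaller k.
    """
    items = sorted(effects.items(), key=lambda kv: kv[1])
    m = len(items)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} exceeds the number of loci ({m})")
    vals = np.array([v for _, v in items], dtype=float)

    # ssq[a][b] = within-SSE of vals[a:b]
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    csq = np.concatenate([[0.0], np.cumsum(vals**2)])

    def ssq(a: int, b: int) -> float:
        s, s2, n = csum[b] - csum[a], csq[b] - csq[a], b - a
        return s2 - s * s / n

    INF = float("inf")
    cost = [[INF] * (m + 1) for _ in range(k + 1)]
    back = [[0] * (m + 1) for _ in range(k + 1)]
    cost[0][0] = 0.0
    for j in range(1, k + 1):
        for b in range(j, m + 1):
            # iterate cut points ascending; ties resolved toward the larger
            # cut (>=), i.e. the smaller upper level
            for a in range(j - 1, b):
                c = cost[j - 1][a] + ssq(a, b)
                if c <= cost[j][b]:
                    cost[j][b], back[j][b] = c, a
    bounds = [m]
    b = m
    for j in range(k, 0, -1):
        b = back[j][b]
        bounds.append(b)
    bounds.reverse()  # 0 = b0 < b1 < ... < bk = m

    names = _LEVEL_NAMES.get(k, [f"level{j + 1}" for j in range(k)])
    assignment, level_means, members = {}, {}, {}
    prev_mean = -INF
    for j in range(k):
        seg = items[bounds[j] : bounds[j + 1]]
        mean = float(np.mean([v for _, v in seg]))
        if mean <= prev_mean:
            raise ValueError(
                f"cannot form {k} levels with strictly increasing means; "
                "use a smaller k"
            )
        prev_mean = mean
        level_means[names[j]] = mean
        members[names[j]] = [name for name, _ in seg]
        for name, _ in seg:
            assignment[name] = names[j]
    return EffectClassification(names, assignment, level_means, members)


def aggregate_by_donor(
    effects: Mapping[str, float],
    panel_or_metadata,
) -> "OrderedDict[str, tuple[float, float, float]]":
    """Per-donor-species (mean, min, max) of single-QTL additive effects."""
    if isinstance(panel_or_metadata, GenotypePanel):
        donor_of = {l.name: l.donor_species for l in panel_or_metadata.loci}
    else:
        donor_of = {
            name: (loc.donor_species if hasattr(loc, "donor_species") else loc)
            for name, loc in panel_or_metadata.items()
        }
    missing = [name for name in effects if name not in donor_of]
    if missing:
        raise ValueError(f"no donor metadata for loci: {missing}")
    out: "OrderedDict[str, tuple[float, float, float]]" = OrderedDict()
    for donor in ("sativa", "glaberrima", "glumaepatula"):
        vals = [v for name, v in effects.items() if donor_of[name] == donor]
        if vals:
            out[donor] = (float(np.mean(vals)), float(min(vals)), float(max(vals)))
    return out


def group_epistasis_table(estimates: Sequence[EpistasisEstimate]):
    """Unweighted per-group means of i and per-QTL i, as printed in reports.

    Returns an OrderedDict group -> dict(n_lines, n_qtl, mean_i, per_qtl_i,
    min_i, max_i).
    """
    out: "OrderedDict[str, dict]" = OrderedDict()
    by_n: dict[int, list[EpistasisEstimate]] = {}
    for est in estimates:
        by_n.setdefault(est.n, []).append(est)
    for n in sorted(by_n):
        ests = by_n[n]
        ivals = [e.i for e in ests]
        mean_i = float(np.mean(ivals))
        out[f"{n}QL"] = {
            "n_lines": len(ests),
            "n_qtl": n,
            "mean_i": mean_i,
            "per_qtl_i": per_qtl_epistasis(mean_i, n),
            "min_i": float(max(ivals)),  # closest to zero first, as ranges print
            "max_i": float(min(ivals)),
        }
    return out
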