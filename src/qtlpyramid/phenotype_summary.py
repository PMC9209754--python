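"""Phenotype ingestion, percentage transformation, and mean/SE summaries.

Stigma exsertion rate (SER) is a percentage trait; hypothesis tests in the
pipeline run by default on the arcsine square-root transformed scale, while
all reported effects stay in raw percentage points.  Replication unit is
the cropping season: plant-level replicates within a season are averaged to
one season value first, and every printed SE is across seasons (for lines)
or across lines (for groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genotype_data import GenotypePanel, lines_by_group

__all__ = [
    "PhenotypeRecord",
    "TraitSummary",
    "arcsine_sqrt",
    "inverse_arcsine_sqrt",
    "read_phenotype_table",
    "records_frame",
    "season_means",
    "summarize",
    "group_mean_from_subgroups",
]

Scale = Literal["raw_percent", "arcsine_sqrt"]

RECORD_COLUMNS = ("line_id", "season_id", "ser")


@dataclass(frozen=True)
class PhenotypeRecord:
    """One SER observation (%) for a line in one cropping season."""

    line_id: str
    season_id: str
    ser: float
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ser <= 100.0:
            raise ValueError(
                f"SER {self.ser} for {self.line_id}/{self.season_id} outside [0, 100]"
            )


@dataclass(frozen=True)
class TraitSummary:
    """Mean +/- SE over n replicates for a line or group, on a stated scale."""

    subject: str
    mean: float
    se: float  # NaN when n == 1
    n: int
    scale: Scale = "raw_percent"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.subject}: replicate count must be >= 1")
        if not math.isnan(self.se) and self.se < 0:
            raise ValueError(f"{self.subject}: SE must be non-negative")


def arcsine_sqrt(p):
    """Arcsine square-root transform of a percentage: asin(sqrt(p/100)), radians.

    Strictly monotone on [0, 100]; 0 -> 0 and 100 -> pi/2.  Accepts scalars
    or arrays; values outside [0, 100] raise.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentage outside [0, 100]")
    out = np.arcsin(np.sqrt(arr / 100.0))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_arcsine_sqrt(theta):
    """Inverse of :func:`arcsine_sqrt`: 100 * sin(theta)^2."""
    arr = np.asarray(theta, dtype=float)
    if np.any((arr < 0) | (arr > np.pi / 2 + 1e-12)):
        raise ValueError("transformed value outside [0, pi/2]")
    out = 100.0 * np.sin(arr) ** 2
    return float(out) if np.isscalar(theta) or arr.ndim == 0 else out


def records_frame(records) -> pd.DataFrame:
    """Coerce records (DataFrame or iterable of PhenotypeRecord) to a frame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"phenotype frame missing columns: {missing}")
        df = records.copy()
    else:
        df = pd.DataFrame(
            [(r.line_id, r.season_id, r.ser, r.replicate) for r in records],
            columns=[*RECORD_COLUMNS, "replicate"],
        )
    bad = df[(df["ser"] < 0) | (df["ser"] > 100)]
    if len(bad):
        raise ValueError(
            f"SER outside [0, 100] for: {bad['line_id'].unique().tolist()}"
        )
    if "replicate" not in df.columns or df["replicate"].isna().all():
        dup = df.duplicated(subset=["line_id", "season_id"])
        if dup.any():
            offenders = df.loc[dup, ["line_id", "season_id"]].drop_duplicates()
            raise ValueError(
                "repeated (line_id, season_id) without a replicate index: "
                + ", ".join(f"{a}/{b}" for a, b in offenders.itertuples(index=False))
            )
    return df


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read the long phenotype CSV (line_id, season_id, [replicate], ser_percent)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"phenotype table not found: {p}")
    df = pd.read_csv(p, comment="#")
    if "ser_percent" in df.columns:
        df = df.rename(columns={"ser_percent": "ser"})
    return records_frame(df)


def season_means(records, *, scale: Scale = "raw_percent") -> pd.DataFrame:
    """Line x season matrix of season-level means.

    Plant replicates within a season are averaged on the raw scale first;
    the transform, when requested, applies to the season means (the season
    is the replication unit of every downstream test).
    """
    df = records_frame(records)
    wide = df.pivot_table(index="line_id", columns="season_id", values="ser", aggfunc="mean")
    if scale == "arcsine_sqrt":
        wide = wide.apply(arcsine_sqrt)
    elif scale != "raw_percent":
        raise ValueError(f"unknown scale {scale!r}")
    return wide


def _mean_se(values: np.ndarray) -> tuple[float, float, int]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        raise ValueError("no observations")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, se, n


def summarize(
    records,
    *,
    by: Literal["line", "group"] = "line",
    panel: GenotypePanel | None = None,
    scale: Scale = "raw_percent",
) -> list[TraitSummary]:
    """Per-line or per-group mean and SE of SER.

    Line summaries: mean and SE over season values (SE = sd/sqrt(seasons)).
    Group summaries: unweighted mean of line means within each pyramid
    group, SE across lines.  A panel is required to place lines in groups
    and to reject unknown line ids.
    """
    df = records_frame(records)
    if panel is not None:
        known = {ln.line_id for ln in panel.lines}
        unknown = sorted(set(df["line_id"]) - known)
        if unknown:
            raise ValueError(f"records reference lines absent from the panel: {unknown}")
    wide = season_means(df, scale=scale)

    if by == "line":
        out = []
        for line_id, row in wide.iterrows():
            mean, se, n = _mean_se(row.to_numpy())
            out.append(TraitSummary(line_id, mean, se, n, scale))
        return out
    if by != "group":
        raise ValueError(f"unknown aggregation {by!r}")
    if panel is None:
        raise ValueError("group summaries need a genotype panel")

    line_means = wide.mean(axis=1)
    out = []
    controls = [ln.line_id for ln in panel.controls if ln.line_id in line_means.index]
    if controls:
        mean, se, n = _mean_se(line_means.loc[controls].to_numpy())
        # single control line: report its across-season SE instead of an
        # undefined across-line one
        if n == 1:
            mean, se, n = _mean_se(wide.loc[controls[0]].to_numpy())
        out.append(TraitSummary("control", mean, se, n, scale))
    for group, members in lines_by_group(panel).items():
        ids = [ln.line_id for ln in members if ln.line_id in line_means.index]
        if not ids:
            continue
        mean, se, n = _mean_se(line_means.loc[ids].to_numpy())
        out.append(TraitSummary(group, mean, se, n, scale))
    return out


def group_mean_from_subgroups(sub_summaries: Sequence[tuple[float, int]]) -> float:
    """Count-weighted mean of subgroup (mean, n) pairs: sum(n*m)/sum(n).

    Reconstructs a group mean from, e.g., with/without-focal-QTL subgroup
    means; equals the direct group mean exactly on any dataset.
    """
    subs = list(sub_summaries)
    if not subs:
        raise ValueError("no subgroup summaries given")
    if any(n < 1 for _, n in subs):
        raise ValueError("subgroup counts must be >= 1")
    total = sum(n for _, n in subs)
    return sum(m * n for m, n in subs) / total
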