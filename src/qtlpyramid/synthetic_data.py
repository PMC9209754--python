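"""Synthetic genotype panels and multi-season percentage phenotypes.

The generator emulates a pyramiding study in an isogenic background: a
baseline control (29.2% SER by default, matching the recipient variety), a
set of single-QTL substitution lines, and pyramids stacking 2-6 QTLs.
Phenotypes are built per line per cropping season as

    SER = clip(P0 + sum(a_j) + E(genotype) + season_offset + eps, 0, 100)

with iid Gaussian season noise, and an epistasis term E that is zero,
pairwise-programmed, or a diminishing-returns model E = -c * n(n-1)/2 in
which the per-QTL interaction deficit grows with the number of stacked
QTLs.  Every run is fully determined by its seed.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .genotype_data import GenotypePanel, PyramidLine, QtlLocus

__all__ = [
    "ArchitectureConfig",
    "no_epistasis",
    "pairwise_epistasis",
    "diminishing_epistasis",
    "paper_like_config",
    "generate_panel",
    "generate_phenotypes",
]

logger = logging.getLogger(__name__)

BASELINE_SER = 29.2  # recipient (HJX74) mean SER, %
DEFAULT_NOISE_SD = 3.0  # season-to-season SD on the raw % scale
DEFAULT_SEASONS = 3
#: per-pair interaction deficit (%) of the diminishing model; least-squares
#: match of -c*n(n-1)/2 to the observed group epistasis -7.8/-14.6/-25.2/
#: -40.4/-47.7 at n=2..6
DEFAULT_DIMINISHING_C = 3.5


@dataclass(frozen=True)
class EpistasisModel:
    kind: Literal["none", "pairwise", "diminishing"]
    pairwise: Mapping[frozenset, float] | None = None
    c: float = DEFAULT_DIMINISHING_C

    def total(self, loci_present: Sequence[str]) -> float:
        """Total epistatic deviation E for a genotype's set of loci."""
        n = len(loci_present)
        if self.kind == "none" or n < 2:
            return 0.0
        if self.kind == "pairwise":
            assert self.pairwise is not None
            total = 0.0
            for idx, a in enumerate(loci_present):
                for b in loci_present[idx + 1 :]:
                    total += self.pairwise.get(frozenset((a, b)), 0.0)
            return total
        return -self.c * n * (n - 1) / 2.0


def no_epistasis() -> EpistasisModel:
    return EpistasisModel("none")


def pairwise_epistasis(pairs: Mapping[tuple[str, str] | frozenset, float]) -> EpistasisModel:
    return EpistasisModel("pairwise", pairwise={frozenset(k): v for k, v in pairs.items()})


def diminishing_epistasis(c: float = DEFAULT_DIMINISHING_C) -> EpistasisModel:
    if c < 0:
        raise ValueError("shrinkage c is a magnitude; must be >= 0")
    return EpistasisModel("diminishing", c=c)


@dataclass
class ArchitectureConfig:
    """Known genetic architecture driving the phenotype simulator."""

    additive: "OrderedDict[str, float]"
    p0: float = BASELINE_SER
    epistasis: EpistasisModel = field(default_factory=no_epistasis)
    noise_sd: float = DEFAULT_NOISE_SD
    seasons: int = DEFAULT_SEASONS
    season_offsets: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.additive = OrderedDict(self.additive)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seasons < 1:
            raise ValueError("need >= 1 season")
        if self.season_offsets is not None and len(self.season_offsets) != self.seasons:
            raise ValueError("season_offsets length must equal seasons")

    def expected_ser(self, loci_present: Sequence[str]) -> float:
        mu = self.p0 + sum(self.additive[l] for l in loci_present)
        return mu + self.epistasis.total(loci_present)


def paper_like_config(
    *,
    epistasis: EpistasisModel | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seasons: int = DEFAULT_SEASONS,
    season_offsets=None,
    seed: int = 0,
) -> ArchitectureConfig:
    """Architecture mirroring the rice study's conditions: baseline 29.2%,
    the 11 reconstructed per-locus additive effects (13.3-27.3%), and a
    diminishing-returns epistasis model by default."""
    return ArchitectureConfig(
        additive=OrderedDict(datasets.load_synthetic_single_effects()),
        p0=BASELINE_SER,
        epistasis=epistasis if epistasis is not None else diminishing_epistasis(),
        noise_sd=noise_sd,
        seasons=seasons,
        season_offsets=season_offsets,
        seed=seed,
    )


def _random_panel(
    k_loci: int, lines_per_group: int, rng: np.random.Generator
) -> GenotypePanel:
    if k_loci < 2:
        raise ValueError("random design needs >= 2 loci")
    suffixes = ["sat", "gla", "glu"]
    loci = [
        QtlLocus.from_name(f"qSYN{j + 1}-{suffixes[j % 3]}") for j in range(k_loci)
    ]
    names = [l.name for l in loci]

    def line(line_id: str, present: Iterable[str], control=False) -> PyramidLine:
        pres = OrderedDict((nm, nm in set(present)) for nm in names)
        return PyramidLine(line_id, pres, is_control=control)

    lines = [line("CTRL", [], control=True)]
    lines += [line(f"SSSL-{nm}", [nm]) for nm in names]
    max_n = min(6, k_loci)
    for n in range(2, max_n + 1):
        for r in range(lines_per_group):
            combo = rng.choice(names, size=n, replace=False)
            lines.append(line(f"{n}QL-r{r + 1}", combo))
    return GenotypePanel(loci=loci, lines=lines)


def generate_panel(
    design: Literal["paper_preset", "paper_preset_full", "random"] = "paper_preset",
    *,
    k_loci: int = 11,
    lines_per_group: int = 5,
    seed: int = 0,
) -> GenotypePanel:
    """Generate a genotype panel.

    ``paper_preset`` reproduces the packaged 11-locus, 31-line pyramiding
    matrix (plus the control) and ignores randomness; ``paper_preset_full``
    adds one reconstructed single-QTL line per locus so that estimators can
    run end to end; ``random`` draws ``lines_per_group`` pyramids for every
    feasible QTL count 2..min(6, k_loci) plus a control and one single-QTL
    line per locus.
    """
    if design in ("paper_preset", "paper_preset_full"):
        panel = datasets.load_table1_panel()
        if design == "paper_preset_full":
            names = panel.locus_names
            singles = [
                PyramidLine(
                    f"SSSL-{nm}",
                    OrderedDict((other, other == nm) for other in names),
                )
                for nm in names
            ]
            panel = GenotypePanel(loci=panel.loci, lines=panel.lines + singles)
        return panel
    if design == "random":
        return _random_panel(k_loci, lines_per_group, np.random.default_rng(seed))
    raise ValueError(f"unknown design {design!r}")


def generate_phenotypes(
    panel: GenotypePanel,
    config: ArchitectureConfig,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate season-level SER records for every line in a panel.

    Returns the long record frame (line_id, season_id, ser).  Values are
    clipped to [0, 100]; clipping events are logged since they break the
    additivity the estimators assume.  Noise applies on the raw percentage
    scale.
    """
    missing = [nm for ln in panel.lines for nm in ln.loci_present if nm not in config.additive]
    if missing:
        raise ValueError(f"config.additive lacks loci: {sorted(set(missing))}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    offsets = (
        np.asarray(config.season_offsets, dtype=float)
        if config.season_offsets is not None
        else np.zeros(config.seasons)
    )
    rows = []
    n_clipped = 0
    for ln in panel.lines:
        mu = config.expected_ser(ln.loci_present)
        eps = rng.normal(0.0, config.noise_sd, size=config.seasons) if config.noise_sd else np.zeros(config.seasons)
        vals = mu + offsets + eps
        clipped = np.clip(vals, 0.0, 100.0)
        n_clipped += int(np.sum(clipped != vals))
        for s in range(config.seasons):
            rows.append((ln.line_id, f"CS{s + 1}", float(clipped[s])))
    if n_clipped:
        logger.warning("clipped %d simulated SER values to [0, 100]", n_clipped)
    return pd.DataFrame(rows, columns=["line_id", "season_id", "ser"])
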