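"""Simulation studies validating the estimators on known architectures.

These are the package's self-checks: because the original per-line field
data are not deposited, the estimators are validated by parameter recovery
and error-rate calibration on synthetic data rather than against published
per-line values.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .effect_estimation import epistasis_from_seasons, estimate_single_effects
from .group_stats import dunnett
from .synthetic_data import generate_panel, generate_phenotypes, paper_like_config

__all__ = [
    "epistasis_ttest_type1",
    "dunnett_fwer",
    "additive_recovery_study",
]


def epistasis_ttest_type1(
    n_sims: int = 2000,
    *,
    additive: tuple[float, float] = (15.0, 20.0),
    p0: float = 29.2,
    noise_sd: float = 3.0,
    seasons: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the season-blocked epistasis t-test.

    Simulates a purely additive 2-QTL architecture (H0: i = 0 true) and
    counts rejections at ``alpha``.  The test runs on the raw percentage
    scale, where the simulated null holds exactly; the arcsine option
    trades a small null bias for variance stabilisation and is exercised
    elsewhere.
    """
    rng = np.random.default_rng(seed)
    a1, a2 = additive
    mus = np.array([p0, p0 + a1, p0 + a2, p0 + a1 + a2])
    rejections = 0
    for _ in range(n_sims):
        vals = mus[:, None] + rng.normal(0.0, noise_sd, size=(4, seasons))
        est = epistasis_from_seasons(
            "sim",
            vals[3],
            vals[0],
            OrderedDict([("L1", vals[1]), ("L2", vals[2])]),
            test_scale="raw_percent",
        )
        rejections += est.p < alpha
    return rejections / n_sims


def dunnett_fwer(
    n_sims: int = 1000,
    *,
    k: int = 3,
    n_per: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error of the many-to-one comparison under a global null.

    All groups are drawn from the control's distribution; an error is any
    adjusted p below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    errors = 0
    for _ in range(n_sims):
        control = rng.normal(size=n_per)
        groups = [rng.normal(size=n_per) for _ in range(k)]
        errors += bool((dunnett(groups, control) < alpha).any())
    return errors / n_sims


def additive_recovery_study(
    n_panels: int = 200,
    *,
    noise_sd: float = 3.0,
    seasons: int = 3,
    seed: int = 0,
) -> dict:
    """Recover single-QTL additive effects over simulated panels.

    Each panel uses the full study design (control, one single-QTL line per
    locus, 31 pyramids), the reconstructed additive architecture with
    diminishing-returns epistasis, and fresh season noise.  Returns the
    mean signed bias and the mean absolute error of the recovered effects
    (percentage points), and the theoretical SE of one effect estimate.
    """
    panel = generate_panel("paper_preset_full")
    base = paper_like_config(noise_sd=noise_sd, seasons=seasons)
    truth = base.additive
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_panels):
        records = generate_phenotypes(panel, base, seed=int(rng.integers(2**31)))
        est = estimate_single_effects(panel, records)
        errors.extend(est[locus] - truth[locus] for locus in truth)
    errors = np.asarray(errors)
    # each effect is a difference of two 'seasons'-replicate means
    se_single = noise_sd * np.sqrt(2.0 / seasons)
    return {
        "n_panels": n_panels,
        "mean_bias": float(errors.mean()),
        "mae": float(np.abs(errors).mean()),
        "se_single_effect": float(se_single),
    }
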