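"""Group comparison toolkit: Student's t, Dunnett's many-to-one test, and
Duncan's multiple range test with significance-letter display.

Dunnett's adjusted p-values come from the multivariate-t distribution of
the maximum |t| statistic (scipy's numerical integration); Duncan's least
significant ranges are built from studentized-range quantiles at the
protection level 1 - (1 - alpha)^(p-1), so no hard-coded tables are
involved.  Percentage traits are normally compared on the arcsine
square-root scale; these functions are scale-agnostic and operate on
whatever values they are handed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TTestResult",
    "LetterDisplay",
    "students_t",
    "dunnett",
    "duncan_mrt",
    "duncan_lsr",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def _check_sample(x: np.ndarray, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"{label}: need >= 2 observations")
    return x


def students_t(
    x: Sequence[float],
    y: Sequence[float] | float | None = None,
    *,
    variant: Literal["welch", "pooled"] = "pooled",
) -> TTestResult:
    """Student's t-test: two-sample against ``y`` (pooled by default, Welch
    optional), or one-sample against the constant ``y`` (0 when omitted).

    Zero-variance degenerate inputs raise unless both samples are identical
    constants, which is reported as t=0, p=1.
    """
    x = _check_sample(x, "x")
    if y is None or np.isscalar(y):
        mu = 0.0 if y is None else float(y)
        if x.std(ddof=1) == 0:
            if x.mean() == mu:
                return TTestResult(0.0, x.size - 1, 1.0)
            raise ValueError("one-sample t undefined: zero variance, nonzero mean")
        t, p = stats.ttest_1samp(x, mu)
        return TTestResult(float(t), x.size - 1, float(p))
    y = _check_sample(y, "y")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, x.size + y.size - 2, 1.0)
        raise ValueError("two-sample t undefined: both samples constant")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    df = float(res.df) if hasattr(res, "df") else x.size + y.size - 2
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def dunnett(
    groups: Sequence[Sequence[float]],
    control: Sequence[float],
    *,
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
) -> np.ndarray:
    """Adjusted p-values for comparing each group to one control.

    Family-wise error is controlled through the joint multivariate-t
    distribution of the comparison statistics (equicorrelated structure for
    balanced designs, exact correlations otherwise).  With a single group
    this reduces to a two-sample pooled t-test.
    """
    if len(groups) < 1:
        raise ValueError("need at least one treatment group")
    control = _check_sample(control, "control")
    samples = [_check_sample(g, f"group {k}") for k, g in enumerate(groups)]
    res = stats.dunnett(*samples, control=control, alternative=alternative)
    return np.asarray(res.pvalue, dtype=float)


@lru_cache(maxsize=4096)
def _srange_ppf(q: float, p: int, df: float) -> float:
    return float(stats.studentized_range.ppf(q, p, df))


def duncan_lsr(p: int, df: float, mse: float, n: float, alpha: float) -> float:
    """Duncan's least significant range for a span of ``p`` ranked means.

    Uses the protected level alpha_p = 1 - (1-alpha)^(p-1) applied to the
    studentized-range distribution: LSR_p = q(1 - alpha_p, p, df) *
    sqrt(MSE / n).
    """
    if p < 2:
        raise ValueError("range span must be >= 2")
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return _srange_ppf(1.0 - alpha_p, p, df) * math.sqrt(mse / n)


@dataclass
class LetterDisplay:
    """Significance letters over means sorted descending.

    Two subjects share a letter iff their difference is non-significant at
    ``alpha`` under the stepwise range procedure; letter blocks are
    contiguous in the sorted order.
    """

    order: list[str]  # subjects, descending mean
    means: dict[str, float]
    letters: dict[str, str]  # subject -> e.g. "AB"
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _nonsig_pairs(means_desc: np.ndarray, lsr: dict[int, float]) -> set[tuple[int, int]]:
    """Pairs (i, j), i<j in rank order, declared non-significant.

    A pair is non-significant when any enclosing interval's range fails to
    exceed its span-specific LSR (the protection rule of multiple range
    tests: once a stretch of means is declared homogeneous, nothing inside
    it is tested).
    """
    k = means_desc.size
    nonsig: set[tuple[int, int]] = set()
    # mark whole intervals homogeneous, outermost spans first
    homogeneous: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            contained = any(a <= i and j <= b for a, b in homogeneous)
            if contained:
                continue
            if means_desc[i] - means_desc[j] <= lsr[span]:
                homogeneous.add((i, j))
    for a, b in homogeneous:
        for i in range(a, b + 1):
            for j in range(i + 1, b + 1):
                nonsig.add((i, j))
    return nonsig


def _letters_from_blocks(k: int, nonsig: set[tuple[int, int]]) -> list[str]:
    """Assign letters from maximal non-significant contiguous blocks."""
    blocks: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all((a, b) in nonsig for a in range(i, j + 2) for b in range(a + 1, j + 2)):
            j += 1
        blocks.append((i, j))
    # keep maximal blocks only
    maximal = [
        (i, j)
        for (i, j) in blocks
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in blocks)
    ]
    maximal.sort()
    letters = [""] * k
    for idx, (a, b) in enumerate(maximal):
        letter = _ALPHABET[idx % len(_ALPHABET)]
        for pos in range(a, b + 1):
            letters[pos] += letter
    return letters


def duncan_mrt(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    *,
    alpha: float = 0.05,
) -> LetterDisplay:
    """Duncan's multiple range test over several groups of replicates.

    Within-group replication supplies the pooled error mean square (df =
    sum(n_k - 1)); unbalanced group sizes enter the critical ranges through
    their harmonic mean.  Groups are ranked by mean and compared stepwise
    against span-dependent least significant ranges; the result is a
    letter display (shared letter = not significantly different).
    """
    if not isinstance(groups, dict):
        groups = {f"g{k + 1}": g for k, g in enumerate(groups)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    names = list(groups)
    samples = {name: _check_sample(groups[name], name) for name in names}
    k = len(names)

    df_err = sum(s.size - 1 for s in samples.values())
    mse = sum(s.var(ddof=1) * (s.size - 1) for s in samples.values()) / df_err
    if mse == 0:
        raise ValueError("zero error mean square: no within-group variation")
    n_h = k / sum(1.0 / s.size for s in samples.values())

    means = {name: float(s.mean()) for name, s in samples.items()}
    order = sorted(names, key=lambda nm: means[nm], reverse=True)
    means_desc = np.array([means[nm] for nm in order])
    lsr = {span: duncan_lsr(span, df_err, mse, n_h, alpha) for span in range(2, k + 1)}

    nonsig = _nonsig_pairs(means_desc, lsr)
    letters = _letters_from_blocks(k, nonsig)
    return LetterDisplay(
        order=order,
        means=means,
        letters={nm: lt for nm, lt in zip(order, letters)},
        alpha=alpha,
    )
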