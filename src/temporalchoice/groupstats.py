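"""Nonparametric group-level statistics.

Mann-Whitney U tests with the normal approximation (tie-corrected variance,
no continuity correction by default), the rank-test effect size
``r = |Z| / sqrt(N)``, normal tail probabilities, baseline normalization,
Bonferroni correction, and Spearman rank correlation with a t-approximation
for the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "GroupTestResult",
    "mann_whitney",
    "effect_size_r",
    "one_tailed_p",
    "two_tailed_p",
    "baseline_normalize",
    "bonferroni",
    "bonferroni_alpha",
    "spearman_correlation",
    "round_half_up",
]


@dataclass(frozen=True)
class GroupTestResult:
    """Result of a rank-sum comparison between two samples.

    ``u`` is the Mann-Whitney statistic for the first sample, ``z`` the
    signed normal deviate (positive when the first sample tends larger),
    ``p`` the probability for the stated tail, and ``r = |z|/sqrt(n_total)``.
    """

    u: float
    z: float
    p: float
    r: float
    n_total: int
    tail: str
    direction: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


def mann_whitney(
    x,
    y,
    tail: str = "two",
    direction: str | None = None,
    continuity: bool = False,
) -> GroupTestResult:
    """Mann-Whitney U test via the normal approximation.

    U is computed from rank sums with mid-ranks for ties; the variance of U
    carries the standard tie correction.  ``z`` is signed so that positive
    means ``x`` tends to exceed ``y``.  For ``tail="one"`` a ``direction``
    of ``"x_greater"`` or ``"y_greater"`` must be given explicitly — the
    hypothesized direction is never inferred from the data.  ``continuity``
    applies a 0.5 continuity correction toward the null (off by default, to
    match common software Z-to-p mappings).

    If every pooled value is identical the statistic is degenerate:
    ``z = 0`` with ``p = 1`` (two-tailed) or ``0.5`` (one-tailed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if tail not in ("one", "two"):
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    if tail == "one" and direction not in ("x_greater", "y_greater"):
        raise ValueError("one-tailed test requires direction 'x_greater' or 'y_greater'")

    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    if var <= 0:
        z = 0.0
    else:
        diff = u1 - mu
        if continuity:
            diff -= 0.5 * np.sign(diff)
        z = diff / np.sqrt(var)

    if tail == "two":
        p = two_tailed_p(z)
    else:
        z_dir = z if direction == "x_greater" else -z
        p = one_tailed_p(z_dir)

    return GroupTestResult(
        u=float(u1),
        z=float(z),
        p=float(p),
        r=effect_size_r(z, n),
        n_total=n,
        tail=tail,
        direction=direction,
    )


def effect_size_r(z: float, n_total: int) -> float:
    """Effect size ``r = |z| / sqrt(n_total)`` for a rank-test deviate."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return float(abs(z) / np.sqrt(n_total))


def one_tailed_p(z: float) -> float:
    """Upper-tail standard normal probability ``1 - Phi(z)``."""
    return float(norm.sf(z))


def two_tailed_p(z: float) -> float:
    """Two-sided standard normal probability ``2 * (1 - Phi(|z|))``."""
    return float(2.0 * norm.sf(abs(z)))


def baseline_normalize(post_minus_pre, pre) -> np.ndarray:
    """Divide pre-to-post difference scores by their baseline values.

    Raises if any baseline value is exactly zero rather than imputing.
    """
    diff = np.asarray(post_minus_pre, dtype=float)
    base = np.asarray(pre, dtype=float)
    if diff.shape != base.shape:
        raise ValueError("post_minus_pre and pre must have equal length")
    if np.any(base == 0):
        raise ValueError("baseline contains zero values; cannot normalize")
    return diff / base


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value ``min(1, m * p)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, m * p))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def spearman_correlation(x, y, tail: str = "two") -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Computed as the Pearson correlation of mid-rank-transformed data.  The
    one-tailed p is the upper tail for positive association.  Raises if
    either vector has zero rank variance (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 paired observations")
    if tail not in ("one", "two"):
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance; Spearman correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        if tail == "two":
            p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
        else:
            p = float(t_dist.sf(t_stat, df=n - 2))
    return rho, p


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
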