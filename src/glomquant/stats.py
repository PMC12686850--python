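"""Group summaries and exact small-sample Mann-Whitney comparisons.

Conventions used throughout (and verified against published quartile
and test values in the test suite):

* Quantiles use linear interpolation at position p*(n-1) in the sorted
  sample (numpy's default).
* Group summaries over the four datasets of an age group are the
  median of the four per-dataset medians.
* The Mann-Whitney U is reported for the *first* sample: the number of
  (a, b) pairs with a > b, counting ties as 0.5. The exact two-sided
  p-value doubles the smaller tail of the exact permutation null
  (enumerated over all assignments, ties included) and caps at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "quantiles_linear",
    "iqr",
    "group_summary",
    "mann_whitney_exact",
    "bootstrap_ci_median",
    "round_half_up",
    "EXACT_ENUMERATION_CAP",
]

# exact enumeration is used while C(n1+n2, n1) stays below this
EXACT_ENUMERATION_CAP = 200_000


@dataclass(frozen=True)
class ComparisonResult:
    """Mann-Whitney comparison of two samples (first vs second)."""

    u_stat: float
    p_exact_two_sided: float
    z_approx: float
    rank_biserial: float
    n1: int
    n2: int
    exact: bool


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-away-from-zero, for display values.

    Median-of-even-sample summaries routinely land exactly on a half
    (e.g. 77.535), where Python's banker's rounding would print 77.53
    but conventional reporting prints 77.54.
    """
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def quantiles_linear(samples) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation at p*(n-1)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def iqr(samples) -> float:
    """Interquartile range Q3 - Q1 under the linear convention."""
    q1, _, q3 = quantiles_linear(samples)
    return q3 - q1


def group_summary(
    per_dataset_medians,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict[str, float]:
    """Summarize an age group from its per-dataset medians.

    Returns the median of the medians, its quartiles, IQR, and a
    percentile-bootstrap confidence interval of the median.
    """
    x = np.asarray(per_dataset_medians, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 per-dataset medians, got {x.size}")
    q1, med, q3 = quantiles_linear(x)
    lo, hi = bootstrap_ci_median(x, level=level, n_boot=n_boot, seed=seed)
    return {
        "median": med, "q1": q1, "q3": q3, "iqr": q3 - q1,
        "ci_low": lo, "ci_high": hi,
    }


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Pairs with a > b, plus 0.5 per tie."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(a, b) -> ComparisonResult:
    """Mann-Whitney U test of two independent samples.

    The exact two-sided p-value is computed by full enumeration of all
    C(n1+n2, n1) group assignments of the pooled values (ties handled
    by midranks) whenever that count is at most
    ``EXACT_ENUMERATION_CAP``; beyond it, a tie-corrected normal
    approximation is used. ``z_approx`` is always the plain
    (uncorrected, uncontinuity-corrected) normal deviate
    (U - n1 n2 / 2) / sqrt(n1 n2 (n1+n2+1) / 12), and
    ``rank_biserial`` is 2U/(n1 n2) - 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")

    u = _u_statistic(a, b)
    mean_u = n1 * n2 / 2.0
    sd_u = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mean_u) / sd_u
    r_rb = 2.0 * u / (n1 * n2) - 1.0

    pooled = np.concatenate([a, b])
    n = n1 + n2
    if comb(n, n1) <= EXACT_ENUMERATION_CAP:
        # midranks turn the pair-count U into a rank-sum; enumerate
        # every assignment of n1 pooled values to the first group
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        us = np.array([
            ranks[list(idx)].sum() - offset
            for idx in combinations(range(n), n1)
        ])
        # tolerance guards the half-integer U values against float noise
        le = np.mean(us <= u + 1e-9)
        ge = np.mean(us >= u - 1e-9)
        p = min(1.0, 2.0 * min(le, ge))
        exact = True
    else:
        # tie-corrected variance for the large-sample approximation
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z_corr = (u - mean_u) / np.sqrt(var_u)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z_corr)))
        exact = False

    return ComparisonResult(
        u_stat=u, p_exact_two_sided=float(p), z_approx=float(z),
        rank_biserial=float(r_rb), n1=n1, n2=n2, exact=exact,
    )


def bootstrap_ci_median(
    samples, level: float = 0.95, n_boot: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the median.

    Deterministic given ``seed``. With very small n (e.g. the four
    datasets of an age group) the interval typically coincides with
    the sample min-max, which is how the published CIs behave.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    medians = np.median(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
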