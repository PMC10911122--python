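"""Statistical kernels: Pearson correlation, Student t-test, SEM, and a
permutation test for the maximum of a searched family of correlations.

The Pearson product-moment correlation with its two-tailed t-based p-value
and the pooled-variance two-sample t-test are the workhorses of the
banding and range-search reports. Because the range search *selects* the
interval with the largest |r| out of tens of thousands of candidates, its
naive Pearson p is badly anti-conservative; :func:`max_r_permutation_test`
supplies the selection-adjusted (family-wise) p by re-running the full
search on label-permuted output variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .cohort import SubjectCohort
from .errors import (
    DegenerateTestError,
    DimensionMismatchError,
    UndefinedCorrelationError,
)

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "PermutationResult",
    "pearson",
    "student_t_test",
    "sem",
    "max_r_permutation_test",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-tailed p and paired-sample count."""

    r: float
    p_two_tailed: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison: group means +/- SEM, t and two-tailed p."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_two_tailed: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class PermutationResult:
    """Family-wise p for the searched maximum |r| and its null distribution."""

    p_fwe: float
    observed_max_abs_r: float
    n_perm: int
    n_exceeding: int
    null_max_abs_r: np.ndarray


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed t-test p.

    ``p`` comes from referring ``t = r*sqrt(n-2)/sqrt(1-r^2)`` to a t
    distribution with ``n-2`` degrees of freedom; ``|r| = 1`` reports
    ``p = 0``.

    Raises
    ------
    UndefinedCorrelationError
        If either vector has zero variance or fewer than 3 pairs.
    DimensionMismatchError
        If the vectors differ in length.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DimensionMismatchError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError("need at least 3 pairs for a correlation")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r = float(xd @ yd) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p_two_tailed=p, n=n)


def sem(values) -> float:
    """Standard error of the mean: sample SD (ddof=1) over sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateTestError("SEM requires at least 2 values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def student_t_test(a, b, welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t-test; classical pooled-variance by default.

    ``welch=True`` drops the equal-variance assumption
    (Welch-Satterthwaite degrees of freedom).

    Raises
    ------
    DegenerateTestError
        If a group has fewer than 2 values or the pooled variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DegenerateTestError("each group needs at least 2 values")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if va == 0.0 and vb == 0.0:
        raise DegenerateTestError("zero pooled variance: groups are constant")
    if welch:
        se2a, se2b = va / na, vb / nb
        t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=sem(a),
        sem_b=sem(b),
        t_statistic=float(t),
        p_two_tailed=p,
        n_a=na,
        n_b=nb,
    )


def max_r_permutation_test(
    cohort: SubjectCohort,
    marker: str,
    search_procedure: Callable[[SubjectCohort, np.ndarray], float] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    constraints=None,
) -> PermutationResult:
    """Selection-adjusted p for the searched maximum |r|.

    The range search reports the interval maximizing |r| over the whole
    family of candidate ranges, so its naive Pearson p ignores selection.
    This test shuffles the output variable across subjects ``n_perm``
    times, reruns the identical search on each shuffle, and reports

        p = (1 + #{permutations with max |r| >= observed}) / (n_perm + 1)

    which is a valid family-wise p-value for the selected range.

    Parameters
    ----------
    search_procedure:
        Callable ``(cohort, y) -> max |r|``; must be deterministic given
        its inputs. Default: the contiguous-range search of
        :mod:`echorange.rangesearch` (prefix tables are then prepared once
        and reused across permutations).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful resolution")
    if len(cohort) < 3:
        raise UndefinedCorrelationError("need at least 3 subjects")
    y = cohort.marker_values(marker)
    if np.isnan(y).any():
        raise UndefinedCorrelationError(f"marker {marker!r} has missing values")
    if np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(f"marker {marker!r} is constant")

    if search_procedure is None:
        from .rangesearch import prepared_max_abs_r

        search_procedure = prepared_max_abs_r(cohort, constraints)

    rng = np.random.default_rng(seed)
    observed = float(search_procedure(cohort, y))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = search_procedure(cohort, rng.permutation(y))
    n_exceeding = int(np.sum(null >= observed))
    p = (1.0 + n_exceeding) / (n_perm + 1.0)
    return PermutationResult(
        p_fwe=p,
        observed_max_abs_r=observed,
        n_perm=n_perm,
        n_exceeding=n_exceeding,
        null_max_abs_r=null,
    )
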