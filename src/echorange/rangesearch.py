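"""Correlation-maximizing intensity-range search ("range search" core).

Given a cohort of subjects, each contributing a pixel-intensity sample and
a numeric output variable (a "marker", e.g. densitometric protein
expression), the search enumerates every contiguous intensity interval
``[lo, hi]`` with ``0 <= lo <= hi <= L``, computes for each interval the
per-subject mean of in-range pixels (the range NPV), correlates those
means with the marker across subjects, and returns the interval with the
largest |r|. Maximizing the *magnitude* matters: strong negative
correlations are as informative as positive ones.

Per-subject cumulative count/sum tables indexed by intensity make every
range mean an O(1) difference, so the exhaustive scan over all
``(L+1)(L+2)/2`` intervals (32,896 for 8-bit) costs O(L^2 * subjects).
Because integer pixel sums below 2^53 are exact in double precision, the
prefix-table means are bit-identical to naive recomputation.

Ranges in which a subject has fewer than ``min_pixels_per_subject`` pixels
are handled by excluding that subject pairwise (with a >= 3 subject floor)
or, in strict mode, by discarding the range. A greedy forward-selection
heuristic (:func:`search_scattered_set`) extends the search to
non-contiguous sets of intensity values, where exhaustive enumeration of
all 2^(L+1) subsets is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SubjectCohort
from .errors import (
    DimensionMismatchError,
    EmptyMaskError,
    NoAdmissibleRangeError,
    UndefinedCorrelationError,
)
from .stats import pearson

__all__ = [
    "RangeConstraints",
    "RangeSearchResult",
    "ScatteredSetResult",
    "PrefixTables",
    "enumerate_ranges",
    "build_prefix_tables",
    "search_best_range",
    "search_scattered_set",
    "prepared_max_abs_r",
    "threshold_map",
    "overlay_rgb",
]

# Two ranges whose exact |r| differ by less than this are reported as ties.
TIE_TOL = 1e-9
# Vectorized scores within this margin of the maximum are re-scored exactly.
_REFINE_TOL = 1e-6


@dataclass(frozen=True)
class RangeConstraints:
    """Admissibility constraints for candidate intensity ranges.

    min_pixels_per_subject:
        A subject enters a range's correlation only if it has at least
        this many pixels in range; ranges keeping < 3 subjects are skipped
        (strict mode instead requires *all* subjects to qualify).
    min_width:
        Minimum number of intensity levels (``hi - lo + 1``).
    """

    min_pixels_per_subject: int = 1
    min_width: int = 1
    strict: bool = False

    def __post_init__(self) -> None:
        if self.min_pixels_per_subject < 1:
            raise ValueError("min_pixels_per_subject must be >= 1")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass(frozen=True)
class RangeSearchResult:
    """Selected intensity interval and its correlation evidence."""

    marker: str
    lo: int
    hi: int
    r: float
    p_naive: float
    per_subject_means: dict[str, float]
    per_subject_ei_percent: dict[str, float]
    per_subject_sd: dict[str, float]
    n_subjects_used: int
    n_ranges_evaluated: int
    ties: tuple[tuple[int, int, float], ...]
    p_fwe: float | None = None

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1


@dataclass(frozen=True)
class ScatteredSetResult:
    """Greedy scattered-intensity-set selection and its audit trace."""

    marker: str
    intensities: tuple[int, ...]
    r: float
    p_naive: float
    per_subject_means: dict[str, float]
    trace: tuple[tuple[int, float], ...]  # (added intensity, |r| after adding)


class PrefixTables:
    """Per-subject cumulative pixel count and intensity-sum by intensity.

    ``cum_count[s, v]`` = number of pixels of subject ``s`` with intensity
    < v, so the in-range count for [lo, hi] is
    ``cum_count[s, hi+1] - cum_count[s, lo]`` (and likewise for sums).
    """

    def __init__(self, cohort: SubjectCohort) -> None:
        L = cohort.L
        S = len(cohort)
        self.L = L
        self.subject_ids = cohort.subject_ids
        hist = np.zeros((S, L + 1), dtype=np.int64)
        for i, subj in enumerate(cohort):
            hist[i] = np.bincount(subj.sample.values, minlength=L + 1)
        self.hist = hist
        self.cum_count = np.zeros((S, L + 2), dtype=np.int64)
        self.cum_sum = np.zeros((S, L + 2), dtype=np.int64)
        np.cumsum(hist, axis=1, out=self.cum_count[:, 1:])
        np.cumsum(hist * np.arange(L + 1, dtype=np.int64), axis=1,
                  out=self.cum_sum[:, 1:])

    def query(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """In-range pixel counts and intensity sums per subject."""
        counts = self.cum_count[:, hi + 1] - self.cum_count[:, lo]
        sums = self.cum_sum[:, hi + 1] - self.cum_sum[:, lo]
        return counts, sums

    def range_means(self, lo: int, hi: int) -> np.ndarray:
        """Per-subject mean of in-range pixels; NaN where no pixel."""
        counts, sums = self.query(lo, hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def build_prefix_tables(cohort: SubjectCohort) -> PrefixTables:
    """Build per-subject cumulative count/sum tables for O(1) range means."""
    return PrefixTables(cohort)


def enumerate_ranges(L: int, min_width: int = 1) -> np.ndarray:
    """All integer intervals [lo, hi] in [0, L], ordered by (lo, hi).

    With ``min_width = 1`` there are ``(L+1)(L+2)/2`` of them.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    lo, hi = np.triu_indices(L + 1, k=min_width - 1)
    return np.column_stack([lo, hi]).astype(np.int64)


def _range_matrices(tables: PrefixTables, ranges: np.ndarray):
    """Counts and means for every (range, subject) pair.

    Returns counts (R, S) int, means (R, S) float with 0 where count = 0.
    Integer sums are exact in float64, so means match naive recomputation
    bitwise.
    """
    lo = ranges[:, 0]
    hi = ranges[:, 1]
    counts = (tables.cum_count[:, hi + 1] - tables.cum_count[:, lo]).T
    sums = (tables.cum_sum[:, hi + 1] - tables.cum_sum[:, lo]).T
    means = np.zeros(counts.shape)
    np.divide(sums, counts, out=means, where=counts > 0)
    return counts, means


def _scores_for_y(counts, means, y, constraints) -> tuple[np.ndarray, np.ndarray]:
    """|r| score for every range against output vector y.

    Inadmissible or degenerate ranges score NaN. Returns (scores, n_used).
    """
    valid = counts >= constraints.min_pixels_per_subject
    n = valid.sum(axis=1)
    if constraints.strict:
        admissible = n == counts.shape[1]
    else:
        admissible = n >= 3
    mx = np.where(valid, means, 0.0)
    sx = mx.sum(axis=1)
    sxx = (mx * mx).sum(axis=1)
    vy = valid.astype(float)
    sy = vy @ y
    syy = vy @ (y * y)
    sxy = mx @ y
    nf = n.astype(float)
    varx = nf * sxx - sx * sx
    vary = nf * syy - sy * sy
    ok = admissible & (varx > 0) & (vary > 0) & (n >= 3)
    scores = np.full(counts.shape[0], np.nan)
    denom = np.sqrt(np.where(ok, varx * vary, 1.0))
    scores[ok] = np.abs((nf * sxy - sx * sy)[ok] / denom[ok])
    np.clip(scores, 0.0, 1.0, out=scores)
    return scores, n


def _exact_r(tables: PrefixTables, lo: int, hi: int, y: np.ndarray,
             constraints: RangeConstraints):
    """Exact Pearson r for one range via stats.pearson on included subjects."""
    counts, sums = tables.query(lo, hi)
    incl = counts >= constraints.min_pixels_per_subject
    means = sums[incl] / counts[incl]
    res = pearson(means, y[incl])
    return res, incl, means


def search_best_range(
    cohort: SubjectCohort,
    marker: str,
    constraints: RangeConstraints | None = None,
    y: np.ndarray | None = None,
    tables: PrefixTables | None = None,
) -> RangeSearchResult:
    """Exhaustive contiguous-range search maximizing |Pearson r|.

    Evaluates every admissible interval [lo, hi], correlating per-subject
    in-range means with the marker values, and returns the interval with
    the largest |r|. Ties (|r| within 1e-9 of the best) are broken toward
    the narrower interval, then the smaller ``lo``, and all tying ranges
    are reported.

    Parameters
    ----------
    y:
        Optional explicit output vector (in cohort subject order),
        overriding the marker column — used by permutation machinery.

    Raises
    ------
    NoAdmissibleRangeError
        If no interval satisfies the constraints with >= 3 subjects.
    UndefinedCorrelationError
        If the marker is constant or has < 3 values.
    """
    constraints = constraints or RangeConstraints()
    if y is None:
        y = cohort.marker_values(marker)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        if keep.sum() < 3:
            raise UndefinedCorrelationError(
                f"marker {marker!r} has fewer than 3 non-missing values"
            )
        sub = SubjectCohort([s for s, k in zip(cohort, keep) if k])
        return search_best_range(sub, marker, constraints, y=y[keep])
    if np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(f"marker {marker!r} is constant")

    if tables is None:
        tables = build_prefix_tables(cohort)
    ranges = enumerate_ranges(cohort.L, constraints.min_width)
    counts, means = _range_matrices(tables, ranges)
    scores, _ = _scores_for_y(counts, means, y, constraints)
    n_eval = int(np.sum(~np.isnan(scores)))
    if n_eval == 0:
        raise NoAdmissibleRangeError(
            "no admissible intensity range under the given constraints"
        )

    # Re-score near-maximal candidates with the exact Pearson kernel so the
    # selection is independent of the vectorized formula's rounding.
    best_score = np.nanmax(scores)
    cand = np.flatnonzero(scores >= best_score - _REFINE_TOL)
    exact = {}
    for idx in cand:
        lo, hi = int(ranges[idx, 0]), int(ranges[idx, 1])
        try:
            res, incl, m = _exact_r(tables, lo, hi, y, constraints)
        except UndefinedCorrelationError:
            continue
        exact[idx] = (res, incl, m)
    if not exact:
        raise NoAdmissibleRangeError("no admissible range with a defined correlation")

    best_abs = max(abs(v[0].r) for v in exact.values())
    tie_idx = [i for i, v in exact.items() if abs(v[0].r) >= best_abs - TIE_TOL]
    # narrower first, then smaller lo
    tie_idx.sort(key=lambda i: (ranges[i, 1] - ranges[i, 0], ranges[i, 0]))
    winner = tie_idx[0]
    res, incl, m = exact[winner]
    lo, hi = int(ranges[winner, 0]), int(ranges[winner, 1])

    ids = np.asarray(tables.subject_ids)
    incl_ids = ids[incl]
    # EI% and in-range SD for the selected range, for reporting
    ei, sd = {}, {}
    for subj in cohort:
        if subj.subject_id not in set(incl_ids):
            continue
        v = subj.sample.values
        sel = v[(v >= lo) & (v <= hi)]
        ei[subj.subject_id] = 100.0 * sel.size / v.size
        sd[subj.subject_id] = float(sel.std(ddof=0))
    ties = tuple(
        (int(ranges[i, 0]), int(ranges[i, 1]), float(exact[i][0].r)) for i in tie_idx
    )
    return RangeSearchResult(
        marker=marker,
        lo=lo,
        hi=hi,
        r=float(res.r),
        p_naive=float(res.p_two_tailed),
        per_subject_means={str(i): float(v) for i, v in zip(incl_ids, m)},
        per_subject_ei_percent=ei,
        per_subject_sd=sd,
        n_subjects_used=int(incl.sum()),
        n_ranges_evaluated=n_eval,
        ties=ties,
    )


def prepared_max_abs_r(cohort: SubjectCohort, constraints: RangeConstraints | None = None):
    """Closure computing max |r| over all admissible ranges for a given y.

    Prefix tables and range count/mean matrices are built once, so each
    call (one permutation of the output variable) costs three small
    matrix-vector products — the workhorse of the permutation test.
    """
    constraints = constraints or RangeConstraints()
    tables = build_prefix_tables(cohort)
    ranges = enumerate_ranges(cohort.L, constraints.min_width)
    counts, means = _range_matrices(tables, ranges)

    # everything not involving y is fixed across permutations
    valid = counts >= constraints.min_pixels_per_subject
    n = valid.sum(axis=1)
    admissible = (n == counts.shape[1]) if constraints.strict else (n >= 3)
    mx = np.where(valid, means, 0.0)
    sx = mx.sum(axis=1)
    sxx = (mx * mx).sum(axis=1)
    nf = n.astype(float)
    varx = nf * sxx - sx * sx
    keep = admissible & (varx > 0) & (n >= 3)
    if not keep.any():
        raise NoAdmissibleRangeError("no admissible range")
    mxk = np.ascontiguousarray(mx[keep])
    vyk = np.ascontiguousarray(valid[keep].astype(float))
    sxk, varxk, nk = sx[keep], varx[keep], nf[keep]

    def max_abs_r(_cohort: SubjectCohort, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        sy = vyk @ y
        syy = vyk @ (y * y)
        sxy = mxk @ y
        vary = nk * syy - sy * sy
        ok = vary > 0
        if not ok.any():
            raise NoAdmissibleRangeError("no admissible range")
        num = np.abs(nk * sxy - sxk * sy)[ok]
        return float(min(1.0, np.max(num / np.sqrt(varxk[ok] * vary[ok]))))

    return max_abs_r


def search_scattered_set(
    cohort: SubjectCohort,
    marker: str,
    constraints: RangeConstraints | None = None,
    max_set_size: int | None = None,
    tol: float = 1e-9,
    y: np.ndarray | None = None,
) -> ScatteredSetResult:
    """Greedy forward selection of a non-contiguous intensity set.

    The per-subject mean over a single intensity value is that value
    itself — constant across subjects — so no singleton has a defined
    correlation. The search therefore bootstraps from the best *pair* of
    intensity values (exhaustively scored, ties to the lexicographically
    smallest pair), then repeatedly adds the intensity whose inclusion
    (means recomputed over the union) most increases |r|, stopping when
    no candidate improves |r| by more than ``tol`` or the set reaches
    ``max_set_size``. Ties go to the lower intensity. This is a
    deterministic heuristic: exhaustive search over all subsets of
    intensity values is combinatorially impossible, and the returned
    trace records every accepted step for audit.
    """
    constraints = constraints or RangeConstraints()
    if max_set_size is not None and max_set_size < 2:
        raise ValueError("max_set_size must be >= 2 (singleton means are constant)")
    if y is None:
        y = cohort.marker_values(marker)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise UndefinedCorrelationError(f"marker {marker!r} has missing values")
    if np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(f"marker {marker!r} is constant")
    tables = build_prefix_tables(cohort)
    L = cohort.L
    S = len(cohort)
    cnt_v = tables.hist.T.astype(np.int64)  # (L+1, S)
    sum_v = cnt_v * np.arange(L + 1, dtype=np.int64)[:, None]
    if max_set_size is None:
        max_set_size = L + 1

    # bootstrap: best two-intensity set, scored exhaustively
    v1, v2 = np.triu_indices(L + 1, k=1)
    pair_cnt = cnt_v[v1] + cnt_v[v2]
    pair_sum = sum_v[v1] + sum_v[v2]
    pair_means = np.zeros(pair_cnt.shape)
    np.divide(pair_sum, pair_cnt, out=pair_means, where=pair_cnt > 0)
    pair_scores, _ = _scores_for_y(pair_cnt, pair_means, y, constraints)
    if np.all(np.isnan(pair_scores)):
        raise NoAdmissibleRangeError(
            "no admissible intensity pair under the constraints"
        )
    j = int(np.nanargmax(pair_scores))  # first index wins ties: smallest pair
    chosen: list[int] = [int(v1[j]), int(v2[j])]
    best_abs = float(pair_scores[j])
    cur_cnt = cnt_v[chosen[0]] + cnt_v[chosen[1]]
    cur_sum = sum_v[chosen[0]] + sum_v[chosen[1]]
    trace: list[tuple[int, float]] = [(chosen[0], best_abs), (chosen[1], best_abs)]

    while len(chosen) < max_set_size:
        mask = np.ones(L + 1, dtype=bool)
        mask[chosen] = False
        cand = np.flatnonzero(mask)
        new_cnt = cur_cnt[None, :] + cnt_v[cand]
        new_sum = cur_sum[None, :] + sum_v[cand]
        means = np.zeros(new_cnt.shape)
        np.divide(new_sum, new_cnt, out=means, where=new_cnt > 0)
        scores, _ = _scores_for_y(new_cnt, means, y, constraints)
        if np.all(np.isnan(scores)):
            break
        j = int(np.nanargmax(scores))  # nanargmax -> first (lowest) on ties
        if scores[j] <= best_abs + tol:
            break
        v = int(cand[j])
        chosen.append(v)
        cur_cnt = cur_cnt + cnt_v[v]
        cur_sum = cur_sum + sum_v[v]
        best_abs = float(scores[j])
        trace.append((v, best_abs))

    incl = cur_cnt >= constraints.min_pixels_per_subject
    means = cur_sum[incl] / cur_cnt[incl]
    res = pearson(means, y[incl])
    ids = np.asarray(tables.subject_ids)[incl]
    return ScatteredSetResult(
        marker=marker,
        intensities=tuple(sorted(chosen)),
        r=float(res.r),
        p_naive=float(res.p_two_tailed),
        per_subject_means={str(i): float(v) for i, v in zip(ids, means)},
        trace=tuple(trace),
    )


def threshold_map(
    img: np.ndarray, mask: np.ndarray, lo: int, hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mark the masked pixels whose intensity falls in [lo, hi].

    Returns the boolean overlay and the (row, col) coordinates of marked
    pixels — the spatial localization of a selected intensity range.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise DimensionMismatchError("image and mask shapes differ")
    if not mask.any():
        raise EmptyMaskError("threshold map requested on an empty mask")
    if lo > hi:
        raise ValueError("lo must be <= hi")
    overlay = mask & (img >= lo) & (img <= hi)
    coords = np.argwhere(overlay)
    return overlay, coords


def overlay_rgb(img: np.ndarray, overlay: np.ndarray,
                color: tuple[int, int, int] = (0, 255, 0)) -> np.ndarray:
    """Render a grayscale image with overlay pixels painted in ``color``."""
    rgb = np.stack([np.asarray(img, dtype=np.uint8)] * 3, axis=-1)
    rgb[np.asarray(overlay, dtype=bool)] = color
    return rgb
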