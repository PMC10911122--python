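import numpy as np
import pytest

from echorange.cohort import PixelSample, Subject, SubjectCohort
from echorange.rangesearch import RangeConstraints, enumerate_ranges
from echorange.stats import pearson


def make_random_cohort(seed: int, n_subjects: int = 10, n_pixels: int = 500,
                       L: int = 31, marker: str = "m") -> SubjectCohort:
    """Random cohort: uniform pixel intensities, independent marker values."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        values = rng.integers(0, L + 1, size=n_pixels)
        outputs = {marker: float(rng.normal())}
        group = "sham" if i < n_subjects // 2 else "surgery"
        subjects.append(
            Subject(f"S{i:02d}", group, PixelSample(f"S{i:02d}", values, L=L), outputs)
        )
    return SubjectCohort(subjects)


def naive_best_range(cohort: SubjectCohort, marker: str,
                     constraints: RangeConstraints | None = None):
    """Brute-force oracle: recompute every range mean from scratch.

    Independent of the prefix-table implementation: filters the raw pixel
    vectors per range, computes Pearson r per range, and applies the same
    selection rule (max |r|; ties within 1e-9 broken by narrower width,
    then smaller lo).
    """
    constraints = constraints or RangeConstraints()
    y = cohort.marker_values(marker)
    scored = []  # (abs_r, width, lo, hi, r)
    for lo, hi in enumerate_ranges(cohort.L, constraints.min_width):
        means, yy = [], []
        for subj, yv in zip(cohort, y):
            v = subj.sample.values
            sel = v[(v >= lo) & (v <= hi)]
            if sel.size >= constraints.min_pixels_per_subject:
                means.append(sel.mean())
                yy.append(yv)
        if constraints.strict and len(means) < len(cohort):
            continue
        if len(means) < 3:
            continue
        try:
            res = pearson(np.array(means), np.array(yy))
        except Exception:
            continue
        scored.append((abs(res.r), hi - lo + 1, int(lo), int(hi), float(res.r)))
    if not scored:
        return None
    best_abs = max(s[0] for s in scored)
    ties = [s for s in scored if s[0] >= best_abs - 1e-9]
    ties.sort(key=lambda s: (s[1], s[2]))  # narrower, then smaller lo
    _, _, lo, hi, r = ties[0]
    return lo, hi, r


@pytest.fixture
def random_cohort():
    return make_random_cohort(seed=42)
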