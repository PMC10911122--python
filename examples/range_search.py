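"""Exhaustive intensity-range search with selection-adjusted inference.

Scans all 32,896 contiguous intensity ranges, selects the one whose
per-subject mean (range NPV) correlates most strongly with a marker, and
contrasts the naive Pearson p (which ignores that the range was selected
as the maximum of a large family) with the permutation family-wise p.
Also marks the selected range's pixels in the first subject's image. Run:

    python examples/range_search.py
"""

from echorange import (
    RangeConstraints,
    SynthParams,
    generate_cohort,
    max_r_permutation_test,
    search_best_range,
    threshold_map,
)
from echorange.imagio import rasterize_roi

bundle = generate_cohort(SynthParams(seed=3))
cohort = bundle.cohort
constraints = RangeConstraints(strict=True)

print(f"planted range: {bundle.truth.planted_range}\n")
for marker in ("CaMKII", "CGRP"):
    res = search_best_range(cohort, marker, constraints)
    perm = max_r_permutation_test(cohort, marker, n_perm=999, seed=1,
                                  constraints=constraints)
    kind = "coupled" if marker in bundle.truth.coupled_markers else "null"
    print(f"{marker} ({kind} marker):")
    print(f"  selected range [{res.lo}, {res.hi}]  "
          f"({res.n_ranges_evaluated} ranges evaluated)")
    print(f"  r = {res.r:+.3f}   p_naive = {res.p_naive:.2e}   "
          f"p_fwe = {perm.p_fwe:.3f}")
    print()

print("the naive p looks impressive even for the null marker — selecting")
print("the maximum |r| of 32,896 ranges guarantees a strong-looking")
print("correlation; only the permutation p separates signal from selection.")

sid = cohort.subject_ids[0]
img = bundle.images[sid]
mask = rasterize_roi(bundle.rois[sid], img.shape[1], img.shape[0])
res = search_best_range(cohort, "CaMKII", constraints)
overlay, coords = threshold_map(img, mask, res.lo, res.hi)
print(f"\nthreshold map for {sid}: {len(coords)} of {mask.sum()} ROI pixels "
      f"fall in [{res.lo}, {res.hi}]")
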