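"""First-order echotexture statistics, whole-ROI and per echointensity band.

Quantitative muscle ultrasonography summarizes the ROI pixel histogram with
first-order statistics: the mean intensity (numerical pixel value, NPV),
its standard deviation (heterogeneity), extremes and pixel count. The
banding approach repeats these statistics inside fixed intensity intervals
("EI bands"): for each band it reports the fraction of ROI pixels that fall
in the band (EI%), the mean of the in-band intensities (NPV) and their SD.
Two conventional presets partition the 8-bit scale into 50-wide and 25-wide
bands (:data:`BANDS50`, :data:`BANDS25`).

Bands with no pixels report *missing* NPV/SD (``NaN``), never zero: a
subject simply has no echotexture in that brightness band. SDs are
population SDs (denominator ``n``), the convention of bitmap-analysis
software; pass ``ddof=1`` for the sample form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PixelSample, SubjectCohort
from .errors import EchorangeError

__all__ = [
    "BandSpec",
    "BandStats",
    "FirstOrderStats",
    "BANDS50",
    "BANDS25",
    "whole_roi_stats",
    "band_stats",
    "range_mean",
    "cohort_band_table",
]


@dataclass(frozen=True)
class BandSpec:
    """Ordered, non-overlapping inclusive intensity intervals ``[lo, hi]``."""

    bands: tuple[tuple[int, int], ...]
    L: int = 255

    def __post_init__(self) -> None:
        bands = tuple((int(lo), int(hi)) for lo, hi in self.bands)
        if not bands:
            raise EchorangeError("band spec must contain at least one band")
        prev_hi = -1
        for lo, hi in bands:
            if not (0 <= lo <= hi <= self.L):
                raise EchorangeError(f"band [{lo}, {hi}] outside [0, {self.L}]")
            if lo <= prev_hi:
                raise EchorangeError("bands must be sorted and non-overlapping")
            prev_hi = hi
        object.__setattr__(self, "bands", bands)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def is_exhaustive(self) -> bool:
        """True if the bands partition [0, L] with no gaps."""
        lo0 = self.bands[0][0]
        if lo0 != 0 or self.bands[-1][1] != self.L:
            return False
        return all(
            self.bands[i + 1][0] == self.bands[i][1] + 1
            for i in range(len(self.bands) - 1)
        )

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.bands]


#: 50-wide echointensity bands partitioning [0, 255].
BANDS50 = BandSpec(((0, 50), (51, 100), (101, 150), (151, 200), (201, 255)))

#: 25-wide echointensity bands partitioning [0, 255].
BANDS25 = BandSpec(
    (
        (0, 25),
        (26, 50),
        (51, 75),
        (76, 100),
        (101, 125),
        (126, 150),
        (151, 175),
        (176, 200),
        (201, 225),
        (226, 250),
        (251, 255),
    )
)


@dataclass(frozen=True)
class FirstOrderStats:
    """Whole-sample histogram summary: mean, SD, extremes, count."""

    mean: float
    sd: float
    min: int
    max: int
    n: int


@dataclass(frozen=True)
class BandStats:
    """Per-band pixel counts, EI%, NPV and SD for one pixel sample.

    Arrays are parallel to ``spec.bands``; ``npv``/``sd`` are NaN for
    empty bands and ``sd`` is 0 for single-pixel bands.
    """

    spec: BandSpec
    n_pixels: np.ndarray
    ei_percent: np.ndarray
    npv: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        los, his = zip(*self.spec.bands)
        return pd.DataFrame(
            {
                "band_lo": los,
                "band_hi": his,
                "n_pixels": self.n_pixels,
                "ei_percent": self.ei_percent,
                "npv": self.npv,
                "sd": self.sd,
            }
        )


def whole_roi_stats(sample: PixelSample, ddof: int = 0) -> FirstOrderStats:
    """First-order statistics over the whole pixel sample.

    ``ddof=0`` (default) gives the population SD.
    """
    v = sample.values
    return FirstOrderStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=ddof)),
        min=int(v.min()),
        max=int(v.max()),
        n=int(v.size),
    )


def band_stats(sample: PixelSample, spec: BandSpec, ddof: int = 0) -> BandStats:
    """Per-band counts, EI%, NPV and SD for one subject's sample."""
    v = sample.values
    k = len(spec)
    n_pixels = np.zeros(k, dtype=np.int64)
    npv = np.full(k, np.nan)
    sd = np.full(k, np.nan)
    for i, (lo, hi) in enumerate(spec.bands):
        sel = v[(v >= lo) & (v <= hi)]
        n_pixels[i] = sel.size
        if sel.size:
            npv[i] = sel.mean()
            sd[i] = sel.std(ddof=ddof) if sel.size > ddof else 0.0
    ei_percent = 100.0 * n_pixels / v.size
    return BandStats(spec, n_pixels, ei_percent, npv, sd)


def range_mean(sample: PixelSample, lo: int, hi: int) -> float:
    """Mean of sample values in the inclusive range [lo, hi]; NaN if none.

    This is the quantity the range search maximizes correlations over:
    the subject's NPV restricted to one intensity interval.
    """
    if lo > hi:
        raise EchorangeError(f"invalid range: lo {lo} > hi {hi}")
    if not (0 <= lo and hi <= sample.L):
        raise EchorangeError(f"range [{lo}, {hi}] outside [0, {sample.L}]")
    v = sample.values
    sel = v[(v >= lo) & (v <= hi)]
    return float(sel.mean()) if sel.size else float("nan")


def cohort_band_table(cohort: SubjectCohort, spec: BandSpec, ddof: int = 0) -> pd.DataFrame:
    """One row per subject x band: n, EI%, NPV, SD (NaN for empty bands)."""
    frames = []
    for subj in cohort:
        df = band_stats(subj.sample, spec, ddof=ddof).to_frame()
        df.insert(0, "subject_id", subj.subject_id)
        df.insert(1, "group", subj.group)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
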