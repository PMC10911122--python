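"""Synthetic speckle-image cohorts with a planted intensity-range signal.

Emulates a two-group small-animal imaging study: ``n_subjects`` subjects
(default 12, split 6 "sham" / 6 "surgery"), one speckle image and one
polygonal ROI each, and a table of per-subject output variables (markers,
mimicking densitometric protein expression). A contiguous intensity range
is *planted*: the values of pixels falling in that range are redrawn so
their mean tracks a per-subject latent severity, and the subject's
in-range mean NPV carries the latent; coupled markers are then linear in
the realized in-range mean plus calibrated noise, which pins their
population Pearson correlation with it at the ``coupling`` target exactly.
Null markers are independent of the images. The "surgery" group gets an
additive latent shift (``group_effect``), so group contrast appears in the
planted range's NPV and in the coupled markers, but is diluted to
invisibility inside wide echointensity bands — the contrast the range
search is designed to recover.

The speckle background is gamma-distributed intensity (shape 4, scale 16
by default), rounded and clipped to [0, L]; a crude but standard
stand-in for the heavy-tailed brightness histogram of B-mode speckle.
Each subject's gamma shape and scale are jittered around the defaults,
because real muscles differ in overall echogenicity independently of any
planted signal — without that between-subject heterogeneity, every
interval containing the planted range would have a mean that is an affine
function of the planted mean and hence an identical Pearson correlation,
and no search could localize the signal. The signal itself is planted by
*redrawing* the values of in-range pixels (counts untouched) from a
truncated normal whose center tracks the latent severity: range NPV
carries the signal while in-range pixel fraction (EI%) and SD do not,
which is exactly the study-design contrast the toolkit must detect.
All randomness flows from one seed through named substreams so images,
markers and noise can be regenerated independently.

Generated frames live directly on the post-normalization 0-255 scale; two
anchor pixels (one black, one white) in the top corners — outside every
default ROI — pin the dynamic range so min-max normalization leaves the
frames unchanged when they pass through the full pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .cohort import PixelSample, SubjectCohort
from .errors import InfeasibleParamsError
from .imagio import RoiPolygon, extract_sample, rasterize_roi

__all__ = [
    "SynthParams",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "save_ground_truth",
    "load_ground_truth",
]

_SUBSTREAMS = ("images", "latent", "markers", "noise")


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic cohort generator.

    n_subjects:
        Even, >= 4; the first half is labelled ``sham``, the second
        ``surgery``.
    image_size:
        (height, width) of each speckle image; the default with the
        default octagonal ROI yields ~8,800 ROI pixels per subject.
    gamma_shape, gamma_scale:
        Speckle background intensity ~ Gamma(shape, scale), rounded and
        clipped to [0, L].
    planted_range:
        Inclusive interval [lo, hi] carrying the planted signal.
    coupling:
        Target Pearson correlation in [0, 1] between each coupled marker
        and the subject's realized in-range mean. 1 means exactly affine.
    group_effect:
        Additive shift (in latent SD units) applied to the latent severity
        of surgery subjects; propagates into in-range NPV and coupled
        markers.
    background_jitter:
        SD of the per-subject log-jitter on the gamma shape and scale:
        between-subject echogenicity heterogeneity independent of the
        planted signal.
    plant_amplitude:
        Fraction of the planted range's half-width the in-range mean
        traverses as tanh(latent / 2) goes from -1 to 1.
    plant_spread:
        SD of the redrawn in-range values as a fraction of the half-width.
    spread_jitter:
        SD of the per-subject log-jitter on ``plant_spread``. The redraws
        are recentered so the whole-range mean stays pinned to the latent
        target, but strip-level masses and means inside the range vary
        with the jittered spread — so only the full planted range, not
        its narrow sub-strips, is deterministically tied to the latent.
    distractor_ranges:
        Additional intensity ranges, disjoint from the planted one, whose
        NPV varies between subjects through independent latents with *no*
        group effect and *no* marker coupling — stand-ins for the many
        biological sources of echotexture variation (septa, fascicle
        brightness) that a real muscle carries besides the signal.
    coupled_markers, null_markers:
        Marker names; null markers are drawn independently of the images.
    marker_cv:
        Coefficient of variation of marker values around their baseline.
    """

    n_subjects: int = 12
    image_size: tuple[int, int] = (110, 110)
    gamma_shape: float = 4.0
    gamma_scale: float = 16.0
    planted_range: tuple[int, int] = (86, 101)
    coupling: float = 0.9
    group_effect: float = 4.0
    background_jitter: float = 0.2
    plant_amplitude: float = 0.15
    plant_spread: float = 0.35
    spread_jitter: float = 0.5
    distractor_ranges: tuple[tuple[int, int], ...] = ((20, 40), (130, 160))
    coupled_markers: tuple[str, ...] = ("CaMKII", "ERK12", "SubstanceP")
    null_markers: tuple[str, ...] = ("CGRP", "PAR2")
    marker_cv: float = 0.4
    L: int = 255
    seed: int = 0
    roi_margin: float = 4.5
    roi_corner_cut: float = 25.0

    def __post_init__(self) -> None:
        if self.n_subjects < 4 or self.n_subjects % 2:
            raise ValueError("n_subjects must be even and >= 4")
        lo, hi = self.planted_range
        if not (0 <= lo <= hi <= self.L):
            raise ValueError("planted_range must lie within [0, L]")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must be in [0, 1]")
        for dlo, dhi in self.distractor_ranges:
            if not (0 <= dlo <= dhi <= self.L):
                raise ValueError("distractor range outside [0, L]")
            if dlo <= hi and lo <= dhi:
                raise ValueError("distractor ranges must not overlap the planted range")


@dataclass(frozen=True)
class GroundTruth:
    """Exactly what the generator planted, for downstream scoring."""

    planted_range: tuple[int, int]
    latent: dict[str, float]
    in_range_means: dict[str, float]
    coupled_markers: tuple[str, ...]
    null_markers: tuple[str, ...]
    realized_coupling: dict[str, float]


@dataclass(frozen=True)
class SyntheticCohort:
    """Bundle of everything one generator run produced."""

    cohort: SubjectCohort
    images: dict[str, np.ndarray]
    rois: dict[str, RoiPolygon]
    truth: GroundTruth
    params: SynthParams


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def _default_roi(height: int, width: int, margin: float, cut: float) -> RoiPolygon:
    """Octagonal ROI: image rectangle with the four corners cut off."""
    m = margin
    # keep the octagon well-formed on small images
    c = min(cut, (min(height, width) - 1 - 2 * margin) / 3.0)
    w, h = width - 1, height - 1
    return RoiPolygon(
        (
            (m + c, m),
            (w - m - c, m),
            (w - m, m + c),
            (w - m, h - m - c),
            (w - m - c, h - m),
            (m + c, h - m),
            (m, h - m - c),
            (m, m + c),
        )
    )


def generate_cohort(params: SynthParams | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort.

    Raises
    ------
    InfeasibleParamsError
        If the background model places no pixel of some subject inside
        the planted range, so no signal can be planted there.
    """
    params = params or SynthParams()
    if seed is not None:
        params = SynthParams(**{**asdict(params), "seed": seed})
    rngs = _substreams(params.seed)
    h, w = params.image_size
    lo, hi = params.planted_range
    n = params.n_subjects
    half = n // 2
    groups = ["sham"] * half + ["surgery"] * half
    ids = [f"S{i+1:02d}" for i in range(n)]

    # latent severity: standard normal + group shift (surgery)
    latent = rngs["latent"].standard_normal(n)
    latent[half:] += params.group_effect

    roi = _default_roi(h, w, params.roi_margin, params.roi_corner_cut)
    mask = rasterize_roi(roi, w, h)

    images: dict[str, np.ndarray] = {}
    rois: dict[str, RoiPolygon] = {}
    samples: list[PixelSample] = []
    in_range_means = np.empty(n)
    img_rng = rngs["images"]

    def _redraw(flat: np.ndarray, rlo: int, rhi: int, z: float,
                sid: str, required: bool) -> None:
        """Redraw in-range pixel values so their mean tracks latent z."""
        half_width = (rhi - rlo) / 2.0
        center = (rlo + rhi) / 2.0
        in_rng = (flat >= rlo) & (flat <= rhi)
        n_in = int(in_rng.sum())
        if n_in == 0:
            if required:
                raise InfeasibleParamsError(
                    f"subject {sid}: background model put no pixel in "
                    f"planted range [{rlo}, {rhi}]"
                )
            return
        mu = center + params.plant_amplitude * half_width * np.tanh(z / 2.0)
        sigma = (params.plant_spread * half_width
                 * np.exp(params.spread_jitter * img_rng.standard_normal()))
        draws = img_rng.normal(mu, sigma, size=n_in)
        draws += mu - draws.mean()  # pin the whole-range mean to the target
        flat[np.flatnonzero(in_rng)] = np.clip(
            np.floor(draws + 0.5), rlo, rhi).astype(np.int64)

    for i, sid in enumerate(ids):
        # per-subject echogenicity: jittered gamma shape and scale
        shape_s = params.gamma_shape * np.exp(
            params.background_jitter * img_rng.standard_normal())
        scale_s = params.gamma_scale * np.exp(
            params.background_jitter * img_rng.standard_normal())
        base = img_rng.gamma(shape_s, scale_s, size=(h, w))
        flat = np.clip(np.floor(base + 0.5), 0, params.L).astype(np.int64).ravel()
        # plant the signal: redraw in-range pixel values (counts untouched)
        # from a normal whose center tracks the latent severity
        _redraw(flat, lo, hi, latent[i], sid, required=True)
        # distractor structure: group-free, marker-free latent directions
        for dlo, dhi in params.distractor_ranges:
            _redraw(flat, dlo, dhi, img_rng.standard_normal(), sid, required=False)
        img = flat.reshape(h, w).astype(np.uint8)
        # anchor the dynamic range in a corner outside the ROI so that
        # min-max normalization is the identity on these frames (they are
        # generated directly on the post-normalization 0-255 scale)
        img[0, 0], img[0, -1] = 0, params.L
        images[sid] = img
        rois[sid] = roi
        sample = extract_sample(img, mask, subject_id=sid, L=params.L)
        samples.append(sample)
        v = sample.values
        sel = v[(v >= lo) & (v <= hi)]
        if sel.size == 0:
            raise InfeasibleParamsError(
                f"subject {sid}: ROI contains no pixel in planted range "
                f"[{lo}, {hi}]"
            )
        in_range_means[i] = sel.mean()

    # markers: coupled = baseline * (1 + cv * (rho*m_std + sqrt(1-rho^2)*eps))
    m = in_range_means
    m_std = (m - m.mean()) / m.std(ddof=0)
    rho = params.coupling
    outputs: list[dict[str, float]] = [dict() for _ in range(n)]
    realized: dict[str, float] = {}
    mk_rng, nz_rng = rngs["markers"], rngs["noise"]
    for name in params.coupled_markers:
        baseline = float(np.exp(mk_rng.normal(0.0, 0.25)))
        eps = nz_rng.standard_normal(n)
        g = rho * m_std + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        # floor keeps rare deep-noise draws from going nonpositive
        # (expression values are positive); never reached when coupling = 1
        vals = np.maximum(baseline * (1.0 + params.marker_cv * g),
                          0.02 * baseline)
        for i in range(n):
            outputs[i][name] = float(vals[i])
        realized[name] = float(np.corrcoef(vals, m)[0, 1])
    for name in params.null_markers:
        baseline = float(np.exp(mk_rng.normal(0.0, 0.25)))
        vals = baseline * np.exp(mk_rng.normal(0.0, params.marker_cv, size=n))
        for i in range(n):
            outputs[i][name] = float(vals[i])
        realized[name] = float(np.corrcoef(vals, m)[0, 1])

    cohort = SubjectCohort.from_samples(samples, groups, outputs)
    truth = GroundTruth(
        planted_range=(lo, hi),
        latent={sid: float(z) for sid, z in zip(ids, latent)},
        in_range_means={sid: float(v) for sid, v in zip(ids, in_range_means)},
        coupled_markers=tuple(params.coupled_markers),
        null_markers=tuple(params.null_markers),
        realized_coupling=realized,
    )
    return SyntheticCohort(cohort, images, rois, truth, params)


def generate_null_cohort(params: SynthParams | None = None,
                         seed: int | None = None) -> SyntheticCohort:
    """Same generator with every marker decoupled from the images.

    All couplings are forced to zero (every marker drawn independently of
    pixel content); used for calibrating selection-adjusted inference.
    """
    params = params or SynthParams()
    null_params = SynthParams(**{
        **asdict(params),
        "coupling": 0.0,
        # with zero coupling the planted shift is still applied through the
        # latent; callers wanting a fully signal-free image set group_effect=0
    })
    if seed is not None:
        null_params = SynthParams(**{**asdict(null_params), "seed": seed})
    return generate_cohort(null_params)


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        planted_range=tuple(d["planted_range"]),
        latent=dict(d["latent"]),
        in_range_means=dict(d["in_range_means"]),
        coupled_markers=tuple(d["coupled_markers"]),
        null_markers=tuple(d["null_markers"]),
        realized_coupling=dict(d["realized_coupling"]),
    )
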