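"""End-to-end orchestration: normalize -> ROI stats -> bands -> search.

:func:`run_pipeline` reproduces the full analysis workflow on a directory
of images, ROI polygons and a cohort table, writing the standard report
bundle: whole-ROI first-order statistics, per-band tables with group
comparisons, band-vs-marker correlation tables, a per-marker range-search
result with naive and selection-adjusted p-values plus group comparisons
of range NPV/EI%/SD, threshold-map overlays, and a run manifest.

Missing statistics propagate as empty CSV cells, never zeros. Every cell
is reproducible by calling the underlying module function directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SubjectCohort
from .echotexture import (
    BANDS25,
    BANDS50,
    BandSpec,
    cohort_band_table,
    whole_roi_stats,
)
from .errors import EchorangeError, UndefinedCorrelationError, DegenerateTestError
from .imagio import (
    extract_sample,
    load_roi,
    normalize_image,
    rasterize_roi,
    read_image,
    write_image,
)
from .rangesearch import (
    RangeConstraints,
    overlay_rgb,
    search_best_range,
    threshold_map,
)
from .stats import max_r_permutation_test, pearson, student_t_test

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "load_config"]

log = logging.getLogger("echorange")

_PRESETS = {"bands50": BANDS50, "bands25": BANDS25}


@dataclass
class PipelineConfig:
    """Paths and knobs of one full analysis run."""

    images_dir: str
    rois_dir: str
    cohort_csv: str
    out_dir: str
    normalize_T: int = 255
    global_minmax: bool = False
    band_presets: tuple[str, ...] = ("bands50", "bands25")
    custom_bands: tuple[tuple[int, int], ...] | None = None
    min_pixels_per_subject: int = 1
    min_width: int = 1
    strict_ranges: bool = False
    n_perm: int = 999
    seed: int = 0
    group_a: str = "sham"
    group_b: str = "surgery"


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "band_presets" in raw:
        raw["band_presets"] = tuple(raw["band_presets"])
    if raw.get("custom_bands"):
        raw["custom_bands"] = tuple(tuple(b) for b in raw["custom_bands"])
    return PipelineConfig(**raw)


def _image_path(images_dir: Path, sid: str) -> Path | None:
    for ext in (".png", ".tif", ".tiff"):
        p = images_dir / f"{sid}{ext}"
        if p.exists():
            return p
    return None


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Check file presence, bit depth, ROI containment and ID agreement.

    Returns a list of human-readable problems; empty means all clear.
    """
    problems: list[str] = []
    images_dir = Path(config.images_dir)
    rois_dir = Path(config.rois_dir)
    cohort_csv = Path(config.cohort_csv)
    if not cohort_csv.exists():
        return [f"cohort table not found: {cohort_csv}"]
    table = pd.read_csv(cohort_csv)
    if "subject_id" not in table.columns or "group" not in table.columns:
        return ["cohort table must have subject_id and group columns"]
    markers = [c for c in table.columns if c not in ("subject_id", "group")]
    for sid in table["subject_id"].astype(str):
        img_path = _image_path(images_dir, sid)
        if img_path is None:
            problems.append(f"subject {sid}: no image in {images_dir}")
            continue
        roi_path = rois_dir / f"{sid}.json"
        if not roi_path.exists():
            problems.append(f"subject {sid}: no ROI file {roi_path}")
            continue
        try:
            img = read_image(img_path)
            poly = load_roi(roi_path)
            rasterize_roi(poly, img.shape[1], img.shape[0])
        except EchorangeError as exc:
            problems.append(f"subject {sid}: {exc}")
    for m in markers:
        vals = pd.to_numeric(table[m], errors="coerce")
        if vals.nunique(dropna=True) <= 1:
            problems.append(f"marker {m}: constant or non-numeric values")
    return problems


def load_cohort_from_files(config: PipelineConfig) -> SubjectCohort:
    """Read images + ROIs + cohort table into a SubjectCohort.

    Pipeline order: convert to grayscale -> min-max normalize -> mask.
    With ``global_minmax`` the normalization extremes are taken over all
    images of the cohort instead of per image.
    """
    table = pd.read_csv(config.cohort_csv)
    images_dir = Path(config.images_dir)
    rois_dir = Path(config.rois_dir)
    raws, sids, groups, outputs = [], [], [], []
    markers = [c for c in table.columns if c not in ("subject_id", "group")]
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        img_path = _image_path(images_dir, sid)
        if img_path is None:
            raise EchorangeError(f"no image for subject {sid}")
        raws.append(read_image(img_path))
        sids.append(sid)
        groups.append(str(row["group"]))
        outputs.append({m: float(row[m]) for m in markers})

    fmin = fmax = None
    if config.global_minmax:
        fmin = min(int(r.min()) for r in raws)
        fmax = max(int(r.max()) for r in raws)
    samples = []
    for sid, raw in zip(sids, raws):
        norm = normalize_image(raw, config.normalize_T, f_min=fmin, f_max=fmax)
        poly = load_roi(rois_dir / f"{sid}.json")
        mask = rasterize_roi(poly, norm.shape[1], norm.shape[0])
        samples.append(extract_sample(norm, mask, subject_id=sid))
    return SubjectCohort.from_samples(samples, groups, outputs)


def _band_specs(config: PipelineConfig) -> dict[str, BandSpec]:
    specs = {name: _PRESETS[name] for name in config.band_presets}
    if config.custom_bands:
        specs["custom"] = BandSpec(tuple(config.custom_bands))
    return specs


def _group_rows(cohort, values: dict[str, float], ga: str, gb: str):
    """Split a per-subject value dict into the two group vectors."""
    a = [values[s.subject_id] for s in cohort
         if s.group == ga and s.subject_id in values
         and not np.isnan(values[s.subject_id])]
    b = [values[s.subject_id] for s in cohort
         if s.group == gb and s.subject_id in values
         and not np.isnan(values[s.subject_id])]
    return np.asarray(a), np.asarray(b)


def band_group_comparisons(cohort: SubjectCohort, spec: BandSpec,
                           ga: str, gb: str) -> pd.DataFrame:
    """Per band x variable (EI%, NPV, SD): group means +/- SEM, t, p."""
    table = cohort_band_table(cohort, spec)
    rows = []
    for (lo, hi), sub in table.groupby(["band_lo", "band_hi"], sort=True):
        for var in ("ei_percent", "npv", "sd"):
            vals = dict(zip(sub["subject_id"], sub[var]))
            a, b = _group_rows(cohort, vals, ga, gb)
            row = {"band_lo": lo, "band_hi": hi, "variable": var,
                   "n_a": len(a), "n_b": len(b)}
            try:
                cmp = student_t_test(a, b)
                row.update(mean_a=cmp.mean_a, mean_b=cmp.mean_b,
                           sem_a=cmp.sem_a, sem_b=cmp.sem_b,
                           t=cmp.t_statistic, p=cmp.p_two_tailed)
            except DegenerateTestError:
                pass
            rows.append(row)
    return pd.DataFrame(rows)


def band_marker_correlations(cohort: SubjectCohort, spec: BandSpec) -> pd.DataFrame:
    """Marker x band x variable Pearson correlations (pooled groups).

    Subjects missing a band are excluded pairwise; cells with fewer than
    3 complete pairs stay empty. No multiplicity correction is applied to
    these per-band tables; the selection-adjusted permutation p of the
    range search is the corrected quantity.
    """
    table = cohort_band_table(cohort, spec)
    rows = []
    for marker in cohort.marker_names:
        y = dict(zip(cohort.subject_ids, cohort.marker_values(marker)))
        for (lo, hi), sub in table.groupby(["band_lo", "band_hi"], sort=True):
            for var in ("ei_percent", "npv", "sd"):
                pairs = [
                    (v, y[s]) for s, v in zip(sub["subject_id"], sub[var])
                    if not (np.isnan(v) or np.isnan(y[s]))
                ]
                row = {"marker": marker, "band_lo": lo, "band_hi": hi,
                       "variable": var, "n": len(pairs)}
                if len(pairs) >= 3:
                    x, yy = map(np.asarray, zip(*pairs))
                    try:
                        res = pearson(x, yy)
                        row.update(r=res.r, p=res.p_two_tailed)
                    except UndefinedCorrelationError:
                        pass
                rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, cohort: SubjectCohort | None = None,
                 images: dict[str, np.ndarray] | None = None,
                 masks: dict[str, np.ndarray] | None = None) -> dict[str, Path]:
    """Run the full workflow and write the report bundle to ``out_dir``.

    A pre-built cohort (e.g. from the synthetic generator) can be passed
    directly; otherwise images/ROIs/table are loaded from the configured
    paths. Returns a name -> path map of everything written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    ga, gb = config.group_a, config.group_b

    if cohort is None:
        log.info("loading cohort from %s", config.cohort_csv)
        cohort = load_cohort_from_files(config)
    log.info("cohort: %d subjects, %d markers, %d pixels total",
             len(cohort), len(cohort.marker_names),
             sum(s.sample.n for s in cohort))

    # (a) whole-ROI first-order stats
    rows = []
    for s in cohort:
        st = whole_roi_stats(s.sample)
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "mean": st.mean, "sd": st.sd, "min": st.min,
                     "max": st.max, "n": st.n})
    _write_csv(pd.DataFrame(rows), out / "whole_roi_stats.csv", written)

    # (b) band tables + group comparisons, (c) band-marker correlations
    for name, spec in _band_specs(config).items():
        _write_csv(cohort_band_table(cohort, spec),
                   out / f"band_table_{name}.csv", written)
        _write_csv(band_group_comparisons(cohort, spec, ga, gb),
                   out / f"band_group_comparison_{name}.csv", written)
        _write_csv(band_marker_correlations(cohort, spec),
                   out / f"band_marker_correlation_{name}.csv", written)

    # (d) per-marker range search + permutation p + group comparison
    constraints = RangeConstraints(
        min_pixels_per_subject=config.min_pixels_per_subject,
        min_width=config.min_width,
        strict=config.strict_ranges,
    )
    search_rows, mean_rows, cmp_rows = [], [], []
    results = {}
    for k, marker in enumerate(cohort.marker_names):
        log.info("range search: marker %s", marker)
        res = search_best_range(cohort, marker, constraints)
        perm = max_r_permutation_test(
            cohort, marker, n_perm=config.n_perm,
            seed=np.random.SeedSequence([config.seed, k]).generate_state(1)[0] % (2**31),
            constraints=constraints,
        )
        results[marker] = res
        search_rows.append({
            "marker": marker, "lo": res.lo, "hi": res.hi, "r": res.r,
            "p_naive": res.p_naive, "p_fwe": perm.p_fwe,
            "n_subjects": res.n_subjects_used,
            "n_ranges_evaluated": res.n_ranges_evaluated,
            "n_ties": len(res.ties),
        })
        for sid, m in res.per_subject_means.items():
            mean_rows.append({"marker": marker, "subject_id": sid,
                              "range_lo": res.lo, "range_hi": res.hi,
                              "npv": m,
                              "ei_percent": res.per_subject_ei_percent[sid],
                              "sd": res.per_subject_sd[sid]})
        for var, vals in (("npv", res.per_subject_means),
                          ("ei_percent", res.per_subject_ei_percent),
                          ("sd", res.per_subject_sd)):
            a, b = _group_rows(cohort, vals, ga, gb)
            row = {"marker": marker, "lo": res.lo, "hi": res.hi,
                   "variable": var, "n_a": len(a), "n_b": len(b)}
            try:
                cmp = student_t_test(a, b)
                row.update(mean_a=cmp.mean_a, mean_b=cmp.mean_b,
                           sem_a=cmp.sem_a, sem_b=cmp.sem_b,
                           t=cmp.t_statistic, p=cmp.p_two_tailed)
            except DegenerateTestError:
                pass
            cmp_rows.append(row)
    _write_csv(pd.DataFrame(search_rows), out / "range_search.csv", written)
    _write_csv(pd.DataFrame(mean_rows), out / "range_subject_means.csv", written)
    _write_csv(pd.DataFrame(cmp_rows), out / "range_group_comparison.csv", written)

    # (e) threshold-map overlays (when pixel-level data are available)
    if images is not None and masks is not None:
        overlays = out / "overlays"
        overlays.mkdir(exist_ok=True)
        for marker, res in results.items():
            for sid, img in images.items():
                ov, _ = threshold_map(img, masks[sid], res.lo, res.hi)
                path = overlays / f"{marker}_{sid}.png"
                write_image(path, overlay_rgb(img, ov))
                written[f"overlay_{marker}_{sid}"] = path

    # (f) manifest
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "n_subjects": len(cohort),
        "markers": cohort.marker_names,
        "outputs": sorted(str(p.relative_to(out)) for p in written.values()),
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written["manifest"] = mpath
    return written


def _write_csv(df: pd.DataFrame, path: Path, written: dict[str, Path]) -> None:
    # empty string for missing cells, never zero
    df.to_csv(path, index=False, na_rep="")
    written[path.stem] = path
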