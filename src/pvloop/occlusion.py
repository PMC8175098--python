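"""Caval-occlusion beat families and the load-varying regressions.

A transient inferior-caval occlusion produces a family of beats at
decreasing preload.  Across that family, three linear relationships
summarise ventricular function:

* ESPVR — end-systolic pressure on end-systolic volume; slope Ees
  (end-systolic elastance, mmHg/ml), x-intercept V0 (ml);
* PRSW — stroke work on end-diastolic volume; slope in mmHg·ml/ml;
* EDPVR — end-diastolic pressure on end-diastolic volume; slope is a
  passive-stiffness index (mmHg/ml).

All three are ordinary least squares with volume as the regressor, the
conductance-laboratory convention.  Preprocessing drops the immediate
post-occlusion transient, guards against reflex contamination at deep
preload reduction, and enforces a monotonically falling EDV sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import Beat, analyze_trace, locate_landmarks, beat_summary
from .trace import PVTrace

__all__ = [
    "LinearFit",
    "OcclusionSeries",
    "OcclusionError",
    "preprocess_series",
    "fit_espvr",
    "fit_prsw",
    "fit_edpvr",
    "fit_occlusion",
    "OcclusionFits",
]

#: Minimum usable beats in a series.
MIN_BEATS = 5
#: Relative EDV span below which a series is flagged as low-range
#: (fits are still produced but carry little preload variation).
LOW_RANGE_FRAC = 0.05


class OcclusionError(ValueError):
    """The beat family cannot support an occlusion fit."""


@dataclass
class LinearFit:
    """An OLS line y = slope*x + intercept over an occlusion family."""

    slope: float
    intercept: float
    r2: float
    n_points: int

    @property
    def x_intercept(self) -> float:
        """-intercept/slope; NaN when the slope is zero (for the ESPVR this
        is V0, the volume-axis intercept)."""
        if self.slope == 0:
            return float("nan")
        return -self.intercept / self.slope


@dataclass
class OcclusionSeries:
    """Ordered, preprocessed beats under preload reduction."""

    beats: list
    ventricle: str = "RV"
    source_stage: str = ""
    low_range: bool = False

    def __len__(self) -> int:
        return len(self.beats)


def preprocess_series(beats: list, ventricle: str = "RV",
                      source_stage: str = "", drop_initial: int = 2,
                      edv_floor_frac: float = 0.60) -> OcclusionSeries:
    """Select usable occlusion beats.

    Drops the first ``drop_initial`` beats (occlusion-onset transient),
    truncates once EDV falls below ``edv_floor_frac`` of the first retained
    beat's EDV (reflex-contamination guard), then applies a monotone filter
    so the retained EDV sequence is strictly decreasing.  A family whose
    total EDV excursion is below 5% of its starting EDV (e.g. steady-state
    beats with no occlusion) skips the monotone filter and is flagged
    ``low_range`` instead.
    """
    if len(beats) < MIN_BEATS:
        raise OcclusionError(
            f"insufficient occlusion beats: {len(beats)} < {MIN_BEATS}")
    kept = beats[drop_initial:]
    if not kept:
        raise OcclusionError("insufficient occlusion beats after transient drop")
    edv0 = kept[0].EDV
    out = []
    for b in kept:
        if b.EDV < edv_floor_frac * edv0:
            break
        out.append(b)
    span = (edv0 - min(b.EDV for b in out)) if out else 0.0
    low_range = edv0 <= 0 or span < LOW_RANGE_FRAC * edv0
    if not low_range:
        out = _longest_decreasing(out)
    if len(out) < MIN_BEATS:
        raise OcclusionError(
            f"insufficient occlusion beats: {len(out)} survive preprocessing")
    return OcclusionSeries(beats=out, ventricle=ventricle,
                           source_stage=source_stage, low_range=low_range)


def _longest_decreasing(beats: list) -> list:
    """Longest strictly-decreasing-EDV subsequence (order preserved).

    More noise-tolerant than a greedy pass: a single upward EDV blip does
    not discard the rest of the ramp.
    """
    n = len(beats)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(1, n):
        for j in range(i):
            if beats[i].EDV < beats[j].EDV and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    i = int(np.argmax(best_len))
    out = []
    while i >= 0:
        out.append(beats[i])
        i = prev[i]
    return out[::-1]


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < MIN_BEATS:
        raise OcclusionError(f"need >= {MIN_BEATS} points, got {x.size}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise OcclusionError("degenerate fit: zero variance in regressor")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    syy = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if syy == 0 else float(1.0 - np.sum(resid ** 2) / syy)
    return LinearFit(slope=slope, intercept=intercept,
                     r2=max(0.0, min(1.0, r2)), n_points=int(x.size))


def fit_espvr(series: OcclusionSeries) -> LinearFit:
    """ESPVR: ESP regressed on ESV; slope = Ees, x-intercept = V0."""
    return _ols([b.ESV for b in series.beats], [b.ESP for b in series.beats])


def fit_prsw(series: OcclusionSeries) -> LinearFit:
    """PRSW: stroke work regressed on EDV; slope in mmHg·ml/ml."""
    return _ols([b.EDV for b in series.beats], [b.SW for b in series.beats])


def fit_edpvr(series: OcclusionSeries) -> LinearFit:
    """EDPVR: EDP regressed on EDV; slope is the stiffness index."""
    return _ols([b.EDV for b in series.beats], [b.EDP for b in series.beats])


@dataclass
class OcclusionFits:
    """The three regressions plus the series they were fitted on."""

    espvr: LinearFit
    prsw: LinearFit
    edpvr: LinearFit
    series: OcclusionSeries

    def as_dict(self) -> dict:
        def fd(f: LinearFit) -> dict:
            return {"slope": f.slope, "intercept": f.intercept,
                    "v0": f.x_intercept, "r2": f.r2, "n": f.n_points}

        return {"espvr": fd(self.espvr), "prsw": fd(self.prsw),
                "edpvr": fd(self.edpvr), "low_range": self.series.low_range}


def fit_occlusion(trace: PVTrace, threshold_frac: float = 0.10,
                  smooth_window: int | None = None,
                  refine_v0: bool = True) -> OcclusionFits:
    """Full occlusion analysis of one trace.

    Segments the trace, locates landmarks with ``V0_ref = 0``, fits the
    ESPVR, and (by default) refines once: end-systole is re-located with
    ``V0_ref`` set to the fitted volume intercept and the regressions are
    re-fitted.  Refinement is skipped when the fitted intercept is not
    safely below the smallest volume in the trace.
    """
    beats = analyze_trace(trace, threshold_frac=threshold_frac,
                          smooth_window=smooth_window)
    series = preprocess_series(beats, ventricle=trace.ventricle,
                               source_stage=trace.stage_label)
    espvr = fit_espvr(series)
    if refine_v0 and np.isfinite(espvr.x_intercept):
        v0 = espvr.x_intercept
        vmin = float(trace.volume.min())
        if v0 < vmin - 1.0:
            for b in series.beats:
                locate_landmarks(b, trace, V0_ref=v0)
                beat_summary(b, trace, smooth_window=smooth_window)
            espvr = fit_espvr(series)
    return OcclusionFits(espvr=espvr, prsw=fit_prsw(series),
                         edpvr=fit_edpvr(series), series=series)
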