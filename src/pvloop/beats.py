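"""Beat segmentation and per-beat pressure-volume indices.

Cycle boundaries are placed at the onset of isovolumic contraction: the
last sample before dP/dt rises above a fraction (default 10%) of the
global dP/dt maximum.  End-systole is located as the maximum of the
instantaneous pressure/volume ratio P/(V - V0_ref) — the standard
conductance-laboratory convention, consistent with a time-varying
elastance model of the ventricle — with ``V0_ref = 0`` by default and an
optional refinement from a previously fitted ESPVR intercept.

Per-beat indices: pressures (EDP, ESP, Pmax, Pmin, time-averaged Pmean),
volumes (EDV, ESV), dP/dt extrema, stroke work (shoelace loop area),
ejection fraction, heart rate and the isovolumic relaxation constant tau
by the Weiss method (log-linear fit of pressure decay from the dP/dt
minimum to recovery of end-diastolic pressure, zero asymptote).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .trace import PVTrace

__all__ = [
    "Beat",
    "BeatError",
    "TauUndefinedError",
    "derivative",
    "segment_beats",
    "locate_landmarks",
    "tau_weiss",
    "stroke_work",
    "beat_summary",
    "analyze_trace",
    "beats_to_frame",
]


class BeatError(ValueError):
    """Segmentation or landmark detection failed."""


class TauUndefinedError(ValueError):
    """The Weiss tau could not be computed for this beat."""


@dataclass
class Beat:
    """One cardiac cycle with landmarks and indices.

    Sample indices are absolute into the parent trace; ``start_idx`` /
    ``end_idx`` bound the half-open window ``[start_idx, end_idx)``.
    ``tau`` is NaN when the Weiss fit is undefined for the beat (the
    ``tau_flag`` then carries the reason).
    """

    start_idx: int
    ed_idx: int
    es_idx: int
    end_idx: int
    EDP: float = math.nan
    ESP: float = math.nan
    Pmax: float = math.nan
    Pmin: float = math.nan
    Pmean: float = math.nan
    EDV: float = math.nan
    ESV: float = math.nan
    dPdt_max: float = math.nan
    dPdt_min: float = math.nan
    tau: float = math.nan
    tau_flag: str = ""
    SW: float = math.nan
    EF: float = math.nan
    HR: float = math.nan

    @property
    def SV(self) -> float:
        return self.EDV - self.ESV


def derivative(trace: PVTrace, smooth_window: int | None = None) -> np.ndarray:
    """dP/dt in mmHg/s: central differences interior, one-sided at the ends.

    ``smooth_window`` switches to a Savitzky–Golay derivative (cubic, odd
    window length in samples) — needed before threshold-based segmentation
    on noisy recordings, off by default for reproducibility.
    """
    if len(trace) < 3:
        raise BeatError("trace shorter than 3 samples")
    if smooth_window is not None:
        if smooth_window % 2 == 0 or smooth_window < 5:
            raise ValueError("smooth_window must be odd and >= 5")
        return savgol_filter(trace.pressure, smooth_window, 3, deriv=1,
                             delta=trace.dt)
    return np.gradient(trace.pressure, trace.dt)


def segment_beats(trace: PVTrace, threshold_frac: float = 0.10,
                  smooth_window: int | None = None,
                  min_period_s: float = 0.2,
                  confirm_frac: float = 0.5) -> list[Beat]:
    """Split a trace into complete cardiac cycles.

    Systolic upstrokes are identified as dP/dt peaks of at least
    ``confirm_frac`` x the global dP/dt maximum, pruned to a
    quasi-periodic train (of any two peaks closer than 60% of the median
    inter-peak spacing, the weaker is dropped — this rejects the
    rapid-filling wave and noise spikes).  Each beat boundary is then the
    last sample before dP/dt rises above ``threshold_frac`` x the global
    maximum ahead of its systolic peak: the onset of isovolumic
    contraction, i.e. end-diastole.  Partial first/last cycles are
    discarded: k systolic peaks yield k-1 complete beats.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    dpdt = derivative(trace, smooth_window=smooth_window)
    peak = dpdt.max()
    if peak <= 0:
        raise BeatError("no beats detected: dP/dt never positive")
    thr = threshold_frac * peak
    from scipy.signal import find_peaks

    min_gap = max(1, int(round(min_period_s * trace.sampling_rate)))
    cand, props = find_peaks(dpdt, height=confirm_frac * peak)
    if cand.size == 0:
        raise BeatError("no beats detected: no confirmed systolic upstroke")
    heights = props["peak_heights"]
    # enforce quasi-periodicity: repeatedly drop the weaker of any peak pair
    # closer than 60% of the median inter-peak gap (guards against the
    # rapid-filling wave, which can rival a weak chamber's systolic dP/dt)
    cand = list(cand)
    heights = list(heights)
    while len(cand) > 2:
        gaps = np.diff(cand)
        floor = max(min_gap, 0.6 * np.median(gaps))
        short = np.flatnonzero(gaps < floor)
        if short.size == 0:
            break
        i = int(short[0])
        drop = i if heights[i] < heights[i + 1] else i + 1
        cand.pop(drop)
        heights.pop(drop)
    # boundary: last sample below the low threshold before each systolic peak
    kept = []
    for c in cand:
        i = int(c)
        while i > 0 and dpdt[i] > thr:
            i -= 1
        if not kept or i - kept[-1] >= min_gap:
            kept.append(i)
    if len(kept) < 2:
        raise BeatError("no beats detected: fewer than one complete cycle")
    return [Beat(start_idx=s, ed_idx=s, es_idx=-1, end_idx=e)
            for s, e in zip(kept[:-1], kept[1:])]


def locate_landmarks(beat: Beat, trace: PVTrace,
                     V0_ref: float = 0.0) -> tuple[int, int]:
    """Set ``ed_idx`` and ``es_idx`` on the beat and return them.

    End-diastole is the segment boundary; end-systole maximises
    P/(V - V0_ref) over the beat.  ``V0_ref`` defaults to 0 ml and can be
    refined with a fitted ESPVR volume intercept.
    """
    s, e = beat.start_idx, beat.end_idx
    p = trace.pressure[s:e]
    v = trace.volume[s:e]
    if np.any(v <= V0_ref):
        raise BeatError(
            f"volume below reference V0: min V {v.min():.2f} <= V0_ref {V0_ref:.2f}"
        )
    es = s + int(np.argmax(p / (v - V0_ref)))
    beat.ed_idx = s
    beat.es_idx = es
    beat.EDP = float(trace.pressure[s])
    beat.EDV = float(trace.volume[s])
    beat.ESP = float(trace.pressure[es])
    beat.ESV = float(trace.volume[es])
    return s, es


def tau_weiss(beat: Beat, trace: PVTrace, min_samples: int = 5) -> float:
    """Isovolumic relaxation constant (Weiss method), in ms.

    Least-squares line through (t, ln P) from the dP/dt minimum to the
    first subsequent sample with P <= EDP; tau = -1/slope.  The fit assumes
    pressure decays toward a zero asymptote; it tolerates noise (monotone
    decrease is not required) but raises :class:`TauUndefinedError` when
    the window is too short, contains non-positive pressure, or yields a
    non-decaying slope.
    """
    s, e = beat.start_idx, beat.end_idx
    p = trace.pressure[s:e]
    # anchor the window on a lightly smoothed derivative so a single noise
    # spike cannot hijack the dP/dt minimum; the regression below still
    # runs on the raw pressures
    if p.size >= 21:
        dpdt = savgol_filter(p, 21, 3, deriv=1, delta=trace.dt)
    else:
        dpdt = np.gradient(p, trace.dt)
    i0 = int(np.argmin(dpdt))
    edp = beat.EDP if np.isfinite(beat.EDP) else float(p[0])
    below = np.flatnonzero(p[i0:] <= edp)
    i1 = i0 + int(below[0]) + 1 if below.size else p.size
    win = p[i0:i1]
    if win.size < min_samples:
        raise TauUndefinedError(
            f"tau undefined: relaxation window has {win.size} samples "
            f"(< {min_samples})")
    if np.any(win <= 0):
        raise TauUndefinedError("tau undefined: non-positive pressure in window")
    t = np.arange(win.size) * trace.dt
    slope = np.polyfit(t, np.log(win), 1)[0]
    if slope >= 0:
        raise TauUndefinedError("tau undefined: pressure does not decay")
    return -1000.0 / slope


def stroke_work(beat: Beat, trace: PVTrace) -> float:
    """Stroke work in mmHg·ml: |shoelace integral| of the closed PV loop."""
    s, e = beat.start_idx, beat.end_idx
    p = trace.pressure[s:e]
    v = trace.volume[s:e]
    distinct = np.unique(np.column_stack([v, p]), axis=0)
    if distinct.shape[0] < 3:
        import warnings

        warnings.warn("degenerate PV loop (< 3 distinct vertices); SW = 0",
                      stacklevel=2)
        return 0.0
    # closed polygon: last vertex joins back to the first
    area2 = np.dot(v, np.roll(p, -1)) - np.dot(np.roll(v, -1), p)
    return abs(area2) / 2.0


def beat_summary(beat: Beat, trace: PVTrace,
                 smooth_window: int | None = None) -> Beat:
    """Populate every index of a located beat (in place) and return it.

    Pmean is the duration-weighted (i.e. sample) mean over the beat; EF is
    (EDV - ESV)/EDV; HR comes from the beat period.  A beat whose Weiss fit
    is undefined gets tau = NaN and a reason in ``tau_flag``.
    """
    if beat.es_idx < 0:
        locate_landmarks(beat, trace)
    s, e = beat.start_idx, beat.end_idx
    p = trace.pressure[s:e]
    beat.Pmax = float(p.max())
    beat.Pmin = float(p.min())
    beat.Pmean = float(p.mean())
    dpdt = derivative(trace.slice(s, e), smooth_window=smooth_window)
    beat.dPdt_max = float(dpdt.max())
    beat.dPdt_min = float(dpdt.min())
    beat.SW = stroke_work(beat, trace)
    if beat.EDV == 0:
        beat.EF = math.nan
    else:
        beat.EF = (beat.EDV - beat.ESV) / beat.EDV
    beat.HR = 60.0 / ((e - s) * trace.dt)
    try:
        beat.tau = tau_weiss(beat, trace)
        beat.tau_flag = ""
    except TauUndefinedError as exc:
        beat.tau = math.nan
        beat.tau_flag = str(exc)
    return beat


def analyze_trace(trace: PVTrace, threshold_frac: float = 0.10,
                  V0_ref: float = 0.0,
                  smooth_window: int | None = None) -> list[Beat]:
    """Segment a trace and return fully populated beats."""
    beats = segment_beats(trace, threshold_frac=threshold_frac,
                          smooth_window=smooth_window)
    for b in beats:
        locate_landmarks(b, trace, V0_ref=V0_ref)
        beat_summary(b, trace, smooth_window=smooth_window)
    return beats


def beats_to_frame(beats: list[Beat]):
    """Beats as a pandas DataFrame, one row per beat."""
    import pandas as pd

    cols = ["start_idx", "ed_idx", "es_idx", "end_idx", "EDP", "ESP", "Pmax",
            "Pmin", "Pmean", "EDV", "ESV", "dPdt_max", "dPdt_min", "tau",
            "tau_flag", "SW", "EF", "HR"]
    return pd.DataFrame([{c: getattr(b, c) for c in cols} for b in beats])
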