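"""Pressure-volume trace container and CSV round-trip.

A :class:`PVTrace` holds the uniformly sampled ventricular pressure and
volume waveforms for one ventricle at one protocol stage, the substrate for
beat segmentation and every downstream index.  Traces are exchanged on disk
as plain CSV with the header ``time_s,pressure_mmHg,volume_ml``; lines
starting with ``#`` carry provenance and are ignored on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PVTrace", "read_trace", "write_trace", "TraceFormatError"]

#: Allowed deviation of the time grid from a perfectly uniform 1/fs step, seconds.
TIME_GRID_TOL = 1e-9


class TraceFormatError(ValueError):
    """Raised when a trace file or array set violates the trace contract."""


@dataclass
class PVTrace:
    """Uniformly sampled ventricular pressure and volume waveforms.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with a constant step
        equal to ``1/sampling_rate``.
    pressure : ndarray
        Ventricular pressure in mmHg.
    volume : ndarray
        Ventricular volume in ml.
    sampling_rate : float
        Sampling frequency in Hz (conductance systems typically record at
        2 kHz).
    ventricle : str
        ``"RV"`` or ``"LV"``.
    stage_label : str
        Free-text protocol stage label (e.g. ``"baseline1"``,
        ``"dobutamine_5.0"``).
    """

    time: np.ndarray
    pressure: np.ndarray
    volume: np.ndarray
    sampling_rate: float
    ventricle: str = "RV"
    stage_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.time.size
        if not (self.pressure.size == self.volume.size == n):
            raise TraceFormatError(
                f"time/pressure/volume lengths differ: "
                f"{n}/{self.pressure.size}/{self.volume.size}"
            )
        if n < 2:
            raise TraceFormatError("trace needs at least 2 samples")
        if not np.isfinite(self.time).all():
            raise TraceFormatError("non-finite values in time column")
        if np.isnan(self.pressure).any() or np.isnan(self.volume).any():
            raise TraceFormatError("NaNs in pressure or volume")
        if self.sampling_rate <= 0:
            raise TraceFormatError("sampling_rate must be positive")
        dt = np.diff(self.time)
        if (dt <= 0).any():
            raise TraceFormatError("non-monotone time")
        step = 1.0 / self.sampling_rate
        if np.abs(dt - step).max() > TIME_GRID_TOL:
            raise TraceFormatError(
                f"time grid is not uniform at 1/sampling_rate={step!r} "
                f"(max deviation {np.abs(dt - step).max():.3e} s)"
            )
        if self.ventricle not in ("RV", "LV"):
            raise TraceFormatError(f"ventricle must be RV or LV, got {self.ventricle!r}")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def slice(self, start: int, stop: int) -> "PVTrace":
        """Return the half-open sample window ``[start, stop)`` as a new trace."""
        return replace(
            self,
            time=self.time[start:stop],
            pressure=self.pressure[start:stop],
            volume=self.volume[start:stop],
        )


def read_trace(path, ventricle: str = "RV", stage_label: str = "",
               sampling_rate: float | None = None) -> PVTrace:
    """Read a PV trace CSV (``time_s,pressure_mmHg,volume_ml``).

    ``sampling_rate`` is inferred from the median time step when not given.
    Malformed rows are rejected with their line number.
    """
    times, pressures, volumes = [], [], []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["time_s", "pressure_mmHg", "volume_ml"]:
                    raise TraceFormatError(
                        f"{path}: line {lineno}: expected header "
                        f"'time_s,pressure_mmHg,volume_ml', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise TraceFormatError(f"{path}: line {lineno}: expected 3 columns")
            try:
                t, p, v = (float(x) for x in parts)
            except ValueError as exc:
                raise TraceFormatError(f"{path}: line {lineno}: {exc}") from None
            times.append(t)
            pressures.append(p)
            volumes.append(v)
    if not header_seen:
        raise TraceFormatError(f"{path}: missing header")
    time = np.array(times)
    if sampling_rate is None:
        if time.size < 2:
            raise TraceFormatError(f"{path}: too few rows to infer sampling rate")
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return PVTrace(time, np.array(pressures), np.array(volumes),
                   sampling_rate=sampling_rate, ventricle=ventricle,
                   stage_label=stage_label)


def write_trace(trace: PVTrace, path, header_comment: str | None = None) -> None:
    """Write a trace in the canonical CSV format (round-trips to 1e-9)."""
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("time_s,pressure_mmHg,volume_ml\n")
        for t, p, v in zip(trace.time, trace.pressure, trace.volume):
            fh.write(f"{t:.12g},{p:.12g},{v:.12g}\n")
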