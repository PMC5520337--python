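"""Capillary-electrophoresis trace processing.

A microfluidic DNA assay reports a fluorescence-versus-migration-time trace
per well.  This module reconstructs the instrument software's steps: size
calibration against a DNA ladder, peak detection and valley-to-valley
integration, mass-to-molar correction, and assignment of detected peaks to
the two amplicons (inclusion / exclusion isoform) expected for an
alternative splicing event.

Sizing model: migration time is interpolated piecewise-linearly against
log10(fragment size), the standard approximation for intercalating-dye
microfluidic electrophoresis.  Fluorescence is mass-proportional, so a
peak's molar amount is its integrated area divided by its called size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

__all__ = [
    "Trace",
    "SizeCalibration",
    "PeakRecord",
    "AmpliconAssignment",
    "AmpliconWindowError",
    "calibrate_ladder",
    "detect_peaks",
    "apply_calibration",
    "quantify_molar",
    "assign_amplicons",
]


class AmpliconWindowError(ValueError):
    """The tolerance windows of the two expected amplicons overlap."""


@dataclass(frozen=True)
class Trace:
    """One electropherogram: fluorescence signal over migration time.

    ``time`` must be strictly increasing and the same length as ``signal``.
    Metadata identifies the sample the trace came from.
    """

    time: np.ndarray
    signal: np.ndarray
    cell_line: str = ""
    condition: str = ""
    batch_day: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class SizeCalibration:
    """Monotone map between migration time and fragment size (bp).

    Fitted as a piecewise-linear interpolation of log10(size) against time
    through the ladder points; exact at every ladder knot.  Evaluation
    outside the ladder range extrapolates the terminal segment and warns.
    """

    times: np.ndarray
    sizes_bp: np.ndarray
    _log_sizes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sizes_bp, dtype=float)
        if t.size < 2:
            raise ValueError("ladder needs at least 2 points")
        if t.size != s.size:
            raise ValueError("ladder times and sizes must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("ladder times must be strictly increasing")
        if not np.all(np.diff(s) > 0) or np.any(s <= 0):
            raise ValueError("ladder sizes must be positive and strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sizes_bp", s)
        object.__setattr__(self, "_log_sizes", np.log10(s))

    def size_at(self, time: float | np.ndarray) -> float | np.ndarray:
        """Called size (bp) at a migration time."""
        t = np.asarray(time, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            warnings.warn(
                "evaluating size calibration outside the ladder range; "
                "extrapolating terminal segment",
                stacklevel=2,
            )
        log_size = self._piecewise(t, self.times, self._log_sizes)
        out = 10.0 ** log_size
        return float(out) if np.isscalar(time) else out

    def time_at(self, size_bp: float | np.ndarray) -> float | np.ndarray:
        """Inverse map: migration time at which a fragment of this size runs."""
        s = np.asarray(size_bp, dtype=float)
        if np.any(s <= 0):
            raise ValueError("size must be positive")
        if np.any(s < self.sizes_bp[0]) or np.any(s > self.sizes_bp[-1]):
            warnings.warn(
                "evaluating size calibration outside the ladder range; "
                "extrapolating terminal segment",
                stacklevel=2,
            )
        out = self._piecewise(np.log10(s), self._log_sizes, self.times)
        return float(out) if np.isscalar(size_bp) else out

    @staticmethod
    def _piecewise(x: np.ndarray, xp: np.ndarray, yp: np.ndarray) -> np.ndarray:
        # np.interp clamps outside the range; extend with terminal slopes
        y = np.interp(x, xp, yp)
        lo = x < xp[0]
        hi = x > xp[-1]
        if np.any(lo):
            slope = (yp[1] - yp[0]) / (xp[1] - xp[0])
            y = np.where(lo, yp[0] + slope * (x - xp[0]), y)
        if np.any(hi):
            slope = (yp[-1] - yp[-2]) / (xp[-1] - xp[-2])
            y = np.where(hi, yp[-1] + slope * (x - xp[-1]), y)
        return y


@dataclass(frozen=True)
class PeakRecord:
    """A detected, integrated peak.

    ``area`` is in signal·time units from valley-to-valley trapezoid
    integration of the baseline-corrected trace.  ``called_size_bp`` is set
    by :func:`apply_calibration`; ``molar_amount`` (area / size) by
    :func:`quantify_molar`.
    """

    apex_time: float
    area: float
    height: float
    called_size_bp: Optional[float] = None
    molar_amount: Optional[float] = None


def calibrate_ladder(ladder_peaks: Sequence[tuple[float, float]]) -> SizeCalibration:
    """Fit the time→size map from (migration time, known size bp) pairs."""
    if len(ladder_peaks) < 2:
        raise ValueError("ladder needs at least 2 points")
    times, sizes = zip(*ladder_peaks)
    return SizeCalibration(np.asarray(times, float), np.asarray(sizes, float))


def detect_peaks(
    trace: Trace,
    min_height: float,
    min_separation: float,
) -> list[PeakRecord]:
    """Detect and integrate peaks in an electropherogram.

    Peaks are local maxima of the baseline-corrected signal above
    ``min_height`` and separated by at least ``min_separation`` time units
    (two candidate apices closer than that are merged; the taller survives).
    The baseline is a constant offset estimated as the trace's 5th
    percentile.  Each peak's area is the trapezoid integral between its
    flanking valleys (the signal minima toward the neighbouring peaks, or
    the trace ends).  Returned sorted by apex time, uncalibrated.
    """
    baseline = float(np.percentile(trace.signal, 5))
    y = trace.signal - baseline
    dt = float(np.median(np.diff(trace.time)))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = _scipy_find_peaks(y, height=min_height, distance=distance)
    if idx.size == 0:
        return []
    # flanking valleys: minima between consecutive apices, trace ends outside
    bounds = [0]
    for left, right in zip(idx[:-1], idx[1:]):
        bounds.append(left + int(np.argmin(y[left : right + 1])))
    bounds.append(y.size - 1)
    records = []
    for j, apex in enumerate(idx):
        lo, hi = bounds[j], bounds[j + 1]
        area = float(np.trapezoid(y[lo : hi + 1], trace.time[lo : hi + 1]))
        records.append(
            PeakRecord(apex_time=float(trace.time[apex]), area=area, height=float(y[apex]))
        )
    return records


def apply_calibration(
    peaks: Sequence[PeakRecord], calibration: SizeCalibration
) -> list[PeakRecord]:
    """Attach called sizes (bp) to detected peaks via the ladder map."""
    return [replace(p, called_size_bp=float(calibration.size_at(p.apex_time))) for p in peaks]


def quantify_molar(peak: PeakRecord) -> float:
    """Mass-to-molar correction: molar amount = area / called size.

    Intercalating-dye fluorescence is proportional to DNA mass; dividing the
    integrated area by the fragment length yields a quantity proportional to
    the number of molecules, which is what isoform ratios must be computed on.
    """
    if peak.called_size_bp is None or peak.called_size_bp <= 0:
        raise ValueError("peak has no positive called size")
    return peak.area / peak.called_size_bp


@dataclass(frozen=True)
class AmpliconAssignment:
    """Detected peaks matched to an event's expected amplicons (or None)."""

    inclusion: Optional[PeakRecord]
    exclusion: Optional[PeakRecord]


def assign_amplicons(
    peaks: Sequence[PeakRecord],
    size_inclusion_bp: float,
    size_exclusion_bp: float,
    rel_tol: float = 0.10,
) -> AmpliconAssignment:
    """Match detected peaks to the expected inclusion/exclusion amplicons.

    Each expected size is matched to the peak whose called size is nearest
    in relative error and within ``rel_tol``; ties on distance go to the
    larger area.  A peak may satisfy only one slot: when the same peak is
    nearest for both expected sizes it goes to the slot it matches better
    and the other slot falls back to its next-best candidate.  The two
    expected sizes must be mutually discriminable — if either lies inside
    the other's tolerance window the configuration is rejected, since no
    called size could then be attributed unambiguously.  Unmatched slots
    come back as ``None``; peaks beyond the two expected amplicons are
    ignored here and excluded from downstream isoform ratios.
    """
    if not 0 < rel_tol < 0.5:
        raise ValueError("rel_tol must be in (0, 0.5)")
    lo_size, hi_size = sorted([size_inclusion_bp, size_exclusion_bp])
    if (hi_size - lo_size) / lo_size <= rel_tol:
        raise AmpliconWindowError(
            f"expected sizes {lo_size} and {hi_size} bp are within rel_tol="
            f"{rel_tol} of each other and cannot be discriminated"
        )

    def candidates(expected: float, exclude: Optional[PeakRecord]) -> list:
        out = []
        for p in peaks:
            if p.called_size_bp is None:
                raise ValueError("peaks must carry called sizes; run apply_calibration")
            if p is exclude:
                continue
            rel_err = abs(p.called_size_bp - expected) / expected
            if rel_err <= rel_tol:
                out.append((rel_err, -p.area, p))
        return sorted(out, key=lambda c: (c[0], c[1]))

    inc_c = candidates(size_inclusion_bp, None)
    exc_c = candidates(size_exclusion_bp, None)
    inc = inc_c[0] if inc_c else None
    exc = exc_c[0] if exc_c else None
    if inc is not None and exc is not None and inc[2] is exc[2]:
        # shared best peak: keep it in the better-matching slot
        if inc[:2] <= exc[:2]:
            exc_c = candidates(size_exclusion_bp, exclude=inc[2])
            exc = exc_c[0] if exc_c else None
        else:
            inc_c = candidates(size_inclusion_bp, exclude=exc[2])
            inc = inc_c[0] if inc_c else None
    return AmpliconAssignment(
        inclusion=inc[2] if inc else None,
        exclusion=exc[2] if exc else None,
    )
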