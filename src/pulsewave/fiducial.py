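"""Fiducial-landmark detection and time-domain pulse features.

One cardiac cycle of a radial pulse waveform carries five canonical
landmarks, measured relative to the cycle-onset baseline:

* percussion wave (main systolic peak): height H1 at phase T1,
* main-wave gorge (trough after the percussion wave): H2 at T2,
* tidal wave (late-systolic reflection peak): H3 at T3,
* dicrotic notch (incisura at aortic-valve closure): H4 at T4,
* dicrotic wave (early-diastolic rebound peak): H5 at T5,

plus the cycle period T and the widths W1 and W2 for which the main wave
exceeds 1/3 and 2/3 of H1 respectively. The nine classical time-domain
features are H2/H1, H3/H1, H4/H1, H5/H1, T1/T, T1/T4, T, W1, W2; ratios of
heights index vascular compliance and peripheral resistance, T1/T and T1/T4
index ejection function, and the widths index sustained high pressure.

In stiffened or aged vasculature the tidal wave often fuses with the
percussion wave and leaves no distinct local extremum; the detector then
falls back to the inflection of minimal curvature on the falling limb and
clears ``tidal_present`` rather than fabricating a peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .exceptions import DetectionError, ParameterError, WidthError

__all__ = [
    "FiducialPoints",
    "TimeDomainFeatures",
    "TD_FEATURE_NAMES",
    "detect_fiducials",
    "width_at_fraction",
    "compute_features",
    "aggregate_recording",
]

#: canonical feature order used in every table and CSV this package writes
TD_FEATURE_NAMES = (
    "h2_h1",
    "h3_h1",
    "h4_h1",
    "h5_h1",
    "t1_t",
    "t1_t4",
    "t_s",
    "w1_s",
    "w2_s",
)


@dataclass(frozen=True)
class FiducialPoints:
    """Landmark heights (mm above cycle-onset baseline) and phases (s).

    Absent landmarks are NaN with the corresponding presence flag cleared.
    """

    h1: float
    h2: float
    h3: float
    h4: float
    h5: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    t: float
    w1: float
    w2: float
    tidal_present: bool = True
    notch_present: bool = True

    def ordering_valid(self) -> bool:
        """Check the landmark ordering chain on the present landmarks."""
        phases = [0.0]
        for val in (self.t1, self.t2, self.t3, self.t4, self.t5):
            if not math.isnan(val):
                phases.append(val)
        phases.append(self.t)
        if any(b <= a for a, b in zip(phases, phases[1:])):
            return False
        for h in (self.h2, self.h3, self.h4, self.h5):
            if not math.isnan(h) and h > self.h1:
                return False
        if not math.isnan(self.h2) and not math.isnan(self.h3) and self.h3 < self.h2:
            return False
        if not math.isnan(self.h4) and not math.isnan(self.h5) and self.h5 < self.h4:
            return False
        if not (math.isnan(self.w1) or math.isnan(self.w2)):
            if not 0 < self.w2 < self.w1 < self.t:
                return False
        return True


@dataclass(frozen=True)
class TimeDomainFeatures:
    """The nine classical time-domain features; NaN marks a missing value."""

    h2_h1: float
    h3_h1: float
    h4_h1: float
    h5_h1: float
    t1_t: float
    t1_t4: float
    t_s: float
    w1_s: float
    w2_s: float
    n_cycles: int | None = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TD_FEATURE_NAMES}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in TD_FEATURE_NAMES])


def _extrema_after(y: np.ndarray, start: int, prominence: float):
    """Interleaved local minima/maxima of ``y`` strictly after ``start``."""
    seg = y[start:]
    maxima, _ = sps.find_peaks(seg, prominence=prominence)
    minima, _ = sps.find_peaks(-seg, prominence=prominence)
    events = sorted(
        [(int(i) + start, "min") for i in minima] + [(int(i) + start, "max") for i in maxima]
    )
    return events


def _min_curvature_inflection(y: np.ndarray, lo: int, hi: int, fs: float) -> int | None:
    """Index of minimal |curvature| in the open interval (lo, hi).

    Used as the fallback location for a fused tidal wave: where the falling
    limb flattens without forming a distinct extremum.
    """
    if hi - lo < 5:
        return None
    window = max(5, int(round(0.02 * fs)) | 1)
    if hi - lo <= window:
        smoothed = y[lo:hi]
    else:
        smoothed = sps.savgol_filter(y[lo:hi], window, polyorder=3)
    d2 = np.gradient(np.gradient(smoothed))
    interior = d2[2:-2]
    if interior.size == 0:
        return None
    return lo + 2 + int(np.argmin(np.abs(interior)))


def detect_fiducials(
    cycle: np.ndarray,
    fs: float,
    *,
    w1_fraction: float = 1.0 / 3.0,
    w2_fraction: float = 2.0 / 3.0,
    prominence_frac: float = 0.015,
) -> FiducialPoints:
    """Locate the five landmarks and widths within one baseline-corrected cycle.

    Parameters
    ----------
    cycle : ndarray
        Samples of one cycle, onset first; heights are measured above the
        onset level so ``cycle[0]`` is subtracted.
    fs : float
        Sampling rate in Hz.
    w1_fraction, w2_fraction : float
        Levels (as fractions of H1) at which the main-wave widths are read.
    prominence_frac : float
        Minimum extremum prominence, as a fraction of H1, for a landmark to
        count as present.
    """
    y = np.asarray(cycle, dtype=float)
    if y.ndim != 1 or len(y) < 8:
        raise ParameterError("cycle must be a 1-D array of at least 8 samples")
    if fs <= 0:
        raise ParameterError("fs must be positive")
    y = y - y[0]
    n = len(y)
    i1 = int(np.argmax(y))
    h1 = float(y[i1])
    if h1 <= 0:
        raise DetectionError("no percussion peak above the onset baseline")
    if i1 < 0.05 * n or i1 > 0.95 * n:
        raise DetectionError(
            f"percussion peak at sample {i1}/{n} lies in the first/last 5% of the cycle"
        )
    prominence = prominence_frac * h1
    events = _extrema_after(y, i1 + 1, prominence)

    i2 = i3 = i4 = i5 = None
    tidal_present = notch_present = False
    minima = [i for i, kind in events if kind == "min"]
    maxima = [i for i, kind in events if kind == "max"]
    if len(minima) >= 2:
        # two troughs after the peak: gorge then notch, tidal between them
        i2, i4 = minima[0], minima[1]
        between = [i for i in maxima if i2 < i < i4]
        if between:
            i3 = between[0]
            tidal_present = True
        notch_present = True
    elif len(minima) == 1:
        # single trough: the dicrotic notch; the tidal wave is fused into
        # the falling limb of the percussion wave
        i4 = minima[0]
        notch_present = True
    if i4 is not None:
        after = [i for i in maxima if i > i4]
        i5 = after[0] if after else None
        if not tidal_present:
            infl = _min_curvature_inflection(y, i1 + 1, i4, fs)
            if infl is not None and 0 < y[infl] <= h1:
                i2 = i3 = infl

    def _ph(i):
        return (float(i) / fs, float(y[i])) if i is not None else (math.nan, math.nan)

    t2, h2 = _ph(i2)
    t3, h3 = _ph(i3)
    t4, h4 = _ph(i4)
    t5, h5 = _ph(i5)
    t1 = i1 / fs
    try:
        w1 = width_at_fraction(y, h1, t1, w1_fraction, fs)
    except WidthError:
        w1 = math.nan
    try:
        w2 = width_at_fraction(y, h1, t1, w2_fraction, fs)
    except WidthError:
        w2 = math.nan
    return FiducialPoints(
        h1=h1, h2=h2, h3=h3, h4=h4, h5=h5,
        t1=t1, t2=t2, t3=t3, t4=t4, t5=t5,
        t=n / fs, w1=w1, w2=w2,
        tidal_present=tidal_present, notch_present=notch_present,
    )


def width_at_fraction(
    cycle: np.ndarray, h1: float, t1: float, fraction: float, fs: float
) -> float:
    """Duration for which the main wave exceeds ``fraction * h1``.

    The rising and falling crossings of the level enclosing the percussion
    peak at ``t1`` are located by linear interpolation between samples.
    Raises :class:`WidthError` if a flank never crosses the level.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    if h1 <= 0:
        raise ParameterError("h1 must be positive")
    y = np.asarray(cycle, dtype=float)
    level = fraction * h1
    i1 = int(round(t1 * fs))
    i1 = min(max(i1, 0), len(y) - 1)
    above = y > level
    if not above[i1]:
        # t1 rounded onto a sample below the level (extremely narrow peak)
        raise WidthError(f"peak sample is not above level {level:.4g}")
    lo = i1
    while lo > 0 and above[lo - 1]:
        lo -= 1
    if lo == 0 and above[0]:
        raise WidthError("level never crossed on the rising flank")
    hi = i1
    while hi < len(y) - 1 and above[hi + 1]:
        hi += 1
    if hi == len(y) - 1 and above[hi]:
        raise WidthError("level never crossed on the falling flank")
    t_rise = (lo - 1 + (level - y[lo - 1]) / (y[lo] - y[lo - 1])) / fs
    t_fall = (hi + (level - y[hi]) / (y[hi + 1] - y[hi])) / fs
    return t_fall - t_rise


def compute_features(fp: FiducialPoints) -> TimeDomainFeatures:
    """Form the nine time-domain features from one cycle's landmarks.

    Landmarks that are absent propagate as NaN; in particular a missing
    dicrotic notch leaves T1/T4, H4/H1 and H5/H1 missing rather than
    fabricated.
    """
    if not fp.h1 > 0:
        raise ParameterError(f"H1 must be positive, got {fp.h1}")
    if not fp.t > 0:
        raise ParameterError(f"T must be positive, got {fp.t}")
    notch_ok = fp.notch_present and not math.isnan(fp.t4)
    return TimeDomainFeatures(
        h2_h1=fp.h2 / fp.h1 if not math.isnan(fp.h2) else math.nan,
        h3_h1=fp.h3 / fp.h1 if not math.isnan(fp.h3) else math.nan,
        h4_h1=fp.h4 / fp.h1 if notch_ok else math.nan,
        h5_h1=fp.h5 / fp.h1 if notch_ok and not math.isnan(fp.h5) else math.nan,
        t1_t=fp.t1 / fp.t,
        t1_t4=fp.t1 / fp.t4 if notch_ok and fp.t4 > 0 else math.nan,
        t_s=fp.t,
        w1_s=fp.w1,
        w2_s=fp.w2,
        n_cycles=1,
    )


def aggregate_recording(
    per_cycle: list[TimeDomainFeatures], min_cycles: int = 10
) -> TimeDomainFeatures:
    """Per-feature median across accepted cycles (one value per subject).

    Missing per-cycle values are excluded feature-wise; a feature missing in
    every cycle stays missing in the aggregate.
    """
    if len(per_cycle) < min_cycles:
        raise ParameterError(
            f"{len(per_cycle)} accepted cycles < min_cycles={min_cycles}"
        )
    matrix = np.vstack([f.as_vector() for f in per_cycle])
    with np.errstate(all="ignore"):
        medians = np.array(
            [
                np.nanmedian(col) if np.any(np.isfinite(col)) else math.nan
                for col in matrix.T
            ]
        )
    values = dict(zip(TD_FEATURE_NAMES, medians))
    return TimeDomainFeatures(n_cycles=len(per_cycle), **values)
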