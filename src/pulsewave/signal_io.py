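"""Recording I/O, signal preconditioning, and cardiac-cycle segmentation.

A pulse recording is a single-channel radial-artery pressure series sampled
at a fixed rate (the study dialect is 720 Hz for 60 s, amplitude in mm).
The on-disk format is a plain-text CSV-like file: ``#``-prefixed header
lines carrying ``subject_id`` and ``fs``, then one amplitude per line.

Cycle onsets are placed at the foot of each beat: the local minimum
immediately preceding the steepest point of the systolic upstroke.
Sample indices are 0-based and cycle ``i`` spans the half-open interval
``[onset_i, onset_{i+1})``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import (
    FormatError,
    ParameterError,
    QualityError,
    SegmentationError,
)

__all__ = [
    "PulseRecording",
    "CycleSegmentation",
    "PreprocessConfig",
    "SegmentConfig",
    "QualityConfig",
    "read_recording",
    "write_recording",
    "preprocess",
    "segment_cycles",
    "quality_filter",
]


@dataclass(frozen=True)
class PulseRecording:
    """A sampled single-channel pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in mm.
    fs : float
        Sampling rate in Hz; must be positive.
    subject_id : str
        Opaque identifier carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ParameterError("samples must be a 1-D array")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ParameterError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "PulseRecording":
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class CycleSegmentation:
    """Cycle onsets (0-based sample indices) and per-cycle acceptance flags.

    ``onset_indices`` has one more entry than there are cycles only when the
    final onset opens a truncated cycle; ``accepted_flags`` has one entry per
    complete cycle, i.e. ``len(onset_indices) - 1``.
    """

    onset_indices: np.ndarray
    accepted_flags: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_indices, dtype=int)
        flags = np.asarray(self.accepted_flags, dtype=bool)
        object.__setattr__(self, "onset_indices", onsets)
        object.__setattr__(self, "accepted_flags", flags)
        if np.any(np.diff(onsets) <= 0):
            raise ParameterError("onset indices must be strictly increasing")
        if len(flags) != max(len(onsets) - 1, 0):
            raise ParameterError("need one accepted flag per complete cycle")

    @property
    def n_cycles(self) -> int:
        return len(self.accepted_flags)

    def cycle_bounds(self, i: int) -> tuple[int, int]:
        return int(self.onset_indices[i]), int(self.onset_indices[i + 1])


@dataclass(frozen=True)
class PreprocessConfig:
    """Zero-phase filtering and foot-anchored baseline removal.

    ``lowpass_hz`` attenuates measurement noise; ``highpass_hz`` removes slow
    respiratory/contact drift. Both filters are applied forward-backward
    (zero phase) so landmark timing is preserved. When ``anchor_baseline`` is
    true the residual baseline is re-referenced by interpolating through the
    detected beat feet so cycle-onset levels sit near 0 mm.
    """

    lowpass_hz: float = 20.0
    highpass_hz: float = 0.5
    filter_order: int = 4
    anchor_baseline: bool = True


@dataclass(frozen=True)
class SegmentConfig:
    min_period_s: float = 0.4
    max_period_s: float = 1.5
    #: fraction of the 99.5th-percentile upstroke slope required of a beat
    slope_height_frac: float = 0.4
    #: how far before the steepest upstroke to search for the foot, seconds
    foot_search_s: float = 0.25


@dataclass(frozen=True)
class QualityConfig:
    min_period_s: float = 0.4
    max_period_s: float = 1.5
    #: reject cycles whose peak-to-peak amplitude falls below this, mm
    min_amplitude: float = 0.5
    min_cycles: int = 10


# ---------------------------------------------------------------------------
# I/O


def write_recording(rec: PulseRecording, path) -> None:
    """Write a recording in the plain-text dialect (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# fs={float(rec.fs)!r}\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")


def read_recording(path, fs_override: float | None = None) -> PulseRecording:
    """Read a recording written by :func:`write_recording`.

    ``fs`` from the file header wins over ``fs_override``; if the header
    lacks ``fs`` and no override is given this is an error — the sampling
    rate is never silently defaulted.
    """
    subject_id = ""
    fs: float | None = None
    values: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key == "subject_id":
                        subject_id = val.strip()
                    elif key == "fs":
                        try:
                            fs = float(val)
                        except ValueError as exc:
                            raise FormatError(
                                f"{path}: line {lineno}: bad fs value {val!r}"
                            ) from exc
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: expected a number, got {line!r}"
                ) from exc
    if fs is None:
        if fs_override is None:
            raise FormatError(f"{path}: no '# fs=' header and no fs_override given")
        fs = float(fs_override)
    return PulseRecording(np.asarray(values, dtype=float), fs, subject_id)


# ---------------------------------------------------------------------------
# Preconditioning


def _sos_filtfilt(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise ParameterError(
            f"recording of {len(x)} samples is shorter than the filter warm-up "
            f"({padlen + 1} samples)"
        )
    return sps.sosfiltfilt(sos, x)


def preprocess(rec: PulseRecording, config: PreprocessConfig | None = None) -> PulseRecording:
    """Denoise and de-trend a recording without shifting landmark times.

    An (almost) constant signal is returned unchanged: there is nothing to
    filter and high-passing it to zero would only destroy information.
    """
    cfg = config or PreprocessConfig()
    x = rec.samples
    if len(x) == 0 or float(np.ptp(x)) < 1e-12:
        return rec
    nyq = rec.fs / 2.0
    if not 0 < cfg.highpass_hz < cfg.lowpass_hz < nyq:
        raise ParameterError(
            f"need 0 < highpass ({cfg.highpass_hz}) < lowpass ({cfg.lowpass_hz}) "
            f"< Nyquist ({nyq})"
        )
    sos_lp = sps.butter(cfg.filter_order, cfg.lowpass_hz / nyq, "lowpass", output="sos")
    y = _sos_filtfilt(x, sos_lp)
    sos_hp = sps.butter(cfg.filter_order, cfg.highpass_hz / nyq, "highpass", output="sos")
    y = _sos_filtfilt(y, sos_hp)
    if cfg.anchor_baseline:
        try:
            onsets = _detect_onsets(y, rec.fs, SegmentConfig())
        except SegmentationError:
            onsets = None
        if onsets is not None and len(onsets) >= 2:
            idx = np.arange(len(y))
            baseline = np.interp(idx, onsets, y[onsets])
            y = y - baseline
    return rec.replace_samples(y)


# ---------------------------------------------------------------------------
# Segmentation


def _detect_onsets(x: np.ndarray, fs: float, cfg: SegmentConfig) -> np.ndarray:
    """Foot detection: local minimum preceding each steepest upstroke."""
    if len(x) < 3 or float(np.ptp(x)) < 1e-12:
        raise SegmentationError("no detectable cycles in a flat signal")
    d = np.gradient(x)
    pos = d[d > 0]
    if pos.size == 0:
        raise SegmentationError("signal has no rising edges")
    height = cfg.slope_height_frac * np.percentile(pos, 99.5)
    # refractory distance from the dominant beat period (autocorrelation),
    # so a prominent tidal/dicrotic upstroke cannot split a cycle; falls
    # back to the minimum plausible period for very short signals
    distance = max(int(cfg.min_period_s * 0.8 * fs), 1)
    lo = int(cfg.min_period_s * fs)
    hi = min(int(cfg.max_period_s * fs), len(x) - 1)
    if hi > lo:
        x0 = x - x.mean()
        ac = sps.correlate(x0, x0, mode="full", method="fft")[len(x) - 1 :]
        est_period = lo + int(np.argmax(ac[lo : hi + 1]))
        distance = max(distance, int(0.7 * est_period))
    upstrokes, _ = sps.find_peaks(d, height=height, distance=distance)
    if len(upstrokes) < 2:
        raise SegmentationError(
            f"found {len(upstrokes)} upstroke(s); need at least 2 cycles"
        )
    # refractory pruning: a secondary (tidal/dicrotic) upstroke splits a true
    # cycle; drop the weaker of any pair closer than 0.55x the median gap
    ups = list(upstrokes)
    while len(ups) > 2:
        gaps = np.diff(ups)
        med = np.median(gaps)
        short = np.nonzero(gaps < 0.55 * med)[0]
        if short.size == 0:
            break
        i = int(short[0])
        ups.pop(i if d[ups[i]] < d[ups[i + 1]] else i + 1)
    upstrokes = np.asarray(ups)
    window = max(int(cfg.foot_search_s * fs), 2)
    onsets = []
    for p in upstrokes:
        lo = max(p - window, 0)
        seg = x[lo : p + 1]
        if len(seg) < 3:
            onsets.append(lo + int(np.argmin(seg)))
            continue
        interior = np.arange(1, len(seg) - 1)
        is_min = (seg[interior] <= seg[interior - 1]) & (seg[interior] <= seg[interior + 1])
        cand = interior[is_min]
        # keep minima near the floor of the window, then take the one closest
        # to the upstroke: that is the foot, not an earlier diastolic dip
        if cand.size:
            floor = seg.min() + 0.2 * np.ptp(seg)
            near_floor = cand[seg[cand] <= floor]
            pick = (near_floor if near_floor.size else cand)[-1]
        else:
            pick = int(np.argmin(seg))
        onsets.append(lo + int(pick))
    onsets = np.unique(np.asarray(onsets, dtype=int))
    if len(onsets) < 2:
        raise SegmentationError("could not place at least two cycle onsets")
    return onsets


def segment_cycles(rec: PulseRecording, config: SegmentConfig | None = None) -> CycleSegmentation:
    """Locate cycle onsets and pre-flag cycles with implausible periods."""
    cfg = config or SegmentConfig()
    onsets = _detect_onsets(rec.samples, rec.fs, cfg)
    periods = np.diff(onsets) / rec.fs
    flags = (periods >= cfg.min_period_s) & (periods <= cfg.max_period_s)
    return CycleSegmentation(onsets, flags)


def quality_filter(
    seg: CycleSegmentation,
    rec: PulseRecording,
    config: QualityConfig | None = None,
) -> CycleSegmentation:
    """Reject cycles outside period bounds or below the amplitude floor.

    Raises :class:`QualityError` (listing the rejection reasons) when fewer
    than ``min_cycles`` cycles survive.
    """
    cfg = config or QualityConfig()
    if seg.n_cycles == 0:
        raise QualityError("segmentation contains no complete cycles")
    reasons: dict[str, int] = {"period": 0, "amplitude": 0}
    flags = np.array(seg.accepted_flags, dtype=bool, copy=True)
    periods = np.diff(seg.onset_indices) / rec.fs
    for i in range(seg.n_cycles):
        if not (cfg.min_period_s <= periods[i] <= cfg.max_period_s):
            flags[i] = False
            reasons["period"] += 1
            continue
        a, b = seg.cycle_bounds(i)
        if float(np.ptp(rec.samples[a:b])) < cfg.min_amplitude:
            flags[i] = False
            reasons["amplitude"] += 1
    n_ok = int(flags.sum())
    if n_ok < cfg.min_cycles:
        detail = ", ".join(f"{k}: {v}" for k, v in reasons.items() if v)
        raise QualityError(
            f"only {n_ok} cycles accepted (< min_cycles={cfg.min_cycles})"
            + (f"; rejections — {detail}" if detail else "")
        )
    return CycleSegmentation(seg.onset_indices, flags)
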