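"""Pattern-recognition measurement stage.

A long recording is split into beats by QRS detection (energy-based,
Pan-Tompkins style), P and T waves are then searched per beat, and the
standard interval measurements are derived from the fiducials: P duration,
PR, QRS, QT, QTc, T duration, atrial and ventricular rate — plus HRV
statistics, the averaged beat template and RR scatter data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError, InsufficientDataError, NoSignalError
from .records import ECGRecord
from .signal_quality import FilterConfig

MIN_RR_S = 0.2  # refractory period between QRS detections


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BeatAnnotation:
    """Per-beat fiducials as 0-based sample indices; absent waves are None."""

    beat_index: int
    qrs_onset: int
    qrs_peak: int
    qrs_offset: int
    p_onset: int | None = None
    p_peak: int | None = None
    p_offset: int | None = None
    t_onset: int | None = None
    t_peak: int | None = None
    t_offset: int | None = None

    @property
    def has_p(self) -> bool:
        return self.p_peak is not None

    @property
    def has_t(self) -> bool:
        return self.t_peak is not None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class WaveAnnotationSet:
    beats: list[BeatAnnotation]
    sampling_rate: float

    def __post_init__(self):
        peaks = [b.qrs_peak for b in self.beats]
        if any(b <= a for a, b in zip(peaks, peaks[1:])):
            raise ConfigError("beats must be strictly increasing by qrs_peak")

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def qrs_peaks(self) -> np.ndarray:
        return np.asarray([b.qrs_peak for b in self.beats], dtype=int)

    def as_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "beats": [b.as_dict() for b in self.beats],
        }


@dataclass
class MeasurementReport:
    """Eight measurements; per-beat values (NaN where absent) + a summary."""

    p_duration_ms: np.ndarray
    pr_interval_ms: np.ndarray
    qrs_interval_ms: np.ndarray
    qt_interval_ms: np.ndarray
    qtc_interval_ms: np.ndarray
    t_duration_ms: np.ndarray
    atrial_rate_bpm: float | None
    ventricular_rate_bpm: float
    summary_stat: str = "median"

    _INTERVAL_FIELDS = (
        "p_duration_ms",
        "pr_interval_ms",
        "qrs_interval_ms",
        "qt_interval_ms",
        "qtc_interval_ms",
        "t_duration_ms",
    )

    def summary(self) -> dict:
        agg = np.nanmedian if self.summary_stat == "median" else np.nanmean
        out = {}
        for name in self._INTERVAL_FIELDS:
            vals = getattr(self, name)
            out[name] = float(agg(vals)) if np.any(np.isfinite(vals)) else None
        out["atrial_rate_bpm"] = self.atrial_rate_bpm
        out["ventricular_rate_bpm"] = self.ventricular_rate_bpm
        return out

    def as_dict(self) -> dict:
        d = {name: [None if not math.isfinite(v) else float(v)
                    for v in getattr(self, name)]
             for name in self._INTERVAL_FIELDS}
        d["atrial_rate_bpm"] = self.atrial_rate_bpm
        d["ventricular_rate_bpm"] = self.ventricular_rate_bpm
        d["summary"] = self.summary()
        return d


@dataclass
class HRVSummary:
    mean_rr: float
    sdnn: float
    rmssd: float
    pnn50: float
    n_intervals: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RRScatter:
    points: np.ndarray  # (n_intervals - 1, 2) of (rr_i, rr_{i+1}) in seconds

    def as_dict(self) -> dict:
        return {"points": [[float(a), float(b)] for a, b in self.points]}


@dataclass
class AverageBeat:
    template: np.ndarray
    pre_samples: int  # samples before the QRS peak within the template
    sampling_rate: float
    n_beats: int


# ---------------------------------------------------------------------------
# QRS detection


def detect_qrs(record: ECGRecord, min_rr_s: float = MIN_RR_S) -> np.ndarray:
    """Detect QRS peaks; returns strictly increasing sample indices.

    Energy-based detection: 5-15 Hz band-pass, differentiation, squaring,
    moving-window integration, then an adaptive signal/noise threshold with
    a 200-ms refractory period and a search-back pass for missed beats.
    Each detection is refined to the largest absolute deflection of the
    input waveform near the energy peak.
    """
    if record.has_flag("empty"):
        raise NoSignalError("record is flagged empty")
    if record.duration < 3.0:
        raise InsufficientDataError("need at least 3 s of signal for QRS detection")
    x = record.samples
    if float(np.std(x)) < FilterConfig().flatline_std_threshold:
        raise NoSignalError("record has no discernible signal")
    fs = record.sampling_rate

    sos = sps.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    energy = uniform_filter1d(np.gradient(band) ** 2, max(3, int(0.15 * fs)))

    dist = max(1, int(min_rr_s * fs))
    cand, _ = sps.find_peaks(energy, distance=dist)
    if cand.size == 0:
        return np.asarray([], dtype=int)

    # Adaptive signal / noise running estimates (Pan-Tompkins style).
    head = energy[: int(2 * fs)]
    spk = float(np.max(head)) * 0.5 if head.size else float(energy.max()) * 0.5
    npk = float(np.mean(head)) * 0.5 if head.size else 0.0
    accepted: list[int] = []
    heights: dict[int, float] = {}
    rr_hist: list[float] = []
    for c in cand:
        h = float(energy[c])
        thr = npk + 0.25 * (spk - npk)
        if h > thr:
            accepted.append(int(c))
            heights[int(c)] = h
            spk = 0.125 * h + 0.875 * spk
            if len(accepted) > 1:
                rr_hist.append(accepted[-1] - accepted[-2])
                rr_hist = rr_hist[-8:]
        else:
            npk = 0.125 * h + 0.875 * npk
        # Search-back: if the gap since the last beat greatly exceeds the
        # running RR average, re-admit the best sub-threshold candidate.
        if rr_hist and accepted and c - accepted[-1] > 1.66 * np.mean(rr_hist):
            lo, hi = accepted[-1] + dist, c
            seg = [cc for cc in cand if lo <= cc < hi]
            if seg:
                best = max(seg, key=lambda cc: energy[cc])
                if energy[best] > 0.5 * thr:
                    accepted.append(int(best))
                    heights[int(best)] = float(energy[best])
                    accepted.sort()

    # Refine each detection to the R-peak of the waveform itself.
    half = int(0.10 * fs)
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        r = lo + int(np.argmax(np.abs(x[lo:hi])))
        refined.append(r)
    refined = sorted(set(refined))

    # Enforce the refractory period, keeping the stronger of close pairs.
    peaks: list[int] = []
    for r in refined:
        if peaks and r - peaks[-1] < dist:
            if abs(x[r]) > abs(x[peaks[-1]]):
                peaks[-1] = r
        else:
            peaks.append(r)
    return np.asarray(peaks, dtype=int)


# ---------------------------------------------------------------------------
# wave delineation


def _slope_edge(deriv, start, stop, step, thr, run=3):
    """March from ``start`` toward ``stop``; return the first index where
    ``run`` consecutive |slopes| fall below ``thr`` (the wave boundary)."""
    count = 0
    j = start
    while True:
        if abs(deriv[j]) < thr:
            count += 1
            if count >= run:
                return j - step * (run - 1)
        else:
            count = 0
        if j == stop:
            return stop
        j += step


def delineate_waves(
    record: ECGRecord,
    qrs_peaks,
    p_min_amp: float = 0.05,
    p_edge_frac: float = 0.25,
    t_edge_frac: float = 0.10,
) -> WaveAnnotationSet:
    """Locate QRS on/offsets and P/T waves for each detected beat.

    Boundaries are placed where the absolute slope falls below a fraction
    of the wave's peak slope (10% for QRS and T; 25% for the low-amplitude
    P, calibrated for the slope widening that smoothing introduces at
    125 Hz).  P and T are marked absent when no deflection above
    ``p_min_amp`` mV (P) or a minimal prominence (T) exists in their search
    windows.
    """
    qrs_peaks = np.asarray(qrs_peaks, dtype=int)
    if qrs_peaks.size < 2:
        raise InsufficientDataError("need at least 2 QRS peaks to delineate")
    fs = record.sampling_rate
    # Light smoothing so slope thresholds are noise-tolerant.
    smooth = uniform_filter1d(record.samples, max(3, int(0.024 * fs) | 1))
    deriv = np.gradient(smooth) * fs  # mV/s
    n = smooth.size

    beats: list[BeatAnnotation] = []
    for i, r in enumerate(qrs_peaks):
        rr_prev = (r - qrs_peaks[i - 1]) / fs if i > 0 else None
        rr_next = (qrs_peaks[i + 1] - r) / fs if i + 1 < qrs_peaks.size else rr_prev
        rr_local = rr_next if rr_next is not None else 0.8

        # --- QRS boundaries
        w = int(0.12 * fs)
        lo, hi = max(0, r - w), min(n, r + w + 1)
        max_slope = float(np.max(np.abs(deriv[lo:hi])))
        thr = 0.10 * max_slope
        onset = _slope_edge(deriv, max(lo, r - 2), lo, -1, thr)
        offset = _slope_edge(deriv, min(hi - 1, r + 2), hi - 1, 1, thr)
        onset = int(max(0, onset))
        offset = int(min(n - 1, offset))

        beat = BeatAnnotation(
            beat_index=i, qrs_onset=onset, qrs_peak=int(r), qrs_offset=offset
        )

        # --- T wave: search after the QRS, within 60% of the local RR
        # Post-QRS blanking shrinks with the local RR so fast rates keep the
        # compressed T peak inside the search window.
        t_lo = offset + int(min(0.08, 0.12 * rr_local) * fs)
        t_hi = min(n, r + int(0.6 * rr_local * fs) + 1)
        if t_hi - t_lo > int(0.05 * fs):
            seg = smooth[t_lo:t_hi]
            base = float(np.median(seg))  # local baseline offset
            tp = t_lo + int(np.argmax(np.abs(seg - base)))
            if abs(smooth[tp] - base) >= 0.05:
                tw = int(0.15 * fs)
                # Slope window must not reach into the QRS.
                tlo2, thi2 = max(offset + 2, tp - tw), min(n, tp + tw + 1)
                t_slope = float(np.max(np.abs(deriv[tlo2:thi2])))
                t_thr = t_edge_frac * t_slope
                t_on = _slope_edge(deriv, max(tlo2, tp - 2), tlo2, -1, t_thr)
                t_off = _slope_edge(deriv, min(thi2 - 1, tp + 2), thi2 - 1, 1, t_thr)
                t_on = int(max(t_on, offset))
                t_off = int(min(t_off, n - 1))
                if t_on <= tp <= t_off:
                    beat.t_onset, beat.t_peak, beat.t_offset = t_on, int(tp), t_off

        # --- P wave: search a window before the QRS onset
        p_lo = max(0, onset - int(0.24 * fs))
        p_hi = onset - int(0.04 * fs)
        if i > 0:
            prev = beats[-1]
            floor = prev.t_offset if prev.t_offset is not None else prev.qrs_offset
            p_lo = max(p_lo, floor)
        if p_hi - p_lo > int(0.03 * fs):
            seg = smooth[p_lo:p_hi]
            base = float(np.median(seg))
            pp = p_lo + int(np.argmax(np.abs(seg - base)))
            if abs(smooth[pp] - base) >= p_min_amp:
                # The walk is capped at the physiological P half-width so a
                # noisy slope cannot drag the onset arbitrarily early.
                pw = int(0.06 * fs)
                plo2, phi2 = max(0, pp - pw), min(onset - 1, pp + pw + 1)
                p_slope = float(np.max(np.abs(deriv[plo2:phi2])))
                p_thr = p_edge_frac * p_slope
                p_on = _slope_edge(deriv, max(plo2, pp - 2), plo2, -1, p_thr)
                p_off = _slope_edge(deriv, min(phi2 - 1, pp + 2), phi2 - 1, 1, p_thr)
                p_on = int(max(0, p_on))
                p_off = int(min(p_off, onset))
                if p_on <= pp <= p_off:
                    beat.p_onset, beat.p_peak, beat.p_offset = p_on, int(pp), p_off

        beats.append(beat)
    return WaveAnnotationSet(beats=beats, sampling_rate=fs)


# ---------------------------------------------------------------------------
# measurements


def _bazett(qt_s: float, rr_s: float) -> float:
    return qt_s / math.sqrt(rr_s)


def _fridericia(qt_s: float, rr_s: float) -> float:
    return qt_s / rr_s ** (1.0 / 3.0)


QTC_FORMULAS = {"bazett": _bazett, "fridericia": _fridericia}


def compute_measurements(
    annotations: WaveAnnotationSet,
    sampling_rate: float | None = None,
    qtc_formula: str = "bazett",
    summary_stat: str = "median",
) -> MeasurementReport:
    """Derive the eight interval/rate measurements from wave fiducials.

    Per-beat values are index differences scaled by 1000/fs (ms); QTc uses
    the local RR (Bazett by default); ventricular rate is 60 / mean RR and
    atrial rate 60 / mean PP (absent when P waves are absent).
    """
    fs = sampling_rate or annotations.sampling_rate
    beats = annotations.beats
    if len(beats) < 2:
        raise InsufficientDataError("need at least 2 annotated beats")
    if qtc_formula not in QTC_FORMULAS:
        raise ConfigError(f"unknown qtc_formula {qtc_formula!r}")
    qtc_fn = QTC_FORMULAS[qtc_formula]
    ms = 1000.0 / fs

    peaks = annotations.qrs_peaks
    rr = np.diff(peaks) / fs
    nb = len(beats)
    cols = {name: np.full(nb, np.nan) for name in MeasurementReport._INTERVAL_FIELDS}
    for i, b in enumerate(beats):
        rr_local = rr[i - 1] if i > 0 else rr[0]
        cols["qrs_interval_ms"][i] = (b.qrs_offset - b.qrs_onset) * ms
        if b.has_p and b.p_onset is not None and b.p_offset is not None:
            cols["p_duration_ms"][i] = (b.p_offset - b.p_onset) * ms
            cols["pr_interval_ms"][i] = (b.qrs_onset - b.p_onset) * ms
        if b.t_offset is not None:
            qt_s = (b.t_offset - b.qrs_onset) / fs
            cols["qt_interval_ms"][i] = qt_s * 1000.0
            cols["qtc_interval_ms"][i] = qtc_fn(qt_s, rr_local) * 1000.0
        if b.t_onset is not None and b.t_offset is not None:
            cols["t_duration_ms"][i] = (b.t_offset - b.t_onset) * ms

    ventricular = 60.0 / float(np.mean(rr))
    p_peaks = [b.p_peak for b in beats if b.has_p]
    atrial = None
    if len(p_peaks) >= 2:
        pp = np.diff(np.asarray(p_peaks)) / fs
        # Ignore PP gaps spanning beats without P waves.
        pp = pp[pp < 2.0 * np.median(rr)]
        if pp.size:
            atrial = 60.0 / float(np.mean(pp))

    return MeasurementReport(
        atrial_rate_bpm=atrial,
        ventricular_rate_bpm=ventricular,
        summary_stat=summary_stat,
        **cols,
    )


def compute_average_beat(
    record: ECGRecord,
    annotations: WaveAnnotationSet,
    pre_s: float = 0.3,
    post_s: float = 0.5,
) -> AverageBeat:
    """Average the waveform over beats, aligned on the QRS peak.

    Only beats whose full (-pre_s, +post_s) window lies inside the record
    are used; at least 5 such beats are required.
    """
    fs = record.sampling_rate
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    windows = []
    for b in annotations.beats:
        lo, hi = b.qrs_peak - pre, b.qrs_peak + post
        if lo >= 0 and hi <= record.n_samples:
            windows.append(record.samples[lo:hi])
    if len(windows) < 5:
        raise InsufficientDataError(
            f"need at least 5 complete beats, got {len(windows)}"
        )
    template = np.mean(np.stack(windows), axis=0)
    return AverageBeat(
        template=template, pre_samples=pre, sampling_rate=fs, n_beats=len(windows)
    )


def compute_hrv(qrs_peaks, sampling_rate: float) -> HRVSummary:
    """SDNN, RMSSD and pNN50 of the RR sequence (sample std, ddof=1)."""
    peaks = np.asarray(qrs_peaks, dtype=float)
    if peaks.size < 3:
        raise InsufficientDataError("need at least 3 peaks for HRV")
    rr = np.diff(peaks) / sampling_rate
    drr = np.diff(rr)
    return HRVSummary(
        mean_rr=float(np.mean(rr)),
        sdnn=float(np.std(rr, ddof=1)),
        rmssd=float(np.sqrt(np.mean(drr**2))),
        pnn50=float(np.mean(np.abs(drr) > 0.05)),
        n_intervals=int(rr.size),
    )


def rr_scatter(qrs_peaks, sampling_rate: float) -> RRScatter:
    """Consecutive (rr_i, rr_{i+1}) pairs for the Poincaré-style scatter."""
    peaks = np.asarray(qrs_peaks, dtype=float)
    if peaks.size < 3:
        raise InsufficientDataError("need at least 3 peaks for an RR scatter")
    rr = np.diff(peaks) / sampling_rate
    points = np.column_stack([rr[:-1], rr[1:]])
    return RRScatter(points=points)
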