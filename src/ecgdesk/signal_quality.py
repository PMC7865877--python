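"""Signal-quality stage: denoising, baseline removal, and lead-off detection.

The cleaning chain mirrors the acquisition software: a 50-Hz low-pass
combined with a 60-Hz notch removes high-frequency interference, and a
0.67-Hz high-pass combined with a moving-average baseline estimator removes
low-frequency wander.  All filters are applied forward-backward so wave
fiducials are not shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError, NonFiniteSignalError, SignalTooShortError
from .records import ECGRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the cleaning chain.

    Cutoffs follow the acquisition software defaults: 50-Hz low-pass,
    60-Hz notch, 0.67-Hz high-pass, 1-s moving-average baseline window.
    """

    lowpass_cutoff: float = 50.0
    notch_freq: float = 60.0
    highpass_cutoff: float = 0.67
    moving_average_window: float = 1.0
    lowpass_order: int = 4
    highpass_order: int = 2
    notch_q: float = 30.0
    flatline_std_threshold: float = 0.01
    flatline_min_duration: float = 2.0
    baseline_first: bool = True
    apply_notch: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not 0 < self.highpass_cutoff < self.lowpass_cutoff:
            raise ConfigError("need 0 < highpass_cutoff < lowpass_cutoff")
        if not self.lowpass_cutoff < nyq:
            raise ConfigError(
                f"lowpass_cutoff {self.lowpass_cutoff} must be below Nyquist {nyq}"
            )
        if self.moving_average_window <= 0:
            raise ConfigError("moving_average_window must be positive")
        if self.flatline_min_duration <= 0 or self.flatline_std_threshold < 0:
            raise ConfigError("invalid flatline parameters")


def _check_input(record: ECGRecord, min_samples: int) -> None:
    if not np.all(np.isfinite(record.samples)):
        raise NonFiniteSignalError(
            f"record {record.record_id!r} contains non-finite samples"
        )
    if record.n_samples < min_samples:
        raise SignalTooShortError(
            f"record {record.record_id!r} has {record.n_samples} samples, "
            f"needs at least {min_samples}"
        )


# Settling length (in samples) used for the too-short check: three times the
# default filtfilt pad length of the highest-order stage.
_SETTLE_SAMPLES = 15


def remove_high_frequency_noise(
    record: ECGRecord, config: FilterConfig | None = None
) -> ECGRecord:
    """Suppress high-frequency interference.

    A zero-phase low-pass (Butterworth, ``lowpass_order``) at
    ``lowpass_cutoff`` plus an IIR notch at ``notch_freq``.  If the notch
    frequency is at or above Nyquist the notch stage is skipped with a
    logged warning.  Output length equals input length and the flag
    ``"hf_denoised"`` is added.
    """
    config = config or FilterConfig()
    config.validate(record.sampling_rate)
    _check_input(record, 3 * _SETTLE_SAMPLES)
    fs = record.sampling_rate

    sos = sps.butter(
        config.lowpass_order, config.lowpass_cutoff, btype="low", fs=fs, output="sos"
    )
    y = sps.sosfiltfilt(sos, record.samples)

    if config.apply_notch:
        if config.notch_freq < fs / 2.0:
            b, a = sps.iirnotch(config.notch_freq, config.notch_q, fs=fs)
            y = sps.filtfilt(b, a, y)
        else:
            log.warning(
                "notch frequency %.1f Hz >= Nyquist %.1f Hz; notch stage skipped",
                config.notch_freq,
                fs / 2.0,
            )
    return record.with_samples(y, add_flags=("hf_denoised",))


def remove_baseline_wander(
    record: ECGRecord, config: FilterConfig | None = None
) -> ECGRecord:
    """Remove low-frequency baseline wander.

    A zero-phase high-pass at ``highpass_cutoff`` followed by subtraction of
    a centered moving-average baseline estimate (window
    ``moving_average_window`` seconds).  Adds the ``"baseline_removed"``
    flag.
    """
    config = config or FilterConfig()
    config.validate(record.sampling_rate)
    _check_input(record, 3 * _SETTLE_SAMPLES)
    fs = record.sampling_rate

    sos = sps.butter(
        config.highpass_order,
        config.highpass_cutoff,
        btype="high",
        fs=fs,
        output="sos",
    )
    y = sps.sosfiltfilt(sos, record.samples)

    window = max(3, int(round(config.moving_average_window * fs)) | 1)
    if window < record.n_samples:
        baseline = uniform_filter1d(y, size=window, mode="reflect")
        y = y - baseline
    return record.with_samples(y, add_flags=("baseline_removed",))


def detect_empty_signal(
    record: ECGRecord, config: FilterConfig | None = None
) -> tuple[bool, list[tuple[int, int]]]:
    """Detect lead-off / flat-line stretches.

    Returns ``(is_empty, intervals)`` where ``is_empty`` is true iff some
    contiguous interval of at least ``flatline_min_duration`` seconds has a
    sample standard deviation below ``flatline_std_threshold``, and
    ``intervals`` are the ``(start, stop)`` sample index spans (half-open)
    of all such stretches.
    """
    config = config or FilterConfig()
    config.validate(record.sampling_rate)
    x = record.samples
    n = x.size
    w = int(round(config.flatline_min_duration * record.sampling_rate))
    if n < max(w, 2):
        flat = float(np.std(x)) < config.flatline_std_threshold
        return flat, [(0, n)] if flat else []

    # Rolling standard deviation over every length-w window via cumsums.
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    flat_mask = np.sqrt(var) < config.flatline_std_threshold  # per window start

    intervals: list[tuple[int, int]] = []
    starts = np.flatnonzero(flat_mask)
    if starts.size:
        # Union of flagged windows [i, i+w), merged into maximal intervals.
        gap = np.flatnonzero(np.diff(starts) > w)
        run_starts = np.concatenate(([0], gap + 1))
        run_stops = np.concatenate((gap, [starts.size - 1]))
        for a, b in zip(run_starts, run_stops):
            intervals.append((int(starts[a]), int(starts[b]) + w))
    return bool(starts.size), intervals


def clean(record: ECGRecord, config: FilterConfig | None = None) -> ECGRecord:
    """Full cleaning chain: lead-off check plus the two filter chains.

    Baseline removal and high-frequency denoising are applied in the order
    selected by ``config.baseline_first``; the empty-signal verdict is
    recorded in provenance.
    """
    config = config or FilterConfig()
    is_empty, _ = detect_empty_signal(record, config)
    out = record
    if config.baseline_first:
        out = remove_baseline_wander(out, config)
        out = remove_high_frequency_noise(out, config)
    else:
        out = remove_high_frequency_noise(out, config)
        out = remove_baseline_wander(out, config)
    if is_empty:
        out = out.with_flags("empty")
    return out
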