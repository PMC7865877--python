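"""Waveform and annotation I/O.

Two dialects are supported: a minimal native WFDB subset (header ``.hea``
plus a format-16 little-endian ``.dat``, single signal) and two-column CSV
(``time_s,amplitude_mV`` with a mandatory header).  Records read at a rate
other than 125 Hz are polyphase-resampled to 125 Hz with a logged notice.
"""

from __future__ import annotations

import json
import logging
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .errors import ParseError
from .records import ECGRecord

log = logging.getLogger(__name__)

WFDB_GAIN = 200.0  # ADC units per mV
CSV_COLUMNS = ("time_s", "amplitude_mV")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".hea", ".dat", ""):
        return "wfdb"
    raise ParseError(f"cannot infer record format from {path.name!r}")


def read_record(path, fmt: str | None = None, resample_to: float | None = 125.0) -> ECGRecord:
    """Read an ECG record from WFDB or CSV.

    CSV sampling rate is inferred from the time column; WFDB from the
    header.  When ``resample_to`` is set and differs from the native rate,
    the waveform is resampled (polyphase) with a logged notice.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        record = _read_csv(path)
    elif fmt == "wfdb":
        record = _read_wfdb(path)
    else:
        raise ParseError(f"unknown format {fmt!r}")

    if resample_to and abs(record.sampling_rate - resample_to) > 1e-6:
        log.info(
            "resampling %r from %.6g Hz to %.6g Hz",
            record.record_id, record.sampling_rate, resample_to,
        )
        frac = Fraction(resample_to / record.sampling_rate).limit_denominator(1000)
        y = resample_poly(record.samples, frac.numerator, frac.denominator)
        record = ECGRecord(
            samples=y,
            sampling_rate=resample_to,
            record_id=record.record_id,
            lead_label=record.lead_label,
            provenance=record.provenance,
        )
    return record


def write_record(record: ECGRecord, path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        return _write_csv(record, path)
    if fmt == "wfdb":
        return _write_wfdb(record, path)
    raise ParseError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# CSV


def _read_csv(path: Path) -> ECGRecord:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if frame.empty and frame.columns.size == 0:
        raise ParseError(f"{path}: empty file")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required columns {missing}; header must be "
            f"'{','.join(CSV_COLUMNS)}'"
        )
    t = frame["time_s"].to_numpy(dtype=float)
    x = frame["amplitude_mV"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 rows to infer the sampling rate")
    dt = np.median(np.diff(t))
    if not np.isfinite(dt) or dt <= 0:
        raise ParseError(f"{path}: time column is not strictly increasing")
    fs = 1.0 / dt
    if fs > 10000 or fs < 1:
        raise ParseError(
            f"{path}: inferred rate {fs:.3g} Hz is implausible; "
            "are time units really seconds?"
        )
    return ECGRecord(samples=x, sampling_rate=float(round(fs, 6)),
                     record_id=path.stem)


def _write_csv(record: ECGRecord, path: Path) -> Path:
    frame = pd.DataFrame({"time_s": record.time, "amplitude_mV": record.samples})
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# WFDB (native minimal subset: single signal, format 16)


def _write_wfdb(record: ECGRecord, path: Path) -> Path:
    stem = path.with_suffix("")
    name = stem.name
    adc = np.clip(np.round(record.samples * WFDB_GAIN), -32768, 32767).astype(
        "<i2"
    )
    (stem.parent / f"{name}.dat").write_bytes(adc.tobytes())
    checksum = int(np.sum(adc.astype(np.int64)) % 65536)
    fs = record.sampling_rate
    fs_str = f"{fs:g}"
    header = (
        f"{name} 1 {fs_str} {record.n_samples}\n"
        f"{name}.dat 16 {WFDB_GAIN:g}/mV 16 0 {int(adc[0])} {checksum} 0 "
        f"{record.lead_label}\n"
    )
    (stem.parent / f"{name}.hea").write_text(header)
    return stem.parent / f"{name}.hea"


def _read_wfdb(path: Path) -> ECGRecord:
    stem = path.with_suffix("")
    hea = stem.parent / f"{stem.name}.hea"
    if not hea.exists():
        raise ParseError(f"missing WFDB header {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if len(lines) < 2:
        raise ParseError(f"{hea}: header must have a record line and a signal line")
    rec_fields = lines[0].split()
    if len(rec_fields) < 4:
        raise ParseError(f"{hea}: bad record line {lines[0]!r}")
    try:
        n_sig = int(rec_fields[1])
        fs = float(rec_fields[2])
        n_samples = int(rec_fields[3])
    except ValueError as exc:
        raise ParseError(f"{hea}: bad record line {lines[0]!r}: {exc}") from exc
    if n_sig != 1:
        raise ParseError(f"{hea}: only single-signal records are supported")
    sig_fields = lines[1].split()
    if len(sig_fields) < 3:
        raise ParseError(f"{hea}: bad signal line {lines[1]!r}")
    dat_name, fmt = sig_fields[0], sig_fields[1]
    if fmt != "16":
        raise ParseError(f"{hea}: only format 16 is supported, got {fmt}")
    gain_field = sig_fields[2].split("/")[0]
    try:
        gain = float(gain_field) or WFDB_GAIN
    except ValueError as exc:
        raise ParseError(f"{hea}: bad gain {sig_fields[2]!r}") from exc
    lead = sig_fields[8] if len(sig_fields) > 8 else "I"

    dat = stem.parent / dat_name
    if not dat.exists():
        raise ParseError(f"missing WFDB data file {dat}")
    adc = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if adc.size < n_samples:
        raise ParseError(
            f"{dat}: expected {n_samples} samples, found {adc.size}"
        )
    samples = adc[:n_samples].astype(np.float64) / gain
    return ECGRecord(
        samples=samples, sampling_rate=fs, record_id=stem.name, lead_label=lead
    )


# ---------------------------------------------------------------------------
# annotations


def write_annotations(annotations, path) -> Path:
    """Write a :class:`WaveAnnotationSet` as JSON (and nothing binary)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(annotations.as_dict(), fh, indent=2, sort_keys=True)
    return path


def write_annotation_table(annotations, path) -> Path:
    """WFDB-style plain-text annotation table: sample index + symbol rows."""
    symbols = {
        "p_onset": "(p", "p_peak": "p", "p_offset": "p)",
        "qrs_onset": "(N", "qrs_peak": "N", "qrs_offset": "N)",
        "t_onset": "(t", "t_peak": "t", "t_offset": "t)",
    }
    rows = []
    for beat in annotations.beats:
        for key, sym in symbols.items():
            idx = getattr(beat, key)
            if idx is not None:
                rows.append((idx, sym, beat.beat_index))
    rows.sort()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\tsymbol\tbeat\n")
        for idx, sym, beat_i in rows:
            fh.write(f"{idx}\t{sym}\t{beat_i}\n")
    return path
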