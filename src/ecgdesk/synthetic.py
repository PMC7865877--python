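"""Seeded generator of labelled single-lead ECGs with analytic ground truth.

Each beat is a sum of Gaussian deflections (P, Q, R, S, T) placed by an
RR-interval process that realizes the requested rhythm class.  Because the
morphology is analytic, every wave onset/peak/offset is known exactly and is
emitted as ground truth, which makes the generator the test substrate for
the cleaning, delineation and diagnosis stages.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .records import ECGRecord

#: Supported rhythm classes and the diagnosis item each one is labelled with.
RHYTHM_TO_ITEM = {
    "normal_sinus": "SN",
    "sinus_tachycardia": "SNT",
    "sinus_bradycardia": "SNB",
    "sinus_arrhythmia": "SNA",
    "irregular_af_like": "AF",
    "ectopic_pvc_like": "PVC",
    "ectopic_pac_like": "PAC",
    "long_pr_block_like": "AVBI",
    "wide_qrs_block_like": "LBBB",
}

#: Default per-wave (amplitude mV, duration ms). Duration is the +-3 sigma
#: support of the Gaussian bump.
DEFAULT_WAVE_PARAMS = {
    "p": (0.15, 80.0),
    "q": (-0.10, 30.0),
    "r": (1.00, 40.0),
    "s": (-0.15, 30.0),
    "t": (0.30, 160.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    duration: float = 30.0
    sampling_rate: float = 125.0
    heart_rate: float = 70.0
    rhythm: str = "normal_sinus"
    hf_noise_amp: float = 0.0
    baseline_amp: float = 0.0
    baseline_freq: float = 0.25
    reversed: bool = False
    wave_params: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_PARAMS))
    pr_ms: float = 160.0
    qt_ms: float = 360.0
    rr_jitter: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if not 20 <= self.heart_rate <= 250:
            raise ConfigError(f"heart_rate {self.heart_rate} outside [20, 250] bpm")
        if self.rhythm not in RHYTHM_TO_ITEM:
            raise ConfigError(
                f"unknown rhythm {self.rhythm!r}; one of {sorted(RHYTHM_TO_ITEM)}"
            )
        for name, (amp, width) in self.wave_params.items():
            if not (np.isfinite(amp) and np.isfinite(width) and width > 0):
                raise ConfigError(f"invalid wave parameters for {name!r}")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")


@dataclass
class BeatTruth:
    """Ground-truth fiducials of one beat, all in seconds from record start."""

    r_peak: float
    p_onset: float | None
    p_peak: float | None
    p_offset: float | None
    qrs_onset: float
    qrs_offset: float
    t_onset: float | None
    t_peak: float | None
    t_offset: float | None
    wide: bool = False
    premature: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class GroundTruth:
    beat_times: np.ndarray  # R-peak times, seconds
    beats: list[BeatTruth]
    reversed: bool
    rhythm: str
    heart_rate: float
    clean_samples: np.ndarray  # waveform before artifacts / reversal

    def as_dict(self) -> dict:
        return {
            "beat_times": [float(t) for t in self.beat_times],
            "beats": [b.as_dict() for b in self.beats],
            "reversed": self.reversed,
            "rhythm": self.rhythm,
            "heart_rate": self.heart_rate,
        }


@dataclass
class LabelledRecording:
    record: ECGRecord
    item_labels: frozenset
    ground_truth: GroundTruth


def _rr_sequence(spec: SyntheticSpec, rng: np.random.Generator):
    """Build (rr_intervals, per-beat modifiers) realizing the rhythm class."""
    base_rr = 60.0 / spec.heart_rate
    n_max = int(np.ceil(spec.duration / base_rr)) + 8
    mods: list[dict] = []
    rhythm = spec.rhythm

    if rhythm in ("normal_sinus", "sinus_tachycardia", "sinus_bradycardia",
                  "long_pr_block_like", "wide_qrs_block_like"):
        rr = base_rr * (1.0 + spec.rr_jitter * rng.standard_normal(n_max))
        mods = [{} for _ in range(n_max)]
    elif rhythm == "sinus_arrhythmia":
        # Respiratory-style modulation, ~10% swing at 0.25 Hz.
        phase = rng.uniform(0, 2 * np.pi)
        k = np.arange(n_max)
        rr = base_rr * (1.0 + 0.10 * np.sin(2 * np.pi * 0.25 * k * base_rr + phase)
                        + 0.01 * rng.standard_normal(n_max))
        mods = [{} for _ in range(n_max)]
    elif rhythm == "irregular_af_like":
        # i.i.d. RR with coefficient of variation >= 0.15, no P waves.
        rr = base_rr * (1.0 + 0.20 * rng.standard_normal(n_max))
        mods = [{"no_p": True} for _ in range(n_max)]
    elif rhythm in ("ectopic_pvc_like", "ectopic_pac_like"):
        rr = base_rr * (1.0 + spec.rr_jitter * rng.standard_normal(n_max))
        mods = [{} for _ in range(n_max)]
        ectopic = rng.random(n_max) < 0.10
        ectopic[:2] = False
        for i in np.flatnonzero(ectopic):
            rr[i - 1] *= 0.65  # premature coupling interval before the ectopic beat
            rr[i] *= 1.25  # compensatory-style pause after it
            if rhythm == "ectopic_pvc_like":
                mods[i] = {"wide": True, "no_p": True, "premature": True}
            else:
                mods[i] = {"premature": True}
    else:  # pragma: no cover - guarded by validate()
        raise ConfigError(f"unknown rhythm {rhythm!r}")

    rr = np.clip(rr, 0.24, 3.0)
    return rr, mods


def _place_beat(spec: SyntheticSpec, t_r: float, rr_local: float, mod: dict):
    """Compute per-beat wave centers/sigmas and the ground-truth fiducials."""
    wp = {k: v for k, v in DEFAULT_WAVE_PARAMS.items()}
    wp.update(spec.wave_params)

    widen = 2.2 if (mod.get("wide") or spec.rhythm == "wide_qrs_block_like") else 1.0
    sig = {k: (wp[k][1] / 1000.0) / 6.0 for k in wp}
    amp = {k: wp[k][0] for k in wp}
    for k in ("q", "r", "s"):
        sig[k] *= widen
    if mod.get("wide"):
        amp["r"] *= 1.25

    q_c = t_r - 2.0 * (sig["r"] + sig["q"])
    s_c = t_r + 2.0 * (sig["r"] + sig["s"])
    qrs_onset = q_c - 3.0 * sig["q"]
    qrs_offset = s_c + 3.0 * sig["s"]

    # Rate-adapted PR and QT targets so beats do not collide at high rates.
    pr = (spec.pr_ms / 1000.0) * float(np.clip(np.sqrt(rr_local / 0.86), 0.6, 1.0))
    if spec.rhythm == "long_pr_block_like":
        pr = max(pr, 0.24)
    qt = (spec.qt_ms / 1000.0) * float(np.clip(np.sqrt(rr_local), 0.55, 1.1))
    qt = min(qt, max(0.6 * rr_local, qrs_offset - qrs_onset + 6.0 * sig["t"] + 0.02))

    centers = {"q": q_c, "r": t_r, "s": s_c}
    truth = {"qrs_onset": qrs_onset, "qrs_offset": qrs_offset}

    no_p = mod.get("no_p", False)
    if no_p:
        amp["p"] = 0.0
        truth.update(p_onset=None, p_peak=None, p_offset=None)
    else:
        p_on = qrs_onset - pr
        p_c = p_on + 3.0 * sig["p"]
        centers["p"] = p_c
        truth.update(p_onset=p_on, p_peak=p_c, p_offset=p_c + 3.0 * sig["p"])

    # Narrow the T wave when the rate-shortened QT cannot hold its full
    # width, so the T never spills into the QRS or the next beat's P.
    avail = qt - (qrs_offset - qrs_onset) - 0.02
    if 6.0 * sig["t"] > avail:
        sig["t"] = max(avail / 6.0, 0.08 / 6.0)
    t_off = qrs_onset + qt
    t_c = t_off - 3.0 * sig["t"]
    if t_c - 3.0 * sig["t"] < qrs_offset:  # pathological fallback
        t_c = qrs_offset + 3.0 * sig["t"] + 0.01
        t_off = t_c + 3.0 * sig["t"]
    centers["t"] = t_c
    truth.update(t_onset=t_c - 3.0 * sig["t"], t_peak=t_c, t_offset=t_off)

    bumps = [(centers[k], sig[k], amp[k]) for k in centers if amp[k] != 0.0]
    bt = BeatTruth(
        r_peak=t_r,
        p_onset=truth.get("p_onset"),
        p_peak=truth.get("p_peak"),
        p_offset=truth.get("p_offset"),
        qrs_onset=truth["qrs_onset"],
        qrs_offset=truth["qrs_offset"],
        t_onset=truth["t_onset"],
        t_peak=truth["t_peak"],
        t_offset=truth["t_offset"],
        wide=bool(mod.get("wide") or spec.rhythm == "wide_qrs_block_like"),
        premature=bool(mod.get("premature", False)),
    )
    return bumps, bt


def generate(spec: SyntheticSpec) -> LabelledRecording:
    """Generate one labelled recording; bit-reproducible for a given seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    rr, mods = _rr_sequence(spec, rng)
    beat_times = 0.4 + np.concatenate(([0.0], np.cumsum(rr[:-1])))

    beats: list[BeatTruth] = []
    kept_times = []
    for i, t_r in enumerate(beat_times):
        if t_r > spec.duration - 0.05:
            break
        rr_local = rr[i] if i < len(rr) else rr[-1]
        bumps, bt = _place_beat(spec, float(t_r), float(rr_local), mods[i])
        for c, s, a in bumps:
            lo = max(0, int((c - 5 * s) * fs))
            hi = min(n, int((c + 5 * s) * fs) + 1)
            if hi > lo:
                x[lo:hi] += a * np.exp(-0.5 * ((t[lo:hi] - c) / s) ** 2)
        beats.append(bt)
        kept_times.append(float(t_r))

    clean = x.copy()
    noisy = _apply_artifacts(x, t, spec, rng)
    if spec.reversed:
        noisy = -noisy

    record = ECGRecord(
        samples=noisy,
        sampling_rate=fs,
        record_id=f"syn-{spec.rhythm}-{spec.seed}",
        provenance=frozenset({"raw"}),
    )
    truth = GroundTruth(
        beat_times=np.asarray(kept_times),
        beats=beats,
        reversed=spec.reversed,
        rhythm=spec.rhythm,
        heart_rate=spec.heart_rate,
        clean_samples=clean,
    )
    labels = frozenset({RHYTHM_TO_ITEM[spec.rhythm]})
    return LabelledRecording(record=record, item_labels=labels, ground_truth=truth)


def _apply_artifacts(x, t, spec: SyntheticSpec, rng: np.random.Generator):
    y = x
    if spec.hf_noise_amp > 0:
        noise = rng.standard_normal(x.size)
        nyq = spec.sampling_rate / 2.0
        if 40.0 < nyq:
            sos = sps.butter(4, 40.0, btype="high", fs=spec.sampling_rate,
                             output="sos")
            noise = sps.sosfiltfilt(sos, noise)
        rms = np.sqrt(np.mean(noise**2))
        if rms > 0:
            noise = noise * (spec.hf_noise_amp / rms)
        y = y + noise
    if spec.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        y = y + spec.baseline_amp * np.sin(2 * np.pi * spec.baseline_freq * t + phase)
    return y


def add_artifacts(record: ECGRecord, spec: SyntheticSpec, seed: int) -> ECGRecord:
    """Add band-limited (>=40 Hz) noise and a baseline sinusoid to a record."""
    rng = np.random.default_rng(seed)
    y = _apply_artifacts(record.samples, record.time, replace(spec,
                         sampling_rate=record.sampling_rate), rng)
    return record.with_samples(y)


def make_dataset(
    n: int,
    class_mix: dict,
    seed: int,
    duration: float = 30.0,
    spec_overrides: dict | None = None,
) -> list[LabelledRecording]:
    """Generate ``n`` recordings with class counts matching ``class_mix``.

    Per-record seeds are derived deterministically from the master seed, so
    two calls with the same arguments produce identical datasets.  Class
    counts follow the fractions by largest remainder.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"class fractions must sum to 1, got {total}")
    for rhythm in class_mix:
        if rhythm not in RHYTHM_TO_ITEM:
            raise ConfigError(f"unknown rhythm {rhythm!r}")

    rhythms = sorted(class_mix)
    raw = np.array([class_mix[r] * n for r in rhythms])
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1

    default_rates = {
        "sinus_tachycardia": 120.0,
        "sinus_bradycardia": 45.0,
    }
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n, dtype=np.uint32)

    out: list[LabelledRecording] = []
    idx = 0
    overrides = spec_overrides or {}
    for rhythm, count in zip(rhythms, counts):
        for _ in range(count):
            kwargs = dict(
                duration=duration,
                rhythm=rhythm,
                heart_rate=default_rates.get(rhythm, 70.0),
                seed=int(child_seeds[idx]),
            )
            kwargs.update(overrides)
            kwargs["rhythm"] = rhythm
            kwargs["seed"] = int(child_seeds[idx])
            out.append(generate(SyntheticSpec(**kwargs)))
            idx += 1
    return out


def write_dataset(recordings: list[LabelledRecording], out_dir) -> Path:
    """Write a dataset as WFDB records + JSON truth sidecars + manifest CSV."""
    from .io import write_record  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record", "labels"])
        for i, rec in enumerate(recordings):
            stem = f"rec{i:05d}"
            write_record(rec.record, out_dir / f"{stem}.hea", fmt="wfdb")
            with open(out_dir / f"{stem}.truth.json", "w") as jf:
                json.dump(rec.ground_truth.as_dict(), jf)
            writer.writerow([stem, ",".join(sorted(rec.item_labels))])
    return manifest
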