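"""Core waveform container used by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError

#: Processing flags a record may accumulate. Flags only ever grow along the
#: pipeline; no stage removes a flag set by an earlier one.
KNOWN_FLAGS = frozenset(
    {"raw", "hf_denoised", "baseline_removed", "reversed_suspected", "empty"}
)

DEFAULT_SAMPLING_RATE = 125.0


@dataclass(frozen=True)
class ECGRecord:
    """A single-lead ECG waveform in millivolts.

    Parameters
    ----------
    samples
        Amplitudes in mV, one per sample.
    sampling_rate
        Samples per second (the target acquisition rate is 125 Hz).
    record_id
        Opaque identifier, e.g. a file stem.
    lead_label
        Lead name; the acquisition hardware is Lead-I equivalent.
    provenance
        Set of processing flags; see :data:`KNOWN_FLAGS`.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    record_id: str = ""
    lead_label: str = "I"
    provenance: frozenset = field(default_factory=lambda: frozenset({"raw"}))

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ConfigError("samples must be a non-empty 1-D sequence")
        if not self.sampling_rate > 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "provenance", frozenset(self.provenance))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, add_flags=()) -> "ECGRecord":
        """Return a copy with new samples and the union of provenance flags."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=np.float64),
            provenance=self.provenance | frozenset(add_flags),
        )

    def with_flags(self, *flags: str) -> "ECGRecord":
        return replace(self, provenance=self.provenance | frozenset(flags))

    def has_flag(self, flag: str) -> bool:
        return flag in self.provenance
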