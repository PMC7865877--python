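import numpy as np
import pytest

from ecgdesk import ECGRecord, SyntheticSpec, generate

FS = 125.0


@pytest.fixture(scope="session")
def normal_recording():
    """30-s clean normal-sinus recording at 60 bpm with ground truth."""
    return generate(SyntheticSpec(duration=30.0, heart_rate=60.0, seed=11))


@pytest.fixture(scope="session")
def noisy_recording():
    """30-s normal-sinus recording with HF noise and baseline drift."""
    return generate(
        SyntheticSpec(
            duration=30.0,
            heart_rate=60.0,
            seed=12,
            hf_noise_amp=0.05,
            baseline_amp=0.5,
            baseline_freq=0.2,
        )
    )


@pytest.fixture()
def zero_record():
    return ECGRecord(samples=np.zeros(int(10 * FS)), sampling_rate=FS,
                     record_id="zeros")


def sine_record(freq, amp=1.0, duration=10.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return ECGRecord(samples=amp * np.sin(2 * np.pi * freq * t), sampling_rate=fs,
                     record_id=f"sine{freq}")


def fourier_amplitude(x, freq, fs):
    """Single-bin Fourier amplitude oracle (independent of scipy filters)."""
    n = len(x)
    t = np.arange(n) / fs
    c = np.sum(x * np.exp(-2j * np.pi * freq * t)) / n
    return 2.0 * np.abs(c)
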