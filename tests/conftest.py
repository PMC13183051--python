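import numpy as np
import pytest

from faakit.synthetic import CohortConfig, EEGSynthesisSpec, cohort_to_frame, generate_cohort, generate_eeg


@pytest.fixture(scope="session")
def default_cohort_df():
    """Moment-matching cohort at the reference group sizes (126/51)."""
    return cohort_to_frame(generate_cohort(CohortConfig(seed=42)))


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free asymmetric recording (target FAA 0.2), 60 s."""
    spec = EEGSynthesisSpec(target_faa=0.2, duration_s=60, noise_sd=0.0,
                            blink_rate=0.0, artifact_rate=0.0, seed=7)
    return generate_eeg(spec)


def sinusoid_recording(freq, fs=500.0, duration_s=10.0, amp=1.0, label="F3"):
    from faakit.eeg import EEGRecording
    t = np.arange(int(duration_s * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return EEGRecording(samples=x[None, :], fs=fs, channel_labels=[label])
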