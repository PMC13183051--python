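"""Synthesize a frontal EEG recording with a known alpha asymmetry and
recover it through the spectral pipeline.

The generator plants alpha-band (10 Hz) sinusoids on F3/F4 whose power
ratio realizes the requested FAA; pink noise, blinks and artifact bursts
are layered on top. The pipeline bandpasses 0.3-40 Hz, masks artifacts by a
robust amplitude rule, runs Welch PSD and forms (P_F4-P_F3)/(P_F4+P_F3).
"""

from faakit import EEGSynthesisSpec, faa_from_recording, generate_eeg

spec = EEGSynthesisSpec(target_faa=0.0891, duration_s=240, noise_sd=0.5,
                        blink_rate=2.0, artifact_rate=0.5, seed=42)
rec = generate_eeg(spec)
res = faa_from_recording(rec)

print(f"target FAA (x1e-3): {1000 * spec.target_faa:.2f}")
print(f"measured FAA (x1e-3): {res['faa_reported']:.2f}")
print(f"alpha power F3 / F4 (uV^2/Hz): {res['p_f3']:.3f} / {res['p_f4']:.3f}")
print(f"clean data used: {res['n_clean_seconds']:.1f} of {spec.duration_s:.0f} s")
# The measured value should sit within a few x1e-3 units of the target:
# the residual gap comes from noise power shared by both channels.
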