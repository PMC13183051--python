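"""Signal chain from raw multichannel EEG to the frontal alpha asymmetry index.

The pipeline mirrors a standard resting-state spectral workflow: common
average re-referencing over scalp channels, zero-phase 0.3–40 Hz bandpass,
amplitude-based artifact masking, Welch power spectral density, mean
alpha-band (8–13 Hz) power at F3 and F4, and the asymmetry ratio

    FAA = (P_F4 - P_F3) / (P_F4 + P_F3),

a dimensionless quantity in [-1, 1], conventionally reported on a x1000
scale. Positive values indicate greater right-frontal alpha power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

ALPHA_BAND = (8.0, 13.0)

#: channel labels never included in the scalp average (ocular / auxiliary)
AUX_LABELS = frozenset(
    {"veog", "heog", "eog", "eogl", "eogr", "ecg", "ekg", "emg", "a1", "a2", "m1", "m2"}
)


def is_scalp_channel(label: str) -> bool:
    return label.strip().lower() not in AUX_LABELS


@dataclass
class EEGRecording:
    """Multichannel EEG: ``samples`` is channels x time in microvolts."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    artifact_mask: np.ndarray | None = None  # True = excluded sample

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} labels"
            )
        lowered = [c.strip().lower() for c in self.channel_labels]
        if len(set(lowered)) != len(lowered):
            raise ValueError("channel labels must be unique (case-insensitive)")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.samples.shape[1],):
                raise ValueError("artifact_mask length must match sample count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        lowered = [c.strip().lower() for c in self.channel_labels]
        key = label.strip().lower()
        if key not in lowered:
            raise KeyError(f"channel {label!r} not present (have {self.channel_labels})")
        return lowered.index(key)

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def scalp_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channel_labels) if is_scalp_channel(c)]


@dataclass
class SpectralEstimate:
    """Per-channel one-sided PSD (uV^2/Hz) on a shared frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs
    channel_labels: list[str]
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(self.psd < -1e-12):
            raise ValueError("PSD must be nonnegative")

    def channel_psd(self, label: str) -> np.ndarray:
        lowered = [c.strip().lower() for c in self.channel_labels]
        key = label.strip().lower()
        if key not in lowered:
            raise KeyError(f"channel {label!r} not in spectral estimate")
        return self.psd[lowered.index(key)]


@dataclass(frozen=True)
class AlphaPower:
    """Mean alpha-band power at the two frontal electrodes."""

    p_f3: float
    p_f4: float
    band: tuple[float, float] = ALPHA_BAND

    def __post_init__(self) -> None:
        if self.p_f3 < 0 or self.p_f4 < 0:
            raise ValueError("alpha powers must be nonnegative")


@dataclass(frozen=True)
class FAAIndex:
    """FAA as a ratio in [-1, 1] and on the conventional x1000 reporting scale."""

    ratio: float

    @property
    def reported(self) -> float:
        return 1000.0 * self.ratio


def rereference_common_average(rec: EEGRecording) -> EEGRecording:
    """Subtract, at each sample, the mean over scalp channels.

    Ocular and auxiliary channels are excluded from the average but are
    passed through re-referenced like the rest (their content is not used
    downstream). Requires at least two scalp channels.
    """
    scalp = rec.scalp_indices()
    if len(scalp) < 2:
        raise ValueError("common average reference requires >= 2 scalp channels")
    avg = rec.samples[scalp].mean(axis=0)
    return replace(rec, samples=rec.samples - avg)


def bandpass(rec: EEGRecording, low: float = 0.3, high: float = 40.0,
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth bandpass (forward-backward, no phase distortion)."""
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def reject_artifacts(rec: EEGRecording, z_threshold: float = 6.0,
                     pad_s: float = 0.2) -> EEGRecording:
    """Mask samples exceeding ``z_threshold`` robust SDs on any scalp channel.

    The robust SD is 1.4826 x MAD about the channel median, so a clean
    oscillation (max robust z below ~1) never triggers. Flagged samples are
    padded by ``pad_s`` seconds on each side. Raises if nothing survives.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    scalp = rec.scalp_indices()
    x = rec.samples[scalp]
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf  # flat channel: nothing to flag
    hit = np.any(np.abs(x - med) > z_threshold * robust_sd, axis=0)

    pad = int(round(pad_s * rec.fs))
    if pad > 0 and hit.any():
        from scipy.ndimage import binary_dilation
        hit = binary_dilation(hit, structure=np.ones(2 * pad + 1, dtype=bool))

    mask = hit if rec.artifact_mask is None else (hit | rec.artifact_mask)
    if mask.all():
        raise ValueError("artifact rejection masked every sample; no clean data")
    return replace(rec, artifact_mask=mask)


def _window_starts(n: int, nperseg: int, step: int,
                   mask: np.ndarray | None) -> list[int]:
    starts = []
    for s in range(0, n - nperseg + 1, step):
        if mask is not None and mask[s:s + nperseg].any():
            continue  # drop windows overlapping masked samples
        starts.append(s)
    return starts


def welch_psd(rec: EEGRecording, window_s: float = 2.0,
              overlap: float = 0.5) -> SpectralEstimate:
    """Welch PSD (Hann window, default 2 s / 50% overlap, density scaling).

    Windows overlapping the artifact mask are dropped entirely, so the
    estimate uses clean data only. Matches :func:`scipy.signal.welch`
    (``detrend=False``) when no mask is set.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nperseg = int(round(window_s * rec.fs))
    step = max(1, int(round(nperseg * (1 - overlap))))
    starts = _window_starts(rec.n_samples, nperseg, step, rec.artifact_mask)
    if len(starts) < 2:
        raise ValueError(
            "insufficient clean data for Welch PSD "
            f"(need >= 2 windows of {window_s} s, found {len(starts)})"
        )
    win = sps.get_window("hann", nperseg)
    scale = 1.0 / (rec.fs * (win * win).sum())
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / rec.fs)
    acc = np.zeros((rec.n_channels, freqs.size))
    for s in starts:
        seg = rec.samples[:, s:s + nperseg] * win
        spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2 * scale
        spec[:, 1:] *= 2.0  # one-sided
        if nperseg % 2 == 0:
            spec[:, -1] /= 2.0  # Nyquist bin is not doubled
        acc += spec
    acc /= len(starts)
    return SpectralEstimate(
        freqs=freqs, psd=acc, channel_labels=list(rec.channel_labels),
        method_params={"window_s": window_s, "overlap": overlap,
                       "window": "hann", "n_windows": len(starts)},
    )


def alpha_band_power(spec: SpectralEstimate, channel: str,
                     band: tuple[float, float] = ALPHA_BAND) -> float:
    """Mean PSD over grid frequencies f with band[0] <= f <= band[1] (inclusive)."""
    psd = spec.channel_psd(channel)
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"frequency grid does not cover the {band} Hz band")
    return float(psd[sel].mean())


def compute_faa(alpha: AlphaPower) -> FAAIndex:
    """FAA ratio (P_F4 - P_F3)/(P_F4 + P_F3); undefined when both powers are 0."""
    total = alpha.p_f4 + alpha.p_f3
    if total <= 0:
        raise ValueError("FAA undefined: p_f3 + p_f4 must be positive")
    return FAAIndex(ratio=(alpha.p_f4 - alpha.p_f3) / total)


def faa_from_recording(rec: EEGRecording, *, low: float = 0.3, high: float = 40.0,
                       z_threshold: float = 6.0, pad_s: float = 0.2,
                       window_s: float = 2.0, overlap: float = 0.5,
                       rereference: bool | None = None) -> dict:
    """Full chain: (re-reference) -> bandpass -> artifact mask -> Welch -> FAA.

    ``rereference=None`` applies the common average reference exactly when
    more than two scalp channels are present; with only F3/F4 the average
    reference is degenerate (it removes the symmetric signal component), so
    the two-channel path skips it.

    Returns a JSON-ready dict with alpha powers, the FAA ratio, the x1000
    reported value, clean-data seconds and the effective parameters.
    """
    if rereference is None:
        rereference = len(rec.scalp_indices()) > 2
    out = rereference_common_average(rec) if rereference else rec
    out = bandpass(out, low=low, high=high)
    out = reject_artifacts(out, z_threshold=z_threshold, pad_s=pad_s)
    spec = welch_psd(out, window_s=window_s, overlap=overlap)
    alpha = AlphaPower(p_f3=alpha_band_power(spec, "F3"),
                       p_f4=alpha_band_power(spec, "F4"))
    faa = compute_faa(alpha)
    n_clean = int((~out.artifact_mask).sum()) if out.artifact_mask is not None else out.n_samples
    return {
        "p_f3": alpha.p_f3,
        "p_f4": alpha.p_f4,
        "faa_ratio": faa.ratio,
        "faa_reported": faa.reported,
        "n_clean_seconds": n_clean / rec.fs,
        "params": {"low_hz": low, "high_hz": high, "z_threshold": z_threshold,
                   "pad_s": pad_s, "window_s": window_s, "overlap": overlap,
                   "rereference": rereference},
    }
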