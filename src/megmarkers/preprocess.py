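"""Resample, filter, epoch and artifact-reject continuous recordings.

The chain mirrors standard resting-state M/EEG reduction: polyphase
downsampling to 250 Hz, zero-phase 0.5 Hz high-pass and 50 Hz notch,
segmentation into non-overlapping 4-s epochs, and automatic rejection of
muscle-contaminated epochs by their 55-100 Hz log band power (z > 3 across
epochs within subject).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .synthetic import Recording

logger = logging.getLogger("megmarkers.preprocess")

__all__ = [
    "PreprocessConfig",
    "EpochSet",
    "resample",
    "filter_recording",
    "epoch_recording",
    "reject_artifacts",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_sfreq_hz: float = 250.0
    highpass_hz: float = 0.5
    notch_hz: float = 50.0
    epoch_length_s: float = 4.0
    artifact_zscore_threshold: float = 3.0
    artifact_band_hz: tuple[float, float] = (55.0, 100.0)
    max_rejection_fraction: float = 0.5

    def validate(self) -> None:
        nyq = self.target_sfreq_hz / 2.0
        if not (0 < self.highpass_hz < self.notch_hz < nyq):
            raise ValueError(
                f"need 0 < highpass ({self.highpass_hz}) < notch "
                f"({self.notch_hz}) < Nyquist ({nyq})"
            )
        n = self.epoch_length_s * self.target_sfreq_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length_s x target_sfreq_hz must be integer")


@dataclass
class EpochSet:
    """Epoch-index x channels x samples array with a kept/rejected mask."""

    epochs: np.ndarray
    sfreq_hz: float
    kept_mask: np.ndarray
    rejection_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        if len(self.kept_mask) != self.epochs.shape[0]:
            raise ValueError("kept_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept(self) -> np.ndarray:
        return self.epochs[self.kept_mask]


def resample(recording: Recording, target_sfreq_hz: float) -> Recording:
    """Anti-aliased polyphase downsampling to ``target_sfreq_hz``.

    Output length is floor(n_in * target / current).  Upsampling is refused:
    it would fabricate bandwidth the sensors never recorded.
    """
    cur = recording.sfreq_hz
    if target_sfreq_hz > cur:
        raise ValueError(
            f"upsampling not supported ({cur} Hz -> {target_sfreq_hz} Hz)"
        )
    if target_sfreq_hz == cur:
        return recording
    frac = Fraction(target_sfreq_hz / cur).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(recording.data, up, down, axis=1)
    n_out = int(np.floor(recording.n_samples * target_sfreq_hz / cur))
    out = out[:, :n_out]
    return Recording(data=out, sfreq_hz=target_sfreq_hz,
                     channel_names=list(recording.channel_names),
                     channel_types=list(recording.channel_types))


def filter_recording(recording: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth high-pass then zero-phase IIR notch (Q=30)."""
    cfg.validate()
    fs = recording.sfreq_hz
    if cfg.notch_hz >= fs / 2.0:
        raise ValueError(
            f"notch at {cfg.notch_hz} Hz is above Nyquist ({fs / 2.0} Hz)"
        )
    sos = sps.butter(4, cfg.highpass_hz, btype="highpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos, recording.data, axis=1)
    b, a = sps.iirnotch(cfg.notch_hz, Q=30.0, fs=fs)
    data = sps.filtfilt(b, a, data, axis=1)
    return Recording(data=data, sfreq_hz=fs,
                     channel_names=list(recording.channel_names),
                     channel_types=list(recording.channel_types))


def epoch_recording(recording: Recording, cfg: PreprocessConfig) -> EpochSet:
    """Cut consecutive non-overlapping epochs from sample 0; drop the tail."""
    n_per = int(round(cfg.epoch_length_s * recording.sfreq_hz))
    n_epochs = recording.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples is shorter than one "
            f"{n_per}-sample epoch"
        )
    data = recording.data[:, :n_epochs * n_per]
    epochs = data.reshape(recording.n_channels, n_epochs, n_per)
    epochs = np.ascontiguousarray(epochs.transpose(1, 0, 2))
    return EpochSet(epochs=epochs, sfreq_hz=recording.sfreq_hz,
                    kept_mask=np.ones(n_epochs, dtype=bool))


def _band_log_power(epochs: np.ndarray, sfreq: float,
                    band: tuple[float, float]) -> np.ndarray:
    """Per-epoch channel-mean log10 band power, via Welch on each channel."""
    n_samp = epochs.shape[-1]
    nperseg = min(512, n_samp)
    freqs, psd = sps.welch(epochs, fs=sfreq, nperseg=nperseg, axis=-1)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"artifact band {band} contains no frequency bins")
    power = np.trapezoid(psd[..., mask], freqs[mask], axis=-1)  # (E, C)
    return np.log10(power.mean(axis=-1) + 1e-300)


def reject_artifacts(epochs: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Mark epochs whose high-frequency log band power is an outlier.

    Scores are channel-averaged 55-100 Hz log band powers, z-scored across
    all epochs of the subject; epochs with z above the threshold are flagged
    in ``kept_mask`` (never deleted, so the audit trail survives).
    """
    cfg.validate()
    scores = _band_log_power(epochs.epochs, epochs.sfreq_hz, cfg.artifact_band_hz)
    if epochs.n_epochs < 2:
        logger.warning("single epoch: artifact rejection skipped (no variance)")
        log = {"scores": scores.tolist(), "zscores": [0.0] * epochs.n_epochs,
               "threshold": cfg.artifact_zscore_threshold, "skipped": True}
        return EpochSet(epochs=epochs.epochs, sfreq_hz=epochs.sfreq_hz,
                        kept_mask=epochs.kept_mask.copy(), rejection_log=log)
    sd = scores.std(ddof=0)
    z = np.zeros_like(scores) if sd == 0 else (scores - scores.mean()) / sd
    reject = z > cfg.artifact_zscore_threshold
    kept = epochs.kept_mask & ~reject
    frac_rejected = 1.0 - kept.sum() / epochs.n_epochs
    if frac_rejected > cfg.max_rejection_fraction:
        logger.warning(
            "rejected %.0f%% of epochs, above the %.0f%% cap: inspect this "
            "subject", 100 * frac_rejected, 100 * cfg.max_rejection_fraction,
        )
    log = {
        "scores": scores.tolist(),
        "zscores": z.tolist(),
        "threshold": cfg.artifact_zscore_threshold,
        "rejected_epochs": np.flatnonzero(reject).tolist(),
    }
    return EpochSet(epochs=epochs.epochs, sfreq_hz=epochs.sfreq_hz,
                    kept_mask=kept, rejection_log=log)


def preprocess_recording(recording: Recording, cfg: PreprocessConfig,
                         apply_filters: bool = True) -> EpochSet:
    """Full chain: resample -> (high-pass + notch) -> epoch -> reject."""
    rec = resample(recording, cfg.target_sfreq_hz)
    if apply_filters:
        rec = filter_recording(rec, cfg)
    return reject_artifacts(epoch_recording(rec, cfg), cfg)
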