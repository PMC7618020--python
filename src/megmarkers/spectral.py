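"""Theta-alpha ratio (TAR): the arousal/drowsiness marker.

TAR is the ratio of theta (3-5 Hz) to alpha (8-12 Hz) band power, with
band powers estimated by Welch's method per channel and averaged over all
gradiometer channels in the epoch.  Eyes-closed wakefulness shows a strong
alpha peak (TAR ~ 1 or below); drowsiness suppresses alpha and boosts
theta, raising TAR.  Note the deliberately narrow theta band: 3-5 Hz, not
the conventional 4-8 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .complexity import MissingMarkerError
from .preprocess import EpochSet

logger = logging.getLogger("megmarkers.spectral")

__all__ = [
    "SpectralConfig",
    "TarEpochResult",
    "welch_psd",
    "band_power",
    "tar_epoch",
    "tar_subject",
]


@dataclass(frozen=True)
class SpectralConfig:
    theta_band_hz: tuple[float, float] = (3.0, 5.0)
    alpha_band_hz: tuple[float, float] = (8.0, 12.0)
    welch_segment_s: float = 2.0
    welch_overlap: float = 0.5
    window: str = "hann"
    alpha_floor: float = 1e-12          # relative to total power
    channel_aggregate: str = "ratio-of-means"   # or "mean-of-ratios"

    def validate(self) -> None:
        t_lo, t_hi = self.theta_band_hz
        a_lo, a_hi = self.alpha_band_hz
        if not (0 < t_lo < t_hi and 0 < a_lo < a_hi):
            raise ValueError("bands must be positive increasing ranges")
        if t_hi > a_lo and a_hi > t_lo:
            raise ValueError("theta and alpha bands must be disjoint")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must lie in [0, 1)")
        if self.welch_segment_s <= 0:
            raise ValueError("welch_segment_s must be > 0")
        if self.channel_aggregate not in ("ratio-of-means", "mean-of-ratios"):
            raise ValueError(
                f"unknown channel_aggregate {self.channel_aggregate!r}"
            )


@dataclass
class TarEpochResult:
    theta_power: float          # sensor-mean band power, a.u.^2
    alpha_power: float
    tar: float                  # theta/alpha; NaN when invalid
    valid: bool = True


def welch_psd(
    epoch_channel: np.ndarray, cfg: SpectralConfig, sfreq_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of one or more channels (last axis=time).

    Tapered, overlapping segments of ``welch_segment_s`` give a frequency
    resolution of 1/welch_segment_s (0.5 Hz by default), enough for >= 5
    bins inside the narrow 3-5 Hz theta band of a 4-s epoch.
    """
    cfg.validate()
    x = np.asarray(epoch_channel, dtype=np.float64)
    nperseg = int(round(cfg.welch_segment_s * sfreq_hz))
    if nperseg > x.shape[-1]:
        raise ValueError(
            f"welch segment of {nperseg} samples exceeds epoch length "
            f"{x.shape[-1]}"
        )
    noverlap = int(round(nperseg * cfg.welch_overlap))
    freqs, psd = sps.welch(x, fs=sfreq_hz, window=cfg.window,
                           nperseg=nperseg, noverlap=noverlap, axis=-1)
    return freqs, psd


def band_power(
    freqs: np.ndarray, psd: np.ndarray, band_hz: tuple[float, float]
) -> np.ndarray:
    """Trapezoidal integral of the PSD over bins with centers in the band."""
    lo, hi = band_hz
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"band {band_hz} Hz covers fewer than two frequency bins"
        )
    return np.trapezoid(psd[..., mask], freqs[mask], axis=-1)


def tar_epoch(
    epoch: np.ndarray, cfg: SpectralConfig, sfreq_hz: float
) -> TarEpochResult:
    """TAR of one epoch from all channels (no subsampling for this marker).

    Default aggregation is ratio-of-means: sensor-mean theta power divided
    by sensor-mean alpha power; mean-of-ratios is available but unstable
    when single channels lose alpha power.  Scale-invariant by construction.
    """
    cfg.validate()
    epoch = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    freqs, psd = welch_psd(epoch, cfg, sfreq_hz)
    theta = band_power(freqs, psd, cfg.theta_band_hz)       # per channel
    alpha = band_power(freqs, psd, cfg.alpha_band_hz)
    total = np.trapezoid(psd, freqs, axis=-1)
    mean_theta = float(theta.mean())
    mean_alpha = float(alpha.mean())
    floor = cfg.alpha_floor * float(total.mean())
    if mean_alpha <= max(floor, 0.0):
        logger.warning("alpha power below floor: epoch marked invalid-TAR")
        return TarEpochResult(theta_power=mean_theta, alpha_power=mean_alpha,
                              tar=float("nan"), valid=False)
    if cfg.channel_aggregate == "ratio-of-means":
        tar = mean_theta / mean_alpha
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = theta / alpha
        tar = float(np.nanmean(np.where(np.isfinite(ratios), ratios, np.nan)))
    return TarEpochResult(theta_power=mean_theta, alpha_power=mean_alpha,
                          tar=float(tar), valid=True)


def tar_subject(
    epochs: EpochSet, cfg: SpectralConfig
) -> tuple[float, pd.DataFrame]:
    """Subject-level TAR: mean over kept, valid epochs + per-epoch table."""
    cfg.validate()
    kept_idx = np.flatnonzero(epochs.kept_mask)
    if kept_idx.size == 0:
        raise MissingMarkerError("no kept epochs: TAR undefined")
    rows = []
    for i in kept_idx:
        res = tar_epoch(epochs.epochs[i], cfg, epochs.sfreq_hz)
        rows.append({"epoch_index": int(i), "tar_epoch": res.tar,
                     "theta_power": res.theta_power,
                     "alpha_power": res.alpha_power, "valid": res.valid})
    table = pd.DataFrame(rows)
    valid = table.loc[table["valid"], "tar_epoch"]
    if valid.empty:
        raise MissingMarkerError("no valid-TAR epochs: TAR undefined")
    return float(valid.mean()), table
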