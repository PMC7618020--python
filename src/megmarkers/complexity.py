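"""Normalized Lempel-Ziv (LZ76) complexity of binarized channel signals.

The marker ("LZsum") is the per-epoch mean, over a random subset of
channels (25 of 204 in a full gradiometer montage), of each channel's
normalized within-channel LZ76 word count.  LZ76 counts the words of an
exhaustive-history production parsing: scanning left to right, a word ends
at the first symbol that makes the current phrase impossible to copy (with
overlap) from the previously seen prefix; the final, possibly uncompleted
word also counts.  Normalizing by n / log2(n) — the asymptotic word count
of an equiprobable random binary string — yields a value near 1 for white
noise and near 0 for regular signals, so the marker reads as "signal
diversity per sample".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .preprocess import EpochSet

logger = logging.getLogger("megmarkers.complexity")

__all__ = [
    "ComplexityConfig",
    "LZEpochResult",
    "MissingMarkerError",
    "binarize",
    "lz76",
    "normalize_lz",
    "lzsum_epoch",
    "lzsum_subject",
]


class MissingMarkerError(ValueError):
    """No valid epochs: the subject has no marker value."""


@dataclass(frozen=True)
class ComplexityConfig:
    n_subsample_channels: int = 25
    binarization: str = "hilbert-mean"      # or "signal-median"
    normalization: str = "asymptotic"       # or "none"
    subset_policy: str = "per-epoch"        # or "per-subject"
    seed: int = 0

    def validate(self) -> None:
        if self.n_subsample_channels < 1:
            raise ValueError("n_subsample_channels must be >= 1")
        if self.binarization not in ("hilbert-mean", "signal-median"):
            raise ValueError(f"unknown binarization {self.binarization!r}")
        if self.normalization not in ("asymptotic", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.subset_policy not in ("per-epoch", "per-subject"):
            raise ValueError(f"unknown subset_policy {self.subset_policy!r}")


@dataclass
class LZEpochResult:
    channel_subset: np.ndarray          # channel indices used
    c_per_channel: np.ndarray           # integer LZ76 word counts
    normalized_per_channel: np.ndarray
    lzsum: float


def binarize(signal: np.ndarray, method: str = "hilbert-mean") -> np.ndarray:
    """Turn one channel's samples into a 0/1 sequence.

    ``hilbert-mean``: 1 where the analytic-signal envelope exceeds its own
    epoch mean — the amplitude-based rule used for sleep/anaesthesia LZ work.
    ``signal-median``: 1 where the raw sample exceeds the channel median.
    Ties map to 0 (strict comparison).  Both rules are invariant to positive
    amplitude scaling.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("binarize expects a 1-D signal of >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("binarize expects finite samples")
    if np.ptp(x) == 0:
        logger.warning("constant input to binarize: all-zero sequence")
        return np.zeros(x.size, dtype=np.uint8)
    if method == "hilbert-mean":
        env = np.abs(hilbert(x))
        return (env > env.mean()).astype(np.uint8)
    if method == "signal-median":
        return (x > np.median(x)).astype(np.uint8)
    raise ValueError(f"unknown binarization {method!r}")


def lz76(seq) -> int:
    """LZ76 word count of a binary sequence (Kaspar-Schuster parsing).

    The sequence is parsed into words left to right; the word starting at
    position p ends with the first symbol making s[p:p+m] absent from
    s[0:p+m-1] (copying may overlap the word itself).  The trailing word
    counts even if it remains reproducible through the end.  Substring
    search is delegated to ``bytes.find`` for speed; a naive reference
    parser exists in the test suite.
    """
    s = np.asarray(seq, dtype=np.uint8)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("lz76 expects a non-empty 1-D binary sequence")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("lz76 expects symbols in {0, 1}")
    b = s.tobytes()
    n = len(b)
    c = 0
    p = 0
    while p < n:
        m = 1
        j = -1          # start of a known occurrence of b[p:p+m-1]
        while p + m <= n:
            # any occurrence starts at j <= p-1, so extending it by one
            # symbol stays inside the allowed prefix: test one byte first
            if j >= 0 and b[j + m - 1] == b[p + m - 1]:
                m += 1
                continue
            j = b.find(b[p:p + m], 0, p + m - 1)
            if j == -1:
                break
            m += 1
        c += 1
        p += m
    return c


def normalize_lz(c: int, n: int) -> float:
    """c divided by n/log2(n), the asymptotic random-string word count."""
    if n < 2:
        raise ValueError("normalization needs sequence length n >= 2")
    return c * np.log2(n) / n


def _channel_subset(rng: np.random.Generator, n_channels: int,
                    n_requested: int) -> np.ndarray:
    if n_channels < n_requested:
        logger.warning(
            "only %d channels available for a %d-channel subsample: using all",
            n_channels, n_requested,
        )
        return np.arange(n_channels)
    return np.sort(rng.choice(n_channels, size=n_requested, replace=False))


def lzsum_epoch(
    epoch: np.ndarray,
    cfg: ComplexityConfig,
    rng: np.random.Generator,
    subset: np.ndarray | None = None,
) -> LZEpochResult:
    """Normalized LZ76 averaged over a random channel subset of one epoch."""
    cfg.validate()
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2 or epoch.shape[0] < 1:
        raise ValueError("epoch must be channels x samples with >= 1 channel")
    if subset is None:
        subset = _channel_subset(rng, epoch.shape[0], cfg.n_subsample_channels)
    n = epoch.shape[1]
    counts = np.empty(len(subset), dtype=np.int64)
    for k, ch in enumerate(subset):
        counts[k] = lz76(binarize(epoch[ch], cfg.binarization))
    if cfg.normalization == "asymptotic":
        norm = np.array([normalize_lz(c, n) for c in counts])
    else:
        norm = counts.astype(np.float64)
    return LZEpochResult(channel_subset=np.asarray(subset),
                         c_per_channel=counts,
                         normalized_per_channel=norm,
                         lzsum=float(norm.mean()))


def lzsum_subject(
    epochs: EpochSet, cfg: ComplexityConfig
) -> tuple[float, pd.DataFrame]:
    """Subject-level LZsum: mean over kept epochs, plus the per-epoch table.

    The channel subset is redrawn per epoch by default (``subset_policy``),
    seeded from ``cfg.seed`` so reruns are identical.
    """
    cfg.validate()
    kept_idx = np.flatnonzero(epochs.kept_mask)
    if kept_idx.size == 0:
        raise MissingMarkerError("no kept epochs: LZsum undefined")
    rng = np.random.default_rng(cfg.seed)
    fixed = None
    n_channels = epochs.epochs.shape[1]
    if cfg.subset_policy == "per-subject" or n_channels <= cfg.n_subsample_channels:
        # warn (if applicable) once per subject, not once per epoch
        fixed = _channel_subset(rng, n_channels, cfg.n_subsample_channels)
    rows = []
    for i in kept_idx:
        res = lzsum_epoch(epochs.epochs[i], cfg, rng, subset=fixed)
        rows.append({"epoch_index": int(i), "lzsum_epoch": res.lzsum})
    table = pd.DataFrame(rows)
    return float(table["lzsum_epoch"].mean()), table
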