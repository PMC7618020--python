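"""Synthetic resting-state M/EEG cohort generator.

Emulates a two-site MCI/control study: eyes-closed alpha-dominant
gradiometer recordings with a 1/f background, group-modulated theta/alpha
gains and temporal predictability, occasional high-frequency muscle-artifact
bursts, and an MMSE score linearly coupled to each subject's realized
signal parameters (lower MMSE <=> more theta-dominant, more predictable
signal).  Every quantity downstream of this module is computable on real
recordings; this module only exists so the pipeline is testable without
access-controlled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("megmarkers.synthetic")

__all__ = [
    "SignalParams",
    "EffectParams",
    "CohortSpec",
    "SubjectMeta",
    "Recording",
    "generate_subject_signal",
    "generate_cohort",
    "iter_cohort",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalParams:
    """Per-group generative parameters for one subject's multichannel signal.

    Each channel is the sum of an alpha oscillation (random frequency in
    8-12 Hz), a theta oscillation (3-5 Hz), a unit-SD 1/f-shaped background
    passed through an AR(1) filter (the predictability knob: higher
    ``ar_coefficient`` means a smoother, more compressible signal and hence
    lower Lempel-Ziv complexity), and white sensor noise.  ``noise_sd``
    scales the whole stochastic background; oscillation gains are amplitudes
    relative to that unit-SD background.
    """

    alpha_gain: float = 1.0
    theta_gain: float = 0.55
    one_over_f_exponent: float = 1.0
    ar_coefficient: float = 0.55
    noise_sd: float = 1.0
    artifact_rate: float = 0.0          # expected muscle bursts per minute
    artifact_band_hz: tuple[float, float] = (55.0, 100.0)

    def validate(self) -> None:
        if min(self.alpha_gain, self.theta_gain, self.noise_sd) < 0:
            raise ValueError("signal gains and noise_sd must be >= 0")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


@dataclass(frozen=True)
class EffectParams:
    """Multiplicative/additive shifts applied to the patient group.

    Defaults are calibrated so a cohort of 83 subjects per group shows the
    expected group separation in both markers (lower complexity, higher
    theta-alpha ratio in patients); they are a simulation convention, not a
    physiological claim.
    """

    theta_gain_scale: float = 1.5
    alpha_gain_scale: float = 1.0
    ar_shift: float = 0.06

    def apply(self, params: SignalParams) -> SignalParams:
        return replace(
            params,
            theta_gain=params.theta_gain * self.theta_gain_scale,
            alpha_gain=params.alpha_gain * self.alpha_gain_scale,
            ar_coefficient=min(params.ar_coefficient + self.ar_shift, 0.98),
        )

    @classmethod
    def null(cls) -> "EffectParams":
        """No group effect: both groups exchangeable."""
        return cls(theta_gain_scale=1.0, alpha_gain_scale=1.0, ar_shift=0.0)


@dataclass(frozen=True)
class SubjectMeta:
    participant_id: str
    group: str                  # "control" | "patient"
    age: int
    sex: str                    # "M" | "F"
    site: str
    mmse: int

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not 0 <= self.mmse <= 30:
            raise ValueError("MMSE must lie in [0, 30]")


@dataclass
class Recording:
    """A channels x samples array with sampling-rate and channel metadata."""

    data: np.ndarray
    sfreq_hz: float
    channel_names: list[str]
    channel_types: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(self.channel_types) != len(self.channel_names):
            raise ValueError("channel_types length must match channel_names")
        if self.sfreq_hz <= 0:
            raise ValueError("sfreq_hz must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq_hz


def _default_mmse() -> dict:
    return {"control": (28.88, 1.3), "patient": (26.07, 2.8)}


def _default_mmse_range() -> dict:
    return {"control": (25, 30), "patient": (17, 30)}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one synthetic cohort reproducibly.

    ``sfreq_hz`` defaults to 250 Hz, the rate the analysis runs at; a
    1000 Hz setting exists to exercise the resampler.  MMSE coupling weights
    set how strongly a subject's MMSE tracks their realized theta/alpha gain
    ratio and AR coefficient (standardized, linear-Gaussian, then rounded
    and clipped to the group's range).
    """

    n_per_group: int = 83
    n_channels: int = 204
    sfreq_hz: float = 250.0
    duration_s: float = 60.0
    sites: tuple[str, ...] = ("CBU", "CTB")
    age_range: tuple[int, int] = (54, 83)
    male_fraction: float = 0.56
    mmse_mean_sd_by_group: dict = field(default_factory=_default_mmse)
    mmse_range_by_group: dict = field(default_factory=_default_mmse_range)
    base_params: SignalParams = field(default_factory=SignalParams)
    effect_params: EffectParams = field(default_factory=EffectParams)
    subject_gain_cv: float = 0.18       # lognormal sd of per-subject gain jitter
    subject_ar_sd: float = 0.04         # sd of per-subject AR jitter
    mmse_signal_weight: float = 0.5     # weight of theta/alpha-ratio deviation
    mmse_ar_weight: float = 0.5         # weight of AR deviation
    mmse_noise_weight: float = 0.707    # weight of pure noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sfreq_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sfreq_hz and duration_s must be > 0")
        n = self.duration_s * self.sfreq_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s x sfreq_hz must be an integer")
        if self.duration_s < 8.0:
            raise ValueError("duration_s must be >= 8 s (two 4-s epochs)")
        if not self.sites:
            raise ValueError("at least one site label required")
        self.base_params.validate()


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _colored_background(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sfreq_hz: float,
    exponent: float,
    ar: float,
) -> np.ndarray:
    """Unit-SD per channel: white noise shaped to 1/f^exponent, then AR(1)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq_hz)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0                      # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    out = sps.lfilter([1.0], [1.0, -ar], shaped, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _artifact_bursts(
    rng: np.random.Generator,
    data: np.ndarray,
    sfreq_hz: float,
    rate_per_min: float,
    band_hz: tuple[float, float],
) -> None:
    """Add Poisson-placed 0.5-s band-limited bursts at 10x channel SD, in place."""
    n_channels, n_samples = data.shape
    duration_min = n_samples / sfreq_hz / 60.0
    n_bursts = rng.poisson(rate_per_min * duration_min)
    if n_bursts == 0:
        return
    burst_len = int(round(0.5 * sfreq_hz))
    nyq = sfreq_hz / 2.0
    lo, hi = band_hz
    hi = min(hi, 0.95 * nyq)
    if lo >= hi:
        raise ValueError("artifact band must fit below Nyquist")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sfreq_hz, output="sos")
    chan_sd = data.std(axis=1, keepdims=True)
    chan_sd[chan_sd == 0] = 1.0
    for _ in range(n_bursts):
        start = rng.integers(0, max(n_samples - burst_len, 1))
        burst = sps.sosfilt(sos, rng.standard_normal((n_channels, burst_len)), axis=1)
        bsd = burst.std(axis=1, keepdims=True)
        bsd[bsd == 0] = 1.0
        data[:, start:start + burst_len] += burst / bsd * 10.0 * chan_sd


def generate_subject_signal(
    params: SignalParams,
    n_channels: int,
    sfreq_hz: float,
    duration_s: float,
    seed: int | np.random.SeedSequence,
) -> Recording:
    """Draw one subject's multichannel recording.

    Per channel: alpha and theta sinusoids with channel-specific random
    frequency and phase, plus the AR(1)-filtered 1/f background and white
    sensor noise (both scaled by ``noise_sd``), plus optional muscle-artifact
    bursts.  Bit-reproducible for a fixed seed.
    """
    params.validate()
    if duration_s <= 0 or sfreq_hz <= 0:
        raise ValueError("duration_s and sfreq_hz must be > 0")
    if duration_s < 8.0:
        raise ValueError("duration_s must be >= 8 s (two 4-s epochs)")
    n_samples = int(round(duration_s * sfreq_hz))
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / sfreq_hz

    f_alpha = rng.uniform(8.0, 12.0, size=(n_channels, 1))
    ph_alpha = rng.uniform(0.0, 2 * np.pi, size=(n_channels, 1))
    f_theta = rng.uniform(3.0, 5.0, size=(n_channels, 1))
    ph_theta = rng.uniform(0.0, 2 * np.pi, size=(n_channels, 1))

    data = params.alpha_gain * np.sin(2 * np.pi * f_alpha * t + ph_alpha)
    data += params.theta_gain * np.sin(2 * np.pi * f_theta * t + ph_theta)

    if params.noise_sd > 0:
        data += params.noise_sd * _colored_background(
            rng, n_channels, n_samples, sfreq_hz,
            params.one_over_f_exponent, params.ar_coefficient,
        )
        # small broadband sensor-noise floor
        data += 0.1 * params.noise_sd * rng.standard_normal((n_channels, n_samples))

    if params.artifact_rate > 0:
        _artifact_bursts(rng, data, sfreq_hz, params.artifact_rate,
                         params.artifact_band_hz)

    names = [f"MEG{i:04d}" for i in range(1, n_channels + 1)]
    return Recording(data=data, sfreq_hz=sfreq_hz, channel_names=names,
                     channel_types=["grad"] * n_channels)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _subject_params(
    base: SignalParams,
    spec: CohortSpec,
    z_ratio_gain: np.ndarray,
    z_ar: float,
) -> SignalParams:
    z_theta, z_alpha = z_ratio_gain
    cv = spec.subject_gain_cv
    theta = base.theta_gain * float(np.exp(cv * z_theta - cv ** 2 / 2))
    alpha = base.alpha_gain * float(np.exp(cv * z_alpha - cv ** 2 / 2))
    ar = float(np.clip(base.ar_coefficient + spec.subject_ar_sd * z_ar, 0.0, 0.98))
    return replace(base, theta_gain=theta, alpha_gain=alpha, ar_coefficient=ar)


def _draw_mmse(
    rng: np.random.Generator,
    spec: CohortSpec,
    group: str,
    z_theta: float,
    z_alpha: float,
    z_ar: float,
) -> int:
    mean, sd = spec.mmse_mean_sd_by_group[group]
    lo, hi = spec.mmse_range_by_group[group]
    # more theta-dominant (higher TAR) and more predictable (lower LZ)
    # subjects score lower; independent noise keeps the link imperfect
    z_ratio = (z_theta - z_alpha) / np.sqrt(2.0)
    z = (spec.mmse_noise_weight * rng.standard_normal()
         - spec.mmse_signal_weight * z_ratio
         - spec.mmse_ar_weight * z_ar)
    val = int(round(np.clip(mean + sd * z, lo, hi)))
    return int(np.clip(val, 0, 30))


def iter_cohort(spec: CohortSpec):
    """Yield ``(SubjectMeta, Recording)`` pairs one subject at a time.

    Subjects are seeded by a counter-based split of the master seed, so each
    subject is reproducible independently of how many others were generated.
    Sites alternate within group (near 50/50 balance); ages are uniform over
    the configured range in both groups (age-matched design).
    """
    spec.validate()
    idx = 0
    for group in ("control", "patient"):
        base = spec.base_params if group == "control" \
            else spec.effect_params.apply(spec.base_params)
        for j in range(spec.n_per_group):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(idx,))
            rng = np.random.default_rng(ss)
            z_theta, z_alpha, z_ar = rng.standard_normal(3)
            params = _subject_params(base, spec, (z_theta, z_alpha), z_ar)
            mmse = _draw_mmse(rng, spec, group, z_theta, z_alpha, z_ar)
            age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
            sex = "M" if rng.random() < spec.male_fraction else "F"
            site = spec.sites[j % len(spec.sites)]
            pid = f"sub-{idx + 1:03d}"
            meta = SubjectMeta(participant_id=pid, group=group, age=age,
                               sex=sex, site=site, mmse=mmse)
            sig_seed = np.random.SeedSequence(spec.seed, spawn_key=(idx, 1))
            rec = generate_subject_signal(
                params, spec.n_channels, spec.sfreq_hz, spec.duration_s, sig_seed
            )
            yield meta, rec
            idx += 1


def generate_cohort(spec: CohortSpec) -> list[tuple[SubjectMeta, Recording]]:
    """Materialize the full cohort (2 x n_per_group subjects) as a list."""
    return list(iter_cohort(spec))
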