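import numpy as np
import pytest

from megmarkers import Recording


def brute_force_lz76(bits) -> int:
    """Independent naive LZ76 reference: explicit substring scan.

    A word starting at p ends with the first symbol that makes s[p:p+m]
    absent from s[0:p+m-1] (overlap allowed); the trailing word counts.
    Quadratic-to-cubic and proudly so — it exists only to check the fast
    parser.
    """
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = 0
    p = 0
    while p < n:
        m = 1
        while p + m <= n and s[p:p + m] in s[0:p + m - 1]:
            m += 1
        c += 1
        p += m
    return c


def tone_recording(freqs_amps, sfreq=250.0, duration=8.0, n_channels=4,
                   phase=0.0) -> Recording:
    """Multichannel sum-of-sinusoids recording for analytic checks."""
    t = np.arange(int(round(duration * sfreq))) / sfreq
    sig = np.zeros_like(t)
    for f, a in freqs_amps:
        sig = sig + a * np.sin(2 * np.pi * f * t + phase)
    data = np.tile(sig, (n_channels, 1))
    return Recording(data=data, sfreq_hz=sfreq,
                     channel_names=[f"MEG{i:04d}" for i in range(n_channels)],
                     channel_types=["grad"] * n_channels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
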