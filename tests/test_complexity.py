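"""LZ76 parsing, binarization, normalization, and the LZsum marker."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megmarkers import (
    ComplexityConfig,
    MissingMarkerError,
    binarize,
    lz76,
    lzsum_epoch,
    lzsum_subject,
    normalize_lz,
)
from megmarkers.preprocess import EpochSet

from conftest import brute_force_lz76


class TestBinarize:
    def test_constant_signal_all_zero_both_methods(self):
        x = np.full(64, 3.3)
        for method in ("hilbert-mean", "signal-median"):
            assert not binarize(x, method).any()

    def test_median_rule_direct_comparison(self):
        # median of [1,3,2,4] is 2.5 -> 0101
        assert binarize(np.array([1.0, 3.0, 2.0, 4.0]),
                        "signal-median").tolist() == [0, 1, 0, 1]

    def test_envelope_rule_balanced_on_am_tone(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) * (1 + 0.5 * np.sin(2 * np.pi * 0.5 * t))
        frac = binarize(x, "hilbert-mean").mean()
        assert 0.4 <= frac <= 0.6

    def test_amplitude_invariance_bit_for_bit(self, rng):
        x = rng.standard_normal(500)
        for method in ("hilbert-mean", "signal-median"):
            assert np.array_equal(binarize(x, method),
                                  binarize(5.0 * x, method))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            binarize(np.array([1.0]))
        with pytest.raises(ValueError):
            binarize(np.array([1.0, np.nan, 2.0]))


class TestLZ76:
    @pytest.mark.parametrize("seq,expected", [
        ([0] * 8, 2),
        ([0, 1, 0, 1, 0, 1, 0, 1], 3),
        ([0], 1),
        ([1], 1),
    ])
    def test_reference_words(self, seq, expected):
        assert lz76(seq) == expected
        assert brute_force_lz76(seq) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            lz76([])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            lz76([0, 1, 2])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, bits):
        assert lz76(bits) == brute_force_lz76(bits)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 1), min_size=2, max_size=60),
           st.integers(1, 59))
    def test_prefix_word_count_never_exceeds_full(self, bits, cut):
        cut = min(cut, len(bits) - 1)
        assert lz76(bits[:cut]) <= lz76(bits)


class TestNormalization:
    def test_arithmetic(self):
        assert normalize_lz(2, 16) == pytest.approx(0.5)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            normalize_lz(1, 1)

    def test_complexity_ordering_constant_periodic_noise(self, rng):
        n = 1000
        constant = np.zeros(n, dtype=int)
        periodic = np.tile([0, 1], n // 2)
        noise = rng.integers(0, 2, n)
        vals = [normalize_lz(lz76(s), n) for s in (constant, periodic, noise)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] - vals[1] > 0.1


class TestLZsum:
    @staticmethod
    def _epochs_from(data, n_epochs=1):
        epochs = np.stack([data] * n_epochs)
        return EpochSet(epochs=epochs, sfreq_hz=250.0,
                        kept_mask=np.ones(n_epochs, dtype=bool))

    def test_identical_channels_collapse_to_single_value(self, rng):
        x = rng.standard_normal(1000)
        epoch = np.tile(x, (25, 1))
        cfg = ComplexityConfig(seed=0)
        res = lzsum_epoch(epoch, cfg, np.random.default_rng(0))
        single = normalize_lz(lz76(binarize(x, cfg.binarization)), 1000)
        assert res.lzsum == pytest.approx(single, abs=1e-12)
        assert len(res.channel_subset) == 25

    def test_noise_epoch_lzsum_near_one(self, rng):
        epoch = rng.standard_normal((4, 1000))
        cfg = ComplexityConfig(binarization="signal-median")
        res = lzsum_epoch(epoch, cfg, np.random.default_rng(0))
        assert 0.85 <= res.lzsum <= 1.15

    def test_same_seed_same_subsets_and_value(self, rng):
        epochs = self._epochs_from(rng.standard_normal((30, 1000)), n_epochs=3)
        cfg = ComplexityConfig(seed=11)
        v1, t1 = lzsum_subject(epochs, cfg)
        v2, t2 = lzsum_subject(epochs, cfg)
        assert v1 == v2
        assert t1.equals(t2)

    def test_subject_value_is_mean_of_epoch_values(self, rng):
        # two distinct epochs, few channels so the subset is all channels
        # and per-epoch values can be recomputed independently
        e1 = rng.standard_normal((3, 1000))
        e2 = np.tile(np.sin(2 * np.pi * 10 * np.arange(1000) / 250), (3, 1))
        epochs = EpochSet(epochs=np.stack([e1, e2]), sfreq_hz=250.0,
                          kept_mask=np.ones(2, dtype=bool))
        cfg = ComplexityConfig(seed=0)
        subj, table = lzsum_subject(epochs, cfg)
        per = [lzsum_epoch(e, cfg, np.random.default_rng(0),
                           subset=np.arange(3)).lzsum for e in (e1, e2)]
        assert subj == pytest.approx(np.mean(per), abs=1e-12)
        assert table["lzsum_epoch"].tolist() == pytest.approx(per, abs=1e-12)

    def test_rejected_epochs_excluded(self, rng):
        epochs = self._epochs_from(rng.standard_normal((3, 1000)), n_epochs=3)
        epochs.kept_mask[1:] = False
        subj, table = lzsum_subject(epochs, ComplexityConfig(seed=0))
        assert len(table) == 1

    def test_no_kept_epochs_signals_missing_marker(self, rng):
        epochs = self._epochs_from(rng.standard_normal((3, 1000)))
        epochs.kept_mask[:] = False
        with pytest.raises(MissingMarkerError):
            lzsum_subject(epochs, ComplexityConfig())

    def test_amplitude_scaling_leaves_lzsum_unchanged(self, rng):
        data = rng.standard_normal((3, 1000))
        cfg = ComplexityConfig(seed=5)
        v1, _ = lzsum_subject(self._epochs_from(data), cfg)
        v2, _ = lzsum_subject(self._epochs_from(7.0 * data), cfg)
        assert v1 == v2

    def test_higher_ar_coefficient_lowers_lzsum(self):
        # more predictable generator signal => lower complexity, paired seeds
        from megmarkers import SignalParams, generate_subject_signal
        from megmarkers.preprocess import PreprocessConfig, epoch_recording
        cfg = ComplexityConfig(seed=0)
        wins = 0
        for seed in range(20):
            vals = []
            for ar in (0.0, 0.9):
                rec = generate_subject_signal(
                    SignalParams(alpha_gain=0.3, theta_gain=0.2,
                                 ar_coefficient=ar),
                    2, 250.0, 8.0, seed=seed)

                es = epoch_recording(rec, PreprocessConfig())
                vals.append(lzsum_subject(es, cfg)[0])
            wins += vals[1] < vals[0]
        assert wins >= 17  # sign test p < 0.01 at n=20
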