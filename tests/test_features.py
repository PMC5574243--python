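"""Unit and property tests for the six per-epoch features."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seizurekit as sk
from conftest import apen_bruteforce, apen_bruteforce_slow

finite_floats = st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False)


def epoch(samples, rate=1.0, subject_id=""):
    return sk.EegEpoch(np.asarray(samples, dtype=float), rate, subject_id=subject_id)


class TestApproximateEntropy:
    def test_constant_epoch_is_exactly_zero(self):
        e = epoch([5.0] * 8)
        cfg = sk.ApEnConfig(m=2, r=0.5, r_mode="absolute")
        assert sk.approximate_entropy(e, cfg) == 0.0

    def test_periodic_epoch_matches_double_loop_oracle(self):
        x = [1.0, 2.0, 3.0] * 20
        got = sk.approximate_entropy(
            epoch(x), sk.ApEnConfig(m=2, r=0.5, r_mode="absolute")
        )
        expected = apen_bruteforce_slow(x, 2, 0.5)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_noise_is_more_irregular_than_periodic(self, rng):
        periodic = [1.0, 2.0, 3.0] * 20
        cfg = sk.ApEnConfig(m=2, r=0.2, r_mode="relative")
        apen_periodic = sk.approximate_entropy(
            epoch(periodic), sk.ApEnConfig(m=2, r=0.5, r_mode="absolute")
        )
        noise = rng.standard_normal(60)
        apen_noise = sk.approximate_entropy(epoch(noise), cfg)
        assert apen_noise > apen_periodic

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_matches_bruteforce_oracle_random_epochs(self, m, rng):
        for _ in range(5):
            n = int(rng.integers(30, 120))
            x = rng.standard_normal(n)
            r = 0.2 * float(np.std(x))
            got = sk.approximate_entropy(
                epoch(x), sk.ApEnConfig(m=m, r=r, r_mode="absolute")
            )
            assert got == pytest.approx(apen_bruteforce(x, m, r), abs=1e-10)

    def test_relative_mode_scales_tolerance_with_sd(self, rng):
        x = rng.standard_normal(80)
        rel = sk.approximate_entropy(epoch(x), sk.ApEnConfig(m=2, r=0.2))
        absolute = sk.approximate_entropy(
            epoch(x), sk.ApEnConfig(m=2, r=0.2 * float(np.std(x)), r_mode="absolute")
        )
        assert rel == absolute

    def test_added_noise_does_not_decrease_apen_in_expectation(self):
        # low-noise regime: beyond ~0.2 of the signal amplitude, finite-N
        # ApEn saturates and declines, so the monotone region is tested
        t = np.arange(128) / 32.0
        sine = np.sin(2 * np.pi * 2.0 * t)
        cfg = sk.ApEnConfig()
        means = []
        for amp in (0.0, 0.1, 0.2):
            vals = []
            for seed in range(20):
                noise = np.random.default_rng(seed).normal(0, amp, sine.size)
                vals.append(sk.approximate_entropy(epoch(sine + noise), cfg))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sk.approximate_entropy(epoch([1.0, 2.0, 3.0]), sk.ApEnConfig(m=2))

    def test_non_finite_samples_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            epoch([1.0, np.nan, 2.0])


class TestAmplitudeFeatures:
    @pytest.mark.parametrize(
        "samples, expected_sd",
        [([7, 7, 7], 0.0), ([2, 4, 4, 4, 5, 5, 7, 9], 2.0), ([-1, 1], 1.0)],
    )
    def test_population_standard_deviation(self, samples, expected_sd):
        assert sk.standard_deviation(epoch(samples)) == pytest.approx(expected_sd)

    @pytest.mark.parametrize(
        "samples, expected_se",
        [([7, 7, 7], 0.0), ([2, 4, 4, 4, 5, 5, 7, 9], 2 / math.sqrt(8)), ([4.2], 0.0)],
    )
    def test_standard_error(self, samples, expected_se):
        assert sk.standard_error(epoch(samples)) == pytest.approx(expected_se)

    @given(st.lists(finite_floats, min_size=2, max_size=64))
    def test_se_is_sd_over_sqrt_n(self, samples):
        e = epoch(samples)
        assert sk.standard_error(e) == pytest.approx(
            sk.standard_deviation(e) / math.sqrt(len(samples)), rel=1e-12, abs=1e-12
        )

    @pytest.mark.parametrize(
        "samples, expected",
        [
            (np.zeros(16), 0.0),
            (np.ones(8), 0.8125),  # window n=2..6: (5*1.0 + 3*0.5)/8
            ([-1, -1, -1, -1], sk.mmav(sk.EegEpoch(np.ones(4), 1.0))),
        ],
    )
    def test_mmav_examples(self, samples, expected):
        assert sk.mmav(epoch(samples)) == pytest.approx(expected)

    def test_mmav_matches_direct_summation(self, rng):
        x = rng.standard_normal(37)
        n = x.size
        total = 0.0
        for i, xi in enumerate(x, start=1):
            w = 1.0 if math.ceil(0.25 * n) <= i <= math.floor(0.75 * n) else 0.5
            total += w * abs(xi)
        assert sk.mmav(epoch(x)) == pytest.approx(total / n)

    @given(
        st.lists(finite_floats, min_size=1, max_size=64),
        st.floats(0.01, 100.0),
    )
    def test_mmav_sign_invariant_and_scale_linear(self, samples, scale):
        x = np.asarray(samples)
        base = sk.mmav(epoch(x)) if np.any(x) else 0.0
        assert sk.mmav(epoch(-x)) == pytest.approx(sk.mmav(epoch(x)), rel=1e-12)
        assert sk.mmav(epoch(scale * x)) == pytest.approx(
            scale * sk.mmav(epoch(x)), rel=1e-9, abs=1e-12
        )


class TestSpectralRolloff:
    def test_dc_only_epoch_rolls_off_at_zero(self):
        assert sk.spectral_rolloff(epoch(np.full(32, 3.0), rate=32.0)) == 0.0

    def test_pure_cosine_at_integer_bin(self):
        t = np.arange(32)
        x = np.cos(2 * np.pi * 4 * t / 32)
        assert sk.spectral_rolloff(epoch(x, rate=32.0)) == pytest.approx(4.0)

    def test_two_tone_rolloff_needs_the_higher_bin(self):
        t = np.arange(64)
        x = np.cos(2 * np.pi * 2 * t / 64) + np.cos(2 * np.pi * 10 * t / 64)
        assert sk.spectral_rolloff(epoch(x, rate=64.0)) == pytest.approx(10.0)

    def test_nondecreasing_in_fraction_and_limit_is_top_bin(self, rng):
        x = rng.standard_normal(64)
        e = epoch(x, rate=64.0)
        fractions = np.linspace(0.05, 0.999, 25)
        vals = [sk.spectral_rolloff(e, f) for f in fractions]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        mag = np.abs(np.fft.rfft(x))
        top = np.flatnonzero(mag > 0)[-1] * 64.0 / 64
        assert vals[-1] == pytest.approx(top)

    def test_all_zero_spectrum_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert sk.spectral_rolloff(epoch(np.zeros(8))) == 0.0
        assert "all-zero" in caplog.text


class TestZeroCrossing:
    @pytest.mark.parametrize(
        "samples, threshold, expected",
        [
            ([1, -1, 1, -1], 0.0, 3),
            ([3, 3, 3, 3], 0.0, 0),
            ([3, 3, 3, 3], 2.5, 0),
            ([1, -0.1, 1, -0.1], 0.5, 3),
            ([1, -0.1, 1, -0.1], 2.5, 0),
            ([1, 0, -1], 0.0, 1),  # touching zero counts once
            ([0, 0, 1, -1], 0.0, 1),  # leading zeros inherit the first sign
        ],
    )
    def test_counts(self, samples, threshold, expected):
        assert sk.zero_crossing(epoch(samples), threshold) == expected

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=64))
    def test_threshold_zero_equals_direct_enumeration(self, samples):
        x = np.asarray(samples)
        signs = []
        prev = None
        for v in x:
            s = np.sign(v)
            if s == 0:
                s = prev
            signs.append(s)
            if s is not None:
                prev = s
        first = next((s for s in signs if s is not None), None)
        signs = [first if s is None else s for s in signs]
        expected = (
            0
            if first is None
            else sum(a != b for a, b in zip(signs, signs[1:]))
        )
        assert sk.zero_crossing(epoch(x)) == expected

    def test_monotone_nonincreasing_in_threshold(self, rng):
        x = rng.standard_normal(128)
        e = epoch(x)
        counts = [sk.zero_crossing(e, th) for th in np.linspace(0, 3, 13)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestExtractAndNormalize:
    def test_constant_epoch_composition(self):
        e = epoch(np.full(16, -2.0))
        cfg = sk.ApEnConfig(m=2, r=0.1, r_mode="absolute")
        v = sk.extract_features(e, cfg)
        assert (v.apen, v.sd, v.se, v.rolloff, v.zc) == (0.0, 0.0, 0.0, 0.0, 0.0)
        assert v.mmav == pytest.approx(sk.mmav(e))
        assert not v.normalized

    def test_epileptic_epoch_less_entropic_than_normal(self):
        ep = sk.generate_epoch(sk.EpochSpec(kind="epileptic", seed=3))
        no = sk.generate_epoch(sk.EpochSpec(kind="normal", seed=3))
        assert sk.extract_features(ep).apen < sk.extract_features(no).apen

    def test_empty_epoch_is_an_error(self):
        with pytest.raises(ValueError):
            epoch([])

    def test_minmax_endpoints(self):
        a = sk.FeatureVector(1, 0, 0, 1, 1, 1)
        b = sk.FeatureVector(3, 1, 1, 2, 2, 2)
        na, nb = sk.normalize_template([a, b])
        assert (na.apen, nb.apen) == (0.0, 1.0)
        assert na.normalized and nb.normalized

    def test_all_values_in_unit_interval_and_idempotent(self, rng):
        vecs = [
            sk.FeatureVector(*rng.uniform(-5, 5, 6), label="x", subject_id=f"S{i}")
            for i in range(8)
        ]
        once = sk.normalize_template(vecs)
        mat = np.stack([v.values() for v in once])
        assert mat.min() >= 0 and mat.max() <= 1
        twice = sk.normalize_template(once)
        np.testing.assert_allclose(
            np.stack([v.values() for v in twice]), mat, atol=1e-12
        )
        assert [v.label for v in twice] == ["x"] * 8

    def test_proportional_columns_normalize_identically(self, rng):
        # SD and SE columns differ by the fixed factor 1/sqrt(N): min-max
        # scaling is scale-invariant, so the normalized columns coincide.
        sds = rng.uniform(0.5, 4.0, 10)
        vecs = [
            sk.FeatureVector(0, sd, sd / math.sqrt(256), 0, 0, 0) for sd in sds
        ]
        normed = sk.normalize_template(vecs)
        np.testing.assert_allclose(
            [v.sd for v in normed], [v.se for v in normed], atol=1e-12
        )

    def test_constant_column_maps_to_half(self):
        vecs = [sk.FeatureVector(7, i, i, i, i, i) for i in range(3)]
        assert all(v.apen == 0.5 for v in sk.normalize_template(vecs))

    def test_fewer_than_two_vectors_rejected(self):
        with pytest.raises(ValueError):
            sk.normalize_template([sk.FeatureVector(1, 1, 1, 1, 1, 1)])
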