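"""HRV indices against independent oracles and invariance properties."""

import numpy as np
import pytest

from rqtecg.hrv import (
    SpectralBands,
    coarse_grain,
    compute_bei,
    compute_lhr,
    compute_mse_ss,
    compute_ssr,
    sample_entropy,
    sample_entropy_counts,
    welch_band_powers,
)


def brute_force_sampen_counts(x, m, r):
    """Explicit O(n^2) template pair counting (the oracle)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    return a, b


def _tone_tachogram(freq, n=400, amp=50.0):
    t = np.cumsum(np.full(n, 1.0))
    return 1000.0 + amp * np.sin(2 * np.pi * freq * t), t


class TestLHR:
    def test_lf_tone_dominates(self):
        x, t = _tone_tachogram(0.1)
        assert compute_lhr(x, t) > 10.0

    def test_hf_tone_dominates(self):
        x, t = _tone_tachogram(0.3)
        assert compute_lhr(x, t) < 0.1

    def test_equal_tones_balanced(self):
        t = np.cumsum(np.full(400, 1.0))
        x = 1000.0 + 50.0 * np.sin(2 * np.pi * 0.1 * t) + 50.0 * np.sin(2 * np.pi * 0.3 * t)
        assert 0.8 <= compute_lhr(x, t) <= 1.25

    def test_welch_cross_check_agrees_on_tone_dominance(self):
        x, t = _tone_tachogram(0.1)
        lfp, hfp = welch_band_powers(x, t)
        assert lfp / hfp > 10.0

    def test_offset_invariance(self):
        x, t = _tone_tachogram(0.1)
        assert compute_lhr(x, t) == pytest.approx(compute_lhr(x + 500.0, t), rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="120 s"):
            compute_lhr(np.full(30, 1000.0), np.arange(30.0))


class TestSSR:
    def test_linear_ramp_has_zero_sd1(self):
        assert compute_ssr(np.arange(200.0)) == pytest.approx(0.0, abs=1e-12)

    def test_iid_gaussian_near_unity(self, rng):
        x = 1000.0 + rng.normal(0.0, 30.0, 5000)
        assert 0.95 <= compute_ssr(x) <= 1.05

    def test_alternating_series_degenerate_at_lag_1(self):
        x = np.tile([1000.0, 900.0], 50)
        with pytest.raises(ValueError, match="SD2"):
            compute_ssr(x)

    def test_offset_and_scale_invariance(self, rng):
        x = 1000.0 + rng.normal(0.0, 30.0, 500)
        base = compute_ssr(x)
        assert compute_ssr(x + 777.0) == pytest.approx(base, abs=1e-9)
        assert compute_ssr(x * 3.5) == pytest.approx(base, abs=1e-9)


class TestCoarseGrain:
    def test_scale_one_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_pairwise_means(self):
        assert np.array_equal(coarse_grain([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_remainder_dropped(self):
        assert np.array_equal(coarse_grain([1, 2, 3, 4, 5], 2), [1.5, 3.5])

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            coarse_grain([1.0, 2.0], 0)
        with pytest.raises(ValueError):
            coarse_grain([1.0, 2.0], 3)


class TestSampleEntropy:
    def test_counts_match_brute_force_oracle(self, rng):
        x = rng.normal(0.0, 1.0, 200)
        r = 0.2 * np.std(x)
        assert sample_entropy_counts(x, m=2, r=r) == brute_force_sampen_counts(x, 2, r)

    def test_counts_match_oracle_for_m3(self, rng):
        x = rng.normal(0.0, 1.0, 120)
        r = 0.25 * np.std(x)
        assert sample_entropy_counts(x, m=3, r=r) == brute_force_sampen_counts(x, 3, r)

    def test_ten_point_series_hand_checked(self):
        # alternating two-level series of length 10: the 8 length-2 templates
        # split into 4 x (0,1) and 4 x (1,0), giving C(4,2)+C(4,2)=12 matched
        # pairs, and every match extends to length 3 -> SampEn = -ln(12/12) = 0
        x = np.array([0.0, 1.0] * 5)
        a, b = sample_entropy_counts(x, m=2, r=0.1)
        assert (a, b) == (12, 12)
        assert (a, b) == brute_force_sampen_counts(x, 2, 0.1)
        assert sample_entropy(x, m=2, r=0.1, min_length=5) == 0.0

    def test_periodic_series_near_zero_entropy(self):
        # period 5 with level gaps above r: every length-2 match is an exact
        # phase match and extends to length 3, so SampEn collapses to ~0
        x = np.tile([0.0, 2.0, 4.0, 1.0, 3.0], 100)
        assert sample_entropy(x, m=2) < 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.full(100, 5.0), m=2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sample_entropy(np.arange(20.0), m=2)


class TestMSE:
    def test_white_noise_entropy_decreases_with_scale(self, rng):
        x = rng.normal(0.0, 1.0, 5000)
        r = 0.2 * np.std(x)
        vals = [sample_entropy(coarse_grain(x, s), m=2, r=r) for s in range(1, 6)]
        assert all(vals[i] > vals[i + 1] for i in range(4))

    def test_single_scale_reduces_to_sampen(self, rng):
        x = rng.normal(0.0, 1.0, 300)
        assert compute_mse_ss(x, scales=[1]) == pytest.approx(sample_entropy(x, m=2))

    def test_seed_stability(self):
        r1 = np.random.default_rng(1).normal(0.0, 1.0, 5000)
        r2 = np.random.default_rng(2).normal(0.0, 1.0, 5000)
        assert abs(compute_mse_ss(r1) - compute_mse_ss(r2)) <= 0.15

    def test_offset_and_scale_invariance(self, rng):
        x = 1000.0 + rng.normal(0.0, 30.0, 600)
        base = compute_mse_ss(x)
        assert compute_mse_ss(x + 123.0) == pytest.approx(base, abs=1e-9)
        assert compute_mse_ss(x * 2.0) == pytest.approx(base, abs=1e-9)


class TestBEI:
    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            compute_bei(np.full(200, 900.0), np.arange(200.0))

    def test_pure_lf_tone_is_nearly_deterministic(self):
        x, t = _tone_tachogram(0.1, n=600)
        assert compute_bei(x, t) < 0.2

    def test_noise_increases_entropy(self, rng):
        x, t = _tone_tachogram(0.1, n=600)
        noisy = x + rng.normal(0.0, 50.0, x.size)
        assert compute_bei(noisy, t) > compute_bei(x, t)

    def test_unknown_implementation_rejected(self):
        with pytest.raises(ValueError, match="implementation"):
            compute_bei(np.zeros(100), np.arange(100.0), implementation="exact")


class TestGeneratorAnalysisConsistency:
    def test_lf_only_vs_hf_only_tachograms(self):
        from rqtecg.synth import SyntheticSpec, generate_rr_series

        lf_rr, lf_t = generate_rr_series(
            SyntheticSpec(n_beats=600, lf_amp=50, hf_amp=0, rr_noise_sd=0, mean_rr=1000)
        )
        hf_rr, hf_t = generate_rr_series(
            SyntheticSpec(n_beats=600, lf_amp=0, hf_amp=50, rr_noise_sd=0, mean_rr=1000)
        )
        assert compute_lhr(lf_rr, lf_t) > 10.0
        assert compute_lhr(hf_rr, hf_t) < 0.1
        assert compute_lhr(lf_rr, lf_t) > compute_lhr(hf_rr, hf_t)
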