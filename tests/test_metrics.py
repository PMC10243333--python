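"""NMSE / PSNR / SSIM identities, hand values and statistical oracles."""

import math

import numpy as np
import pytest

from renalscint.dataset import build_pairs
from renalscint.metrics import (
    evaluate_split,
    joint_histogram,
    nmse,
    psnr,
    ssim,
    summarize_metric,
)
from renalscint.phantom import PhantomSpec, generate_phantom


class TestNMSE:
    def test_identity_is_zero(self, rng):
        y = rng.poisson(10, (8, 8)).astype(float) + 1
        assert nmse(y, y) == 0.0

    def test_zero_image_is_hundred_percent(self, rng):
        y = rng.poisson(10, (8, 8)).astype(float) + 1
        assert nmse(np.zeros_like(y), y) == pytest.approx(100.0)

    def test_hand_value(self):
        assert nmse(np.array([1.0, 1.0]), np.array([2.0, 2.0])) == pytest.approx(25.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            nmse(np.ones(4), np.zeros(4))


class TestPSNR:
    def test_identical_images_infinite(self):
        y = np.array([1.0, 2.0])
        assert psnr(y, y) == math.inf

    def test_hand_value(self):
        # MSE = 2, peak 10 -> 20 log10(10/sqrt(2))
        val = psnr(np.array([8.0, 10.0]), np.array([10.0, 10.0]))
        assert val == pytest.approx(16.9897, abs=1e-4)

    def test_more_noise_decreases_psnr(self, rng):
        y = rng.poisson(100, (64, 64)).astype(float)
        low = y + rng.normal(0, 1, y.shape)
        high = y + rng.normal(0, 5, y.shape)
        assert psnr(high, y) < psnr(low, y)


class TestSSIM:
    def test_identity_is_one(self, rng):
        y = rng.poisson(50, (16, 16)).astype(float)
        assert ssim(y, y) == pytest.approx(1.0)

    def test_constant_offset_below_one_and_monotone(self, rng):
        y = rng.poisson(50, (16, 16)).astype(float)
        vals = [ssim(y + c, y, dynamic_range=1000.0) for c in (8.0, 4.0, 2.0, 0.5)]
        assert all(v < 1 for v in vals[:-1])
        assert vals == sorted(vals)  # approaches 1 as the offset shrinks

    def test_constant_images_closed_form(self):
        # constant x=2, y=4, L=4: luminance term only, sigma terms cancel
        x = np.full((5, 5), 2.0)
        y = np.full((5, 5), 4.0)
        c1 = (0.01 * 4) ** 2
        expected = (2 * 2 * 4 + c1) / (4 + 16 + c1)
        assert ssim(x, y, dynamic_range=4.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.80002, abs=5e-6)

    def test_symmetry_in_arguments(self, rng):
        y = rng.poisson(50, (16, 16)).astype(float)
        x = y + rng.normal(0, 3, y.shape)
        L = float(max(x.max(), y.max()))
        assert ssim(x, y, dynamic_range=L) == pytest.approx(ssim(y, x, dynamic_range=L))

    def test_windowed_mode_agrees_on_identical_images(self, rng):
        y = rng.poisson(50, (32, 32)).astype(float)
        assert ssim(y, y, windowed=True) == pytest.approx(1.0)


def test_nmse_psnr_are_direction_sensitive(rng):
    """NMSE/PSNR depend on which argument is the reference; SSIM does not."""
    y = rng.poisson(100, (16, 16)).astype(float)
    x = 0.2 * y
    assert nmse(x, y) != pytest.approx(nmse(y, x))
    assert psnr(x, y) != pytest.approx(psnr(y, x))


def test_metrics_invariant_to_common_translation(rng):
    y = rng.poisson(30, (32, 32)).astype(float)
    x = y + rng.normal(0, 2, y.shape)
    xs, ys = np.roll(x, 5, axis=1), np.roll(y, 5, axis=1)
    assert nmse(x, y) == pytest.approx(nmse(xs, ys))
    assert psnr(x, y) == pytest.approx(psnr(xs, ys))
    assert ssim(x, y) == pytest.approx(ssim(xs, ys))


class TestJointHistogram:
    def test_identical_images_perfect_correlation(self, rng):
        y = rng.poisson(20, (32, 32)).astype(float)
        hist, xe, ye, r, r2 = joint_histogram(y, y, bins=16)
        assert r2 == pytest.approx(1.0)
        # mass confined to diagonal bins
        off_diag = hist.sum() - np.trace(hist)
        assert off_diag == 0

    def test_linear_scaling_preserves_correlation(self, rng):
        x = rng.poisson(20, (32, 32)).astype(float)
        _, _, _, _, r2 = joint_histogram(x, 5.0 * x)
        assert r2 == pytest.approx(1.0)

    def test_attenuation_matches_variance_ratio(self, rng):
        """r^2 of y vs y+noise equals var(y)/(var(y)+var(noise))."""
        y = rng.normal(0, 2.0, size=200_000)
        x = y + rng.normal(0, 1.0, size=y.size)
        _, _, _, _, r2 = joint_histogram(x.reshape(500, 400), y.reshape(500, 400))
        expected = 4.0 / (4.0 + 1.0)
        assert r2 == pytest.approx(expected, abs=0.01)


def test_short_time_nmse_matches_poisson_closed_form():
    """Mean NMSE of 2-of-10 frame sums follows the subset-sum expectation.

    With per-pixel per-frame means mu, E[sum (y-x)^2] = sum(64 mu^2 + 8 mu)
    and E[sum y^2] = sum(100 mu^2 + 10 mu); the Monte-Carlo mean over all 45
    pairs of several phantoms must sit within 3 standard errors.
    """
    vals = []
    for seed in range(5):
        series, gt = generate_phantom(PhantomSpec(seed=seed))
        vals.extend(nmse(p.short_time, p.full_time) for p in build_pairs(series, "c"))
    mu = generate_phantom(PhantomSpec(seed=0))[1].noiseless_map
    expected = 100.0 * np.sum(64 * mu**2 + 8 * mu) / np.sum(100 * mu**2 + 10 * mu)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert np.mean(vals) == pytest.approx(expected, abs=3 * se + 0.05)


class TestEvaluateSplit:
    def test_perfect_prediction_row(self, rng):
        ref = [rng.poisson(30, (16, 16)).astype(float)]
        table = evaluate_split({"model": [ref[0].copy()]}, [0.2 * ref[0]], ref)
        row = table[(table.method == "model") & (table.metric == "nmse_percent")].iloc[0]
        assert row["mean"] == 0.0
        srow = table[(table.method == "model") & (table.metric == "ssim")].iloc[0]
        assert srow["mean"] == pytest.approx(1.0)

    def test_aggregation_rule(self):
        s = summarize_metric([1.0, 2.0, 3.0])
        assert (s["mean"], s["median"], s["q1"], s["q3"]) == (2.0, 2.0, 1.5, 2.5)

    def test_infinite_psnr_excluded_from_mean(self):
        s = summarize_metric([10.0, math.inf, 20.0], "psnr")
        assert s["mean"] == pytest.approx(15.0)
        assert s["n_excluded_inf"] == 1
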