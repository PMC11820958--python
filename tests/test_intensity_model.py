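import numpy as np
import pytest
from scipy import integrate
from scipy import stats

from somatrack.intensity_model import (
    BinarizeParams,
    beta_pdf,
    binarize_stack,
    e_step,
    fit_two_beta_em,
    intersect_threshold,
    intersect_threshold_theta,
    loglik,
    m_step,
    premask_and_rescale,
)

from conftest import mixture_sample


# ---------------------------------------------------------------------------
# premask / rescale


class TestPremask:
    def test_percentile_zero_retains_every_pixel(self, rng):
        slice_ = rng.integers(0, 256, (16, 16)).astype(float)
        obs = premask_and_rescale(slice_, premask_percentile=0)
        assert obs.mask.all()
        assert obs.values.size == slice_.size

    def test_retained_set_matches_sort_oracle(self):
        """Oracle: sort, walk to the interpolated 99th-percentile rank, keep
        everything at or above it."""
        slice_ = np.arange(1.0, 101.0).reshape(10, 10)
        obs = premask_and_rescale(slice_, premask_percentile=99)
        v = np.sort(slice_.ravel())
        pos = (v.size - 1) * 0.99  # fractional rank of the 99th percentile
        lo = int(np.floor(pos))
        cut = v[lo] + (v[lo + 1] - v[lo]) * (pos - lo)
        expected = slice_ >= cut
        assert np.array_equal(obs.mask, expected)
        assert np.all(obs.raw[~obs.mask] < cut)

    def test_values_rescaled_and_clamped(self, rng):
        slice_ = rng.uniform(0, 255, (32, 32))
        obs = premask_and_rescale(slice_, premask_percentile=90)
        assert obs.values.min() >= 1e-6
        assert obs.values.max() <= 1 - 1e-6
        # monotone map: order of retained values preserved
        raw_order = np.argsort(obs.raw[obs.mask])
        assert np.all(np.diff(obs.values[raw_order]) >= 0)

    def test_constant_slice_is_degenerate(self):
        obs = premask_and_rescale(np.full((8, 8), 7.0))
        assert obs.degenerate
        assert obs.values.size == 0

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            premask_and_rescale(np.zeros((4, 4)), premask_percentile=101)


# ---------------------------------------------------------------------------
# densities and EM steps


class TestBetaPdf:
    def test_closed_forms(self):
        assert beta_pdf(0.5, 1, 1) == pytest.approx(1.0)
        assert beta_pdf(0.5, 2, 2) == pytest.approx(1.5)

    @pytest.mark.parametrize("a,b", [(2, 8), (5, 5), (0.7, 3)])
    def test_integrates_to_one(self, a, b):
        val, _ = integrate.quad(lambda y: beta_pdf(y, a, b), 0, 1)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            beta_pdf(0.5, 0, 1)
        with pytest.raises(ValueError):
            beta_pdf(0.5, 1, -2)


class TestEStep:
    def test_identical_components_posterior_equals_prior(self, rng):
        y = rng.uniform(0.05, 0.95, 100)
        r1 = e_step(y, (3.0, 3.0, 3.0, 3.0, 0.3))
        assert np.allclose(r1, 0.7)

    def test_pure_background_prior(self, rng):
        y = rng.uniform(0.05, 0.95, 50)
        r1 = e_step(y, (2.0, 5.0, 5.0, 2.0, 1.0))
        assert np.allclose(r1, 0.0)

    def test_matches_direct_ratio_formula(self, rng):
        """Log-space implementation agrees with the plain posterior ratio."""
        y = rng.uniform(0.01, 0.99, 50)
        theta = (1.7, 6.2, 5.9, 1.3, 0.41)
        a0, b0, a1, b1, p0 = theta
        num = (1 - p0) * stats.beta.pdf(y, a1, b1)
        den = p0 * stats.beta.pdf(y, a0, b0) + num
        assert np.allclose(e_step(y, theta), num / den, atol=1e-12)

    def test_responsibilities_sum_to_one(self, rng):
        y = rng.uniform(0.01, 0.99, 200)
        r1 = e_step(y, (2.0, 8.0, 8.0, 2.0, 0.6))
        assert np.all((0 <= r1) & (r1 <= 1))


class TestMStep:
    def test_hard_assignment_recovers_per_class_mle(self, rng):
        """With 0/1 responsibilities each component's (a, b) equals the
        plain beta maximum-likelihood fit of its assigned values."""
        y0 = rng.beta(2, 6, 4000)
        y1 = rng.beta(7, 2, 4000)
        y = np.concatenate([y0, y1])
        r1 = np.concatenate([np.zeros(4000), np.ones(4000)])
        a0, b0, a1, b1, p0 = m_step(y, r1, (2.0, 2.0, 2.0, 2.0, 0.5))
        ref0 = stats.beta.fit(y0, floc=0, fscale=1)
        ref1 = stats.beta.fit(y1, floc=0, fscale=1)
        assert (a0, b0) == pytest.approx(ref0[:2], rel=1e-3)
        assert (a1, b1) == pytest.approx(ref1[:2], rel=1e-3)
        assert p0 == pytest.approx(0.5)

    def test_p0_update_is_mean_class0_responsibility(self, rng):
        y = rng.uniform(0.05, 0.95, 300)
        r1 = rng.uniform(0, 1, 300)
        theta = m_step(y, r1, (2.0, 2.0, 2.0, 2.0, 0.5))
        assert theta[4] == pytest.approx(1 - r1.mean())

    def test_symmetric_responsibilities_give_identical_updates(self, rng):
        y = rng.beta(3, 4, 500)
        theta = m_step(y, np.full(500, 0.5), (2.0, 3.0, 2.0, 3.0, 0.5))
        assert theta[0] == pytest.approx(theta[2])
        assert theta[1] == pytest.approx(theta[3])

    def test_q_never_decreases(self, rng):
        """Each M-step weakly increases the observed-data log-likelihood."""
        y = np.clip(mixture_sample(rng, 2000), 1e-6, 1 - 1e-6)
        theta = (1.5, 4.0, 4.0, 1.5, 0.4)
        for _ in range(10):
            r1 = e_step(y, theta)
            before = loglik(y, theta)
            theta = m_step(y, r1, theta)
            assert loglik(y, theta) >= before - 1e-8


# ---------------------------------------------------------------------------
# full EM fit


class TestFitTwoBetaEM:
    def test_recovers_known_mixture(self, rng):
        y = mixture_sample(rng, 10000)
        fit = fit_two_beta_em(y, seed=4)
        assert fit.n_components_detected == 2
        assert fit.threshold_source == "intersection"
        assert abs(fit.p0 - 0.5) < 0.05
        assert abs(fit.mean0 - 0.2) < 0.02
        assert abs(fit.mean1 - 0.8) < 0.02

    def test_loglik_trace_nondecreasing(self, rng):
        y = mixture_sample(rng, 5000)
        fit = fit_two_beta_em(y, seed=1)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_single_component_collapses_to_fallback(self, rng):
        y = rng.beta(3, 3, 5000)
        fit = fit_two_beta_em(y, seed=2)
        assert fit.n_components_detected == 1
        assert fit.threshold_source == "fallback_percentile"
        assert fit.threshold == pytest.approx(np.percentile(np.clip(y, 1e-6, 1 - 1e-6), 80))

    def test_too_few_values_fall_back(self, rng):
        y = rng.beta(2, 8, 10)
        fit = fit_two_beta_em(y, seed=0, min_retained=50)
        assert fit.n_components_detected == 1
        assert fit.threshold_source == "fallback_percentile"

    def test_brighter_component_is_second(self, rng):
        y = mixture_sample(rng, 8000, p0=0.7)
        fit = fit_two_beta_em(y, seed=9)
        assert fit.mean1 >= fit.mean0

    def test_fallback_percentile_is_configurable(self, rng):
        y = rng.beta(3, 3, 5000)
        fit = fit_two_beta_em(y, seed=2, fallback_percentile=70)
        assert fit.threshold == pytest.approx(np.percentile(np.clip(y, 1e-6, 1 - 1e-6), 70))


# ---------------------------------------------------------------------------
# intersection threshold


class TestIntersectThreshold:
    def test_mirror_symmetric_mixture_crosses_at_half(self):
        tau = intersect_threshold_theta((2.0, 5.0, 5.0, 2.0, 0.5))
        assert tau == pytest.approx(0.5, abs=1e-6)

    def test_matches_dense_grid_search(self):
        theta = (2.0, 8.0, 8.0, 2.0, 0.7)
        tau = intersect_threshold_theta(theta)
        ys = np.linspace(1e-6, 1 - 1e-6, 10**6)
        g = 0.7 * stats.beta.pdf(ys, 2, 8) - 0.3 * stats.beta.pdf(ys, 8, 2)
        m0, m1 = 0.2, 0.8
        inside = (ys > m0) & (ys < m1)
        crossings = ys[inside][np.nonzero(np.diff(np.sign(g[inside])))[0]]
        assert tau == pytest.approx(crossings[0], abs=1e-5)

    def test_weighted_densities_equal_at_root(self, rng):
        for _ in range(20):
            a0, b0 = rng.uniform(1, 10), rng.uniform(2, 15)
            a1, b1 = rng.uniform(2, 15), rng.uniform(1, 10)
            p0 = rng.uniform(0.2, 0.8)
            theta = (a0, b0, a1, b1, p0)
            tau = intersect_threshold_theta(theta)
            if tau is None:
                continue
            resid = p0 * stats.beta.pdf(tau, a0, b0) - (1 - p0) * stats.beta.pdf(tau, a1, b1)
            assert abs(resid) < 1e-6

    def test_threshold_monotone_in_background_weight(self):
        """Growing the background proportion pushes the crossing brighter."""
        taus = []
        for p0 in np.linspace(0.3, 0.9, 7):
            tau = intersect_threshold_theta((2.0, 8.0, 8.0, 2.0, float(p0)))
            assert tau is not None
            taus.append(tau)
        assert np.all(np.diff(taus) > 0)

    def test_requires_two_components(self, rng):
        fit = fit_two_beta_em(rng.beta(3, 3, 5000), seed=2)
        assert fit.n_components_detected == 1
        with pytest.raises(ValueError):
            intersect_threshold(fit)


# ---------------------------------------------------------------------------
# whole-stack binarization


class TestBinarizeStack:
    def test_all_zero_stack_is_all_background(self):
        binary, fits, errors = binarize_stack(np.zeros((8, 8, 3, 2), dtype=np.uint8))
        assert not binary.any()
        assert not errors
        assert all(f.threshold_source == "fallback_percentile" for f in fits.values())

    def test_bright_disks_detected_against_dim_background(self, rng):
        """A slice large enough for the mixture path: >=99% of disk-interior
        pixels become ROI and <=1% of far background does."""
        I = J = 160
        slice_ = rng.beta(2, 20, (I, J)) * 255
        xx, yy = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
        disk = (xx - 80) ** 2 + (yy - 80) ** 2 <= 5**2
        slice_[disk] = 230 * rng.beta(20, 3, disk.sum())
        stack = np.rint(slice_)[:, :, None, None].astype(np.uint8)
        binary, fits, _ = binarize_stack(stack, seed=0)
        fit = fits[(0, 0)]
        assert fit.n_components_detected == 2
        b = binary[:, :, 0, 0]
        far = (xx - 80) ** 2 + (yy - 80) ** 2 > 20**2
        assert b[disk].mean() >= 0.99
        assert b[far].mean() <= 0.01

    def test_roi_voxels_are_exactly_those_at_or_above_threshold(self, rng):
        stack = rng.integers(0, 256, (16, 16, 2, 2)).astype(np.uint8)
        binary, fits, _ = binarize_stack(stack, seed=3)
        for (k, t), fit in fits.items():
            expected = stack[:, :, k, t] >= fit.threshold_raw
            assert np.array_equal(binary[:, :, k, t].astype(bool), expected)

    def test_slice_permutation_equivariance_in_fallback_regime(self, rng):
        """Slices are processed independently: permuting z-slices permutes
        the output identically (percentile path has no randomness)."""
        stack = rng.integers(0, 256, (12, 12, 4, 2)).astype(np.uint8)
        binary, _, _ = binarize_stack(stack, seed=0)
        perm = [2, 0, 3, 1]
        binary_perm, _, _ = binarize_stack(stack[:, :, perm, :], seed=0)
        assert np.array_equal(binary_perm, binary[:, :, perm, :])

    def test_serial_equals_parallel(self, rng):
        stack = rng.integers(0, 256, (16, 16, 3, 2)).astype(np.uint8)
        b1, _, _ = binarize_stack(stack, seed=5, n_jobs=1)
        b2, _, _ = binarize_stack(stack, seed=5, n_jobs=2)
        assert np.array_equal(b1, b2)
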