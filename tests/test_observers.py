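"""Decision variables, noise model, and measurement-space boundaries."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

import psyconf as pc
from psyconf import observers as obs
from psyconf.observers import (CategoryBeliefs, NoiseParams, bayes_boundaries,
                               category_likelihood, dnoise_grid,
                               heuristic_boundaries, hybrid_decision_variable,
                               hybrid_thresholds, linear_neural_moments,
                               log_posterior_ratio, map_orientation_estimate,
                               orientation_estimator, prob_correct, sigma_of)


def make_noise(sigma_low=6.0, sigma_high=1.5, beta=1.0, psi=0.0):
    return NoiseParams(mode="parametric", psi=psi, sigma_low=sigma_low,
                       sigma_high=sigma_high, beta=beta,
                       c_lo=pc.GABOR_CONTRASTS[0], c_hi=pc.GABOR_CONTRASTS[-1])


class TestSigmaOf:
    def test_endpoints_exact(self):
        n = make_noise()
        assert sigma_of(n, pc.GABOR_CONTRASTS[0], 0.0) == pytest.approx(6.0)
        assert sigma_of(n, pc.GABOR_CONTRASTS[-1], 0.0) == pytest.approx(1.5)

    def test_orientation_independence_without_psi(self):
        n = make_noise(psi=0.0)
        c = pc.GABOR_CONTRASTS[2]
        vals = sigma_of(n, c, np.array([-40.0, 0.0, 17.0, 45.0]))
        assert np.ptp(vals) == 0.0

    def test_oblique_orientation_adds_psi(self):
        n = make_noise(psi=2.0)
        c = pc.GABOR_CONTRASTS[2]
        base = sigma_of(make_noise(psi=0.0), c, 45.0)
        assert sigma_of(n, c, 45.0) == pytest.approx(base + 2.0)

    def test_monotone_decreasing_in_reliability(self):
        n = make_noise()
        sig = sigma_of(n, np.array(pc.GABOR_CONTRASTS), 0.0)
        assert np.all(np.diff(sig) < 0)

    def test_out_of_range_reliability_rejected(self):
        with pytest.raises(ValueError):
            sigma_of(make_noise(), 0.5, 0.0)

    def test_nonparametric_lookup(self):
        n = NoiseParams(mode="nonparametric", sigma_per_level=(6, 5, 4, 3, 2, 1),
                        levels=pc.GABOR_CONTRASTS)
        assert sigma_of(n, pc.GABOR_CONTRASTS[3], 0.0) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            sigma_of(n, 0.05, 0.0)


class TestCategoryLikelihood:
    def test_peak_density(self):
        val = category_likelihood(0.0, 4.0, 0.0, 3.0)
        assert val == pytest.approx(1.0 / math.sqrt(2 * math.pi * 25.0))

    def test_task_b_wide_category_zero_noise(self):
        val = category_likelihood(0.0, 0.0, 0.0, 12.0)
        assert val == pytest.approx(1.0 / (12.0 * math.sqrt(2 * math.pi)),
                                    rel=1e-9)

    def test_normalization(self):
        from scipy.integrate import quad
        total, _ = quad(lambda x: category_likelihood(x, 4.0, -4.0, 5.0),
                        -100, 100)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestLogPosteriorRatio:
    def test_task_a_symmetry_point(self, task_A):
        assert log_posterior_ratio(task_A, 0.0, 5.0) == pytest.approx(0.0)

    def test_task_a_direct_value(self, task_A):
        d = log_posterior_ratio(task_A, -5.0, 5.0)
        assert d == pytest.approx(2 * (-5.0) * (-4.0) / 50.0)

    def test_task_b_direct_value(self, task_B):
        d = log_posterior_ratio(task_B, 0.0, 4.0)
        assert d == pytest.approx(0.5 * math.log(160.0 / 25.0))

    def test_prior_shifts_d_additively(self, task_A):
        beliefs = CategoryBeliefs((-4, 4), (5, 5), log_prior_ratio=0.7)
        d0 = log_posterior_ratio(task_A, 2.0, 5.0)
        d1 = log_posterior_ratio(task_A, 2.0, 5.0, beliefs)
        assert d1 - d0 == pytest.approx(0.7)


class TestProbCorrect:
    @pytest.mark.parametrize("d,expect", [(0.0, 0.5),
                                          (0.8, 1 / (1 + math.exp(-0.8))),
                                          (50.0, 1.0)])
    def test_logistic_values(self, d, expect):
        assert prob_correct(d) == pytest.approx(expect, abs=1e-9)


class TestBayesBoundaries:
    def test_task_a_zero_criterion(self, task_A):
        b = bayes_boundaries(task_A, [0.0], np.array([1.0, 4.0, 9.0]))
        assert np.allclose(b, 0.0)

    def test_task_b_worked_value(self, task_B):
        b = bayes_boundaries(task_B, [0.0], np.array([4.0]))
        expect = math.sqrt(0.5 * math.log(160 / 25) * 2 * 25 * 160 / 135)
        assert b[0, 0] == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(7.42, abs=0.005)

    def test_task_b_unreachable_criterion_collapses(self, task_B):
        # d_B at sigma=4 never exceeds its x=0 maximum
        dmax = log_posterior_ratio(task_B, 0.0, 4.0)
        b = bayes_boundaries(task_B, [dmax + 1.0], np.array([4.0]))
        assert b[0, 0] == 0.0

    def test_equal_category_sds_rejected(self):
        task = pc.TaskSpec("B", mu=(0, 0), sigma_cat=(5.0, 5.0))
        with pytest.raises(ValueError):
            bayes_boundaries(task, [0.0], np.array([2.0]))

    def test_matches_bisection_root_finding(self, task_A, task_B, rng):
        """Closed-form inversion vs a brentq solve of d(x) = k."""
        for _ in range(100):
            sigma = float(rng.uniform(0.3, 20.0))
            task = task_A if rng.random() < 0.5 else task_B
            if task.task_id == "A":
                k = float(rng.uniform(-5, 5))
                b = bayes_boundaries(task, [k], np.array([sigma]))[0, 0]
                root = optimize.brentq(
                    lambda x: log_posterior_ratio(task, x, sigma) - k,
                    -1e4, 1e4, xtol=1e-12)
                assert b == pytest.approx(root, abs=1e-9)
            else:
                dmax = log_posterior_ratio(task, 0.0, sigma)
                k = float(rng.uniform(min(dmax - 5, -1), dmax - 1e-3))
                b = bayes_boundaries(task, [k], np.array([sigma]))[0, 0]
                root = optimize.brentq(
                    lambda x: log_posterior_ratio(task, x, sigma) - k,
                    0.0, 1e4, xtol=1e-12)
                assert b == pytest.approx(root, abs=1e-9)

    def test_task_a_boundaries_affine_in_sigma_squared(self, task_A):
        k = np.array([-2.0, -0.5, 1.0, 3.0])
        sigma = np.linspace(0.5, 15, 40)
        b = bayes_boundaries(task_A, k, sigma)
        s2 = sigma**2
        for j in range(b.shape[1]):
            coef = np.polyfit(s2, b[:, j], 1)
            assert np.allclose(np.polyval(coef, s2), b[:, j], atol=1e-9)

    def test_sorted_output(self, task_B, rng):
        for _ in range(20):
            k = rng.uniform(-3, 3, size=7)
            b = bayes_boundaries(task_B, k, rng.uniform(0.5, 10, size=5))
            assert np.all(np.diff(b, axis=-1) >= 0)


class TestDnoiseGrid:
    def test_weights_normalized_and_symmetric(self):
        eta, w = dnoise_grid(1.3)
        assert len(eta) == 101
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, w[::-1])
        assert np.allclose(eta, -eta[::-1])

    def test_marginal_choice_probability_at_symmetry_point(self, task_A):
        # at x = 0 with equal priors the marginalized category probability
        # stays 1/2 for any d-noise level
        eta, w = dnoise_grid(2.0)
        b = bayes_boundaries(task_A, -eta[:, None], 3.0)[:, 0]
        p_cat1 = np.sum(w * (0.0 < b)) + 0.5 * np.sum(w * (b == 0.0))
        assert p_cat1 == pytest.approx(0.5, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dnoise_grid(0.0)
        with pytest.raises(ValueError):
            dnoise_grid(1.0, n_draws=100)


class TestHeuristicBoundaries:
    def test_lin_at_zero_slope_equals_fixed(self, rng):
        k = np.sort(rng.uniform(-10, 10, 7))
        sigma = rng.uniform(0.5, 8, 5)
        fixed = heuristic_boundaries("fixed", k, None, sigma, "A")
        lin = heuristic_boundaries("lin", k, np.zeros(7), sigma, "A")
        assert np.array_equal(fixed, lin)

    def test_quad_direct_value(self):
        b = heuristic_boundaries("quad", [1.0], [2.0], np.array([3.0]), "A")
        assert b[0, 0] == pytest.approx(19.0)

    def test_task_b_clipped_at_zero(self):
        b = heuristic_boundaries("lin", [-5.0, 2.0], [0.0, 0.0],
                                 np.array([1.0]), "B")
        assert b[0, 0] == 0.0 and b[0, 1] == 2.0

    def test_quad_reproduces_bayes_task_a(self, task_A):
        """Task A Bayes boundaries are exactly quadratic in sigma."""
        k = np.array([-2.0, 0.5, 1.5])
        sigma = np.linspace(0.5, 12, 30)
        bb = bayes_boundaries(task_A, k, sigma)
        kq = np.sort(k * 25.0 / (2 * task_A.mu[0]))
        mq = np.sort(k / (2 * task_A.mu[0]))
        # sorting reverses index order identically for both coefficients
        hq = heuristic_boundaries("quad", kq, mq[::-1] if task_A.mu[0] > 0
                                  else np.sort(k / (2 * task_A.mu[0]))[::-1],
                                  sigma, "A")
        direct = np.sort((k * 25.0 + k * sigma[:, None]**2)
                         / (2 * task_A.mu[0]), axis=1)
        assert np.allclose(bb, direct, atol=1e-12)


class TestBoundaryProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(k=st.lists(st.floats(-20, 20), min_size=7, max_size=7),
           m=st.lists(st.floats(-5, 5), min_size=7, max_size=7),
           sigma=st.floats(0.2, 30), family=st.sampled_from(
               ["fixed", "lin", "quad"]),
           task_id=st.sampled_from(["A", "B"]))
    def test_boundaries_sorted_and_clipped(self, k, m, sigma, family,
                                           task_id):
        """Boundary vectors are always nondecreasing, and Task B
        boundaries never cross below 0."""
        b = heuristic_boundaries(family, np.array(k), np.array(m),
                                 np.array([sigma]), task_id)
        assert np.all(np.diff(b, axis=-1) >= 0)
        if task_id == "B":
            assert np.all(b >= 0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(k=st.lists(st.floats(-10, 10), min_size=7, max_size=7),
           sigma=st.floats(0.2, 30), task_id=st.sampled_from(["A", "B"]))
    def test_bayes_boundaries_sorted(self, k, sigma, task_id):
        task = pc.task_a() if task_id == "A" else pc.task_b()
        b = bayes_boundaries(task, np.array(k), np.array([sigma]))
        assert np.all(np.diff(b, axis=-1) >= 0)
        if task_id == "B":
            assert np.all(b >= 0)


class TestOrientationEstimation:
    def test_symmetric_measurement_maps_to_zero(self, task_B):
        assert map_orientation_estimate(0.0, 3.0, task_B) == pytest.approx(
            0.0, abs=1e-6)

    def test_small_noise_estimate_tracks_measurement(self, task_B):
        x = 6.0
        shat = map_orientation_estimate(x, 0.05, task_B)
        assert shat == pytest.approx(x, abs=0.1)

    def test_shrinkage_toward_prior_mode(self, task_B):
        shat = map_orientation_estimate(5.0, 10.0, task_B)
        assert 0.0 < shat < 5.0

    def test_matches_brute_force_maximization(self, task_A, task_B, rng):
        for task in (task_A, task_B):
            est = orientation_estimator(task)
            for _ in range(10):
                x = float(rng.uniform(-25, 25))
                sigma = float(rng.uniform(0.3, 15))
                s_grid = np.linspace(-60, 60, 10_000)
                post = (stats.norm.pdf(s_grid, x, sigma)
                        * task.stimulus_pdf(s_grid))
                brute = s_grid[np.argmax(post)]
                cell = est.x_grid[1] - est.x_grid[0]
                assert abs(est.estimate(x, sigma) - brute) < max(cell, 0.05) * 2

    def test_halved_lookup_resolution_barely_moves_likelihood(
            self, monkeypatch, make_params):
        """Dataset log likelihoods are insensitive to the lookup-table
        resolution: halving both axes changes them by less than 0.1."""
        from psyconf.likelihood import dataset_log_likelihood
        model, pv = make_params("orientation_estimation", seed=6)
        ds = pc.generate_dataset(
            [pc.task_a(), pc.task_b()],
            pc.SessionStructure(n_sessions=1, testing_blocks=(1, 200)),
            model, pv, seed=4)
        ll_full = dataset_log_likelihood(model, pv, ds)
        monkeypatch.setattr(obs, "OE_DEFAULT_RESOLUTION", (250, 25))
        obs._cached_estimator.cache_clear()
        ll_half = dataset_log_likelihood(model, pv, ds)
        obs._cached_estimator.cache_clear()
        assert abs(ll_full - ll_half) < 0.1

    def test_inversion_consistency(self, task_B):
        est = orientation_estimator(task_B)
        sigma = 4.0
        for k in (0.5, 2.0, 5.0):
            x = est.invert([k], sigma)[0]
            assert est.estimate(x, sigma) == pytest.approx(k, abs=0.05)


class TestLinearNeural:
    def test_zero_stimulus_moments(self):
        mean, var = linear_neural_moments(0.0, 2.0, a=1.5, sigma_tc=10.0)
        amp = 1.5 * 0.25 * math.sqrt(2 * math.pi * 100.0)
        assert mean == 0.0
        assert var == pytest.approx(1.5 * amp * 100.0)

    def test_parity(self):
        m1, v1 = linear_neural_moments(7.0, 3.0, 1.0, 8.0)
        m2, v2 = linear_neural_moments(-7.0, 3.0, 1.0, 8.0)
        assert m1 == -m2 and v1 == v2

    def test_against_poisson_population_simulation(self, rng):
        """Oracle: simulate the Poisson population on a dense grid of
        preferred orientations and check the readout moments."""
        a, sigma_tc, sigma, s = 0.8, 6.0, 1.5, 4.0
        g = 1.0 / sigma**2
        pref = np.arange(-200.0, 200.0, 0.25)
        rates = g * np.exp(-0.5 * (s - pref) ** 2 / sigma_tc**2)
        w = a * pref
        n_rep = 40_000
        counts = rng.poisson(rates, size=(n_rep, len(pref)))
        z = counts @ w
        # the continuum integrals equal the grid sums times the spacing
        mean_th, var_th = linear_neural_moments(s, sigma, a, sigma_tc)
        spacing = 0.25
        assert abs(z.mean() - mean_th / spacing) < 4 * z.std() / math.sqrt(n_rep)
        assert abs(z.var() - var_th / spacing) < 4 * math.sqrt(2.0 / n_rep) * z.var()

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            linear_neural_moments(0.0, 1.0, a=-1.0, sigma_tc=5.0)


class TestHybrid:
    def test_zero_weight_reduces_to_probability_correct(self):
        d = np.array([-2.0, 0.0, 1.5])
        v = hybrid_decision_variable(d, 2.0, omega=0.0)
        assert np.allclose(v, prob_correct(np.abs(d)))

    def test_zero_evidence_value(self):
        assert hybrid_decision_variable(0.0, 2.0, omega=3.0) == pytest.approx(
            3.0 / 4.0 + 0.5)

    def test_strictly_decreasing_in_sigma(self):
        sig = np.linspace(0.5, 10, 50)
        v = hybrid_decision_variable(np.full_like(sig, 1.2), sig, omega=2.0)
        assert np.all(np.diff(v) < 0)

    def test_threshold_saturation(self):
        t = hybrid_thresholds(np.array([0.2, 0.8, 5.0]), np.array([1.0]),
                              omega=0.0)
        assert t[0, 0] == 0.0          # below the attainable range
        assert np.isfinite(t[0, 1])
        assert np.isinf(t[0, 2])       # above the attainable range
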