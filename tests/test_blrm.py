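"""The two-parameter logistic dose-toxicity model and its posterior machinery."""

import math

import numpy as np
import pytest
from scipy.special import logit

from toxbridge import (
    DoseLevel,
    GridSpec,
    PriorSpec,
    TrialDataset,
    likelihood_exponents,
    log_likelihood,
    mtd_posterior,
    mtd_transform,
    posterior_grid,
    sample_posterior,
    simulate_trial,
)
from toxbridge.trial_io import TrialValidationError

XR = 400.0


def _trial(*levels):
    return TrialDataset(label="t", dose_levels=tuple(DoseLevel(*lv) for lv in levels))


class TestLogLikelihood:
    def test_half_probability_at_reference_dose(self):
        # one DLT in one patient dosed at xr with beta0 = 0 -> p = 0.5
        assert log_likelihood(_trial((XR, 1, 1)), 0.0, 0.0, XR) == pytest.approx(
            math.log(0.5), abs=1e-9
        )

    def test_prior_centring_probability(self):
        # p(xr) = 0.1 when beta0 = logit(0.1), regardless of slope
        t = _trial((XR, 0, 2))
        for beta1 in (-3.0, 0.0, 2.0):
            assert log_likelihood(t, float(logit(0.1)), beta1, XR) == pytest.approx(
                2 * math.log(0.9), abs=1e-9
            )

    def test_zero_patient_level_contributes_nothing(self):
        with_empty = _trial((XR, 1, 1), (2 * XR, 0, 0))
        assert log_likelihood(with_empty, 0.3, -0.2, XR) == pytest.approx(
            log_likelihood(_trial((XR, 1, 1)), 0.3, -0.2, XR)
        )

    def test_finite_at_extreme_parameters(self):
        t = _trial((100.0, 0, 3), (800.0, 3, 3))
        grid = np.linspace(-40, 40, 9)
        vals = log_likelihood(t, grid[:, None], grid[None, :], XR)
        assert np.all(np.isfinite(vals))

    def test_broadcasts_over_grids(self):
        t = _trial((XR, 1, 2))
        out = log_likelihood(t, np.zeros((5, 1)), np.zeros((1, 7)), XR)
        assert out.shape == (5, 7)


class TestLikelihoodExponents:
    @pytest.mark.parametrize(
        "nc,na,expected",
        [
            (24, 12, (0.5, 1.0)),
            (20, 20, (1.0, 1.0)),
            (24, 20, (20 / 24, 1.0)),
            (12, 24, (1.0, 0.5)),
        ],
    )
    def test_values(self, nc, na, expected):
        ec, ea = likelihood_exponents(nc, na)
        assert (ec, ea) == pytest.approx(expected)
        assert max(ec, ea) == 1.0

    def test_rejects_nonpositive_totals(self):
        with pytest.raises(TrialValidationError):
            likelihood_exponents(0, 10)


class TestPosteriorGrid:
    def test_normalized_and_nonnegative(self, synthetic_pair):
        c, _ = synthetic_pair
        post = posterior_grid(c, 1.0, PriorSpec(), XR, GridSpec(n_points=150))
        assert np.all(post.density >= 0)
        assert post.integral() == pytest.approx(1.0, abs=1e-6)

    def test_flat_prior_marginal_mode_at_zero(self):
        # single cohort at xr with 1/2 DLTs: profile likelihood peaks at p = 0.5
        t = _trial((XR, 1, 2))
        post = posterior_grid(
            t, 1.0, None, XR, GridSpec(n_points=201, bounds=((-5, 5), (-2, 2)))
        )
        marginal = post.density.sum(axis=1)
        assert abs(post.grid_beta0[np.argmax(marginal)]) < 0.06

    def test_huge_covariance_prior_matches_flat(self, synthetic_pair):
        c, _ = synthetic_pair
        bounds = ((-10.0, 10.0), (-5.0, 5.0))
        spec = GridSpec(n_points=150, bounds=bounds)
        flat = posterior_grid(c, 1.0, None, XR, spec)
        wide = posterior_grid(
            c, 1.0, PriorSpec(covariance=((1e8, 0.0), (0.0, 1e8))), XR, spec
        )
        assert np.max(np.abs(flat.density - wide.density)) < 1e-3

    def test_requires_bounds_for_flat_prior(self, synthetic_pair):
        with pytest.raises(ValueError):
            posterior_grid(synthetic_pair[0], 1.0, None, XR, GridSpec(n_points=150))

    def test_exponent_below_one_inflates_variance(self, synthetic_pair):
        c, _ = synthetic_pair
        spec = GridSpec(n_points=200)
        v_full = posterior_grid(c, 1.0, PriorSpec(), XR, spec).variance()
        v_half = posterior_grid(c, 0.5, PriorSpec(), XR, spec).variance()
        assert v_half[0] >= v_full[0]

    def test_minimum_resolution_enforced(self):
        with pytest.raises(ValueError):
            GridSpec(n_points=50)


class TestSamplePosterior:
    def test_mean_matches_grid_expectation(self, synthetic_pair):
        c, _ = synthetic_pair
        post = posterior_grid(c, 1.0, PriorSpec(), XR, GridSpec(n_points=200))
        draws = sample_posterior(post, 100_000, seed=7)
        m0, m1 = post.mean()
        v0, v1 = post.variance()
        for k, (m, v) in enumerate(((m0, v0), (m1, v1))):
            se = math.sqrt(v / draws.shape[0])
            assert abs(draws[:, k].mean() - m) < 3 * se + 1e-3

    def test_deterministic_for_fixed_seed(self, synthetic_pair):
        c, _ = synthetic_pair
        post = posterior_grid(c, 1.0, PriorSpec(), XR, GridSpec(n_points=120))
        a = sample_posterior(post, 5000, seed=11)
        b = sample_posterior(post, 5000, seed=11)
        assert np.array_equal(a, b)

    def test_concentrated_posterior_stays_in_cell(self, synthetic_pair):
        c, _ = synthetic_pair
        post = posterior_grid(c, 1.0, PriorSpec(), XR, GridSpec(n_points=120))
        peak = np.unravel_index(np.argmax(post.density), post.density.shape)
        concentrated = np.zeros_like(post.density)
        concentrated[peak] = 1.0
        post.density = concentrated / (post.weights[peak])
        draws = sample_posterior(post, 2000, seed=3)
        step0 = post.grid_beta0[1] - post.grid_beta0[0]
        step1 = post.grid_beta1[1] - post.grid_beta1[0]
        assert np.all(np.abs(draws[:, 0] - post.grid_beta0[peak[0]]) <= step0 / 2)
        assert np.all(np.abs(draws[:, 1] - post.grid_beta1[peak[1]]) <= step1 / 2)


class TestMtdTransform:
    def test_zero_when_beta0_hits_target(self):
        assert mtd_transform(float(logit(0.25)), 0.0, 0.25) == pytest.approx(0.0)
        assert mtd_transform(float(logit(0.25)), math.log(2), 0.25) == pytest.approx(0.0)

    def test_reference_centred_prior_mean_case(self):
        # beta0 = logit(0.1), unit slope, tau = 0.25: x* = xr * e^1.0986
        val = mtd_transform(float(logit(0.1)), 0.0, 0.25)
        assert val == pytest.approx(math.log(0.25 / 0.75) - math.log(0.1 / 0.9), abs=1e-9)
        assert XR * math.exp(val) == pytest.approx(1200.0, rel=1e-6)

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            mtd_transform(0.0, 0.0, 1.5)


class TestMtdPosterior:
    def _standard_normal_params(self, n, rng, tau=0.25):
        # beta1 = 0 makes x** = logit(tau) - beta0; choose beta0 so x** ~ N(0,1)
        z = rng.standard_normal(n)
        return np.column_stack([float(logit(tau)) - z, np.zeros(n)])

    def test_truncation_bounds_and_retention(self, rng):
        params = self._standard_normal_params(100_000, rng)
        m = mtd_posterior(params, tau=0.25)
        assert m.truncation_bounds[0] == pytest.approx(-1.2816, abs=0.02)
        assert m.truncation_bounds[1] == pytest.approx(1.2816, abs=0.02)
        assert abs(m.samples.size - 80_000) <= 1

    def test_symmetric_input_median_close_to_map(self, rng):
        m = mtd_posterior(self._standard_normal_params(50_000, rng), tau=0.25)
        spread = m.truncation_bounds[1] - m.truncation_bounds[0]
        assert abs(m.median - m.map) < 0.05 * spread

    def test_density_normalized_and_summaries_inside_bounds(self, rng):
        m = mtd_posterior(self._standard_normal_params(20_000, rng), tau=0.25)
        assert np.trapezoid(m.density, m.density_grid) == pytest.approx(1.0, abs=1e-6)
        lo, hi = m.truncation_bounds
        assert lo <= m.median <= hi and lo <= m.map <= hi
        assert np.all((m.samples >= lo) & (m.samples <= hi))

    def test_degenerate_samples_yield_point_mass(self):
        params = np.column_stack([np.full(2000, float(logit(0.25)) - 0.7), np.zeros(2000)])
        with pytest.warns(UserWarning, match="degenerate"):
            m = mtd_posterior(params, tau=0.25)
        assert m.degenerate and m.median == m.map == pytest.approx(0.7)

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            mtd_posterior(np.zeros((10, 2)), tau=0.25)


class TestParameterRecovery:
    def test_posterior_concentrates_on_truth(self):
        """A 200-patient trial pins down both parameters to within 0.15."""
        truth = (float(logit(0.2)), math.log(1.5))
        trial = simulate_trial(
            truth[0],
            truth[1],
            doses=[100, 200, 400, 600, 800, 1000],
            n_per_dose=[33, 33, 33, 33, 34, 34],
            xr=XR,
            rng=20210209,
        )
        assert trial.total_n == 200
        post = posterior_grid(trial, 1.0, PriorSpec(), XR, GridSpec(n_points=300))
        mean = post.mean()
        assert abs(mean[0] - truth[0]) < 0.15
        assert abs(mean[1] - truth[1]) < 0.15

    def test_extra_dlt_at_top_dose_lowers_mtd(self, synthetic_pair):
        c, _ = synthetic_pair
        worse_levels = list(c.dose_levels)
        top = worse_levels[-1]
        worse_levels[-1] = DoseLevel(top.dose, top.n_dlt + 1, top.n_patients + 1)
        worse = TrialDataset(label="worse", dose_levels=tuple(worse_levels))
        medians = []
        for t in (c, worse):
            post = posterior_grid(t, 1.0, PriorSpec(), XR, GridSpec(n_points=200))
            draws = sample_posterior(post, 50_000, seed=5)
            medians.append(mtd_posterior(draws, tau=0.3).median)
        assert medians[1] <= medians[0] + 1e-6
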