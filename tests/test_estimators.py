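import numpy as np
import pytest

from redoxcb import (
    PosteriorDensity,
    WorkSet,
    bar_estimate,
    convergence_curve,
    crooks_bayes,
    crooks_bayes_estimate,
    crooks_bayes_posterior,
    fep_estimate,
    histogram_crossing,
    jarzynski_estimate,
    lr_estimate,
)
from redoxcb.estimators import write_posterior_tsv
from redoxcb.exceptions import (
    DataError,
    DegenerateCrossingError,
    NoCrossingError,
    UnsupportedMethodError,
)


class TestCrooksBayes:
    def test_single_pair_posterior_symmetric_about_two(self, single_pair_ws):
        post = crooks_bayes_posterior(single_pair_ws)
        est = crooks_bayes_estimate(post)
        assert est.delta_g == pytest.approx(2.0, abs=1e-6)
        assert est.method == "cb"
        # density is symmetric: evaluate at ±d around the mean
        mid = np.interp(2.0, post.grid, post.density)
        for d in (0.5, 1.0, 3.0):
            lo = np.interp(2.0 - d, post.grid, post.density)
            hi = np.interp(2.0 + d, post.grid, post.density)
            assert lo == pytest.approx(hi, rel=1e-6)
            assert lo < mid

    def test_identical_multisets_give_zero(self, unit_thermo):
        vals = [0.3, -1.2, 2.5, 0.0]
        ws = WorkSet(vals, vals, unit_thermo)
        assert crooks_bayes(ws).delta_g == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_synthetic_within_three_sd(self, gaussian_ws):
        est = crooks_bayes(gaussian_ws)
        assert abs(est.delta_g - 5.0) <= 3 * est.std_error

    def test_moments_of_discretized_gaussian(self, thermo298):
        grid = np.linspace(-7, 13, 5001)
        dens = np.exp(-0.5 * ((grid - 3.0) / 0.5) ** 2)
        dens /= np.trapezoid(dens, grid)
        post = PosteriorDensity(grid, dens, thermo298)
        est = crooks_bayes_estimate(post)
        assert est.delta_g == pytest.approx(3.0, abs=1e-3)
        assert est.std_error == pytest.approx(0.5, abs=1e-3)

    def test_translation_covariance(self, gaussian_ws):
        base = crooks_bayes(gaussian_ws)
        c = 8.0
        shifted = WorkSet(
            gaussian_ws.forward + c, gaussian_ws.backward - c, gaussian_ws.thermo
        )
        assert crooks_bayes(shifted).delta_g - base.delta_g == pytest.approx(c, abs=1e-9)

    def test_one_sided_rejected(self, unit_thermo):
        ws = WorkSet([1.0, 2.0], [], unit_thermo)
        with pytest.raises(UnsupportedMethodError, match="jarzynski"):
            crooks_bayes_posterior(ws)

    def test_posterior_normalized_and_uniform_grid(self, gaussian_ws):
        post = crooks_bayes_posterior(gaussian_ws)
        assert np.trapezoid(post.density, post.grid) == pytest.approx(1.0, abs=1e-6)
        assert post.grid.size >= 101
        steps = np.diff(post.grid)
        assert np.allclose(steps, steps[0], rtol=1e-9)

    def test_unnormalized_density_rejected(self, thermo298):
        grid = np.linspace(0, 1, 201)
        with pytest.raises(ValueError, match="normalized"):
            PosteriorDensity(grid, np.full(201, 3.0), thermo298)

    def test_posterior_tsv_export(self, single_pair_ws, tmp_path):
        post = crooks_bayes_posterior(single_pair_ws)
        out = tmp_path / "post.tsv"
        write_posterior_tsv(post, out)
        data = np.loadtxt(out, skiprows=1)
        assert np.array_equal(data[:, 0], post.grid)
        assert np.array_equal(data[:, 1], post.density)


class TestBar:
    def test_single_pair_root(self, single_pair_ws):
        est = bar_estimate(single_pair_ws)
        assert est.delta_g == pytest.approx(2.0, abs=1e-10)
        assert est.method == "bar"

    def test_identical_multisets_give_zero(self, unit_thermo):
        vals = [0.5, 1.5, -0.7]
        ws = WorkSet(vals, vals, unit_thermo)
        assert bar_estimate(ws).delta_g == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_synthetic_within_three_se(self, gaussian_ws):
        est = bar_estimate(gaussian_ws)
        assert abs(est.delta_g - 5.0) <= 3 * est.std_error

    def test_mode_matches_bar_root(self, gaussian_ws):
        # the CB posterior and the BAR likelihood are the same function,
        # so the posterior mode sits on the BAR root (within grid spacing)
        post = crooks_bayes_posterior(gaussian_ws)
        spacing = post.grid[1] - post.grid[0]
        assert abs(post.mode() - bar_estimate(gaussian_ws).delta_g) <= spacing

    def test_unequal_counts_handled(self, unit_thermo, rng):
        # M = ln(n_F/n_R) enters both likelihood and residual; a 3:1 set
        # must still recover a sensible estimate near the true value
        ws = WorkSet(rng.normal(5.5, 1, 900), rng.normal(-4.5, 1, 300), unit_thermo)
        est = bar_estimate(ws)
        assert abs(est.delta_g - 5.0) <= 5 * est.std_error

    def test_one_sided_rejected(self, unit_thermo):
        with pytest.raises(UnsupportedMethodError):
            bar_estimate(WorkSet([], [1.0], unit_thermo))


class TestHistogramCrossing:
    def test_equal_variance_gaussians_cross_at_mean_midpoint(self, unit_thermo):
        rng = np.random.default_rng(7)
        ws = WorkSet(
            rng.normal(6, 1, 100_000), -rng.normal(4, 1, 100_000), unit_thermo
        )
        est = histogram_crossing(ws)
        assert est.delta_g == pytest.approx(5.0, abs=0.05)
        assert est.std_error is None

    def test_disjoint_support_raises(self, unit_thermo):
        ws = WorkSet([10.0] * 12, [10.0] * 12, unit_thermo)  # negated backward = -10
        with pytest.raises(NoCrossingError):
            histogram_crossing(ws)

    def test_degenerate_identical_samples(self, unit_thermo):
        vals = list(np.linspace(-1, 1, 15))
        ws = WorkSet(vals, [-v for v in vals], unit_thermo)
        with pytest.raises(DegenerateCrossingError):
            histogram_crossing(ws)

    def test_minimum_sample_size(self, unit_thermo):
        ws = WorkSet([1.0] * 5, [-1.0] * 5, unit_thermo)
        with pytest.raises(DataError, match=">= 10"):
            histogram_crossing(ws)


class TestOneSided:
    def test_single_value_identity(self, unit_thermo):
        assert jarzynski_estimate([5.0], unit_thermo).delta_g == pytest.approx(5.0)

    def test_constant_values(self, unit_thermo):
        assert jarzynski_estimate([3.3] * 9, unit_thermo).delta_g == pytest.approx(3.3)

    def test_two_value_logsumexp(self, unit_thermo):
        # -ln((1 + e^-100)/2) = ln 2 - ln(1 + e^-100) ~= 0.693147
        est = jarzynski_estimate([0.0, 100.0], unit_thermo)
        assert est.delta_g == pytest.approx(0.6931471805599453, rel=1e-12)

    def test_fep_is_alias(self, unit_thermo):
        w = [0.1, 2.3, -1.0]
        assert fep_estimate(w, unit_thermo).delta_g == jarzynski_estimate(
            w, unit_thermo
        ).delta_g
        assert fep_estimate(w, unit_thermo).method == "fep"

    def test_jensen_bound(self, unit_thermo, rng):
        for _ in range(20):
            w = rng.normal(0, 10, 50)
            assert jarzynski_estimate(w, unit_thermo).delta_g <= w.mean() + 1e-9

    def test_empty_rejected(self, unit_thermo):
        with pytest.raises(DataError):
            jarzynski_estimate([], unit_thermo)

    def test_lr_formula(self):
        from redoxcb import make_thermo

        thermo = make_thermo(1.0 / 0.008314462618 / 0.4)  # beta = 0.4
        vals = [10.0 - np.sqrt(2.0), 10.0 + np.sqrt(2.0)]  # mean 10, var(ddof=1) = 4
        assert lr_estimate(vals, thermo).delta_g == pytest.approx(9.2, rel=1e-9)

    def test_lr_zero_variance(self, unit_thermo):
        assert lr_estimate([7.7, 7.7, 7.7], unit_thermo).delta_g == pytest.approx(7.7)

    def test_lr_needs_two(self, unit_thermo):
        with pytest.raises(DataError):
            lr_estimate([1.0], unit_thermo)

    def test_lr_recovers_gaussian_ground_truth(self):
        from redoxcb import SyntheticWorkSpec, generate_crooks_gaussian

        ws = generate_crooks_gaussian(SyntheticWorkSpec(5.0, 2.0, 10_000, 298.0, 3))
        est = lr_estimate(ws.forward, ws.thermo)
        # sampling error of the mean is sigma/sqrt(n) = 0.02
        assert est.delta_g == pytest.approx(5.0, abs=0.1)


class TestConvergence:
    def test_full_schedule_is_identity(self, gaussian_ws):
        series = convergence_curve(gaussian_ws, [gaussian_ws.n_forward])
        full = crooks_bayes(gaussian_ws)
        assert series.estimates[0] == pytest.approx(full.delta_g, abs=1e-12)
        assert series.errors[0] == pytest.approx(full.std_error, abs=1e-12)

    def test_series_length(self, gaussian_ws):
        series = convergence_curve(gaussian_ws, [100, 200, 400, 800, 1600])
        assert len(series.mu_values) == 5

    def test_overlong_schedule_truncated_with_warning(self, gaussian_ws):
        with pytest.warns(UserWarning, match="truncated"):
            series = convergence_curve(gaussian_ws, [1000, 10_000])
        assert list(series.mu_values) == [1000]

    def test_non_increasing_schedule_rejected(self, gaussian_ws):
        with pytest.raises(DataError):
            convergence_curve(gaussian_ws, [500, 500])
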