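"""Direct least-squares, MLE and bootstrap estimators for (J, t_g)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleokin import (
    DistributionParams,
    FitError,
    InductionDataset,
    bootstrap_fit,
    fit_direct,
    fit_mle,
    fit_quality,
    generate_induction_times,
    invert_cdf,
)


class TestMLE:
    def test_closed_form_micro_example(self, three_times_dataset):
        res = fit_mle(three_times_dataset)
        assert res.params.t_g == 10_000.0
        # J*V = M / sum(t_i - min) = 3/3000 = 1e-3 #/s -> J = 0.1
        assert res.params.J == pytest.approx(0.1, rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(times=st.lists(st.floats(min_value=1.0, max_value=1e6),
                          min_size=2, max_size=40, unique=True),
           volume=st.floats(min_value=1e-6, max_value=1.0))
    def test_identities_hold_exactly(self, times, volume):
        ds = InductionDataset("h", tuple(times), volume)
        res = fit_mle(ds)
        t = ds.times_array
        assert res.params.t_g == t.min()
        # J_hat * V * sum(t_i - t_g_hat) == M exactly (up to float rounding)
        assert res.params.J * volume * np.sum(t - t.min()) == pytest.approx(
            ds.M, rel=1e-12)

    def test_loglikelihood_maximized_at_estimate(self, three_times_dataset):
        res = fit_mle(three_times_dataset)
        t = three_times_dataset.times_array
        tg = res.params.t_g
        jv_hat = res.params.J * three_times_dataset.volume_V

        def loglik(jv):
            return len(t) * np.log(jv) - jv * np.sum(t - tg)

        grid = np.linspace(0.2 * jv_hat, 5 * jv_hat, 2001)
        assert loglik(jv_hat) >= loglik(grid).max() - 1e-12

    def test_degenerate_and_short_data_rejected(self):
        with pytest.raises(FitError):
            fit_mle(InductionDataset("a", (5.0, 5.0, 5.0), 1e-3))
        with pytest.raises(FitError):
            fit_mle(InductionDataset("a", (5.0,), 1e-3))

    def test_upward_bias_of_both_parameters(self, ref_params, ref_volume, rng):
        # the sample minimum can never undershoot the true growth time
        n, M = 1000, 10
        u = rng.random((n, M))
        times = ref_params.t_g - np.log1p(-u) / (ref_params.J * ref_volume)
        tg_hat = times.min(axis=1)
        J_hat = (M / (times.sum(axis=1) - M * tg_hat)) / ref_volume
        assert np.all(tg_hat >= ref_params.t_g)
        assert tg_hat.mean() > ref_params.t_g
        assert J_hat.mean() > ref_params.J


class TestDirectFit:
    def _quantile_dataset(self, params, volume, M):
        # noise-free construction: times at the i/(M+1) plotting positions
        p = np.arange(1, M + 1) / (M + 1)
        times = invert_cdf(p, params, volume)
        return InductionDataset("q", tuple(times), volume)

    def test_recovers_noise_free_quantile_data(self, ref_params, ref_volume):
        ds = self._quantile_dataset(ref_params, ref_volume, 20)
        res = fit_direct(ds, convention="i/(M+1)")
        assert res.params.J == pytest.approx(ref_params.J, rel=0.01)
        assert res.params.t_g == pytest.approx(ref_params.t_g, rel=0.01)
        assert res.fit_rmse < 1e-8

    def test_growth_time_clamps_to_lower_bound(self, ref_volume):
        truth = DistributionParams(J=1.0, t_g=1000.0)  # below the 3000 s bound
        ds = self._quantile_dataset(truth, ref_volume, 20)
        res = fit_direct(ds, convention="i/(M+1)")
        assert res.params.t_g == pytest.approx(3000.0, abs=1e-6)

    def test_params_respect_bounds(self, ref_params, ref_volume):
        ds = generate_induction_times(ref_params, ref_volume, 12, seed=3)
        res = fit_direct(ds)
        assert 0.01 <= res.params.J <= 20.0
        assert 3000.0 <= res.params.t_g <= 30_000.0

    def test_too_few_observations_rejected(self, ref_volume):
        with pytest.raises(FitError):
            fit_direct(InductionDataset("a", (5000.0,), ref_volume))

    def test_invalid_bounds_rejected(self, three_times_dataset):
        with pytest.raises(ValueError):
            fit_direct(three_times_dataset, bounds_J=(1.0, 1.0))


class TestFitQuality:
    def test_worked_residual_arithmetic(self, three_times_dataset, ref_params):
        # empirical (1/3, 2/3, 1) vs model (0, 1-e^-1, 1-e^-2)
        rmse = fit_quality(three_times_dataset, ref_params)
        assert rmse == pytest.approx(0.2087, abs=2e-4)

    def test_zero_for_matching_quantile_construction(self, ref_params, ref_volume):
        p = np.arange(1, 11) / 11
        times = invert_cdf(p, ref_params, ref_volume)
        ds = InductionDataset("q", tuple(times), ref_volume)
        assert fit_quality(ds, ref_params, convention="i/(M+1)") < 1e-10

    def test_growth_time_beyond_data_gives_mean_square_of_ranks(self):
        ds = InductionDataset("a", (100.0, 200.0, 300.0), 1e-3)
        params = DistributionParams(J=0.1, t_g=1000.0)  # model P == 0 everywhere
        _, p_emp = (ds.times_array, np.array([1 / 3, 2 / 3, 1.0]))
        assert fit_quality(ds, params) == pytest.approx(
            np.sqrt(np.mean(p_emp**2)))


class TestBootstrap:
    def test_seeded_runs_are_bit_identical(self, three_times_dataset):
        a = bootstrap_fit(three_times_dataset, n_boot=50, base="mle", seed=11)
        b = bootstrap_fit(three_times_dataset, n_boot=50, base="mle", seed=11)
        assert (a.params, a.std_J, a.std_tg, a.n_failed) == \
            (b.params, b.std_J, b.std_tg, b.n_failed)

    def test_spread_fields_and_resampled_minimum_bound(self, ref_params,
                                                       ref_volume):
        ds = generate_induction_times(ref_params, ref_volume, 15, seed=2)
        res = bootstrap_fit(ds, n_boot=200, base="mle", seed=0)
        assert res.std_J >= 0 and res.std_tg >= 0
        assert res.params.t_g <= ds.times_array.max()
        assert res.n_boot == 200

    def test_direct_base_reports_method_and_runs(self, ref_params, ref_volume):
        ds = generate_induction_times(ref_params, ref_volume, 8, seed=4)
        res = bootstrap_fit(ds, n_boot=20, base="direct", seed=0)
        assert res.method == "bootstrap"
        assert res.n_boot == 20

    def test_growth_time_spread_shrinks_with_sample_size(self, ref_params,
                                                         ref_volume):
        # Monte-Carlo: bootstrap std of t_g over replicate datasets at M=40
        # must fall below that at M=10
        stds = {}
        for M in (10, 40):
            vals = []
            for rep in range(50):
                ds = generate_induction_times(ref_params, ref_volume, M,
                                              seed=1000 * M + rep)
                vals.append(bootstrap_fit(ds, n_boot=200, base="mle",
                                          seed=rep).std_tg)
            stds[M] = np.mean(vals)
        assert stds[40] < stds[10]

    def test_bootstrap_mean_is_stable_across_independent_replications(
            self, ref_params, ref_volume):
        # two independent bootstrap runs agree within Monte-Carlo error
        ds = generate_induction_times(ref_params, ref_volume, 20, seed=9)
        a = bootstrap_fit(ds, n_boot=2000, base="mle", seed=1)
        b = bootstrap_fit(ds, n_boot=2000, base="mle", seed=2)
        tol_J = 3 * np.hypot(a.std_J, b.std_J) / np.sqrt(2000)
        tol_tg = 3 * np.hypot(a.std_tg, b.std_tg) / np.sqrt(2000)
        assert abs(a.params.J - b.params.J) < tol_J
        assert abs(a.params.t_g - b.params.t_g) < tol_tg

    def test_all_degenerate_resamples_error(self):
        ds = InductionDataset("a", (5.0, 5.0), 1e-3)
        with pytest.raises(FitError):
            bootstrap_fit(ds, n_boot=10, base="mle", seed=0)
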