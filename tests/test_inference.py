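"""Source-localization estimators."""

import numpy as np
import pytest
from scipy.stats import gumbel_l, kstest

from gradsense import (
    CountTable,
    CumulativeSignal,
    SourceSpec,
    angular_gain,
    exact_landscape,
    extreme_angle_variance,
    extreme_mean,
    extreme_params,
    ks_uniformity_pvalue,
    mle_landscape,
    polar_average,
    simulate_absorbing_circle,
    solve_static,
    splitting_probability,
    three_receptor_config,
    triangulate_source,
    uniform_config,
)
from gradsense.inference import extreme_time_mean_large_M
from gradsense.simulate import ArrivalTable

X0 = np.array([2.0, 0.0])

COARSE = dict(radii=np.geomspace(1.1, 20.0, 28),
              angles=np.linspace(-np.pi, np.pi, 72, endpoint=False))


class TestLandscapes:
    def test_exact_counts_recover_source(self, fixture_config):
        signal = CumulativeSignal(fixture_config, np.inf)
        phi = signal.q_points(X0[None, :])[0]
        counts = CountTable(np.round(phi * 1e6).astype(int), total=10**6)
        ls = mle_landscape(counts, signal, **COARSE)
        assert np.linalg.norm(ls.x_hat - X0) < 0.05

    def test_gibbs_inequality_pointwise(self, fixture_config):
        signal = CumulativeSignal(fixture_config, np.inf)
        ls = exact_landscape(X0, signal, **COARSE, refine=False)
        q0 = signal.q_points(X0[None, :])[0]
        L_at_source = -np.sum(q0 * np.log(q0))
        assert np.nanmin(ls.values) >= L_at_source - 1e-9

    def test_uniform_counts_rotationally_symmetric(self):
        # uniform counts on a symmetric cell: L is invariant under the
        # cell's rotation group (2 pi / 8 here)
        cfg = uniform_config(8, 0.1)
        signal = CumulativeSignal(cfg, np.inf)
        counts = CountTable(np.full(8, 1000), total=8000)
        ls = mle_landscape(counts, signal, **COARSE, refine=False)
        shift = ls.angles.size // 8
        np.testing.assert_allclose(ls.values,
                                   np.roll(ls.values, shift, axis=1),
                                   atol=1e-10)

    @pytest.mark.parametrize("t", [10.0, 1e3, np.inf])
    def test_contours_envelop_source(self, fixture_config, t):
        """1%-sublevel region of the cross-entropy landscape contains x0."""
        signal = CumulativeSignal(fixture_config, t)
        ls = exact_landscape(X0, signal, **COARSE, refine=False)
        mask = ls.sublevel_mask(0.01)
        i = np.argmin(np.abs(ls.radii - 2.0))
        j = np.argmin(np.abs(ls.angles - 0.0))
        assert mask[i, j]

    def test_infinite_time_equals_splitting_cross_entropy(self, fixture_config):
        signal = CumulativeSignal(fixture_config, np.inf)
        ls = exact_landscape(X0, signal, **COARSE, refine=False)
        sol = solve_static(fixture_config)
        pts = np.stack([np.outer(ls.radii, np.cos(ls.angles)),
                        np.outer(ls.radii, np.sin(ls.angles))], axis=-1)
        phi = splitting_probability(pts, sol)
        q0 = splitting_probability(X0, sol)
        direct = -np.sum(q0 * np.log(phi), axis=-1)
        np.testing.assert_allclose(ls.values, direct, atol=1e-10)

    def test_noisy_counts_cluster_near_source(self, fixture_config,
                                              table1_splitting):
        signal = CumulativeSignal(fixture_config, np.inf)
        ls = mle_landscape(table1_splitting, signal, **COARSE)
        # one M=1e4 draw localizes the source to within ~30% in distance
        assert abs(np.arctan2(ls.x_hat[1], ls.x_hat[0])) < 0.4
        assert 1.2 < np.linalg.norm(ls.x_hat) < 3.5


class TestTriangulation:
    def test_exact_fractions_unique_recovery(self, fixture_config):
        sol = solve_static(fixture_config)
        phi = splitting_probability(X0, sol)
        counts = CountTable(np.round(phi * 1e7).astype(int), total=10**7)
        x_hat = triangulate_source(counts, sol, **COARSE)
        assert np.linalg.norm(x_hat - X0) < 0.02

    def test_two_receptors_not_identifiable(self):
        from gradsense import build_config

        sol = solve_static(build_config([0.5, -0.5], [0.1, 0.1]))
        with pytest.raises(ValueError):
            triangulate_source(CountTable([5, 5], total=10), sol)

    def test_noisy_counts_near_mle(self, fixture_config, table1_splitting):
        sol = solve_static(fixture_config)
        x_tri = triangulate_source(table1_splitting, sol, **COARSE)
        signal = CumulativeSignal(fixture_config, np.inf)
        x_mle = mle_landscape(table1_splitting, signal, **COARSE).x_hat
        # both estimators answer the same least-squares/likelihood geometry
        assert np.linalg.norm(x_tri - x_mle) < 1.0


class TestPolarAverage:
    def _table(self, times, ids, config):
        n = len(times)
        return ArrivalTable(times=np.asarray(times, float),
                            angles=config.angles[np.asarray(ids)],
                            receptor_ids=np.asarray(ids, dtype=np.int64),
                            censored=np.zeros(n, bool), M=n, T_max=np.inf,
                            seed=0)

    def test_single_receptor_batches(self, fixture_config):
        tab = self._table([1, 2, 3, 4], [0, 0, 0, 0], fixture_config)
        series = polar_average(tab, 2, fixture_config)
        np.testing.assert_allclose(series.theta_pa,
                                   fixture_config.angles[0])
        assert series.complete.all()

    def test_symmetric_counts_give_central_angle(self):
        cfg = uniform_config(8, 0.1)
        # equal counts on receptors flanking receptor 0 (angles 0, pi/4,
        # pi/2): the circular mean is receptor 0's angle pi/4
        ids = [7, 0, 1, 7, 0, 1]
        tab = self._table(np.arange(6), ids, cfg)
        series = polar_average(tab, 6, cfg)
        assert series.theta_pa[0] == pytest.approx(cfg.angles[0], abs=1e-12)

    def test_partial_final_batch_flagged(self, fixture_config):
        tab = self._table([1, 2, 3], [0, 1, 2], fixture_config)
        series = polar_average(tab, 2, fixture_config)
        assert series.complete.tolist() == [True, False]

    def test_early_batches_directional_late_batches_not(self):
        """Half-covered cell: early polar averages point at the source."""
        from gradsense import simulate_arrivals

        cfg = uniform_config(100, np.pi / 100)
        src = SourceSpec(R=5.0, theta0=0.0)
        tab = simulate_arrivals(4_000, cfg, src, T_max=2e4, seed=77)
        series = polar_average(tab, 501, cfg)
        assert abs(series.theta_pa[0]) < 0.25
        early = ks_uniformity_pvalue(
            cfg.angles[tab.sorted_by_time().receptor_ids[
                ~tab.sorted_by_time().censored][:501]])
        assert early < 0.05  # early arrivals are decidedly non-uniform


class TestKSUniformity:
    def test_null_calibration(self, rng):
        ps = []
        for _ in range(100):
            ps.append(ks_uniformity_pvalue(rng.uniform(-np.pi, np.pi, 200)))
        ps = np.array(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.05).mean() < 0.15

    def test_point_mass_rejected(self):
        assert ks_uniformity_pvalue(np.full(100, 0.3)) < 1e-10

    def test_asymptotic_matches_resampling_oracle(self, rng):
        """Asymptotic p within 0.02 of a brute-force resampling p at n=1001."""
        n = 1001
        sample = rng.uniform(-np.pi, np.pi, n) * 0.97  # mildly non-uniform
        p_asym = ks_uniformity_pvalue(sample)
        from scipy.stats import kstest

        stat = kstest(sample, "uniform", args=(-np.pi, 2 * np.pi)).statistic
        null = np.empty(10_000)
        for i in range(10_000):
            null[i] = kstest(rng.uniform(0, 1, n), "uniform").statistic
        p_resample = np.mean(null >= stat)
        assert abs(p_asym - p_resample) < 0.02


class TestExtremeStatistics:
    def test_short_time_constants(self):
        p = extreme_params(10**6, 2.0, 206.98)
        assert p.B == pytest.approx(0.25)
        assert p.q == 1.5
        assert p.A == pytest.approx(
            4 * 206.98 * np.sqrt(1 / (2 * np.pi)), rel=1e-12)

    def test_monotonicity_in_M(self):
        ws, bs = [], []
        for M in (10**2, 10**4, 10**6, 10**8):
            p = extreme_params(M, 2.0, 206.98)
            ws.append(p.W_M)
            bs.append(p.b_M)
        assert np.all(np.diff(ws) > 0)
        assert np.all(np.diff(bs) < 0)

    def test_mean_variance_forms(self):
        p = extreme_params(10**6, 2.0, 206.98)
        mean, var = extreme_mean(p)
        assert mean == pytest.approx(p.b_M - 0.5772156649 * p.a_M, rel=1e-9)
        assert var == pytest.approx(np.pi**2 * p.a_M**2 / 6, rel=1e-12)
        assert extreme_time_mean_large_M(p) == pytest.approx(mean, rel=1e-9)

    def test_angle_variance_identities(self):
        # Robin cell: sigma^2 = g(R)/W_M with g(R) = (R-1)^2/(3R)
        M, R, kap = 10**6, 2.0, 206.98
        p = extreme_params(M, R, kap)
        assert extreme_angle_variance(M, R, kap) == \
            pytest.approx(angular_gain(R) / p.W_M, rel=1e-12)
        assert angular_gain(1.0) == 0.0
        vars_ = [extreme_angle_variance(M, R, kap)
                 for M in (10**3, 10**5, 10**7)]
        assert np.all(np.diff(vars_) < 0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            extreme_params(1, 2.0, 1.0)
        with pytest.raises(ValueError):
            extreme_params(100, 0.9, 1.0)
        with pytest.raises(ValueError):
            extreme_params(100, 2.0, -1.0)

    def test_simulated_minima_follow_gumbel(self):
        """First-arrival minima over M walkers pass a 5% KS test."""
        M, reps = 10_000, 100
        src = SourceSpec(R=2.0)
        p = extreme_params(M, 2.0, np.inf)
        horizon = p.b_M + 25 * p.a_M
        tab = simulate_absorbing_circle(M * reps, src, T_max=horizon,
                                        seed=42, max_dt=horizon / 150)
        tt = np.where(tab.censored, np.inf, tab.times).reshape(reps, M)
        tmin = tt.min(axis=1)
        assert np.all(np.isfinite(tmin))
        res = kstest(tmin, gumbel_l(loc=p.b_M, scale=p.a_M).cdf)
        assert res.pvalue > 0.05
        mean, var = extreme_mean(p)
        assert abs(tmin.mean() - mean) < 3 * np.sqrt(var / reps) + 0.1 * mean

    def test_first_arrival_angle_variance(self, first_arrival_angles):
        """Angle variance of 1000 simulated first arrivals within 20%."""
        angles = first_arrival_angles
        assert np.all(np.isfinite(angles))
        theory = extreme_angle_variance(10_000, 2.0, np.inf)
        assert abs(np.var(angles) - theory) < 0.2 * theory

    def test_first_arrival_angles_nearly_gaussian(self, first_arrival_angles):
        """Kurtosis of first-arrival angles consistent with normality."""
        from scipy.stats import kurtosis

        assert 2.5 < kurtosis(first_arrival_angles, fisher=False) < 3.5
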