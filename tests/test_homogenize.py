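"""Homogenized Robin-surface model: permeability, modes, moments."""

import numpy as np
import pytest
from scipy.special import kv

from gradsense import (
    HomogenizedModel,
    capture_cdf,
    gaussian_approx,
    homogenized_flux_density,
    homogenized_permeability,
    mode_ratio,
    robin_flux_mode,
    short_time_moments,
    survival,
    talbot_invert,
)
from gradsense.homogenize import _chi_modes


class TestPermeability:
    def test_half_coverage_reference(self):
        # N=100 equally spaced receptors covering half the unit circle
        assert homogenized_permeability(100, np.pi / 100, 1.0) == \
            pytest.approx(206.98, abs=0.005)

    def test_log_argument_minus_one(self):
        # eps*N = 4/e makes the log term -1: kappa = N*D/2
        n, d = 50, 2.0
        assert homogenized_permeability(n, 4.0 / np.e / n, d) == \
            pytest.approx(n * d / 2.0, rel=1e-12)

    def test_perfect_absorption_limit(self):
        vals = [homogenized_permeability(100, eps) for eps in
                (0.01, 0.02, 0.039, 0.03999)]
        assert np.all(np.diff(vals) > 0) and vals[-1] > 1e3

    def test_overcovered_surface_rejected(self):
        with pytest.raises(ValueError):
            homogenized_permeability(100, 0.04)
        with pytest.raises(ValueError):
            homogenized_permeability(0, 0.01)


class TestFluxModes:
    def test_immediate_capture_limit(self):
        # source on the membrane of a perfect absorber: chi_m = 1
        model = HomogenizedModel(kappa=np.inf, R=1.0 + 1e-12)
        for m in (0, 1, 5):
            assert robin_flux_mode(m, 2.0 + 1.0j, model) == \
                pytest.approx(1.0, abs=1e-9)

    def test_certain_eventual_capture_trend(self):
        # chi_0 -> 1 as alpha -> 0 (logarithmically slowly)
        model = HomogenizedModel(kappa=206.98, R=2.0)
        vals = [robin_flux_mode(0, a, model).real for a in
                (1e-2, 1e-4, 1e-8, 1e-12)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0.9

    def test_dirichlet_mode_value(self):
        model = HomogenizedModel(kappa=np.inf, R=2.0)
        assert robin_flux_mode(0, 1.0, model) == \
            pytest.approx(0.2705160613, abs=1e-9)
        # independent check through scipy at a second argument
        assert robin_flux_mode(0, 2.0, model).real == \
            pytest.approx(float(kv(0, 4.0) / kv(0, 2.0)), rel=1e-12)

    def test_scaled_evaluation_no_overflow(self):
        model = HomogenizedModel(kappa=206.98, R=20.0)
        val = robin_flux_mode(0, 400.0, model)
        assert np.isfinite(val.real) and abs(val) < 1.0


class TestSurvival:
    MODEL = HomogenizedModel(kappa=206.98, R=5.0, D=1.0)

    def test_capture_cdf_monotone(self):
        ts = np.geomspace(1.0, 1e5, 9)
        cdf = np.array([capture_cdf(t, self.MODEL) for t in ts])
        assert np.all(np.diff(cdf) > 0)
        assert cdf[0] > -1e-9 and cdf[-1] < 1.0

    def test_survival_complements_capture(self):
        t = 100.0
        assert survival(t, self.MODEL) == \
            pytest.approx(1.0 - capture_cdf(t, self.MODEL), abs=1e-12)

    def test_survival_at_transition_time(self):
        # ~60% captured / ~40% free at t = 1e3 (validated against both an
        # eps-exact collocation solve and brute-force Monte Carlo)
        assert survival(1e3, self.MODEL) == pytest.approx(0.4045, abs=0.005)


class TestFluxDensity:
    MODEL = HomogenizedModel(kappa=206.98, R=2.0, D=1.0)

    def test_angular_integral_equals_total_flux(self):
        t = 0.1
        theta = np.linspace(-np.pi, np.pi, 4001)
        J = homogenized_flux_density(theta, t, self.MODEL)
        total = np.trapezoid(J[:, 0], theta)
        m0 = talbot_invert(
            lambda s: _chi_modes(np.sqrt(s / self.MODEL.D), self.MODEL, 0)[0],
            t,
        )
        assert total == pytest.approx(m0, rel=1e-6)

    def test_density_peaks_at_source_direction(self):
        theta = np.linspace(-np.pi, np.pi, 721)
        J = homogenized_flux_density(theta, 0.05, self.MODEL)[:, 0]
        assert theta[np.argmax(J)] == pytest.approx(0.0, abs=0.01)

    def test_gaussian_vs_full_series_total_variation(self):
        """The angular profile tends to the Gaussian as t -> 0+."""
        theta = np.linspace(-np.pi, np.pi, 2001)
        tvs = []
        for t in (0.2, 0.1, 0.05):
            J = homogenized_flux_density(theta, t, self.MODEL)[:, 0]
            G = gaussian_approx(theta, t, self.MODEL)
            total = np.trapezoid(J, theta)
            tvs.append(0.5 * np.trapezoid(np.abs(J - G), theta) / total)
        assert np.all(np.diff(tvs) < 0)
        assert tvs[-1] < 0.05


class TestModeRatio:
    def test_directional_information_decays(self):
        model = HomogenizedModel(kappa=206.98, R=5.0, D=1.0)
        ts = np.geomspace(1e2, 1e4, 7)
        ratios = np.array([mode_ratio(t, model) for t in ts])
        assert np.all(np.diff(np.abs(ratios)) < 0)
        assert abs(ratios[-1]) < 0.01

    def test_fully_directional_near_membrane(self):
        # source grazing a perfect absorber at short time: ratio -> 1-
        model = HomogenizedModel(kappa=np.inf, R=1.01, D=1.0)
        r = mode_ratio(2e-4, model)
        assert 0.9 < r < 1.0


class TestShortTimeMoments:
    MODEL = HomogenizedModel(kappa=206.98, R=2.0, D=1.0)

    def test_gaussian_moments(self):
        st = short_time_moments(1e-3, self.MODEL)
        assert st.variance == pytest.approx(2.0 * 1e-3 / 2.0, rel=1e-12)
        assert st.kurtosis == 3.0

    @pytest.mark.parametrize("t", [4e-3, 1e-2, 2e-2])
    def test_total_flux_matches_inversion(self, t):
        """Closed-form M0 vs Talbot inversion of chi_0 within 5%."""
        m0 = short_time_moments(t, self.MODEL).M0
        ilt = talbot_invert(
            lambda s: _chi_modes(np.sqrt(s / self.MODEL.D), self.MODEL, 0)[0],
            t,
        )
        assert m0 == pytest.approx(ilt, rel=0.05)

    def test_gaussian_normalization(self):
        t = 1e-3
        theta = np.linspace(-np.pi, np.pi, 200_001)
        g = gaussian_approx(theta, t, self.MODEL)
        assert np.trapezoid(g, theta) == pytest.approx(
            short_time_moments(t, self.MODEL).M0, rel=1e-6)

    def test_regime_warning(self):
        with pytest.warns(RuntimeWarning):
            short_time_moments(2.0, self.MODEL)


class TestDiscreteToRobinConvergence:
    def test_fourier_coefficients_converge_to_robin_modes(self):
        """Discrete receptor fluxes homogenize: chi-bar_q -> chi_q as N grows.

        Uniform cells with fixed coverage eps*N; the discrete Fourier
        coefficients of the strength vector approach the Robin-mode values
        and the sine (asymmetric) parts vanish.
        """
        from gradsense import SourceSpec, solve_strengths, uniform_config

        eps_n = np.pi / 2.0  # quarter coverage
        R, D, s = 2.0, 1.0, 1.0
        src = SourceSpec(R=R, theta0=0.3, D=D)
        kappa = None
        errs = {0: [], 1: [], 2: []}
        sines = []
        for N in (16, 32, 64, 128):
            eps = eps_n / N
            cfg = uniform_config(N, eps)
            kappa = homogenized_permeability(N, eps, D)
            model = HomogenizedModel(kappa=kappa, R=R, D=D)
            chi = _chi_modes(np.sqrt(s / D), model, 2)
            A = solve_strengths(s, cfg, src)
            nu = cfg.nu[0]
            for q in (0, 1, 2):
                cbar = np.pi * D * nu * np.sum(
                    A * np.cos(q * (cfg.angles - src.theta0)))
                errs[q].append(abs(cbar - chi[q]))
            sbar = np.pi * D * nu * np.sum(
                A * np.sin(1 * (cfg.angles - src.theta0)))
            sines.append(abs(sbar))
        for q in (0, 1, 2):
            assert errs[q][-1] < errs[q][0]
            assert errs[q][-1] < 0.02
        assert sines[-1] < 1e-10  # symmetric configuration: no sine part
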