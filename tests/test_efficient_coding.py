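"""Analytic channel gains, mutual information, and the 2-D filter optimum."""

import numpy as np
import pytest

from glidertex import efficient_coding as ec


class TestAnalyticGain:
    def test_critical_point_zero_gain(self):
        # s^2 = Lambda/(1-Lambda) = 1 at Lambda = 0.5
        sol = ec.analytic_gain(1.0, 0.5)
        assert sol.gain == 0.0
        assert not sol.encoded

    def test_direct_evaluation(self):
        sol = ec.analytic_gain(2.0, 0.5)
        assert sol.gain**2 == pytest.approx((-6 + np.sqrt(48)) / 10)
        assert sol.gain == pytest.approx(0.3047, abs=2e-4)
        assert sol.encoded

    def test_encoding_condition_is_square_law(self):
        # the gain vanishes exactly when s^2 <= Lambda/(1-Lambda)
        Lam = 0.3
        s_crit = np.sqrt(Lam / (1 - Lam))
        assert not ec.analytic_gain(s_crit * 0.999, Lam).encoded
        assert ec.analytic_gain(s_crit * 1.001, Lam).encoded

    def test_continuous_at_threshold(self):
        Lam = 0.4
        s_crit = np.sqrt(Lam / (1 - Lam))
        assert ec.analytic_gain(s_crit * 1.0001, Lam).gain < 0.02

    def test_large_signal_whitening_asymptote(self):
        # |L|^2 -> (1/Lambda - 1)/(1 + s^2) for s -> infinity
        Lam, s = 0.9, 100.0
        expected = (1 / Lam - 1) / (1 + s**2)
        assert ec.analytic_gain(s, Lam).gain ** 2 == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize(
        "Lam,lo,hi,slope",
        [(1e-6, 1e-2, 1e-1, 0.5), (0.99, 1e2, 1e4, -1.0)],
        ids=["sampling-limited sqrt law", "whitening inverse law"],
    )
    def test_loglog_gain_slopes(self, Lam, lo, hi, slope):
        s = np.logspace(np.log10(lo), np.log10(hi), 50)
        gain = np.array([ec.analytic_gain(x, Lam).gain for x in s])
        fitted = np.polyfit(np.log(s), np.log(gain), 1)[0]
        assert abs(fitted - slope) < 0.02

    def test_invalid_lambda(self):
        for Lam in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                ec.analytic_gain(1.0, Lam)


class TestMutualInfo:
    def test_zero_filter_zero_info(self):
        assert ec.mutual_info(np.zeros((2, 2)), np.diag([0.3, 0.7]), 1.0, 0.1) == 0.0

    def test_diagonal_closed_form(self):
        L, S = np.diag([0.5, 1.2]), np.diag([0.3, 0.7])
        Xi, Sig = 1.0, 0.1
        expected = sum(
            0.5 * np.log(1 + S[k, k] * L[k, k] ** 2 / (Sig + Xi * L[k, k] ** 2))
            for k in range(2)
        )
        assert ec.mutual_info(L, S, Xi, Sig) == pytest.approx(expected, abs=1e-10)

    def test_rotation_invariance(self, rng):
        L = rng.standard_normal((2, 2))
        S = ec.random_signal_covariance(rng)
        th = 0.61
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert ec.mutual_info(L, S, 0.8, 0.2) == pytest.approx(
            ec.mutual_info(L @ R.T, R @ S @ R.T, 0.8, 0.2), abs=1e-12
        )

    def test_singular_noise_rejected(self):
        with pytest.raises(ValueError):
            ec.mutual_info(np.zeros((2, 2)), np.eye(2), 1.0, 0.0)


class TestOptimizeFilter:
    def test_infeasible_above_half(self):
        S = np.diag([0.6, 0.4])
        with pytest.raises(ec.InfeasibleError):
            ec.optimize_filter(S, 1.0, 0.6)
        with pytest.raises(ec.InfeasibleError):
            ec.optimize_filter(S, 1.0, 0.5)

    def test_power_constraint_active(self, rng):
        S = ec.random_signal_covariance(rng)
        opt = ec.optimize_filter(S, 0.5, 0.1, seed=2, n_restarts=4)
        assert ec.output_power(opt.L, opt.S, 0.5, 0.1) == pytest.approx(1.0, abs=1e-8)

    def test_whitening_regime_antialigned(self, rng):
        """Xi=0, Sigma=0.2: the filter tilt is offset by pi/2 from the signal
        and the eccentricities match."""
        S = ec.random_signal_covariance(rng)
        opt = ec.optimize_filter(S, 0.0, 0.2, seed=0, n_restarts=6)
        assert opt.alignment == "antialigned"
        offset = ec._tilt_distance(opt.filter_tilt, opt.signal_tilt)
        assert abs(offset - np.pi / 2) < np.radians(2)
        assert abs(opt.filter_ecc - opt.signal_ecc) < 0.02

    def test_sampling_regime_aligned(self, rng):
        """Xi=4, Sigma=0: the filter tilt matches the signal tilt."""
        S = ec.random_signal_covariance(rng)
        opt = ec.optimize_filter(S, 4.0, 0.0, seed=0, n_restarts=6)
        assert opt.alignment == "aligned"
        assert ec._tilt_distance(opt.filter_tilt, opt.signal_tilt) < np.radians(2)

    def test_matches_analytic_gains_in_diagonal_case(self):
        """Oracle equivalence: with a diagonal signal and unit sampling noise
        the numerical optimum reproduces the water-filling gains of the
        analytic formula (same implied Lambda on both channels)."""
        S = np.diag([0.3, 0.7])
        Sigma = 0.1
        opt = ec.optimize_filter(S, 1.0, Sigma, seed=1, n_restarts=6)
        LLt = opt.L @ opt.L.T
        assert abs(LLt[0, 1]) < 1e-6  # optimum is diagonal
        g = np.diag(LLt) / Sigma  # gains in unit-channel-noise units
        s = np.sqrt(np.diag(S))
        implied = [
            4 * sk**2 / ((2 * gk * (1 + sk**2) + 2 + sk**2) ** 2 - sk**4)
            for sk, gk in zip(s, g)
        ]
        assert implied[0] == pytest.approx(implied[1], rel=1e-4)
        for sk, gk in zip(s, g):
            analytic = ec.analytic_gain(sk, float(np.mean(implied))).gain ** 2
            assert gk == pytest.approx(analytic, rel=0.01)

    def test_isotropic_signal_flagged_degenerate(self):
        opt = ec.optimize_filter(0.5 * np.eye(2), 1.0, 0.1, seed=0, n_restarts=2)
        assert opt.alignment == "degenerate"


class TestRegimes:
    def test_regime_map_extremes(self):
        table = ec.regime_map([0.15, 0.35], [0.15, 0.35], n_signals=12, seed=0,
                              n_restarts=3)
        low = table[table.total_noise == 0.3].frac_aligned.iloc[0]
        high = table[table.total_noise == 0.7].frac_aligned.iloc[0]
        assert low < 0.1
        assert high > 0.9

    def test_transition_near_half(self):
        t = ec.alignment_transition(n_signals=16, seed=0, n_restarts=3)
        assert abs(t - 0.5) < 0.05
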