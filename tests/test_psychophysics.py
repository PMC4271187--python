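"""Session designs, Weibull psychometrics, sensitivity pooling, ellipsoids."""

import numpy as np
import pandas as pd
import pytest

from glidertex import psychophysics as pp
from glidertex import synthetic_data as sd


class TestDesignSession:
    def test_printed_totals(self):
        cfg = pp.SessionConfig()
        assert cfg.trials_per_block == 288
        design = pp.design_session("beta_h:beta_v", cfg, seed=0)
        assert len(design) == 288 * 15 == 4320

    def test_full_study_total(self):
        # 11 planes at the default composition reproduce 47,520 trials
        assert 11 * pp.SessionConfig().trials_per_block * 15 == 47_520

    def test_eight_rays_and_balance(self):
        design = pp.design_session("beta_d1:alpha", seed=1)
        assert set(design["ray"]) == set(pp.RAYS)
        by_loc = design.groupby("target_loc").size()
        assert by_loc.nunique() == 1
        by_type = design.groupby("trial_type").size()
        assert by_type.nunique() == 1

    def test_unbalanced_config_rejected(self):
        with pytest.raises(ValueError):
            pp.design_session("beta_h:alpha", pp.SessionConfig(on_axis_reps=6))

    def test_zero_blocks_warns_empty(self):
        with pytest.warns(UserWarning):
            design = pp.design_session("beta_h:alpha", pp.SessionConfig(blocks=0))
        assert design.empty


class TestWeibullFunction:
    @pytest.mark.parametrize("a,b", [(0.3, 2.5), (1.2, 1.0), (0.05, 4.0)])
    def test_criterion_and_chance(self, a, b):
        assert pp.weibull_fc(a, a, b) == pytest.approx(0.625)
        assert pp.weibull_fc(0.0, a, b) == pytest.approx(0.25)

    def test_monotone_and_bounded(self):
        x = np.linspace(0, 5, 200)
        fc = pp.weibull_fc(x, 0.5, 2.2)
        assert np.all(np.diff(fc) >= 0)
        assert np.all((fc >= 0.25) & (fc <= 1.0))
        assert fc[x < 2 * 0.5].max() < 1.0  # strictly below 1 near threshold


@pytest.fixture(scope="module")
def simulated_plane():
    """One plane at the full standard trial count from a known observer."""
    s_true = np.array([6, 6, 3, 3, 1.2, 1.2, 1.2, 1.2, 2.5], float)
    Q = np.diag(s_true**2)
    model = sd.ObserverModel(Q, b=2.5)
    design = pp.design_session("beta_h:alpha", seed=7)
    trials = sd.simulate_observer(design, model, seed=8)
    return trials, Q, model


class TestFitWeibull:
    def test_parameter_recovery(self, simulated_plane):
        trials, Q, model = simulated_plane
        fit = pp.fit_weibull(trials)
        assert abs(fit.shared_b - model.b) / model.b < 0.15
        for ray in pp.RAYS:
            u = pp.ray_direction("beta_h:alpha", ray)
            a_true = 1.0 / np.sqrt(u @ Q @ u)
            assert abs(fit.thresholds[ray] - a_true) / a_true < 0.10

    def test_boundary_ray_flagged(self, simulated_plane):
        trials, _, _ = simulated_plane
        forced = trials.copy()
        forced.loc[forced["ray"] == "+x", "correct"] = True
        fit = pp.fit_weibull(forced)
        assert fit.boundary.get("+x") == "all_correct"
        assert "+x" not in fit.thresholds


class TestPoolSensitivities:
    @staticmethod
    def make_fit(plane, thresholds):
        return pp.WeibullFit(plane, thresholds, 2.5, {}, {}, {})

    FILLERS = [
        ("beta_h:beta_d1", {"+x": 1, "-x": 1, "+y": 1, "-y": 1}),
        ("beta_d2:theta_tl", {"+x": 1, "-x": 1, "+y": 1, "-y": 1}),
        ("theta_tr:theta_br", {"+x": 1, "-x": 1, "+y": 1, "-y": 1}),
        ("beta_h:theta_bl", {"+x": 1, "-x": 1, "+y": 1, "-y": 1}),
    ]

    def fillers(self):
        return [self.make_fit(p, dict(t)) for p, t in self.FILLERS]

    def test_single_plane_mean_over_signs(self):
        fit = self.make_fit(
            "beta_v:alpha", {"+x": 0.5, "-x": 0.5, "+y": 0.4, "-y": 0.4}
        )
        s = pp.pool_sensitivities([fit] + self.fillers())
        assert s[0] == pytest.approx(2.0)  # beta_v: 1/0.5 both signs
        assert s[8] == pytest.approx(2.5)  # alpha: 1/0.4

    def test_mean_across_planes(self):
        f1 = self.make_fit("beta_v:alpha", {"+x": 0.5, "-x": 0.5, "+y": 1, "-y": 1})
        f2 = self.make_fit(
            "beta_v:beta_h", {"+x": 1 / 3, "-x": 1 / 3, "+y": 1, "-y": 1}
        )
        with pytest.raises(ValueError):
            pp.pool_sensitivities([f1])  # coverage error: most coords unmeasured
        s = pp.pool_sensitivities([f1, f2] + self.fillers())
        assert s[0] == pytest.approx(2.5)  # beta_v: mean of 2 and 3

    def test_rotational_pooling_shares_values(self):
        fits = [
            self.make_fit("beta_v:beta_h", {"+x": 0.5, "-x": 0.5, "+y": 0.25, "-y": 0.25}),
            self.make_fit("beta_d1:beta_d2", {"+x": 1, "-x": 1, "+y": 0.5, "-y": 0.5}),
            self.make_fit("theta_tl:theta_br", {"+x": 1, "-x": 1, "+y": 0.8, "-y": 0.8}),
            self.make_fit("theta_tr:theta_bl", {"+x": 1, "-x": 1, "+y": 0.8, "-y": 0.8}),
            self.make_fit("beta_h:alpha", {"+x": 0.25, "-x": 0.25, "+y": 0.4, "-y": 0.4}),
        ]
        s = pp.pool_sensitivities(fits, pool_rotations=True)
        assert s[0] == s[1]
        assert s[2] == s[3]
        assert len(set(s[4:8])) == 1


class TestFitEllipsoid:
    def test_unit_circle_gives_identity_block(self):
        angles = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.zeros((8, 9))
        pts[:, 0] = np.cos(angles)
        pts[:, 1] = np.sin(angles)
        ell = pp.fit_ellipsoid(pts)
        assert ell.Q[:2, :2] == pytest.approx(np.eye(2), abs=1e-10)
        assert ell.rms_residual == pytest.approx(0.0, abs=1e-10)

    def test_exact_axis_ratio(self):
        # points on x^2/4 + y^2 = 1
        angles = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.zeros((8, 9))
        pts[:, 3] = 2 * np.cos(angles)
        pts[:, 8] = np.sin(angles)
        ell = pp.fit_ellipsoid(pts)
        assert ell.Q[3, 3] == pytest.approx(0.25)
        assert ell.Q[8, 8] == pytest.approx(1.0)
        assert ell.Q[3, 8] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        pts = rng.normal(0.3, 0.05, size=(40, 9))
        perm = rng.permutation(9)
        q1 = pp.fit_ellipsoid(pts).Q
        q2 = pp.fit_ellipsoid(pts[:, perm]).Q
        assert q2 == pytest.approx(q1[np.ix_(perm, perm)], abs=1e-8)
        # point order is irrelevant
        q3 = pp.fit_ellipsoid(pts[::-1]).Q
        assert q3 == pytest.approx(q1)

    def test_end_to_end_contour_recovery(self, simulated_plane):
        """design -> simulate -> fit_weibull -> fit_ellipsoid recovers the
        generating plane contour's tilt and eccentricity."""
        from glidertex.ensemble_analysis import plane_contour

        trials, Q, _ = simulated_plane
        fit = pp.fit_weibull(trials)
        pts = pp.criterion_points([fit])
        ell = pp.fit_ellipsoid(pts)
        idx = [pp.COORD_NAMES_9.index("beta_h"), pp.COORD_NAMES_9.index("alpha")]
        truth = plane_contour(Q[np.ix_(idx, idx)])
        est = plane_contour(ell.Q[np.ix_(idx, idx)])
        assert abs(est.eccentricity - truth.eccentricity) < 0.05
        d = abs(est.tilt - truth.tilt) % np.pi
        assert min(d, np.pi - d) < np.radians(5)
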