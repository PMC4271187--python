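"""Texture rollout, noise, coordinate ensembles, and the simulated observer."""

import numpy as np
import pytest

from glidertex import glider_stats as gs
from glidertex import psychophysics as pp
from glidertex import synthetic_data as sd


def measure(patches):
    coords = np.stack(
        [gs.coords_from_histogram(gs.count_colorings(p)) for p in patches]
    )
    mean = coords.mean(axis=0)
    se = coords.std(axis=0, ddof=1) / np.sqrt(len(patches)) + 1e-12
    return mean, se


class TestGenTexture:
    def test_zero_coords_fair_coin(self):
        patches = sd.gen_texture_ensemble(np.zeros(10), 64, 100, seed=0)
        mean, se = measure(patches)
        assert np.all(np.abs(mean) < 5 * se)

    @pytest.mark.parametrize(
        "name,value",
        [
            ("beta_h", 0.45),
            ("beta_v", -0.45),
            ("beta_d1", 0.75),
            ("beta_d2", -0.75),
            ("theta_br", 0.8),
            ("alpha", 0.85),
            ("alpha", -0.85),
        ],
    )
    def test_single_coordinate_gamut_closure(self, name, value):
        """Generator and extractor close the loop on the stimulus gamuts:
        the measured coordinate sits within 3 SE of the prescription and all
        others stay consistent with their implied values."""
        v = sd.maxent_texture_coords(name, value)
        patches = sd.gen_texture_ensemble(v, 64, 200, seed=17)
        mean, se = measure(patches)
        k = gs.COORD_NAMES.index(name)
        assert abs(mean[k] - value) < 3 * se[k]
        others = [i for i in range(1, 10) if i != k]
        assert np.all(np.abs(mean[others] - v[others]) < 5 * se[others])

    def test_high_beta_includes_induced_alpha(self):
        v = sd.maxent_texture_coords("beta_h", 0.8)
        patches = sd.gen_texture_ensemble(v, 64, 200, seed=3)
        mean, se = measure(patches)
        assert abs(mean[2] - 0.8) < 3 * se[2]
        assert abs(mean[9] - 0.64) < 3 * se[9]

    def test_infeasible_coordinates_propagate(self):
        v = sd.coords_by_name(beta_h=0.8)  # literal zeros elsewhere: infeasible
        with pytest.raises(gs.InfeasibleCoordinatesError):
            sd.gen_texture(v, 16, seed=0)

    def test_reproducible(self):
        a = sd.gen_texture(sd.coords_by_name(alpha=0.5), 32, seed=9)
        b = sd.gen_texture(sd.coords_by_name(alpha=0.5), 32, seed=9)
        assert np.array_equal(a, b)


class TestWhiteNoise:
    def test_flat_statistics(self):
        patches = sd.gen_white_noise(32, 150, seed=1)
        mean, se = measure(patches)
        assert np.all(np.abs(mean) < 5 * se)
        coords = np.stack(
            [gs.coords_from_histogram(gs.count_colorings(p)) for p in patches]
        )
        stds = coords.std(axis=0)[1:]
        assert stds.max() / stds.min() < 1.8  # flat across the nine coordinates

    def test_seed_reproducibility(self):
        a = sd.gen_white_noise(16, 3, seed=5)
        b = sd.gen_white_noise(16, 3, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestCoordinateEnsemble:
    def test_covariance_recovery(self, correlated_cov):
        spec = {"means": [np.zeros(9)], "covariances": [0.01 * correlated_cov]}
        X = sd.gen_coordinate_ensemble(spec, 50_000, seed=2)
        cov = np.cov(X.T, ddof=0)
        err = np.linalg.norm(cov - 0.01 * correlated_cov) / np.linalg.norm(
            0.01 * correlated_cov
        )
        assert err < 0.02

    def test_skew_inflates_ratio(self):
        from glidertex.ensemble_analysis import summarize

        spec = {
            "means": [np.zeros(9)],
            "covariances": [0.04 * np.eye(9)],
            "skew": {8: 2.0},
        }
        X = sd.gen_coordinate_ensemble(spec, 20_000, seed=3)
        s = summarize(X)
        assert s.pos_neg_std_ratio[8] > 1.5
        assert abs(s.pos_neg_std_ratio[0] - 1) < 0.1

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            sd.gen_coordinate_ensemble(
                {"means": [np.zeros(9)], "covariances": [np.eye(9)],
                 "weights": [0.5]},
                10, seed=0,
            )
        with pytest.raises(ValueError):
            sd.gen_coordinate_ensemble(
                {"means": [np.zeros(2)], "covariances": [-np.eye(2)]}, 10, seed=0
            )


class TestObserver:
    def test_probabilities(self):
        model = sd.ObserverModel(np.eye(9), b=2.0)
        assert model.p_correct(np.zeros(9)) == pytest.approx(0.25)
        unit = np.zeros(9)
        unit[0] = 1.0  # c^T Q c = 1: criterion performance
        assert model.p_correct(unit) == pytest.approx(0.625)
        assert model.p_correct(100 * unit) == pytest.approx(1.0)

    def test_simulated_fraction_correct(self):
        """Empirical fraction correct at criterion magnitude approaches 0.625."""
        model = sd.ObserverModel(4.0 * np.eye(9), b=2.5)  # thresholds 0.5
        design = pp.design_session(
            "theta_tl:theta_tr",
            pp.SessionConfig(blocks=10),
            seed=4,
        )
        trials = sd.simulate_observer(design, model, seed=5)
        on_axis = trials[(trials.ray == "+x") & np.isclose(trials.magnitude, 0.6)]
        fc = on_axis["correct"].mean()
        expected = pp.weibull_fc(0.6, 0.5, 2.5)
        assert abs(fc - expected) < 3 * np.sqrt(expected * (1 - expected) / len(on_axis))

    def test_wrong_responses_not_target(self):
        model = sd.ObserverModel(np.eye(9), b=2.0)
        design = pp.design_session("beta_h:alpha", pp.SessionConfig(blocks=1), seed=6)
        trials = sd.simulate_observer(design, model, seed=7)
        wrong = trials[~trials["correct"].astype(bool)]
        assert (wrong["response_loc"] != wrong["target_loc"]).all()
        right = trials[trials["correct"].astype(bool)]
        assert (right["response_loc"] == right["target_loc"]).all()
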