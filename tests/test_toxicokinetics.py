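"""One-compartment model: closed forms, fitting, BCFs, plateau detection,
bootstrap uncertainty."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from sklearn.base import clone

import bcfkit as bk
from bcfkit.exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedPlateauError,
)
from bcfkit.toxicokinetics import FirstOrderUptakeModel
from conftest import make_series


def ode_uptake(k1, k2, cw, t_eval):
    """Independent oracle: numerical integration of dCf/dt = k1 Cw - k2 Cf."""
    sol = solve_ivp(lambda s, c: k1 * cw - k2 * c, (0.0, float(np.max(t_eval))),
                    [0.0], t_eval=np.atleast_1d(t_eval), rtol=1e-10, atol=1e-12)
    return sol.y[0]


class TestClosedForms:
    def test_uptake_zero_at_start(self):
        assert bk.predict_uptake(10.0, 0.05, 80.0, 0.0) == 0.0

    def test_uptake_plateau(self):
        # plateau = (k1/k2) * cw
        assert bk.predict_uptake(10.0, 0.05, 80.0, 1e6) == pytest.approx(16000.0)

    def test_uptake_against_ode_integration(self):
        t = np.array([6.0, 24.0, 45.0, 48.0])
        expected = ode_uptake(10.0, 0.05, 80.0, t)
        assert bk.predict_uptake(10.0, 0.05, 80.0, t) == pytest.approx(
            expected, rel=1e-3)
        assert bk.predict_uptake(10.0, 0.05, 80.0, 48.0) == pytest.approx(
            14548.8, rel=1e-4)

    def test_uptake_k2_zero_limit_is_linear(self):
        assert bk.predict_uptake(2.0, 0.0, 80.0, 10.0) == pytest.approx(1600.0)

    @given(k1=st.floats(0.01, 50), k2=st.floats(1e-4, 1.0),
           cw=st.floats(1, 500), t=st.floats(0, 96))
    def test_uptake_monotone_in_k1_and_cw(self, k1, k2, cw, t):
        base = bk.predict_uptake(k1, k2, cw, t)
        assert bk.predict_uptake(k1 * 1.5, k2, cw, t) >= base
        assert bk.predict_uptake(k1, k2, cw * 1.5, t) >= base

    @pytest.mark.parametrize("cf0, k2, t, expected", [
        (500.0, 0.3, 0.0, 500.0),
        (500.0, 0.0, 100.0, 500.0),               # no elimination
        (500.0, 0.1, np.log(2) / 0.1, 250.0),     # half-life identity
    ])
    def test_depuration(self, cf0, k2, t, expected):
        assert bk.predict_depuration(cf0, k2, t) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            bk.predict_uptake(-1.0, 0.1, 80.0, 1.0)
        with pytest.raises(InvalidInputError):
            bk.predict_depuration(500.0, -0.1, 1.0)


class TestFitting:
    def test_noise_free_recovery_is_exact(self, noise_free_pair):
        body, water = noise_free_pair
        fit = bk.fit_first_order(body, water)
        assert fit.k1 == pytest.approx(20.0, rel=1e-6)
        assert fit.k2 == pytest.approx(0.1, rel=1e-6)
        assert fit.bcf_k == pytest.approx(200.0, rel=1e-6)
        assert fit.converged

    def test_matches_dense_grid_search(self):
        """Estimates agree with a brute-force 2-D grid refined twice."""
        rng = np.random.default_rng(11)
        t = np.repeat([6.0, 24.0, 45.0, 48.0], 3)
        y = bk.predict_uptake(5.0, 0.06, 80.0, t) * rng.lognormal(0, 0.1, len(t))
        body = make_series("x", "organism", t, y)
        water = make_series("x", "water", [0.0, 24.0], [80.0, 80.0])
        fit = bk.fit_first_order(body, water)

        def sse(k1, k2):
            return np.sum((y - bk.predict_uptake(k1, k2, 80.0, t)) ** 2)

        k1_grid = np.geomspace(0.5, 50, 80)
        k2_grid = np.geomspace(1e-3, 1.0, 80)
        for window in (1.5, 1.02, None):  # two refinement passes, shrinking windows
            sses = np.array([[sse(a, b) for b in k2_grid] for a in k1_grid])
            i, j = np.unravel_index(np.argmin(sses), sses.shape)
            k1_best, k2_best = k1_grid[i], k2_grid[j]
            if window is None:
                break
            k1_grid = np.geomspace(k1_best / window, k1_best * window, 80)
            k2_grid = np.geomspace(k2_best / window, k2_best * window, 80)
        assert fit.k1 == pytest.approx(k1_best, rel=0.01)
        assert fit.k2 == pytest.approx(k2_best, rel=0.01)
        # and the analytic fit is at least as good as the brute-force one
        assert fit.residual_sse <= sse(k1_best, k2_best) * (1 + 1e-9)

    def test_monte_carlo_bcf_recovery(self):
        """Median recovered k1/k2 lands within 15% of truth under the study
        design (5 sampling times, 3 pools, 10% CV noise, semi-static
        renewal).  The ratio is what the design identifies robustly: the
        sawtooth-vs-constant water mismatch inflates k1 and k2 together and
        largely cancels in BCF_k."""
        bcfs = []
        for seed in range(40):
            ds = bk.generate_dataset(bk.SimulationConfig(
                analytes=(bk.AnalyteKinetics("p", k1=20.0, k2=0.1),),
                nominal_cw=80.0, seed=seed))
            fit = bk.fit_first_order(ds.body["p"], ds.water["p"])
            bcfs.append(fit.bcf_k)
        assert np.median(bcfs) == pytest.approx(200.0, rel=0.15)

    def test_too_few_points_raises(self):
        body = make_series("x", "organism", [6.0, 24.0], [100.0, 200.0])
        water = make_series("x", "water", [0.0], [80.0])
        with pytest.raises(InsufficientDataError):
            bk.fit_first_order(body, water)

    def test_all_censored_body_raises(self):
        body = make_series("x", "organism", [6.0, 24.0, 45.0, 48.0],
                           [1.0, 2.0, 3.0, 4.0], censoring="below_lod")
        water = make_series("x", "water", [0.0, 24.0], [80.0, 80.0])
        with pytest.raises(InsufficientDataError):
            bk.fit_first_order(body, water)

    def test_stepwise_cw_mode_exact_on_step_profile(self):
        """When the water really is piecewise constant at the measured
        values, integrating the model against the step profile recovers the
        generating parameters exactly."""
        from bcfkit.toxicokinetics import _step_uptake_response

        step_t = np.array([0.0, 24.0])
        step_c = np.array([100.0, 50.0])
        t = np.array([6.0, 24.0, 30.0, 45.0, 48.0])
        y = 8.0 * _step_uptake_response(t, 0.07, step_t, step_c)
        body = make_series("x", "organism", t, y)
        water = make_series("x", "water", step_t, step_c)
        fit = bk.fit_first_order(body, water, cw_mode="stepwise")
        assert fit.k1 == pytest.approx(8.0, rel=1e-6)
        assert fit.k2 == pytest.approx(0.07, rel=1e-6)


class TestEstimatorInterface:
    def test_clone_and_params_round_trip(self):
        m = FirstOrderUptakeModel(cw=80.0, n_grid=30)
        m2 = clone(m)
        assert m2.get_params()["cw"] == 80.0
        assert m2.get_params()["n_grid"] == 30

    def test_predict_reproduces_training_curve(self, noise_free_pair):
        body, _ = noise_free_pair
        pts = body.data[body.data["time_h"] > 0]
        X = pts["time_h"].to_numpy().reshape(-1, 1)
        y = pts["value"].to_numpy()
        m = FirstOrderUptakeModel(cw=80.0).fit(X, y)
        assert m.predict(X) == pytest.approx(y, rel=1e-6)
        assert m.score(X, y) == pytest.approx(1.0, abs=1e-9)


class TestBcf:
    @pytest.mark.parametrize("k1, k2, expected", [
        (1.0, 1.0, 1.0),
        (7.5, 0.05, 150.0),   # study-maximum magnitude (sertraline)
        (0.0, 0.1, 0.0),
    ])
    def test_kinetic(self, k1, k2, expected):
        assert bk.bcf_kinetic(k1, k2) == pytest.approx(expected)

    def test_kinetic_undefined_for_zero_elimination(self):
        with pytest.raises(UndefinedPlateauError):
            bk.bcf_kinetic(1.0, 0.0)

    def test_steady_state_ratio(self):
        body = make_series("x", "organism", [48.0, 48.0, 48.0],
                           [4000.0, 4000.0, 4000.0],
                           replicate=["r1", "r2", "r3"])
        water = make_series("x", "water", [0.0, 24.0], [80.0, 80.0])
        assert bk.bcf_steady_state(body, water, 48.0) == pytest.approx(50.0)

    def test_steady_state_all_censored_raises(self):
        body = make_series("x", "organism", [48.0], [2.0], censoring="below_lod")
        water = make_series("x", "water", [0.0, 24.0], [80.0, 80.0])
        with pytest.raises(InsufficientDataError):
            bk.bcf_steady_state(body, water, 48.0)

    def test_agrees_with_kinetic_bcf_at_plateau(self):
        """BCF_48h within 10% of BCF_k on noise-free data with k2*t_end >= 5."""
        t = np.array([0.0, 6.0, 24.0, 45.0, 48.0])
        y = bk.predict_uptake(15.0, 0.12, 80.0, t)   # k2 * 48 = 5.76
        body = make_series("x", "organism", t, y)
        water = make_series("x", "water", [0.0, 24.0], [80.0, 80.0])
        fit = bk.fit_first_order(body, water)
        bcf48 = bk.bcf_steady_state(body, water, 48.0)
        assert bcf48 == pytest.approx(fit.bcf_k, rel=0.10)


class TestSteadyStateDetection:
    def test_small_late_change_is_steady(self):
        body = make_series("x", "organism", [45.0, 48.0], [1000.0, 1050.0])
        r = bk.detect_steady_state(body, tolerance=0.20)
        assert r.steady and r.relative_change == pytest.approx(0.05)

    def test_large_late_change_is_not_steady(self):
        body = make_series("x", "organism", [45.0, 48.0], [1000.0, 1500.0])
        assert not bk.detect_steady_state(body, tolerance=0.20).steady

    def test_slow_uptake_far_from_plateau_is_not_steady(self):
        """A slow noise-free uptake curve (k2=0.005) has nearly flat late
        samples but sits at only ~21% of its plateau after 48 h."""
        t = np.array([0.0, 6.0, 24.0, 45.0, 48.0])
        body = make_series("x", "organism", t, bk.predict_uptake(20.0, 0.005, 80.0, t))
        r = bk.detect_steady_state(body, tolerance=0.20)
        assert not r.steady
        assert r.plateau_fraction == pytest.approx(-np.expm1(-0.005 * 48), rel=0.05)

    def test_single_time_point_raises(self):
        with pytest.raises(InsufficientDataError):
            bk.detect_steady_state(make_series("x", "organism", [48.0], [100.0]))


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, noise_free_pair):
        body, water = noise_free_pair
        r1 = bk.bootstrap_uncertainty(body, water, b=120, seed=5)
        r2 = bk.bootstrap_uncertainty(body, water, b=120, seed=5)
        assert r1.intervals == r2.intervals

    def test_zero_width_on_identical_replicates(self):
        t = np.repeat([6.0, 24.0, 45.0, 48.0], 3)
        y = bk.predict_uptake(20.0, 0.1, 80.0, t)
        body = make_series("x", "organism", t, y,
                           replicate=np.tile(["r1", "r2", "r3"], 4))
        water = make_series("x", "water", [0.0, 24.0], [80.0, 80.0])
        r = bk.bootstrap_uncertainty(body, water, b=150, seed=0)
        lo, hi = r.intervals["bcf_k"]
        assert hi - lo == pytest.approx(0.0, abs=1e-6 * 200.0)

    def test_small_b_warns(self, noise_free_pair):
        body, water = noise_free_pair
        with pytest.warns(UserWarning, match="B=50"):
            r = bk.bootstrap_uncertainty(body, water, b=50, seed=1)
        assert r.warning is not None
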