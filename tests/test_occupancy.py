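import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camtrapniche._utils import expit, logit
from camtrapniche.detections import DetectionHistory
from camtrapniche.occupancy import (
    ModelSet,
    OccuModelSpec,
    aicc,
    fit_occu,
    mb_gof,
    occu_loglik,
    qaicc,
    rank_and_average,
    selection_workflow,
)
from camtrapniche.simulate import simulate_history_matrix

from .conftest import enumeration_loglik


def _hist(matrix) -> DetectionHistory:
    matrix = np.asarray(matrix, dtype=float)
    ids = tuple(f"s{i}" for i in range(matrix.shape[0]))
    return DetectionHistory("sp", ids, 6, matrix)


def _designs(n, k):
    return np.ones((n, 1)), np.ones((n, k, 1))


class TestLoglik:
    def test_forced_product(self):
        # 1 site, 1 occasion, psi = p = 0.5, y = [1] -> likelihood 0.25
        h = _hist([[1]])
        ll = occu_loglik(h.matrix, h.active, *_designs(1, 1),
                         beta=[0.0], alpha=[0.0])
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    def test_forced_mixture(self):
        # y = [0] -> 0.5*0.5 + 0.5 = 0.75
        h = _hist([[0]])
        ll = occu_loglik(h.matrix, h.active, *_designs(1, 1),
                         beta=[0.0], alpha=[0.0])
        assert ll == pytest.approx(np.log(0.75), abs=1e-12)

    def test_random_3x3_enumeration(self):
        rng = np.random.default_rng(5)
        y = (rng.random((3, 3)) < 0.4).astype(float)
        psi, p = rng.random(3), rng.random((3, 3))
        h = _hist(y)
        psi_x = np.eye(3)
        p_x = np.zeros((3, 3, 9))
        for i in range(3):
            for j in range(3):
                p_x[i, j, 3 * i + j] = 1.0
        ll = occu_loglik(y, h.active, psi_x, p_x,
                         beta=logit(psi), alpha=logit(p).ravel())
        assert ll == pytest.approx(
            enumeration_loglik(y, h.active, psi, p), abs=1e-10)

    @settings(max_examples=120, deadline=None)
    @given(st.data())
    def test_property_sweep_vs_enumeration(self, data):
        n = data.draw(st.integers(1, 4))
        k = data.draw(st.integers(1, 4))
        bits = data.draw(st.lists(st.integers(0, 3), min_size=n * k,
                                  max_size=n * k))
        y = (np.array(bits).reshape(n, k) == 1).astype(float)
        active = np.array(bits).reshape(n, k) != 3
        if not active.any(axis=1).all():
            active[~active.any(axis=1), 0] = True
        y = np.where(active, y, np.nan)
        psi_v = data.draw(st.floats(0.05, 0.95))
        p_v = data.draw(st.floats(0.05, 0.95))
        psi = np.full(n, psi_v)
        p = np.full((n, k), p_v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll = occu_loglik(y, active, *_designs(n, k),
                             beta=[logit(psi_v)], alpha=[logit(p_v)])
        assert ll == pytest.approx(enumeration_loglik(y, active, psi, p),
                                   abs=1e-10)

    def test_site_permutation_invariance(self):
        rng = np.random.default_rng(7)
        y = (rng.random((6, 4)) < 0.3).astype(float)
        h = _hist(y)
        ll = occu_loglik(y, h.active, *_designs(6, 4), beta=[0.3], alpha=[-0.4])
        perm = rng.permutation(6)
        ll2 = occu_loglik(y[perm], h.active[perm], *_designs(6, 4),
                          beta=[0.3], alpha=[-0.4])
        assert ll == pytest.approx(ll2, abs=1e-12)

    def test_occasion_permutation_invariance_constant_p(self):
        rng = np.random.default_rng(8)
        y = (rng.random((5, 6)) < 0.3).astype(float)
        h = _hist(y)
        ll = occu_loglik(y, h.active, *_designs(5, 6), beta=[0.1], alpha=[0.2])
        perm = rng.permutation(6)
        ll2 = occu_loglik(y[:, perm], h.active[:, perm], *_designs(5, 6),
                          beta=[0.1], alpha=[0.2])
        assert ll == pytest.approx(ll2, abs=1e-12)

    def test_dimension_mismatch(self):
        h = _hist([[1, 0]])
        with pytest.raises(ValueError):
            occu_loglik(h.matrix, h.active, *_designs(1, 2),
                        beta=[0.0, 0.0], alpha=[0.0])


class TestInformationCriteria:
    def test_aicc_hand_value(self):
        assert aicc(-100.0, 3, 127) == pytest.approx(206 + 24 / 123, abs=1e-10)

    def test_qaicc_chat_one_differs_only_via_extra_param(self):
        base = qaicc(-100.0, 3, 127, 1.0)
        k4 = 4
        expected = 200.0 + 2 * k4 + 2 * k4 * (k4 + 1) / (127 - k4 - 1)
        assert base == pytest.approx(expected, abs=1e-10)

    def test_qaicc_chat_two_hand_value(self):
        k4 = 4
        expected = 100.0 + 2 * k4 + 2 * k4 * (k4 + 1) / (127 - k4 - 1)
        assert qaicc(-100.0, 3, 127, 2.0) == pytest.approx(expected, abs=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestFitOccu:
    def test_grid_oracle_intercept_only(self):
        rng = np.random.default_rng(11)
        y = simulate_history_matrix(40, 5, 0.6, 0.4, rng)
        h = _hist(y)
        fit = fit_occu(h)
        # brute-force profile over a 1000x1000 (psi, p) grid
        grid = np.linspace(0.001, 0.999, 1000)
        d = np.nansum(y, axis=1)
        a = h.active.sum(axis=1)
        best = (-np.inf, None, None)
        p_pow = grid[None, :]  # p values
        for psi in grid:
            lik = psi * p_pow ** d[:, None] * (1 - p_pow) ** (a - d)[:, None]
            lik[d == 0] += 1 - psi
            ll = np.log(lik).sum(axis=0)
            j = np.argmax(ll)
            if ll[j] > best[0]:
                best = (ll[j], psi, grid[j])
        assert fit.psi_hat()[0] == pytest.approx(best[1], abs=1e-3)
        assert fit.p_hat()[0] == pytest.approx(best[2], abs=1e-3)
        assert fit.loglik >= best[0] - 1e-6

    def test_parameter_recovery(self):
        # scaled-down version of the 100-replicate recovery oracle (the full
        # scale runs in the acceptance suite)
        psis, ps = [], []
        for rep in range(25):
            rng = np.random.default_rng(300 + rep)
            y = simulate_history_matrix(500, 13, 0.6, 0.3, rng)
            fit = fit_occu(_hist(y), compute_vcov=False)
            psis.append(fit.psi_hat()[0])
            ps.append(fit.p_hat()[0])
        assert abs(np.mean(psis) - 0.6) < 0.05
        assert abs(np.mean(ps) - 0.3) < 0.05

    def test_all_detected_boundary_no_crash(self):
        y = np.ones((10, 4))
        fit = fit_occu(_hist(y))
        assert fit.psi_hat()[0] > 0.95

    def test_never_detected_rejected(self):
        with pytest.raises(ValueError):
            fit_occu(_hist(np.zeros((5, 3))))

    def test_monotone_psi_in_detections(self):
        rng = np.random.default_rng(13)
        y = simulate_history_matrix(30, 6, 0.5, 0.4, rng)
        zero_rows = np.flatnonzero(~(y == 1).any(axis=1))
        fit0 = fit_occu(_hist(y), compute_vcov=False)
        y2 = y.copy()
        y2[zero_rows[0], 0] = 1.0
        fit1 = fit_occu(_hist(y2), compute_vcov=False)
        assert fit1.psi_hat()[0] >= fit0.psi_hat()[0] - 1e-6

    def test_covariate_fit(self):
        rng = np.random.default_rng(17)
        n = 300
        x = rng.standard_normal(n)
        psi = expit(0.3 + 0.9 * x)
        y = simulate_history_matrix(n, 8, psi, 0.35, rng)
        cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(n)])
        fit = fit_occu(_hist(y), cov, OccuModelSpec(("x",), ()))
        assert fit.beta[1] == pytest.approx(0.9, abs=0.35)
        assert fit.converged

    def test_wald_coverage(self):
        # 95% CI for logit(psi) should cover truth 90-98% of the time at the
        # survey's scale (reduced replicate count; seeds fixed)
        hits = 0
        reps = 120
        for rep in range(reps):
            rng = np.random.default_rng(5000 + rep)
            y = simulate_history_matrix(127, 13, 0.6, 0.3, rng)
            fit = fit_occu(_hist(y))
            se = fit.se[0]
            lo, hi = fit.beta[0] - 1.96 * se, fit.beta[0] + 1.96 * se
            hits += lo <= logit(0.6) <= hi
        assert 0.90 - 0.05 <= hits / reps <= 0.98 + 0.02


class TestGof:
    def test_calibration(self):
        chats = []
        for rep in range(6):
            rng = np.random.default_rng(700 + rep)
            y = simulate_history_matrix(200, 10, 0.6, 0.3, rng)
            h = _hist(y)
            fit = fit_occu(h)
            chats.append(mb_gof(fit, h, n_boot=100, seed=rep).chat)
        assert 0.8 < np.mean(chats) < 1.2

    def test_overdispersion_detected(self):
        chats = []
        for rep in range(4):
            rng = np.random.default_rng(800 + rep)
            p_site = rng.beta(1.2, 2.8, 200)
            y = simulate_history_matrix(200, 10, 0.6,
                                        np.tile(p_site[:, None], (1, 10)), rng)
            h = _hist(y)
            fit = fit_occu(h)
            chats.append(mb_gof(fit, h, n_boot=100, seed=rep).chat)
        assert np.mean(chats) > 1.0

    def test_small_nboot_warns(self):
        rng = np.random.default_rng(0)
        y = simulate_history_matrix(50, 5, 0.6, 0.4, rng)
        h = _hist(y)
        fit = fit_occu(h)
        with pytest.warns(UserWarning, match="n_boot"):
            mb_gof(fit, h, n_boot=20, seed=0)


class TestRankAndAverage:
    @pytest.fixture
    def one_fit(self):
        rng = np.random.default_rng(31)
        y = simulate_history_matrix(80, 8, 0.6, 0.35, rng)
        return fit_occu(_hist(y))

    def test_single_model(self, one_fit):
        ms = rank_and_average([one_fit])
        assert ms.weights[0] == pytest.approx(1.0)
        est = ms.averaged.set_index("term")["estimate"]
        assert est["psi_(intercept)"] == pytest.approx(one_fit.beta[0])

    def test_equal_criterion_gives_half_weights(self, one_fit):
        import copy
        ms = rank_and_average([one_fit, copy.deepcopy(one_fit)])
        np.testing.assert_allclose(ms.weights, [0.5, 0.5])

    def test_three_model_hand_average(self):
        rng = np.random.default_rng(37)
        n = 150
        x = rng.standard_normal(n)
        y = simulate_history_matrix(n, 8, expit(0.2 + 0.6 * x), 0.35, rng)
        cov = pd.DataFrame({"x": x, "z": rng.standard_normal(n)},
                           index=[f"s{i}" for i in range(n)])
        h = _hist(y)
        fits = [fit_occu(h),
                fit_occu(h, cov, OccuModelSpec(("x",), ())),
                fit_occu(h, cov, OccuModelSpec(("z",), ()))]
        ms = rank_and_average(fits)
        # hand-recompute the weighted intercept average
        w = ms.weights
        ests = [f.beta[0] for f in ms.fits]
        expected = np.sum(w * np.array(ests)) / w.sum()
        got = ms.averaged.set_index("term")["estimate"]["psi_(intercept)"]
        assert got == pytest.approx(expected, abs=1e-10)
        assert ms.deltas[0] == 0.0
        assert ms.weights.sum() == pytest.approx(1.0)

    def test_delta_max_excludes(self, one_fit):
        import copy
        worse = copy.deepcopy(one_fit)
        worse.loglik -= 50.0
        ms = rank_and_average([one_fit, worse], delta_max=6.0)
        assert ms.weights[1] == 0.0

    def test_qaicc_used_when_overdispersed(self, one_fit):
        ms = rank_and_average([one_fit], chat=1.5)
        assert ms.criterion == "QAICc"
        ms2 = rank_and_average([one_fit], chat=0.9)
        assert ms2.criterion == "AICc"


class TestSelectionWorkflow:
    def _simulate(self, seed, effect=1.0):
        rng = np.random.default_rng(seed)
        n = 127
        cov = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["good", "noise1", "noise2"],
            index=[f"s{i}" for i in range(n)])
        cov["det"] = rng.standard_normal(n)
        psi = expit(0.4 + effect * cov["good"].to_numpy())
        y = simulate_history_matrix(n, 13, psi, 0.35, rng)
        return _hist(y), cov

    def test_recovers_active_covariate(self):
        wins = 0
        reps = 12
        for rep in range(reps):
            h, cov = self._simulate(900 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ms = selection_workflow(h, cov, ["det"],
                                        ["good", "noise1", "noise2"])
            top = ms.fits[0].spec.psi_covariates
            avg = ms.averaged.set_index("term")
            if "good" in top and "psi_good" in avg.index:
                row = avg.loc["psi_good"]
                wins += (row["lcl"] > 0) or (row["ucl"] < 0)
        assert wins > reps / 2

    def test_null_competitive_under_zero_effect(self):
        close = 0
        reps = 8
        for rep in range(reps):
            h, cov = self._simulate(950 + rep, effect=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ms = selection_workflow(h, cov, ["det"],
                                        ["good", "noise1", "noise2"])
            null_delta = min(d for f, d in zip(ms.fits, ms.deltas)
                             if not f.spec.psi_covariates)
            close += null_delta < 2.0
        assert close > reps / 2

    def test_empty_candidates_returns_null_set(self):
        h, cov = self._simulate(999)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = selection_workflow(h, cov, [], [])
        assert isinstance(ms, ModelSet)
        assert all(not f.spec.psi_covariates for f in ms.fits)
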