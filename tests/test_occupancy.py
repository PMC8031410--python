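"""Occupancy likelihood, MLE, model selection, GOF and prediction."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from vernal import (
    DetectionHistory,
    OccupancyModel,
    OccupancyModelSpec,
    enumerate_models,
    fit_occupancy,
    gof_mackenzie_bailey,
    negloglik,
)
from vernal.occupancy import _chisq_statistic, simulate_from_fit
from vernal.simulate import SimConfig, simulate_study
from vernal import build_detection_history

from conftest import make_history, nll_oracle


class TestNegLogLik:
    def test_single_detection_hand_value(self):
        h = make_history([[1.0]])
        assert negloglik([0.0, 0.0], h) == pytest.approx(-np.log(0.25), abs=1e-12)

    def test_all_zero_history_includes_unoccupied_branch(self):
        h = make_history([[0.0, 0.0]])
        assert negloglik([0.0, 0.0], h) == pytest.approx(-np.log(0.625), abs=1e-12)

    def test_known_occupied_drops_unoccupied_branch(self):
        h = make_history([[0.0, 0.0]], known=[True])
        assert negloglik([0.0, 0.0], h) == pytest.approx(-np.log(0.5 * 0.25), abs=1e-12)

    def test_certain_codes_collapse_to_binary(self):
        h2 = make_history([[2.0, 0.0]], known=[True])
        h1 = make_history([[1.0, 0.0]], known=[True])
        assert negloglik([0.3, -0.2], h2) == negloglik([0.3, -0.2], h1)

    def test_matches_enumeration_oracle_on_toy(self, toy_history):
        params = [0.4, -0.3]
        psi = [expit(0.4)] * toy_history.n_sites
        p = [[expit(-0.3)] * 3] * toy_history.n_sites
        expected = nll_oracle(psi, p, toy_history.observations, toy_history.known_occupied)
        assert negloglik(params, toy_history) == pytest.approx(expected, abs=1e-12)

    def test_oracle_equivalence_with_covariates_randomized(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 8))
            J = int(rng.integers(1, 5))
            obs = rng.choice([0.0, 1.0, np.nan], size=(n, J), p=[0.45, 0.45, 0.1])
            known = rng.random(n) < 0.3
            vol = rng.uniform(0, 10, (n, J))
            h = make_history(obs, known=known, covariates={"volume_per_replicate": vol})
            spec = OccupancyModelSpec(detection_covariates=("volume_per_replicate",))
            a0, b0, b1 = rng.normal(0, 1, 3)
            got = negloglik([a0, b0, b1], h, spec)
            psi = [expit(a0)] * n
            p = [[expit(b0 + b1 * vol[i, j]) for j in range(J)] for i in range(n)]
            want = nll_oracle(psi, p, obs, known)
            assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_under_site_and_replicate_permutation(self, toy_history, rng):
        params = [0.2, 0.5]
        base = negloglik(params, toy_history)
        order = rng.permutation(toy_history.n_sites)
        assert negloglik(params, toy_history.subset(order)) == pytest.approx(base, abs=1e-12)
        cols = rng.permutation(toy_history.n_replicates)
        shuffled = make_history(toy_history.observations[:, cols],
                                known=toy_history.known_occupied)
        assert negloglik(params, shuffled) == pytest.approx(base, abs=1e-12)

    def test_nonfinite_covariates_rejected_before_optimization(self):
        h = make_history([[1.0, 0.0]], covariates={"pool_area": np.array([np.inf])})
        with pytest.raises(ValueError, match="non-finite"):
            negloglik([0.0, 0.0, 0.0], h,
                      OccupancyModelSpec(detection_covariates=("pool_area",)))


class TestFit:
    def test_no_covariate_mle_matches_dense_grid_search(self, toy_history):
        model = fit_occupancy(toy_history)
        grid = np.linspace(1e-3, 1 - 1e-3, 1000)
        psi_g, p_g = np.meshgrid(grid, grid, indexing="ij")
        Y = toy_history.binary().observations
        known = toy_history.known_occupied
        det = np.nansum(Y, axis=1)
        tot = np.sum(~np.isnan(Y), axis=1)
        ll = np.zeros_like(psi_g)
        for i in range(toy_history.n_sites):
            occ = p_g ** det[i] * (1 - p_g) ** (tot[i] - det[i])
            lik = psi_g * occ
            if not known[i] and det[i] == 0:
                lik = lik + (1 - psi_g)
            ll += np.log(lik)
        best = np.unravel_index(np.argmax(ll), ll.shape)
        psi_grid, p_grid = grid[best[0]], grid[best[1]]
        assert model.psi_hat_ == pytest.approx(psi_grid, abs=2e-3)
        assert expit(model.beta_[0]) == pytest.approx(p_grid, abs=2e-3)
        assert model.loglik_ >= ll[best] - 1e-6

    def test_recovers_truth_within_three_standard_errors(self):
        cfg = SimConfig(n_sites=500, psi=0.6, detect_intercept=float(logit(0.75)),
                        dipnet_sensitivity=0.8, seed=42)
        h = build_detection_history(simulate_study(cfg).events, "BRLY",
                                    certain_from_dipnet=False)
        m = fit_occupancy(h, seed=1)
        assert m.converged_ and not m.boundary_
        se = np.sqrt(np.diag(m.vcov_))
        assert abs(m.alpha_[0] - logit(0.6)) < 3 * se[0]
        assert abs(m.beta_[0] - logit(0.75)) < 3 * se[1]

    def test_saturated_detections_hit_boundary_flag(self):
        h = make_history(np.ones((8, 3)))
        with pytest.warns(UserWarning, match="boundary"):
            m = fit_occupancy(h)
        assert m.boundary_
        assert m.psi_hat_ > 0.999
        assert expit(m.beta_[0]) > 0.999

    def test_known_occupied_only_data_reduces_to_bernoulli_closed_form(self):
        obs = np.array([[1, 0, 1], [1, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float)
        h = make_history(obs, known=[True] * 4)
        with pytest.warns(UserWarning):      # psi runs to its boundary
            m = fit_occupancy(h)
        assert expit(m.beta_[0]) == pytest.approx(obs.mean(), abs=1e-4)

    def test_standardization_does_not_change_the_fit(self, rng):
        cfg = SimConfig(n_sites=150, psi=0.6, coef_volume=0.3, seed=3)
        h = build_detection_history(simulate_study(cfg).events, "BRLY",
                                    certain_from_dipnet=False)
        spec = ("volume_per_replicate",)
        m_std = OccupancyModel(detection_covariates=spec, standardize=True, seed=0).fit(h)
        m_raw = OccupancyModel(detection_covariates=spec, standardize=False, seed=0).fit(h)
        assert m_std.loglik_ == pytest.approx(m_raw.loglik_, abs=1e-4)
        assert m_std.beta_raw_[1] == pytest.approx(m_raw.beta_[1], rel=1e-2)


@pytest.fixture(scope="module")
def sim_history():
    cfg = SimConfig(n_sites=250, psi=0.6, detect_intercept=0.0,
                    coef_protocol=1.8, seed=5)
    return build_detection_history(simulate_study(cfg).events, "BRLY",
                                   certain_from_dipnet=False)


class TestModelSelection:
    def test_full_pool_gives_sixteen_ranked_rows(self, sim_history):
        table = enumerate_models(sim_history,
                                 ("volume_per_replicate", "avg_volume",
                                  "pool_area", "protocol"), n_starts=2)
        assert len(table) == 16
        assert table["aic"].is_monotonic_increasing
        assert table["delta_aic"].iloc[0] == 0.0
        assert table["selected"].sum() == 1

    def test_empty_pool_gives_single_base_model(self, toy_history):
        table = enumerate_models(toy_history, ())
        assert len(table) == 1
        assert table["model"].iloc[0] == ()

    def test_strong_effect_is_selected(self, sim_history):
        table = enumerate_models(sim_history, ("protocol", "pool_area"), n_starts=2)
        selected = table[table["selected"]]["model"].iloc[0]
        assert "protocol" in selected


class TestGof:
    def test_expected_frequencies_match_exhaustive_enumeration(self, rng):
        obs = np.array([[1, 0], [0, 0], [1, 1], [0, 1]], dtype=float)
        h = make_history(obs)
        m = fit_occupancy(h)
        psi, p = m.site_probabilities(h)
        t_direct = 0.0
        for i in range(4):
            for hist in itertools.product((0.0, 1.0), repeat=2):
                prob = np.prod([p[i, j] if hist[j] else 1 - p[i, j] for j in range(2)])
                e = psi[i] * prob + (1 - psi[i]) * (sum(hist) == 0)
                o = 1.0 if tuple(obs[i]) == hist else 0.0
                t_direct += (o - e) ** 2 / e
        assert _chisq_statistic(m, h) == pytest.approx(t_direct, abs=1e-10)

    def test_perfect_fit_degenerate_case(self):
        # saturated detections: the boundary fit reproduces the single
        # observed history with probability ~1, so T ~ 0 and p = 1
        h = make_history(np.ones((6, 2)))
        with pytest.warns(UserWarning):
            m = fit_occupancy(h)
        t = _chisq_statistic(m, h)
        assert t == pytest.approx(0.0, abs=1e-4)

    def test_small_bootstrap_warns(self, toy_history):
        m = fit_occupancy(toy_history)
        with pytest.warns(UserWarning, match="unstable"):
            gof = gof_mackenzie_bailey(m, toy_history, B=20, seed=1)
        assert 0.0 <= gof.p_value <= 1.0
        assert gof.n_boot == 20

    def test_simulation_respects_known_occupied_and_na_pattern(self, rng):
        obs = np.array([[1, np.nan, 0], [0, 0, np.nan], [1, 1, 1]])
        h = make_history(obs, known=[True, False, True])
        m = fit_occupancy(h)
        sim = simulate_from_fit(m, h, rng)
        assert np.array_equal(np.isnan(sim.observations), np.isnan(obs))
        assert np.array_equal(sim.known_occupied, h.known_occupied)


class TestPredictDetection:
    def _degenerate_model(self, beta0):
        m = OccupancyModel()
        m.spec_ = OccupancyModelSpec()
        m.alpha_ = np.array([0.0])
        m.beta_ = np.array([beta0])
        m.vcov_ = np.zeros((2, 2))
        m.standardization_ = {}
        m.covariate_ranges_ = {}
        return m

    def test_zero_variance_intercept_only_prediction(self):
        pred = self._degenerate_model(0.0).predict_detection({})
        assert (pred.p, pred.lo, pred.hi) == (0.5, 0.5, 0.5)

    def test_back_transformed_point_estimate(self):
        pred = self._degenerate_model(float(logit(0.7564))).predict_detection({})
        assert pred.p == pytest.approx(0.7564, abs=1e-10)

    def test_ci_matches_monte_carlo_normal_oracle(self):
        cfg = SimConfig(n_sites=300, psi=0.6, seed=9)
        h = build_detection_history(simulate_study(cfg).events, "BRLY",
                                    certain_from_dipnet=False)
        m = fit_occupancy(h, seed=2)
        pred = m.predict_detection({})
        draws = np.random.default_rng(0).normal(m.beta_[0], pred.se_link, 1_000_000)
        lo, hi = np.quantile(expit(draws), [0.025, 0.975])
        assert pred.lo == pytest.approx(lo, abs=1e-3)
        assert pred.hi == pytest.approx(hi, abs=1e-3)
        assert 0.0 <= pred.lo <= pred.p <= pred.hi <= 1.0

    def test_extrapolation_flagged(self):
        cfg = SimConfig(n_sites=80, psi=0.7, coef_volume=0.2, seed=4)
        h = build_detection_history(simulate_study(cfg).events, "BRLY",
                                    certain_from_dipnet=False)
        m = OccupancyModel(detection_covariates=("volume_per_replicate",)).fit(h)
        with pytest.warns(UserWarning, match="extrapolat"):
            pred = m.predict_detection({"volume_per_replicate": 5000.0})
        assert pred.extrapolated

    def test_missing_covariate_value_is_an_error(self):
        cfg = SimConfig(n_sites=80, psi=0.7, seed=4)
        h = build_detection_history(simulate_study(cfg).events, "BRLY",
                                    certain_from_dipnet=False)
        m = OccupancyModel(detection_covariates=("protocol",)).fit(h)
        with pytest.raises(KeyError):
            m.predict_detection({})
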