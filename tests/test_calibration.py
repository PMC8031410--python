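"""Standard-curve fitting, Low95/LOD/LOQ rules, quantification."""

import numpy as np
import pytest

from vernal import (
    ABOVE_MAX_TESTED,
    StandardCurve,
    StandardPanel,
    estimate_lod,
    estimate_loq,
    fit_curve,
    low95,
    quantify,
)
from vernal.calibration import CurveFit, replicate_adjusted_lod
from vernal.simulate import simulate_standard_panel

# printed calibration row used as a closed-form anchor (slope, intercept)
BRCO_SLOPE, BRCO_INTERCEPT = -3.609, 38.664


def noiseless_panel(slope=-3.3219, intercept=38.0, concs=(1, 2, 5, 10, 100), reps=8):
    pts = [(c, slope * np.log10(c) + intercept) for c in concs for _ in range(reps)]
    return StandardPanel.from_points(pts)


def panel_with_fractions(frac_by_conc, reps=8, slope=-3.5, intercept=39.0):
    """Panel with a prescribed number of amplifying wells per level."""
    pts = []
    for conc, n_amp in frac_by_conc.items():
        for i in range(reps):
            cq = slope * np.log10(conc) + intercept if i < n_amp else None
            pts.append((conc, cq))
    return StandardPanel.from_points(pts)


class TestFitCurve:
    def test_noiseless_wells_recover_coefficients_exactly(self):
        fit = fit_curve(noiseless_panel())
        assert fit.slope == pytest.approx(-3.3219, abs=1e-12)
        assert fit.intercept == pytest.approx(38.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.efficiency == pytest.approx(1.0, abs=1e-4)

    def test_efficiency_closed_form_from_printed_slope(self):
        fit = fit_curve(noiseless_panel(slope=BRCO_SLOPE, intercept=BRCO_INTERCEPT))
        assert fit.efficiency == pytest.approx(10 ** (1 / 3.609) - 1, rel=1e-9)
        assert fit.efficiency == pytest.approx(0.893, abs=5e-4)

    def test_matches_normal_equations_on_noisy_toy(self, rng):
        concs = np.repeat([1.0, 2.0, 5.0, 10.0, 100.0], 3)
        cqs = -3.4 * np.log10(concs) + 39.0 + rng.normal(0, 0.5, concs.size)
        panel = StandardPanel(copies=concs, cq=cqs)
        fit = fit_curve(panel)
        # independent solve of the normal equations X'X beta = X'y
        X = np.column_stack([np.log10(concs), np.ones(concs.size)])
        beta = np.linalg.solve(X.T @ X, X.T @ cqs)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_nonamplifying_wells_excluded_from_regression(self):
        panel = panel_with_fractions({1.0: 4, 10.0: 8, 100.0: 8})
        fit = fit_curve(panel)
        assert fit.n_wells == 20
        assert fit.r_squared == pytest.approx(1.0)

    def test_all_dropout_is_an_error(self):
        panel = StandardPanel.from_points([(1.0, None), (10.0, None)])
        with pytest.raises(ValueError):
            fit_curve(panel)

    def test_positive_slope_warns(self):
        panel = StandardPanel.from_points([(1.0, 30.0), (1.0, 30.1), (100.0, 39.0)])
        with pytest.warns(UserWarning, match="slope"):
            fit_curve(panel)

    def test_efficiency_invariant_to_intercept_shift(self):
        f1 = fit_curve(noiseless_panel(intercept=38.0))
        f2 = fit_curve(noiseless_panel(intercept=45.0))
        assert f1.efficiency == pytest.approx(f2.efficiency, rel=1e-12)


class TestLow95:
    def test_seven_of_eight_misses_the_bar(self):
        panel = panel_with_fractions({1.0: 5, 2.0: 7, 5.0: 8, 10.0: 8, 100.0: 8})
        assert low95(panel) == 5.0  # 7/8 = 87.5% < 95%

    def test_full_detection_everywhere_gives_lowest_tested(self):
        assert low95(noiseless_panel()) == 1.0

    def test_no_level_reaching_95_gives_sentinel(self):
        panel = panel_with_fractions({c: 6 for c in (1.0, 2.0, 5.0, 10.0, 100.0)})
        assert low95(panel) == ABOVE_MAX_TESTED


class TestLOD:
    def test_full_detection_gives_smallest_tested_concentration(self):
        for method in ("discrete", "curvefit"):
            assert estimate_lod(noiseless_panel(), method) == 1.0

    def test_all_or_nothing_discrete_lod(self):
        panel = panel_with_fractions({1.0: 0, 2.0: 0, 5.0: 0, 10.0: 8, 100.0: 8})
        assert estimate_lod(panel, "discrete") == 10.0

    def test_curvefit_recovers_logistic_crossing(self):
        # generated dropout crosses 95% detection at 3.0 copies/reaction:
        # expit(s * (log10(c95) - log10(c50))) = 0.95
        detect_slope = 4.0
        detect50 = 3.0 / 10 ** (np.log(0.95 / 0.05) / detect_slope)
        lods = []
        for seed in range(8):
            panel = simulate_standard_panel(
                concentrations=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0), replicates=24,
                detect50=detect50, detect_slope=detect_slope, seed=seed,
            )
            lods.append(estimate_lod(panel, "curvefit"))
        assert np.mean(lods) == pytest.approx(3.0, rel=0.25)

    def test_decreasing_detection_pattern_falls_back_to_discrete(self):
        panel = panel_with_fractions({1.0: 8, 2.0: 8, 5.0: 6, 10.0: 4, 100.0: 2})
        with pytest.warns(UserWarning, match="discrete"):
            lod = estimate_lod(panel, "curvefit")
        assert lod == estimate_lod(panel, "discrete")


class TestLOQ:
    def test_noiseless_panel_quantifies_down_to_lowest_level(self):
        panel = noiseless_panel()
        assert estimate_loq(panel, method="discrete") == 1.0

    def test_discrete_cv_threshold_crossing(self, rng):
        # Cq noise tuned per level so back-calculated CV crosses 0.35
        # between 10 and 100 copies; direct-formula CV is the oracle
        slope, intercept = -3.4, 39.0
        pts = []
        sd_by_conc = {1.0: 1.2, 2.0: 1.2, 5.0: 1.0, 10.0: 0.8, 100.0: 0.05}
        for conc, sd in sd_by_conc.items():
            for _ in range(24):
                pts.append((conc, slope * np.log10(conc) + intercept + rng.normal(0, sd)))
        panel = StandardPanel.from_points(pts)
        fit = fit_curve(panel)
        loq = estimate_loq(panel, 0.35, "discrete", fit)
        # oracle: compute each level's CV directly and apply the rule
        crossing = []
        for conc in sd_by_conc:
            cqs = panel.cq[panel.copies == conc]
            est = 10 ** ((cqs - fit.intercept) / fit.slope)
            if est.std(ddof=1) / est.mean() <= 0.35:
                crossing.append(conc)
        assert loq == min(crossing)
        assert loq == 100.0

    def test_curvefit_interpolates_threshold_crossing(self, rng):
        # decreasing noise generated so the CV curve crosses 0.35
        # between tested levels; interpolated LOQ lands near 24 copies
        slope, intercept = -3.4, 39.0
        loqs = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            pts = []
            for conc in (1.0, 5.0, 24.0, 120.0, 600.0):
                sd = 1.5 / (1 + np.log10(conc)) ** 1.6
                for _ in range(48):
                    pts.append((conc, slope * np.log10(conc) + intercept + r.normal(0, sd)))
            panel = StandardPanel.from_points(pts)
            loqs.append(estimate_loq(panel, 0.35, "curvefit"))
        assert np.median(loqs) == pytest.approx(24.0, rel=0.5)

    def test_nothing_meets_threshold_gives_sentinel(self, rng):
        pts = [(c, -3.4 * np.log10(c) + 39.0 + rng.normal(0, 2.5))
               for c in (1.0, 10.0, 100.0) for _ in range(24)]
        panel = StandardPanel.from_points(pts)
        assert estimate_loq(panel, 0.05, "discrete") == ABOVE_MAX_TESTED


class TestQuantify:
    def test_cq_at_intercept_is_one_copy(self):
        fit = CurveFit(slope=-3.5, intercept=38.0, r_squared=1.0, efficiency=0.93)
        assert quantify(38.0, fit) == pytest.approx(1.0)

    def test_one_slope_step_is_ten_copies(self):
        fit = CurveFit(slope=-3.5, intercept=38.0, r_squared=1.0, efficiency=0.93)
        assert quantify(38.0 - 3.5, fit) == pytest.approx(10.0)

    def test_printed_coefficients_give_hundred_copies_two_steps_up(self):
        fit = CurveFit(slope=BRCO_SLOPE, intercept=BRCO_INTERCEPT,
                       r_squared=0.97, efficiency=0.893)
        assert quantify(BRCO_INTERCEPT + BRCO_SLOPE * 2, fit) == pytest.approx(100.0)

    def test_quantify_inverts_the_curve_model_on_noiseless_data(self):
        panel = noiseless_panel()
        fit = fit_curve(panel)
        est = quantify(panel.cq, fit)
        assert np.allclose(est, panel.copies, rtol=1e-8)

    def test_requires_negative_slope(self):
        fit = CurveFit(slope=0.5, intercept=38.0, r_squared=0.9, efficiency=np.nan)
        with pytest.raises(ValueError):
            quantify(30.0, fit)


class TestEstimatorWrapper:
    def test_fit_populates_sensitivity_attributes(self):
        sc = StandardCurve().fit(noiseless_panel())
        assert sc.slope_ == pytest.approx(-3.3219, abs=1e-10)
        assert sc.low95_ == 1.0 and sc.lod_ == 1.0 and sc.loq_ == 1.0
        assert np.allclose(sc.predict([38.0]), [1.0])

    def test_get_params_round_trip(self):
        sc = StandardCurve(cv_threshold=0.2, lod_method="discrete")
        assert StandardCurve(**sc.get_params()).get_params() == sc.get_params()


def test_replicate_adjustment_reaches_target_with_more_replicates():
    assert not replicate_adjusted_lod(0.7564, 1)
    assert replicate_adjusted_lod(0.7564, 3)
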