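"""Multi-contrast grid co-refinement, profiling, and model selection."""

import numpy as np
import pytest

from monofilm.cofit import (
    ConfidenceRange,
    cofit_grid,
    cofit_single,
    confidence_ranges,
    profile_chi2,
    select_best_model,
)
from monofilm.monolayer import ContrastSpec, MonolayerParams, make_composition
from monofilm.synth import gen_reflectivity


def _dmpg_truth(n_w=1.0, d_hg=8.0, V_tail=668.0, d_tail=16.2, sigma=3.6):
    comp = make_composition("d54-DMPG:1.0")
    f = n_w * 30.0 / ((V_tail / d_tail) * d_hg)
    return MonolayerParams(composition=comp, V_tail=V_tail, d_tail=d_tail, d_hg=d_hg,
                           sigma=sigma, headgroup_solvent_fraction=f)


def _neutron_pair():
    scen = {"d54-DMPG": 2}
    return [
        ContrastSpec(radiation="neutron", subphase="D2O", exchange_scenario=scen, label="D2O"),
        ContrastSpec(radiation="neutron", subphase="ACMW", exchange_scenario=scen, label="ACMW"),
    ]


def _template(truth):
    from dataclasses import replace

    return replace(truth, d_tail=16.0, d_hg=7.0, headgroup_solvent_fraction=0.2)


class TestCofit:
    def test_noise_free_xrr_recovers_d_tail(self, xray_contrast, dmpg_params):
        """Noise-free single-curve fit lands on the true thickness to 0.5%."""
        curves, truth = gen_reflectivity(dmpg_params, [xray_contrast], noise_rel=0.0,
                                         dq_over_q=0.0, seed=0)
        res = cofit_single(curves, _template(dmpg_params), [xray_contrast],
                           sigma=dmpg_params.sigma, V_tail=dmpg_params.V_tail,
                           dq_over_q=0.0, seed=0)
        assert res.converged
        assert res.params.d_tail == pytest.approx(truth["d_tail"], rel=0.005)
        assert res.params.d_hg == pytest.approx(truth["d_hg"], rel=0.01)

    def test_two_contrast_cofit_recovers_waters(self):
        """D2O + ACMW pair at 1% noise returns n_w within +-0.3."""
        truth_p = _dmpg_truth(n_w=1.0)
        contrasts = _neutron_pair()
        curves, truth = gen_reflectivity(truth_p, contrasts, noise_rel=0.01, seed=7)
        res = cofit_single(curves, _template(truth_p), contrasts, sigma=3.6, V_tail=668.0, seed=0)
        assert res.derived.n_w == pytest.approx(truth["n_w"], abs=0.3)

    def test_refit_from_optimum_does_not_change_chi2(self):
        truth_p = _dmpg_truth()
        contrasts = _neutron_pair()
        curves, _ = gen_reflectivity(truth_p, contrasts, noise_rel=0.02, seed=3)
        res1 = cofit_single(curves, _template(truth_p), contrasts, sigma=3.6, V_tail=668.0, seed=0)
        from dataclasses import replace

        res2 = cofit_single(curves, replace(res1.params), contrasts, sigma=3.6, V_tail=668.0,
                            n_starts=1, seed=0)
        assert res2.chi2 <= res1.chi2 * (1 + 1e-6)

    def test_parameter_recovery_over_replicates(self):
        """Median |error| over seeded replicates: < 2% for both thicknesses,
        < 0.3 waters for n_w (1-3% noise, 7% dq/q)."""
        truth_p = _dmpg_truth(n_w=1.0)
        contrasts = _neutron_pair()
        errs_dt, errs_dh, errs_nw = [], [], []
        for seed in range(20):
            noise = 0.01 + 0.02 * (seed % 3) / 2.0
            curves, truth = gen_reflectivity(truth_p, contrasts, noise_rel=noise, seed=seed)
            res = cofit_single(curves, _template(truth_p), contrasts, sigma=3.6,
                               V_tail=668.0, n_starts=3, seed=seed)
            errs_dt.append(abs(res.params.d_tail - truth["d_tail"]) / truth["d_tail"])
            errs_dh.append(abs(res.params.d_hg - truth["d_hg"]) / truth["d_hg"])
            errs_nw.append(abs(res.derived.n_w - truth["n_w"]))
        assert np.median(errs_dt) < 0.02
        assert np.median(errs_dh) < 0.02
        assert np.median(errs_nw) < 0.3

    def test_cofit_not_worse_than_worst_single_contrast(self):
        """Joint refinement of two contrasts recovers the shared thickness at
        least as well as the worse of the two single-contrast fits."""
        truth_p = _dmpg_truth()
        contrasts = _neutron_pair()
        curves, truth = gen_reflectivity(truth_p, contrasts, noise_rel=0.03, seed=11)
        single_errs = []
        for c, con in zip(curves, contrasts):
            r = cofit_single([c], _template(truth_p), [con], sigma=3.6, V_tail=668.0,
                             n_starts=3, seed=1)
            single_errs.append(abs(r.params.d_tail - truth["d_tail"]))
        joint = cofit_single(curves, _template(truth_p), contrasts, sigma=3.6, V_tail=668.0,
                             n_starts=3, seed=1)
        assert abs(joint.params.d_tail - truth["d_tail"]) <= max(single_errs) + 1e-6

    def test_grid_results_sorted_by_chi2(self):
        truth_p = _dmpg_truth()
        contrasts = _neutron_pair()
        curves, _ = gen_reflectivity(truth_p, contrasts, noise_rel=0.02, seed=5)
        results = cofit_grid(curves, _template(truth_p), contrasts,
                             sigma_grid=[3.4, 3.6], vtail_grid=[660.0, 668.0],
                             n_starts=2, seed=0)
        chis = [r.chi2 for r in results]
        assert chis == sorted(chis)
        assert len(results) == 4

    def test_empty_inputs_rejected(self):
        truth_p = _dmpg_truth()
        with pytest.raises(ValueError):
            cofit_grid([], _template(truth_p), [])


class TestConfidenceRanges:
    def test_quadratic_surface_matches_gaussian_closed_form(self):
        """For a linear model y = a x + b with unit-weight residuals the
        95% profile interval equals a +- 1.96 sigma_a exactly."""
        rng = np.random.default_rng(2)
        x = np.linspace(0.0, 1.0, 50)
        sigma_y = 0.1
        y = 2.0 * x + 1.0 + rng.normal(0, sigma_y, x.size)

        def objective(theta):
            return (theta[0] * x + theta[1] - y) / sigma_y

        from scipy.optimize import least_squares

        sol = least_squares(objective, [1.0, 0.0])
        X = np.column_stack((x, np.ones_like(x))) / sigma_y
        cov = np.linalg.inv(X.T @ X)
        se_a = np.sqrt(cov[0, 0])
        lo, hi, ol, oh = profile_chi2(objective, sol.x, 0,
                                      (np.array([-10.0, -10.0]), np.array([10.0, 10.0])),
                                      delta=3.84)
        assert not ol and not oh
        assert hi - sol.x[0] == pytest.approx(1.9600 * se_a, rel=0.01)
        assert sol.x[0] - lo == pytest.approx(1.9600 * se_a, rel=0.01)

    def test_range_width_shrinks_with_noise(self):
        truth_p = _dmpg_truth()
        contrasts = _neutron_pair()
        widths = []
        for noise in (0.03, 0.003):
            curves, _ = gen_reflectivity(truth_p, contrasts, noise_rel=noise, seed=4)
            res = cofit_single(curves, _template(truth_p), contrasts, sigma=3.6,
                               V_tail=668.0, n_starts=2, seed=0)
            (cr,) = confidence_ranges(res, curves, contrasts, parameters=("d_tail",))
            assert cr.low <= res.params.d_tail <= cr.high
            widths.append(cr.high - cr.low)
        assert widths[1] < widths[0]

    def test_parameter_at_bound_flagged_open(self):
        def objective(theta):
            return np.array([theta[0] - 5.0])  # flat in theta[1]

        lo, hi, ol, oh = profile_chi2(objective, np.array([5.0]), 0,
                                      (np.array([4.9]), np.array([5.05])), delta=3.84)
        assert oh  # upper bound hit before the chi2 crossing

    def test_validation(self):
        with pytest.raises(ValueError):
            ConfidenceRange(parameter="x", best=1.0, low=2.0, high=3.0)


class TestSelectBestModel:
    def _mk(self, chi2, A_M, dmpg_params):
        from dataclasses import replace

        from monofilm.cofit import FitResult

        p = replace(dmpg_params, d_tail=dmpg_params.V_tail / A_M)
        return FitResult(params=p, scales=np.ones(1), chi2=chi2, redchi=chi2,
                         n_points=100, n_free=4, grid_point=(4.2, dmpg_params.V_tail),
                         per_dataset_chi2=[chi2])

    def test_single_candidate_returned(self, dmpg_params):
        r = self._mk(10.0, 41.0, dmpg_params)
        assert select_best_model([r], 41.2) is r

    def test_equal_chi2_tie_broken_by_area(self, dmpg_params):
        r1 = self._mk(10.0, 41.0, dmpg_params)
        r2 = self._mk(10.0, 43.0, dmpg_params)
        assert select_best_model([r2, r1], 41.2) is r1

    def test_candidate_outside_chi2_band_not_selected(self, dmpg_params):
        """5% worse chi2 but closer area loses under a 2% band."""
        good_fit = self._mk(10.0, 43.0, dmpg_params)
        close_area = self._mk(10.5, 41.2, dmpg_params)
        best = select_best_model([good_fit, close_area], 41.2, chi2_rel_tol=0.02)
        assert best is good_fit

    def test_selected_chi2_within_band_invariant(self, dmpg_params):
        rng = np.random.default_rng(1)
        results = [self._mk(float(c), float(a), dmpg_params)
                   for c, a in zip(rng.uniform(10, 20, 30), rng.uniform(39, 43, 30))]
        best = select_best_model(results, 40.8, chi2_rel_tol=0.02)
        assert best.chi2 <= 1.02 * min(r.chi2 for r in results)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([], 41.0)
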