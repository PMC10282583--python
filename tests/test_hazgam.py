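"""P-spline Poisson hazard model: basis algebra, limits, AIC selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import flymort as fm
from flymort.hazgam import CANDIDATE_SPECS, FitError, SmoothBasis
from flymort.lifetable import LifeTable


def _single_group_table(starts, D, E, bin_width=3.0):
    t = pd.DataFrame(
        {
            "isoline": "iso01",
            "sex": "female",
            "treatment": "control",
            "age_bin_start": np.asarray(starts, dtype=float),
            "D": np.asarray(D, dtype=int),
            "E": np.asarray(E, dtype=float),
        }
    )[["isoline", "sex", "treatment", "age_bin_start", "D", "E"]]
    return LifeTable(t.reset_index(drop=True), bin_width)


PLAIN = fm.HazardModelSpec("plain", fixed_terms=(), smooth_by="shared",
                           isoline_effects="none")


class TestSmoothBasis:
    def test_partition_of_unity(self):
        basis = SmoothBasis.from_range(0.0, 100.0, k=10)
        x = np.linspace(0, 100, 57)
        B = basis.design(x)
        assert B.shape == (57, 10)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_penalty_psd_with_polynomial_nullspace(self):
        basis = SmoothBasis.from_range(0.0, 50.0, k=8)
        P = basis.penalty()
        w = np.linalg.eigvalsh(P)
        assert w.min() > -1e-10
        # 2nd-order differences annihilate constant and linear coefficients
        for v in (np.ones(8), np.arange(8.0)):
            assert np.allclose(P @ v, 0.0)
        assert basis.penalty_nullspace().shape == (8, 2)

    def test_extrapolation_rejected(self):
        basis = SmoothBasis.from_range(0.0, 50.0)
        with pytest.raises(ValueError, match="extrapolation"):
            basis.design(np.array([60.0]))


class TestFitting:
    def test_constant_hazard_recovered_at_any_lambda(self):
        starts = np.arange(0, 30, 3.0)
        lt = _single_group_table(starts, D=[12] * 10, E=[480.0] * 10)
        for lam in (1e-4, 1.0, 1e6):
            fit = fm.fit_hazard_model(lt, PLAIN, lambdas=lam)
            pred = fm.predict_log_hazard(fit, starts + 1.5, "female", "control")
            assert np.allclose(pred.log_mu, np.log(12 / 480), atol=1e-6)

    def test_unpenalized_saturated_fit_matches_empirical_rates(self):
        starts = np.arange(0, 15, 3.0)
        D = [4, 7, 11, 16, 22]
        E = [300.0, 280.0, 250.0, 210.0, 160.0]
        lt = _single_group_table(starts, D, E)
        basis = SmoothBasis.from_range(1.5, 13.5, k=5)
        fit = fm.fit_hazard_model(lt, PLAIN, basis=basis, lambdas=1e-10)
        pred = fm.predict_log_hazard(fit, starts + 1.5, "female", "control")
        assert np.allclose(np.exp(pred.log_mu), np.array(D) / np.array(E), rtol=1e-6)

    def test_infinite_smoothing_gives_poisson_glm_line(self):
        # lambda -> inf with a 2nd-order penalty collapses the smooth to the
        # Gompertz straight line; cross-check against statsmodels GLM
        rng = np.random.default_rng(8)
        starts = np.arange(0, 60, 3.0)
        x = starts + 1.5
        E = np.full(x.size, 900.0)
        D = rng.poisson(np.exp(-6.0 + 0.07 * x) * E)
        lt = _single_group_table(starts, D, E)
        fit = fm.fit_hazard_model(lt, PLAIN, lambdas=1e12)
        pred = fm.predict_log_hazard(fit, x, "female", "control")
        ours = np.polyfit(x, pred.log_mu, 1)
        glm = sm.GLM(
            D, sm.add_constant(x), family=sm.families.Poisson(), offset=np.log(E)
        ).fit()
        assert ours[0] == pytest.approx(glm.params[1], abs=1e-4)
        assert ours[1] == pytest.approx(glm.params[0], abs=1e-4)

    def test_edf_monotone_in_lambda(self):
        rng = np.random.default_rng(9)
        starts = np.arange(0, 60, 3.0)
        x = starts + 1.5
        E = np.full(x.size, 600.0)
        D = rng.poisson(np.exp(-6.0 + 0.07 * x) * E)
        lt = _single_group_table(starts, D, E)
        edfs = [
            fm.fit_hazard_model(lt, PLAIN, lambdas=lam).edf
            for lam in 10.0 ** np.arange(-3, 7)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))
        # and the high-lambda limit keeps the 2-dim penalty null space
        assert edfs[-1] == pytest.approx(2.0, abs=0.01)

    def test_total_deaths_reproduced(self, study_fit, study_lifetable):
        # Poisson score equation for the intercept
        fitted = study_fit.fitted_rate() * study_lifetable.table["E"].to_numpy()
        assert fitted.sum() == pytest.approx(study_lifetable.total_deaths, rel=1e-6)

    def test_aic_consistency_of_fit_fields(self, study_fit):
        assert study_fit.aic == pytest.approx(
            -2 * study_fit.loglik + 2 * study_fit.edf
        )
        p_total = study_fit.design.p
        assert 0 < study_fit.edf < p_total
        assert all(lam >= 0 for lam in study_fit.lambdas.values())

    def test_no_deaths_rejected(self):
        lt = _single_group_table([0.0, 3.0], D=[0, 0], E=[10.0, 10.0])
        with pytest.raises(ValueError, match="no deaths"):
            fm.fit_hazard_model(lt, PLAIN, lambdas=1.0)


class TestSelection:
    def test_duplicate_candidates_tie_broken_deterministically(self, study_lifetable):
        spec = CANDIDATE_SPECS["no_isoline"]
        dup = fm.HazardModelSpec("no_isoline_b", spec.fixed_terms, spec.smooth_by,
                                 spec.isoline_effects)
        fits = fm.select_model(study_lifetable, [spec, dup])
        assert fits[0].aic == pytest.approx(fits[1].aic, abs=1e-9)
        assert fits[0].delta_aic == 0.0
        assert fits[0].edf <= fits[1].edf + 1e-9

    def test_ranking_sorted_with_delta(self, study_lifetable):
        fits = fm.select_model(study_lifetable, ["full", "no_isoline", "no_treatment"])
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)
        assert fits[0].delta_aic == 0.0
        assert all(f.delta_aic == pytest.approx(f.aic - fits[0].aic) for f in fits)

    def test_strong_frailty_favors_factor_smooths(self, study_lifetable):
        # the study cohort has sigma = 0.3; isoline structure must win
        fits = fm.select_model(study_lifetable, ["full", "no_isoline"])
        assert fits[0].spec.name == "full"

    def test_needs_two_candidates(self, study_lifetable):
        with pytest.raises(ValueError):
            fm.select_model(study_lifetable, ["full"])


class TestPrediction:
    def test_without_random_effects_modes_agree(self, study_lifetable):
        fit = fm.fit_hazard_model(study_lifetable, "no_isoline")
        ages = np.array([10.5, 30.5, 60.5])
        cond = fm.predict_log_hazard(fit, ages, "female", "control")
        per = fm.predict_log_hazard(fit, ages, "female", "control", "per_isoline")
        for curve in per.values():
            assert np.allclose(curve.log_mu, cond.log_mu)

    def test_per_isoline_curves_average_to_conditional(self, study_fit):
        # sum-to-zero constraint across isolines at every basis coefficient
        ages = np.linspace(5, 60, 12)
        cond = fm.predict_log_hazard(study_fit, ages, "male", "control")
        per = fm.predict_log_hazard(study_fit, ages, "male", "control", "per_isoline")
        mean = np.mean([c.log_mu for c in per.values()], axis=0)
        assert np.allclose(mean, cond.log_mu, atol=1e-8)

    def test_extrapolation_rejected(self, study_fit):
        with pytest.raises(ValueError, match="extrapolation"):
            fm.predict_log_hazard(study_fit, np.array([500.0]), "female", "control")

    def test_monotone_gompertz_fit_predicts_monotone_curve(self, study_fit):
        grid = fm.observable_grid(study_fit, ("female", "control"))
        lo, hi = grid.min() + 0.1 * np.ptp(grid), grid.min() + 0.9 * np.ptp(grid)
        central = grid[(grid >= lo) & (grid <= hi)]
        cond = fm.predict_log_hazard(study_fit, central, "female", "control")
        assert np.all(np.diff(cond.log_mu) > 0)
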