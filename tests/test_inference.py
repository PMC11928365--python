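"""MLE fitting, likelihood-ratio tests, model selection."""

import numpy as np
import pytest
from scipy.stats import chi2

from tsce.inference import FitResult, ModelSpec, fit_mle, lrt, select_model
from tsce.likelihood import cohort_loglik
from tsce.params import REFERENCE_PARAMS
from tsce.synthetic import generate_cohort, single_group_config
from tsce.validation import single_group_spec


@pytest.fixture(scope="module")
def small_fit(small_cohort):
    return fit_mle(small_cohort, single_group_spec(), seed=0, n_starts=2)


class TestModelSpec:
    def test_parameter_naming(self):
        spec = ModelSpec(sharing={"mu0": "by_race", "g": "shared",
                                  "g_c": "by_gender",
                                  "mu1_c": "by_race_gender"})
        names = spec.param_names()
        assert "mu0[NHB]" in names and "g[all]" in names
        assert "g_c[female]" in names and "mu1_c[NHW:male]" in names
        assert spec.k == 2 + 1 + 2 + 4

    def test_nesting_partial_order(self):
        shared = ModelSpec(sharing={p: "shared"
                                    for p in ("mu0", "g", "g_c", "mu1_c")})
        by_rg = ModelSpec()
        by_race = ModelSpec(sharing={"mu0": "by_race", "g": "by_race",
                                     "g_c": "by_race", "mu1_c": "by_race"})
        assert shared.is_nested_in(by_race)
        assert by_race.is_nested_in(by_rg)
        assert not by_rg.is_nested_in(by_race)
        by_gender = ModelSpec(sharing={"mu0": "by_gender", "g": "by_gender",
                                       "g_c": "by_gender",
                                       "mu1_c": "by_gender"})
        assert not by_race.is_nested_in(by_gender)

    def test_build_params_routes_levels(self):
        spec = ModelSpec(sharing={"mu0": "by_race", "g": "shared",
                                  "g_c": "shared", "mu1_c": "shared"})
        est = {"mu0[NHB]": 4e-7, "mu0[NHW]": 1e-7, "g[all]": 0.05,
               "g_c[all]": 0.3, "mu1_c[all]": 0.3}
        by_group = spec.build_params(est)
        assert by_group[("NHB", "male")].mu0 == 4e-7
        assert by_group[("NHW", "female")].mu0 == 1e-7
        assert by_group[("NHW", "male")].g == 0.05

    def test_aic_identity(self, small_fit):
        assert small_fit.aic == pytest.approx(
            2 * small_fit.k - 2 * small_fit.loglik)


class TestFitMle:
    def test_estimate_at_optimum_beats_neighbours(self, small_cohort,
                                                  small_fit):
        """The fitted point is a local maximum of the cohort likelihood."""
        spec = single_group_spec()
        best = cohort_loglik(small_cohort,
                             spec.build_params(small_fit.estimates))
        for name in small_fit.estimates:
            for fac in (0.9, 1.1):
                est = dict(small_fit.estimates)
                est[name] *= fac
                assert cohort_loglik(small_cohort,
                                     spec.build_params(est)) <= best + 1e-6

    def test_profile_matches_grid_search(self, small_cohort):
        """1-D MLE in g (others at truth) agrees with a brute-force grid."""
        truth = REFERENCE_PARAMS[("NHB", "male")]
        grid = np.linspace(0.02, 0.09, 141)
        vals = [cohort_loglik(small_cohort, truth.with_updates(g=g))
                for g in grid]
        g_grid = grid[int(np.argmax(vals))]
        # quasi-Newton on the same 1-D profile
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(
            lambda lg: -cohort_loglik(small_cohort,
                                      truth.with_updates(g=np.exp(lg))),
            bounds=(np.log(0.02), np.log(0.09)), method="bounded")
        assert abs(np.exp(res.x) - g_grid) <= (grid[1] - grid[0])

    def test_deterministic_given_seed(self, small_cohort):
        spec = single_group_spec()
        a = fit_mle(small_cohort, spec, seed=5, n_starts=2)
        b = fit_mle(small_cohort, spec, seed=5, n_starts=2)
        assert a.estimates == b.estimates

    def test_reports_convergence_metadata(self, small_fit):
        assert small_fit.converged
        assert small_fit.n_iter > 0
        assert np.isfinite(small_fit.grad_norm)


class TestLrt:
    def test_identical_models_statistic_zero(self, small_fit):
        stat, df, p = lrt(small_fit, small_fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_chi_square_reference_value(self, small_fit):
        """3.84 on 1 df sits at the 5% tail."""
        assert chi2.sf(3.84, 1) == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self, small_fit):
        by_race = ModelSpec(sharing={"mu0": "by_race", "g": "by_race",
                                     "g_c": "by_race", "mu1_c": "by_race"})
        other = FitResult(spec=by_race, estimates={}, loglik=-1.0,
                          converged=True, n_iter=1, grad_norm=0.0,
                          n_starts=1, seed=0)
        with pytest.raises(ValueError):
            lrt(other, small_fit)

    def test_full_model_never_fits_worse(self, small_cohort, small_fit):
        """Monotone refinement: more free parameters, no worse likelihood."""
        richer = ModelSpec(sharing={"mu0": "shared", "g": "shared",
                                    "g_c": "shared", "mu1_c": "shared"},
                           initiation_effect=True)
        full = fit_mle(small_cohort, richer, seed=0, n_starts=2,
                       start=dict(small_fit.estimates, **{"mu0_c[all]": 1e-6}))
        assert full.loglik >= small_fit.loglik - 1e-6
        stat, df, p = lrt(small_fit, full)
        assert stat >= 0.0 and df == 1 and 0.0 <= p <= 1.0


class TestNullCalibration:
    def test_spurious_initiation_effect_rarely_significant(self):
        """Data with no smoking effect on initiation: adding one should not
        look significant (and should usually worsen AIC)."""
        base = single_group_spec()
        richer = ModelSpec(sharing=dict(base.sharing), initiation_effect=True,
                           name="with_initiation")
        rejections = 0
        aic_worse = 0
        n_reps = 8
        for seed in range(n_reps):
            cohort = generate_cohort(
                single_group_config("NHB", "male", 4000, seed=100 + seed))
            f0 = fit_mle(cohort, base, seed=seed, n_starts=1)
            f1 = fit_mle(cohort, richer, seed=seed, n_starts=1,
                         start=dict(f0.estimates, **{"mu0_c[all]": 1e-6}))
            stat, df, p = lrt(f0, f1)
            rejections += p < 0.05
            aic_worse += f1.aic > f0.aic
        assert rejections <= 2  # ~binomial(8, 0.05) upper tail
        assert aic_worse >= n_reps // 2


class TestSelectModel:
    def test_single_candidate_returned(self, small_cohort):
        table = select_model(small_cohort, [single_group_spec()], seed=0,
                             n_starts=1)
        assert len(table) == 1
        assert table.iloc[0]["delta_aic"] == 0.0

    def test_ranking_and_lrt_annotation(self, small_cohort):
        base = single_group_spec()
        richer = ModelSpec(sharing=dict(base.sharing), initiation_effect=True,
                           name="with_initiation")
        table = select_model(small_cohort, [base, richer], seed=0, n_starts=1)
        assert list(table["aic"]) == sorted(table["aic"])
        # the runner-up is nested in or nests the winner; LRT filled when nested
        runner = table.iloc[1]
        if runner["name"] == "single_group":
            assert np.isfinite(runner["lrt_stat"])

    def test_empty_candidates_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            select_model(small_cohort, [])
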