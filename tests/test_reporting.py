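"""Incidence tables, scenario curves, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

from tsce.exposure import DoseHistory
from tsce.likelihood import Cohort, Individual
from tsce.params import REFERENCE_PARAMS
from tsce.reporting import (Scenario, observed_incidence, poisson_rate_ci,
                            predicted_hazard_curve, relative_risk_curve)


def plain_individual(id, ae, al, case=False):
    return Individual(id=id, race="NHB", gender="male", entry_age=ae,
                      exit_age=al, is_case=case, dose_history=DoseHistory())


class TestObservedIncidence:
    def test_single_individual_person_years(self):
        coh = Cohort([plain_individual("a", 60.0, 70.0)])
        tab = observed_incidence(coh)
        by_bin = tab.set_index("age_lo")["person_years"]
        assert by_bin[60.0] == pytest.approx(5.0)
        assert by_bin[65.0] == pytest.approx(5.0)
        assert tab["events"].sum() == 0

    def test_person_year_conservation(self, small_cohort):
        tab = observed_incidence(small_cohort)
        total = sum(i.exit_age - i.entry_age for i in small_cohort)
        assert tab["person_years"].sum() == pytest.approx(total, abs=1e-9)

    def test_event_assigned_to_exit_bin(self):
        coh = Cohort([plain_individual("a", 60.0, 67.0, case=True)])
        tab = observed_incidence(coh).set_index("age_lo")
        assert tab.loc[65.0, "events"] == 1
        assert tab.loc[60.0, "events"] == 0

    def test_zero_event_bin_upper_ci(self):
        """0 events in 1000 PY: exact Poisson upper bound 3.6889 events."""
        lo, hi = poisson_rate_ci(0, 1000.0)
        assert lo == 0.0
        assert hi == pytest.approx(368.9, abs=0.1)

    def test_rate_arithmetic(self):
        coh = Cohort([plain_individual(f"i{k}", 60.0, 70.0, case=(k < 4))
                      for k in range(1000)])
        tab = observed_incidence(coh)
        # 4 events / 10,000 PY -> 40 per 100k
        assert tab["events"].sum() == 4
        assert tab["person_years"].sum() == pytest.approx(10_000.0)
        pooled = 1e5 * tab["events"].sum() / tab["person_years"].sum()
        assert pooled == pytest.approx(40.0)

    def test_ci_contains_rate(self, small_cohort):
        tab = observed_incidence(small_cohort)
        pos = tab[tab["events"] > 0]
        assert ((pos["ci_lo"] <= pos["rate"]) & (pos["rate"] <= pos["ci_hi"])).all()

    def test_bad_bin_width(self, small_cohort):
        with pytest.raises(ValueError):
            observed_incidence(small_cohort, bin_width=0.0)


class TestCurves:
    def test_never_scenario_equals_background(self, nhb_male,
                                              background_schedule):
        from tsce.core import solve_tsce

        curve = predicted_hazard_curve(nhb_male, Scenario.never(),
                                       ages=[60.0, 70.0, 80.0])
        for age, hz in zip(curve["age"], curve["hazard"]):
            assert hz == pytest.approx(1e5 * solve_tsce(background_schedule,
                                                        age).h, rel=1e-10)

    def test_heavier_smoking_higher_hazard(self, nhb_male):
        ages = np.arange(30.0, 95.0)
        h20 = predicted_hazard_curve(nhb_male, Scenario.smoker(20), ages)
        h40 = predicted_hazard_curve(nhb_male, Scenario.smoker(40), ages)
        assert (h40["hazard"].to_numpy() >= h20["hazard"].to_numpy()).all()

    def test_nhb_never_exceeds_nhw_never(self, nhb_male, nhw_male):
        ages = np.arange(40.0, 91.0)
        hb = predicted_hazard_curve(nhb_male, Scenario.never(), ages)
        hw = predicted_hazard_curve(nhw_male, Scenario.never(), ages)
        assert (hb["hazard"].to_numpy() > hw["hazard"].to_numpy()).all()

    def test_identical_scenarios_unit_ratio(self, nhb_male):
        rr = relative_risk_curve(nhb_male, Scenario.smoker(20),
                                 Scenario.smoker(20), ages=np.arange(1.0, 90.0))
        np.testing.assert_allclose(rr["ratio"], 1.0, rtol=1e-12)

    def test_smoker_rr_rises_then_declines(self, nhb_male):
        rr = relative_risk_curve(nhb_male, Scenario.smoker(20),
                                 Scenario.never(),
                                 ages=np.arange(25.0, 100.0))
        r = rr["ratio"].to_numpy()
        peak = int(np.argmax(r))
        assert 0 < peak < len(r) - 1
        assert r[-1] < r[peak]
        assert r[peak] > 1.0

    def test_quit_reduces_risk_progressively(self, nhb_male):
        rr = relative_risk_curve(nhb_male, Scenario.quitter(20, quit_age=50.0),
                                 Scenario.smoker(20),
                                 ages=np.arange(51.0, 90.0))
        r = rr["ratio"].to_numpy()
        assert (r < 1.0).all()
        assert (np.diff(r) < 0).all()

    def test_cross_group_labelled_hazard_ratio(self, nhb_male, nhw_male):
        hr = relative_risk_curve(nhb_male, Scenario.smoker(20),
                                 Scenario.smoker(20), params_b=nhw_male,
                                 ages=np.arange(40.0, 90.0))
        assert (hr["kind"] == "hazard_ratio").all()
        assert (hr["ratio"] > 1.0).all()

    def test_age_grid_validation(self, nhb_male):
        with pytest.raises(ValueError):
            predicted_hazard_curve(nhb_male, Scenario.never(), ages=[0.0, 50.0])


class TestPipeline:
    def test_end_to_end_smoke(self, tmp_path):
        """Minimal config runs every stage and all outputs parse."""
        from tsce.io import PipelineConfig
        from tsce.reporting import run_pipeline
        from tsce.synthetic import single_group_config
        from tsce.validation import single_group_spec

        cfg = PipelineConfig(
            generator=single_group_config("NHB", "male", 2000, seed=31),
            spec=single_group_spec(), n_starts=1, mcmc_steps=1000)
        out = run_pipeline(cfg, tmp_path / "run1")
        for fname in ("cohort.csv", "fit.json", "chain.csv", "ci.csv",
                      "incidence_observed.csv", "hazard_curves.csv", "run.log"):
            assert (out / fname).exists(), fname
        ci = pd.read_csv(out / "ci.csv")
        assert (ci["lo"] < ci["hi"]).all()
        import json
        fit = json.loads((out / "fit.json").read_text())
        assert fit["converged"]

    def test_rerun_same_seed_identical(self, tmp_path):
        from tsce.io import PipelineConfig
        from tsce.reporting import run_pipeline
        from tsce.synthetic import single_group_config
        from tsce.validation import single_group_spec

        cfg = PipelineConfig(
            generator=single_group_config("NHB", "male", 1000, seed=41),
            spec=single_group_spec(), n_starts=1, mcmc_steps=1000)
        a = run_pipeline(cfg, tmp_path / "a")
        b = run_pipeline(cfg, tmp_path / "b")
        for fname in ("cohort.csv", "fit.json", "chain.csv", "ci.csv"):
            assert (a / fname).read_bytes() == (b / fname).read_bytes(), fname


class TestSensitivity:
    def test_censoring_window_sweep_recovers_consistently(self):
        """Fits under 5/10/15/30-year censoring agree within simulation error."""
        from tsce.inference import fit_mle
        from tsce.synthetic import generate_cohort, single_group_config
        from tsce.validation import single_group_spec

        truth = REFERENCE_PARAMS[("NHB", "male")]
        spec = single_group_spec()
        est = {}
        for window in (5.0, 10.0, 15.0, 30.0):
            cfg = single_group_config("NHB", "male", 6000, seed=51,
                                      censor_window=window)
            fit = fit_mle(generate_cohort(cfg), spec, seed=51, n_starts=1)
            assert fit.converged
            est[window] = fit.estimates
        for name in ("mu0[all]", "g[all]"):
            vals = np.array([est[w][name] for w in est])
            assert vals.max() / vals.min() < 2.0
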