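"""Random-slope model fitting: engines, recovery, contrasts."""

import numpy as np
import pandas as pd
import pytest

from trialpower import lme
from trialpower import _reml

from conftest import balanced_lme_table


class TestEngineAgreement:
    """The native profiled-REML solver against statsmodels MixedLM.

    Both maximise the same restricted likelihood, so the native solution
    must never score worse; whenever both optimisers land on the same
    optimum the estimates must coincide to optimiser tolerance.  (MixedLM
    occasionally stops at an inferior local solution on unbalanced data,
    which is its own limitation, not a disagreement about the model.)
    """

    @staticmethod
    def _criterion(table, fit):
        g = table.subject_id.to_numpy()
        t = table.visit_month.to_numpy() / 12.0
        y = table.value.to_numpy()
        patterns, _, _ = _reml._collect(g, t, y, None)
        stacked = _reml._Stacked(patterns)
        G = np.array(
            [[fit.sigma_b0_sq, fit.cov_b0b1], [fit.cov_b0b1, fit.sigma_b1_sq]]
        ) / fit.sigma_w_sq
        return _reml._neg2_reml(stacked, G, 2, t.size)[0]

    @pytest.mark.parametrize("seed, missing", [(3, 0.0), (4, 0.3), (5, 0.15)])
    def test_slope_model(self, seed, missing):
        table = balanced_lme_table(150, (0, 6, 12, 24, 36), seed=seed)
        if missing:
            rng = np.random.default_rng(seed)
            drop = (rng.random(len(table)) < missing) & (table.visit_month > 0)
            table = table[~drop]
        table = table.dropna()
        a = lme.fit_slope_model(table, engine="native")
        b = lme.fit_slope_model(table, engine="statsmodels")
        crit_a = self._criterion(table, a)
        crit_b = self._criterion(table, b)
        assert crit_a <= crit_b + 1e-4  # native never beaten on its own objective
        if abs(crit_a - crit_b) < 1e-3:  # same optimum: estimates must agree
            assert a.beta1 == pytest.approx(b.beta1, abs=1e-5)
            assert a.beta0 == pytest.approx(b.beta0, abs=1e-5)
            assert a.sigma_w_sq == pytest.approx(b.sigma_w_sq, rel=5e-3)
            assert a.sigma_b1_sq == pytest.approx(b.sigma_b1_sq, rel=1e-2, abs=1e-5)
            assert a.se_beta1 == pytest.approx(b.se_beta1, rel=5e-3)

    def test_interaction_model(self):
        t1 = balanced_lme_table(80, (0, 6, 12, 24), beta1=-0.2, seed=10)
        t2 = balanced_lme_table(80, (0, 6, 12, 24), beta1=-0.1, seed=11)
        t2 = t2.assign(subject_id="X" + t2.subject_id)
        table = pd.concat(
            [t1.assign(group="a"), t2.assign(group="b")], ignore_index=True
        )
        a = lme.fit_group_interaction(table, "a", "b", engine="native")
        b = lme.fit_group_interaction(table, "a", "b", engine="statsmodels")
        assert a.delta_beta == pytest.approx(b.delta_beta, abs=1e-5)
        assert a.se == pytest.approx(b.se, rel=2e-3)
        assert a.baseline_diff == pytest.approx(b.baseline_diff, abs=1e-5)


class TestFitSlopeModel:
    @pytest.mark.parametrize("engine", ["native", "statsmodels"])
    def test_degenerate_common_line(self, engine):
        # every subject lies exactly on 2 - 0.5 t: variances collapse
        months = np.array([0.0, 6.0, 12.0, 24.0])
        table = pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{i}" for i in range(12)], months.size),
                "visit_month": np.tile(months, 12),
                "value": np.tile(2.0 - 0.5 * months / 12.0, 12),
            }
        )
        fit = lme.fit_slope_model(table, engine=engine)
        assert fit.beta1 == pytest.approx(-0.5, abs=1e-6)
        assert fit.beta0 == pytest.approx(2.0, abs=1e-6)
        assert fit.sigma_w_sq == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma_b1_sq == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_large_cohort(self):
        table = balanced_lme_table(
            500, (0, 6, 12, 24, 36, 48, 60),
            beta1=-0.20, sigma_b1=0.10, sigma_w=0.30, seed=42,
        )
        fit = lme.fit_slope_model(table, engine="native")
        assert fit.converged
        assert fit.beta1 == pytest.approx(-0.20, rel=0.05)
        assert fit.sigma_w_sq == pytest.approx(0.09, rel=0.05)
        assert fit.sigma_b1_sq == pytest.approx(0.01, rel=0.15)

    def test_duplication_leaves_point_estimates_unchanged(self):
        table = balanced_lme_table(60, (0, 6, 12, 24), seed=5)
        doubled = pd.concat(
            [table, table.assign(subject_id="D" + table.subject_id)],
            ignore_index=True,
        )
        f1 = lme.fit_slope_model(table, engine="native")
        f2 = lme.fit_slope_model(doubled, engine="native")
        assert f2.beta1 == pytest.approx(f1.beta1, abs=1e-6)
        assert f2.beta0 == pytest.approx(f1.beta0, abs=1e-6)

    def test_location_invariances(self):
        table = balanced_lme_table(100, (0, 6, 12, 24), seed=6)
        f1 = lme.fit_slope_model(table, engine="native")
        f2 = lme.fit_slope_model(table.assign(value=table.value + 5.0), engine="native")
        assert f2.sigma_w_sq == pytest.approx(f1.sigma_w_sq, rel=1e-6)
        assert f2.beta1 == pytest.approx(f1.beta1, abs=1e-8)
        assert f2.beta0 == pytest.approx(f1.beta0 + 5.0, abs=1e-6)

    def test_time_rescaling_scales_slope_terms(self):
        table = balanced_lme_table(100, (0, 6, 12, 24), seed=8)
        t_years = table.visit_month.to_numpy() / 12.0
        y = table.value.to_numpy()
        g = table.subject_id.to_numpy()
        yearly = _reml.reml_fit(g, t_years, y)
        monthly = _reml.reml_fit(g, t_years * 12.0, y)
        assert monthly.beta[1] * 12 == pytest.approx(yearly.beta[1], rel=1e-4)
        assert monthly.cov_re[1, 1] * 144 == pytest.approx(
            yearly.cov_re[1, 1], rel=5e-3
        )
        assert monthly.sigma_w_sq == pytest.approx(yearly.sigma_w_sq, rel=1e-4)

    def test_insufficient_data_raises(self):
        table = pd.DataFrame(
            {"subject_id": ["a", "a"], "visit_month": [0, 12], "value": [1.0, 2.0]}
        )
        with pytest.raises(lme.InsufficientDataError):
            lme.fit_slope_model(table)

    def test_intercept_only_structure_pins_slope_variance(self):
        table = balanced_lme_table(80, (0, 6, 12, 24), sigma_b1=0.0, seed=9)
        res = _reml.reml_fit(
            table.subject_id.to_numpy(),
            table.visit_month.to_numpy() / 12.0,
            table.value.to_numpy(),
            structure="intercept_only",
        )
        assert res.cov_re[1, 1] == 0.0
        assert res.converged


class TestGroupInteraction:
    def make_two_group(self, delta=0.04, n=400, seed=21):
        a = balanced_lme_table(n, (0, 6, 12, 24, 36, 48), beta1=0.10, seed=seed)
        b = balanced_lme_table(
            n, (0, 6, 12, 24, 36, 48), beta1=0.10 + delta, seed=seed + 1
        )
        b = b.assign(subject_id="X" + b.subject_id)
        return pd.concat(
            [a.assign(group="control"), b.assign(group="preclinical_ad")],
            ignore_index=True,
        )

    def test_recovers_small_slope_contrast(self):
        table = self.make_two_group(delta=0.04)
        c = lme.fit_group_interaction(table, "control", "preclinical_ad", engine="native")
        assert c.converged
        assert abs(c.delta_beta - 0.04) < 2.5 * c.se  # inside the Wald CI

    def test_relabeling_flips_sign_exactly(self):
        table = self.make_two_group(delta=0.1, n=80)
        c1 = lme.fit_group_interaction(table, "control", "preclinical_ad", engine="native")
        c2 = lme.fit_group_interaction(table, "preclinical_ad", "control", engine="native")
        assert c1.delta_beta == pytest.approx(-c2.delta_beta, abs=1e-6)
        assert c1.p_value == pytest.approx(c2.p_value, abs=1e-6)

    def test_missing_group_rejected(self):
        table = self.make_two_group(n=30)
        with pytest.raises(lme.InsufficientDataError):
            lme.fit_group_interaction(table, "control", "mild_ad")


class TestExtractPowerInputs:
    FIT = lme.LMEFit(
        beta0=0.0, beta1=-0.20, se_beta1=0.02, sigma_b0_sq=0.8,
        sigma_b1_sq=0.01, cov_b0b1=0.0, sigma_w_sq=0.09, n_subjects=100,
        n_obs=500, converged=True, method="native:unstructured",
    )
    CONTROL = lme.LMEFit(
        beta0=0.0, beta1=-0.05, se_beta1=0.02, sigma_b0_sq=0.8,
        sigma_b1_sq=0.02, cov_b0b1=0.0, sigma_w_sq=0.10, n_subjects=100,
        n_obs=500, converged=True, method="native:unstructured",
    )

    def test_full_mechanism_uses_group_slope(self):
        sw2, sb2, slope = lme.extract_power_inputs(self.FIT, None, "full")
        assert (sw2, sb2, slope) == (0.09, 0.01, -0.20)

    def test_disease_specific_subtracts_control(self):
        _, sb2, slope = lme.extract_power_inputs(
            self.FIT, self.CONTROL, "disease_specific"
        )
        assert slope == pytest.approx(-0.15)
        assert sb2 == 0.01  # group's slope variance regardless of mechanism

    def test_disease_specific_requires_control(self):
        with pytest.raises(ValueError):
            lme.extract_power_inputs(self.FIT, None, "disease_specific")

    def test_nonconverged_fit_refused(self):
        from dataclasses import replace

        bad = replace(self.FIT, converged=False)
        with pytest.raises(lme.NotConvergedError):
            lme.extract_power_inputs(bad, None, "full")
        sw2, _, _ = lme.extract_power_inputs(bad, None, "full", force=True)
        assert sw2 == 0.09
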