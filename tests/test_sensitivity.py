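"""Sensitivity variants, chained-equations imputation and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

from trialcea import GeneratorConfig, TrialData, generate
from trialcea.dataset import build_analysis_dataset, complete_cases
from trialcea.inference import cluster_bootstrap
from trialcea.programme import add_programme_cost
from trialcea.sensitivity import SensitivityConfig, impute, pool, run_variant
from trialcea.synthetic import MissingnessConfig


@pytest.fixture(scope="module")
def trial_data():
    trial = generate(GeneratorConfig(n_schools=30, pupils_per_school_mean=40, seed=11))
    return TrialData(waves=trial.waves, pupils=trial.pupils)


@pytest.fixture(scope="module")
def variant_rows(trial_data):
    rows = {}
    for v in ("complete_case_primary", "costs_up_5", "costs_down_5",
              "discount_1_5", "cluster_only"):
        rows[v] = run_variant(SensitivityConfig(variant=v, seed=4, B=60), trial_data)
    return rows


class TestPooling:
    def test_zero_between_variance(self):
        p = pool([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert p.estimate == 2.0
        assert p.variance == pytest.approx(1.0)

    def test_closed_form_with_between_variance(self):
        p = pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert p.estimate == 2.0
        assert p.variance == pytest.approx(1.0 + (1 + 1 / 3) * 1.0)
        assert p.ci[0] < 2.0 < p.ci[1]

    def test_order_invariance_and_errors(self):
        assert pool([3.0, 1.0, 2.0], [1.0, 1.0, 1.0]).estimate == pool(
            [1.0, 2.0, 3.0], [1.0, 1.0, 1.0]
        ).estimate
        with pytest.raises(ValueError, match="equal length"):
            pool([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="m >= 2"):
            pool([1.0], [1.0])


class TestImpute:
    def test_no_missingness_is_identity(self, trial_data):
        analysis = complete_cases(build_analysis_dataset(trial_data))
        analysis = analysis.drop(columns=["education_cost", "health_cost", "criminal_cost"])
        for d in impute(analysis, m=2, seed=0):
            pd.testing.assert_frame_equal(d, analysis)

    def test_pmm_only_borrows_observed_values(self):
        rng = np.random.default_rng(5)
        n = 120
        frame = pd.DataFrame(
            {
                "arm": np.where(rng.random(n) < 0.5, "intervention", "control"),
                "location": "NI",
                "fsm_band": "low",
                "school_type": "coed",
                "baseline_cost": rng.gamma(2, 50, n).round(2),
                "baseline_hed": rng.integers(0, 2, n),
                "hed33": rng.integers(0, 2, n).astype(float),
                "total_cost": rng.gamma(2, 800, n).round(2),
            }
        )
        missing = rng.random(n) < 0.3
        observed_values = set(frame.loc[~missing, "total_cost"])
        frame.loc[missing, "total_cost"] = np.nan
        for d in impute(frame, m=3, seed=1):
            assert set(d.loc[missing, "total_cost"]) <= observed_values

    def test_deterministic_given_seed(self, trial_data):
        analysis = build_analysis_dataset(trial_data).drop(
            columns=["education_cost", "health_cost", "criminal_cost"]
        )
        a = impute(analysis, m=2, seed=42)
        b = impute(analysis, m=2, seed=42)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_all_missing_variable_rejected(self):
        frame = pd.DataFrame(
            {
                "arm": ["intervention", "control"] * 4,
                "location": "NI",
                "fsm_band": "low",
                "school_type": "coed",
                "baseline_cost": 1.0,
                "baseline_hed": 0,
                "hed33": [np.nan] * 8,
                "total_cost": 1.0,
            }
        )
        with pytest.raises(ValueError, match="no observed values"):
            impute(frame, m=2, seed=0)

    def test_mcar_pooled_effect_near_complete_case(self):
        """Under MCAR the pooled MI risk difference tracks the complete-case
        one within Monte-Carlo tolerance."""
        config = GeneratorConfig(
            n_schools=40,
            pupils_per_school_mean=60,
            seed=77,
            missingness=MissingnessConfig(
                mechanism="MCAR", wave_missing_base_prob=0.05, outcome_missing_base_prob=0.08
            ),
        )
        trial = generate(config)
        td = TrialData(waves=trial.waves, pupils=trial.pupils)
        cc_row = run_variant(SensitivityConfig(variant="complete_case_primary", seed=1, B=40), td)
        mi_row = run_variant(SensitivityConfig(variant="multiple_imputation", seed=1, m=5), td)
        assert mi_row["delta_e"] == pytest.approx(cc_row["delta_e"], abs=0.03)


class TestVariants:
    def test_cost_scaling_is_exactly_linear(self, variant_rows):
        base = variant_rows["complete_case_primary"]
        up = variant_rows["costs_up_5"]
        down = variant_rows["costs_down_5"]
        assert up["delta_c"] == pytest.approx(1.05 * base["delta_c"], rel=1e-12)
        assert down["delta_c"] == pytest.approx(0.95 * base["delta_c"], rel=1e-12)
        assert np.allclose(up["ci_c"], np.array(base["ci_c"]) * 1.05)
        assert np.allclose(down["ci_c"], np.array(base["ci_c"]) * 0.95)

    def test_cost_scaling_leaves_effects_untouched(self, variant_rows):
        base = variant_rows["complete_case_primary"]
        for v in ("costs_up_5", "costs_down_5"):
            assert variant_rows[v]["delta_e"] == base["delta_e"]
            assert variant_rows[v]["ci_e"] == base["ci_e"]

    def test_lower_discount_rate_matches_independent_rerun(self, trial_data, variant_rows):
        """The 1.5% variant equals re-running the whole chain at 1.5% and
        scaling the outcome by (1.015)^-2."""
        analysis = build_analysis_dataset(trial_data, discount_rate=0.015)
        cc = add_programme_cost(complete_cases(analysis), 15.0)
        est = cluster_bootstrap(cc, B=60, seed=4)
        row = variant_rows["discount_1_5"]
        assert row["delta_c"] == pytest.approx(est.delta_c, rel=1e-12)
        assert row["delta_e"] == pytest.approx(est.delta_e * 1.015**-2, rel=1e-12)

    def test_cluster_only_drops_covariates(self, trial_data, variant_rows):
        analysis = build_analysis_dataset(trial_data)
        cc = add_programme_cost(complete_cases(analysis), 15.0)
        est = cluster_bootstrap(cc, B=60, seed=4, adjusted=False)
        assert variant_rows["cluster_only"]["delta_c"] == pytest.approx(est.delta_c)

    def test_variants_reproducible_for_fixed_seed(self, trial_data, variant_rows):
        again = run_variant(
            SensitivityConfig(variant="complete_case_primary", seed=4, B=60), trial_data
        )
        base = variant_rows["complete_case_primary"]
        assert again["delta_c"] == base["delta_c"]
        assert again["ci_e"] == base["ci_e"]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            SensitivityConfig(variant="bogus")
        with pytest.raises(ValueError, match="m >= 2"):
            SensitivityConfig(variant="multiple_imputation", m=1)
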