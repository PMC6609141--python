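import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trialcea import GeneratorConfig, TrialData, UnitCostTable, generate
from trialcea.dataset import build_analysis_dataset, complete_cases

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

# degenerate bootstrap resamples at small scale are expected; keep logs quiet
logging.getLogger("trialcea.inference").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def unit_table() -> UnitCostTable:
    return UnitCostTable.default()


@pytest.fixture(scope="session")
def small_trial():
    """One simulated trial at reduced scale (30 schools x 40 pupils)."""
    return generate(GeneratorConfig(n_schools=30, pupils_per_school_mean=40, seed=20))


@pytest.fixture(scope="session")
def small_analysis(small_trial):
    trial_data = TrialData(waves=small_trial.waves, pupils=small_trial.pupils)
    return build_analysis_dataset(trial_data)


@pytest.fixture(scope="session")
def small_cc(small_analysis):
    return complete_cases(small_analysis)


def make_waves(rows: dict) -> pd.DataFrame:
    """Wide wave frame from {(pupil, wave): {service: count}}; absent
    (pupil, wave) keys are wave-missing."""
    records = []
    for (pupil, wave), counts in rows.items():
        records.append({"pupil_id": pupil, "wave": wave, **counts})
    return pd.DataFrame(records)


def two_arm_frame(costs_int, costs_ctl, hed_int=None, hed_ctl=None, pupils_per_school=1):
    """Tiny hand-built analysis dataset: one school per pupil group, two+
    schools per arm, balanced school-level covariates."""
    rows = []
    for arm, costs, heds in (
        ("intervention", costs_int, hed_int),
        ("control", costs_ctl, hed_ctl),
    ):
        n_schools = max(2, len(costs) // max(pupils_per_school, 1))
        for i, c in enumerate(costs):
            h = heds[i] if heds is not None else 0
            s = i % n_schools  # school-level covariates keyed by school index
            rows.append(
                {
                    "pupil_id": f"{arm[:3]}{i}",
                    "school_id": f"{arm[:3]}_{s}",
                    "arm": arm,
                    "location": "NI" if s % 2 == 0 else "Scotland",
                    "fsm_band": ("low", "moderate", "high")[s % 3],
                    "school_type": "coed",
                    "baseline_cost": 10.0 * (i % 4),
                    "baseline_hed": i % 2,
                    "total_cost": float(c),
                    "hed33": float(h),
                    "complete": True,
                }
            )
    return pd.DataFrame(rows)
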