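"""Assembly of the pupil-level analysis dataset from costed waves.

``TrialData`` bundles the raw ingredients (service-use waves, pupil frame,
unit-cost table); ``build_analysis_dataset`` prices the waves, merges in
covariates and outcomes, and flags complete cases (all four cost windows
observed *and* the 33-month outcome answered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .costing import UnitCostTable, build_cost_dataset

__all__ = ["TrialData", "build_analysis_dataset", "complete_cases"]

PUPIL_COLUMNS = [
    "pupil_id",
    "school_id",
    "arm",
    "location",
    "fsm_band",
    "school_type",
    "baseline_hed",
    "hed33",
]


@dataclass
class TrialData:
    """Raw trial ingredients, before costing."""

    waves: pd.DataFrame  # wide: pupil_id, wave, one column per service
    pupils: pd.DataFrame  # PUPIL_COLUMNS (hed33 may be NaN = outcome missing)
    table: UnitCostTable = field(default_factory=UnitCostTable.default)
    discount_rate: float = 0.035


def build_analysis_dataset(trial: TrialData, discount_rate: float | None = None) -> pd.DataFrame:
    """Pupil-level analysis frame.

    Columns: identifiers and covariates, ``baseline_cost`` (pre-baseline
    window, anchor only), ``total_cost`` (discounted 33-month public-sector
    cost; NaN when any window missing), sector totals, auxiliary MI
    variables (``cost_m7_12``, ``hed12`` when available) and ``complete``.
    """
    rate = trial.discount_rate if discount_rate is None else discount_rate
    costs = build_cost_dataset(trial.waves, trial.table, annual_rate=rate)
    missing_cols = set(PUPIL_COLUMNS) - set(trial.pupils.columns)
    if missing_cols:
        raise ValueError(f"pupil frame missing columns: {sorted(missing_cols)}")
    keep = [c for c in trial.pupils.columns if c in PUPIL_COLUMNS + ["hed12", "sex"]]
    out = trial.pupils[keep].merge(costs, on="pupil_id", how="left")
    # pupils with no wave rows at all never appear in `costs`
    out["complete"] = out["complete"].notna() & out["complete"].eq(True)
    out["complete"] &= out["hed33"].notna()  # cost windows AND outcome observed
    out = out.rename(columns={"total_discounted": "total_cost"})
    return out


def complete_cases(analysis: pd.DataFrame) -> pd.DataFrame:
    return analysis.loc[analysis["complete"]].reset_index(drop=True)
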