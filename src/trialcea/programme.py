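"""Programme (intervention) costing.

The intervention's resource ledger is split into stage 1 (planning and
preparation: materials, teacher training) and stage 2 (delivery: classroom
teaching, the facilitator for the parental component), valued at
opportunity cost.  Pre-start-up development costs are excluded by
construction: the ledger has no slot for them.

Three delivery scenarios are supported:

* ``full`` - every component;
* ``no_parental`` - drops the parental-component facilitator, reflecting
  the very low observed uptake of parent evenings;
* ``classroom_only`` - stage 1 only, the marginal cost if classroom
  delivery displaces existing curriculum time at no extra teaching cost.

Monetary arithmetic is carried at full precision; rounding to whole pounds
happens only at report time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SCENARIOS",
    "ProgrammeCostLedger",
    "ProgrammeCostSummary",
    "aggregate",
    "extrapolate",
    "add_programme_cost",
]

SCENARIOS = ("full", "no_parental", "classroom_only")

# Trial denominators: schools randomised to the intervention arm, pupils
# present at baseline in those schools, classes taught.
DEFAULT_N_SCHOOLS = 105
DEFAULT_N_PUPILS = 5749
DEFAULT_N_CLASSES = 192


class ProgrammeCostError(ValueError):
    pass


@dataclass(frozen=True)
class ProgrammeCostLedger:
    """Itemised intervention costs plus the denominators used to express
    them per school and per pupil."""

    components: pd.DataFrame = field(repr=False)  # stage, label, amount, parental
    n_schools: int = DEFAULT_N_SCHOOLS
    n_pupils: int = DEFAULT_N_PUPILS
    n_classes: int = DEFAULT_N_CLASSES

    def __post_init__(self) -> None:
        required = {"stage", "label", "amount", "parental"}
        missing = required - set(self.components.columns)
        if missing:
            raise ProgrammeCostError(f"ledger missing columns: {sorted(missing)}")
        if (self.components["amount"] < 0).any():
            raise ProgrammeCostError("ledger amounts must be non-negative")
        if not set(self.components["stage"]) <= {1, 2}:
            raise ProgrammeCostError("ledger stages must be 1 or 2")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ProgrammeCostLedger":
        frame = pd.read_csv(path)
        frame["parental"] = frame["parental"].astype(bool)
        return cls(frame, **kwargs)

    @classmethod
    def default(cls) -> "ProgrammeCostLedger":
        ref = importlib.resources.files("trialcea.data").joinpath("programme_costs.csv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass(frozen=True)
class ProgrammeCostSummary:
    scenario: str
    stage1_subtotal: float
    stage2_subtotal: float
    total: float
    per_school: float
    per_pupil: float

    def rounded(self) -> dict:
        """Report-level whole-pound figures."""
        return {
            "scenario": self.scenario,
            "stage1_subtotal": round(self.stage1_subtotal),
            "stage2_subtotal": round(self.stage2_subtotal),
            "total": round(self.total),
            "per_school": round(self.per_school),
            "per_pupil": round(self.per_pupil),
        }


def aggregate(ledger: ProgrammeCostLedger, scenario: str = "full") -> ProgrammeCostSummary:
    """Aggregate the ledger under a delivery scenario."""
    if scenario not in SCENARIOS:
        raise ProgrammeCostError(f"unknown scenario: {scenario!r}")
    if ledger.n_schools <= 0 or ledger.n_pupils <= 0:
        raise ProgrammeCostError("n_schools and n_pupils must be positive")
    comp = ledger.components
    if scenario == "no_parental":
        comp = comp.loc[~comp["parental"]]
    elif scenario == "classroom_only":
        comp = comp.loc[comp["stage"] == 1]
    stage1 = float(comp.loc[comp["stage"] == 1, "amount"].sum())
    stage2 = float(comp.loc[comp["stage"] == 2, "amount"].sum())
    total = stage1 + stage2
    return ProgrammeCostSummary(
        scenario=scenario,
        stage1_subtotal=stage1,
        stage2_subtotal=stage2,
        total=total,
        per_school=total / ledger.n_schools,
        per_pupil=total / ledger.n_pupils,
    )


def extrapolate(per_pupil: float, population: int) -> float:
    """National roll-out cost: per-pupil cost times the eligible population,
    reported to 3 significant figures."""
    if per_pupil < 0:
        raise ProgrammeCostError("per_pupil must be non-negative")
    total = per_pupil * population
    if total == 0:
        return 0.0
    from math import floor, log10

    digits = 3 - 1 - floor(log10(abs(total)))
    return round(total, digits)


def add_programme_cost(dataset: pd.DataFrame, per_pupil: float) -> pd.DataFrame:
    """Add the per-pupil programme cost to every intervention-arm pupil's
    total cost; the control arm is unchanged."""
    if "arm" not in dataset.columns or "total_cost" not in dataset.columns:
        raise ProgrammeCostError("dataset needs 'arm' and 'total_cost' columns")
    out = dataset.copy()
    mask = out["arm"] == "intervention"
    out.loc[mask, "total_cost"] = out.loc[mask, "total_cost"] + per_pupil
    return out
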