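"""Unit costing of pupil service use over a 33-month trial horizon.

Service-use questionnaires cover four 6-month recall windows (6 months
pre-baseline and months 7-12, 19-24, 28-33 relative to baseline).  Each
observed window is priced against a unit-cost table, converted to a monthly
rate anchored at the window midpoint, and the gaps between windows are
filled by linear interpolation of those rates.  Monthly costs over months
1-33 are then discounted (second and third study year) and summed to a
per-pupil total from a public-sector perspective.

Rules encoded here:

* an item left blank inside an otherwise-present questionnaire means the
  service was not used (count 0);
* a wave whose entire instrument is absent makes the pupil's total
  incomputable (complete-case flag false);
* the pre-baseline window anchors the interpolation but is never included
  in totals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WAVES",
    "POST_WAVES",
    "WAVE_MIDPOINTS",
    "N_MONTHS",
    "SECTORS",
    "UnitCostTable",
    "CostTrajectory",
    "cost_wave",
    "interpolate_trajectory",
    "discount_total",
    "discount_factors",
    "window_weights",
    "cost_trajectory",
    "build_cost_dataset",
]

#: Recall windows in chronological order.
WAVES = ("pre_baseline", "m7_12", "m19_24", "m28_33")
#: Windows that contribute to 33-month totals (pre-baseline is anchor only).
POST_WAVES = ("m7_12", "m19_24", "m28_33")
#: Midpoint (months from baseline) of each 6-month recall window.
WAVE_MIDPOINTS = {"pre_baseline": -3.0, "m7_12": 9.5, "m19_24": 21.5, "m28_33": 30.5}
N_MONTHS = 33
SECTORS = ("education", "health", "criminal_justice")


class CostingError(ValueError):
    """Invalid costing input (unknown service, negative count, duplicates)."""


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs (GBP, 2013-14 prices) of public-sector services.

    The default ledger covers 17 services across three public-sector
    categories (5 education, 10 health, 2 criminal justice).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"service_id", "label", "sector", "unit_cost"}
        missing = required - set(self.frame.columns)
        if missing:
            raise CostingError(f"unit cost table missing columns: {sorted(missing)}")
        if self.frame["service_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["service_id"].duplicated(), "service_id"]
            raise CostingError(f"duplicate service ids: {sorted(set(dupes))}")
        bad_sector = set(self.frame["sector"]) - set(SECTORS)
        if bad_sector:
            raise CostingError(f"unknown sectors: {sorted(bad_sector)}")
        if not (self.frame["unit_cost"] > 0).all():
            raise CostingError("all unit costs must be positive")

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "UnitCostTable":
        """The 2013-14 unit-cost ledger shipped with the package."""
        ref = importlib.resources.files("trialcea.data").joinpath("unit_costs.csv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    @property
    def service_ids(self) -> list[str]:
        return list(self.frame["service_id"])

    def unit_cost(self, service_id: str) -> float:
        row = self.frame.loc[self.frame["service_id"] == service_id, "unit_cost"]
        if row.empty:
            raise CostingError(f"unknown service id: {service_id!r}")
        return float(row.iloc[0])

    def sector_of(self, service_id: str) -> str:
        row = self.frame.loc[self.frame["service_id"] == service_id, "sector"]
        if row.empty:
            raise CostingError(f"unknown service id: {service_id!r}")
        return str(row.iloc[0])

    def scaled(self, k: float) -> "UnitCostTable":
        out = self.frame.copy()
        out["unit_cost"] = out["unit_cost"] * k
        return UnitCostTable(out)


@dataclass
class CostTrajectory:
    """Per-pupil costed trajectory over months 1-33."""

    pupil_id: object
    window_costs: dict  # wave -> GBP (absent key = wave missing)
    monthly_costs: np.ndarray | None  # 33 values, months 1..33
    total_undiscounted: float | None
    total_discounted: float | None
    discount_rate: float
    complete: bool


def cost_wave(counts: dict, table: UnitCostTable) -> tuple[float, dict]:
    """Price one observed 6-month window of service use.

    ``counts`` maps service_id to a non-negative count; ``None``/NaN marks an
    item left blank, which is costed as zero use.  Returns the window total
    and its decomposition by public-sector category.
    """
    total = 0.0
    by_sector = {s: 0.0 for s in SECTORS}
    for service_id, count in counts.items():
        sector = table.sector_of(service_id)  # raises on unknown id
        if count is None or (isinstance(count, float) and np.isnan(count)):
            continue  # blank item: service assumed not used
        if count < 0:
            raise CostingError(f"negative count for {service_id!r}: {count}")
        amount = float(count) * table.unit_cost(service_id)
        total += amount
        by_sector[sector] += amount
    return total, by_sector


def _month_centres() -> np.ndarray:
    return np.arange(1, N_MONTHS + 1) - 0.5


def interpolate_trajectory(window_costs: dict) -> np.ndarray:
    """Monthly costs for months 1-33 from four observed window totals.

    Each window total is turned into a monthly rate (cost / 6) anchored at
    the window midpoint; the rate at each month centre is the piecewise
    linear interpolation between anchors, held constant beyond the last
    anchor (month 30.5).
    """
    missing = [w for w in WAVES if w not in window_costs]
    if missing:
        raise CostingError(f"cannot interpolate, missing waves: {missing}")
    anchors = np.array([WAVE_MIDPOINTS[w] for w in WAVES])
    rates = np.array([float(window_costs[w]) / 6.0 for w in WAVES])
    return np.interp(_month_centres(), anchors, rates)


def discount_factors(annual_rate: float) -> np.ndarray:
    """Per-month discount factors: study year 1 undiscounted, year 2 by
    1/(1+r), months 25-33 by 1/(1+r)^2."""
    if annual_rate < 0:
        raise CostingError(f"negative discount rate: {annual_rate}")
    months = np.arange(1, N_MONTHS + 1)
    year = np.ceil(months / 12.0).astype(int)  # 1, 2, 3
    return (1.0 + annual_rate) ** (-(year - 1).astype(float))


def discount_total(monthly_costs: np.ndarray, annual_rate: float) -> float:
    monthly_costs = np.asarray(monthly_costs, dtype=float)
    if monthly_costs.shape != (N_MONTHS,):
        raise CostingError(f"expected {N_MONTHS} monthly values, got {monthly_costs.shape}")
    return float(monthly_costs @ discount_factors(annual_rate))


def window_weights(annual_rate: float = 0.035) -> dict:
    """Weight of each observed window total in the discounted 33-month total.

    The interpolation and discounting steps are linear in the window costs,
    so the discounted total is an exact weighted sum of the four window
    totals.  Useful for calibration and fast vectorised costing.  Note the
    pre-baseline window carries a small positive weight: its own six months
    are excluded from totals but it anchors the interpolated rates for
    months 1-6.
    """
    vec = _window_weight_vector(annual_rate)
    return {w: float(vec[j]) for j, w in enumerate(WAVES)}


def _window_weight_vector(annual_rate: float) -> np.ndarray:
    """weights[j] such that total_discounted = sum_j weights[j] * window_cost_j."""
    out = np.empty(len(WAVES))
    for j, wave in enumerate(WAVES):
        unit = {w: (1.0 if w == wave else 0.0) for w in WAVES}
        out[j] = discount_total(interpolate_trajectory(unit), annual_rate)
    return out


def cost_trajectory(
    pupil_id,
    wave_counts: dict,
    table: UnitCostTable,
    annual_rate: float = 0.035,
) -> CostTrajectory:
    """Cost a single pupil.  ``wave_counts`` maps wave -> counts dict for
    observed waves; absent keys are wave-missing."""
    window_costs = {}
    for wave, counts in wave_counts.items():
        if wave not in WAVES:
            raise CostingError(f"unknown wave: {wave!r}")
        window_costs[wave], _ = cost_wave(counts, table)
    complete = all(w in window_costs for w in WAVES)
    if complete:
        monthly = interpolate_trajectory(window_costs)
        total_undisc = float(monthly.sum())
        total_disc = discount_total(monthly, annual_rate)
    else:
        monthly = None
        total_undisc = None
        total_disc = None
    return CostTrajectory(
        pupil_id=pupil_id,
        window_costs=window_costs,
        monthly_costs=monthly,
        total_undiscounted=total_undisc,
        total_discounted=total_disc,
        discount_rate=annual_rate,
        complete=complete,
    )


def build_cost_dataset(
    waves: pd.DataFrame,
    table: UnitCostTable,
    annual_rate: float = 0.035,
) -> pd.DataFrame:
    """Cost a cohort and return per-pupil 33-month cost summaries.

    ``waves`` is wide-format: one row per observed (pupil_id, wave) with one
    column per service id (NaN = item blank).  A (pupil, wave) with no row
    is wave-missing.  Returns a frame indexed by pupil with columns
    ``baseline_cost`` (pre-baseline window, undiscounted, excluded from
    totals), ``total_discounted``, per-sector discounted totals over months
    1-33 and the ``complete`` flag.
    """
    if waves.duplicated(subset=["pupil_id", "wave"]).any():
        dup = waves.loc[waves.duplicated(subset=["pupil_id", "wave"]), ["pupil_id", "wave"]]
        raise CostingError(f"duplicate (pupil, wave) rows, e.g. {dup.iloc[0].tolist()}")
    unknown_waves = set(waves["wave"]) - set(WAVES)
    if unknown_waves:
        raise CostingError(f"unknown waves: {sorted(unknown_waves)}")

    service_ids = [s for s in table.service_ids if s in waves.columns]
    extra = set(waves.columns) - set(table.service_ids) - {"pupil_id", "wave"}
    if extra:
        raise CostingError(f"unknown service columns: {sorted(extra)}")
    counts = waves[service_ids].to_numpy(dtype=float)
    if np.nanmin(counts, initial=0.0) < 0:
        raise CostingError("negative service-use count")
    counts = np.nan_to_num(counts, nan=0.0)  # blank item = not used

    prices = table.frame.set_index("service_id").loc[service_ids, "unit_cost"].to_numpy()
    sectors = table.frame.set_index("service_id").loc[service_ids, "sector"].to_numpy()

    window_total = counts @ prices
    sector_window = {
        s: counts[:, sectors == s] @ prices[sectors == s] for s in SECTORS
    }

    pupils = pd.unique(waves["pupil_id"])
    pupil_idx = pd.Series(np.arange(len(pupils)), index=pupils)
    wave_idx = {w: j for j, w in enumerate(WAVES)}
    rows = pupil_idx[waves["pupil_id"]].to_numpy()
    cols = waves["wave"].map(wave_idx).to_numpy()

    # (n_pupils, 4) window-cost matrices; NaN marks wave-missing
    W = np.full((len(pupils), len(WAVES)), np.nan)
    W[rows, cols] = window_total
    W_sector = {}
    for s in SECTORS:
        M = np.full((len(pupils), len(WAVES)), np.nan)
        M[rows, cols] = sector_window[s]
        W_sector[s] = M

    complete = ~np.isnan(W).any(axis=1)
    weights = _window_weight_vector(annual_rate)

    total = np.full(len(pupils), np.nan)
    total[complete] = W[complete] @ weights
    out = pd.DataFrame(
        {
            "pupil_id": pupils,
            "baseline_cost": W[:, wave_idx["pre_baseline"]],
            "cost_m7_12": W[:, wave_idx["m7_12"]],
            "total_discounted": total,
            "complete": complete,
        }
    )
    for s, col in zip(SECTORS, ("education_cost", "health_cost", "criminal_cost")):
        sector_total = np.full(len(pupils), np.nan)
        sector_total[complete] = W_sector[s][complete] @ weights
        out[col] = sector_total
    return out
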