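"""Costing chain: wave pricing, interpolation, discounting, cohort build.

The independent oracle used throughout is a deliberately naive per-pupil
reimplementation (dicts and month-by-month loops, no numpy) of the same
rules: price each window, convert to monthly rates at window midpoints,
linearly interpolate between anchors, discount by study year.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_waves
from trialcea.costing import (
    N_MONTHS,
    WAVES,
    CostingError,
    UnitCostTable,
    build_cost_dataset,
    cost_trajectory,
    cost_wave,
    discount_total,
    interpolate_trajectory,
    window_weights,
)

MIDPOINTS = {"pre_baseline": -3.0, "m7_12": 9.5, "m19_24": 21.5, "m28_33": 30.5}


# --------------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------------

def oracle_monthly(window_costs):
    anchors = sorted((MIDPOINTS[w], window_costs[w] / 6.0) for w in WAVES)
    out = []
    for m in range(1, N_MONTHS + 1):
        x = m - 0.5
        if x <= anchors[0][0]:
            out.append(anchors[0][1])
            continue
        if x >= anchors[-1][0]:
            out.append(anchors[-1][1])
            continue
        for (x0, r0), (x1, r1) in zip(anchors, anchors[1:]):
            if x0 <= x <= x1:
                out.append(r0 + (r1 - r0) * (x - x0) / (x1 - x0))
                break
    return out


def oracle_discounted_total(window_costs, rate):
    total = 0.0
    for m, c in enumerate(oracle_monthly(window_costs), start=1):
        year = (m - 1) // 12  # 0, 1, 2
        total += c / (1 + rate) ** year
    return total


def oracle_pupil(wave_counts, table_frame, rate):
    prices = dict(zip(table_frame["service_id"], table_frame["unit_cost"]))
    windows = {}
    for wave, counts in wave_counts.items():
        windows[wave] = sum(
            (0 if c is None or c != c else c) * prices[s] for s, c in counts.items()
        )
    if set(windows) != set(WAVES):
        return windows, None
    return windows, oracle_discounted_total(windows, rate)


# --------------------------------------------------------------------------
# unit-cost table and wave pricing
# --------------------------------------------------------------------------

def test_default_table_shape(unit_table):
    """The shipped 2013-14 ledger: 17 services, 5/10/2 across sectors."""
    counts = unit_table.frame.groupby("sector").size().to_dict()
    assert counts == {"education": 5, "health": 10, "criminal_justice": 2}
    assert unit_table.frame["service_id"].is_unique
    assert (unit_table.frame["unit_cost"] > 0).all()


@pytest.mark.parametrize(
    "counts, expected_total, expected_sector",
    [
        # one GP visit (46.00) plus one A&E attendance (233.00)
        ({"gp_surgery_visit": 1, "accident_emergency": 1}, 279.00, {"health": 279.00}),
        ({s: 0 for s in ("gp_surgery_visit", "police_service", "school_nurse")}, 0.0, {}),
        # blank police item costs zero; overnight stay priced at 658.33
        (
            {"overnight_hospital_stay": 1, "police_service": None},
            658.33,
            {"health": 658.33, "criminal_justice": 0.0},
        ),
    ],
)
def test_cost_wave_examples(unit_table, counts, expected_total, expected_sector):
    total, by_sector = cost_wave(counts, unit_table)
    assert total == pytest.approx(expected_total)
    for sector, value in expected_sector.items():
        assert by_sector[sector] == pytest.approx(value)
    assert sum(by_sector.values()) == pytest.approx(total)


def test_cost_wave_errors(unit_table):
    with pytest.raises(CostingError, match="no_such_service"):
        cost_wave({"no_such_service": 1}, unit_table)
    with pytest.raises(CostingError, match="negative"):
        cost_wave({"gp_surgery_visit": -1}, unit_table)


def test_bad_tables_rejected(unit_table):
    dupe = pd.concat([unit_table.frame, unit_table.frame.iloc[[0]]])
    with pytest.raises(CostingError, match="duplicate"):
        UnitCostTable(dupe)
    zero = unit_table.frame.copy()
    zero.loc[zero.index[0], "unit_cost"] = 0.0
    with pytest.raises(CostingError, match="positive"):
        UnitCostTable(zero)


# --------------------------------------------------------------------------
# interpolation and discounting
# --------------------------------------------------------------------------

def test_constant_windows_give_flat_rate():
    monthly = interpolate_trajectory({w: 60.0 for w in WAVES})
    assert np.allclose(monthly, 10.0)
    assert monthly.sum() == pytest.approx(330.0)


def test_zero_windows_give_zero():
    monthly = interpolate_trajectory({w: 0.0 for w in WAVES})
    assert np.all(monthly == 0.0)


def test_interpolation_matches_piecewise_linear_oracle():
    windows = dict(zip(WAVES, (0.0, 60.0, 120.0, 180.0)))
    assert np.allclose(interpolate_trajectory(windows), oracle_monthly(windows))


def test_missing_window_rejected():
    with pytest.raises(CostingError, match="missing waves"):
        interpolate_trajectory({"m7_12": 60.0})


def test_discounting_closed_forms():
    base = np.zeros(N_MONTHS)
    assert discount_total(base + 1.0, 0.0) == pytest.approx(33.0)  # identity at rate 0
    spike18 = np.zeros(N_MONTHS)
    spike18[17] = 100.0
    assert discount_total(spike18, 0.035) == pytest.approx(100 / 1.035)
    spike30 = np.zeros(N_MONTHS)
    spike30[29] = 100.0
    assert discount_total(spike30, 0.035) == pytest.approx(100 / 1.035**2)
    with pytest.raises(CostingError, match="negative"):
        discount_total(base, -0.01)


@given(
    windows=st.lists(st.floats(0, 500), min_size=4, max_size=4),
    rate=st.floats(0, 0.10),
)
def test_trajectory_chain_matches_oracle(windows, rate):
    wc = dict(zip(WAVES, windows))
    monthly = interpolate_trajectory(wc)
    assert np.allclose(monthly, oracle_monthly(wc), atol=1e-9)
    assert discount_total(monthly, rate) == pytest.approx(
        oracle_discounted_total(wc, rate), abs=1e-8
    )


@given(rates=st.lists(st.floats(0, 0.15), min_size=2, max_size=2))
def test_discounting_monotone_in_rate(rates):
    """For non-negative trajectories the discounted total never grows with
    the rate."""
    lo, hi = sorted(rates)
    monthly = interpolate_trajectory(dict(zip(WAVES, (30.0, 90.0, 10.0, 200.0))))
    assert discount_total(monthly, hi) <= discount_total(monthly, lo) + 1e-9


def test_window_weights_reconstruct_total():
    wc = dict(zip(WAVES, (12.0, 66.0, 180.0, 42.0)))
    weights = window_weights(0.035)
    direct = discount_total(interpolate_trajectory(wc), 0.035)
    assert sum(weights[w] * wc[w] for w in WAVES) == pytest.approx(direct)


# --------------------------------------------------------------------------
# cohort build
# --------------------------------------------------------------------------

def _toy_cohort():
    return make_waves(
        {
            ("a", "pre_baseline"): {"gp_surgery_visit": 1},
            ("a", "m7_12"): {"gp_surgery_visit": 2, "school_nurse": 1},
            ("a", "m19_24"): {"police_service": 1},
            ("a", "m28_33"): {"gp_surgery_visit": 0},
            ("b", "pre_baseline"): {"accident_emergency": 1},
            ("b", "m7_12"): {"gp_surgery_visit": None},
            ("b", "m28_33"): {"overnight_hospital_stay": 1},  # m19_24 wave missing
            ("c", "pre_baseline"): {},
            ("c", "m7_12"): {},
            ("c", "m19_24"): {},
            ("c", "m28_33"): {"school_nurse": 3},
        }
    )


def test_build_cost_dataset_complete_case_logic(unit_table):
    out = build_cost_dataset(_toy_cohort(), unit_table).set_index("pupil_id")
    assert out.loc["a", "complete"] and out.loc["c", "complete"]
    assert not out.loc["b", "complete"]
    # incomplete pupil: totals absent, baseline anchor still populated
    assert np.isnan(out.loc["b", "total_discounted"])
    assert out.loc["b", "baseline_cost"] == pytest.approx(233.0)


def test_build_cost_dataset_matches_per_pupil_oracle(unit_table):
    waves = _toy_cohort()
    out = build_cost_dataset(waves, unit_table, annual_rate=0.035).set_index("pupil_id")
    for pupil in ("a", "c"):
        sub = waves[waves["pupil_id"] == pupil]
        wave_counts = {
            row["wave"]: {
                s: row[s]
                for s in waves.columns
                if s not in ("pupil_id", "wave") and not pd.isna(row[s])
            }
            for _, row in sub.iterrows()
        }
        _, expected = oracle_pupil(wave_counts, unit_table.frame, 0.035)
        assert out.loc[pupil, "total_discounted"] == pytest.approx(expected)


def test_duplicate_wave_rows_rejected(unit_table):
    waves = _toy_cohort()
    dup = pd.concat([waves, waves.iloc[[0]]], ignore_index=True)
    with pytest.raises(CostingError, match="duplicate"):
        build_cost_dataset(dup, unit_table)


def test_sector_conservation_and_scaling(unit_table):
    out = build_cost_dataset(_toy_cohort(), unit_table)
    ok = out["complete"]
    sector_sum = out.loc[ok, ["education_cost", "health_cost", "criminal_cost"]].sum(axis=1)
    assert np.allclose(sector_sum, out.loc[ok, "total_discounted"], atol=1e-9)
    # multiplying every unit cost by k multiplies every total by k exactly
    k = 3.5
    scaled = build_cost_dataset(_toy_cohort(), unit_table.scaled(k))
    assert np.allclose(
        scaled.loc[ok, "total_discounted"], k * out.loc[ok, "total_discounted"]
    )
    assert np.allclose(scaled["baseline_cost"], k * out["baseline_cost"], equal_nan=True)


@given(data=st.data())
def test_random_small_cohorts_match_oracle(data, unit_table):
    """Full chain vs the naive oracle on random cohorts of <=10 pupils and
    <=3 services, month by month."""
    services = ["gp_surgery_visit", "overnight_hospital_stay", "school_nurse"]
    n_pupils = data.draw(st.integers(1, 10))
    rows = {}
    for p in range(n_pupils):
        for wave in WAVES:
            if data.draw(st.booleans(), label=f"present_{p}_{wave}"):
                counts = {
                    s: data.draw(
                        st.one_of(st.none(), st.integers(0, 4)), label=f"{p}{wave}{s}"
                    )
                    for s in services
                }
                rows[(f"p{p}", wave)] = counts
    if not rows:
        return
    out = build_cost_dataset(make_waves(rows), unit_table).set_index("pupil_id")
    for p in range(n_pupils):
        pid = f"p{p}"
        wave_counts = {w: c for (q, w), c in rows.items() if q == pid}
        if not wave_counts:
            assert pid not in out.index
            continue
        windows, expected = oracle_pupil(wave_counts, unit_table.frame, 0.035)
        if expected is None:
            assert not out.loc[pid, "complete"]
        else:
            assert out.loc[pid, "total_discounted"] == pytest.approx(expected, abs=1e-8)


def test_single_pupil_api_consistent(unit_table):
    traj = cost_trajectory(
        "a",
        {
            "pre_baseline": {"gp_surgery_visit": 1},
            "m7_12": {"gp_surgery_visit": 2, "school_nurse": 1},
            "m19_24": {"police_service": 1},
            "m28_33": {},
        },
        unit_table,
    )
    assert traj.complete
    assert traj.total_undiscounted == pytest.approx(traj.monthly_costs.sum())
    assert traj.total_discounted <= traj.total_undiscounted
    out = build_cost_dataset(_toy_cohort(), unit_table).set_index("pupil_id")
    assert traj.total_discounted == pytest.approx(out.loc["a", "total_discounted"])
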