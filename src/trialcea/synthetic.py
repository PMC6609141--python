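"""Synthetic two-arm cluster-RCT generator with known ground truth.

No pupil-level data from the motivating trial are deposited, so every
pipeline stage is exercised against simulated cohorts that share the
trial's statistical structure: ~105 schools (~108 pupils each) randomised
1:1, stratified covariates (location, free-school-meals band, school type),
four 6-month service-use recall windows with overdispersed counts, a binary
heavy-episodic-drinking (HED) outcome at 33 months with arm prevalences
0.23 (control) vs 0.15 (intervention), and wave-level missingness that is
by default informative (heavier service users, high-FSM schools and
baseline drinkers are more likely to miss questionnaires, leaving roughly
two-thirds of pupils complete).

Costs are induced through service *counts* - priced later by the costing
module - so the generator exercises the full costing chain, including the
blank-item rule.  The intervention's true incremental cost is embedded by
scaling post-baseline count means so that the expected discounted 33-month
cost differs by exactly ``true_delta_cost``.

School-level heterogeneity:

* cost: a lognormal school multiplier (mean 1) whose variance is solved
  from ``icc_cost`` via the exact between/within variance decomposition of
  the discounted total cost implied by the count model;
* outcome: a normal perturbation of the arm prevalence on the probability
  scale with variance ``icc_outcome * p * (1 - p)``, clipped to (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

from .costing import POST_WAVES, WAVES, UnitCostTable, _window_weight_vector

__all__ = [
    "DEFAULT_SERVICE_PARAMS",
    "MissingnessConfig",
    "OutcomeDefinition",
    "GeneratorConfig",
    "SimulatedTrial",
    "generate",
    "describe",
]


class InfeasibleConfigError(ValueError):
    """A configuration implying impossible distributions (named constraint)."""


#: Per-service zero-inflated negative-binomial parameters for one 6-month
#: window: pi (structural-zero probability), mu (NB mean given not a
#: structural zero), k (NB size / inverse dispersion).  Chosen for
#: order-of-magnitude realism of early-adolescent public-service use; the
#: implied mean window cost is roughly GBP 400.
DEFAULT_SERVICE_PARAMS = {
    "school_nurse": (0.70, 1.00, 0.7),
    "school_counsellor": (0.85, 1.00, 0.7),
    "intervention_teacher": (0.80, 1.00, 0.7),
    "educational_psychologist": (0.95, 1.00, 0.6),
    "education_welfare_officer": (0.95, 1.00, 0.6),
    "gp_surgery_visit": (0.45, 1.80, 0.9),
    "gp_out_of_hours": (0.95, 1.00, 0.6),
    "nurse_other": (0.70, 1.30, 0.8),
    "hospital_appointment": (0.75, 2.00, 0.6),
    "accident_emergency": (0.80, 1.25, 0.7),
    "overnight_hospital_stay": (0.85, 1.45, 0.5),
    "psychologist": (0.93, 2.00, 0.5),
    "counsellor_other": (0.93, 2.00, 0.5),
    "social_worker": (0.92, 2.50, 0.5),
    "telephone_helpline": (0.90, 2.50, 0.6),
    "youth_justice": (0.97, 1.60, 0.5),
    "police_service": (0.96, 1.50, 0.5),
}


@dataclass(frozen=True)
class MissingnessConfig:
    """Wave- and outcome-level missingness model.

    ``mechanism``: MCAR (base rates only), MAR (odds shifted by high-FSM
    school and baseline drinking, both observed) or MNAR (MAR shifts plus a
    shift in the pupil's own latent service-use frailty, so complete cases
    are systematically lighter service users).
    """

    mechanism: str = "MNAR"
    wave_missing_base_prob: float = 0.06
    outcome_missing_base_prob: float = 0.09
    or_fsm_high: float = 1.5
    or_baseline_hed: float = 1.8
    or_heavy_user: float = 1.3


@dataclass(frozen=True)
class OutcomeDefinition:
    """HED definition: units in a single episode at/above the sex-specific
    threshold."""

    male_threshold: float = 6.0
    female_threshold: float = 4.5


@dataclass(frozen=True)
class GeneratorConfig:
    n_schools: int = 105
    pupils_per_school_mean: float = 108.0
    pupils_per_school_size: float = 25.0  # NB size; larger = less dispersed
    location_ni_prob: float = 0.67
    fsm_probs: tuple = (1 / 3, 1 / 3, 1 / 3)  # low, moderate, high
    school_type_probs: tuple = (0.15, 0.15, 0.70)  # boys, girls, coed
    service_params: dict = field(default_factory=lambda: dict(DEFAULT_SERVICE_PARAMS))
    cost_trend: tuple = (1.0, 1.0, 1.0, 1.0)  # multiplicative drift per wave
    true_delta_cost: float = -30.0
    control_hed_prev: float = 0.23
    intervention_hed_prev: float = 0.15
    baseline_hed_prev: float = 0.05
    baseline_hed_assoc: float = 0.30  # added HED-at-33m probability for baseline drinkers
    icc_cost: float = 0.02
    icc_outcome: float = 0.02
    pupil_frailty_sd: float = 0.8  # log-scale sd of the pupil service-use frailty
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    item_blank_prob: float = 0.30  # chance a zero count is left blank on the form
    emit_units: bool = False  # derive HED from simulated episode units instead
    outcome_definition: OutcomeDefinition = field(default_factory=OutcomeDefinition)
    discount_rate: float = 0.035  # rate under which true_delta_cost is defined
    seed: int = 0

    @property
    def true_delta_e(self) -> float:
        return self.control_hed_prev - self.intervention_hed_prev

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class SimulatedTrial:
    waves: pd.DataFrame  # wide: pupil_id, wave, one column per service
    pupils: pd.DataFrame
    schools: pd.DataFrame
    truth: dict


def _zinb_moments(pi: float, mu: float, k: float) -> tuple[float, float]:
    """Mean and variance of a zero-inflated negative binomial."""
    mean = (1 - pi) * mu
    ex2 = (1 - pi) * (mu + mu**2 * (1 + 1 / k))
    return mean, ex2 - mean**2


def _cost_calibration(config: GeneratorConfig, table: UnitCostTable) -> dict:
    """Closed-form calibration of the post-baseline scaling (embedding the
    true incremental cost) and the school cost-multiplier variance
    (matching icc_cost for the discounted 33-month total)."""
    prices = table.frame.set_index("service_id")["unit_cost"]
    weights = _window_weight_vector(config.discount_rate)

    mean_w = np.zeros(len(WAVES))
    var_w = np.zeros(len(WAVES))
    for sid, (pi, mu, k) in config.service_params.items():
        price = float(prices[sid])
        m, v = _zinb_moments(pi, mu, k)
        for j, _wave in enumerate(WAVES):
            drift = config.cost_trend[j]
            mean_w[j] += price * m * drift
            var_w[j] += price**2 * v * drift**2

    post = np.array([w in POST_WAVES for w in WAVES])
    denom = float(weights[post] @ mean_w[post])
    rho = 1.0 + config.true_delta_cost / denom
    if rho <= 0:
        raise InfeasibleConfigError(
            f"true_delta_cost={config.true_delta_cost} implies negative service use"
        )

    mu_t = float(weights @ mean_w)
    sigma_s2 = float((weights**2) @ var_w)
    sp2 = config.pupil_frailty_sd**2
    within = np.exp(sp2) * (sigma_s2 + mu_t**2) - mu_t**2
    icc = config.icc_cost
    denom_v = mu_t**2 * (1 - icc) - icc * within
    if denom_v <= 0:
        raise InfeasibleConfigError(
            f"icc_cost={icc} unattainable given the count-model noise "
            f"(within-school variance {within:.3g} vs squared mean {mu_t**2:.3g})"
        )
    v = icc * within / denom_v
    return {
        "rho": rho,
        "school_lognorm_var": np.log1p(v),
        "expected_total_cost_control": mu_t,
        "mean_window_cost": dict(zip(WAVES, mean_w)),
    }


def _school_prevalences(rng, p: float, icc: float, n: int) -> np.ndarray:
    sigma_b = np.sqrt(icc * p * (1 - p))
    if not (0 < p - 2 * sigma_b and p + 2 * sigma_b < 1):
        raise InfeasibleConfigError(
            f"icc_outcome with prevalence {p} puts school prevalences outside (0,1): "
            f"{p} +/- 2*{sigma_b:.3f}"
        )
    return np.clip(rng.normal(p, sigma_b, size=n), 0.005, 0.995)


def _zinb_draw(rng, pi, mu, k, size):
    lam = rng.gamma(shape=k, scale=np.asarray(mu) / k, size=size)
    counts = rng.poisson(lam)
    counts[rng.random(size) < pi] = 0
    return counts


def generate(config: GeneratorConfig, table: UnitCostTable | None = None) -> SimulatedTrial:
    """Simulate one trial.  Deterministic given ``config.seed``."""
    for name, probs in (("fsm_probs", config.fsm_probs), ("school_type_probs", config.school_type_probs)):
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise InfeasibleConfigError(f"{name} must be a probability vector")
    table = table or UnitCostTable.default()
    missing_prices = set(config.service_params) - set(table.service_ids)
    if missing_prices:
        raise InfeasibleConfigError(f"services without unit costs: {sorted(missing_prices)}")
    cal = _cost_calibration(config, table)
    rng = np.random.default_rng(config.seed)

    # --- schools ---------------------------------------------------------
    n = config.n_schools
    n_int = n // 2 + rng.integers(0, 2) if n % 2 else n // 2
    arm = np.array(["control"] * n, dtype=object)
    arm[rng.choice(n, size=int(n_int), replace=False)] = "intervention"
    schools = pd.DataFrame(
        {
            "school_id": [f"S{j:03d}" for j in range(n)],
            "arm": arm,
            "location": np.where(rng.random(n) < config.location_ni_prob, "NI", "Scotland"),
            "fsm_band": rng.choice(["low", "moderate", "high"], size=n, p=config.fsm_probs),
            "school_type": rng.choice(["boys", "girls", "coed"], size=n, p=config.school_type_probs),
        }
    )
    su2 = cal["school_lognorm_var"]
    schools["cost_multiplier"] = np.exp(rng.normal(-su2 / 2, np.sqrt(su2), size=n))
    p_by_arm = {
        "control": _school_prevalences(rng, config.control_hed_prev, config.icc_outcome, n),
        "intervention": _school_prevalences(rng, config.intervention_hed_prev, config.icc_outcome, n),
    }
    schools["p_hed33"] = np.where(arm == "intervention", p_by_arm["intervention"], p_by_arm["control"])

    # --- pupils ----------------------------------------------------------
    size_k = config.pupils_per_school_size
    n_pupils_per = np.maximum(
        2, _zinb_draw(rng, 0.0, np.full(n, config.pupils_per_school_mean), size_k, n)
    )
    school_of = np.repeat(np.arange(n), n_pupils_per)
    n_total = len(school_of)
    pupils = pd.DataFrame(
        {
            "pupil_id": [f"P{j:06d}" for j in range(n_total)],
            "school_id": schools["school_id"].to_numpy()[school_of],
            "arm": schools["arm"].to_numpy()[school_of],
            "location": schools["location"].to_numpy()[school_of],
            "fsm_band": schools["fsm_band"].to_numpy()[school_of],
            "school_type": schools["school_type"].to_numpy()[school_of],
            "sex": np.where(rng.random(n_total) < 0.5, "male", "female"),
        }
    )
    # single-sex schools get a single sex
    boys = pupils["school_type"] == "boys"
    girls = pupils["school_type"] == "girls"
    pupils.loc[boys, "sex"] = "male"
    pupils.loc[girls, "sex"] = "female"
    pupils["baseline_hed"] = (rng.random(n_total) < config.baseline_hed_prev).astype(int)

    sp = config.pupil_frailty_sd
    log_frailty = rng.normal(-sp**2 / 2, sp, size=n_total)
    frailty = np.exp(log_frailty)
    z_frailty = (log_frailty + sp**2 / 2) / sp if sp > 0 else np.zeros(n_total)

    # --- outcomes --------------------------------------------------------
    p_school = schools["p_hed33"].to_numpy()[school_of]
    shift = config.baseline_hed_assoc * (pupils["baseline_hed"].to_numpy() - config.baseline_hed_prev)
    p33 = np.clip(p_school + shift, 0.001, 0.999)
    p12 = np.clip(0.6 * p_school + 0.5 * shift, 0.001, 0.999)
    u = rng.random(n_total)
    if config.emit_units:
        # episode units calibrated so that P(units >= sex threshold) = p33
        thr = np.where(pupils["sex"] == "male",
                       config.outcome_definition.male_threshold,
                       config.outcome_definition.female_threshold)
        sigma_units = 0.6
        units = thr * np.exp(sigma_units * (ndtri(p33) - ndtri(u)))
        pupils["max_episode_units"] = units
        hed33 = (units >= thr).astype(float)
    else:
        hed33 = (u < p33).astype(float)
    pupils["hed12"] = (u < p12).astype(int)  # shared latent: nested in hed33
    pupils["hed33"] = hed33

    # --- service-use counts ---------------------------------------------
    is_int = (pupils["arm"] == "intervention").to_numpy()
    mult_school = schools["cost_multiplier"].to_numpy()[school_of]
    base_mult = mult_school * frailty
    service_ids = list(config.service_params)
    count_blocks = {}
    for j, wave in enumerate(WAVES):
        drift = config.cost_trend[j]
        arm_scale = np.where(is_int & (wave in POST_WAVES), cal["rho"], 1.0)
        block = np.empty((n_total, len(service_ids)), dtype=float)
        for s, sid in enumerate(service_ids):
            pi, mu, k = config.service_params[sid]
            mu_vec = mu * drift * base_mult * arm_scale
            block[:, s] = _zinb_draw(rng, pi, mu_vec, k, n_total)
        count_blocks[wave] = block

    # --- missingness -----------------------------------------------------
    mech = config.missingness.mechanism
    if mech not in ("MCAR", "MAR", "MNAR"):
        raise InfeasibleConfigError(f"unknown missingness mechanism: {mech!r}")
    shift_lp = np.zeros(n_total)
    if mech in ("MAR", "MNAR"):
        shift_lp += np.log(config.missingness.or_fsm_high) * (
            pupils["fsm_band"] == "high"
        ).to_numpy(dtype=float)
        shift_lp += np.log(config.missingness.or_baseline_hed) * pupils["baseline_hed"].to_numpy(
            dtype=float
        )
    if mech == "MNAR":
        shift_lp += np.log(config.missingness.or_heavy_user) * z_frailty

    def _missing(base_prob):
        if base_prob <= 0:
            return np.zeros(n_total, dtype=bool)
        return rng.random(n_total) < expit(logit(base_prob) + shift_lp)

    wave_present = {w: ~_missing(config.missingness.wave_missing_base_prob) for w in WAVES}
    outcome_missing = _missing(config.missingness.outcome_missing_base_prob)
    pupils.loc[outcome_missing, "hed33"] = np.nan

    # --- assemble wide wave rows ----------------------------------------
    frames = []
    for wave in WAVES:
        present = wave_present[wave]
        block = count_blocks[wave][present]
        # a zero sometimes left blank on the form (costed as zero by rule)
        if config.item_blank_prob > 0:
            blank = (block == 0) & (rng.random(block.shape) < config.item_blank_prob)
            block = np.where(blank, np.nan, block)
        frame = pd.DataFrame(block, columns=service_ids)
        frame.insert(0, "wave", wave)
        frame.insert(0, "pupil_id", pupils["pupil_id"].to_numpy()[present])
        frames.append(frame)
    waves = pd.concat(frames, ignore_index=True)

    truth = {
        "delta_c": config.true_delta_cost,
        "delta_e": config.true_delta_e,
        "icc_cost": config.icc_cost,
        "icc_outcome": config.icc_outcome,
        "rho": cal["rho"],
        "expected_total_cost_control": cal["expected_total_cost_control"],
        "seed": config.seed,
    }
    return SimulatedTrial(waves=waves, pupils=pupils, schools=schools, truth=truth)


def describe(analysis: pd.DataFrame) -> pd.DataFrame:
    """Per-arm descriptive summary of an analysis dataset (generated or
    real-shaped): n, completeness, mean costs (overall and by sector) and
    HED prevalences among complete cases."""
    rows = []
    for arm in ("intervention", "control"):
        sub = analysis.loc[analysis["arm"] == arm] if len(analysis) else analysis
        complete = sub.loc[sub["complete"]] if len(sub) else sub
        rows.append(
            {
                "arm": arm,
                "n": len(sub),
                "n_complete": len(complete),
                "completeness": len(complete) / len(sub) if len(sub) else 0.0,
                "mean_total_cost": float(complete["total_cost"].mean()) if len(complete) else 0.0,
                "mean_education_cost": float(complete["education_cost"].mean()) if len(complete) else 0.0,
                "mean_health_cost": float(complete["health_cost"].mean()) if len(complete) else 0.0,
                "mean_criminal_cost": float(complete["criminal_cost"].mean()) if len(complete) else 0.0,
                "hed33_prevalence": float(complete["hed33"].mean()) if len(complete) else 0.0,
                "baseline_hed_prevalence": float(sub["baseline_hed"].mean()) if len(sub) else 0.0,
            }
        )
    return pd.DataFrame(rows)
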