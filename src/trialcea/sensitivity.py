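"""One-way sensitivity analyses around the primary cost-effectiveness model.

Variants:

* ``complete_case_primary`` - the base case (complete cases, 3.5% cost
  discounting, full covariate adjustment, school bootstrap);
* ``multiple_imputation`` - missing total costs and outcomes filled by
  chained equations (predictive mean matching for costs, a posterior-draw
  logistic model for the binary outcome), m completed datasets combined by
  Rubin's rules;
* ``discount_1_5`` - costs re-discounted at 1.5% and the 33-month outcome
  discounted by (1.015)^-2 (it is realised in study year 3);
* ``cluster_only`` - both models drop baseline covariates but keep the
  school random intercept;
* ``costs_up_5`` / ``costs_down_5`` - every pupil's total cost (including
  the programme cost) scaled by 1.05 / 0.95, probing the linear-trend
  interpolation assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from . import programme
from .dataset import TrialData, build_analysis_dataset, complete_cases
from .inference import cluster_bootstrap, fit_cost_model, fit_effect_model

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "SensitivityConfig",
    "PooledEstimate",
    "impute",
    "pool",
    "run_variant",
    "run_all_variants",
]

VARIANTS = (
    "complete_case_primary",
    "multiple_imputation",
    "discount_1_5",
    "cluster_only",
    "costs_up_5",
    "costs_down_5",
)

_CONTINUOUS = ("baseline_cost", "cost_m7_12", "total_cost")
_BINARY = ("baseline_hed", "hed12", "hed33")


@dataclass(frozen=True)
class SensitivityConfig:
    variant: str
    m: int = 5  # imputation count
    seed: int = 0
    B: int = 1000  # bootstrap replicates (non-MI variants)
    k_pmm: int = 5  # PMM donor-pool size
    cycles: int = 10  # chained-equation sweeps
    programme_per_pupil: float | None = None  # None -> shipped ledger default

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant: {self.variant!r}")
        if self.variant == "multiple_imputation" and self.m < 2:
            raise ValueError("multiple_imputation requires m >= 2")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m imputed-data estimates."""

    estimate: float
    variance: float
    ci: tuple
    within_variance: float
    between_variance: float
    df: float


# ---------------------------------------------------------------------------
# multiple imputation by chained equations
# ---------------------------------------------------------------------------

def _base_predictors(data: pd.DataFrame) -> np.ndarray:
    """Fully observed design: intercept, arm, and the school-level strata.

    Cluster membership enters the imputation model through the school-level
    strata (location, FSM band, school type) rather than per-school dummies.
    """
    n = len(data)
    cols = [np.ones(n), (data["arm"] == "intervention").to_numpy(dtype=float)]
    for var, levels in (
        ("location", ("Scotland",)),
        ("fsm_band", ("moderate", "high")),
        ("school_type", ("girls", "coed")),
    ):
        for lv in levels:
            cols.append((data[var] == lv).to_numpy(dtype=float))
    return np.column_stack(cols)


def _design_for(data: pd.DataFrame, base: np.ndarray, target: str, variables) -> np.ndarray:
    others = [v for v in variables if v != target]
    if not others:
        return base
    return np.column_stack([base] + [data[v].to_numpy(dtype=float) for v in others])


def _draw_ols_coefficients(rng, y: np.ndarray, X: np.ndarray):
    """Posterior draw (noninformative prior) of OLS coefficients; returns
    (beta_hat, beta_draw)."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    cov = sigma2 * np.linalg.inv(XtX)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    return beta_hat, beta_hat + L @ rng.standard_normal(p)


def _pmm_step(rng, y, X, obs_mask, k: int) -> np.ndarray:
    """Predictive-mean-matching draw for the missing entries of ``y``.

    Predictions for observed cases use the ML fit, predictions for missing
    cases a posterior coefficient draw (type-1 matching); each missing case
    borrows the observed value of one of its ``k`` nearest predicted-mean
    donors.  Only values actually observed can ever be imputed.
    """
    y_obs, X_obs, X_mis = y[obs_mask], X[obs_mask], X[~obs_mask]
    beta_hat, beta_draw = _draw_ols_coefficients(rng, y_obs, X_obs)
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_draw

    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    n_obs = len(y_obs)
    k = min(k, n_obs)
    imputed = np.empty(len(pred_mis))
    for i, (p_i, at) in enumerate(zip(pred_mis, pos)):
        lo = max(0, at - k)
        hi = min(n_obs, at + k)
        window = np.arange(lo, hi)
        nearest = window[np.argsort(np.abs(sorted_pred[window] - p_i))[:k]]
        donor = order[rng.choice(nearest)]
        imputed[i] = y_obs[donor]
    return imputed


def _logit_step(rng, y, X, obs_mask) -> np.ndarray:
    """Posterior-draw logistic imputation for a binary variable."""
    y_obs, X_obs, X_mis = y[obs_mask], X[obs_mask], X[~obs_mask]
    try:
        fit = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit(maxiter=50)
        beta = np.asarray(fit.params)
        cov = np.asarray(fit.cov_params())
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(beta)))
        beta_draw = beta + L @ rng.standard_normal(len(beta))
        p = expit(X_mis @ beta_draw)
    except (np.linalg.LinAlgError, ValueError):  # separation / singular fit
        logger.warning("logistic imputation fell back to the marginal rate")
        p = np.full(len(X_mis), float(y_obs.mean()))
    return (rng.random(len(X_mis)) < p).astype(float)


def impute(
    data: pd.DataFrame, m: int = 5, seed: int = 0, k_pmm: int = 5, cycles: int = 10
) -> list[pd.DataFrame]:
    """Chained-equations imputation; returns m completed copies of ``data``.

    Costs are imputed by PMM (``k_pmm`` donors), binary drinking variables
    by a logistic model; predictors are arm, the school-level strata and the
    other analysis/auxiliary variables.  Deterministic given ``seed``; with
    no missing values the completed datasets equal the input.
    """
    variables = [v for v in _CONTINUOUS + _BINARY if v in data.columns]
    for v in variables:
        if data[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no observed values to learn from")
    targets = [v for v in variables if data[v].isna().any()]
    if not targets:
        return [data.copy() for _ in range(m)]

    rng = np.random.default_rng(seed)
    base = _base_predictors(data)
    masks = {v: data[v].notna().to_numpy() for v in targets}
    completed = []
    for _ in range(m):
        d = data.copy()
        for v in targets:  # initialise from the observed margins
            obs_values = d.loc[masks[v], v].to_numpy(dtype=float)
            d.loc[~masks[v], v] = rng.choice(obs_values, size=(~masks[v]).sum())
        for _cycle in range(cycles):
            for v in targets:
                X = _design_for(d, base, v, variables)
                y = d[v].to_numpy(dtype=float)
                if v in _CONTINUOUS:
                    y_new = _pmm_step(rng, y, X, masks[v], k_pmm)
                else:
                    y_new = _logit_step(rng, y, X, masks[v])
                d.loc[~masks[v], v] = y_new
        d["complete"] = True
        completed.append(d)
    return completed


def pool(estimates, variances) -> PooledEstimate:
    """Rubin's rules: pooled mean, within + inflated between variance, and a
    t-interval with Rubin-Satterthwaite degrees of freedom."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-d and equal length")
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires m >= 2")
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1 + 1 / m) * between
    if between > 0:
        df = (m - 1) * (1 + within / ((1 + 1 / m) * between)) ** 2
        tcrit = float(stats.t.ppf(0.975, df))
    else:
        df = np.inf
        tcrit = float(stats.norm.ppf(0.975))
    half = tcrit * np.sqrt(total)
    return PooledEstimate(
        estimate=qbar,
        variance=total,
        ci=(qbar - half, qbar + half),
        within_variance=within,
        between_variance=between,
        df=df,
    )


# ---------------------------------------------------------------------------
# variant runner
# ---------------------------------------------------------------------------

def _default_per_pupil() -> float:
    return float(round(programme.aggregate(programme.ProgrammeCostLedger.default()).per_pupil))


def run_variant(config: SensitivityConfig, trial: TrialData) -> dict:
    """Run one sensitivity variant end to end and return a results row
    (n per arm, delta_c with CI, delta_e with CI, bootstrap estimates where
    applicable)."""
    per_pupil = (
        _default_per_pupil() if config.programme_per_pupil is None else config.programme_per_pupil
    )
    variant = config.variant

    rate = 0.015 if variant == "discount_1_5" else trial.discount_rate
    analysis = build_analysis_dataset(trial, discount_rate=rate)

    if variant == "multiple_imputation":
        analysis = analysis.drop(columns=["education_cost", "health_cost", "criminal_cost"])
        completed = impute(
            analysis, m=config.m, seed=config.seed, k_pmm=config.k_pmm, cycles=config.cycles
        )
        qc, uc, qe, ue = [], [], [], []
        for d in completed:
            d = programme.add_programme_cost(d, per_pupil)
            fc = fit_cost_model(d, adjusted=True)
            fe = fit_effect_model(d, adjusted=True)
            qc.append(fc.delta)
            uc.append(fc.se**2)
            qe.append(fe.delta)
            ue.append(fe.se**2)
        pc = pool(qc, uc)
        pe = pool(qe, ue)
        n_int = int((analysis["arm"] == "intervention").sum())
        n_ctl = int((analysis["arm"] == "control").sum())
        return {
            "variant": variant,
            "n_intervention": n_int,
            "n_control": n_ctl,
            "delta_c": pc.estimate,
            "ci_c": pc.ci,
            "delta_e": pe.estimate,
            "ci_e": pe.ci,
            "pooled_cost": pc,
            "pooled_effect": pe,
            "estimates": None,
        }

    cc = complete_cases(analysis)
    cc = programme.add_programme_cost(cc, per_pupil)
    if variant == "costs_up_5":
        cc["total_cost"] *= 1.05
    elif variant == "costs_down_5":
        cc["total_cost"] *= 0.95
    adjusted = variant != "cluster_only"

    est = cluster_bootstrap(cc, B=config.B, seed=config.seed, adjusted=adjusted)
    delta_e, ci_e = est.delta_e, est.ci_e
    if variant == "discount_1_5":
        # outcome realised in study year 3
        f = (1.015) ** -2
        delta_e *= f
        ci_e = (ci_e[0] * f, ci_e[1] * f)
        est.replicates = est.replicates.copy()
        est.replicates[:, 1] *= f
        est.delta_e = delta_e
        est.ci_e = ci_e
    return {
        "variant": variant,
        "n_intervention": est.n_intervention,
        "n_control": est.n_control,
        "delta_c": est.delta_c,
        "ci_c": est.ci_c,
        "delta_e": delta_e,
        "ci_e": ci_e,
        "estimates": est,
    }


def run_all_variants(
    trial: TrialData, seed: int = 0, B: int = 1000, m: int = 5
) -> pd.DataFrame:
    """All variants as a results table (one row per analysis)."""
    rows = []
    for variant in VARIANTS:
        row = run_variant(SensitivityConfig(variant=variant, seed=seed, B=B, m=m), trial)
        rows.append({k: v for k, v in row.items() if k not in ("estimates", "pooled_cost", "pooled_effect")})
    return pd.DataFrame(rows)
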