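"""Covariate-adjusted incremental costs and effects with cluster bootstrap.

The estimand pair is (delta_c, delta_e): the between-arm difference in mean
33-month public-sector cost, and the adjusted risk difference in the binary
heavy-episodic-drinking (HED) outcome expressed as *cases avoided* (control
minus intervention, so positive favours the intervention).

Both quantities come from linear models with a school-level random
intercept, fitted by feasible GLS: variance components are estimated by a
Swamy-Arora-type moment decomposition (within/between school), then the
data are partially demeaned by the usual random-effects transform and the
arm coefficient read off an OLS fit of the transformed data.  This is
numerically equivalent (to estimation error in the variance components) to
a REML mixed model and an order of magnitude faster, which matters inside
the bootstrap; a REML mixed model (statsmodels MixedLM) is used as an
independent cross-check in the test suite.

Uncertainty is quantified by resampling schools - the randomisation and
clustering unit - with replacement, stratified by arm so every resample
keeps the observed number of schools per arm.  Both models are refitted on
each resample, preserving the cost-effect correlation in the replicate
pairs; percentile intervals are taken over the replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateDesignError",
    "FitResult",
    "IncrementalEstimates",
    "fit_cost_model",
    "fit_effect_model",
    "cluster_bootstrap",
]

# Fixed dummy-coding orders (first *present* level is the reference) so that
# estimates do not depend on row order or incidental label ordering.
_LEVELS = {
    "location": ("NI", "Scotland"),
    "fsm_band": ("low", "moderate", "high"),
    "school_type": ("boys", "girls", "coed"),
}


class DegenerateDesignError(ValueError):
    """The design matrix is singular (e.g. a stratum confounded with arm)."""


@dataclass(frozen=True)
class FitResult:
    delta: float  # arm contrast on the outcome's natural scale
    se: float
    coefficients: dict


@dataclass
class IncrementalEstimates:
    """Point estimates and bootstrap replicates of (delta_c, delta_e)."""

    delta_c: float
    delta_e: float
    replicates: np.ndarray  # shape (B, 2): columns delta_c, delta_e
    ci_c: tuple
    ci_e: tuple
    B: int
    seed: int
    n_intervention: int
    n_control: int

    def to_dict(self) -> dict:
        return {
            "delta_c": self.delta_c,
            "delta_e": self.delta_e,
            "ci_c": list(self.ci_c),
            "ci_e": list(self.ci_e),
            "B": self.B,
            "seed": self.seed,
            "n_intervention": self.n_intervention,
            "n_control": self.n_control,
        }


def _group_means(values: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    if values.ndim == 1:
        sums = np.bincount(groups, weights=values, minlength=n_groups)
        return sums / counts
    out = np.empty((n_groups, values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.bincount(groups, weights=values[:, j], minlength=n_groups)
    return out / counts[:, None]


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, arm_col: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feasible-GLS fit of a linear model with a group random intercept.

    Returns (beta, cov, kept) where ``kept`` is the boolean mask of columns
    retained (zero-variance covariate columns are dropped, as happens when a
    bootstrap resample loses a stratum).  Raises DegenerateDesignError when
    the arm column is constant or the retained design is singular.
    """
    n, p = X.shape
    if X[:, arm_col].max() == X[:, arm_col].min():
        raise DegenerateDesignError("treatment indicator is constant")
    # The arm effect must not lie in the span of the covariates (e.g. a
    # stratum present in one arm only); aliased covariates are dropped, as
    # happens when a bootstrap resample loses a stratum.
    others = np.delete(X, arm_col, axis=1)
    coef, *_ = np.linalg.lstsq(others, X[:, arm_col], rcond=None)
    resid = X[:, arm_col] - others @ coef
    if float(resid @ resid) <= 1e-8 * float(X[:, arm_col] @ X[:, arm_col]):
        raise DegenerateDesignError("singular design: arm collinear with covariates")
    keep = np.zeros(p, dtype=bool)
    keep[[0, arm_col]] = True
    for j in range(p):
        if keep[j]:
            continue
        A = X[:, keep]
        b = X[:, j]
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        r = b - A @ coef
        if float(r @ r) > 1e-8 * max(float(b @ b), 1e-30):
            keep[j] = True
    Xk = X[:, keep]
    pk = Xk.shape[1]

    groups = np.asarray(groups)
    n_groups = int(groups.max()) + 1
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    ybar = _group_means(y, groups, n_groups)
    Xbar = _group_means(Xk, groups, n_groups)

    # Within-school residual variance
    yw = y - ybar[groups]
    Xw = Xk - Xbar[groups]
    bw, res_w, rank_w, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    ssr_w = float(((yw - Xw @ bw) ** 2).sum())
    df_w = max(n - n_groups - rank_w, 1)
    sigma_e2 = ssr_w / df_w

    # Between-school variance from the school-means regression
    bb, _, rank_b, _ = np.linalg.lstsq(Xbar, ybar, rcond=None)
    ssr_b = float(((ybar - Xbar @ bb) ** 2).sum())
    df_b = n_groups - rank_b
    if df_b > 0:
        ms_b = ssr_b / df_b
        sigma_u2 = max(0.0, ms_b - sigma_e2 * float(np.mean(1.0 / counts)))
    else:
        sigma_u2 = 0.0

    # Random-effects (partial demeaning) transform; sigma_u2 == 0 -> OLS
    if sigma_u2 > 0:
        se2 = max(sigma_e2, 1e-12)
        theta = 1.0 - np.sqrt(se2 / (se2 + counts * sigma_u2))
    else:
        theta = np.zeros(n_groups)
    ys = y - theta[groups] * ybar[groups]
    Xs = Xk - theta[groups, None] * Xbar[groups]

    beta_k, _, rank_s, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    if rank_s < pk:
        raise DegenerateDesignError("singular design after random-effects transform")
    resid = ys - Xs @ beta_k
    # cluster-robust (CR1) sandwich over schools on the transformed data
    bread = np.linalg.inv(Xs.T @ Xs)
    Xe = Xs * resid[:, None]
    S = np.empty((n_groups, pk))
    for j in range(pk):
        S[:, j] = np.bincount(groups, weights=Xe[:, j], minlength=n_groups)
    meat = S.T @ S
    adj = (n_groups / max(n_groups - 1, 1)) * ((n - 1) / max(n - pk, 1))
    cov_k = adj * bread @ meat @ bread

    beta = np.zeros(p)
    beta[keep] = beta_k
    cov = np.full((p, p), np.nan)
    cov[np.ix_(keep, keep)] = cov_k
    return beta, cov, keep


def _dummies(series: pd.Series, name: str) -> tuple[np.ndarray, list]:
    levels = [lv for lv in _LEVELS[name] if lv in set(series)]
    unknown = set(series) - set(_LEVELS[name])
    if unknown:
        raise ValueError(f"unknown {name} levels: {sorted(unknown)}")
    cols, labels = [], []
    for lv in levels[1:]:  # first present level is the reference
        cols.append((series == lv).to_numpy(dtype=float))
        labels.append(f"{name}[{lv}]")
    return cols, labels


def build_design(
    data: pd.DataFrame, outcome: str, adjusted: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Assemble (y, X, school_codes, column_names) for one of the two models.

    ``outcome`` is "cost" (models total_cost, adjusting additionally for the
    pupil's pre-baseline cost) or "effect" (models hed33, adjusting for
    baseline drinking).  The arm indicator (1 = intervention) is always
    column 1.
    """
    if outcome == "cost":
        y = data["total_cost"].to_numpy(dtype=float)
        baseline_col = "baseline_cost"
    elif outcome == "effect":
        y = data["hed33"].to_numpy(dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("hed33 outcome must be binary 0/1")
        baseline_col = "baseline_hed"
    else:
        raise ValueError(f"unknown outcome: {outcome!r}")
    if np.isnan(y).any():
        raise ValueError(f"missing {outcome} outcome values in analysis data")

    n = len(data)
    cols = [np.ones(n), (data["arm"] == "intervention").to_numpy(dtype=float)]
    names = ["intercept", "arm"]
    if adjusted:
        for covariate in ("location", "fsm_band", "school_type"):
            c, lab = _dummies(data[covariate], covariate)
            cols.extend(c)
            names.extend(lab)
        cols.append(data[baseline_col].to_numpy(dtype=float))
        names.append(baseline_col)
    X = np.column_stack(cols)
    schools = pd.factorize(data["school_id"], sort=True)[0]
    return y, X, schools, names


def _fit(data: pd.DataFrame, outcome: str, adjusted: bool) -> FitResult:
    y, X, schools, names = build_design(data, outcome, adjusted)
    beta, cov, keep = fit_random_intercept(y, X, schools)
    arm = beta[1]
    se = float(np.sqrt(cov[1, 1]))
    sign = -1.0 if outcome == "effect" else 1.0  # effect reported as cases avoided
    coeffs = {nm: float(b) for nm, b, k in zip(names, beta, keep) if k}
    return FitResult(delta=sign * float(arm), se=se, coefficients=coeffs)


def fit_cost_model(data: pd.DataFrame, adjusted: bool = True) -> FitResult:
    """Incremental cost delta_c (intervention minus control), from a linear
    model of total cost with school random intercept; when ``adjusted``,
    covariates are location, FSM band, school type and baseline cost."""
    _check_two_schools_per_arm(data)
    return _fit(data, "cost", adjusted)


def fit_effect_model(
    data: pd.DataFrame, adjusted: bool = True, model: str = "linear"
) -> FitResult:
    """Incremental effect delta_e: adjusted risk difference in HED at 33
    months, reported as cases avoided (control minus intervention).

    ``model="linear"`` (default) is a linear probability model whose arm
    coefficient *is* the adjusted risk difference; ``model="logistic"``
    fits a logistic regression (cluster-robust over schools) and returns
    the marginally standardised risk difference instead.
    """
    _check_two_schools_per_arm(data)
    if model == "linear":
        return _fit(data, "effect", adjusted)
    if model == "logistic":
        return _fit_effect_logistic(data, adjusted)
    raise ValueError(f"unknown effect model: {model!r}")


def _fit_effect_logistic(data: pd.DataFrame, adjusted: bool) -> FitResult:
    """Logistic effect model with marginal standardisation: average the
    fitted risk over the sample with arm set to 0 and to 1; delta-method
    standard error using a school-clustered covariance."""
    import statsmodels.api as sm
    from scipy.special import expit

    y, X, schools, names = build_design(data, "effect", adjusted)
    keep = [0, 1] + [
        j for j in range(2, X.shape[1]) if X[:, j].max() > X[:, j].min()
    ]
    X = X[:, keep]
    names = [names[j] for j in keep]
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            cov_type="cluster", cov_kwds={"groups": schools}
        )
    except (np.linalg.LinAlgError, ValueError) as err:
        raise DegenerateDesignError(f"logistic effect model failed: {err}") from err
    beta = np.asarray(fit.params)
    X1, X0 = X.copy(), X.copy()
    X1[:, 1], X0[:, 1] = 1.0, 0.0
    p1, p0 = expit(X1 @ beta), expit(X0 @ beta)
    delta = float(p0.mean() - p1.mean())  # cases avoided
    grad = (p0 * (1 - p0))[:, None] * X0 - (p1 * (1 - p1))[:, None] * X1
    g = grad.mean(axis=0)
    se = float(np.sqrt(g @ np.asarray(fit.cov_params()) @ g))
    coeffs = dict(zip(names, (float(b) for b in beta)))
    return FitResult(delta=delta, se=se, coefficients=coeffs)


def _check_two_schools_per_arm(data: pd.DataFrame) -> None:
    per_arm = data.groupby("arm")["school_id"].nunique()
    for arm in ("intervention", "control"):
        if per_arm.get(arm, 0) < 2:
            raise DegenerateDesignError(f"need at least 2 schools in arm {arm!r}")


def cluster_bootstrap(
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    adjusted: bool = True,
    max_retries: int = 100,
) -> IncrementalEstimates:
    """Joint school-level bootstrap of (delta_c, delta_e).

    Schools are resampled with replacement within arm; a school drawn twice
    enters as two distinct clusters.  Each resample draws G_a - 1 of the
    G_a schools observed in arm a: with-replacement resampling of all G_a
    clusters understates the sampling variance by the factor (G_a - 1)/G_a,
    and drawing one fewer cluster is the standard correction, which matters
    at the small cluster counts where this estimator is typically used.
    Both models are refitted per resample so each replicate is a correlated
    (delta_c, delta_e) pair.  Deterministic for a fixed seed.  Replicates
    with a degenerate design (a resample can lose a stratum needed for
    identification) are redrawn up to ``max_retries`` times with a logged
    warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _check_two_schools_per_arm(data)
    data = data.reset_index(drop=True)

    y_c, X_c, schools, _ = build_design(data, "cost", adjusted)
    y_e, X_e, _, _ = build_design(data, "effect", adjusted)

    point_c = _fit(data, "cost", adjusted)
    point_e = _fit(data, "effect", adjusted)

    n_schools = schools.max() + 1
    school_rows = [np.flatnonzero(schools == g) for g in range(n_schools)]
    arm_int = (data["arm"] == "intervention").to_numpy()
    schools_int = np.unique(schools[arm_int])
    schools_ctl = np.unique(schools[~arm_int])

    rng = np.random.default_rng(seed)
    reps = np.empty((B, 2))
    n_redraws = 0
    for b in range(B):
        for attempt in range(max_retries + 1):
            draw = np.concatenate(
                [
                    rng.choice(schools_int, size=max(len(schools_int) - 1, 2), replace=True),
                    rng.choice(schools_ctl, size=max(len(schools_ctl) - 1, 2), replace=True),
                ]
            )
            rows = np.concatenate([school_rows[g] for g in draw])
            new_groups = np.repeat(
                np.arange(len(draw)), [len(school_rows[g]) for g in draw]
            )
            try:
                beta_c, _, _ = fit_random_intercept(y_c[rows], X_c[rows], new_groups)
                beta_e, _, _ = fit_random_intercept(y_e[rows], X_e[rows], new_groups)
                reps[b, 0] = beta_c[1]
                reps[b, 1] = -beta_e[1]
                break
            except DegenerateDesignError:
                n_redraws += 1
                continue
        else:
            raise DegenerateDesignError(
                f"bootstrap replicate {b} degenerate after {max_retries} redraws"
            )
    if n_redraws:
        logger.warning("cluster_bootstrap redrew %d degenerate resamples", n_redraws)

    ci_c = tuple(float(x) for x in np.percentile(reps[:, 0], [2.5, 97.5]))
    ci_e = tuple(float(x) for x in np.percentile(reps[:, 1], [2.5, 97.5]))
    return IncrementalEstimates(
        delta_c=point_c.delta,
        delta_e=point_e.delta,
        replicates=reps,
        ci_c=ci_c,
        ci_e=ci_e,
        B=B,
        seed=seed,
        n_intervention=int(arm_int.sum()),
        n_control=int((~arm_int).sum()),
    )
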