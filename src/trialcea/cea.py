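"""Decision-analytic outputs: dominance, ICERs, CE plane and CEACs.

Conventions (documented, deliberately fixed):

* The cost-effectiveness plane has incremental effect (cases avoided) on
  the x axis and incremental cost on the y axis.  Quadrants: NE (more
  effective, more costly), SE (more effective, cheaper), NW (less
  effective, more costly), SW (less effective, cheaper).
* Boundary ties: delta_c == 0 is assigned to the southern side and
  delta_e == 0 to the western side.
* An ICER is reported only when delta_c and delta_e share a sign and
  delta_e != 0; a negative ICER's magnitude carries no meaning, so it is
  suppressed.
* Acceptability at willingness-to-pay lambda uses the strict rule
  NMB = lambda * delta_e - delta_c > 0; a replicate exactly on the
  boundary counts as not cost-effective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NOT_REPORTED",
    "DominanceResult",
    "CEACCurve",
    "classify",
    "ceac",
    "ce_plane_summary",
    "default_lambda_grid",
]

NOT_REPORTED = "not_reported"
QUADRANTS = ("NE", "SE", "NW", "SW")


@dataclass(frozen=True)
class DominanceResult:
    quadrant: str
    label: str  # dominant | weakly_dominant | dominated | weakly_dominated | trade_off
    icer: float | str  # GBP per case avoided, or NOT_REPORTED


@dataclass(frozen=True)
class CEACCurve:
    lambda_grid: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambda_grid, "probability": self.probabilities})


def _quadrant(delta_c: float, delta_e: float) -> str:
    # ties: delta_c == 0 -> south, delta_e == 0 -> west
    north = delta_c > 0
    east = delta_e > 0
    return {(True, True): "NE", (False, True): "SE", (True, False): "NW", (False, False): "SW"}[
        (north, east)
    ]


def _spans_zero(ci) -> bool:
    lo, hi = ci
    if lo > hi:
        raise ValueError(f"CI not ordered: {ci}")
    return lo < 0 < hi


def classify(delta_c: float, delta_e: float, ci_c, ci_e) -> DominanceResult:
    """Classify the point estimate on the CE plane with conventional
    decision rules, downgrading to weak dominance when either CI spans 0."""
    quadrant = _quadrant(delta_c, delta_e)
    uncertain = _spans_zero(ci_c) or _spans_zero(ci_e)

    if delta_e == 0:
        if delta_c != 0:
            logger.info("delta_e is exactly 0; ICER undefined, reporting trade_off")
        return DominanceResult(quadrant=quadrant, label="trade_off", icer=NOT_REPORTED)
    if quadrant == "SE":  # cheaper and more effective
        label = "weakly_dominant" if uncertain else "dominant"
        return DominanceResult(quadrant=quadrant, label=label, icer=NOT_REPORTED)
    if quadrant == "NW":  # costlier and less effective
        label = "weakly_dominated" if uncertain else "dominated"
        return DominanceResult(quadrant=quadrant, label=label, icer=NOT_REPORTED)
    # NE / SW: a genuine trade-off; delta_c and delta_e share a sign
    return DominanceResult(quadrant=quadrant, label="trade_off", icer=delta_c / delta_e)


def default_lambda_grid(upper: float = 2000.0, step: float = 5.0) -> np.ndarray:
    """Willingness-to-pay grid, GBP 0 to 2000 per HED case avoided."""
    return np.arange(0.0, upper + step / 2, step)


def ceac(replicates: np.ndarray, lambda_grid=None) -> CEACCurve:
    """Cost-effectiveness acceptability curve over the replicate cloud.

    probability(lambda) = share of replicates with lambda*delta_e - delta_c > 0.
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size == 0:
        raise ValueError("empty replicate set")
    if replicates.ndim != 2 or replicates.shape[1] != 2:
        raise ValueError("replicates must be (B, 2): columns delta_c, delta_e")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if (grid < 0).any():
        raise ValueError("lambda values must be non-negative")
    dc, de = replicates[:, 0], replicates[:, 1]
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    return CEACCurve(lambda_grid=grid, probabilities=(nmb > 0).mean(axis=1))


def ce_plane_summary(replicates: np.ndarray) -> tuple[dict, pd.DataFrame]:
    """Quadrant proportions of the replicate cloud plus plotting data
    (effect on x, cost on y)."""
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size == 0:
        raise ValueError("empty replicate set")
    dc, de = replicates[:, 0], replicates[:, 1]
    quadrants = np.array([_quadrant(c, e) for c, e in zip(dc, de)])
    proportions = {q: float((quadrants == q).mean()) for q in QUADRANTS}
    frame = pd.DataFrame({"delta_e": de, "delta_c": dc, "quadrant": quadrants})
    return proportions, frame
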