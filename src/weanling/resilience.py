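"""Area-between-curves (ABC) resilience index and population summaries.

For each animal two fitted curves are compared: the unperturbed reference
(Gompertz fitted to the weaning weight plus the last four in-horizon
weighings) and the perturbed Gompertz-Makeham fit.  The ABC index is the
signed area between them from weaning to the first time the curves
intersect after the recovery switch,

    ABC = integral_0^{t*} [W_unpert(t) - W_pert(t)] dt      [kg * d],

so it summarises both the amplitude and the duration of the growth
perturbation.  If the curves do not intersect within the 75-day horizon the
integral is taken to the horizon and the record is flagged as censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .growth import (
    HORIZON_DAYS,
    GompertzParams,
    PerturbedParams,
    gompertz_weight,
    perturbed_weight,
)

__all__ = [
    "IntersectionResult",
    "ResilienceRecord",
    "find_intersection_time",
    "compute_abc",
    "build_resilience_record",
    "summarize_population",
]

_SCAN_STEP = 0.1  # days; bracketing grid for the intersection search
_ROOT_TOL = 1e-8  # days; bisection tolerance on the crossing time


@dataclass(frozen=True)
class IntersectionResult:
    """First crossing of the reference and perturbed curves after ts."""

    time: float  # days; horizon if censored, 0 if degenerate
    censored: bool  # no crossing found within the horizon
    degenerate: bool  # curves coincide (C = 0, matched parameters)
    pre_ts_crossing: bool  # anomaly flag: curves also cross before ts


@dataclass(frozen=True)
class ResilienceRecord:
    """Per-animal resilience summary."""

    animal_id: str
    C: float
    ts: float
    ABC: float
    intersection_time: float
    censored: bool
    J_rank: Optional[int] = None

    @property
    def flagged_negative(self) -> bool:
        """Anomaly surface: the perturbed curve dominated the reference."""
        return self.ABC < 0


def _difference(unpert: GompertzParams, pert: PerturbedParams):
    def diff(t):
        return gompertz_weight(unpert, t) - perturbed_weight(pert, t)

    return diff


def _is_degenerate(unpert: GompertzParams, pert: PerturbedParams) -> bool:
    return (
        pert.C == 0.0
        and unpert.W0 == pert.W0
        and unpert.mu0 == pert.mu0
        and unpert.D == pert.D
    )


def find_intersection_time(
    unpert: GompertzParams,
    pert: PerturbedParams,
    horizon: float = HORIZON_DAYS,
) -> IntersectionResult:
    """Smallest t* > ts where the two curves meet.

    Sign-change bracketing on a 0.1-day grid over (ts, horizon], refined by
    bisection.  Both curves must share W0 and the weaning time origin.
    A crossing of the two curves before ts (reference below the perturbed
    curve during the perturbation window) is anomalous and only flagged.
    """
    if _is_degenerate(unpert, pert):
        return IntersectionResult(0.0, censored=False, degenerate=True,
                                  pre_ts_crossing=False)
    diff = _difference(unpert, pert)

    # sanity scan before ts: the reference should dominate there
    pre_grid = np.arange(_SCAN_STEP, pert.ts, _SCAN_STEP)
    pre_cross = bool(pre_grid.size) and bool(np.any(diff(pre_grid) < 0))

    grid = np.arange(pert.ts, horizon + _SCAN_STEP / 2, _SCAN_STEP)
    grid[-1] = min(grid[-1], horizon)
    vals = diff(grid)
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    exact_zero = np.flatnonzero(vals == 0.0)
    if exact_zero.size and grid[exact_zero[0]] > pert.ts:
        t_star = float(grid[exact_zero[0]])
    elif sign_change.size:
        lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
        t_star = float(brentq(diff, lo, hi, xtol=_ROOT_TOL))
    else:
        return IntersectionResult(float(horizon), censored=True,
                                  degenerate=False, pre_ts_crossing=pre_cross)
    return IntersectionResult(t_star, censored=False, degenerate=False,
                              pre_ts_crossing=pre_cross)


def compute_abc(
    unpert: GompertzParams,
    pert: PerturbedParams,
    horizon: float = HORIZON_DAYS,
) -> float:
    """Signed area between the reference and perturbed curves, kg*d.

    Integrates (W_unpert - W_pert) from 0 to the intersection time (horizon
    when censored) by adaptive quadrature with the recovery switch as an
    interior breakpoint.  Exactly 0 for coincident curves.  A negative ABC
    is possible (perturbed curve above the reference) and left signed.
    """
    inter = find_intersection_time(unpert, pert, horizon)
    if inter.degenerate:
        return 0.0
    t_star = inter.time
    diff = _difference(unpert, pert)
    pts = [pert.ts] if 0.0 < pert.ts < t_star else None
    val, _ = quad(diff, 0.0, t_star, points=pts, epsrel=1e-10,
                  epsabs=1e-12, limit=200)
    return float(val)


def build_resilience_record(
    animal_id: str,
    unpert: GompertzParams,
    pert: PerturbedParams,
    horizon: float = HORIZON_DAYS,
    j_rank: Optional[int] = None,
) -> ResilienceRecord:
    """Assemble the per-animal record (C, ts, ABC, intersection, rank)."""
    inter = find_intersection_time(unpert, pert, horizon)
    abc = compute_abc(unpert, pert, horizon)
    return ResilienceRecord(
        animal_id=animal_id,
        C=pert.C,
        ts=pert.ts,
        ABC=abc,
        intersection_time=inter.time,
        censored=inter.censored,
        J_rank=j_rank,
    )


def summarize_population(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Descriptive statistics (mean, SD, min, quartiles, max) per parameter.

    SD uses the n-1 denominator; with a single animal the SD is NaN.  Row
    order of the input does not affect the summary.
    """
    if table.empty:
        raise ValueError("cannot summarise an empty table")
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])
                   and c not in ("J_rank",)]
    rows = []
    for col in columns:
        vals = np.sort(table[col].dropna().to_numpy(dtype=float))
        if vals.size == 0:
            continue
        rows.append(
            {
                "parameter": col,
                "n": vals.size,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan,
                "min": float(np.min(vals)),
                "q25": float(np.quantile(vals, 0.25)),
                "median": float(np.quantile(vals, 0.5)),
                "q75": float(np.quantile(vals, 0.75)),
                "max": float(np.max(vals)),
            }
        )
    return pd.DataFrame(rows)
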