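"""Gompertz and piecewise Gompertz-Makeham growth laws.

The unperturbed growth of a piglet after weaning is described by a Gompertz
law in which the specific growth rate decays exponentially,

    mu(t) = mu0 * exp(-D * t),
    W(t)  = W0 * exp[(mu0 / D) * (1 - exp(-D * t))],

with ``t`` the time since weaning in days, ``W0`` the weaning weight (kg),
``mu0`` the specific growth rate at weaning (1/d) and ``D`` (1/d) the decay
coefficient of the growth rate.  The mature-weight asymptote is
``W0 * exp(mu0 / D)``.

Weaning is a perturbation: for a transient window the growth rate is reduced
by an environment-dependent Makeham term ``C`` (1/d), switched off at a
per-animal recovery time ``ts`` (d).  In differential form,

    dW/dt = (mu(t) - C(t)) * W,   dmu/dt = -D * mu,
    C(t) = C for t <= ts,  C(t) = 0 for t > ts,

which integrates piecewise to closed form:

    t <= ts:  W(t) = W0 * exp[(mu0/D) * (1 - e^{-Dt}) - C t]
    t >  ts:  W(t) = W(ts) * exp[(mu0/D) * (e^{-D ts} - e^{-D t})]

With ``C = 0`` the perturbed model reduces exactly to the Gompertz law.
When ``C > mu(t)`` the animal loses weight, which reproduces the weight loss
commonly observed in the first days after weaning.

The closed forms are the primary implementation; :func:`integrate_ode_oracle`
integrates the ODE system numerically (with the recovery switch handled as an
integration breakpoint) and serves as an independent numerical cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "HORIZON_DAYS",
    "GrowthDomainError",
    "GompertzParams",
    "PerturbedParams",
    "TimeGrid",
    "gompertz_weight",
    "specific_growth_rate",
    "perturbed_weight",
    "integrate_ode_oracle",
]

#: Analysis horizon: growth is modelled over the first 75 days after weaning.
HORIZON_DAYS = 75.0


class GrowthDomainError(ValueError):
    """Raised when growth-law parameters or times are outside their domain."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise GrowthDomainError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the unperturbed Gompertz growth law.

    Attributes
    ----------
    W0 : float
        Live weight at weaning (t = 0), kg.  Must be positive.
    mu0 : float
        Specific growth rate at weaning, 1/d.  Must be non-negative.
    D : float
        Exponential decay coefficient of the growth rate, 1/d.  Positive.
    """

    W0: float
    mu0: float
    D: float

    def __post_init__(self) -> None:
        if _require_finite("W0", self.W0) <= 0:
            raise GrowthDomainError(f"W0 must be > 0, got {self.W0}")
        if _require_finite("mu0", self.mu0) < 0:
            raise GrowthDomainError(f"mu0 must be >= 0, got {self.mu0}")
        if _require_finite("D", self.D) <= 0:
            raise GrowthDomainError(f"D must be > 0, got {self.D}")

    @property
    def asymptote(self) -> float:
        """Mature weight W0 * exp(mu0 / D), kg."""
        return self.W0 * math.exp(self.mu0 / self.D)


@dataclass(frozen=True)
class PerturbedParams:
    """Parameters of the piecewise Gompertz-Makeham (perturbed) growth law.

    Extends :class:`GompertzParams` with the perturbation depth ``C`` (1/d,
    non-negative) and the recovery-switch time ``ts`` (days since weaning,
    strictly inside the 75-day analysis horizon).
    """

    W0: float
    mu0: float
    D: float
    C: float
    ts: float

    def __post_init__(self) -> None:
        GompertzParams(self.W0, self.mu0, self.D)  # reuse base validation
        if _require_finite("C", self.C) < 0:
            raise GrowthDomainError(f"C must be >= 0, got {self.C}")
        ts = _require_finite("ts", self.ts)
        if not (0.0 < ts < HORIZON_DAYS):
            raise GrowthDomainError(
                f"ts must lie in (0, {HORIZON_DAYS}) days, got {ts}"
            )

    @property
    def unperturbed(self) -> GompertzParams:
        """The matched Gompertz law obtained by dropping the perturbation."""
        return GompertzParams(self.W0, self.mu0, self.D)


GrowthParams = Union[GompertzParams, PerturbedParams]


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing grid of non-negative times (days since weaning)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise GrowthDomainError("times must be a non-empty 1-D array")
        if not np.all(np.isfinite(times)):
            raise GrowthDomainError("times must be finite")
        if times[0] < 0:
            raise GrowthDomainError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise GrowthDomainError("times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise GrowthDomainError("t must be finite")
    if np.any(t < 0):
        raise GrowthDomainError("t must be >= 0 (days since weaning)")
    return t


def gompertz_weight(p: GompertzParams, t) -> np.ndarray:
    """Closed-form Gompertz weight ``W(t)``, kg.

    Uses ``W(t) = W0 * exp[-(mu0/D) * expm1(-D t)]`` which is accurate for
    small ``D`` (the limit D -> 0 recovers exponential growth at rate mu0).
    """
    t = _check_times(t)
    return p.W0 * np.exp(-(p.mu0 / p.D) * np.expm1(-p.D * t))


def specific_growth_rate(p: GrowthParams, t) -> np.ndarray:
    """Specific growth rate ``mu(t) = mu0 * exp(-D t)``, 1/d.

    The perturbation term C does not enter mu; it acts directly on dW/dt.
    """
    t = _check_times(t)
    return p.mu0 * np.exp(-p.D * t)


def perturbed_weight(p: PerturbedParams, t) -> np.ndarray:
    """Closed-form piecewise Gompertz-Makeham weight ``W(t)``, kg.

    The perturbation window is ``t <= ts`` (the boundary point belongs to the
    window; the trajectory is continuous there, so the choice is
    measure-zero).  With ``C = 0`` the result equals
    :func:`gompertz_weight` for all t.
    """
    t = _check_times(t)
    ratio = p.mu0 / p.D
    during = p.W0 * np.exp(-ratio * np.expm1(-p.D * t) - p.C * t)
    w_ts = p.W0 * math.exp(-ratio * math.expm1(-p.D * p.ts) - p.C * p.ts)
    after = w_ts * np.exp(ratio * (math.exp(-p.D * p.ts) - np.exp(-p.D * t)))
    return np.where(t <= p.ts, during, after)


def integrate_ode_oracle(
    p: PerturbedParams,
    grid: TimeGrid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Reference trajectory from numerical integration of the ODE system.

    Integrates ``dW/dt = (mu - C(t)) W``, ``dmu/dt = -D mu`` with the
    recovery switch at ``ts`` handled as a hard integration breakpoint: the
    solver is run on [0, ts] with C active and restarted on [ts, t_max] with
    C = 0, so the discontinuity is never stepped over.  Intended as a
    high-accuracy cross-check of the closed forms, not for production use.

    Raises
    ------
    RuntimeError
        If either integration segment fails; the message echoes ``p``.
    """
    times = grid.times
    t_max = float(times[-1])

    def rhs(c_active: float):
        def f(_t, y):
            w, mu = y
            return [(mu - c_active) * w, -p.D * mu]

        return f

    out = np.empty_like(times)
    y = [p.W0, p.mu0]

    # Segment 1: perturbation window [0, min(ts, t_max)], C active.
    t_split = min(p.ts, t_max)
    mask1 = times <= p.ts
    n1 = int(mask1.sum())
    t_eval1 = times[mask1]
    if t_eval1.size == 0 or t_eval1[-1] < t_split:
        t_eval1 = np.concatenate([t_eval1, [t_split]])  # carry state to ts
    sol1 = solve_ivp(
        rhs(p.C),
        (0.0, t_split),
        y,
        t_eval=t_eval1,
        rtol=rtol,
        atol=atol,
        method="RK45",
        max_step=5.0,
    )
    if not sol1.success:
        raise RuntimeError(f"ODE integration failed on [0, ts] for {p}: {sol1.message}")
    out[:n1] = sol1.y[0][:n1]
    y = [sol1.y[0][-1], sol1.y[1][-1]]

    # Segment 2: recovery window (ts, t_max], C = 0.
    if t_max > p.ts:
        sol2 = solve_ivp(
            rhs(0.0),
            (p.ts, t_max),
            y,
            t_eval=times[~mask1],
            rtol=rtol,
            atol=atol,
            method="RK45",
            max_step=5.0,
        )
        if not sol2.success:
            raise RuntimeError(
                f"ODE integration failed on (ts, horizon] for {p}: {sol2.message}"
            )
        out[n1:] = sol2.y[0]
    return out
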