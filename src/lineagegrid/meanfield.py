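"""Non-spatial (well-mixed) cell-lineage models.

Two ODE systems describe the average dynamics of a stem (S) /
differentiated (D) lineage under negative feedback on the stem-cell
self-renewal probability:

Model 1 — no carrying capacity, feedback acts through D directly::

    dS/dt = r S (2p - 1)
    dD/dt = 2 r S (1 - p) - alpha D
    p = p' / (1 + f1 D^kappa1),   r = r' / (1 + f2 D^kappa2)

A positive equilibrium exists iff ``p' > 0.5``:

    D* = ((2p' - 1) / f1)^(1/kappa1)
    S* = (alpha / r') * D* * (1 + f2 D*^kappa2)

At constant ``p = 0.5`` (``f1 = 0``, ``p' = 0.5``) there is instead a
neutrally stable continuum of equilibria: dS/dt = 0 for every S.

Model 2 — carrying capacity K plus an explicitly tracked mediator pool Z
(the mean-field limit of the lattice model)::

    dS/dt = r S (2p - 1) (1 - (S+D)/K) - eta S
    dD/dt = 2 r S (1 - p) (1 - (S+D)/K) - alpha D
    dZ/dt = xi D - beta Z
    p = p' / (1 + f Z / K)

The mediator abundance is divided by K because in a larger system the
same amount of secreted factor yields a lower concentration per cell.
A consequence is exact scale invariance: rescaling (S, D, Z, K) by a
common factor maps solutions onto solutions, so every equilibrium
coordinate is proportional to K — density, not number, is regulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "Model1Params",
    "Model2Params",
    "model1_rhs",
    "model1_equilibrium",
    "integrate_model1",
    "model2_rhs",
    "model2_equilibrium",
    "integrate_model2",
    "Trajectory",
]


@dataclass(frozen=True)
class Model1Params:
    """Rates of model 1 (per hour where dimensional)."""

    r_basal: float  # r', basal division rate
    p_basal: float  # p', basal self-renewal probability
    alpha: float  # differentiated-cell death rate
    f1: float = 0.0  # feedback strength on p
    kappa1: float = 1.0  # feedback exponent on p
    f2: float = 0.0  # feedback strength on r
    kappa2: float = 1.0  # feedback exponent on r

    def __post_init__(self) -> None:
        for name in ("r_basal", "p_basal", "alpha", "f1", "kappa1", "f2", "kappa2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.p_basal > 1:
            raise ValueError("p_basal is a probability")


@dataclass(frozen=True)
class Model2Params:
    """Rates of model 2 (per hour where dimensional)."""

    r: float  # stem division rate
    p_basal: float  # p'
    f: float  # feedback strength
    K: float  # carrying capacity (cells)
    alpha: float  # differentiated-cell death rate
    xi: float  # mediator production per differentiated cell
    beta: float  # mediator decay rate
    eta: float = 0.0  # stem-cell death rate

    def __post_init__(self) -> None:
        for name in ("r", "p_basal", "f", "K", "alpha", "xi", "beta", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.p_basal > 1:
            raise ValueError("p_basal is a probability")


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # shape (n_states, len(t))

    @property
    def final(self) -> np.ndarray:
        return self.y[:, -1]


def model1_rhs(state, params: Model1Params) -> np.ndarray:
    S, D = state
    p = params.p_basal / (1.0 + params.f1 * D**params.kappa1)
    r = params.r_basal / (1.0 + params.f2 * D**params.kappa2)
    dS = r * S * (2.0 * p - 1.0)
    dD = 2.0 * r * S * (1.0 - p) - params.alpha * D
    return np.array([dS, dD])


def model1_equilibrium(params: Model1Params) -> tuple[float, float] | None:
    """Closed-form positive equilibrium of model 1, or ``None``.

    Requires feedback on p (``f1 > 0``) and ``p' > 0.5``; otherwise no
    finite positive equilibrium exists.
    """
    if params.p_basal <= 0.5 or params.f1 <= 0.0:
        return None
    D = ((2.0 * params.p_basal - 1.0) / params.f1) ** (1.0 / params.kappa1)
    if params.r_basal == 0.0:
        return None
    S = (params.alpha / params.r_basal) * D * (1.0 + params.f2 * D**params.kappa2)
    return S, D


def integrate_model1(
    params: Model1Params,
    init,
    horizon: float,
    t_eval=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    sol = solve_ivp(
        lambda t, y: model1_rhs(y, params),
        (0.0, horizon),
        np.asarray(init, dtype=float),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"model 1 integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y)


def model2_rhs(state, params: Model2Params) -> np.ndarray:
    S, D, Z = state
    p = params.p_basal / (1.0 + params.f * Z / params.K)
    brake = 1.0 - (S + D) / params.K
    dS = params.r * S * (2.0 * p - 1.0) * brake - params.eta * S
    dD = 2.0 * params.r * S * (1.0 - p) * brake - params.alpha * D
    dZ = params.xi * D - params.beta * Z
    return np.array([dS, dD, dZ])


def integrate_model2(
    params: Model2Params,
    init,
    horizon: float,
    t_eval=None,
    rtol: float = 1e-10,
    atol: float | None = None,
) -> Trajectory:
    if atol is None:
        atol = 1e-12 * params.K
    y0 = np.asarray(init, dtype=float)
    if y0.min() < 0:
        raise ValueError("initial state must be non-negative")
    sol = solve_ivp(
        lambda t, y: model2_rhs(y, params),
        (0.0, horizon),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"model 2 integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y)


def model2_equilibrium(
    params: Model2Params, init=None, settle_horizon: float = 1e5
) -> np.ndarray:
    """Attracting equilibrium of model 2: positive root or ``(0, 0, 0)``.

    When the population is not viable at low density (the growth
    condition ``r (2p' - 1) > eta`` fails, reducing to ``p' > 0.5`` when
    ``eta = 0``) the trivial equilibrium is returned.  Otherwise a long
    integration from ``init`` (default: the 49-stem-cell seed) locates
    the attractor and a root find polishes it to ``||rhs|| <= 1e-10 K``;
    near the viability threshold, where the Jacobian degenerates, the
    settled integration endpoint is accepted if it already meets that
    residual.
    """
    if params.r * (2.0 * params.p_basal - 1.0) <= params.eta:
        return np.zeros(3)
    if init is None:
        init = (49.0, 0.0, 0.0)
    tol = 1e-10 * params.K
    fun = lambda y: model2_rhs(y, params)  # noqa: E731
    x = None
    for horizon in (settle_horizon, 100.0 * settle_horizon):
        traj = integrate_model2(params, init, horizon)
        x0 = traj.final
        if np.all(x0 < 1e-8 * params.K):
            return np.zeros(3)
        sol = root(fun, x0, method="hybr", tol=1e-14)
        if sol.success and np.linalg.norm(fun(sol.x)) <= tol:
            x = sol.x
            break
        if np.linalg.norm(fun(x0)) <= tol:
            x = x0
            break
    if x is None:
        raise RuntimeError(
            f"equilibrium root-finding failed; residual {np.linalg.norm(fun(x0)):g}"
        )
    if np.any(x < 1e-8 * params.K):
        return np.zeros(3)
    return x
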