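"""Slow-fast separation: quasi-steady-state hormones and the 2-D reduction.

Hormone lifetimes are minutes while gland-mass and CNS turnover are weeks,
so on the slow timescale the hormones sit at the quasi-steady state (QSS)
determined by the instantaneous gland masses, stress input and CNS
activity.  Substituting the QSS into the slow equations, and fixing the
pituitary at its cortisol-independent steady-state size, reduces the model
to a two-dimensional system in the adrenal mass ``A`` and CNS activity
``h`` — the toggle-switch phase plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._switching import build_pieces, integrate_switched
from .model import cns_drive
from .params import ConfigError, DomainError, ModelParameters
from .protocol import Protocol


@dataclass(frozen=True)
class ReducedState:
    """State of the reduced slow system."""
    A: float
    h: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.h > 0):
            raise DomainError(
                f"reduced state must be positive, got A={self.A}, h={self.h}")


def fast_qss(A: float, P: float, u: float, h: float,
             params: ModelParameters) -> tuple[float, float, float]:
    """Hormone levels (x1, x2, x3) at quasi-steady state.

    Cortisol balances total production against removal across the cascade,
    x3 = sqrt((a1 a2 a3)/(b1 b2 b3) * A P u / h); CRH and ACTH follow from
    their own balances at that cortisol level.
    """
    for name, value in (("A", A), ("P", P), ("u", u), ("h", h)):
        if not value > 0:
            raise DomainError(f"{name} must be positive, got {value}")
    gain = (params.a1 * params.a2 * params.a3
            / (params.b1 * params.b2 * params.b3))
    x3 = np.sqrt(gain * A * P * u / h)
    x1 = params.a1 * u / (params.b1 * h * x3)
    x2 = params.a2 * x1 * P / params.b2
    return float(x1), float(x2), float(x3)


def slow_steady_hormones(params: ModelParameters) -> tuple[float, float]:
    """Slow steady states of CRH and ACTH, (bP/aP, bA/aA).

    The gland-mass equations implement integral feedback on their growth
    factors, so these values are independent of the stress input u.
    """
    return params.bP / params.aP, params.bA / params.aA


def pituitary_steady_state(params: ModelParameters,
                           gr_factor: float = 1.0) -> float:
    """Pituitary steady-state mass bA aP b2 / (aA bP a2), times ``gr_factor``.

    In the simplified model the pituitary size is independent of cortisol
    (``gr_factor`` = 1).  In the full model GR-mediated inhibition of ACTH
    secretion is compensated by growth, P_st proportional to GR(x3); pass
    ``gr_factor = gr_activity(x3, params)`` for that variant.
    """
    if not gr_factor > 0:
        raise DomainError(f"gr_factor must be positive, got {gr_factor}")
    base = (params.bA * params.aP * params.b2
            / (params.aA * params.bP * params.a2))
    return base * gr_factor


def cortisol_slow_steady_state(u: float, h: float,
                               params: ModelParameters) -> float:
    """Slow steady-state cortisol a1 aP/(b1 bP) * u/h.

    Cortisol tracks its hypothalamic input: proportional to stress u,
    inversely proportional to CNS inhibition h.
    """
    if not (u > 0 and h > 0):
        raise DomainError(f"u and h must be positive, got u={u}, h={h}")
    return params.cortisol_gain * u / h


def reduced_cortisol(A: float, u: float, h: float,
                     params: ModelParameters) -> float:
    """QSS cortisol in the reduced system (pituitary at its steady size)."""
    return fast_qss(A, pituitary_steady_state(params), u, h, params)[2]


def slow_rhs(reduced: ReducedState, u: float, D: float,
             params: ModelParameters, *, drive_mode: str = "step",
             steepness: float = 50.0) -> tuple[float, float]:
    """Time derivative (dA/dt, dh/dt) of the reduced 2-D system."""
    if not u > 0:
        raise DomainError(f"stress input u must be positive, got {u}")
    if not D >= 1:
        raise DomainError(f"treatment factor D must be >= 1, got {D}")
    A, h = reduced.A, reduced.h
    P_st = pituitary_steady_state(params)
    _, x2, x3 = fast_qss(A, P_st, u, h, params)
    dA = params.aA * A * x2 - params.bA * A
    dh = params.ah * D / cns_drive(x3, params, drive_mode, steepness) \
        - params.bh * h
    return float(dA), float(dh)


SLOW_COLUMNS = ["t", "P", "A", "h", "x3_qss", "u", "D"]


def integrate_slow(init: tuple[float, float, float], protocol: Protocol,
                   params: ModelParameters, t_grid: np.ndarray, *,
                   drive_mode: str = "step", steepness: float = 50.0,
                   rtol: float = 1e-9, atol: float = 1e-11,
                   method: str = "LSODA") -> pd.DataFrame:
    """Integrate the three-variable slow subsystem (P, A, h).

    Hormones are slaved to their quasi-steady state; unlike the 2-D phase
    plane this keeps the pituitary dynamic, capturing its transient growth
    during multi-week stress episodes.  ``init`` is (P, A, h).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ConfigError("t_grid must be a strictly increasing 1-D array")
    span = protocol.span
    if t_grid[0] < span[0] - 1e-9 or t_grid[-1] > span[1] + 1e-9:
        raise ConfigError("t_grid not covered by the protocol span")
    gain = (params.a1 * params.a2 * params.a3
            / (params.b1 * params.b2 * params.b3))

    def x3_qss(y, u):
        return np.sqrt(gain * y[1] * y[0] * u / y[2])

    pieces = build_pieces(protocol, t_grid[0], t_grid[-1], {})

    def rhs(t, y, u, D, branch):
        P, A, h = y
        x1, x2, x3 = fast_qss(A, P, u, h, params)
        if branch is None:
            drive = cns_drive(x3, params, "smooth", steepness)
        else:
            drive = params.a + params.b * branch
        return np.array([params.aP * P * x1 - params.bP * P,
                         params.aA * A * x2 - params.bA * A,
                         params.ah * D / drive - params.bh * h])

    def switch_value(y, u, D):
        return x3_qss(y, u) - params.T

    def nudge(y, branch, u, D):
        y = y.copy()
        x3 = x3_qss(y, u)
        target = params.T * (1 + 1e-10) if branch == 1 else params.T * (1 - 1e-10)
        y[1] *= (target / x3) ** 2
        return y

    Y, u_arr, D_arr = integrate_switched(
        rhs, np.asarray(init, dtype=float), pieces, t_grid,
        switch_value=switch_value, nudge=nudge,
        smooth=(drive_mode == "smooth"), rtol=rtol, atol=atol, method=method)
    frame = pd.DataFrame({"t": t_grid, "P": Y[:, 0], "A": Y[:, 1],
                          "h": Y[:, 2]})
    frame["x3_qss"] = np.sqrt(gain * frame["A"] * frame["P"] * u_arr
                              / frame["h"])
    frame["u"] = u_arr
    frame["D"] = D_arr
    return frame[SLOW_COLUMNS]


REDUCED_COLUMNS = ["t", "A", "h", "x3_qss", "u", "D"]


def integrate_reduced(init: ReducedState, protocol: Protocol,
                      params: ModelParameters, t_grid: np.ndarray, *,
                      drive_mode: str = "step", steepness: float = 50.0,
                      rtol: float = 1e-9, atol: float = 1e-11,
                      method: str = "LSODA") -> pd.DataFrame:
    """Integrate the reduced (A, h) system; columns t, A, h, x3_qss, u, D."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ConfigError("t_grid must be a strictly increasing 1-D array")
    span = protocol.span
    if t_grid[0] < span[0] - 1e-9 or t_grid[-1] > span[1] + 1e-9:
        raise ConfigError("t_grid not covered by the protocol span")
    P_st = pituitary_steady_state(params)
    qss_gain = (params.a1 * params.a2 * params.a3
                / (params.b1 * params.b2 * params.b3)) * P_st

    def x3_qss(y, u):
        return np.sqrt(qss_gain * y[0] * u / y[1])

    pieces = build_pieces(protocol, t_grid[0], t_grid[-1], {})

    def rhs(t, y, u, D, branch):
        A, h = y
        x3 = x3_qss(y, u)
        x2 = (params.a2 / params.b2) * (params.a1 * u
                                        / (params.b1 * h)) * P_st / x3
        dA = params.aA * A * x2 - params.bA * A
        if branch is None:
            drive = cns_drive(x3, params, "smooth", steepness)
        else:
            drive = params.a + params.b * branch
        dh = params.ah * D / drive - params.bh * h
        return np.array([dA, dh])

    def switch_value(y, u, D):
        return x3_qss(y, u) - params.T

    def nudge(y, branch, u, D):
        # displace A multiplicatively so x3_qss lands strictly on one side
        y = y.copy()
        x3 = x3_qss(y, u)
        target = params.T * (1 + 1e-10) if branch == 1 else params.T * (1 - 1e-10)
        y[0] *= (target / x3) ** 2
        return y

    Y, u_arr, D_arr = integrate_switched(
        rhs, np.array([init.A, init.h]), pieces, t_grid,
        switch_value=switch_value, nudge=nudge,
        smooth=(drive_mode == "smooth"), rtol=rtol, atol=atol, method=method)

    frame = pd.DataFrame({"t": t_grid, "A": Y[:, 0], "h": Y[:, 1]})
    frame["x3_qss"] = np.sqrt(qss_gain * frame["A"] * u_arr / frame["h"])
    frame["u"] = u_arr
    frame["D"] = D_arr
    return frame[REDUCED_COLUMNS]
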