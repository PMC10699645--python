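"""Right-hand sides and numerical integration of the HPA-CNS model.

Two variants of the fast hormone dynamics are provided:

* the **full** model, in which cortisol inhibits the hypothalamus through
  both MR and GR receptors and the pituitary through GR only;
* the **simplified** model, valid in the physiological regime
  KMR << x3 << KGR where MR(x3) ~ x3/KMR and GR(x3) ~ 1, which is the
  variant used for all phase-plane algebra.

Both share the slow equations: gland functional-mass turnover driven by the
upstream hormone, and CNS inhibitory activity ``h`` produced under a
divisor that steps from ``a`` to ``a + b`` when cortisol crosses the
threshold ``T`` (GR recruitment in the hippocampus/prefrontal cortex).

In the full model the CRH secretion gain is rescaled by MR(1)*GR(1) so that
the euthymic baseline remains at hormone level 1, preserving the
normalization of the simplified variant.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
import pandas as pd

from ._switching import build_pieces, integrate_switched
from .params import (ConfigError, DomainError, MINUTES_PER_DAY,
                     ModelParameters, STATE_FIELDS, SystemState)
from .protocol import Protocol

#: half-life of synthetic (injected) CRH, minutes
SYNTHETIC_CRH_HALFLIFE_MIN = 43.0

#: first-order decay rate of exogenous CRH, per day
CRH_EX_DECAY = np.log(2.0) / SYNTHETIC_CRH_HALFLIFE_MIN * MINUTES_PER_DAY

#: indices of the injectable state components
LIGAND_INDEX = {"CRH_ex": STATE_FIELDS.index("c_ex"),
                "DEX": STATE_FIELDS.index("d_ex")}

StateRates = namedtuple("StateRates", STATE_FIELDS)


def mr_activity(x3: float, params: ModelParameters) -> float:
    """MR occupancy factor 1 + x3/KMR (non-cooperative, high affinity)."""
    x3 = np.asarray(x3, dtype=float)
    if np.any(x3 < 0):
        raise DomainError("cortisol level must be non-negative")
    out = 1.0 + x3 / params.KMR
    return float(out) if out.ndim == 0 else out


def gr_activity(x: float, params: ModelParameters) -> float:
    """GR occupancy factor 1 + (x/KGR)^n (cooperative, low affinity).

    The ligand ``x`` is cortisol plus any exogenous GR agonist (DEX).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("GR ligand level must be non-negative")
    out = 1.0 + (x / params.KGR) ** params.n_GR
    return float(out) if out.ndim == 0 else out


def cns_drive(x3: float, params: ModelParameters, mode: str = "step",
              steepness: float = 50.0) -> float:
    """Inhibition divisor acting on CNS production.

    ``step`` mode returns ``a`` for x3 <= T and ``a + b`` for x3 > T (the
    boundary belongs to the low branch).  ``smooth`` mode replaces the step
    with a steep Hill sigmoid in (x3/T) of exponent ``steepness``.
    """
    x3 = np.asarray(x3, dtype=float)
    if np.any(x3 < 0):
        raise DomainError("cortisol level must be non-negative")
    if mode == "step":
        out = params.a + params.b * (x3 > params.T)
    elif mode == "smooth":
        # sigma = 1 / (1 + (T/x3)^m), overflow-safe: sigma -> 0 as x3 -> 0
        with np.errstate(over="ignore", divide="ignore"):
            ratio = np.where(x3 > 0, params.T / np.maximum(x3, 1e-300), np.inf)
            sigma = 1.0 / (1.0 + ratio ** steepness)
        out = params.a + params.b * sigma
    else:
        raise ConfigError(f"unknown drive mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def full_input_gain(params: ModelParameters) -> float:
    """CRH secretion gain of the full model.

    Rescales a1 by MR(1)*GR(1) so that the full model's euthymic fixed
    point keeps the normalized baseline x3 = 1 at u = h = 1.
    """
    return params.a1 * mr_activity(1.0, params) * gr_activity(1.0, params)


def _check_rhs_args(y: np.ndarray, u: float, D: float) -> None:
    if y[2] <= 0:
        raise DomainError("singular state: cortisol x3 must be positive")
    if np.any(y < 0):
        raise DomainError("state components must be non-negative")
    if not u > 0:
        raise DomainError(f"stress input u must be positive, got {u}")
    if not D >= 1:
        raise DomainError(f"treatment factor D must be >= 1, got {D}")


def _rhs_array(y: np.ndarray, u: float, D: float, params: ModelParameters,
               *, mode: str, drive: float | None = None,
               drive_mode: str = "step", steepness: float = 50.0,
               freeze_slow: bool = False,
               c_ex_decay: bool = True) -> np.ndarray:
    """Vector field on the flat state array (no argument validation)."""
    x1, x2, x3, P, A, h, c, d = y
    if mode == "simplified":
        crh_production = params.a1 * u / (h * x3)
        acth_production = params.a2 * (x1 + c) * P
    elif mode == "full":
        gr = gr_activity(x3 + d, params)
        crh_production = (full_input_gain(params) * u
                          / (h * mr_activity(x3, params) * gr))
        acth_production = params.a2 * (x1 + c) * P / gr
    else:
        raise ConfigError(f"unknown rhs mode {mode!r}")
    if drive is None:
        drive = cns_drive(x3, params, drive_mode, steepness)
    dx1 = crh_production - params.b1 * x1
    dx2 = acth_production - params.b2 * x2
    dx3 = params.a3 * x2 * A - params.b3 * x3
    if freeze_slow:
        dP = dA = dh = 0.0
    else:
        dP = params.aP * P * x1 - params.bP * P
        dA = params.aA * A * x2 - params.bA * A
        dh = params.ah * D / drive - params.bh * h
    dc = -CRH_EX_DECAY * c if c_ex_decay else 0.0
    return np.array([dx1, dx2, dx3, dP, dA, dh, dc, 0.0])


def simplified_rhs(state: SystemState, u: float, D: float,
                   params: ModelParameters, *, drive_mode: str = "step",
                   steepness: float = 50.0) -> StateRates:
    """Time derivative of the simplified model (MR-dominated feedback)."""
    y = state.as_array()
    _check_rhs_args(y, u, D)
    return StateRates(*_rhs_array(y, u, D, params, mode="simplified",
                                  drive_mode=drive_mode, steepness=steepness))


def full_rhs(state: SystemState, u: float, D: float,
             params: ModelParameters, *, drive_mode: str = "step",
             steepness: float = 50.0) -> StateRates:
    """Time derivative of the full model (explicit MR and GR feedback).

    DEX (``d_ex``) adds to the GR ligand at the hypothalamus and pituitary
    but never to the MR ligand; exogenous CRH (``c_ex``) adds to endogenous
    CRH in the ACTH production term only.
    """
    y = state.as_array()
    _check_rhs_args(y, u, D)
    return StateRates(*_rhs_array(y, u, D, params, mode="full",
                                  drive_mode=drive_mode, steepness=steepness))


TRAJECTORY_COLUMNS = ["t", "x1", "x2", "x3", "P", "A", "h",
                      "u", "D", "c_ex", "d_ex"]


def integrate(rhs_mode: str, init: SystemState, protocol: Protocol,
              params: ModelParameters, t_grid: np.ndarray, *,
              drive_mode: str = "step", steepness: float = 50.0,
              rtol: float = 1e-7, atol: float = 1e-9,
              freeze_slow: bool = False, c_ex_decay: bool = True,
              method: str = "LSODA") -> pd.DataFrame:
    """Integrate the model over ``t_grid`` (days) under a protocol.

    With ``drive_mode='step'`` the CNS step is handled exactly by event
    detection at cortisol-threshold crossings; ``'smooth'`` integrates the
    Hill-smoothed drive instead.  Returns a trajectory DataFrame with
    columns ``t, x1, x2, x3, P, A, h, u, D, c_ex, d_ex``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ConfigError("t_grid must be a strictly increasing 1-D array")
    span = protocol.span
    if t_grid[0] < span[0] - 1e-9 or t_grid[-1] > span[1] + 1e-9:
        raise ConfigError(
            f"t_grid [{t_grid[0]}, {t_grid[-1]}] not covered by the "
            f"protocol span [{span[0]}, {span[1]}]")
    if rhs_mode not in ("full", "simplified"):
        raise ConfigError(f"unknown rhs mode {rhs_mode!r}")

    y0 = init.as_array()
    _check_rhs_args(y0, protocol.u(t_grid[0]), protocol.D(t_grid[0]))
    pieces = build_pieces(protocol, t_grid[0], t_grid[-1], LIGAND_INDEX)

    def rhs(t, y, u, D, branch):
        drive = None if branch is None else params.a + params.b * branch
        return _rhs_array(y, u, D, params, mode=rhs_mode, drive=drive,
                          drive_mode=drive_mode, steepness=steepness,
                          freeze_slow=freeze_slow, c_ex_decay=c_ex_decay)

    def switch_value(y, u, D):
        return y[2] - params.T

    def nudge(y, branch, u, D):
        y = y.copy()
        offset = _relative_nudge(params.T)
        y[2] = params.T + offset if branch == 1 else params.T - offset
        return y

    Y, u_arr, D_arr = integrate_switched(
        rhs, y0, pieces, t_grid, switch_value=switch_value, nudge=nudge,
        smooth=(drive_mode == "smooth"), rtol=rtol, atol=atol, method=method)

    frame = pd.DataFrame(Y, columns=list(STATE_FIELDS))
    frame.insert(0, "t", t_grid)
    frame["u"] = u_arr
    frame["D"] = D_arr
    return frame[TRAJECTORY_COLUMNS]


def _relative_nudge(scale: float) -> float:
    return 1e-10 * max(scale, 1.0)


def save_trajectory(frame: pd.DataFrame, path) -> None:
    """Write a trajectory CSV (round-trips at full precision)."""
    frame[TRAJECTORY_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def load_trajectory(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"trajectory file missing column(s): {sorted(missing)}")
    return frame[TRAJECTORY_COLUMNS]
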