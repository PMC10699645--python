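"""Phase-plane analysis of the reduced (A, h) toggle switch.

Because the CNS drive is an exact step, the reduced vector field is smooth
on each side of the switching manifold ``x3_qss(A, h) = T`` and the fixed
points can be enumerated in closed form:

* **euthymic** branch — h pinned at h_high = ah D/(bh a), A on the adrenal
  nullcline, valid while its cortisol stays at or below the threshold T;
* **depressed** branch — h pinned at h_low = ah D/(bh (a+b)), valid while
  its cortisol exceeds T;
* **threshold** point — the adrenal nullcline's crossing of the switching
  manifold, present exactly when both stable branches coexist; it plays
  the role of the saddle through which the separatrix passes.

This yields the bistability census, the fold-change-to-bifurcation
sensitivity of every parameter, and the stress hysteresis thresholds
u1 (loss of the euthymic state) and u2 < u1 (loss of the depressed state).
A numeric root finder on the Hill-smoothed system provides an independent
cross-check of the piecewise algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .params import ConfigError, DomainError, IntegrationError, ModelParameters
from .protocol import Protocol
from .qss import (ReducedState, cortisol_slow_steady_state, integrate_reduced,
                  pituitary_steady_state, slow_rhs)

BRANCHES = ("euthymic", "depressed", "threshold")


@dataclass(frozen=True)
class FixedPoint:
    A: float
    h: float
    x3: float
    branch: str       # euthymic | depressed | threshold
    stability: str    # stable | unstable

    def to_dict(self) -> dict:
        return {"A": self.A, "h": self.h, "x3": self.x3,
                "branch": self.branch, "stability": self.stability}


@dataclass(frozen=True)
class BifurcationResult:
    parameter_name: str
    direction: str                 # decrease | increase
    critical_fold_change: float    # nan when exists is False
    exists: bool

    def to_dict(self) -> dict:
        return {"parameter_name": self.parameter_name,
                "direction": self.direction,
                "critical_fold_change": self.critical_fold_change,
                "exists": self.exists}


@dataclass(frozen=True)
class HysteresisResult:
    u1: float                  # stress above which the euthymic state is lost
    u2: float                  # stress below which the depressed state is lost
    branches: pd.DataFrame     # columns u, A_euthymic, A_depressed
    bistable_in_range: bool

    def to_dict(self) -> dict:
        return {"u1": self.u1, "u2": self.u2,
                "bistable_in_range": self.bistable_in_range,
                "branches": self.branches.to_dict(orient="list")}


def adrenal_nullcline(h: float, u: float, params: ModelParameters) -> float:
    """Adrenal mass with dA/dt = 0 at given (h, u): A proportional to u/h.

    Setting the QSS ACTH equal to its slow steady state bA/aA gives
    A = (aA/bA)^2 (a1 a2 b3)/(b1 b2 a3) P_st u / h.
    """
    if not (h > 0 and u > 0):
        raise DomainError(f"h and u must be positive, got h={h}, u={u}")
    coeff = ((params.aA / params.bA) ** 2
             * params.a1 * params.a2 * params.b3
             / (params.b1 * params.b2 * params.a3)
             * pituitary_steady_state(params))
    return coeff * u / h


def cns_nullcline(A: float, u: float, D: float,
                  params: ModelParameters) -> list[tuple[float, str]]:
    """Self-consistent CNS steady states at given (A, u).

    ``h`` relaxes to h_high when QSS cortisol is at or below T and to h_low
    when above, so each level is valid only where its own cortisol verdict
    agrees.  Both can be valid at once (the overlap that makes the
    h-nullcline step-like and the system bistable).
    """
    if not (A > 0 and u > 0):
        raise DomainError(f"A and u must be positive, got A={A}, u={u}")
    from .qss import reduced_cortisol
    out = []
    h_high = params.h_high(D)
    if reduced_cortisol(A, u, h_high, params) <= params.T:
        out.append((h_high, "euthymic"))
    h_low = params.h_low(D)
    if reduced_cortisol(A, u, h_low, params) > params.T:
        out.append((h_low, "depressed"))
    return out


def find_fixed_points(u: float, D: float,
                      params: ModelParameters) -> list[FixedPoint]:
    """Enumerate the fixed points of the reduced system in closed form.

    Returns one to three points.  On each frozen branch the cortisol at the
    candidate point is x3 = (a1 aP)/(b1 bP) u/h; the branch is valid when
    that cortisol is consistent with the branch's side of the threshold.
    """
    if not (u > 0 and D >= 1):
        raise DomainError(f"need u > 0 and D >= 1, got u={u}, D={D}")
    points: list[FixedPoint] = []

    h_high = params.h_high(D)
    x3_eu = cortisol_slow_steady_state(u, h_high, params)
    euthymic = None
    if x3_eu <= params.T:
        euthymic = FixedPoint(adrenal_nullcline(h_high, u, params), h_high,
                              x3_eu, "euthymic", "stable")

    h_low = params.h_low(D)
    x3_dep = cortisol_slow_steady_state(u, h_low, params)
    depressed = None
    if x3_dep > params.T:
        depressed = FixedPoint(adrenal_nullcline(h_low, u, params), h_low,
                               x3_dep, "depressed", "stable")

    if euthymic is not None:
        points.append(euthymic)
    if euthymic is not None and depressed is not None:
        # saddle on the switching manifold: x3 = T on the adrenal nullcline
        h_thr = params.cortisol_gain * u / params.T
        points.append(FixedPoint(adrenal_nullcline(h_thr, u, params), h_thr,
                                 params.T, "threshold", "unstable"))
    if depressed is not None:
        points.append(depressed)

    return [fp.__class__(fp.A, fp.h, fp.x3, fp.branch,
                         classify_stability(fp, u, D, params))
            for fp in points]


def classify_stability(fp: FixedPoint, u: float, D: float,
                       params: ModelParameters) -> str:
    """Stability from the Jacobian of the branch-frozen reduced system.

    Threshold-branch points sit on the switching manifold, where the flow
    is repulsive in h on both sides; they are classified unstable by
    construction (under Hill smoothing they become genuine saddles).
    """
    if fp.branch == "threshold":
        return "unstable"
    dA, dh = slow_rhs(ReducedState(fp.A, fp.h), u, D, params)
    scale = max(params.bA * fp.A, params.bh * fp.h)
    if max(abs(dA), abs(dh)) > 1e-6 * scale:
        raise DomainError(
            f"({fp.A}, {fp.h}) is not a fixed point of the reduced system")
    jac = _branch_jacobian(fp, u, D, params)
    return "stable" if np.all(np.linalg.eigvals(jac).real < 0) else "unstable"


def _branch_jacobian(fp: FixedPoint, u: float, D: float,
                     params: ModelParameters,
                     rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian with the CNS drive frozen on fp's branch."""
    drive = params.a if fp.branch == "euthymic" else params.a + params.b

    def field(z):
        A, h = z
        from .qss import fast_qss
        _, x2, _ = fast_qss(A, pituitary_steady_state(params), u, h, params)
        return np.array([params.aA * A * x2 - params.bA * A,
                         params.ah * D / drive - params.bh * h])

    z0 = np.array([fp.A, fp.h])
    jac = np.empty((2, 2))
    for j in range(2):
        step = rel_step * max(abs(z0[j]), 1e-3)
        zp, zm = z0.copy(), z0.copy()
        zp[j] += step
        zm[j] -= step
        jac[:, j] = (field(zp) - field(zm)) / (2 * step)
    return jac


def classify_basin(init: ReducedState, u: float, D: float,
                   params: ModelParameters, *, tol: float = 1e-4,
                   t_cap: float = 3000.0) -> str:
    """Attractor label reached from ``init`` by forward integration.

    In a monostable regime the unique attractor's label is returned with a
    warning.  Raises :class:`IntegrationError` if the trajectory has not
    approached a stable fixed point within ``t_cap`` days.
    """
    stable = [fp for fp in find_fixed_points(u, D, params)
              if fp.stability == "stable"]
    if len(stable) == 1:
        warnings.warn("monostable regime: returning the unique attractor",
                      stacklevel=2)
        return stable[0].branch
    t_grid = np.arange(0.0, t_cap + 1e-9, 25.0)
    traj = integrate_reduced(init, Protocol.constant(u=u, D=D, t_end=t_cap),
                             params, t_grid)
    pts = traj[["A", "h"]].to_numpy()
    # the attractor reached first wins (each is invariant once entered)
    best = None
    for fp in stable:
        dist = np.hypot(pts[:, 0] - fp.A, pts[:, 1] - fp.h)
        hits = np.nonzero(dist < tol)[0]
        if hits.size and (best is None or hits[0] < best[1]):
            best = (fp.branch, hits[0])
    if best is None:
        raise IntegrationError(
            f"no convergence to a stable fixed point within {t_cap} days "
            f"from (A={init.A}, h={init.h})")
    return best[0]


def separatrix(u: float, D: float, params: ModelParameters,
               h_grid: np.ndarray, *, tol: float = 1e-4,
               A_bracket: tuple[float, float] = (0.05, 20.0)) -> pd.DataFrame:
    """Basin boundary A*(h) located by bisection on the attractor label.

    For each ``h`` the returned ``A_star`` satisfies: initial conditions
    with A just below flow to the euthymic state and just above to the
    depressed state.  Requires a bistable regime.
    """
    stable = [fp for fp in find_fixed_points(u, D, params)
              if fp.stability == "stable"]
    if len(stable) < 2:
        raise DomainError("separatrix requires a bistable regime")
    rows = []
    for h in np.asarray(h_grid, dtype=float):
        lo, hi = A_bracket
        lab_lo = classify_basin(ReducedState(lo, h), u, D, params)
        lab_hi = classify_basin(ReducedState(hi, h), u, D, params)
        if lab_lo == lab_hi:
            raise DomainError(
                f"basin labels agree at both A-bracket ends for h={h}; "
                "widen A_bracket")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if classify_basin(ReducedState(mid, h), u, D, params) == lab_lo:
                lo = mid
            else:
                hi = mid
        rows.append({"h": h, "A_star": 0.5 * (lo + hi)})
    return pd.DataFrame(rows)


#: parameters eligible for fold-change scans ("u" scales the stress input)
SCANNABLE = ("u", "a", "b", "T", "a1", "b1", "a2", "b2", "a3", "b3",
             "aP", "bP", "aA", "bA", "ah", "bh")


def bifurcation_foldchange(parameter_name: str, direction: str,
                           u_base: float, params: ModelParameters, *,
                           D: float = 1.0,
                           fold_limits: tuple[float, float] = (0.1, 10.0),
                           tol: float = 0.005) -> BifurcationResult:
    """Critical fold-change of one parameter at which bistability is lost.

    Bisects the multiplicative factor applied to ``parameter_name`` until
    the reduced system's fixed-point count drops from 3 to 1.  ``exists``
    is False when no transition occurs within ``fold_limits``.
    """
    if parameter_name not in SCANNABLE:
        raise ConfigError(
            f"unknown parameter {parameter_name!r}; scannable: {SCANNABLE}")
    if direction not in ("decrease", "increase"):
        raise ConfigError("direction must be 'decrease' or 'increase'")

    def bistable(fold: float) -> bool:
        if parameter_name == "u":
            return len(find_fixed_points(u_base * fold, D, params)) == 3
        scaled = params.replace(
            **{parameter_name: getattr(params, parameter_name) * fold})
        return len(find_fixed_points(u_base, D, scaled)) == 3

    if not bistable(1.0):
        raise DomainError("nominal regime must have 3 fixed points")
    outer = fold_limits[0] if direction == "decrease" else fold_limits[1]
    if bistable(outer):
        return BifurcationResult(parameter_name, direction, float("nan"),
                                 False)
    lo, hi = (outer, 1.0) if direction == "decrease" else (1.0, outer)
    # invariant: exactly one endpoint is bistable
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if bistable(mid) == bistable(lo):
            lo = mid
        else:
            hi = mid
    return BifurcationResult(parameter_name, direction, 0.5 * (lo + hi), True)


def hysteresis_scan(u_range: tuple[float, float], params: ModelParameters,
                    *, D: float = 1.0, num: int = 161) -> HysteresisResult:
    """Stable-branch adrenal size versus stress, with thresholds u1 > u2.

    The euthymic branch exists up to u1 = T h_high (b1 bP)/(a1 aP) and the
    depressed branch down to u2 = T h_low (b1 bP)/(a1 aP); their overlap is
    the hysteresis window.
    """
    if not 0 < u_range[0] < u_range[1]:
        raise ConfigError("u_range must be an increasing positive interval")
    gain = params.cortisol_gain
    u1 = params.T * params.h_high(D) / gain
    u2 = params.T * params.h_low(D) / gain
    if not u2 < u1:
        raise DomainError("degenerate hysteresis window (u2 >= u1)")
    rows = []
    for u in np.linspace(u_range[0], u_range[1], num):
        row = {"u": u, "A_euthymic": np.nan, "A_depressed": np.nan}
        for fp in find_fixed_points(u, D, params):
            if fp.branch == "euthymic":
                row["A_euthymic"] = fp.A
            elif fp.branch == "depressed":
                row["A_depressed"] = fp.A
        rows.append(row)
    branches = pd.DataFrame(rows)
    both = branches.dropna()
    return HysteresisResult(u1, u2, branches, bistable_in_range=len(both) > 0)


def smoothed_fixed_points(u: float, D: float, params: ModelParameters, *,
                          steepness: float = 200.0,
                          starts: list[tuple[float, float]] | None = None
                          ) -> list[tuple[float, float]]:
    """Roots of the Hill-smoothed reduced system (independent cross-check).

    Starts default to the closed-form piecewise fixed points; each is
    refined by a Newton-type root finder on the smoothed vector field.
    """
    if starts is None:
        starts = [(fp.A, fp.h) for fp in find_fixed_points(u, D, params)]

    def field(z):
        return slow_rhs(ReducedState(z[0], z[1]), u, D, params,
                        drive_mode="smooth", steepness=steepness)

    roots = []
    for A0, h0 in starts:
        sol = optimize.root(field, [A0, h0], method="hybr",
                            options={"xtol": 1e-12})
        if sol.success:
            roots.append((float(sol.x[0]), float(sol.x[1])))
    return roots
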