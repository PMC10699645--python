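"""Event-segmented integration of the piecewise-smooth model.

The CNS equation contains a hard step at the cortisol threshold, so the
vector field is smooth on each side of a switching manifold.  The integrator
here freezes the step branch, integrates with a stiff adaptive solver until
the trajectory crosses the manifold (located by solver event detection),
flips the branch and restarts.  Injections and stress/treatment changes from
the protocol define additional restart points.

The switching manifold of this model is repulsive on both sides (the CNS
drive pushes ``h`` away from it), so crossings are transversal and no
Filippov sliding arises; a generous switch cap guards against pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import IntegrationError
from .protocol import Protocol

_NUDGE = 1e-10  # relative offset applied to restart strictly on one side


@dataclass
class Piece:
    """One span of constant (u, D), with state jumps applied at its start."""
    t0: float
    t1: float
    u: float
    D: float
    jumps: list[tuple[int, float]] = field(default_factory=list)


def build_pieces(protocol: Protocol, t0: float, t1: float,
                 ligand_index: dict[str, int]) -> list[Piece]:
    """Split [t0, t1] at segment boundaries and injection times."""
    cuts = {t0, t1}
    for seg in protocol.segments:
        for t in (seg.t_start, seg.t_end):
            if t0 < t < t1:
                cuts.add(t)
    for ev in protocol.events:
        if t0 <= ev.time < t1:
            cuts.add(max(ev.time, t0))
    times = sorted(cuts)
    pieces = []
    for ta, tb in zip(times[:-1], times[1:]):
        mid = 0.5 * (ta + tb)
        pieces.append(Piece(ta, tb, protocol.u(mid), protocol.D(mid)))
    for ev in protocol.events:
        if not t0 <= ev.time < t1:
            continue  # an event at exactly t1 has no dynamics to affect
        for piece in pieces:
            if abs(piece.t0 - ev.time) <= 1e-9:
                piece.jumps.append((ligand_index[ev.ligand], ev.amount))
                break
    return pieces


def integrate_switched(
    rhs: Callable[[float, np.ndarray, float, float, int | None], np.ndarray],
    y0: np.ndarray,
    pieces: Sequence[Piece],
    t_grid: np.ndarray,
    *,
    switch_value: Callable[[np.ndarray, float, float], float],
    nudge: Callable[[np.ndarray, int, float, float], np.ndarray],
    smooth: bool = False,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    method: str = "LSODA",
    max_switches: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate over ``pieces`` and sample the solution on ``t_grid``.

    ``rhs(t, y, u, D, branch)`` is the frozen-branch vector field
    (``branch`` is ``None`` in smooth mode); ``switch_value(y, u, D)`` is
    the signed distance of the state from the switching manifold (negative
    on the low branch); ``nudge(y, branch, u, D)`` returns a copy of ``y``
    displaced strictly onto the given branch's side.

    Returns ``(Y, u_at_grid, D_at_grid)`` with ``Y`` of shape
    ``(len(t_grid), len(y0))``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n = len(t_grid)
    Y = np.empty((n, len(y0)))
    u_arr = np.empty(n)
    D_arr = np.empty(n)
    k = 0  # next grid index to fill
    y = np.asarray(y0, dtype=float).copy()
    switches = 0

    for piece in pieces:
        for idx, amount in piece.jumps:
            y[idx] = max(y[idx] + amount, 0.0)
        # grid points coinciding with the piece start
        while k < n and t_grid[k] <= piece.t0 + 1e-12:
            Y[k] = y
            u_arr[k] = piece.u
            D_arr[k] = piece.D
            k += 1
        t = piece.t0
        while t < piece.t1 - 1e-12:
            if smooth:
                branch = None
                events = None
            else:
                g0 = switch_value(y, piece.u, piece.D)
                if g0 == 0.0:  # tie-break: low branch, restart just below
                    y = nudge(y, 0, piece.u, piece.D)
                    g0 = switch_value(y, piece.u, piece.D)
                branch = 1 if g0 > 0 else 0

                def crossing(tt, yy, *_args, _u=piece.u, _D=piece.D):
                    return switch_value(yy, _u, _D)

                crossing.terminal = True
                crossing.direction = 1.0 if branch == 0 else -1.0
                events = crossing

            pending = [tg for tg in t_grid[k:] if t < tg <= piece.t1 + 1e-12]
            t_eval = sorted(set(pending) | {piece.t1})
            sol = solve_ivp(
                rhs, (t, piece.t1), y, method=method, t_eval=t_eval,
                events=events, rtol=rtol, atol=atol, args=(piece.u, piece.D, branch))
            if not sol.success:
                raise IntegrationError(
                    f"solver failed on [{t}, {piece.t1}] "
                    f"(u={piece.u}, D={piece.D}): {sol.message}")
            # record solved grid points (t_eval entries <= stop time)
            sol_y = np.asarray(sol.y)
            for tt, yy in zip(sol.t, sol_y.T if sol_y.size else []):
                while k < n and abs(t_grid[k] - tt) <= 1e-12:
                    Y[k] = yy
                    u_arr[k] = piece.u
                    D_arr[k] = piece.D
                    k += 1
            if sol.status == 1:  # hit the switching manifold
                t_event = float(sol.t_events[0][0])
                y = np.asarray(sol.y_events[0][0], dtype=float)
                dy = rhs(t_event, y, piece.u, piece.D, branch)
                moving_up = switch_deriv_sign(
                    lambda yy: switch_value(yy, piece.u, piece.D), y, dy)
                new_branch = 1 if moving_up > 0 else 0
                y = nudge(y, new_branch, piece.u, piece.D)
                t = t_event
                switches += 1
                if switches > max_switches:
                    raise IntegrationError(
                        "too many switching-manifold crossings; "
                        "the trajectory appears to chatter")
                if t >= piece.t1 - 1e-12:
                    break
            else:
                y = sol.y[:, -1].copy()
                t = piece.t1

    # trailing grid points at the final time
    while k < n:
        Y[k] = y
        u_arr[k] = pieces[-1].u
        D_arr[k] = pieces[-1].D
        k += 1
    return Y, u_arr, D_arr


def switch_deriv_sign(switch_value, y, dy, eps: float = 1e-8) -> float:
    """Sign of d/dt switch_value along the flow, by forward difference."""
    g0 = switch_value(y)
    g1 = switch_value(y + eps * dy)
    return np.sign(g1 - g0) or -1.0  # tangential graze: fall to low branch
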