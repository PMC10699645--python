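"""In-silico experiments: stress episodes, treatment, and endocrine tests.

The scenario runners reproduce the model's core dynamic claims — prolonged
but not acute stress tips a susceptible system into the self-sustaining
depressed state, recovery needs prolonged below-baseline stress (hysteresis),
and CNS-boosting treatment must last weeks.  The endocrine tests simulate
the clinical CRH and DEX/CRH challenges on subjects parked at the full
model's euthymic (control) or depressed (MDD) fixed point, with gland
masses and CNS activity frozen over the hours-long test window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (LIGAND_INDEX, MINUTES_PER_DAY, full_input_gain,
                    gr_activity, integrate, mr_activity)
from .params import (ConfigError, DomainError, ModelParameters, SystemState)
from .phase import classify_basin, find_fixed_points
from .protocol import Injection, Protocol, Segment
from .qss import (ReducedState, fast_qss, integrate_reduced,
                  pituitary_steady_state)

SUBJECT_LABELS = ("control", "MDD")


@dataclass(frozen=True)
class Subject:
    """An individual parked at a full-model fixed point.

    ``control`` sits at the euthymic point (normal gland sizes); ``MDD`` at
    the depressed point, with the full model's compensation pattern —
    adrenal mass proportional to cortisol, pituitary mass proportional to
    GR(cortisol), so the adrenal is enlarged more than the pituitary.
    """
    label: str
    state: SystemState
    u: float = 1.0


def make_subject(label: str, u: float,
                 params: ModelParameters) -> Subject:
    """Construct a subject at the full model's steady state.

    The fixed point is found by solving the hypothalamic balance
    a1_full u / (b1 h MR(x3) GR(x3)) = bP/aP for cortisol on the requested
    branch; gland masses follow from the hormone balances (A proportional
    to x3, P proportional to GR(x3)).  Raises :class:`DomainError` for an
    MDD subject when no depressed fixed point exists (resilient regime).
    """
    if label not in SUBJECT_LABELS:
        raise ConfigError(f"unknown subject label {label!r}; "
                          f"valid: {SUBJECT_LABELS}")
    if not u > 0:
        raise DomainError(f"stress input u must be positive, got {u}")
    x1_st = params.bP / params.aP
    x2_st = params.bA / params.aA
    h = params.h_high() if label == "control" else params.h_low()

    def balance(x3):
        return (full_input_gain(params) * u
                / (params.b1 * h * mr_activity(x3, params)
                   * gr_activity(x3, params))) - x1_st

    x3 = optimize.brentq(balance, 1e-9, 1e3, xtol=1e-14, rtol=1e-15)
    if label == "control" and x3 > params.T:
        raise DomainError(
            f"no euthymic fixed point at u={u}: cortisol {x3:.3f} exceeds "
            f"the CNS threshold {params.T}")
    if label == "MDD" and x3 <= params.T:
        raise DomainError(
            f"no depressed fixed point at u={u}: cortisol {x3:.3f} does not "
            f"exceed the CNS threshold {params.T} (resilient regime)")
    A = params.b3 * x3 / (params.a3 * x2_st)
    P = params.b2 * x2_st * gr_activity(x3, params) / (params.a2 * x1_st)
    state = SystemState(x1=x1_st, x2=x2_st, x3=x3, P=P, A=A, h=h)
    return Subject(label, state, u)


def simplified_fixed_state(branch: str, u: float, D: float,
                           params: ModelParameters) -> SystemState:
    """Six-variable fixed point of the simplified model on a branch."""
    for fp in find_fixed_points(u, D, params):
        if fp.branch == branch:
            P_st = pituitary_steady_state(params)
            x1, x2, x3 = fast_qss(fp.A, P_st, u, fp.h, params)
            return SystemState(x1=x1, x2=x2, x3=x3, P=P_st, A=fp.A, h=fp.h)
    raise DomainError(f"no {branch!r} fixed point at u={u}, D={D}")


def _run_protocol(protocol: Protocol, init: SystemState, u_final: float,
                  params: ModelParameters, total: float, mode: str,
                  points_per_day: float = 2.0
                  ) -> tuple[pd.DataFrame, str]:
    n = max(int(total * points_per_day), 50)
    t_grid = np.linspace(0.0, total, n + 1)
    if mode == "reduced":
        traj = integrate_reduced(ReducedState(init.A, init.h), protocol,
                                 params, t_grid)
    elif mode in ("simplified", "full"):
        traj = integrate(mode, init, protocol, params, t_grid)
    else:
        raise ConfigError(f"unknown scenario mode {mode!r}")
    final = traj.iloc[-1]
    outcome = classify_basin(ReducedState(final["A"], final["h"]),
                             u_final, 1.0, params)
    return traj, outcome


def run_stress_scenario(u_base: float, u_event: float, t_on: float,
                        duration: float, total: float,
                        params: ModelParameters, *,
                        mode: str = "simplified"
                        ) -> tuple[pd.DataFrame, str]:
    """Euthymic start; stress raised to ``u_event`` for ``duration`` days.

    Returns the trajectory and the attractor ('euthymic' or 'depressed')
    the final state belongs to under baseline stress.
    """
    protocol = Protocol.pulse(u_base, u_event, t_on, duration, total)
    init = simplified_fixed_state("euthymic", u_base, 1.0, params)
    return _run_protocol(protocol, init, u_base, params, total, mode)


def run_relief_scenario(u_base: float, u_relief: float, duration: float,
                        total: float, params: ModelParameters, *,
                        t_on: float = 0.0, mode: str = "simplified"
                        ) -> tuple[pd.DataFrame, str]:
    """Depressed start; stress lowered to ``u_relief`` for ``duration`` days."""
    protocol = Protocol.pulse(u_base, u_relief, t_on, duration, total)
    init = simplified_fixed_state("depressed", u_base, 1.0, params)
    return _run_protocol(protocol, init, u_base, params, total, mode)


def run_treatment_scenario(D_value: float, duration: float, total: float,
                           params: ModelParameters, *, u: float = 1.0,
                           mode: str = "simplified"
                           ) -> tuple[pd.DataFrame, str]:
    """Depressed start; CNS activity boosted by D for ``duration`` days."""
    if not D_value >= 1:
        raise DomainError(f"treatment factor D must be >= 1, got {D_value}")
    segments = [Segment(0.0, duration, u, D_value)]
    if duration < total:
        segments.append(Segment(duration, total, u, 1.0))
    protocol = Protocol(tuple(segments))
    init = simplified_fixed_state("depressed", u, 1.0, params)
    return _run_protocol(protocol, init, u, params, total, mode)


def critical_stress_duration(u_base: float, u_event: float,
                             params: ModelParameters, *,
                             lo: float = 1.0, hi: float = 120.0,
                             tol: float = 1.0, total_margin: float = 200.0,
                             mode: str = "reduced") -> float:
    """Shortest stress duration (days) that tips the system into depression.

    Bisects between a duration that recovers and one that does not; the
    boundary scales with the gland turnover time (weeks at nominal rates).
    """
    def depressed_after(duration: float) -> bool:
        _, outcome = run_stress_scenario(
            u_base, u_event, 0.0, duration, duration + total_margin,
            params, mode=mode)
        return outcome == "depressed"

    if depressed_after(lo) or not depressed_after(hi):
        raise DomainError("bisection bracket does not straddle the "
                          "critical duration")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if depressed_after(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class TestResult:
    """Summary of a simulated endocrine stimulation test."""
    series: pd.DataFrame       # t_min, crh, acth, cortisol, c_ex, d_ex
    baseline_acth: float       # ACTH at the CRH injection time
    peak_acth: float
    peak_time_min: float       # minutes after the CRH injection
    auc_acth: float            # area under ACTH, from injection to end

    def to_dict(self) -> dict:
        return {"baseline_acth": self.baseline_acth,
                "peak_acth": self.peak_acth,
                "peak_time_min": self.peak_time_min,
                "auc_acth": self.auc_acth}


def _endocrine_run(subject: Subject, params: ModelParameters,
                   events: tuple[Injection, ...], span_days: float,
                   c_ex_decay: bool) -> pd.DataFrame:
    protocol = Protocol.constant(u=subject.u, t_end=span_days, events=events)
    n_min = int(round(span_days * MINUTES_PER_DAY))
    t_grid = np.linspace(0.0, span_days, n_min + 1)
    traj = integrate("full", subject.state, protocol, params, t_grid,
                     freeze_slow=True, c_ex_decay=c_ex_decay)
    series = pd.DataFrame({
        "t_min": traj["t"] * MINUTES_PER_DAY,
        "crh": traj["x1"], "acth": traj["x2"], "cortisol": traj["x3"],
        "c_ex": traj["c_ex"], "d_ex": traj["d_ex"]})
    return series


def _summarize(series: pd.DataFrame, injection_min: float) -> TestResult:
    after = series[series["t_min"] >= injection_min - 1e-9]
    baseline = float(after["acth"].iloc[0])
    peak_idx = after["acth"].idxmax()
    peak = float(after.loc[peak_idx, "acth"])
    peak_time = float(after.loc[peak_idx, "t_min"] - injection_min)
    auc = float(np.trapezoid(after["acth"], after["t_min"]))
    return TestResult(series, baseline, peak, peak_time, auc)


def crh_test(subject: Subject, crh_dose: float, params: ModelParameters, *,
             window: float = 240.0, pulse_mode: str = "bolus") -> TestResult:
    """Simulated CRH stimulation test (ACTH response to injected CRH).

    ``window`` is the observation span in minutes.  In ``bolus`` mode the
    dose appears instantaneously and decays with the 43-minute half-life of
    synthetic CRH; ``square`` holds the dose constant for 30 minutes.
    Gland masses and CNS activity are frozen (the test lasts hours, gland
    turnover takes weeks).
    """
    if crh_dose < 0:
        raise DomainError(f"CRH dose must be non-negative, got {crh_dose}")
    span = window / MINUTES_PER_DAY
    events: tuple[Injection, ...] = ()
    if crh_dose > 0:
        if pulse_mode == "bolus":
            events = (Injection(0.0, "CRH_ex", crh_dose),)
            decay = True
        elif pulse_mode == "square":
            t_off = min(30.0 / MINUTES_PER_DAY, span)
            events = (Injection(0.0, "CRH_ex", crh_dose),
                      Injection(t_off, "CRH_ex", -crh_dose))
            decay = False
        else:
            raise ConfigError(f"unknown pulse mode {pulse_mode!r}")
    else:
        decay = True
    series = _endocrine_run(subject, params, events, span, decay)
    return _summarize(series, 0.0)


def dex_crh_test(subject: Subject, dex_level: float, crh_dose: float,
                 params: ModelParameters, *, delay: float = 15.0,
                 window: float = 240.0) -> TestResult:
    """Simulated DEX/CRH test: DEX at time zero, CRH ``delay`` hours later.

    DEX is a long-lived GR-selective agonist: it is held constant over the
    test and acts only through the GR terms (hypothalamic and pituitary),
    never through MR.  The summary covers the post-CRH window; the series
    also shows the preceding DEX suppression phase.
    """
    if dex_level < 0 or crh_dose < 0:
        raise DomainError("DEX level and CRH dose must be non-negative")
    delay_days = delay / 24.0
    span = delay_days + window / MINUTES_PER_DAY
    events = []
    if dex_level > 0:
        events.append(Injection(0.0, "DEX", dex_level))
    if crh_dose > 0:
        events.append(Injection(delay_days, "CRH_ex", crh_dose))
    series = _endocrine_run(subject, params, tuple(events), span, True)
    return _summarize(series, delay_days * MINUTES_PER_DAY)
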