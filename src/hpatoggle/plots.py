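"""Figure regeneration: phase portraits, stress dynamics, endocrine tests.

Each figure writer also exports its underlying data (CSV/JSON) next to the
plot so the numbers can be inspected without re-running the model.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .params import ConfigError, ModelParameters
from .phase import (adrenal_nullcline, find_fixed_points, hysteresis_scan)
from .scenarios import (crh_test, dex_crh_test, make_subject,
                        run_relief_scenario, run_stress_scenario,
                        run_treatment_scenario)

FIGURES = ("fig1", "fig2", "fig3", "fig4")


def regenerate_figure(which: str, out_dir: str | Path,
                      params: ModelParameters | None = None) -> list[Path]:
    """Regenerate one figure family; returns the written file paths."""
    params = params or ModelParameters()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    makers = {"fig1": _phase_portraits, "fig2": _stress_dynamics,
              "fig3": _endocrine_tests, "fig4": _treatment_dynamics}
    if which not in makers:
        raise ConfigError(f"unknown figure {which!r}; valid: {FIGURES}")
    return makers[which](params, out)


def _nullcline_frame(u: float, params: ModelParameters) -> pd.DataFrame:
    h_grid = np.geomspace(0.2, 2.5, 300)
    A_null = [adrenal_nullcline(h, u, params) for h in h_grid]
    return pd.DataFrame({"h": h_grid, "A_nullcline": A_null})


def _phase_portraits(params: ModelParameters, out: Path) -> list[Path]:
    written = []
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, u, title in zip(axes, (1.0, 0.4),
                            ("susceptible (u = 1)", "resilient (u = 0.4)")):
        frame = _nullcline_frame(u, params)
        csv_path = out / f"fig1_nullclines_u{u}.csv"
        frame.to_csv(csv_path, index=False)
        written.append(csv_path)
        ax.plot(frame["A_nullcline"], frame["h"], "r-", label="dA/dt = 0")
        # step-like h nullcline: h_high where x3 <= T, h_low where x3 > T
        A_grid = np.geomspace(0.2, 4.0, 400)
        for level, name in ((params.h_high(), "high"), (params.h_low(), "low")):
            from .qss import reduced_cortisol
            x3 = np.array([reduced_cortisol(A, u, level, params)
                           for A in A_grid])
            ok = (x3 <= params.T) if name == "high" else (x3 > params.T)
            ax.plot(np.where(ok, A_grid, np.nan),
                    np.full_like(A_grid, level), "k-",
                    label="dh/dt = 0" if name == "high" else None)
        for fp in find_fixed_points(u, 1.0, params):
            marker = "o" if fp.stability == "stable" else "x"
            ax.plot(fp.A, fp.h, "k" + marker, ms=8)
        ax.set_xlabel("adrenal mass A")
        ax.set_title(title)
        ax.legend(loc="upper right", fontsize=8)
    axes[0].set_ylabel("CNS inhibitory activity h")
    png = out / "fig1_phase_portraits.png"
    fig.tight_layout()
    fig.savefig(png, dpi=150)
    plt.close(fig)
    written.append(png)
    points = [fp.to_dict() | {"u": u}
              for u in (1.0, 0.4) for fp in find_fixed_points(u, 1.0, params)]
    jpath = out / "fig1_fixed_points.json"
    jpath.write_text(json.dumps(points, indent=2))
    written.append(jpath)
    return written


def _stress_dynamics(params: ModelParameters, out: Path) -> list[Path]:
    written = []
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    runs = [
        ("brief stress", run_stress_scenario(1.0, 2.0, 5.0, 3.0, 120.0, params)),
        ("prolonged stress", run_stress_scenario(1.0, 2.0, 5.0, 60.0, 160.0, params)),
        ("brief relief", run_relief_scenario(1.0, 0.5, 3.0, 120.0, params)),
        ("prolonged relief", run_relief_scenario(1.0, 0.5, 60.0, 160.0, params)),
    ]
    for ax, (title, (traj, outcome)) in zip(axes.ravel(), runs):
        csv_path = out / f"fig2_{title.replace(' ', '_')}.csv"
        traj.to_csv(csv_path, index=False)
        written.append(csv_path)
        ax.plot(traj["t"], traj["A"], label="A")
        ax.plot(traj["t"], traj["h"], label="h")
        ax.plot(traj["t"], traj["u"], "k:", label="u")
        ax.set_title(f"{title} -> {outcome}", fontsize=9)
        ax.set_xlabel("t (days)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    png = out / "fig2_stress_dynamics.png"
    fig.savefig(png, dpi=150)
    plt.close(fig)
    written.append(png)

    hyst = hysteresis_scan((0.4, 2.0), params)
    csv_path = out / "fig2_hysteresis.csv"
    hyst.branches.to_csv(csv_path, index=False)
    written.append(csv_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(hyst.branches["u"], hyst.branches["A_euthymic"], label="euthymic")
    ax.plot(hyst.branches["u"], hyst.branches["A_depressed"], label="depressed")
    ax.axvline(hyst.u1, ls="--", c="gray")
    ax.axvline(hyst.u2, ls="--", c="gray")
    ax.set_xlabel("stress input u")
    ax.set_ylabel("steady-state adrenal mass A")
    ax.set_title(f"hysteresis: u1 = {hyst.u1:.3g}, u2 = {hyst.u2:.3g}")
    ax.legend()
    fig.tight_layout()
    png = out / "fig2_hysteresis.png"
    fig.savefig(png, dpi=150)
    plt.close(fig)
    written.append(png)
    return written


def _endocrine_tests(params: ModelParameters, out: Path) -> list[Path]:
    written = []
    control = make_subject("control", 1.0, params)
    mdd = make_subject("MDD", 1.0, params)
    dose, dex = 5.0, 3.0 * params.KGR
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    summary = {}
    for ax, test_name in zip(axes, ("crh", "dex_crh")):
        for subject in (control, mdd):
            if test_name == "crh":
                result = crh_test(subject, dose, params)
                offset = 0.0
            else:
                result = dex_crh_test(subject, dex, dose, params)
                offset = 15.0 * 60.0
            series = result.series
            mask = series["t_min"] >= offset
            ax.plot(series.loc[mask, "t_min"] - offset,
                    series.loc[mask, "acth"], label=subject.label)
            summary[f"{test_name}_{subject.label}"] = result.to_dict()
            csv_path = out / f"fig3_{test_name}_{subject.label}.csv"
            series.to_csv(csv_path, index=False)
            written.append(csv_path)
        ax.set_xlabel("minutes after CRH")
        ax.set_ylabel("ACTH (normalized)")
        ax.set_title("CRH test" if test_name == "crh" else "DEX/CRH test")
        ax.legend()
    fig.tight_layout()
    png = out / "fig3_endocrine_tests.png"
    fig.savefig(png, dpi=150)
    plt.close(fig)
    written.append(png)
    jpath = out / "fig3_peaks.json"
    jpath.write_text(json.dumps(summary, indent=2))
    written.append(jpath)
    return written


def _treatment_dynamics(params: ModelParameters, out: Path) -> list[Path]:
    written = []
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    runs = [("brief treatment", run_treatment_scenario(2.0, 5.0, 120.0, params)),
            ("prolonged treatment", run_treatment_scenario(2.0, 60.0, 160.0, params))]
    for ax, (title, (traj, outcome)) in zip(axes, runs):
        csv_path = out / f"fig4_{title.replace(' ', '_')}.csv"
        traj.to_csv(csv_path, index=False)
        written.append(csv_path)
        ax.plot(traj["t"], traj["A"], label="A")
        ax.plot(traj["t"], traj["h"], label="h")
        ax.plot(traj["t"], traj["D"], "k:", label="D")
        ax.set_title(f"{title} -> {outcome}", fontsize=9)
        ax.set_xlabel("t (days)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    png = out / "fig4_treatment.png"
    fig.savefig(png, dpi=150)
    plt.close(fig)
    written.append(png)
    return written
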