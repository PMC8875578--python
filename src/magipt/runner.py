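"""Scenario orchestration: flow → magnetics → transport → efficacy metrics.

The pipeline is fully deterministic: the steady interstitial flow is
solved once, the magnetophoretic velocity field is evaluated from the
analytic magnet field, the three-species transport system is integrated
over the treatment hour, and the efficacy report is computed from the
final fields.  Conventional IP chemotherapy is simply the B_rem = 0 limit
of the same pipeline.

Two scalar calibrations anchor the model to measurable quantities:

* ``calibrate_boundary_concentration`` — the rim drug concentration is the
  one free concentration scale; by linearity a single unit-concentration
  run fixes it from a target tumor-mean free-drug level.
* ``calibrate_magnetic_mobility`` — a single dimensionless factor on the
  magnetic force absorbs the particle magnetic content that published
  parameter tables leave open (susceptibility, saturation moment, carrier
  loading); it is root-found so the baseline magnetic penetration
  half-depth matches a target, after which every other magnetic scenario
  is a prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flow import solve_darcy, velocity_from_pressure
from .grid import build_grid
from .metrics import EfficacyReport, compute_efficacy
from .params import Scenario, write_config
from .transport import TransientResult, build_operators, run_transient

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "sweep",
    "calibrate_boundary_concentration",
    "calibrate_magnetic_mobility",
    "write_result",
    "PENETRATION_ANGLE",
]

#: Angle at which the magnetophoretic force enters the tumor (the rim face
#: away from the magnet on the +y side): the bottom of the vertical diameter.
PENETRATION_ANGLE = 3.0 * np.pi / 2.0

SWEEP_AXES = {
    "particle_radius": "nanoparticle.radius_a",
    "B_rem": "magnet.B_rem",
    "distance": "magnet.distance_d",
}


@dataclass
class ScenarioResult:
    name: str
    config: dict                 # resolved scenario snapshot (SI)
    report: EfficacyReport
    means: pd.DataFrame          # tumor-mean concentration time series
    transient: TransientResult = field(repr=False)
    pressure: np.ndarray = field(repr=False)
    provenance: dict = field(default_factory=dict)


def run_scenario(scenario: Scenario, record_states: bool = False) -> ScenarioResult:
    """Execute the full pipeline for one configuration."""
    scenario.validate()
    grid = build_grid(scenario.geometry, scenario.solver)
    pressure = solve_darcy(grid, scenario.tissue, scenario.boundary)
    velocity = velocity_from_pressure(
        pressure, grid, scenario.tissue.kappa, scenario.boundary.Pi_outer
    )
    ops = build_operators(scenario, grid, pressure, velocity)
    transient = run_transient(
        ops, scenario.boundary, scenario.solver, record_states=record_states
    )
    ray = PENETRATION_ANGLE if scenario.magnet.B_rem > 0 else None
    report = compute_efficacy(
        transient.final.C_F,
        transient.final.C_B,
        transient.final.C_I,
        grid,
        scenario.boundary,
        scenario.kinetics.omega,
        ray_angle=ray,
    )
    prov = {
        "code_version": __version__,
        "n_r": grid.n_r,
        "n_theta": grid.n_theta,
        "dt_s": scenario.solver.dt,
        "C_outer": scenario.boundary.C_outer,
        "mobility_scale": scenario.nanoparticle.mobility_scale,
        "chi": scenario.nanoparticle.chi,
    }
    return ScenarioResult(
        name=scenario.name,
        config=scenario.to_dict(),
        report=report,
        means=transient.means,
        transient=transient,
        pressure=pressure.Pi,
        provenance=prov,
    )


def sweep(
    scenario: Scenario, axis: str, values: Iterable[float]
) -> tuple[list[ScenarioResult], pd.DataFrame]:
    """Run one scenario per value of ``axis``, all else fixed to ``scenario``.

    ``axis`` is one of ``particle_radius``, ``B_rem``, ``distance``.
    Returns the per-value results and a comparison table (one row per value
    with w½, PA_rel, FK_PA, FK_eff).
    """
    values = list(values)
    if not values:
        raise ValueError("sweep values must be non-empty")
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; use one of {sorted(SWEEP_AXES)}")
    key = SWEEP_AXES[axis]
    results = []
    rows = []
    for v in values:
        sc = scenario.replace(**{key: v})
        sc.name = f"{scenario.name}_{axis}={v:g}"
        res = run_scenario(sc)
        results.append(res)
        rows.append(
            {
                axis: v,
                "w_half_cm": res.report.w_half * 100.0,
                "PA_rel_pct": res.report.PA_rel,
                "FK_PA_pct": res.report.FK_PA,
                "FK_eff_pct": res.report.FK_eff,
            }
        )
    return results, pd.DataFrame(rows)


def calibrate_boundary_concentration(
    scenario: Scenario, target_mean_CF: float
) -> float:
    """Rim concentration for which the end-of-treatment tumor-mean free drug
    equals ``target_mean_CF`` (mol/m³).

    The transport system is linear in the rim concentration, so one run at
    C_outer = 1 determines the answer exactly.
    """
    if target_mean_CF <= 0:
        raise ValueError("target mean concentration must be > 0")
    unit = scenario.replace(**{"boundary.C_outer": 1.0})
    res = run_scenario(unit)
    mean_unit = res.report.mean_CF
    if mean_unit <= 0:
        raise RuntimeError("degenerate run: unit-concentration mean is zero")
    return target_mean_CF / mean_unit


def calibrate_magnetic_mobility(
    scenario: Scenario,
    target_w_half: float,
    scale_range: tuple[float, float] = (1.0, 1e4),
    rtol: float = 0.01,
    max_iter: int = 60,
) -> float:
    """Mobility scale for which the scenario's w½ equals ``target_w_half`` (m).

    Monotone bisection on log(scale); raises if the target lies outside the
    achievable range, reporting that range.  The penetration half-depth
    increases monotonically with the force scale, so the root is unique.
    """
    if scenario.magnet.B_rem <= 0:
        raise ValueError("mobility calibration needs a magnetic scenario (B_rem > 0)")

    def w_of(scale: float) -> float:
        sc = scenario.replace(**{"nanoparticle.mobility_scale": scale})
        return run_scenario(sc).report.w_half

    lo, hi = scale_range
    w_lo, w_hi = w_of(lo), w_of(hi)
    if not (w_lo <= target_w_half <= w_hi):
        raise ValueError(
            f"target w_half {target_w_half:.3e} m outside achievable range "
            f"[{w_lo:.3e}, {w_hi:.3e}] m for scale in [{lo:g}, {hi:g}]"
        )
    a, b = np.log(lo), np.log(hi)
    for _ in range(max_iter):
        m = 0.5 * (a + b)
        w = w_of(float(np.exp(m)))
        if abs(w - target_w_half) <= rtol * target_w_half:
            return float(np.exp(m))
        if w < target_w_half:
            a = m
        else:
            b = m
    return float(np.exp(0.5 * (a + b)))


def write_result(result: ScenarioResult, outdir: str | Path) -> Path:
    """Persist one scenario run: config snapshot, metrics JSON, time series,
    and the final concentration fields as CSV (r, θ, x, y, C_F, C_B, C_I)."""
    outdir = Path(outdir) / result.name
    outdir.mkdir(parents=True, exist_ok=True)
    sc = Scenario.from_dict(result.config)
    write_config(sc, outdir / "config.yaml")
    payload = {
        "scenario": result.name,
        "metrics": result.report.to_dict(),
        "provenance": result.provenance,
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
    result.means.to_csv(outdir / "mean_concentrations.csv", index=False)

    grid = build_grid(sc.geometry, sc.solver)
    final = result.transient.final
    df = pd.DataFrame(
        {
            "r": np.repeat(grid.radii, grid.n_theta),
            "theta": np.tile(grid.angles, grid.n_r),
            "x": grid.x.ravel(),
            "y": grid.y.ravel(),
            "Pi": result.pressure.ravel(),
            "C_F": final.C_F.ravel(),
            "C_B": final.C_B.ravel(),
            "C_I": final.C_I.ravel(),
        }
    )
    df.to_csv(outdir / "fields.csv", index=False)
    return outdir
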