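"""Independent reference solutions used for verification.

These deliberately use different discretization families than the main
solvers (finite differences and quadrature rather than finite volumes) so
a shared bug cannot hide:

* a dense 1D radial finite-difference solve of the two-region
  Darcy–Starling problem;
* a 1D slab integrator for the free/bound/internalized system on a fine
  explicit grid;
* numerical quadrature (Biot–Savart over the equivalent surface currents)
  for the magnet field;
* a discrete mass-balance auditor that re-derives every flux and source
  of a recorded transient from the stored states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.integrate as integrate
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import PolarGrid
from .params import (
    BoundaryConditions,
    Geometry,
    KineticParams,
    MagnetSpec,
    TissueParams,
    VascularParams,
)
from .transport import ConcentrationState, TransportOperators

__all__ = [
    "RadialDarcyResult",
    "SlabResult",
    "radial_darcy_oracle",
    "slab_transport_oracle",
    "biot_savart_oracle",
    "mass_balance_audit",
]


@dataclass
class RadialDarcyResult:
    r: np.ndarray
    P: np.ndarray
    v: np.ndarray            # radial Darcy velocity at nodes
    plateau: float           # pressure at the center
    rim_velocity: float      # outward velocity at r = R


def radial_darcy_oracle(
    tissue: TissueParams,
    geometry: Geometry,
    bc: BoundaryConditions,
    n_points: int = 4000,
) -> RadialDarcyResult:
    """1D radial finite-difference solve of the steady flow problem.

    (κ/r)(r P')' + L_p(S/V)(P_e − P)·[r ≥ R_n] = 0, P'(0) = 0, P(R) given.
    Node-centered second-order differences on a uniform grid.
    """
    R, Rn = geometry.R, geometry.Rn
    h = R / n_points
    r = np.linspace(0.0, R, n_points + 1)
    k = tissue.kappa
    a = tissue.Lp * tissue.SV
    Pe = tissue.starling_equilibrium

    n = n_points  # unknowns 0..n-1; node n is Dirichlet
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    rhs = np.zeros(n)
    for i in range(n):
        if i == 0:
            # symmetry: lim (1/r)(rP')' = 2P'' -> 4(P1-P0)/h^2 (P'(0)=0)
            main[0] = -4 * k / h**2
            upper[0] = 4 * k / h**2
        else:
            rp = r[i] + h / 2
            rm = r[i] - h / 2
            main[i] = -k * (rp + rm) / (r[i] * h**2)
            lower[i - 1] = k * rm / (r[i] * h**2)
            if i < n - 1:
                upper[i] = k * rp / (r[i] * h**2)
        if r[i] >= Rn:
            main[i] -= a
            rhs[i] -= a * Pe
    rhs[n - 1] -= k * (r[n - 1] + h / 2) / (r[n - 1] * h**2) * bc.Pi_outer

    A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    P = np.empty(n + 1)
    P[:n] = spla.spsolve(A, rhs)
    P[n] = bc.Pi_outer
    v = np.gradient(P, r)
    v = -k * v
    return RadialDarcyResult(r=r, P=P, v=v, plateau=float(P[0]), rim_velocity=float(v[-1]))


@dataclass
class SlabResult:
    x: np.ndarray
    C_F: np.ndarray
    C_B: np.ndarray
    C_I: np.ndarray
    half_depth: float


def slab_transport_oracle(
    kinetics: KineticParams,
    vasc: VascularParams,
    tissue: TissueParams,
    v_const: float,
    t_end: float,
    D: float | None = None,
    C_b: float = 1.0,
    length: float = 1.5e-3,
    n_cells: int = 600,
) -> SlabResult:
    """Fine-grid explicit 1D slab integration of the three-species system.

    A semi-infinite slab (approximated by ``length``) with the drug held at
    C_b on the x = 0 face, constant inward velocity ``v_const``, uniform
    vascular loss P·S/V, and the binding/internalization chain.  The time
    step refines itself to satisfy the CFL and reaction constraints.
    """
    D = kinetics.D_eff if D is None else D
    dx = length / n_cells
    x = (np.arange(n_cells) + 0.5) * dx
    loss = vasc.P_perm * tissue.SV
    k_on = kinetics.K_ON * kinetics.C_rec / kinetics.phi
    beta = kinetics.K_OFF + kinetics.K_INT

    dt = 0.8 / (2 * D / dx**2 + abs(v_const) / dx + loss + k_on + beta)
    n_steps = int(math.ceil(t_end / dt))
    dt = t_end / n_steps

    CF = np.zeros(n_cells)
    CB = np.zeros(n_cells)
    CI = np.zeros(n_cells)
    for _ in range(n_steps):
        # ghost at x=0 is the boundary value; far end: outflow
        CFx = np.concatenate([[C_b], CF, [CF[-1]]])
        diff = D * (CFx[2:] - 2 * CFx[1:-1] + CFx[:-2]) / dx**2
        if v_const >= 0:
            conv = -v_const * (CFx[1:-1] - CFx[:-2]) / dx
        else:
            conv = -v_const * (CFx[2:] - CFx[1:-1]) / dx
        dCF = diff + conv - loss * CF - k_on * CF + kinetics.K_OFF * CB
        dCB = k_on * CF - beta * CB
        dCI = kinetics.K_INT * CB
        CF = CF + dt * dCF
        CB = CB + dt * dCB
        CI = CI + dt * dCI

    # half-depth relative to the boundary value
    below = CF < 0.5 * C_b
    if below.any():
        k = int(np.argmax(below))
        xs = np.concatenate([[0.0], x])
        cs = np.concatenate([[C_b], CF])
        c0, c1 = cs[k], cs[k + 1]
        half = xs[k] + (c0 - 0.5 * C_b) / (c0 - c1) * (xs[k + 1] - xs[k])
    else:
        half = length
    return SlabResult(x=x, C_F=CF, C_B=CB, C_I=CI, half_depth=float(half))


def biot_savart_oracle(magnet: MagnetSpec, points: np.ndarray) -> np.ndarray:
    """Magnet field H at exterior ``points`` (n, 2) by adaptive quadrature
    over the two equivalent surface-current sheets."""
    from .magnetostatics import MU0

    M = magnet.B_rem / MU0
    y1 = magnet.distance_d
    y2 = magnet.distance_d + magnet.height_h
    pts = np.atleast_2d(np.asarray(points, float))
    out = np.zeros_like(pts)
    for n, (px, py) in enumerate(pts):
        for x0, K in ((magnet.length_l / 2, M), (-magnet.length_l / 2, -M)):
            hx = integrate.quad(
                lambda yp: -(py - yp) / ((px - x0) ** 2 + (py - yp) ** 2),
                y1,
                y2,
                epsabs=0.0,
                epsrel=1e-12,
            )[0]
            hy = integrate.quad(
                lambda yp: (px - x0) / ((px - x0) ** 2 + (py - yp) ** 2),
                y1,
                y2,
                epsabs=0.0,
                epsrel=1e-12,
            )[0]
            out[n, 0] += K / (2 * math.pi) * hx
            out[n, 1] += K / (2 * math.pi) * hy
    return out


def mass_balance_audit(
    ops: TransportOperators,
    bc: BoundaryConditions,
    states: list[ConcentrationState],
    dt: float,
) -> pd.DataFrame:
    """Re-derive the discrete solute balance of a recorded backward-Euler
    transient from the stored states.

    For each step: accumulation of ∫(C_F+C_B+C_I)dA must equal
    dt·(rim influx − vascular loss + plasma source + advective-form
    compensation), with fluxes evaluated at the end-of-step state.  The
    residual is normalized by the largest term of the balance.
    """
    grid = ops.grid
    area = grid.cell_areas
    rows = []
    for sold, snew in zip(states[:-1], states[1:]):
        C = snew.C_F
        total_new = ((snew.C_F + snew.C_B + snew.C_I) * area).sum()
        total_old = ((sold.C_F + sold.C_B + sold.C_I) * area).sum()

        # rim flux (inward positive): upwind convection + diffusion
        Af = grid.R * grid.dtheta
        dist = grid.R - grid.radii[-1]
        v = ops.v_face_r[-1, :]
        conv_out = np.where(v > 0, v * C[-1, :], v * bc.C_outer) * Af
        diff_in = ops.D_mnp * Af * (bc.C_outer - C[-1, :]) / dist
        influx = (diff_in - conv_out).sum()

        loss = (ops.loss * C * area).sum()
        source = (ops.phi_source * area).sum()
        comp = (ops.div_v * C * area).sum()

        resid = (total_new - total_old) - dt * (influx - loss + source + comp)
        scale = max(abs(total_new - total_old), dt * abs(influx), dt * abs(loss), 1e-300)
        rows.append(
            {
                "t": snew.t,
                "accumulation": total_new - total_old,
                "influx": dt * influx,
                "vascular_loss": dt * loss,
                "compensation": dt * comp,
                "residual": resid,
                "residual_rel": resid / scale,
            }
        )
    return pd.DataFrame(rows)
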