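"""Steady interstitial fluid flow: Darcy's law with a Starling source.

The interstitium is a porous medium, v_i = −κ∇P_i, with steady
incompressible mass balance ∇·v_i = ϕ_B − ϕ_L.  Transvascular filtration
follows Starling's law, ϕ_B = L_p(S/V)(P_B − P_i − σ_s(π_B − π_i)),
linear in P_i; lymphatic drainage ϕ_L is zero (solid tumors lack a
functional lymphatic system), and the necrotic core has no functional
vessels, so ϕ_B is switched off there while κ is unchanged.

Because the source is linear in P_i the steady problem is one sparse
linear solve (no time marching).  With the shipped parameters the
dimensionless ratio α = R√(L_p(S/V)/κ) ≈ 37 ≫ 1, so the pressure sits at
the Starling equilibrium P_e = P_B − σ_s(π_B − π_i) throughout the bulk
and falls to the rim value across a thin boundary layer ~R/α, which is
where essentially all the interstitial velocity lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import PolarGrid
from .params import BoundaryConditions, TissueParams

__all__ = [
    "PressureField",
    "VelocityField",
    "starling_source",
    "solve_darcy",
    "velocity_from_pressure",
    "radial_profile",
]


@dataclass
class PressureField:
    Pi: np.ndarray  # (n_r, n_theta), Pa


@dataclass
class VelocityField:
    """Interstitial Darcy velocity.

    ``v_face_r`` holds outward radial face velocities, shape (n_r+1, n_theta):
    row 0 is the (zero-area) center face, row n_r the rim face.  ``vx, vy``
    are interpolated cell-center vectors for output; ``v_face_t`` angular
    face velocities (zero for the radially symmetric flow problem but kept
    for generality).
    """

    v_face_r: np.ndarray
    v_face_t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    @property
    def max_magnitude(self) -> float:
        return float(
            max(np.abs(self.v_face_r).max(), np.abs(self.v_face_t).max())
        )


def starling_source(
    Pi: PressureField | np.ndarray, tissue: TissueParams, grid: PolarGrid
) -> np.ndarray:
    """Net per-volume fluid source ϕ_B − ϕ_L (1/s) for a given pressure field."""
    P = Pi.Pi if isinstance(Pi, PressureField) else np.asarray(Pi, float)
    phi_B = tissue.Lp * tissue.SV * (tissue.starling_equilibrium - P)
    phi_B = np.where(grid.necrotic_mask, 0.0, phi_B)
    phi_L = tissue.Lpl * tissue.SLV * (P - tissue.PL)
    phi_L = np.where(grid.necrotic_mask, 0.0, phi_L)
    return phi_B - phi_L


def _flow_operator(grid: PolarGrid, tissue: TissueParams, bc: BoundaryConditions):
    """Assemble A P = b for the steady Darcy–Starling problem (FV)."""
    nr, nt = grid.n_r, grid.n_theta
    N = nr * nt
    idx = np.arange(N).reshape(nr, nt)
    kappa = tissue.kappa

    rows, cols, vals = [], [], []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    area = grid.cell_areas
    # radial faces between ring i and i+1
    for i in range(nr - 1):
        A_f = grid.r_faces[i + 1] * grid.dtheta
        dist = grid.radii[i + 1] - grid.radii[i]
        g = kappa * A_f / dist
        for j in range(nt):
            c0, c1 = idx[i, j], idx[i + 1, j]
            add(c0, c0, g / area[i, j])
            add(c0, c1, -g / area[i, j])
            add(c1, c1, g / area[i + 1, j])
            add(c1, c0, -g / area[i + 1, j])
    # rim Dirichlet face
    A_f = grid.r_faces[-1] * grid.dtheta
    dist = grid.R - grid.radii[-1]
    g = kappa * A_f / dist
    for j in range(nt):
        c = idx[nr - 1, j]
        add(c, c, g / area[nr - 1, j])
        b[c] += g / area[nr - 1, j] * bc.Pi_outer
    # angular faces (periodic)
    for i in range(nr):
        A_f = grid.dr[i]
        dist = grid.radii[i] * grid.dtheta
        g = kappa * A_f / dist
        for j in range(nt):
            jn = (j + 1) % nt
            c0, c1 = idx[i, j], idx[i, jn]
            add(c0, c0, g / area[i, j])
            add(c0, c1, -g / area[i, j])
            add(c1, c1, g / area[i, jn])
            add(c1, c0, -g / area[i, jn])
    # Starling source, linear in P: phi = Lp SV (Pe - P) on viable cells
    coef = tissue.Lp * tissue.SV
    Pe = tissue.starling_equilibrium
    viable = ~grid.necrotic_mask
    for i in range(nr):
        for j in range(nt):
            if viable[i, j]:
                c = idx[i, j]
                add(c, c, coef)
                b[c] += coef * Pe
            if tissue.Lpl * tissue.SLV > 0 and viable[i, j]:
                c = idx[i, j]
                add(c, c, tissue.Lpl * tissue.SLV)
                b[c] += tissue.Lpl * tissue.SLV * tissue.PL

    A = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    return A, b


def solve_darcy(
    grid: PolarGrid, tissue: TissueParams, bc: BoundaryConditions
) -> PressureField:
    """Solve the steady flow problem by sparse direct factorization."""
    A, b = _flow_operator(grid, tissue, bc)
    P = spla.spsolve(A.tocsc(), b)
    if not np.all(np.isfinite(P)):
        raise RuntimeError("singular Darcy assembly (degenerate grid?)")
    return PressureField(Pi=P.reshape(grid.n_r, grid.n_theta))


def velocity_from_pressure(
    Pi: PressureField, grid: PolarGrid, kappa: float, Pi_outer: float = 0.0
) -> VelocityField:
    """Face-centered Darcy flux v = −κ∇P, with interpolated cell vectors."""
    P = Pi.Pi
    nr, nt = grid.n_r, grid.n_theta
    v_face_r = np.zeros((nr + 1, nt))
    # interior radial faces
    dist = grid.radii[1:] - grid.radii[:-1]
    v_face_r[1:nr, :] = -kappa * (P[1:, :] - P[:-1, :]) / dist[:, None]
    # rim face (Dirichlet)
    v_face_r[nr, :] = -kappa * (Pi_outer - P[-1, :]) / (grid.R - grid.radii[-1])
    # angular faces
    v_face_t = np.zeros((nr, nt))
    Pn = np.roll(P, -1, axis=1)
    v_face_t[:, :] = -kappa * (Pn - P) / (grid.radii[:, None] * grid.dtheta)

    # cell-center vectors (radial/angular averaged, rotated to Cartesian)
    v_r_c = 0.5 * (v_face_r[:-1, :] + v_face_r[1:, :])
    v_t_c = 0.5 * (v_face_t + np.roll(v_face_t, 1, axis=1))
    cos = np.cos(grid.angles)[None, :]
    sin = np.sin(grid.angles)[None, :]
    vx = v_r_c * cos - v_t_c * sin
    vy = v_r_c * sin + v_t_c * cos
    return VelocityField(v_face_r=v_face_r, v_face_t=v_face_t, vx=vx, vy=vy)


def radial_profile(field: np.ndarray, grid: PolarGrid) -> pd.DataFrame:
    """Angle-averaged profile of a (n_r, n_theta) cell field vs radius."""
    vals = np.asarray(field, float).reshape(grid.n_r, grid.n_theta).mean(axis=1)
    return pd.DataFrame({"radius": grid.radii, "value": vals})
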