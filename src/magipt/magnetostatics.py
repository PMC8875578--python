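"""Permanent-magnet field, magnetic force on a nanoparticle, and the
Stokes equilibrium velocity.

The magnet is treated as an infinitely long bar of rectangular
cross-section (plane magnetostatics), uniformly magnetized along −y with
magnitude M = B_rem/μ₀.  Outside the magnet the field is curl- and
divergence-free and equals that of the two equivalent surface-current
sheets on the faces x = ±l/2 — a closed form in arctan/log terms, with an
analytic Jacobian, so no mesh solve is needed on the tumor domain (which
excludes the magnet body; the body's permeability is absorbed by the
equivalent-current representation).

Geometry convention: tumor center at the origin, magnet face at
y = distance_d, body occupying y ∈ [d, d+h], x ∈ [−l/2, l/2].  The force
on a particle inside the tumor points toward the magnet (+y), so drug is
driven into the tumor from the face away from the magnet (−y side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import MagnetSpec, NanoparticleSpec

__all__ = [
    "MU0",
    "FieldSample",
    "ParticleForce",
    "field_of_rect_magnet",
    "particle_magnetization",
    "magnetic_force",
    "equilibrium_velocity",
    "effective_susceptibility",
    "field_on_grid",
]

MU0 = 4e-7 * math.pi  # vacuum permeability, N/A^2


@dataclass
class FieldSample:
    """Field quantities at one or more points (arrays broadcast over points)."""

    H: np.ndarray        # magnetic field vectors (..., 2), A/m
    B: np.ndarray        # flux density vectors (..., 2), T  (= mu0*H outside the magnet)
    gradH2: np.ndarray   # gradient of |H|^2, (..., 2), A^2/m^3
    jac: np.ndarray      # Jacobian dH_i/dx_j, (..., 2, 2), A/m^2


@dataclass
class ParticleForce:
    F_m: np.ndarray      # magnetic force vectors (..., 2), N
    saturated: np.ndarray  # bool: saturation branch used
    v_e: np.ndarray      # Stokes equilibrium velocity (..., 2), m/s


def effective_susceptibility(chi: float) -> float:
    """Demagnetization-corrected susceptibility χ/(1+χ/3) of a sphere."""
    return chi / (1.0 + chi / 3.0)


def _inside_magnet(x: np.ndarray, y: np.ndarray, magnet: MagnetSpec) -> np.ndarray:
    return (
        (np.abs(x) <= magnet.length_l / 2)
        & (y >= magnet.distance_d)
        & (y <= magnet.distance_d + magnet.height_h)
    )


def field_of_rect_magnet(point: np.ndarray, magnet: MagnetSpec) -> FieldSample:
    """Closed-form exterior field of the 2D magnet at ``point`` (..., 2).

    Raises ``ValueError`` if any point lies inside the magnet body (the
    domain of interest excludes the interior, where B = μ₀μ_rH + B_rem
    would apply instead).
    """
    pt = np.asarray(point, dtype=float)
    x = pt[..., 0]
    y = pt[..., 1]
    if np.any(_inside_magnet(x, y, magnet)):
        raise ValueError("field requested inside the magnet body")

    M = magnet.B_rem / MU0  # magnetization magnitude, A/m
    y1 = magnet.distance_d
    y2 = magnet.distance_d + magnet.height_h

    Hx = np.zeros_like(x)
    Hy = np.zeros_like(x)
    J = np.zeros(x.shape + (2, 2))
    # equivalent sheets: K = M x n_hat; for magnetization -M y_hat the sheet
    # at x=+l/2 carries +M z_hat, at x=-l/2 carries -M z_hat
    for x0, K in ((magnet.length_l / 2, M), (-magnet.length_l / 2, -M)):
        dx = x - x0
        u1 = y - y1
        u2 = y - y2
        N = dx * dx + u1 * u1
        D = dx * dx + u2 * u2
        with np.errstate(divide="ignore", invalid="ignore"):
            Hx += (-K / (4 * math.pi)) * np.log(N / D)
            Hy += (K / (2 * math.pi)) * (np.arctan2(u1, dx) - np.arctan2(u2, dx))
            # analytic Jacobian of the sheet field
            J[..., 0, 0] += (-K / (2 * math.pi)) * (dx / N - dx / D)
            J[..., 0, 1] += (-K / (2 * math.pi)) * (u1 / N - u2 / D)
            J[..., 1, 0] += (K / (2 * math.pi)) * (-u1 / N + u2 / D)
            J[..., 1, 1] += (K / (2 * math.pi)) * (dx / N - dx / D)

    H = np.stack([Hx, Hy], axis=-1)
    grad = 2.0 * np.einsum("...ji,...j->...i", J, H)  # grad|H|^2 = 2 J^T H
    return FieldSample(H=H, B=MU0 * H, gradH2=grad, jac=J)


def particle_magnetization(H: np.ndarray, particle: NanoparticleSpec) -> np.ndarray:
    """Particle magnetization M = min(χ_eff·|H|, M_sat)·Ĥ (A/m).

    Continuous at the saturation threshold; zero field gives zero moment.
    """
    H = np.asarray(H, dtype=float)
    chie = effective_susceptibility(particle.chi)
    Msat = particle.mu0_Msat / MU0
    Hn = np.linalg.norm(H, axis=-1, keepdims=True)
    mag = np.minimum(chie * Hn, Msat)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(Hn > 0, H / np.where(Hn > 0, Hn, 1.0), 0.0)
    return mag * unit


def magnetic_force(
    point: np.ndarray, magnet: MagnetSpec, particle: NanoparticleSpec
) -> ParticleForce:
    """Saturable magnetic force and Stokes equilibrium velocity at ``point``.

    Unsaturated branch: F = ½ V μ₀ χ_eff ∇|H|².  Once the magnetization
    clamps at M_sat the field factor |H| is replaced by M_sat, i.e.
    F = V μ₀ (∂H/∂x)ᵀ M_sat Ĥ — same direction, capped magnitude; the two
    branches agree at the threshold.  The particle's dimensionless
    ``mobility_scale`` multiplies the force.
    """
    fs = field_of_rect_magnet(point, magnet)
    chie = effective_susceptibility(particle.chi)
    Msat = particle.mu0_Msat / MU0
    V = particle.volume

    Hn = np.linalg.norm(fs.H, axis=-1, keepdims=True)
    saturated = (chie * Hn[..., 0]) > Msat

    F_unsat = 0.5 * V * MU0 * chie * fs.gradH2
    with np.errstate(invalid="ignore", divide="ignore"):
        Hhat = np.where(Hn > 0, fs.H / np.where(Hn > 0, Hn, 1.0), 0.0)
    JtH = np.einsum("...ji,...j->...i", fs.jac, Hhat)
    F_sat = V * MU0 * Msat * JtH

    F = np.where(saturated[..., None], F_sat, F_unsat) * particle.mobility_scale
    v_e = equilibrium_velocity(F, particle)
    return ParticleForce(F_m=F, saturated=saturated, v_e=v_e)


def equilibrium_velocity(
    F: np.ndarray, particle: NanoparticleSpec, eta: float = 1.12e-3
) -> np.ndarray:
    """Stokes equilibrium velocity v_e = F / (6π a η), componentwise."""
    if particle.radius_a <= 0:
        raise ValueError("radius_a must be > 0")
    if eta <= 0:
        raise ValueError("eta must be > 0")
    return np.asarray(F, dtype=float) / (6.0 * math.pi * particle.radius_a * eta)


def field_on_grid(
    magnet: MagnetSpec,
    x: np.ndarray,
    y: np.ndarray,
) -> "np.ndarray":
    """Probe the field on a rectilinear grid; returns records (x, y, Hx, Hy, |H|).

    Points inside the magnet body are reported as NaN.  Intended for
    field-map export (CSV) around the magnet and tumor.
    """
    X, Y = np.meshgrid(np.asarray(x, float), np.asarray(y, float), indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    inside = _inside_magnet(X, Y, magnet)
    out = np.full(X.shape + (2,), np.nan)
    if np.any(~inside):
        fs = field_of_rect_magnet(pts[~inside], magnet)
        out[~inside] = fs.H
    Hn = np.linalg.norm(out, axis=-1)
    return np.stack([X, Y, out[..., 0], out[..., 1], Hn], axis=-1).reshape(-1, 5)
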