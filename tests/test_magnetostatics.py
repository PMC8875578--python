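"""Analytic magnet field, saturable particle force, Stokes velocity."""

import math

import numpy as np
import pytest

from magipt.magnetostatics import (
    MU0,
    effective_susceptibility,
    equilibrium_velocity,
    field_of_rect_magnet,
    magnetic_force,
    particle_magnetization,
)
from magipt.oracles import biot_savart_oracle
from magipt.params import MagnetSpec, NanoparticleSpec


@pytest.fixture()
def magnet():
    return MagnetSpec()  # 20 x 10 cm, 1.5 T, face 5 cm above the tumor center


def test_transverse_component_vanishes_on_symmetry_axis(magnet):
    pts = np.array([[0.0, y] for y in (-0.02, 0.0, 0.02, 0.04)])
    fs = field_of_rect_magnet(pts, magnet)
    assert np.all(np.abs(fs.H[:, 0]) < 1e-10 * np.abs(fs.H[:, 1]))


def test_no_remanence_no_field():
    magnet = MagnetSpec(B_rem=0.0)
    fs = field_of_rect_magnet(np.array([[0.003, -0.004]]), magnet)
    assert np.all(fs.H == 0.0) and np.all(fs.gradH2 == 0.0)


def test_field_matches_biot_savart_quadrature(magnet, rng):
    pts = rng.uniform([-0.15, -0.12], [0.15, 0.04], size=(20, 2))
    H = field_of_rect_magnet(pts, magnet).H
    Hq = biot_savart_oracle(magnet, pts)
    rel = np.linalg.norm(H - Hq, axis=1) / np.linalg.norm(Hq, axis=1)
    assert rel.max() < 1e-3


def test_field_is_curl_and_divergence_free(magnet, rng):
    """Numerical curl/div of the closed form vanish off the magnet."""
    pts = rng.uniform([-0.08, -0.05], [0.08, 0.03], size=(30, 2))
    h = 1e-6
    def H(p):
        return field_of_rect_magnet(p, magnet).H
    dx = (H(pts + [h, 0]) - H(pts - [h, 0])) / (2 * h)
    dy = (H(pts + [0, h]) - H(pts - [0, h])) / (2 * h)
    div = dx[:, 0] + dy[:, 1]
    curl = dx[:, 1] - dy[:, 0]
    scale = np.linalg.norm(H(pts), axis=1) / 0.01  # |H| per cm length scale
    assert np.max(np.abs(div) / scale) < 1e-4
    assert np.max(np.abs(curl) / scale) < 1e-4


def test_analytic_jacobian_matches_finite_differences(magnet):
    pts = np.array([[0.004, -0.007], [-0.03, 0.02]])
    fs = field_of_rect_magnet(pts, magnet)
    h = 1e-7
    dHx = (field_of_rect_magnet(pts + [h, 0], magnet).H
           - field_of_rect_magnet(pts - [h, 0], magnet).H) / (2 * h)
    dHy = (field_of_rect_magnet(pts + [0, h], magnet).H
           - field_of_rect_magnet(pts - [0, h], magnet).H) / (2 * h)
    jac_fd = np.stack([dHx, dHy], axis=-1)  # [..., i, j] = dH_i/dx_j
    assert np.allclose(fs.jac, jac_fd, rtol=1e-5, atol=1e-3)


def test_point_inside_magnet_rejected(magnet):
    with pytest.raises(ValueError):
        field_of_rect_magnet(np.array([0.0, 0.08]), magnet)


def test_magnetization_zero_field_and_saturation(magnet):
    p = NanoparticleSpec()
    assert np.all(particle_magnetization(np.zeros(2), p) == 0.0)
    # far above the threshold the moment clamps at mu0*M = 0.5 T
    strong = np.array([1e9, 0.0])
    M = particle_magnetization(strong, p)
    assert MU0 * np.linalg.norm(M) == pytest.approx(0.5, rel=1e-12)
    # moment lines up with H
    assert M[1] == 0.0 and M[0] > 0


def test_effective_susceptibility_limits():
    assert effective_susceptibility(1.0) == pytest.approx(0.75)
    assert effective_susceptibility(1e9) == pytest.approx(3.0, rel=1e-6)


def test_magnetization_continuous_at_saturation_threshold():
    p = NanoparticleSpec(chi=1.0)
    chie = effective_susceptibility(1.0)
    Hth = p.mu0_Msat / MU0 / chie
    lo = particle_magnetization(np.array([Hth * 0.999999, 0.0]), p)
    hi = particle_magnetization(np.array([Hth * 1.000001, 0.0]), p)
    assert np.allclose(lo, hi, rtol=1e-4)


def test_force_volume_scaling(magnet):
    """Doubling the radius multiplies the unsaturated force by 8."""
    pt = np.array([0.002, -0.005])
    f1 = magnetic_force(pt, magnet, NanoparticleSpec(radius_a=1e-7))
    f2 = magnetic_force(pt, magnet, NanoparticleSpec(radius_a=2e-7))
    assert not f1.saturated and not f2.saturated
    assert np.allclose(f2.F_m, 8.0 * f1.F_m, rtol=1e-12)


def test_saturation_changes_magnitude_not_direction(magnet):
    pt = np.array([0.004, -0.006])
    unsat = magnetic_force(pt, magnet, NanoparticleSpec(chi=1.0))
    sat = magnetic_force(pt, magnet, NanoparticleSpec(chi=1e4))
    assert not unsat.saturated and sat.saturated
    d1 = unsat.F_m / np.linalg.norm(unsat.F_m)
    d2 = sat.F_m / np.linalg.norm(sat.F_m)
    assert np.allclose(d1, d2, atol=1e-10)


def test_force_is_gradient_of_potential(magnet):
    """Unsaturated F = ∇Φ with Φ = ¼Vμ₀χ_eff|H|² (finite-difference check)."""
    p = NanoparticleSpec()
    chie = effective_susceptibility(p.chi)
    pt = np.array([0.003, -0.004])
    h = 1e-6
    def phi(q):
        H = field_of_rect_magnet(q, magnet).H
        return 0.5 * p.volume * MU0 * chie * (H @ H)
    grad = np.array(
        [
            (phi(pt + [h, 0]) - phi(pt - [h, 0])) / (2 * h),
            (phi(pt + [0, h]) - phi(pt - [0, h])) / (2 * h),
        ]
    )
    F = magnetic_force(pt, magnet, p).F_m
    assert np.allclose(F, grad, rtol=1e-4)


def test_force_decays_down_axis(magnet):
    ys = -np.linspace(0.0, 0.25, 40)
    mags = [
        np.linalg.norm(magnetic_force(np.array([0.0, y]), magnet, NanoparticleSpec()).F_m)
        for y in ys
    ]
    assert np.all(np.diff(mags) < 0)


def test_equilibrium_velocity_values():
    p = NanoparticleSpec(radius_a=1e-7)
    v = equilibrium_velocity(np.array([0.0, 2.111e-15]), p, eta=1.12e-3)
    assert np.linalg.norm(v) == pytest.approx(1.0e-6, rel=1e-3)
    assert np.all(equilibrium_velocity(np.zeros(2), p) == 0.0)
    # 1/a: doubling the radius at fixed force halves the speed
    v2 = equilibrium_velocity(np.array([0.0, 2.111e-15]), NanoparticleSpec(radius_a=2e-7))
    assert np.linalg.norm(v2) == pytest.approx(np.linalg.norm(v) / 2, rel=1e-12)


def test_force_points_toward_magnet_inside_tumor(magnet):
    """The magnet sits above (+y); the force on tumor particles points up."""
    pts = np.array([[0.0, -0.009], [0.004, 0.0], [-0.006, 0.005]])
    F = magnetic_force(pts, magnet, NanoparticleSpec()).F_m
    assert np.all(F[:, 1] > 0)
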