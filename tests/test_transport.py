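"""Transport system: exchange terms, kinetics, stepping, conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from magipt.flow import solve_darcy, velocity_from_pressure
from magipt.grid import build_grid
from magipt.oracles import mass_balance_audit, slab_transport_oracle
from magipt.params import KineticParams, Scenario
from magipt.transport import (
    ConcentrationState,
    build_operators,
    reaction_rates,
    run_transient,
    transvascular_exchange,
)


def _pipeline(sc):
    grid = build_grid(sc.geometry, sc.solver)
    P = solve_darcy(grid, sc.tissue, sc.boundary)
    v = velocity_from_pressure(P, grid, sc.tissue.kappa, sc.boundary.Pi_outer)
    ops = build_operators(sc, grid, P, v)
    return grid, P, v, ops


class TestTransvascularExchange:
    def test_plateau_washout_rate(self, fast_scenario):
        """With C_p = 0 and ϕ_B = 0 the exchange is a pure P·S/V sink."""
        sc = fast_scenario
        grid, P, _, _ = _pipeline(sc)
        shape = (grid.n_r, grid.n_theta)
        C = np.full(shape, 2.0)
        Pi = np.full(shape, sc.tissue.starling_equilibrium)  # ϕ_B = 0
        Phi = transvascular_exchange(C, Pi, sc.vascular, sc.tissue, grid)
        viable = ~grid.necrotic_mask
        assert np.allclose(Phi[viable], -0.06 * 2.0, rtol=1e-12)
        assert np.all(Phi[grid.necrotic_mask] == 0.0)

    def test_full_reflection_forces_pe_zero(self, fast_scenario):
        sc = fast_scenario.replace(**{"vascular.sigma_f": 1.0})
        grid, P, _, _ = _pipeline(sc)
        shape = (grid.n_r, grid.n_theta)
        C = np.ones(shape)
        Phi = transvascular_exchange(C, np.zeros(shape), sc.vascular, sc.tissue, grid)
        viable = ~grid.necrotic_mask
        assert np.allclose(Phi[viable], -0.06, rtol=1e-12)  # limit Pe/(e^Pe−1) → 1

    def test_no_gradient_no_exchange(self, fast_scenario):
        sc = fast_scenario.replace(**{"vascular.C_p": 0.7})
        grid, _, _, _ = _pipeline(sc)
        shape = (grid.n_r, grid.n_theta)
        C = np.full(shape, 0.7)
        Pi = np.full(shape, sc.tissue.starling_equilibrium)
        Phi = transvascular_exchange(C, Pi, sc.vascular, sc.tissue, grid)
        assert np.allclose(Phi, 0.0, atol=1e-15)


class TestKinetics:
    def test_binding_equilibrium_ratio(self):
        """C_B/C_F = K_ON·C_rec/(φ·K_OFF) = 0.625 is stationary when K_INT = 0."""
        kin = KineticParams(K_INT=0.0)
        c = 0.3
        state = ConcentrationState(
            0.0, np.full((2, 2), c), np.full((2, 2), 0.625 * c), np.zeros((2, 2))
        )
        dF, dB, dI = reaction_rates(state, kin)
        assert np.allclose(dF, 0.0, atol=1e-15)
        assert np.allclose(dB, 0.0, atol=1e-15)
        assert np.all(dI == 0.0)

    def test_zero_state_is_stationary(self):
        state = ConcentrationState(0.0, *(np.zeros((3, 3)) for _ in range(3)))
        for d in reaction_rates(state, KineticParams()):
            assert np.all(d == 0.0)

    @given(
        cf=st.floats(0, 10),
        cb=st.floats(0, 10),
        ci=st.floats(0, 10),
    )
    def test_binding_exchange_conserves_total(self, cf, cb, ci):
        state = ConcentrationState(
            0.0, np.full((2, 2), cf), np.full((2, 2), cb), np.full((2, 2), ci)
        )
        dF, dB, dI = reaction_rates(state, KineticParams())
        assert np.allclose(dF + dB + dI, 0.0, atol=1e-12)


class TestStepping:
    def test_zero_boundary_stays_zero(self, fast_scenario):
        sc = fast_scenario.replace(**{"boundary.C_outer": 0.0})
        grid, _, _, ops = _pipeline(sc)
        res = run_transient(ops, sc.boundary, sc.solver)
        assert np.all(res.final.C_F == 0.0)
        assert np.all(res.final.C_B == 0.0)
        assert np.all(res.final.C_I == 0.0)

    def test_linear_in_boundary_concentration(self, fast_scenario):
        grid, _, _, ops = _pipeline(fast_scenario)
        r1 = run_transient(ops, fast_scenario.boundary, fast_scenario.solver)
        sc2 = fast_scenario.replace(**{"boundary.C_outer": 2.0})
        r2 = run_transient(ops, sc2.boundary, sc2.solver)
        assert np.allclose(r2.final.C_F, 2.0 * r1.final.C_F, rtol=1e-10, atol=1e-14)
        assert np.allclose(r2.final.C_I, 2.0 * r1.final.C_I, rtol=1e-10, atol=1e-14)

    def test_nonnegativity_and_internalized_monotone(self, fast_scenario):
        sc = fast_scenario.replace(**{"nanoparticle.mobility_scale": 150.0})
        grid, _, _, ops = _pipeline(sc)
        res = run_transient(ops, sc.boundary, sc.solver)
        for f in (res.final.C_F, res.final.C_B, res.final.C_I):
            assert f.min() >= 0.0
        for a, b in zip(res.checkpoints[:-1], res.checkpoints[1:]):
            assert np.all(b.C_I >= a.C_I - 1e-18)

    def test_means_rise_to_plateau(self, fast_scenario):
        grid, _, _, ops = _pipeline(fast_scenario)
        res = run_transient(ops, fast_scenario.boundary, fast_scenario.solver)
        m = res.means
        assert m["C_F"].is_monotonic_increasing
        assert m["C_I"].is_monotonic_increasing
        # free drug approaches a plateau: late increments much smaller than early
        dcf = np.diff(m["C_F"])
        assert dcf[-1] < 0.1 * dcf[0]

    def test_magnetic_pipeline_reduces_to_conventional_bit_for_bit(self, fast_scenario):
        conv = fast_scenario.replace(**{"magnet.B_rem": 0.0})
        mag0 = fast_scenario.replace(
            **{"magnet.B_rem": 0.0, "nanoparticle.mobility_scale": 77.0}
        )
        outs = []
        for sc in (conv, mag0):
            _, _, _, ops = _pipeline(sc)
            outs.append(run_transient(ops, sc.boundary, sc.solver).final)
        assert np.array_equal(outs[0].C_F, outs[1].C_F)
        assert np.array_equal(outs[0].C_I, outs[1].C_I)


class TestMassBalance:
    @pytest.mark.parametrize("mobility", [0.0, 120.0])
    def test_audit_residual_below_one_percent(self, fast_scenario, mobility):
        sc = fast_scenario.replace(
            **{
                "nanoparticle.mobility_scale": mobility,
                "magnet.B_rem": 1.5 if mobility else 0.0,
                "solver.t_end": 200.0,
            }
        )
        grid, _, _, ops = _pipeline(sc)
        res = run_transient(ops, sc.boundary, sc.solver, record_states=True)
        audit = mass_balance_audit(ops, sc.boundary, res.states, sc.solver.dt)
        assert audit["residual_rel"].abs().max() < 1e-2


class TestSlabOracle:
    def test_conventional_half_depth_matches_1d_slab(self, scenario):
        """Angle-independent rim physics: the 2D run reproduces the 1D slab
        half-depth (≈ √(D/(P·S/V))·ln2 ≈ 50–60 μm) within a few %."""
        sc = scenario.replace(**{"magnet.B_rem": 0.0, "solver.t_end": 600.0})
        grid, _, _, ops = _pipeline(sc)
        res = run_transient(ops, sc.boundary, sc.solver)
        from magipt.metrics import penetration_half_depth

        w2d = penetration_half_depth(res.final.C_F, grid, sc.boundary).depth
        slab = slab_transport_oracle(
            sc.kinetics, sc.vascular, sc.tissue, v_const=0.0, t_end=600.0
        )
        assert w2d == pytest.approx(slab.half_depth, rel=0.05)
        assert 40e-6 < w2d < 80e-6

    def test_slab_oracle_self_consistency(self, scenario):
        """Oracle converges under its own refinement and scales linearly."""
        kw = dict(v_const=0.0, t_end=300.0)
        a = slab_transport_oracle(scenario.kinetics, scenario.vascular, scenario.tissue,
                                  n_cells=300, **kw)
        b = slab_transport_oracle(scenario.kinetics, scenario.vascular, scenario.tissue,
                                  n_cells=600, **kw)
        assert a.half_depth == pytest.approx(b.half_depth, rel=0.04)
        c = slab_transport_oracle(scenario.kinetics, scenario.vascular, scenario.tissue,
                                  C_b=2.0, n_cells=300, **kw)
        assert np.allclose(c.C_F, 2.0 * a.C_F, rtol=1e-10, atol=1e-14)
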