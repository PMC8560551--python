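"""Membrane reaction-transport: reaction terms, pool bookkeeping,
confinement operator, seeding and nucleation noise."""

import math

import numpy as np
import pytest

from macrocup import axisym, fields, kinetics, mechanics, reactions
from macrocup.params import NoiseParams, SimulationParams


class TestReactionTerms:
    def test_zero_activator(self):
        dA, dI = reactions.reaction_terms(0.0, 2.0, 1.5, 1.0, 0.1, 0.5)
        assert dA == 0.0
        assert dI == pytest.approx(-0.5 * 2.0)

    def test_simple_substitution(self):
        dA, _ = reactions.reaction_terms(1.0, 0.0, 2.0, math.inf, 0.0, 1.0)
        assert dA == pytest.approx(1.0)  # 1*2/(1)/(1) - 1

    @pytest.mark.parametrize("alpha,k1,k2,B", [
        (math.inf, 0.088, 0.54, 2.0), (1.0, 2e-4, 2e-4, 2.5),
    ])
    def test_vanishes_at_wellmixed_fixed_points(self, alpha, k1, k2, B):
        rep = kinetics.fixed_points(B, k1, k2, alpha)
        for fp in rep.points:
            dA, dI = reactions.reaction_terms(fp.A, fp.I, B, alpha, k1, k2)
            assert abs(dA) < 1e-10 and abs(dI) < 1e-10


class TestGlobalPool:
    def test_empty_membrane_gives_at(self, coarse_params):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        B, S, totalA = reactions.global_B(state.A, psi, state.grid,
                                          coarse_params)
        assert totalA == 0.0
        # S of the discrete sphere is within 1% of 4 pi R0^2
        assert B == pytest.approx(coarse_params.at, rel=0.015)

    def test_arithmetic_identity(self, coarse_params):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        state.A[:] = 0.5  # uniform activator
        B, S, totalA = reactions.global_B(state.A, psi, state.grid,
                                          coarse_params)
        assert B == pytest.approx(
            coarse_params.At_total / S - totalA / S, rel=1e-12)
        # <A> of a uniform field is the field value
        assert totalA / S == pytest.approx(0.5, rel=1e-9)

    def test_negative_pool_clipped_with_warning(self, coarse_params):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        state.A[:] = 100.0
        with pytest.warns(RuntimeWarning):
            B, _, _ = reactions.global_B(state.A, psi, state.grid,
                                         coarse_params.replace(clamp=200.0))
        assert B == 0.0


class TestConfinementOperator:
    def _sphere_setup(self, dx=0.1):
        p = SimulationParams(dx=dx, R0=5.0, Lr=8.0, Lz=16.0)
        grid = fields.AxisymGrid.from_extents(p.Lr, p.Lz, p.dx)
        phi = fields.init_sphere_phi(grid, (0.0, 8.0), 5.0, p.eps)
        psi = fields.compute_psi(phi, p.beta, p.theta)
        r, z = grid.coords()
        A = np.exp(-((z - 10.0) ** 2) / 4.0)  # smooth along the membrane
        return p, grid, phi, psi, A

    def _identity_ratio(self, dx):
        p, grid, phi, psi, A = self._sphere_setup(dx)
        term = reactions.confinement_term(A, phi, psi, p.DA, grid, p.beta,
                                          scheme="central")
        gpsi_r, gpsi_z = fields.gradient_axisym(psi, grid.dx)
        gA_r, gA_z = fields.gradient_axisym(A, grid.dx)
        direct = p.DA * (gpsi_r * gA_r + gpsi_z * gA_z) \
            / np.maximum(psi, 1e-12)
        sel = (psi > 0.1) & (psi < 0.9)
        return (np.linalg.norm((term - direct)[sel])
                / np.linalg.norm(direct[sel]))

    def test_central_form_matches_grad_psi_identity(self):
        """The drift coefficient beta (1-psi)(1-2phi) grad(phi) equals
        grad(psi)/psi analytically: the two discrete forms converge to
        each other under refinement (the band is steep, so pointwise
        agreement needs a fine mesh)."""
        ratios = [self._identity_ratio(dx) for dx in (0.1, 0.05, 0.025)]
        assert ratios[2] < 0.05
        assert ratios[0] > ratios[1] > ratios[2]

    def test_flux_form_equals_expanded_form_under_refinement(self):
        """band_diffusion = lap + confinement drift analytically; the
        discrete forms converge to each other on the band interior."""
        ratios = []
        for dx in (0.1, 0.05, 0.025):
            p, grid, phi, psi, A = self._sphere_setup(dx)
            flux = reactions.band_diffusion(A, psi, grid)
            lap = fields.laplacian_axisym(A, grid.dx)
            drift = reactions.confinement_term(A, phi, psi, 1.0, grid,
                                               p.beta, scheme="central")
            sel = psi > 0.5
            sel[0, :] = sel[-1, :] = False
            sel[:, 0] = sel[:, -1] = False
            ratios.append(np.linalg.norm((flux - (lap + drift))[sel])
                          / np.linalg.norm((lap + drift)[sel]))
        assert ratios[2] < 0.05
        assert ratios[0] > ratios[1] > ratios[2]

    def test_uniform_field_is_stationary_under_diffusion(self):
        p, grid, phi, psi, A = self._sphere_setup()
        out = reactions.band_diffusion(np.full_like(A, 2.0), psi, grid)
        assert np.abs(out[1:-1, 1:-1]).max() < 1e-9


class TestTransportConservation:
    def test_advection_diffusion_conserves_band_mass(self):
        """Reaction off: the upwind advection + confined diffusion step
        conserves the membrane total of A within 1% per 10 s while the
        sphere shrinks under curvature flow."""
        p = SimulationParams(dx=0.2, R0=5.0, Lr=10.0, Lz=20.0, MV=0.0)
        grid = fields.AxisymGrid.from_extents(p.Lr, p.Lz, p.dx)
        phi = fields.init_sphere_phi(grid, (0.0, 10.0), 5.0, p.eps)
        r, z = grid.coords()
        psi = fields.compute_psi(phi, p.beta, p.theta)
        A = np.where(psi > p.psi_cut, np.exp(-((z - 12.0) ** 2)), 0.0)
        m0 = fields.integrate(A * psi, grid) / p.eps
        T = 10.0
        for _ in range(int(T / p.dt)):
            V = fields.volume_of(phi, grid)
            (vr, vz), s, gmag = mechanics.velocity_field(
                phi, np.zeros_like(phi), V, p, grid)
            adv = -fields.upwind_div_axisym(A, vr, vz, grid.dx)
            diff = p.DA * reactions.band_diffusion(A, psi, grid)
            A = A + p.dt * (adv + diff)
            phi = mechanics.advance_phi(phi, np.zeros_like(phi), p, grid)
            psi = fields.compute_psi(phi, p.beta, p.theta)
        m1 = fields.integrate(A * psi, grid) / p.eps
        assert abs(m1 - m0) / m0 < 0.01


class TestSeeding:
    def test_seed_statistics(self, coarse_params, rng):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        _, n = reactions.seed_initial_patch(
            state.A, state.phi, psi, state.grid, 1.5, rng)
        vals = state.A[state.A > 0]
        assert n > 20
        assert vals.mean() == pytest.approx(2.5, abs=0.5)
        assert vals.max() <= 5.0

    def test_zero_radius_is_noop(self, coarse_params, rng):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        _, n = reactions.seed_initial_patch(
            state.A, state.phi, psi, state.grid, 0.0, rng)
        assert n == 0 and not np.any(state.A)

    def test_different_seeds_differ(self, coarse_params):
        fields_out = []
        for seed in (1, 2):
            state = axisym.make_cell(coarse_params)
            psi = fields.compute_psi(state.phi)
            reactions.seed_initial_patch(state.A, state.phi, psi,
                                         state.grid, 1.5,
                                         np.random.default_rng(seed))
            fields_out.append(state.A.copy())
        assert not np.array_equal(*fields_out)
        # same support, different values
        assert np.array_equal(fields_out[0] > 0, fields_out[1] > 0)


class TestNucleation:
    def test_zero_rate_is_noop(self, coarse_params, rng):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        before = state.A.copy()
        n = reactions.nucleate(state.A, psi, state.grid,
                               NoiseParams(lam=0.0), 1.0, rng)
        assert n == 0 and np.array_equal(state.A, before)

    def test_poisson_event_statistics(self, coarse_params, rng):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        noise = NoiseParams(sigma=8.0, d=1.5, lam=3.0e-5)
        Vdom = math.pi * state.grid.Lr**2 * state.grid.Lz
        T, dt = 50.0, 0.1
        total = sum(reactions.nucleate(state.A, psi, state.grid, noise,
                                       dt, rng)
                    for _ in range(int(T / dt)))
        lam_eff = noise.lam * Vdom
        expect = lam_eff * T
        # within 3 standard errors of the Poisson mean
        assert abs(total - expect) <= 3.0 * math.sqrt(expect) + 1

    def test_bump_lands_on_band_and_respects_clamp(self, coarse_params):
        state = axisym.make_cell(coarse_params)
        psi = fields.compute_psi(state.phi)
        rng = np.random.default_rng(7)
        # crank the rate so at least one event lands on the band
        noise = NoiseParams(sigma=8.0, d=1.5, lam=1.0)
        reactions.nucleate(state.A, psi, state.grid, noise, 1.0, rng,
                           clamp=coarse_params.clamp)
        assert state.A.max() <= coarse_params.clamp
        assert np.all(state.A[psi <= 1e-3] == 0.0)
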