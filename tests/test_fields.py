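"""Grids, interface kernels, integrals and discrete operators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macrocup import fields
from macrocup.fields import (AxisymGrid, CartesianGrid3D, compute_psi,
                             divergence_axisym, double_well_prime,
                             gradient_axisym, grad_magnitude,
                             init_sphere_phi, laplacian_axisym,
                             laplacian_cart3d, phi_kernel, surface_area_of,
                             volume_of)


class TestInterfaceKernel:
    def test_midpoint_and_limits(self):
        assert phi_kernel(0.0, 0.8) == 0.5
        assert phi_kernel(-100.0, 0.8) == pytest.approx(1.0)
        assert phi_kernel(100.0, 0.8) == pytest.approx(0.0)

    def test_value_at_half_eps(self):
        # n = eps/2 with kernel steepness 2: (1 - tanh(1))/2
        expected = (1.0 - math.tanh(1.0)) / 2.0
        assert phi_kernel(0.4, 0.8) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.11920, abs=1e-5)

    def test_sphere_monotone_along_radius(self):
        grid = AxisymGrid.from_extents(10.0, 20.0, 0.2)
        phi = init_sphere_phi(grid, (0.0, 10.0), 5.0, 0.8)
        profile = phi[:, 50]  # z through the center
        assert np.all(np.diff(profile) <= 1e-12)
        assert phi[0, 50] > 0.999

    def test_sphere_out_of_bounds_raises(self):
        grid = AxisymGrid.from_extents(10.0, 20.0, 0.2)
        with pytest.raises(ValueError):
            init_sphere_phi(grid, (0.0, 10.0), 9.0, 0.8)
        with pytest.raises(ValueError):
            init_sphere_phi(grid, (0.0, 2.0), 5.0, 0.8)


class TestDoubleWell:
    @pytest.mark.parametrize("phi", [0.0, 0.5, 1.0])
    def test_roots(self, phi):
        assert double_well_prime(phi) == 0.0

    def test_quarter_value(self):
        assert double_well_prime(0.25) == pytest.approx(1.5)

    @given(st.floats(-0.5, 1.5))
    @settings(deadline=None)
    def test_antisymmetry_about_half(self, phi):
        assert double_well_prime(phi) == pytest.approx(
            -double_well_prime(1.0 - phi), abs=1e-9)


class TestPsi:
    def test_logistic_midpoint(self):
        # phi(1-phi) = theta -> psi = 1/2
        theta = 0.105
        phi = (1.0 - math.sqrt(1.0 - 4.0 * theta)) / 2.0
        assert compute_psi(phi) == pytest.approx(0.5, abs=1e-9)

    def test_band_center_value(self):
        assert compute_psi(0.5) == pytest.approx(
            1.0 / (1.0 + math.exp(-14.5)), abs=1e-12)
        assert compute_psi(0.5) > 1.0 - 1e-6

    def test_bulk_value(self):
        expected = 1.0 / (1.0 + math.exp(10.5))
        assert compute_psi(0.0) == pytest.approx(expected, rel=1e-9)
        assert compute_psi(1.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2.75e-5, rel=0.01)

    def test_band_width_close_to_eps(self):
        # the psi > 0.5 band around the interface is ~ eps thick
        grid = AxisymGrid.from_extents(12.0, 24.0, 0.1)
        phi = init_sphere_phi(grid, (0.0, 12.0), 8.0, 0.8)
        psi = compute_psi(phi)
        # measure along z through the center at r = 0
        band = np.sum(psi[0, :] > 0.5) / 2.0 * grid.dx  # two crossings
        assert band == pytest.approx(0.8, abs=0.11)


class TestIntegrals:
    def test_sphere_volume_and_area_axisym(self):
        grid = AxisymGrid.from_extents(13.0, 26.0, 0.1)
        phi = init_sphere_phi(grid, (0.0, 13.0), 10.0, 0.8)
        V = volume_of(phi, grid)
        assert V == pytest.approx(4.0 * math.pi * 1000.0 / 3.0, rel=0.01)
        S = surface_area_of(compute_psi(phi), grid, 0.8)
        assert S == pytest.approx(4.0 * math.pi * 100.0, rel=0.03)

    @pytest.mark.parametrize("R", [5.0, 8.0, 12.0])
    def test_sphere_areas_scale(self, R):
        grid = AxisymGrid.from_extents(R + 3.0, 2 * R + 6.0, 0.1)
        phi = init_sphere_phi(grid, (0.0, R + 3.0), R, 0.8)
        S = surface_area_of(compute_psi(phi), grid, 0.8)
        assert S == pytest.approx(4.0 * math.pi * R**2, rel=0.03)

    def test_empty_field(self):
        grid = AxisymGrid.from_extents(5.0, 10.0, 0.2)
        z = np.zeros(grid.shape)
        assert volume_of(z, grid) == 0.0
        assert surface_area_of(z, grid, 0.8) == 0.0

    def test_cartesian_volume(self):
        grid = CartesianGrid3D(101, 101, 101, 0.1)
        phi = init_sphere_phi(grid, (5.0, 5.0, 5.0), 3.0, 0.2)
        assert volume_of(phi, grid) == pytest.approx(
            4.0 * math.pi * 27.0 / 3.0, rel=0.01)


class TestOperators:
    def test_laplacian_axisym_quadratics(self):
        grid = AxisymGrid.from_extents(5.0, 10.0, 0.1)
        r, z = grid.coords()
        lap_r2 = laplacian_axisym(r**2, grid.dx)
        assert np.allclose(lap_r2[:-1, 1:-1], 4.0, atol=1e-9)
        lap_z = laplacian_axisym(z.copy(), grid.dx)
        assert np.allclose(lap_z[:-1, 1:-1], 0.0, atol=1e-9)

    def test_laplacian_cart3d_quadratic(self):
        grid = CartesianGrid3D(21, 21, 21, 0.1)
        x, y, z = grid.coords()
        lap = laplacian_cart3d(x**2 + y**2 + z**2, grid.dx)
        assert np.allclose(lap[1:-1, 1:-1, 1:-1], 6.0, atol=1e-8)

    def test_laplacian_second_order_convergence(self):
        errs = []
        for dx in (0.2, 0.1):
            grid = AxisymGrid.from_extents(4.0, 8.0, dx)
            r, z = grid.coords()
            f = np.cos(r) * np.sin(z)
            # axisym laplacian of cos(r) sin(z):
            # (-cos r - sin r / r) sin z - cos r sin z, with r->0 limit
            with np.errstate(divide="ignore", invalid="ignore"):
                exact = (-np.cos(r) - np.sin(r) / r) * np.sin(z) \
                    - np.cos(r) * np.sin(z)
            exact[0, :] = -3.0 * np.cos(0.0) * np.sin(z[0, :])
            num = laplacian_axisym(f, dx)
            err = np.abs(num - exact)[:-1, 1:-1].max()
            errs.append(err)
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)

    def test_divergence_axisym_examples(self):
        grid = AxisymGrid.from_extents(5.0, 10.0, 0.1)
        r, z = grid.coords()
        div = divergence_axisym(r.copy(), np.zeros_like(r), grid.dx)
        assert np.allclose(div[:-1, 1:-1], 2.0, atol=1e-9)
        div = divergence_axisym(np.zeros_like(r), np.full_like(r, 3.0),
                                grid.dx)
        assert np.allclose(div[:-1, 1:-1], 0.0, atol=1e-9)
        div = divergence_axisym(np.zeros_like(r), z.copy(), grid.dx)
        assert np.allclose(div[:-1, 1:-1], 1.0, atol=1e-9)

    def test_gradient_magnitude(self):
        grid = AxisymGrid.from_extents(5.0, 10.0, 0.1)
        r, z = grid.coords()
        assert np.allclose(
            grad_magnitude(gradient_axisym(np.ones_like(r), grid.dx)), 0.0)
        gm = grad_magnitude(gradient_axisym(2.0 * z, grid.dx))
        assert np.allclose(gm[:, 1:-1], 2.0, atol=1e-9)

    def test_kernel_gradient_peak(self):
        # |grad phi| of the tanh kernel peaks at a_k/(2 eps) on the
        # interface (analytic derivative of (1 - tanh(2 n / eps))/2)
        eps = 0.8
        grid = AxisymGrid.from_extents(10.0, 20.0, 0.05)
        phi = init_sphere_phi(grid, (0.0, 10.0), 5.0, eps)
        gm = grad_magnitude(gradient_axisym(phi, grid.dx))
        assert gm.max() == pytest.approx(2.0 / (2.0 * eps), rel=0.01)


def test_upwind_divergence_conserves_mass():
    """The conservative upwind advection telescopes: total r-weighted
    mass change is only through the outer boundary."""
    grid = AxisymGrid.from_extents(5.0, 10.0, 0.1)
    r, z = grid.coords()
    c = np.exp(-((r - 2.0) ** 2 + (z - 5.0) ** 2) / 0.25)
    vr = 0.1 * np.ones_like(c)
    vz = 0.05 * np.ones_like(c)
    div = fields.upwind_div_axisym(c, vr, vz, grid.dx)
    total = np.sum(div * grid.node_volumes())
    # fluxes vanish at the boundaries and on the axis ring where c ~ 0
    assert abs(total) < 1e-7 * np.sum(c * grid.node_volumes())
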