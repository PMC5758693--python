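"""Modified integral method: differential operators and elastogram sweeps."""

import numpy as np
import pytest

from mresim.forward import HarmonicField
from mresim.inversion import (
    InversionOptions,
    TestDomain,
    curl,
    curl_2d,
    elastogram_2d,
    elastogram_3d,
    interior_roi_mask,
    laplacian,
    material_node_masks,
    mollify,
    recover_modulus,
)
from mresim.phantom import VoxelGrid, add_cylindrical_inclusion, make_block_phantom
from mresim.rheology import complex_shear_modulus

from conftest import plane_shear_wave

RHO = 1000.0
FREQ = 250.0
OMEGA = 2 * np.pi * FREQ


def wavenumber(g_complex):
    return OMEGA * np.sqrt(RHO / g_complex)


def grid_field(shape, spacing, fn):
    """HarmonicField with u = fn(x, y, z) -> (3,) evaluated on nodes."""
    g = VoxelGrid(shape, spacing)
    X, Y, Z = np.meshgrid(*(g.node_coords(a) for a in range(3)), indexing="ij")
    vals = np.stack(fn(X, Y, Z), axis=-1).astype(complex)
    return HarmonicField(grid=g, values=vals, frequency=FREQ)


class TestCurl:
    def test_uniform_field_has_zero_curl(self):
        f = grid_field((6, 6, 6), 1e-3, lambda X, Y, Z: (X * 0 + 1, X * 0 + 2, X * 0 - 1))
        w = curl(f)
        assert np.abs(w.values[w.mask]).max() == 0

    def test_gradient_of_quadratic_is_curl_free(self):
        # u = grad(phi), phi = x^2 + 2 y^2 - z^2 + xy: exact on quadratics
        f = grid_field(
            (6, 6, 6),
            1e-3,
            lambda X, Y, Z: (2 * X + Y, 4 * Y + X, -2 * Z),
        )
        w = curl(f)
        assert np.abs(w.values[w.mask]).max() < 1e-12

    def test_plane_shear_wave_curl_is_analytic(self):
        k = wavenumber(15000.0 + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 24)
        w = curl(f)
        x = f.grid.node_coords(0)
        expected = (1j * k * np.exp(1j * k * x))[:, None, None]
        err = np.abs(w.values[..., 2] - expected)[w.mask]
        assert err.max() < (k * f.grid.spacing) ** 2 * k / 4  # O(h^2 k^3)
        assert np.abs(w.values[..., 0][w.mask]).max() < 1e-12
        assert np.abs(w.values[..., 1][w.mask]).max() < 1e-12

    def test_too_small_grid_rejected(self):
        f = grid_field((1, 6, 6), 1e-3, lambda X, Y, Z: (X, Y, Z))
        with pytest.raises(ValueError):
            curl(f)

    def test_2d_scalar_curl(self):
        k = wavenumber(15000.0 + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 24)
        w2 = curl_2d(f, f.grid.node_shape[2] // 2)
        x = f.grid.node_coords(0)
        expected = (1j * k * np.exp(1j * k * x))[:, None]
        assert np.abs(w2.values - expected)[w2.mask].max() < (
            k * f.grid.spacing
        ) ** 2 * k / 4


class TestMollify:
    def test_constant_field_unchanged(self):
        a = np.full((10, 10, 10), 3.7)
        out = mollify(a, width=2e-3, spacing=1e-3)
        assert np.allclose(out, 3.7)

    def test_zero_width_is_identity(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((8, 8, 8))
        assert np.array_equal(mollify(a, 0.0, 1e-3), a)

    def test_white_noise_variance_shrinks_by_kernel_norm(self):
        """Interior output variance of white noise ~ sigma^2 ||kernel||_2^2."""
        from scipy import ndimage

        rng = np.random.default_rng(123)
        sigma_vox = 1.5
        spacing = 1e-3
        a = rng.standard_normal((120, 120))
        out = mollify(a, width=sigma_vox * spacing, spacing=spacing)
        # discrete kernel L2 norm measured from an impulse
        imp = np.zeros((41, 41))
        imp[20, 20] = 1.0
        kernel = ndimage.gaussian_filter(imp, sigma_vox, truncate=3.0)
        expected = (kernel**2).sum()
        measured = out[10:-10, 10:-10].var()
        assert measured == pytest.approx(expected, rel=0.1)


class TestLaplacian:
    def test_linear_field_maps_to_zero(self):
        f = grid_field((6, 6, 6), 1e-3, lambda X, Y, Z: (X + Y, Z, X - 2 * Z))
        lap = laplacian(curl(f))
        # zero up to differencing roundoff amplified by 1/h^2
        assert np.abs(lap.values[lap.mask]).max() < 1e-7

    def test_exact_on_quadratics(self):
        # w_x = x^2 -> lap = 2, built directly as a curl-like field
        g = VoxelGrid((7, 7, 7), 1e-3)
        X = np.meshgrid(*(g.node_coords(a) for a in range(3)), indexing="ij")[0]
        from mresim.inversion import CurlField

        vals = np.zeros(g.node_shape + (3,), complex)
        vals[..., 0] = X**2
        mask = np.zeros(g.node_shape, bool)
        mask[1:-1, 1:-1, 1:-1] = True
        w = CurlField(grid=g, values=vals, mask=mask, spacing=g.spacing)
        lap = laplacian(w)
        assert np.allclose(lap.values[..., 0][lap.mask], 2.0, rtol=1e-6)

    def test_plane_wave_eigenvalue(self):
        k = wavenumber(15000.0 + 0j).real
        spacing = 2 * np.pi / k / 32
        f = plane_shear_wave(k, spacing=spacing)
        w = curl(f)
        lap = laplacian(w)
        ratio = lap.values[..., 2][lap.mask] / w.values[..., 2][lap.mask]
        expected = -(2 - 2 * np.cos(k * spacing)) / spacing**2
        assert np.allclose(ratio, expected, rtol=1e-9)
        assert expected == pytest.approx(-(k**2), rel=(k * spacing) ** 2 / 6)

    def test_mask_grows_by_one_node(self):
        f = grid_field((6, 6, 6), 1e-3, lambda X, Y, Z: (X, Y, Z))
        w = curl(f)
        lap = laplacian(w)
        assert lap.mask.sum() < w.mask.sum()
        assert not lap.mask[1, :, :].any()


class TestRecoverModulus:
    def test_elastic_plane_wave_dispersion(self):
        g_true = 15000.0
        k = wavenumber(g_true + 0j).real
        for npw, tol in ((12, 0.025), (24, 0.01)):
            f = plane_shear_wave(k, spacing=2 * np.pi / k / npw)
            w = curl(f)
            lap = laplacian(w)
            center = tuple(s // 2 for s in f.grid.node_shape)
            cm = recover_modulus(
                w, lap, TestDomain(center, spacing=f.grid.spacing), RHO, FREQ
            )
            assert abs(cm.G_storage - g_true) / g_true < tol
            assert cm.G_loss < 1e-6 * g_true

    def test_damped_wave_recovers_both_parts(self, gel):
        g_cm = complex_shear_modulus(gel, FREQ)
        g_true = complex(15000.0, g_cm.G_loss)
        k = wavenumber(g_true)
        f = plane_shear_wave(k, spacing=2 * np.pi / k.real / 16)
        w = curl(f)
        lap = laplacian(w)
        center = tuple(s // 2 for s in f.grid.node_shape)
        cm = recover_modulus(
            w, lap, TestDomain(center, spacing=f.grid.spacing), RHO, FREQ
        )
        assert abs(cm.G_storage - g_true.real) / g_true.real < 0.02
        assert abs(cm.G_loss - g_true.imag) / g_true.imag < 0.02

    def test_second_order_convergence(self):
        g_true = 15000.0
        k = wavenumber(g_true + 0j).real
        errs = []
        for npw in (12, 24, 48):
            f = plane_shear_wave(k, spacing=2 * np.pi / k / npw)
            w = curl(f)
            lap = laplacian(w)
            center = tuple(s // 2 for s in f.grid.node_shape)
            cm = recover_modulus(
                w, lap, TestDomain(center, spacing=f.grid.spacing), RHO, FREQ
            )
            errs.append(abs(cm.G_storage - g_true) / g_true)
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 1.8)

    def test_scale_invariance(self):
        k = wavenumber(15000.0 + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 16)
        center = tuple(s // 2 for s in f.grid.node_shape)
        td = TestDomain(center, spacing=f.grid.spacing)
        w = curl(f)
        lap = laplacian(w)
        base = recover_modulus(w, lap, td, RHO, FREQ)
        f2 = HarmonicField(grid=f.grid, values=f.values * (0.3 - 2.4j), frequency=FREQ)
        w2 = curl(f2)
        lap2 = laplacian(w2)
        scaled = recover_modulus(w2, lap2, td, RHO, FREQ)
        assert scaled.G_storage == pytest.approx(base.G_storage, rel=1e-12)

    def test_domain_outside_mask_rejected(self):
        k = wavenumber(15000.0 + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 16)
        w = curl(f)
        lap = laplacian(w)
        with pytest.raises(ValueError):
            recover_modulus(
                w, lap, TestDomain((1, 1, 1), spacing=f.grid.spacing), RHO, FREQ
            )


class TestElastograms:
    def test_plane_wave_elastogram_constant(self):
        g_true = 15000.0
        k = wavenumber(g_true + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 16)
        el = elastogram_3d(f, rho=RHO)
        vals = el.storage[el.valid_mask]
        assert vals.std() / vals.mean() < 0.01
        assert abs(vals.mean() - g_true) / g_true < 0.02

    def test_elastogram_scale_invariant(self):
        k = wavenumber(15000.0 + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 16)
        el1 = elastogram_3d(f, rho=RHO)
        f2 = HarmonicField(grid=f.grid, values=f.values * (5.5 + 1.2j), frequency=FREQ)
        el2 = elastogram_3d(f2, rho=RHO)
        assert np.array_equal(el1.valid_mask, el2.valid_mask)
        assert np.allclose(el1.storage, el2.storage, rtol=1e-9)

    def test_2d_matches_3d_for_in_plane_wave(self):
        k = wavenumber(15000.0 + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 16, shape=(36, 14, 14))
        mid = f.grid.node_shape[2] // 2
        el3 = elastogram_3d(f, rho=RHO)
        el2 = elastogram_2d(f, mid, rho=RHO)
        m3 = el3.storage[:, :, mid][el3.valid_mask[:, :, mid] & el2.valid_mask]
        m2 = el2.storage[el3.valid_mask[:, :, mid] & el2.valid_mask]
        assert np.abs(m2 - m3).max() / m3.mean() < 0.01

    def test_2d_overestimates_oblique_wave_by_secant_squared(self):
        g_true = 15000.0
        alpha = np.deg2rad(30.0)
        k = wavenumber(g_true + 0j).real
        direction = np.array([np.cos(alpha), 0.0, np.sin(alpha)])
        f = plane_shear_wave(
            k, spacing=2 * np.pi / k / 20, shape=(40, 14, 40), direction=direction
        )
        mid = f.grid.node_shape[2] // 2
        el2 = elastogram_2d(f, mid, rho=RHO)
        vals = el2.storage[el2.valid_mask]
        assert vals.mean() / g_true == pytest.approx(1.0 / np.cos(alpha) ** 2, rel=0.05)

    def test_curl_free_field_is_all_masked(self):
        f = grid_field((10, 10, 10), 1e-3, lambda X, Y, Z: (2 * X + Y, 4 * Y + X, -2 * Z))
        with pytest.raises(ValueError, match="invalid"):
            elastogram_3d(f, rho=RHO)

    def test_deterministic(self):
        k = wavenumber(15000.0 + 0j).real
        f = plane_shear_wave(k, spacing=2 * np.pi / k / 16)
        a = elastogram_3d(f, rho=RHO)
        b = elastogram_3d(f, rho=RHO)
        assert np.array_equal(a.storage, b.storage)
        assert np.array_equal(a.valid_mask, b.valid_mask)


class TestMasksAndROI:
    def test_interior_roi_margin(self):
        mask = np.ones((20, 20, 20), bool)
        roi = interior_roi_mask(mask, margin=5)
        assert roi.sum() == 10**3
        assert not roi[4, :, :].any()

    def test_material_node_masks_separate_phases(self, gel, stiff):
        m = make_block_phantom((0.05, 0.035, 0.0275), 1.25e-3, gel)
        m = add_cylindrical_inclusion(m, (0.025, 0.0175), 0.02, stiff)
        masks = material_node_masks(m, interface_margin=2)
        assert set(masks) == {0, 1}
        assert not (masks[0] & masks[1]).any()
        # eroded inclusion nodes stay well inside the cylinder radius
        g = m.grid
        X, Y = np.meshgrid(g.node_coords(0), g.node_coords(1), indexing="ij")
        r = np.hypot(X - 0.025, Y - 0.0175)
        inside = masks[1].any(axis=2)
        assert r[inside].max() <= 0.01 - 1 * g.spacing
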