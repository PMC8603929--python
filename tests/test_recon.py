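"""Derivatives, phase-based σ, and the convection–reaction solver."""

import warnings

import numpy as np
import pytest

from mrept.constants import rhs_constant
from mrept.grids import ConductivityMap, PhaseMap, VOISet
from mrept.phantom import ellipsoid_mask, forward_phase
from mrept.recon import (
    ReconConfig,
    cr_mrept_solve,
    erode_and_mask,
    phase_based_sigma,
    spatial_derivatives,
)

from conftest import F_400MHZ, SPACING

CFG = ReconConfig(larmor_hz=F_400MHZ)


def _phase(values):
    return PhaseMap(values=values, spacing_mm=SPACING, wrapped=False)


def _coords(shape):
    hy, hx = SPACING[1] * 1e-3, SPACING[2] * 1e-3
    y = (np.arange(shape[1]) - (shape[1] - 1) / 2) * hy
    x = (np.arange(shape[2]) - (shape[2] - 1) / 2) * hx
    return np.broadcast_to(y[:, None], shape[1:]), np.broadcast_to(x[None, :], shape[1:])


class TestSpatialDerivatives:
    def test_quadratic_laplacian_exact(self):
        """Central stencils differentiate a(x²+y²) exactly: lap = 4a."""
        a = 789.57
        shape = (1, 32, 24)
        y, x = _coords(shape)
        phi = (a * (y**2 + x**2))[None]
        grad, lap = spatial_derivatives(_phase(phi), CFG)
        assert np.nanmax(np.abs(lap - 4 * a)) < 1e-6

    def test_constant_phase(self):
        grad, lap = spatial_derivatives(_phase(np.zeros((1, 16, 16))), CFG)
        assert np.nanmax(np.abs(grad)) == 0
        assert np.nanmax(np.abs(lap)) == 0

    def test_linear_phase(self):
        shape = (1, 16, 16)
        _, x = _coords(shape)
        g = 37.0
        grad, lap = spatial_derivatives(_phase((g * x)[None]), CFG)
        assert np.nanmax(np.abs(grad[2] - g)) < 1e-9
        assert np.nanmax(np.abs(grad[1])) < 1e-9
        assert np.nanmax(np.abs(lap)) < 1e-5

    def test_savgol_quadratic_exact(self):
        a = 500.0
        shape = (1, 32, 24)
        y, x = _coords(shape)
        phi = (a * (y**2 + x**2))[None]
        cfg = ReconConfig(larmor_hz=F_400MHZ, laplacian_kernel="savgol",
                          savgol_radius_vox=3)
        _, lap = spatial_derivatives(_phase(phi), cfg)
        assert np.nanmax(np.abs(lap - 4 * a)) < 1e-5

    def test_grid_thinner_than_kernel_rejected(self):
        cfg = ReconConfig(larmor_hz=F_400MHZ, laplacian_kernel="savgol",
                          savgol_radius_vox=4)
        with pytest.raises(ValueError, match="thinner"):
            spatial_derivatives(_phase(np.zeros((1, 6, 6))), cfg)


class TestPhaseBasedSigma:
    def test_quadratic_gives_half_siemens(self):
        """a = 789.57 rad/m² at 400 MHz: σ = 4a/(2μ₀ω) = 0.5000 S/m."""
        a = rhs_constant(F_400MHZ) * 0.5 / 4.0
        assert a == pytest.approx(789.57, abs=0.01)
        shape = (1, 32, 24)
        y, x = _coords(shape)
        est = phase_based_sigma(_phase((a * (y**2 + x**2))[None]), CFG)
        assert np.nanmax(np.abs(est.values - 0.5)) < 1e-6

    def test_scaled_laplacian_gives_cortex_value(self):
        a = rhs_constant(F_400MHZ) * 0.44 / 4.0
        shape = (1, 24, 24)
        y, x = _coords(shape)
        est = phase_based_sigma(_phase((a * (y**2 + x**2))[None]), CFG)
        assert np.nanmedian(est.values) == pytest.approx(0.44, abs=1e-9)

    def test_constant_phase_fully_masked(self):
        est = phase_based_sigma(_phase(np.zeros((1, 16, 16))), CFG)
        assert not est.mask.any()


class TestCrMreptSolve:
    def test_uniform_exact_boundary(self, uniform_phantom):
        """Consistent system: interior σ within 0.1% of truth at c = 0."""
        _, phase, _ = uniform_phantom
        cfg = ReconConfig(larmor_hz=F_400MHZ, c_mode="fixed", c_value=0.0,
                          boundary_mode="provided")
        res = cr_mrept_solve(phase, cfg, boundary_u=2.0)
        interior = res.sigma.values[0, 3:-3, 3:-3]
        assert np.nanmax(np.abs(interior - 0.5)) / 0.5 < 1e-3

    def test_zero_rhs_zero_boundary_gives_zero(self, uniform_phantom):
        _, phase, _ = uniform_phantom
        cfg = ReconConfig(larmor_hz=F_400MHZ, c_mode="fixed", c_value=0.0,
                          boundary_mode="provided")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cr_mrept_solve(phase, cfg, boundary_u=0.0, rhs_override=0.0)
        assert np.nanmax(np.abs(res.u)) == 0.0

    def test_two_compartment_auto_c(self):
        """Round trip on the cortex/rim two-compartment phantom within 10%."""
        shape = (1, 128, 64)
        vals = np.full(shape, 0.44)
        inner = ellipsoid_mask(shape, (0, 64, 32), (2, 20, 14))
        vals[inner] = 0.96
        sigma = ConductivityMap(values=vals, spacing_mm=SPACING)
        phase = forward_phase(sigma, larmor_hz=F_400MHZ)
        cfg = ReconConfig(larmor_hz=F_400MHZ, c_mode="auto")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cr_mrept_solve(phase, cfg)
        from scipy.ndimage import binary_dilation, binary_erosion

        core = binary_erosion(inner[0], iterations=3)
        outside = ~binary_dilation(inner[0], iterations=3)
        outside[:5] = outside[-5:] = outside[:, :5] = outside[:, -5:] = False
        sv = res.sigma.values[0]
        assert abs(np.nanmedian(sv[core]) - 0.96) / 0.96 < 0.10
        assert abs(np.nanmedian(sv[outside]) - 0.44) / 0.44 < 0.10

    def test_residual_norm_matches_independent_stencil(self, uniform_phantom):
        """Plugging u into a separately coded discretisation reproduces the
        solver's residual norm."""
        _, phase, _ = uniform_phantom
        cfg = ReconConfig(larmor_hz=F_400MHZ, c_mode="fixed", c_value=1e-3,
                          boundary_mode="provided")
        res = cr_mrept_solve(phase, cfg, boundary_u=2.0)
        oracle = _independent_cr_residual(phase, cfg, res.u, 2.0)
        assert abs(oracle - res.residual_norm) < 1e-10

    def test_monotone_noise_response(self, uniform_phantom):
        """Median |σ error| does not decrease as phase noise grows."""
        _, phase, _ = uniform_phantom
        cfg = ReconConfig(larmor_hz=F_400MHZ, c_mode="local",
                          laplacian_kernel="savgol", savgol_radius_vox=3)
        med_err = []
        for noise in (0.0, 0.003, 0.03):
            errs = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                noisy = PhaseMap(
                    values=phase.values + noise * rng.standard_normal(phase.shape),
                    spacing_mm=SPACING, wrapped=False,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = cr_mrept_solve(noisy, cfg)
                errs.append(np.nanmedian(np.abs(r.sigma.values - 0.5)))
            med_err.append(np.median(errs))
        assert med_err[0] <= med_err[1] <= med_err[2]

    def test_physical_range_masked_not_clipped(self, uniform_phantom):
        _, phase, _ = uniform_phantom
        cfg = ReconConfig(larmor_hz=F_400MHZ, c_mode="fixed", c_value=0.0,
                          boundary_mode="provided")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cr_mrept_solve(phase, cfg, boundary_u=-1.0, rhs_override=0.0)
        on = res.sigma.values[res.sigma.mask]
        if on.size:
            assert np.all((on > 0) & (on < 10))


def _independent_cr_residual(phase, cfg, u, bu_scalar):
    """Re-code the cr discretisation from its written definition and return
    ‖A·u − b‖₂ over the solved voxels."""
    hy, hx = SPACING[1] * 1e-3, SPACING[2] * 1e-3
    phi = phase.values[0]
    gy = np.gradient(phi, hy, axis=0)
    gx = np.gradient(phi, hx, axis=1)
    lap = (
        (np.roll(phi, -1, 0) - 2 * phi + np.roll(phi, 1, 0)) / hy**2
        + (np.roll(phi, -1, 1) - 2 * phi + np.roll(phi, 1, 1)) / hx**2
    )
    c = cfg.c_value
    uu = np.where(np.isfinite(u[0]), u[0], bu_scalar)
    ny, nx = phi.shape
    total = 0.0
    for j in range(2, ny - 2):
        for i in range(2, nx - 2):
            diff = -c * (
                (uu[j + 1, i] + uu[j - 1, i] - 2 * uu[j, i]) / hy**2
                + (uu[j, i + 1] + uu[j, i - 1] - 2 * uu[j, i]) / hx**2
            )
            pe_y = abs(gy[j, i]) * hy / c if c > 0 else np.inf
            pe_x = abs(gx[j, i]) * hx / c if c > 0 else np.inf
            if pe_y > cfg.peclet_upwind_threshold:
                conv_y = gy[j, i] * (
                    (uu[j, i] - uu[j - 1, i]) / hy if gy[j, i] > 0
                    else (uu[j + 1, i] - uu[j, i]) / hy
                )
            else:
                conv_y = gy[j, i] * (uu[j + 1, i] - uu[j - 1, i]) / (2 * hy)
            if pe_x > cfg.peclet_upwind_threshold:
                conv_x = gx[j, i] * (
                    (uu[j, i] - uu[j, i - 1]) / hx if gx[j, i] > 0
                    else (uu[j, i + 1] - uu[j, i]) / hx
                )
            else:
                conv_x = gx[j, i] * (uu[j, i + 1] - uu[j, i - 1]) / (2 * hx)
            r = diff + conv_y + conv_x + lap[j, i] * uu[j, i] - rhs_constant(cfg.larmor_hz)
            total += r * r
    return np.sqrt(total)


class TestErodeAndMask:
    def _result_and_vois(self, region_slice, shape=(1, 16, 16)):
        labels = np.zeros(shape, dtype=np.int32)
        labels[region_slice] = 1
        vois = VOISet(labels=labels, label_names={1: "square"}, spacing_mm=SPACING)
        sigma = ConductivityMap(values=np.full(shape, 0.5), spacing_mm=SPACING)
        from mrept.recon import ReconResult

        res = ReconResult(sigma=sigma, u=1.0 / sigma.values, residual_norm=0.0,
                          solver_iterations=1, config_echo=CFG)
        return res, vois

    def test_zero_erosion_is_identity(self):
        res, vois = self._result_and_vois(np.s_[0, 4:13, 4:13])
        out = erode_and_mask(res, vois, 0)
        assert np.array_equal(out.sigma.mask, res.sigma.mask)

    def test_square_region_erosion(self):
        """9×9 square, erosion 2 → 5×5 valid core."""
        res, vois = self._result_and_vois(np.s_[0, 4:13, 4:13])
        out = erode_and_mask(res, vois, 2)
        region_valid = out.sigma.mask & (vois.labels == 1)
        assert region_valid.sum() == 25
        expected = np.zeros_like(vois.labels, dtype=bool)
        expected[0, 6:11, 6:11] = True
        assert np.array_equal(region_valid, expected)

    def test_over_erosion_empties_region_with_warning(self):
        res, vois = self._result_and_vois(np.s_[0, 4:13, 4:13])
        with pytest.warns(UserWarning, match="fully masked"):
            out = erode_and_mask(res, vois, 5)
        assert not (out.sigma.mask & (vois.labels == 1)).any()
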