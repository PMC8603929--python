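"""Phantom construction and forward simulation."""

import numpy as np
import pytest

from mrept.constants import rhs_constant
from mrept.grids import ConductivityMap, MDMap
from mrept.phantom import (
    RAT_BRAIN_TISSUES,
    PhantomSpec,
    RegionSpec,
    build_phantom,
    day_schedule_spec,
    divergence_residual,
    ellipsoid_mask,
    forward_phase,
    quadratic_phase,
    simulate_acquisition,
    simulate_dwi,
)
from mrept.recon import ReconConfig, phase_based_sigma

from conftest import F_400MHZ, SPACING


class TestBuildPhantom:
    def test_homogeneous(self):
        spec = PhantomSpec(grid_shape=(1, 16, 16), spacing_mm=SPACING, regions=[],
                           background_sigma=0.5)
        sigma, md, t2, vois = build_phantom(spec)
        assert np.all(sigma.values == 0.5)
        assert np.all(vois.labels == 0)

    def test_default_regions_hit_reference_conductivities(self, rat_phantom):
        """Region means of the ground-truth map equal the tissue table values."""
        sigma, md, _, vois = rat_phantom
        for name, (sig_ref, md_ref) in RAT_BRAIN_TISSUES.items():
            m = vois.region_mask(name)
            assert m.sum() > 0, name
            assert sigma.values[m].mean() == pytest.approx(sig_ref, abs=1e-12)
            assert md.values[m].mean() == pytest.approx(md_ref, abs=1e-12)

    def test_ellipsoid_count_matches_brute_force(self):
        shape, center, semi = (1, 40, 30), (0.0, 19.0, 14.0), (2.0, 8.0, 5.5)
        mask = ellipsoid_mask(shape, center, semi)
        count = 0
        for y in range(shape[1]):
            for x in range(shape[2]):
                q = ((0 - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2 \
                    + ((x - center[2]) / semi[2]) ** 2
                count += q <= 1.0
        assert mask.sum() == count

    def test_duplicate_label_overlap_rejected(self):
        r = dict(center_vox=(0.0, 8.0, 8.0), semi_axes_vox=(1.0, 4.0, 4.0),
                 sigma=0.5, md=0.7)
        spec = PhantomSpec(
            grid_shape=(1, 20, 20), spacing_mm=SPACING,
            regions=[RegionSpec(label="a", **r), RegionSpec(label="a", **r)],
        )
        with pytest.raises(ValueError, match="overlap"):
            build_phantom(spec)

    def test_out_of_plane_bounds_rejected(self):
        spec = PhantomSpec(
            grid_shape=(1, 20, 20), spacing_mm=SPACING,
            regions=[RegionSpec(label="a", center_vox=(0.0, 18.0, 10.0),
                                semi_axes_vox=(1.0, 5.0, 3.0), sigma=0.5, md=0.7)],
        )
        with pytest.raises(ValueError, match="exceeds grid bounds"):
            build_phantom(spec)

    def test_day8_phantom_lacks_core(self):
        spec8 = day_schedule_spec(8)
        assert "tumor_core" not in {r.label for r in spec8.regions}
        assert "tumor_core" in {r.label for r in day_schedule_spec(11).regions}


class TestForwardPhase:
    def test_uniform_matches_quadratic(self, uniform_phantom):
        """∇²ϕ = 2μ₀ωσ has the closed-form solution a·(x²+y²), 4a = 2μ₀ωσ."""
        _, phase, boundary = uniform_phantom
        scale = np.abs(boundary).max()
        assert np.max(np.abs(phase.values - boundary)) / scale < 1e-6

    def test_scaling_symmetry(self):
        shape = (1, 24, 20)
        s1 = ConductivityMap(values=np.full(shape, 0.4), spacing_mm=SPACING)
        s2 = ConductivityMap(values=np.full(shape, 0.8), spacing_mm=SPACING)
        b = quadratic_phase(shape, SPACING, 0.4, F_400MHZ)
        p1 = forward_phase(s1, larmor_hz=F_400MHZ, boundary=b)
        p2 = forward_phase(s2, larmor_hz=F_400MHZ, boundary=2 * b)
        np.testing.assert_allclose(p2.values, 2 * p1.values, rtol=1e-10)

    def test_two_compartment_residual(self):
        """Independent stencil application: residual far below the RHS scale."""
        shape = (1, 48, 40)
        vals = np.full(shape, 0.44)
        vals[ellipsoid_mask(shape, (0, 24, 20), (1, 10, 8))] = 0.96
        sigma = ConductivityMap(values=vals, spacing_mm=SPACING)
        phase = forward_phase(sigma, larmor_hz=F_400MHZ)
        res = divergence_residual(phase.values, vals, SPACING, F_400MHZ)
        assert np.nanmax(np.abs(res)) < 1e-8 * rhs_constant(F_400MHZ)

    def test_nonpositive_sigma_rejected(self):
        vals = np.full((1, 10, 10), 0.5)
        vals[0, 5, 5] = np.nan
        with pytest.raises(ValueError):
            forward_phase(
                ConductivityMap(values=vals, spacing_mm=SPACING,
                                mask=np.isfinite(vals)),
                larmor_hz=F_400MHZ,
            )

    def test_roundtrip_phase_based(self, uniform_phantom):
        """phase_based_sigma(forward_phase(σ)) recovers uniform σ within 1%."""
        sigma, phase, _ = uniform_phantom
        est = phase_based_sigma(phase, ReconConfig(larmor_hz=F_400MHZ))
        interior = est.values[0, 2:-2, 2:-2]
        assert np.all(np.abs(interior - 0.5) / 0.5 < 0.01)


class TestSimulateAcquisition:
    def test_noiseless_single_channel_zero_offset(self, small_spec):
        from mrept.grids import wrap_to_pi

        spec = small_spec
        sigma, md, t2, _ = build_phantom(spec)
        phase = forward_phase(sigma, larmor_hz=spec.larmor_hz)
        shape = spec.grid_shape
        fields = (np.ones((1,) + shape), np.zeros((1,) + shape))
        spec1 = PhantomSpec(grid_shape=shape, spacing_mm=spec.spacing_mm,
                            regions=[], coil_count=1)
        raw = simulate_acquisition(sigma, t2, phase, spec1, noise_sd=0.0,
                                   seed=0, coil_fields=fields)
        stored = np.angle(raw.complex_values[0, 0])
        np.testing.assert_allclose(stored, wrap_to_pi(phase.values), atol=1e-12)

    def test_echo_decay_ratio(self, rat_spec, rat_phantom, rat_raw_noiseless):
        _, _, t2, _ = rat_phantom
        raw = rat_raw_noiseless
        te = raw.te_ms
        mag = np.abs(raw.complex_values[0])
        ratio = mag[4] / mag[0]
        expected = np.exp(-(te[4] - te[0]) / t2)
        np.testing.assert_allclose(ratio, expected, rtol=1e-10)

    def test_seed_determinism(self, small_spec):
        sigma, md, t2, _ = build_phantom(small_spec)
        phase = forward_phase(sigma, larmor_hz=small_spec.larmor_hz)
        a = simulate_acquisition(sigma, t2, phase, small_spec, 0.01, seed=5)
        b = simulate_acquisition(sigma, t2, phase, small_spec, 0.01, seed=5)
        c = simulate_acquisition(sigma, t2, phase, small_spec, 0.01, seed=6)
        assert np.array_equal(a.complex_values, b.complex_values)
        assert not np.array_equal(a.complex_values, c.complex_values)

    def test_bad_t2_rejected(self, small_spec):
        sigma, md, t2, _ = build_phantom(small_spec)
        phase = forward_phase(sigma, larmor_hz=small_spec.larmor_hz)
        t2bad = t2.copy()
        t2bad[0, 3, 3] = 0.0
        with pytest.raises(ValueError, match="t2"):
            simulate_acquisition(sigma, t2bad, phase, small_spec, 0.0, seed=0)


class TestSimulateDWI:
    def _md(self, value, shape=(1, 6, 6)):
        return MDMap(values=np.full(shape, value), spacing_mm=SPACING)

    def test_monoexponential_closed_form(self):
        """1000 s/mm² × 0.7 µm²/ms → attenuation exp(−0.7)."""
        bvals = np.array([0.0, 1000.0])
        bvecs = np.array([[0, 0, 0], [1.0, 0, 0]])
        stack = simulate_dwi(self._md(0.7), bvals, bvecs)
        np.testing.assert_allclose(stack.signal[1], np.exp(-0.7), rtol=1e-12)
        np.testing.assert_allclose(stack.signal[0], 1.0)

    def test_zero_md_gives_constant_signal(self):
        bvals = np.array([0.0, 1000.0, 2000.0])
        bvecs = np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        stack = simulate_dwi(self._md(0.0), bvals, bvecs)
        np.testing.assert_allclose(stack.signal, 1.0)

    def test_missing_b0_rejected(self):
        with pytest.raises(ValueError, match="b=0"):
            simulate_dwi(self._md(0.7), np.array([1000.0]),
                         np.array([[1.0, 0, 0]]))

    def test_rician_noise_determinism(self):
        bvals = np.array([0.0, 1000.0])
        bvecs = np.array([[0, 0, 0], [1.0, 0, 0]])
        a = simulate_dwi(self._md(0.7), bvals, bvecs, noise_sd=0.02, seed=3)
        b = simulate_dwi(self._md(0.7), bvals, bvecs, noise_sd=0.02, seed=3)
        assert np.array_equal(a.signal, b.signal)
        assert np.all(a.signal > 0)  # magnitude data
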