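"""Synthetic phantoms and forward simulation of the raw data.

The phantom is a piecewise-constant ellipsoid composition over a voxel grid:
each region carries a conductivity (S/m), a mean diffusivity (µm²/ms) and a
T2 (ms, a simulation nuisance parameter).  The forward B1-phase model is the
divergence-form elliptic PDE

    ∇·((1/σ_H) ∇ϕ_tr) = 2 μ₀ ω ,

solved per slice with Dirichlet boundary conditions — exactly the equation the
convection–reaction reconstruction inverts, so forward/inverse round trips are
self-consistent.  Raw multi-coil multi-echo complex images and multi-shell DWI
stacks are then synthesised on top with seeded complex-Gaussian noise.

Default tissue values mirror a 9.4 T rat glioma study: six regions
(contralateral cortex, tumor rim, viable tumor, tumor core, ventricles,
edema) with conductivities 0.44–0.96 S/m and diffusivities 0.69–1.23 µm²/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import larmor_frequency_hz, rhs_constant
from .grids import (
    ConductivityMap,
    DWIStack,
    MDMap,
    MultiCoilEchoData,
    PhaseMap,
    VOISet,
)

#: Region order and per-tissue (σ S/m, MD µm²/ms) defaults for the six VOIs.
RAT_BRAIN_TISSUES: dict[str, tuple[float, float]] = {
    "contralateral_cortex": (0.44, 0.69),
    "tumor_rim": (0.96, 0.81),
    "viable_tumor": (0.93, 0.76),
    "tumor_core": (0.84, 0.89),
    "ventricles": (0.72, 1.23),
    "edema": (0.77, 0.89),
}

# T2 (ms) at 9.4 T per tissue: plumbing defaults, not measured values.
_DEFAULT_T2_MS: dict[str, float] = {
    "contralateral_cortex": 40.0,
    "tumor_rim": 60.0,
    "viable_tumor": 55.0,
    "tumor_core": 90.0,
    "ventricles": 150.0,
    "edema": 80.0,
}


class SolverError(RuntimeError):
    """Raised when the elliptic forward/inverse solve fails; carries residual."""

    def __init__(self, message: str, residual_norm: float = np.nan):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass
class RegionSpec:
    """An ellipsoidal tissue region.

    center_vox and semi_axes_vox are (z, y, x) in voxel units.  A voxel
    belongs to the region when Σ ((idx−center)/semi)² ≤ 1.
    """

    label: str
    center_vox: tuple[float, float, float]
    semi_axes_vox: tuple[float, float, float]
    sigma: float
    md: float
    t2_ms: float = 60.0

    def __post_init__(self) -> None:
        if any(a < 1 for a in self.semi_axes_vox):
            raise ValueError(f"{self.label}: semi-axes must be >= 1 voxel")
        if self.sigma <= 0:
            raise ValueError(f"{self.label}: sigma must be > 0")
        if self.md < 0:
            raise ValueError(f"{self.label}: md must be >= 0")
        if self.t2_ms <= 0:
            raise ValueError(f"{self.label}: t2_ms must be > 0")


@dataclass
class PhantomSpec:
    """Geometry, tissue values and acquisition constants of a phantom.

    Later regions overwrite earlier ones, so nested structures (rim ⊃ viable
    ⊃ core) are expressed by listing them outside-in.
    """

    grid_shape: tuple[int, int, int] = (3, 128, 64)
    spacing_mm: tuple[float, float, float] = (0.3, 0.313, 0.313)
    regions: list[RegionSpec] = field(default_factory=list)
    background_sigma: float = 0.5
    background_md: float = 0.70
    background_t2_ms: float = 50.0
    b0_tesla: float = 9.4
    coil_count: int = 4
    te_first_ms: float = 8.0
    echo_spacing_ms: float = 8.0
    n_echoes: int = 10

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be > 0")
        if self.background_md < 0:
            raise ValueError("background_md must be >= 0")

    @property
    def larmor_hz(self) -> float:
        return larmor_frequency_hz(self.b0_tesla)

    @property
    def te_ms(self) -> np.ndarray:
        return self.te_first_ms + self.echo_spacing_ms * np.arange(self.n_echoes)


def default_rat_brain_spec(
    include_core: bool = True,
    sigma_overrides: dict[str, float] | None = None,
) -> PhantomSpec:
    """Six-region rat-brain tumor phantom on the 128×64 in-plane grid.

    The tumor complex (edema ⊃ rim ⊃ viable ⊃ core) sits in the right
    hemisphere, the contralateral cortex in the left, ventricles midline.
    ``include_core=False`` drops the necrotic core (early time point);
    ``sigma_overrides`` rescales per-region conductivity (tumor growth).
    """
    sigma_overrides = sigma_overrides or {}

    def reg(label, center, semi):
        sigma, md = RAT_BRAIN_TISSUES[label]
        return RegionSpec(
            label=label,
            center_vox=center,
            semi_axes_vox=semi,
            sigma=sigma_overrides.get(label, sigma),
            md=md,
            t2_ms=_DEFAULT_T2_MS[label],
        )

    regions = [
        reg("contralateral_cortex", (1.0, 70.0, 16.0), (9.0, 12.0, 7.0)),
        reg("ventricles", (1.0, 42.0, 26.0), (9.0, 7.0, 5.0)),
        reg("edema", (1.0, 70.0, 40.0), (9.0, 16.0, 12.0)),
        reg("tumor_rim", (1.0, 70.0, 40.0), (9.0, 10.0, 8.0)),
        reg("viable_tumor", (1.0, 70.0, 40.0), (9.0, 7.0, 5.5)),
    ]
    if include_core:
        regions.append(reg("tumor_core", (1.0, 70.0, 40.0), (9.0, 4.0, 3.0)))
    return PhantomSpec(regions=regions)


def ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center_vox: tuple[float, float, float],
    semi_axes_vox: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of voxels inside the ellipsoid (normalized equation ≤ 1)."""
    zz, yy, xx = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    cz, cy, cx = center_vox
    az, ay, ax = semi_axes_vox
    q = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    return q <= 1.0


def build_phantom(
    spec: PhantomSpec,
) -> tuple[ConductivityMap, MDMap, np.ndarray, VOISet]:
    """Rasterise a PhantomSpec into σ, MD and T2 maps plus the VOI labels.

    Later regions overwrite earlier ones; the VOI label of a voxel is the last
    region containing it.  Rejects duplicate-label overlaps and regions that
    extend beyond the grid.
    """
    shape = tuple(spec.grid_shape)
    sigma = np.full(shape, spec.background_sigma, dtype=float)
    md = np.full(shape, spec.background_md, dtype=float)
    t2 = np.full(shape, spec.background_t2_ms, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)

    label_names: dict[int, str] = {}
    name_to_id: dict[str, int] = {}
    seen_masks: dict[str, np.ndarray] = {}

    for region in spec.regions:
        # in-plane overflow is rejected; z overflow is allowed (a structure
        # cut through by the slice stack is normal in multi-slice imaging)
        for axis in (1, 2):
            lo = region.center_vox[axis] - region.semi_axes_vox[axis]
            hi = region.center_vox[axis] + region.semi_axes_vox[axis]
            if lo < 0 or hi > shape[axis] - 1:
                raise ValueError(
                    f"region {region.label!r} exceeds grid bounds on axis {axis}: "
                    f"extent [{lo:.1f}, {hi:.1f}] vs grid [0, {shape[axis] - 1}]"
                )
        mask = ellipsoid_mask(shape, region.center_vox, region.semi_axes_vox)
        if region.label in seen_masks and np.any(mask & seen_masks[region.label]):
            raise ValueError(
                f"two regions labelled {region.label!r} overlap; "
                "identical-label overlaps are ambiguous"
            )
        seen_masks[region.label] = (
            mask | seen_masks.get(region.label, np.zeros(shape, bool))
        )
        if region.label not in name_to_id:
            new_id = len(name_to_id) + 1
            name_to_id[region.label] = new_id
            label_names[new_id] = region.label
        sigma[mask] = region.sigma
        md[mask] = region.md
        t2[mask] = region.t2_ms
        labels[mask] = name_to_id[region.label]

    vois = VOISet(labels=labels, label_names=label_names, spacing_mm=spec.spacing_mm)
    return (
        ConductivityMap(values=sigma, spacing_mm=spec.spacing_mm),
        MDMap(values=md, spacing_mm=spec.spacing_mm),
        t2,
        vois,
    )


def quadratic_phase(
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    sigma_s_per_m: float,
    larmor_hz: float,
) -> np.ndarray:
    """Closed-form phase for a homogeneous medium: ϕ = a(x²+y²), 4a = 2μ₀ωσ.

    Coordinates are metres from the in-plane grid centre; the same quadratic
    is used on every slice (2D solve convention).
    """
    a = rhs_constant(larmor_hz) * sigma_s_per_m / 4.0
    _, ny, nx = grid_shape
    hy, hx = spacing_mm[1] * 1e-3, spacing_mm[2] * 1e-3
    y = (np.arange(ny) - (ny - 1) / 2.0) * hy
    x = (np.arange(nx) - (nx - 1) / 2.0) * hx
    phi2d = a * (y[:, None] ** 2 + x[None, :] ** 2)
    return np.broadcast_to(phi2d, grid_shape).copy()


def _assemble_divergence_system(
    a2d: np.ndarray, hy: float, hx: float, rhs_val: float, boundary2d: np.ndarray
):
    """Sparse 5-point flux discretisation of ∇·(a∇ϕ) = rhs on one slice.

    Face coefficients are harmonic means (standard for discontinuous a).
    Edge voxels are Dirichlet from boundary2d.
    """
    ny, nx = a2d.shape
    interior = np.zeros((ny, nx), dtype=bool)
    interior[1:-1, 1:-1] = True
    idx = -np.ones((ny, nx), dtype=np.int64)
    idx[interior] = np.arange(interior.sum())
    n = interior.sum()

    def hmean(a, b):
        return 2.0 * a * b / (a + b)

    rows, cols, vals = [], [], []
    b = np.full(n, rhs_val, dtype=float)
    jj, ii = np.nonzero(interior)
    for dj, di, h in ((1, 0, hy), (-1, 0, hy), (0, 1, hx), (0, -1, hx)):
        nj, ni = jj + dj, ii + di
        aface = hmean(a2d[jj, ii], a2d[nj, ni]) / h**2
        rows.append(idx[jj, ii])
        cols.append(idx[jj, ii])
        vals.append(-aface)
        nbr_interior = interior[nj, ni]
        rows.append(idx[jj, ii][nbr_interior])
        cols.append(idx[nj, ni][nbr_interior])
        vals.append(aface[nbr_interior])
        # Dirichlet neighbours move to the RHS
        bmask = ~nbr_interior
        np.subtract.at(b, idx[jj, ii][bmask], aface[bmask] * boundary2d[nj, ni][bmask])
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, b, idx, interior


def forward_phase(
    sigma: ConductivityMap,
    larmor_hz: float | None = None,
    boundary: np.ndarray | None = None,
    b0_tesla: float = 9.4,
    rhs_scale: float = 1.0,
) -> PhaseMap:
    """Solve the forward model ∇·((1/σ)∇ϕ_tr) = rhs_scale·2μ₀ω per slice.

    ``boundary`` supplies Dirichlet ϕ on the full grid (only edge voxels are
    read); default is the homogeneous quadratic for the slice-median
    conductivity.  ``rhs_scale`` = 1 gives the transceive phase; 0 gives the
    source-free extension of the boundary values (how a receive coil's phase
    propagates through the conductive sample).  Returns an unwrapped PhaseMap
    satisfying the discrete equation to solver tolerance.
    """
    if larmor_hz is None:
        larmor_hz = larmor_frequency_hz(b0_tesla)
    vals = sigma.values
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("forward_phase requires strictly positive σ everywhere")
    if boundary is None:
        boundary = rhs_scale * quadratic_phase(
            vals.shape, sigma.spacing_mm, float(np.median(vals)), larmor_hz
        )
    boundary = np.asarray(boundary, dtype=float)
    if not np.all(np.isfinite(boundary)):
        raise ValueError("boundary phase values must be finite")

    rhs_val = rhs_scale * rhs_constant(larmor_hz)
    hy, hx = sigma.spacing_mm[1] * 1e-3, sigma.spacing_mm[2] * 1e-3
    phi = np.array(boundary, dtype=float, copy=True)
    for z in range(vals.shape[0]):
        a2d = 1.0 / vals[z]
        A, b, idx, interior = _assemble_divergence_system(
            a2d, hy, hx, rhs_val, boundary[z]
        )
        sol = spla.spsolve(A, b)
        res = np.linalg.norm(A @ sol - b)
        if not np.all(np.isfinite(sol)) or res > 1e-6 * max(
            1.0, np.linalg.norm(b)
        ):
            raise SolverError(
                f"forward solve failed on slice {z} (residual {res:.3e})",
                residual_norm=res,
            )
        phi[z][interior] = sol[idx[interior]]
    return PhaseMap(values=phi, spacing_mm=sigma.spacing_mm, wrapped=False)


def divergence_residual(
    phi: np.ndarray,
    sigma: np.ndarray,
    spacing_mm: tuple[float, float, float],
    larmor_hz: float,
) -> np.ndarray:
    """Apply the discrete divergence stencil to ϕ and subtract the RHS.

    Returns ∇·((1/σ)∇ϕ) − 2μ₀ω per interior voxel (NaN at edges); used as the
    independent residual oracle on forward solutions.
    """
    hy, hx = spacing_mm[1] * 1e-3, spacing_mm[2] * 1e-3
    out = np.full(phi.shape, np.nan)
    a = 1.0 / sigma

    def hmean(p, q):
        return 2.0 * p * q / (p + q)

    for z in range(phi.shape[0]):
        p, av = phi[z], a[z]
        flux = np.zeros_like(p)
        fN = hmean(av[1:-1, 1:-1], av[2:, 1:-1]) * (p[2:, 1:-1] - p[1:-1, 1:-1]) / hy**2
        fS = hmean(av[1:-1, 1:-1], av[:-2, 1:-1]) * (p[:-2, 1:-1] - p[1:-1, 1:-1]) / hy**2
        fE = hmean(av[1:-1, 1:-1], av[1:-1, 2:]) * (p[1:-1, 2:] - p[1:-1, 1:-1]) / hx**2
        fW = hmean(av[1:-1, 1:-1], av[1:-1, :-2]) * (p[1:-1, :-2] - p[1:-1, 1:-1]) / hx**2
        flux[1:-1, 1:-1] = fN + fS + fE + fW
        out[z, 1:-1, 1:-1] = flux[1:-1, 1:-1] - rhs_constant(larmor_hz)
    return out


def coil_profiles(
    grid_shape: tuple[int, int, int], n_channels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth per-channel sensitivity magnitudes and phase offsets.

    Magnitudes are Gaussians centred at the in-plane image corners (a surface
    array looking at the sample from four sides); offsets are smooth
    harmonic quadratics (y²−x², xy and linear terms) with distinct
    per-channel coefficients — structure the referenceless combination step
    has to remove.  Harmonic offsets keep the phantom's transceive-phase
    model exact: whatever single-channel offset survives the referenceless
    combination is curvature-free and cannot alias into conductivity.
    Returns (S, psi), each (channel, z, y, x).
    """
    _, ny, nx = grid_shape
    yn = np.linspace(-1.0, 1.0, ny)[:, None]
    xn = np.linspace(-1.0, 1.0, nx)[None, :]
    # physical-aspect coordinates on the longer axis' scale, so that
    # (yp² − xp²) and yp·xp are harmonic in physical space
    aspect = nx / ny
    yp, xp = (yn, xn * aspect) if ny >= nx else (yn / aspect, xn)
    corners = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    mags, offs = [], []
    for k in range(n_channels):
        cy, cx = corners[k % 4]
        r2 = (yn - cy) ** 2 + (xn - cx) ** 2
        mag = 0.3 + np.exp(-r2 / 1.2)
        # ∇²ψ = 0 for each term; amplitudes give ~0.3 rad variation across
        # the FOV (large constant parts are harmless and realistic)
        psi = (
            0.7 * k
            + 0.15 * np.cos(0.9 * k + 1.0) * (yp**2 - xp**2)
            + 0.12 * np.sin(0.6 * k + 0.3) * (yp * xp)
            + 0.10 * np.cos(1.3 * k) * yp
            + 0.08 * np.sin(0.8 * k + 0.9) * xp
        )
        mags.append(np.broadcast_to(mag, grid_shape))
        offs.append(np.broadcast_to(psi, grid_shape))
    return np.stack(mags), np.stack(offs)


def simulate_acquisition(
    sigma: ConductivityMap,
    t2_map: np.ndarray,
    phase: PhaseMap,
    spec: PhantomSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    coil_fields: tuple[np.ndarray, np.ndarray] | None = None,
) -> MultiCoilEchoData:
    """Synthesise multi-coil multi-echo complex images from a phase map.

    Channel k, echo n:  M₀·exp(−TEₙ/T2)·S_k·exp(i(ϕ_tr+ψ_k)) + ε,
    ε complex Gaussian with per-component sd ``noise_sd``.  M₀ = 1.

    The per-channel offsets ψ_k are physical receive-phase fields: the
    harmonic boundary traces from :func:`coil_profiles` extended into the
    interior by the source-free conductivity equation, so each channel's
    total phase ϕ_tr+ψ_k satisfies the full transceive model exactly (the
    receive field contributes its half of the 2μ₀ω source through ϕ_tr's
    own construction).  ``coil_fields`` overrides (S, ψ) for experiments.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t2_map = np.asarray(t2_map, dtype=float)
    if t2_map.shape != phase.shape or sigma.shape != phase.shape:
        raise ValueError("sigma, t2 and phase must share the grid")
    if np.any(t2_map[sigma.mask] <= 0):
        raise ValueError("t2 must be > 0 everywhere in the mask")

    te = spec.te_ms
    if coil_fields is not None:
        S, psi = coil_fields
        S = np.asarray(S, dtype=float)
        psi = np.asarray(psi, dtype=float)
    else:
        S, trace = coil_profiles(phase.shape, spec.coil_count)
        psi = np.stack(
            [
                forward_phase(
                    sigma,
                    larmor_hz=spec.larmor_hz,
                    boundary=trace[k],
                    rhs_scale=0.0,
                ).values
                for k in range(spec.coil_count)
            ]
        )
    decay = np.exp(-te[:, None, None, None] / t2_map[None])  # (echo, z, y, x)
    phasor = np.exp(1j * (phase.values[None] + psi))  # (channel, z, y, x)
    data = S[:, None] * decay[None] * phasor[:, None]

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        noise = noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        data = data + noise
    return MultiCoilEchoData(
        complex_values=data,
        te_ms=te,
        spacing_mm=phase.spacing_mm,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_dwi(
    md_map: MDMap,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0_map: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    tensor_field: np.ndarray | None = None,
) -> DWIStack:
    """Synthesise a DWI stack; isotropic mono-exponential by default.

    Noiseless signal is S₀·exp(−b·MD) with b in s/mm² and MD in µm²/ms
    (b·MD/1000 dimensionless).  If ``tensor_field`` (z,y,x,3,3) is given the
    exponent is −b·gᵀDg instead.  Noise is added on the complex channels and
    the magnitude taken (Rician).
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if not np.any(bvals == 0):
        raise ValueError("a b=0 volume is required")
    if np.any(md_map.values[md_map.mask] < 0):
        raise ValueError("md must be >= 0")
    shape = md_map.shape
    s0 = np.ones(shape) if s0_map is None else np.asarray(s0_map, dtype=float)

    if tensor_field is None:
        exponent = bvals[:, None, None, None] / 1000.0 * md_map.values[None]
    else:
        # gᵀDg per volume, then b·(gᵀDg)/1000
        gdg = np.einsum("vi,zyxij,vj->vzyx", bvecs, tensor_field, bvecs)
        exponent = bvals[:, None, None, None] / 1000.0 * gdg
    signal = s0[None] * np.exp(-exponent)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        re = signal + noise_sd * rng.standard_normal(signal.shape)
        im = noise_sd * rng.standard_normal(signal.shape)
        signal = np.hypot(re, im)
    return DWIStack(
        signal=signal,
        bvals=bvals,
        bvecs=bvecs,
        spacing_mm=md_map.spacing_mm,
        seed=seed,
    )


def day_schedule_spec(day: int, tumor_sigma_growth: float = 0.04) -> PhantomSpec:
    """Phantom for a longitudinal time point.

    Day 8 lacks the necrotic core (not evident early); tumor-region
    conductivity grows linearly with day at ``tumor_sigma_growth`` S/m/day
    relative to day 11 defaults, mirroring tumor progression.
    """
    delta = (day - 11) * tumor_sigma_growth
    overrides = {
        name: RAT_BRAIN_TISSUES[name][0] + delta
        for name in ("tumor_rim", "viable_tumor", "tumor_core")
    }
    return default_rat_brain_spec(include_core=day > 8, sigma_overrides=overrides)
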