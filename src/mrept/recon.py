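"""Conductivity reconstruction from the optimized transceive phase.

Two estimators of the high-frequency conductivity σ_H at the Larmor
frequency ω = 2πf:

* phase-based: the piecewise-constant approximation σ = ∇²ϕ_tr / (2μ₀ω),
  a direct voxelwise formula — fast, but biased wherever σ varies;
* convection–reaction (cr-MREPT): solve for u = 1/σ_H the stabilized PDE

      −c ∇²u + ∇ϕ_tr·∇u + (∇²ϕ_tr) u = 2 μ₀ ω ,

  where c is an artificial diffusion coefficient that suppresses the
  oscillations the pure convection–reaction problem develops.  The equation
  follows from expanding ∇·((1/σ)∇ϕ) = 2μ₀ω, so for exact data and c = 0 it
  is consistent with the forward model.

The transceive-phase convention keeps the factor 2 on the right-hand side
(no division of ϕ_tr by two anywhere).

Reconstruction is per slice (2D five-point stencils): slice thickness and
in-plane resolution are comparable and the acquisition is multi-slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    distance_transform_edt,
    median_filter,
)
from scipy.signal import savgol_filter

from .constants import MU0, rhs_constant
from .grids import ConductivityMap, PhaseMap, VOISet
from .phantom import SolverError

#: σ outside this range (S/m) is unphysical for tissue and gets masked.
SIGMA_PHYSICAL_RANGE = (0.0, 10.0)


@dataclass
class ReconConfig:
    """Configuration of the conductivity reconstruction.

    c_mode "auto" sets c = ½·h·max|∇ϕ_tr| (h the largest in-plane voxel
    spacing), capping the mesh Péclet number near 1; "local" uses the
    voxelwise c = ½·h·|∇ϕ_tr|, which stabilises convection-dominated spots
    without blurring regions where the phase is flat; "fixed" uses c_value.
    boundary_mode "phase_based" derives Dirichlet values for u = 1/σ from a
    median-filtered phase-based estimate on the domain's boundary ring.
    """

    larmor_hz: float
    mu0: float = MU0
    c_mode: str = "auto"
    c_value: float = 0.0
    laplacian_kernel: str = "central"
    savgol_radius_vox: int = 2
    boundary_mode: str = "phase_based"
    erosion_vox: int = 0
    peclet_upwind_threshold: float = 2.0
    c_local_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.larmor_hz <= 0:
            raise ValueError("larmor_hz must be > 0")
        if self.c_mode not in ("auto", "local", "fixed"):
            raise ValueError(f"unknown c_mode {self.c_mode!r}")
        if self.c_value < 0:
            raise ValueError("c_value must be >= 0")
        if self.laplacian_kernel not in ("central", "savgol"):
            raise ValueError(f"unknown laplacian_kernel {self.laplacian_kernel!r}")
        if self.savgol_radius_vox < 1:
            raise ValueError("savgol_radius_vox must be >= 1")
        if self.boundary_mode not in ("phase_based", "provided"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class ReconResult:
    """Output of cr_mrept_solve: σ map, its reciprocal u, and solver stats."""

    sigma: ConductivityMap
    u: np.ndarray
    residual_norm: float
    solver_iterations: int
    config_echo: ReconConfig
    c_used: float = 0.0
    n_nonphysical: int = 0


def spatial_derivatives(
    phase: PhaseMap, cfg: ReconConfig
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane gradient (rad/m) and Laplacian (rad/m²) of the phase.

    Returns (grad, lap); grad has shape (3, z, y, x) with the slice-normal
    component zero (per-slice reconstruction).  Voxels where the kernel
    does not fit (the edge ring) are NaN.
    """
    if phase.wrapped:
        raise ValueError("derivatives require an unwrapped phase map")
    phi = phase.values
    hy, hx = phase.spacing_mm[1] * 1e-3, phase.spacing_mm[2] * 1e-3
    r = 1 if cfg.laplacian_kernel == "central" else cfg.savgol_radius_vox
    if phi.shape[1] <= 2 * r or phi.shape[2] <= 2 * r:
        raise ValueError(
            f"grid {phi.shape[1:]} thinner than the derivative kernel (radius {r})"
        )

    grad = np.zeros((3,) + phi.shape)
    lap = np.zeros(phi.shape)
    if cfg.laplacian_kernel == "central":
        gy, gx = np.gradient(phi, hy, hx, axis=(1, 2))
        grad[1], grad[2] = gy, gx
        lap = (
            (np.roll(phi, -1, 1) - 2 * phi + np.roll(phi, 1, 1)) / hy**2
            + (np.roll(phi, -1, 2) - 2 * phi + np.roll(phi, 1, 2)) / hx**2
        )
    else:
        win = 2 * cfg.savgol_radius_vox + 1
        filled = phi
        if not np.all(np.isfinite(phi)):
            # SG fits cannot digest NaN; fill from the nearest valid voxel
            # and re-invalidate afterwards
            filled = phi.copy()
            for z in range(phi.shape[0]):
                bad = ~np.isfinite(phi[z])
                if bad.all():
                    filled[z] = 0.0
                elif bad.any():
                    ind = distance_transform_edt(
                        bad, return_distances=False, return_indices=True
                    )
                    filled[z] = phi[z][tuple(ind)]
        grad[1] = savgol_filter(filled, win, 2, deriv=1, delta=hy, axis=1, mode="interp")
        grad[2] = savgol_filter(filled, win, 2, deriv=1, delta=hx, axis=2, mode="interp")
        lap = savgol_filter(
            filled, win, 2, deriv=2, delta=hy, axis=1, mode="interp"
        ) + savgol_filter(filled, win, 2, deriv=2, delta=hx, axis=2, mode="interp")

    invalid = np.zeros(phi.shape, dtype=bool)
    invalid[:, :r, :] = invalid[:, -r:, :] = True
    invalid[:, :, :r] = invalid[:, :, -r:] = True
    # a kernel touching any off-mask voxel is contaminated
    bad = ~phase.mask
    if bad.any():
        for z in range(phi.shape[0]):
            invalid[z] |= binary_dilation(bad[z], iterations=r)
    grad[:, invalid] = np.nan
    lap[invalid] = np.nan
    return grad, lap


def phase_based_sigma(phase: PhaseMap, cfg: ReconConfig) -> ConductivityMap:
    """Direct phase-based estimate σ = ∇²ϕ_tr / (2μ₀ω).

    Exact for homogeneous media; non-positive or non-finite values (σ must be
    physically positive) are masked invalid, never clipped.
    """
    _, lap = spatial_derivatives(phase, cfg)
    sigma = lap / rhs_constant(cfg.larmor_hz)
    valid = np.isfinite(sigma) & (sigma > SIGMA_PHYSICAL_RANGE[0]) & (
        sigma < SIGMA_PHYSICAL_RANGE[1]
    )
    vals = np.where(valid, sigma, np.nan)
    return ConductivityMap(values=vals, spacing_mm=phase.spacing_mm, mask=valid)


def _auto_c(grad: np.ndarray, spacing_m: tuple[float, float]) -> float:
    h = max(spacing_m)
    gmax = np.nanmax(np.hypot(grad[1], grad[2]))
    return 0.5 * h * float(gmax)


def _assemble_cr_slice(
    gy: np.ndarray,
    gx: np.ndarray,
    lap_phi: np.ndarray,
    c,
    hy: float,
    hx: float,
    rhs_val: float,
    boundary_u: np.ndarray,
    unknown: np.ndarray,
    pe_threshold: float,
):
    """Sparse assembly of −c∇²u + ∇ϕ·∇u + (∇²ϕ)u = rhs on one slice.

    ``c`` is a scalar or a per-voxel (ny, nx) array.  Central-difference
    convection, switching to first-order upwind where the local per-axis
    Péclet |g|·h/c exceeds ``pe_threshold`` (always upwind at c = 0).
    ``unknown`` marks solved voxels; every neighbour of an unknown that is
    not itself unknown reads its Dirichlet value from boundary_u.
    """
    ny, nx = gy.shape
    idx = -np.ones((ny, nx), dtype=np.int64)
    idx[unknown] = np.arange(unknown.sum())
    n = unknown.sum()
    jj, ii = np.nonzero(unknown)

    diag = np.full(n, 0.0)
    b = np.full(n, rhs_val, dtype=float)
    rows, cols, vals = [], [], []

    def add(coef, nj, ni, sel):
        """Add coef·u(nj,ni) for selected unknowns (Dirichlet → RHS)."""
        inside = idx[nj[sel], ni[sel]] >= 0
        s_in = np.nonzero(sel)[0][inside]
        s_out = np.nonzero(sel)[0][~inside]
        rows.append(idx[jj[s_in], ii[s_in]])
        cols.append(idx[nj[s_in], ni[s_in]])
        vals.append(coef[s_in])
        np.subtract.at(b, idx[jj[s_out], ii[s_out]], coef[s_out] * boundary_u[nj[s_out], ni[s_out]])

    all_sel = np.ones(n, dtype=bool)
    cv = (np.broadcast_to(np.asarray(c, dtype=float), (ny, nx)))[jj, ii]

    # reaction + diffusion diagonal
    diag += lap_phi[jj, ii]
    active = cv > 0
    if active.any():
        diag += 2.0 * cv / hy**2 + 2.0 * cv / hx**2
        add(-cv / hy**2, jj + 1, ii, active)
        add(-cv / hy**2, jj - 1, ii, active)
        add(-cv / hx**2, jj, ii + 1, active)
        add(-cv / hx**2, jj, ii - 1, active)

    # convection, per axis
    for g, h, dj, di in ((gy[jj, ii], hy, 1, 0), (gx[jj, ii], hx, 0, 1)):
        with np.errstate(divide="ignore"):
            pe = np.where(cv > 0, np.abs(g) * h / np.where(cv > 0, cv, 1.0), np.inf)
        upwind = pe > pe_threshold
        central = ~upwind
        if central.any():
            add(g / (2 * h), jj + dj, ii + di, central)
            add(-g / (2 * h), jj - dj, ii - di, central)
        if upwind.any():
            pos = upwind & (g > 0)
            neg = upwind & (g < 0)
            # g>0: g·(u_p − u_upstream)/h ; g<0: g·(u_downstream − u_p)/h
            np.add.at(diag, np.nonzero(pos)[0], g[pos] / h)
            add(-g / h, jj - dj, ii - di, pos)
            np.subtract.at(diag, np.nonzero(neg)[0], g[neg] / h)
            add(g / h, jj + dj, ii + di, neg)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, b, idx


def _stencil_residual_slice(
    gy, gx, lap_phi, c, hy, hx, rhs_val, uu, unknown, thr
) -> float:
    """Sum of squared residuals of the discrete equation at the unknowns.

    This is the definition of the solver's reported residual: the stencil
    (diffusion + convection with the Péclet-based upwind switch + reaction)
    applied to the solution with Dirichlet values in place.
    """
    cv = np.broadcast_to(np.asarray(c, dtype=float), uu.shape)
    u0 = uu
    uSp, uSm = np.roll(uu, -1, 0), np.roll(uu, 1, 0)
    uEp, uEm = np.roll(uu, -1, 1), np.roll(uu, 1, 1)
    diff = -cv * (
        (uSp + uSm - 2 * u0) / hy**2 + (uEp + uEm - 2 * u0) / hx**2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pe_y = np.where(cv > 0, np.abs(gy) * hy / np.where(cv > 0, cv, 1.0), np.inf)
        pe_x = np.where(cv > 0, np.abs(gx) * hx / np.where(cv > 0, cv, 1.0), np.inf)
    conv_y = np.where(
        pe_y > thr,
        np.where(gy > 0, gy * ((u0 - uSm) / hy), gy * ((uSp - u0) / hy)),
        gy * (uSp - uSm) / (2 * hy),
    )
    conv_x = np.where(
        pe_x > thr,
        np.where(gx > 0, gx * ((u0 - uEm) / hx), gx * ((uEp - u0) / hx)),
        gx * (uEp - uEm) / (2 * hx),
    )
    r = diff + conv_y + conv_x + lap_phi * u0 - rhs_val
    return float(np.sum(r[unknown] ** 2))


def cr_mrept_solve(
    phase: PhaseMap,
    cfg: ReconConfig,
    boundary_u: np.ndarray | float | None = None,
    rhs_override: float | None = None,
) -> ReconResult:
    """Solve the stabilized convection–reaction equation for u = 1/σ_H.

    Per slice: derivatives of ϕ_tr, artificial diffusion c (auto or fixed),
    sparse direct solve with Dirichlet boundary on the outermost ring of the
    derivative-valid domain.  Boundary u comes from a 3×3-median-filtered
    phase-based estimate unless ``boundary_u`` is given (scalar or full grid).
    Non-physical u ≤ 0 voxels are masked with a warning, never clipped.
    """
    grad, lap = spatial_derivatives(phase, cfg)
    hy, hx = phase.spacing_mm[1] * 1e-3, phase.spacing_mm[2] * 1e-3
    rhs_val = rhs_constant(cfg.larmor_hz) if rhs_override is None else rhs_override

    if cfg.c_mode == "auto":
        c_field = _auto_c(grad, (hy, hx))
        c_report = float(c_field)
    elif cfg.c_mode == "local":
        h = max(hy, hx)
        c_field = cfg.c_local_alpha * h * np.nan_to_num(np.hypot(grad[1], grad[2]))
        c_report = float(np.nanmax(c_field))
    else:
        c_field = cfg.c_value
        c_report = float(cfg.c_value)

    if boundary_u is None and cfg.boundary_mode == "provided":
        raise ValueError("boundary_mode 'provided' requires boundary_u")
    if boundary_u is None:
        sigma_pb = phase_based_sigma(phase, cfg)
        filt = np.empty_like(sigma_pb.values)
        for z in range(filt.shape[0]):
            filled = sigma_pb.values[z]
            if not sigma_pb.mask[z].all():
                if not sigma_pb.mask[z].any():
                    filled = np.full_like(filled, 0.5)
                else:
                    # nearest-valid fill so Dirichlet values never come from
                    # masked (edge/non-physical) estimates
                    ind = distance_transform_edt(
                        ~sigma_pb.mask[z], return_distances=False, return_indices=True
                    )
                    filled = sigma_pb.values[z][tuple(ind)]
            filt[z] = median_filter(filled, size=3, mode="nearest")
        filt = np.clip(filt, 0.05, SIGMA_PHYSICAL_RANGE[1])
        bu = 1.0 / filt
    elif np.isscalar(boundary_u):
        bu = np.full(phase.shape, float(boundary_u))
    else:
        bu = np.asarray(boundary_u, dtype=float)
        if bu.shape != phase.shape:
            raise ValueError("boundary_u grid must match the phase grid")

    nz, ny, nx = phase.shape
    r = 1 if cfg.laplacian_kernel == "central" else cfg.savgol_radius_vox
    # derivative-valid domain is the r-inset; unknowns are its interior,
    # its outermost ring is the Dirichlet layer
    valid = np.zeros((ny, nx), dtype=bool)
    valid[r:-r, r:-r] = True
    unknown2d = np.zeros((ny, nx), dtype=bool)
    unknown2d[r + 1 : -r - 1, r + 1 : -r - 1] = True

    u = np.full(phase.shape, np.nan)
    total_res = 0.0
    for z in range(nz):
        finite = np.isfinite(lap[z]) & np.isfinite(grad[1][z]) & np.isfinite(grad[2][z])
        unk = unknown2d & finite
        if not unk.any():
            continue
        c_slice = c_field[z] if isinstance(c_field, np.ndarray) else c_field
        A, b, idx = _assemble_cr_slice(
            grad[1][z], grad[2][z], lap[z], c_slice, hy, hx, rhs_val, bu[z], unk,
            cfg.peclet_upwind_threshold,
        )
        sol = spla.spsolve(A, b)
        if not np.all(np.isfinite(sol)):
            raise SolverError(
                f"cr-MREPT solve diverged on slice {z}",
                residual_norm=float("inf"),
            )
        uu = bu[z].copy()
        uu[unk] = sol[idx[unk]]
        total_res += _stencil_residual_slice(
            grad[1][z], grad[2][z], lap[z], c_slice, hy, hx, rhs_val, uu, unk,
            cfg.peclet_upwind_threshold,
        )
        u[z][unk] = sol[idx[unk]]
        ring = valid & ~unknown2d
        u[z][ring] = bu[z][ring]
    residual_norm = float(np.sqrt(total_res))

    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_vals = 1.0 / u
    physical = (
        np.isfinite(sigma_vals)
        & (sigma_vals > SIGMA_PHYSICAL_RANGE[0])
        & (sigma_vals < SIGMA_PHYSICAL_RANGE[1])
    )
    n_bad = int(np.isfinite(u).sum() - physical.sum())
    if n_bad:
        warnings.warn(
            f"masked {n_bad} non-physical voxel(s) (u <= 0 or sigma out of range)",
            stacklevel=2,
        )
    sigma_map = ConductivityMap(
        values=np.where(physical, sigma_vals, np.nan),
        spacing_mm=phase.spacing_mm,
        mask=physical,
    )
    return ReconResult(
        sigma=sigma_map,
        u=u,
        residual_norm=residual_norm,
        solver_iterations=1,  # sparse direct solve
        config_echo=cfg,
        c_used=c_report,
        n_nonphysical=n_bad,
    )


def erode_and_mask(
    result: ReconResult, vois: VOISet, erosion_vox: int
) -> ReconResult:
    """Mask voxels within ``erosion_vox`` of any VOI boundary.

    Counters the boundary blurring of Laplacian-based reconstruction: each
    label's mask (background included) is eroded in-plane and only the eroded
    cores stay valid.  A region fully consumed by the erosion triggers a
    warning.
    """
    if erosion_vox < 0:
        raise ValueError("erosion_vox must be >= 0")
    if erosion_vox == 0:
        return result
    labels = vois.labels
    keep = np.zeros(labels.shape, dtype=bool)
    for lab in np.unique(labels):
        lab_mask = labels == lab
        eroded = np.zeros_like(lab_mask)
        for z in range(labels.shape[0]):
            eroded[z] = binary_erosion(lab_mask[z], iterations=erosion_vox)
        if lab != 0 and lab_mask.any() and not eroded.any():
            warnings.warn(
                f"region {vois.label_names.get(int(lab), lab)!r} fully masked "
                f"by erosion of {erosion_vox} voxel(s)",
                stacklevel=2,
            )
        keep |= eroded
    new_mask = result.sigma.mask & keep
    sigma = ConductivityMap(
        values=np.where(new_mask, result.sigma.values, np.nan),
        spacing_mm=result.sigma.spacing_mm,
        mask=new_mask,
    )
    return replace(result, sigma=sigma)
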