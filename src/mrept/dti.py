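"""Diffusion-tensor fitting and mean-diffusivity maps.

The tensor is estimated voxelwise by log-linear least squares:

    ln S(b, g) = ln S₀ − b gᵀ D g

with the six unique tensor elements and ln S₀ as unknowns.  Both shells
(b = 1000 and 2000 s/mm²) enter one mono-exponential fit.  Mean diffusivity
is MD = (λ1+λ2+λ3)/3 = trace(D)/3 in µm²/ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DWIStack, MDMap

# design-matrix column order for the symmetric tensor
_TENSOR_COLS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class TensorMap:
    """Fitted diffusion tensor field.

    tensor: (z, y, x, 3, 3) symmetric, µm²/ms; s0: non-DW signal estimate;
    fit_residual: per-voxel RMS residual of ln-signal; negative_eigen marks
    voxels where the linear fit produced a negative eigenvalue (permitted,
    flagged).
    """

    tensor: np.ndarray
    s0: np.ndarray
    fit_residual: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    @property
    def negative_eigen(self) -> np.ndarray:
        evals = np.linalg.eigvalsh(self.tensor)
        return self.mask & (evals.min(axis=-1) < 0)

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues per voxel, ascending, shape (z, y, x, 3)."""
        return np.linalg.eigvalsh(self.tensor)


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, −b·gx², −b·gy², −b·gz², −2b·gxgy, −2b·gxgz, −2b·gygz].

    b is rescaled from s/mm² to ms/µm² (÷1000) so the tensor comes out in
    µm²/ms.  Column 0 carries ln S₀.
    """
    b = np.asarray(bvals, dtype=float) / 1000.0
    g = np.asarray(bvecs, dtype=float)
    X = np.empty((len(b), 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return X


def fit_tensor(dwi: DWIStack) -> TensorMap:
    """Log-linear least-squares tensor fit over all voxels at once.

    Requires ≥6 non-collinear directions at b > 0 plus a b = 0 volume.
    Voxels with any non-positive signal are excluded from the fit (masked).
    Raises on a rank-deficient design (e.g. all b = 0, or coplanar
    directions) with a diagnostic.
    """
    X = design_matrix(dwi.bvals, dwi.bvecs)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise ValueError(
            f"rank-deficient DTI design (rank {rank} < 7): "
            f"{int((dwi.bvals > 0).sum())} DW volumes; directions must span "
            "6 independent tensor components"
        )

    sig = dwi.signal
    shape = sig.shape[1:]
    flat = sig.reshape(sig.shape[0], -1)
    good = np.all(flat > 0, axis=0) & np.all(np.isfinite(flat), axis=0)

    coeffs = np.zeros((7, flat.shape[1]))
    resid = np.full(flat.shape[1], np.nan)
    if good.any():
        y = np.log(flat[:, good])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coeffs[:, good] = beta
        r = y - X @ beta
        resid[good] = np.sqrt(np.mean(r**2, axis=0))

    dxx, dyy, dzz, dxy, dxz, dyz = coeffs[1:7]
    tensor = np.zeros(shape + (3, 3))
    flatT = tensor.reshape(-1, 3, 3)
    flatT[:, 0, 0] = dxx
    flatT[:, 1, 1] = dyy
    flatT[:, 2, 2] = dzz
    flatT[:, 0, 1] = flatT[:, 1, 0] = dxy
    flatT[:, 0, 2] = flatT[:, 2, 0] = dxz
    flatT[:, 1, 2] = flatT[:, 2, 1] = dyz

    return TensorMap(
        tensor=tensor,
        s0=np.exp(coeffs[0]).reshape(shape),
        fit_residual=resid.reshape(shape),
        mask=good.reshape(shape),
        spacing_mm=dwi.spacing_mm,
    )


def mean_diffusivity(tensors: TensorMap) -> MDMap:
    """MD = trace(D)/3 per voxel (equals the eigenvalue mean identically)."""
    md = np.trace(tensors.tensor, axis1=-2, axis2=-1) / 3.0
    vals = np.where(tensors.mask, md, np.nan)
    return MDMap(values=vals, spacing_mm=tensors.spacing_mm, mask=tensors.mask.copy())


def repulsion_directions(n: int = 15, seed: int = 7, n_iter: int = 2000) -> np.ndarray:
    """n unit vectors spread by electrostatic repulsion (antipodally symmetric).

    Deterministic for a fixed seed: random init on the sphere, then gradient
    descent on the Coulomb energy of the 2n antipodal point set.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sgn in (1.0, -1.0):
            d = v[:, None, :] - sgn * v[None, :, :]
            r2 = (d**2).sum(-1)
            np.fill_diagonal(r2, np.inf)
            if sgn < 0:
                r2[r2 < 1e-12] = np.inf  # a vector vs its own antipode
            force += (d / (r2[..., None] ** 1.5 + 1e-12)).sum(axis=1)
        v = v + step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def default_btable(
    bvals_shell: tuple[float, ...] = (1000.0, 2000.0),
    n_directions: int = 15,
    n_b0: int = 1,
    seed: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """b-table of a multi-shell acquisition: n_b0 b=0 volumes plus each
    shell repeated over the repulsion direction set.  Returns (bvals, bvecs)."""
    dirs = repulsion_directions(n_directions, seed=seed)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in bvals_shell:
        bvals.extend([b] * n_directions)
        bvecs.extend(dirs)
    return np.asarray(bvals), np.asarray(bvecs)
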