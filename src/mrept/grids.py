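"""Voxel-grid containers shared across the pipeline.

Index order is (z, y, x), 0-based, voxel-centred.  Spacing is stored in mm.
Every map carries a boolean validity mask; invalid voxels hold NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Shape3 = tuple[int, int, int]
Spacing3 = tuple[float, float, float]


def _check_spacing(spacing_mm) -> Spacing3:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_mm must be 3 positive values, got {spacing_mm}")
    return spacing  # type: ignore[return-value]


@dataclass
class ConductivityMap:
    """High-frequency conductivity σ_H on a voxel grid, S/m.

    Serves both as ground truth (phantom) and as reconstruction output.
    σ must be positive wherever the mask is true; NaN only off-mask.
    """

    values: np.ndarray
    spacing_mm: Spacing3
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        on = self.values[self.mask]
        if on.size and (not np.all(np.isfinite(on)) or np.any(on <= 0)):
            raise ValueError("conductivity must be finite and > 0 on the mask")

    @property
    def shape(self) -> Shape3:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class PhaseMap:
    """Transceive B1 phase ϕ_tr in radians.

    ``wrapped`` marks whether values live in [−π, π).  After unwrapping, the
    integer wrap counts are retained in ``wrap_counts`` together with the
    original wrapped array in ``wrapped_base`` so that re-wrapping is exact:
    an unwrapped map differs from its wrapped origin by integer multiples of
    2π only, and those integers are part of the representation.
    """

    values: np.ndarray
    spacing_mm: Spacing3
    wrapped: bool = True
    mask: np.ndarray | None = None
    wrap_counts: np.ndarray | None = field(default=None, repr=False)
    wrapped_base: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.wrapped:
            on = self.values[self.mask]
            if on.size and (on.min() < -np.pi or on.max() >= np.pi):
                raise ValueError("wrapped phase must lie in [-pi, pi)")

    @property
    def shape(self) -> Shape3:
        return self.values.shape  # type: ignore[return-value]

    def rewrap(self) -> np.ndarray:
        """Return the wrapped representative congruent to this map.

        For a map produced by the unwrapper this is the stored wrapped input,
        bit-for-bit.  For any other map it is values wrapped into [−π, π).
        """
        if self.wrapped_base is not None:
            return self.wrapped_base.copy()
        return wrap_to_pi(self.values)


def wrap_to_pi(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values into [−π, π)."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class MultiCoilEchoData:
    """Complex multi-channel multi-echo images, indexed (channel, echo, z, y, x)."""

    complex_values: np.ndarray
    te_ms: np.ndarray
    spacing_mm: Spacing3
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.complex_values = np.asarray(self.complex_values, dtype=complex)
        if self.complex_values.ndim != 5:
            raise ValueError("complex_values must be (channel, echo, z, y, x)")
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.te_ms.ndim != 1 or self.te_ms.size != self.complex_values.shape[1]:
            raise ValueError("te_ms length must match the echo axis")
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("te_ms must be strictly increasing")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def n_channels(self) -> int:
        return self.complex_values.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.complex_values.shape[1]


@dataclass
class DWIStack:
    """Diffusion-weighted volumes with their b-table, indexed (volume, z, y, x)."""

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    spacing_mm: Spacing3
    seed: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be (volume, z, y, x)")
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        n = self.signal.shape[0]
        if self.bvals.shape != (n,):
            raise ValueError("bvals length must match the volume axis")
        if self.bvecs.shape != (n, 3):
            raise ValueError("bvecs must be (n_volumes, 3)")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 volume is required")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("bvecs must have unit norm where bval > 0")
        self.spacing_mm = _check_spacing(self.spacing_mm)


@dataclass
class MDMap:
    """Mean diffusivity (λ1+λ2+λ3)/3 on a voxel grid, µm²/ms."""

    values: np.ndarray
    spacing_mm: Spacing3
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> Shape3:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class VOISet:
    """Integer label masks for the segmented regions (0 = background)."""

    labels: np.ndarray
    label_names: dict[int, str]
    spacing_mm: Spacing3
    day: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        if self.labels.min() < 0:
            raise ValueError("label ids must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    def region_mask(self, name: str) -> np.ndarray:
        ids = [i for i, n in self.label_names.items() if n == name]
        if not ids:
            raise KeyError(f"no region named {name!r}")
        return np.isin(self.labels, ids)

    @property
    def names(self) -> list[str]:
        return [self.label_names[i] for i in sorted(self.label_names)]
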