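"""From raw multi-channel multi-echo complex data to one optimized phase map.

Three stages:

1. ``grpc_combine`` — two-step referenceless channel combination: estimate
   each channel's smooth phase offset against the strongest channel, subtract
   it, and form a magnitude²-weighted complex sum.  No body-coil reference is
   needed; the combined phase equals the true transceive phase up to the
   reference channel's own (smooth) offset, which is harmless because only
   spatial derivatives of the phase enter the reconstruction.
2. ``unwrap_phase`` — 2D/3D unwrapping with exact congruence: the output
   differs from the input by integer multiples of 2π only, and those integers
   are stored on the map so re-wrapping is bit-exact.
3. ``combine_echoes`` — SNR-optimal echo averaging with weights
   wₙ = Mₙ²/Σₖ Mₖ² (the magnitude² weighting that minimises phase-noise
   variance for complex Gaussian noise under T2 decay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .grids import MultiCoilEchoData, PhaseMap

TWO_PI = 2.0 * np.pi


@dataclass
class CombinedComplexImage:
    """Channel-combined complex images, indexed (echo, z, y, x)."""

    complex_values: np.ndarray
    te_ms: np.ndarray
    spacing_mm: tuple[float, float, float]
    reference_channel: int = 0
    smoothing_radius_vox: int = 3

    def __post_init__(self) -> None:
        self.complex_values = np.asarray(self.complex_values, dtype=complex)
        if self.complex_values.ndim != 4:
            raise ValueError("complex_values must be (echo, z, y, x)")
        self.te_ms = np.asarray(self.te_ms, dtype=float)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.complex_values)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.complex_values)


@dataclass
class EchoWeights:
    """Per-voxel echo-averaging weights; sum to 1 over the echo axis."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")


def _smooth_complex(field: np.ndarray, radius_vox: int) -> np.ndarray:
    """Low-pass a complex field slice-wise (wrap-safe phase smoothing)."""
    if radius_vox <= 0:
        return field
    out = np.empty_like(field)
    for z in range(field.shape[0]):
        out[z] = gaussian_filter(field[z].real, radius_vox) + 1j * gaussian_filter(
            field[z].imag, radius_vox
        )
    return out


def grpc_combine(
    raw: MultiCoilEchoData, smoothing_radius_vox: int = 3
) -> CombinedComplexImage:
    """Two-step referenceless phase combination across receive channels.

    Step 1: pick the reference channel with the highest mean magnitude and
    estimate every channel's offset map as the low-pass-filtered phase of
    channel × conj(reference), accumulated over echoes for SNR.
    Step 2: subtract the offsets and form the magnitude²-weighted complex sum
    per voxel and echo.  All-zero channels are excluded with a warning; a
    single channel passes through unchanged.
    """
    data = raw.complex_values
    if not np.all(np.isfinite(data.view(float))):
        raise ValueError("raw complex data must be finite")

    live = [k for k in range(raw.n_channels) if np.any(np.abs(data[k]) > 0)]
    if not live:
        raise ValueError("all channels are zero")
    if len(live) < raw.n_channels:
        warnings.warn(
            f"excluding {raw.n_channels - len(live)} all-zero channel(s)",
            stacklevel=2,
        )
    data = data[live]

    if len(live) == 1:
        return CombinedComplexImage(
            complex_values=data[0],
            te_ms=raw.te_ms,
            spacing_mm=raw.spacing_mm,
            reference_channel=live[0],
            smoothing_radius_vox=smoothing_radius_vox,
        )

    mean_mag = np.abs(data).mean(axis=(1, 2, 3, 4))
    ref = int(np.argmax(mean_mag))

    combined = np.zeros(data.shape[1:], dtype=complex)
    for k in range(data.shape[0]):
        # offset estimate from the echo-summed cross product (phase is TE-
        # independent for spin echoes, so echoes only add SNR here)
        cross = (data[k] * np.conj(data[ref])).sum(axis=0)
        offset = np.angle(_smooth_complex(cross[None], smoothing_radius_vox)[0])
        corrected = data[k] * np.exp(-1j * offset)[None]
        combined += np.abs(corrected) * corrected

    return CombinedComplexImage(
        complex_values=combined,
        te_ms=raw.te_ms,
        spacing_mm=raw.spacing_mm,
        reference_channel=live[ref],
        smoothing_radius_vox=smoothing_radius_vox,
    )


def unwrap_phase(wrapped: PhaseMap) -> PhaseMap:
    """Unwrap a wrapped phase map with exact 2π-congruence.

    The continuous estimate comes from a quality-guided unwrapper; the result
    is then snapped to the congruent lattice: output = input + 2π·k with k an
    integer grid stored on the returned map, so ``rewrap()`` recovers the
    input bit-for-bit.  Disconnected mask components are unwrapped
    independently (each carries its own 2π·k constant ambiguity).
    """
    if not wrapped.wrapped:
        raise ValueError("unwrap_phase expects a wrapped PhaseMap")
    vals = wrapped.values
    mask = wrapped.mask
    counts = np.zeros(vals.shape, dtype=np.int64)

    # per-slice 2D unwrap (slices are independent acquisitions)
    for z in range(vals.shape[0]):
        m = mask[z]
        if not m.any():
            continue
        if m.all():
            cont = _skimage_unwrap(vals[z])
        else:
            # the unwrapper stalls on NaN payloads beneath the mask
            ma = np.ma.array(np.where(m, vals[z], 0.0), mask=~m)
            cont = np.asarray(_skimage_unwrap(ma).filled(0.0))
        counts[z][m] = np.rint((cont[m] - vals[z][m]) / TWO_PI).astype(np.int64)

    unwrapped_vals = np.where(mask, vals + TWO_PI * counts, np.nan)
    return PhaseMap(
        values=unwrapped_vals,
        spacing_mm=wrapped.spacing_mm,
        wrapped=False,
        mask=mask.copy(),
        wrap_counts=counts,
        wrapped_base=vals.copy(),
    )


def combine_echoes(
    combined: CombinedComplexImage, unwrap: bool = True
) -> tuple[PhaseMap, EchoWeights]:
    """Average per-echo phases with magnitude²-derived weights.

    Weights wₙ = Mₙ²/Σₖ Mₖ² per voxel; output phase Σₙ wₙ·ϕₙ.  Late echoes,
    attenuated by T2 decay, contribute proportionally less, which minimises
    the phase-noise variance of the average.  Per-echo phases are unwrapped
    slice-wise and aligned to the first echo modulo 2π before averaging (the
    transceive phase of a spin echo is TE-independent in expectation).
    Voxels with zero total magnitude are masked out.
    """
    mag = combined.magnitude
    m2 = mag**2
    total = m2.sum(axis=0)
    valid = total > 0
    weights = np.zeros_like(m2)
    weights[:, valid] = m2[:, valid] / total[valid]

    phases = np.empty_like(mag)
    for n in range(phases.shape[0]):
        pm = PhaseMap(
            values=np.angle(combined.complex_values[n]),
            spacing_mm=combined.spacing_mm,
            wrapped=True,
            mask=valid,
        )
        phases[n] = unwrap_phase(pm).values if unwrap else pm.values
    # align echo n to echo 0 by the median 2π offset (global constant per echo)
    for n in range(1, phases.shape[0]):
        diff = phases[n][valid] - phases[0][valid]
        k = np.rint(np.median(diff) / TWO_PI)
        phases[n] -= TWO_PI * k

    avg = np.where(valid, (weights * np.nan_to_num(phases)).sum(axis=0), np.nan)
    phase_map = PhaseMap(
        values=avg,
        spacing_mm=combined.spacing_mm,
        wrapped=False,
        mask=valid,
    )
    return phase_map, EchoWeights(weights=weights)


def combine_and_unwrap(
    raw: MultiCoilEchoData, smoothing_radius_vox: int = 3
) -> tuple[PhaseMap, EchoWeights]:
    """Convenience: GRPC combine, per-echo unwrap, and echo weighting."""
    combined = grpc_combine(raw, smoothing_radius_vox=smoothing_radius_vox)
    return combine_echoes(combined)
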