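"""NIfTI-1 and text-table I/O plus YAML config parsing.

Grids are stored internally as (z, y, x); NIfTI data order is (x, y, z), so
axes are transposed at this boundary.  Spacing is written into the header
zooms in mm.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import PhantomSpec, RegionSpec


class FormatError(ValueError):
    """Input file is not what its extension claims."""


def write_nifti(path, grid: np.ndarray, spacing_mm) -> None:
    """Write a (z, y, x) grid as NIfTI-1 with the given zooms (mm)."""
    data = np.asarray(grid)
    affine = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    img = nib.Nifti1Image(np.transpose(data), affine)
    zooms = (spacing_mm[2], spacing_mm[1], spacing_mm[0]) + (1.0,) * (data.ndim - 3)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Read a NIfTI-1 file: returns ((z,y,x) grid, spacing_mm, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        magic = b""
        if path.exists():
            with open(path, "rb") as fh:
                magic = fh.read(4)
        raise FormatError(
            f"{path} is not a readable NIfTI file (leading bytes {magic!r}): {exc}"
        ) from exc
    zooms = img.header.get_zooms()[:3]
    spacing_mm = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.transpose(data), spacing_mm, img.affine


def write_btable(prefix, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """FSL-style .bval/.bvec text files (3 rows of components)."""
    np.savetxt(str(prefix) + ".bval", bvals[None], fmt="%.1f")
    np.savetxt(str(prefix) + ".bvec", bvecs.T, fmt="%.8f")


def read_btable(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    """Build a PhantomSpec from a plain dict (YAML/JSON payload)."""
    regions = [
        RegionSpec(
            label=r["label"],
            center_vox=tuple(r["center_vox"]),
            semi_axes_vox=tuple(r["semi_axes_vox"]),
            sigma=float(r["sigma"]),
            md=float(r["md"]),
            t2_ms=float(r.get("t2_ms", 60.0)),
        )
        for r in d.get("regions", [])
    ]
    kwargs = {k: v for k, v in d.items() if k != "regions"}
    if "grid_shape" in kwargs:
        kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
    if "spacing_mm" in kwargs:
        kwargs["spacing_mm"] = tuple(kwargs["spacing_mm"])
    return PhantomSpec(regions=regions, **kwargs)


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        return phantom_spec_from_dict(yaml.safe_load(fh))
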