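"""NIfTI and FSL gradient-table input/output.

All volumes are written as NIfTI-1 with a diagonal affine built from the
isotropic voxel size; gradient tables use the FSL dialect (one
whitespace-separated row of b-values in ``.bval``, three rows of gradient
components in ``.bvec``).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


def save_nifti(path: str | os.PathLike, data: np.ndarray, voxel_size_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, os.fspath(path))


def load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Return (data, isotropic voxel size in mm)."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.get_fdata())
    zooms = img.header.get_zooms()[:3]
    return data, float(zooms[0])


def save_bvals_bvecs(prefix: str | os.PathLike, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """Write FSL-style ``<prefix>.bval`` / ``<prefix>.bvec`` files.

    ``bvecs`` is (n_volumes, 3) in memory and transposed to the FSL
    three-row layout on disk.
    """
    prefix = os.fspath(prefix)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values")
    with open(prefix + ".bval", "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in bvals) + "\n")
    with open(prefix + ".bvec", "w") as fh:
        for row in bvecs.T:
            fh.write(" ".join(f"{g:.8f}" for g in row) + "\n")


def load_bvals_bvecs(bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(os.fspath(bval_path), ndmin=1)
    bvecs = np.loadtxt(os.fspath(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous square table: FSL convention is three rows of components
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"gradient table mismatch: {bvals.size} b-values but bvec shape {bvecs.shape}"
        )
    return bvals, bvecs
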