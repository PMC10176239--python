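"""Per-voxel diffusion tensor fitting and derived scalar maps.

The fit solves the log-linearized Stejskal–Tanner model

    ln S_i = ln S0 - b_i * g_i^T D g_i

by weighted least squares with weights equal to the squared predicted
signal (the standard variance-stabilizing choice for log-transformed
magnitude data): a first ordinary-least-squares pass provides predicted
signals, a second pass reweights. S0 enters the design as the intercept
term, so it is estimated jointly rather than from b=0 averaging alone.

Eigenvalues are clamped to a small positive floor and the tensor is
reconstructed from the clamped eigensystem, so the diagonal elements
(Dxx, Dyy, Dzz — the quantities the ALPS index consumes) stay consistent
with the eigenvalue trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EIGENVALUE_FLOOR = 1e-6  # mm^2/s

#: Fixed laboratory-frame axis semantics shared by the simulator, the
#: tensor fit and the ALPS module: x = right–left, y = anterior–posterior,
#: z = inferior–superior.
AXIS_CONVENTION = ("right-left", "anterior-posterior", "inferior-superior")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with eigensystem and scalar maps.

    Attributes
    ----------
    tensors : (X, Y, Z, 3, 3) float array, mm^2/s
    mask : (X, Y, Z) bool — True where a tensor was fitted
    evals : (X, Y, Z, 3) eigenvalues, descending
    evecs : (X, Y, Z, 3, 3) eigenvectors as columns, matching ``evals``
    fa, md : (X, Y, Z) fractional anisotropy and mean diffusivity
    voxel_size_mm : isotropic voxel size
    n_clamped : number of voxels whose eigenvalues hit the positivity floor
    """

    tensors: np.ndarray
    mask: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    voxel_size_mm: float = 1.0
    s0: np.ndarray | None = None
    n_clamped: int = 0
    axis_convention: tuple = AXIS_CONVENTION

    @property
    def dxx(self) -> np.ndarray:
        return self.tensors[..., 0, 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.tensors[..., 1, 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.tensors[..., 2, 2]

    @property
    def v1(self) -> np.ndarray:
        """Principal eigenvector, (X, Y, Z, 3)."""
        return self.evecs[..., :, 0]

    @classmethod
    def from_tensors(
        cls,
        tensors: np.ndarray,
        mask: np.ndarray | None = None,
        voxel_size_mm: float = 1.0,
        clamp_floor: float = EIGENVALUE_FLOOR,
    ) -> "TensorField":
        """Build a TensorField from an array of symmetric tensors."""
        tensors = np.asarray(tensors, dtype=float)
        if mask is None:
            mask = np.ones(tensors.shape[:-2], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        evals, evecs, n_clamped = _eigensystem(tensors, mask, clamp_floor)
        out = np.zeros_like(tensors)
        # reconstruct from the clamped eigensystem so trace identities hold
        out[mask] = np.einsum(
            "nij,nj,nkj->nik", evecs[mask], evals[mask], evecs[mask]
        )
        fa = fractional_anisotropy(evals) * mask
        md = evals.mean(axis=-1) * mask
        return cls(
            tensors=out,
            mask=mask,
            evals=evals,
            evecs=evecs,
            fa=fa,
            md=md,
            voxel_size_mm=voxel_size_mm,
            n_clamped=n_clamped,
        )


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (last axis), 0 for all-zero tensors."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def _eigensystem(tensors, mask, clamp_floor):
    shp = tensors.shape[:-2]
    evals = np.zeros(shp + (3,))
    evecs = np.zeros(shp + (3, 3))
    evecs[..., :, :] = np.eye(3)
    if mask.any():
        w, v = np.linalg.eigh(tensors[mask])
        # eigh returns ascending; flip to descending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        clamped = (w < clamp_floor).any(axis=1)
        w = np.maximum(w, clamp_floor)
        evals[mask] = w
        evecs[mask] = v
        n_clamped = int(clamped.sum())
    else:
        n_clamped = 0
    return evals, evecs, n_clamped


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear design matrix, one row per volume.

    Columns: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz].
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def _tensor_from_coeffs(coef: np.ndarray) -> np.ndarray:
    """(..., 6) -> (..., 3, 3) symmetric tensors; order xx,yy,zz,xy,xz,yz."""
    out = np.empty(coef.shape[:-1] + (3, 3))
    out[..., 0, 0] = coef[..., 0]
    out[..., 1, 1] = coef[..., 1]
    out[..., 2, 2] = coef[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = coef[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = coef[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = coef[..., 5]
    return out


def fit_tensor(dwi, mask: np.ndarray | None = None, b_max: float | None = None) -> TensorField:
    """Weighted least-squares tensor fit of a :class:`~dtialps.synthdata.DWIVolume`.

    Parameters
    ----------
    dwi : DWIVolume
        4D signal with gradient table.
    mask : optional boolean volume restricting the fit.
    b_max : optional shell ceiling; volumes with b above it are dropped
        (b=0 volumes are always kept). By default all shells enter one fit.

    Raises
    ------
    ValueError
        If the gradient table is rank deficient (fewer than six
        non-collinear diffusion directions plus a baseline).

    Notes
    -----
    Non-positive signals are excluded per voxel; a voxel with fewer than
    seven usable measurements is flagged unfitted in ``mask`` rather than
    silently zeroed. The fit errors out only if no voxel can be fitted.
    """
    signal = np.asarray(dwi.signal, dtype=float)
    bvals = np.asarray(dwi.bvals, dtype=float)
    bvecs = np.asarray(dwi.bvecs, dtype=float)
    if signal.shape[-1] != bvals.size or bvecs.shape != (bvals.size, 3):
        raise ValueError("signal / bval / bvec volume counts disagree")

    keep = np.ones(bvals.size, dtype=bool)
    if b_max is not None:
        keep = (bvals <= b_max) | (bvals == 0)
    signal = signal[..., keep]
    bvals = bvals[keep]
    bvecs = bvecs[keep]

    X = design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        uniq = np.unique(np.round(np.abs(bvecs[bvals > 0]), 6), axis=0)
        raise ValueError(
            "rank-deficient gradient table: need >=6 non-collinear diffusion "
            f"directions plus a baseline, got {len(uniq)} distinct |direction|s "
            f"over {int((bvals > 0).sum())} diffusion volumes"
        )
    if mask is None:
        mask = np.ones(signal.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    S = signal[mask]  # (N, V)
    valid = S > 0
    n_valid = valid.sum(axis=1)
    fittable = n_valid >= 7
    if not fittable.any():
        raise ValueError("no voxel has >=7 positive signal measurements")

    logS = np.zeros_like(S)
    np.log(S, out=logS, where=valid)

    # unit-norm column scaling: the intercept and the b-weighted quadratic
    # columns differ by ~3 orders of magnitude, which costs precision in
    # the normal equations
    col_scale = np.linalg.norm(X, axis=0)
    Xs = X / col_scale

    def wls(weights):
        A = np.einsum("nv,vi,vj->nij", weights, Xs, Xs)
        rhs = np.einsum("nv,vi->ni", weights * logS, Xs)
        return np.einsum("nij,nj->ni", np.linalg.pinv(A), rhs) / col_scale

    beta = wls(valid.astype(float))
    pred = np.exp(np.clip(X @ beta.T, -700, 700)).T  # (N, V)
    pred = pred / pred.max(axis=1, keepdims=True)  # relative weights suffice
    beta = wls(valid * pred**2)

    coef = np.zeros((mask.sum(), 6))
    coef[fittable] = beta[fittable, 1:7]
    tensors = np.zeros(mask.shape + (3, 3))
    tensors[mask] = _tensor_from_coeffs(coef)

    fit_mask = np.zeros(mask.shape, dtype=bool)
    fit_mask[mask] = fittable

    tf = TensorField.from_tensors(tensors, fit_mask, voxel_size_mm=dwi.voxel_size_mm)
    s0 = np.zeros(mask.shape)
    s0_vals = np.zeros(mask.sum())
    s0_vals[fittable] = np.exp(beta[fittable, 0])
    s0[mask] = s0_vals
    tf.s0 = s0
    return tf


def direction_encoded_map(tf: TensorField) -> np.ndarray:
    """Direction-encoded (RGB-style) map: |v1| components scaled by FA.

    Returns an (X, Y, Z, 3) array; unfitted voxels are zero.
    """
    dec = np.abs(tf.v1) * tf.fa[..., None]
    return dec * tf.mask[..., None]
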