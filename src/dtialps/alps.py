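"""ROI placement on direction-encoded maps and the ALPS index.

The ALPS (diffusion "along the perivascular space") index compares
right–left diffusivity — the orientation of periventricular medullary
veins and their perivascular spaces — against diffusivity along the
dominant fiber axes of the surrounding tracts:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where each D is the ROI-mean diagonal tensor element, the projection ROI
sits in z-dominant fibers and the association ROI in y-dominant fibers,
bilaterally at the level of the lateral ventricle. The left and right
indices are averaged for analysis. An isotropic medium gives exactly 1.0;
perivascular diffusion raises Dxx only, pushing the index above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from dtialps.tensorfit import TensorField, direction_encoded_map

ROI_NAMES = ("proj_left", "proj_right", "assoc_left", "assoc_right")
DOMINANCE_THRESHOLD = 0.7  # |v1 component| required for auto placement
DEFAULT_ROI_SIZE_MM = 5.0


@dataclass
class ROISet:
    """The four ALPS ROIs as in-plane square masks on one axial slice."""

    masks: dict  # name -> (X, Y, Z) boolean
    slice_index: int
    roi_size_mm: float
    placement_mode: str  # "auto" | "manual"
    centers: dict  # name -> (x, y)

    def validate(self) -> None:
        total = np.zeros_like(next(iter(self.masks.values())), dtype=int)
        for name in ROI_NAMES:
            m = self.masks[name]
            if not m.any():
                raise ValueError(f"ROI {name} is empty")
            total += m.astype(int)
        if (total > 1).any():
            raise ValueError("ROIs must be disjoint")
        nx = total.shape[0]
        for side, cmp in (("left", lambda x: x < nx / 2), ("right", lambda x: x >= nx / 2)):
            for kind in ("proj", "assoc"):
                cx = self.centers[f"{kind}_{side}"][0]
                if not cmp(cx):
                    raise ValueError(f"{kind}_{side} ROI center x={cx} is on the wrong side of the midline")


@dataclass
class AlpsResult:
    """Per-hemisphere ROI-mean diffusivities and the ALPS indices.

    Diffusivities are mm^2/s; ``per_hemisphere`` maps 'left'/'right' to
    dicts with keys dxx_proj, dxx_assoc, dyy_proj, dzz_assoc, fa_proj,
    fa_assoc, md_proj, md_assoc.
    """

    per_hemisphere: dict
    alps_left: float
    alps_right: float

    @property
    def alps_mean(self) -> float:
        return 0.5 * (self.alps_left + self.alps_right)

    def to_dict(self) -> dict:
        out = {
            "alps_left": self.alps_left,
            "alps_right": self.alps_right,
            "alps_mean": self.alps_mean,
        }
        for side, vals in self.per_hemisphere.items():
            out.update({f"{k}_{side}": v for k, v in vals.items()})
        return out


def roi_size_voxels(roi_size_mm: float, voxel_size_mm: float) -> int:
    """In-plane ROI edge in voxels: nearest odd count to roi_size_mm."""
    exact = roi_size_mm / voxel_size_mm
    n = int(round(exact))
    if n % 2 == 0:
        n = n + 1 if exact >= n else n - 1
    return max(n, 1)


def _square_mask(shape, center_xy, slice_index, half):
    x, y = center_xy
    m = np.zeros(shape, dtype=bool)
    if not (half <= x < shape[0] - half and half <= y < shape[1] - half):
        raise ValueError(f"ROI centered at {center_xy} extends outside the grid")
    if not (0 <= slice_index < shape[2]):
        raise ValueError(f"slice {slice_index} outside the volume")
    m[x - half : x + half + 1, y - half : y + half + 1, slice_index] = True
    return m


def find_ventricle_slice(tf: TensorField, md_threshold: float = 1.0e-3) -> tuple[int, int]:
    """Locate the ventricle-proxy landmark from the tensor field.

    CSF-like voxels are those with high mean diffusivity and low FA.
    The MD threshold is deliberately below free-water diffusivity because
    Rician bias at high b-values pulls fitted CSF diffusivity down.
    Returns ``(alps_slice, superior_slice)``: the central axial level of
    the landmark and the slice one above its superior extent.
    """
    csf = (tf.md > md_threshold) & (tf.fa < 0.25) & tf.mask
    counts = csf.sum(axis=(0, 1))
    zs = np.nonzero(counts)[0]
    if zs.size == 0:
        raise ValueError(
            "no ventricle-proxy landmark found (no high-MD low-FA voxels); "
            "supply slice_index explicitly"
        )
    alps_slice = int(round(np.average(zs, weights=counts[zs])))
    return alps_slice, int(zs.max()) + 1


def place_rois(
    tf: TensorField,
    slice_index: int | None = None,
    centers: dict | None = None,
    roi_size_mm: float = DEFAULT_ROI_SIZE_MM,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> ROISet:
    """Place the four ALPS ROIs.

    Manual mode (``centers`` given, mapping ROI name to an (x, y) voxel
    coordinate) builds the squares exactly as specified. Auto mode
    searches each hemisphere at the chosen axial slice: the projection
    ROI centers on the candidate maximizing ``|v1_z| * FA`` and the
    association ROI on the one maximizing ``|v1_y| * FA``, among voxels
    whose principal-eigenvector component exceeds ``dominance_threshold``.
    Ties (exactly degenerate scores, as in ideal phantoms) are broken
    toward the centroid of the tied voxels so the ROI lands mid-block.

    Raises ``ValueError`` when no voxel passes the dominance threshold
    (e.g. isotropic data), advising manual placement.
    """
    shape = tf.mask.shape
    half = roi_size_voxels(roi_size_mm, tf.voxel_size_mm) // 2

    if slice_index is None:
        slice_index, _ = find_ventricle_slice(tf)

    if centers is not None:
        missing = set(ROI_NAMES) - set(centers)
        if missing:
            raise ValueError(f"manual placement missing ROI centers: {sorted(missing)}")
        masks = {
            name: _square_mask(shape, centers[name], slice_index, half) for name in ROI_NAMES
        }
        rois = ROISet(masks, slice_index, roi_size_mm, "manual", dict(centers))
        rois.validate()
        return rois

    dec = direction_encoded_map(tf)  # |v1| * FA per axis
    v1 = np.abs(tf.v1)
    nx = shape[0]
    k = 2 * half + 1
    found_centers = {}
    for side, xsel in (("left", np.arange(nx) < nx // 2), ("right", np.arange(nx) >= (nx + 1) // 2)):
        for kind, axis in (("proj", 2), ("assoc", 1)):
            score = dec[..., axis][:, :, slice_index].copy()
            eligible = (v1[..., axis][:, :, slice_index] > dominance_threshold) & tf.mask[:, :, slice_index]
            eligible &= xsel[:, None]
            # candidate centers are scored by the mean over the whole ROI
            # square, and every ROI voxel must itself pass the dominance
            # threshold — a single noise-favoured voxel at a tract edge
            # must not drag the ROI into surrounding tissue
            roi_score = uniform_filter(score * eligible, size=k, mode="constant")
            roi_elig = uniform_filter(eligible.astype(float), size=k, mode="constant")
            ok = roi_elig > 1.0 - 0.5 / (k * k)  # all k*k voxels eligible
            ok &= xsel[:, None]
            if not ok.any():
                raise ValueError(
                    f"no {k}x{k} ROI with |v1_{'xyz'[axis]}| > {dominance_threshold} at "
                    f"every voxel in the {side} hemisphere at slice {slice_index}; "
                    "use manual ROI placement (centers=...)"
                )
            roi_score[~ok] = -np.inf
            best = roi_score.max()
            cand = np.argwhere(roi_score >= best - 1e-12)
            centroid = cand.mean(axis=0)
            order = np.lexsort((cand[:, 1], cand[:, 0], ((cand - centroid) ** 2).sum(axis=1)))
            cx, cy = cand[order[0]]
            found_centers[f"{kind}_{side}"] = (int(cx), int(cy))
    masks = {
        name: _square_mask(shape, found_centers[name], slice_index, half) for name in ROI_NAMES
    }
    rois = ROISet(masks, slice_index, roi_size_mm, "auto", found_centers)
    rois.validate()
    # every ROI voxel must be inside the fitted mask
    for name, m in masks.items():
        if not tf.mask[m].all():
            raise ValueError(f"ROI {name} extends outside the fitted mask")
    return rois


def compute_alps(tf: TensorField, rois: ROISet) -> AlpsResult:
    """ROI-mean diffusivities and the per-hemisphere / averaged ALPS index.

    The ratio is computed from ROI means (not a mean of voxelwise
    ratios): per hemisphere,
    ``ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)``.
    """
    rois.validate()
    per_hemisphere = {}
    alps = {}
    for side in ("left", "right"):
        proj = rois.masks[f"proj_{side}"]
        assoc = rois.masks[f"assoc_{side}"]
        for name, m in ((f"proj_{side}", proj), (f"assoc_{side}", assoc)):
            if not tf.mask[m].all():
                raise ValueError(f"ROI {name} contains unfitted voxels")
        vals = {
            "dxx_proj": float(tf.dxx[proj].mean()),
            "dxx_assoc": float(tf.dxx[assoc].mean()),
            "dyy_proj": float(tf.dyy[proj].mean()),
            "dzz_assoc": float(tf.dzz[assoc].mean()),
            "fa_proj": float(tf.fa[proj].mean()),
            "fa_assoc": float(tf.fa[assoc].mean()),
            "md_proj": float(tf.md[proj].mean()),
            "md_assoc": float(tf.md[assoc].mean()),
        }
        for key in ("dxx_proj", "dxx_assoc", "dyy_proj", "dzz_assoc"):
            if vals[key] <= 0:
                raise ValueError(f"ROI-mean diffusivity {key} ({side}) is non-positive")
        per_hemisphere[side] = vals
        alps[side] = (0.5 * (vals["dxx_proj"] + vals["dxx_assoc"])) / (
            0.5 * (vals["dyy_proj"] + vals["dzz_assoc"])
        )
    return AlpsResult(per_hemisphere, alps["left"], alps["right"])
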