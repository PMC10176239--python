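"""Perivascular-space enhancement, segmentation and scoring.

PVS are thin CSF-filled tubules: dark on T1w, bright on T2w. Dividing an
edge-preserving-denoised T2w by the matching T1w therefore amplifies PVS
contrast relative to white matter. A multiscale Hessian tubularity
(Frangi vesselness) filter on the enhanced volume, thresholded inside
the white-matter mask and cleaned of sub-cluster-size components, yields
the PVS mask. From the mask come whole-volume burden (mL and % of
intracranial volume), the single-slice count in the centrum semiovale
(one slice above the superior extent of the lateral ventricle), and the
conventional 0–4 visual-rating severity score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import frangi
from skimage.measure import label
from skimage.restoration import denoise_tv_chambolle

from dtialps.synthdata import StructuralPair

#: severity bins of the widely used visual-rating scale:
#: score s applies when count is in (edge[s-1], edge[s]]
DEFAULT_SEVERITY_EDGES = (0, 10, 20, 40)

DEFAULT_VESSELNESS_SIGMAS = (0.8, 1.2)
DEFAULT_VESSELNESS_THRESHOLD = 0.15
DEFAULT_MIN_CLUSTER_VOXELS = 5
DEFAULT_DENOISE_WEIGHT = 0.02


@dataclass
class PVSResult:
    """Segmented PVS mask with volume, slice count and severity score."""

    pvs_mask: np.ndarray
    pvs_volume_ml: float
    pvs_volume_pct_icv: float
    slice_count: int | None
    severity: int | None
    slice_index: int | None
    voxel_size_mm: float

    def to_dict(self) -> dict:
        return {
            "pvs_volume_ml": self.pvs_volume_ml,
            "pvs_volume_pct_icv": self.pvs_volume_pct_icv,
            "pvs_count": self.slice_count,
            "pvs_score": self.severity,
            "slice_index": self.slice_index,
        }


def enhance_pvs(
    structural: StructuralPair,
    denoise_weight: float = DEFAULT_DENOISE_WEIGHT,
) -> np.ndarray:
    """T2w/T1w ratio volume after edge-preserving (total-variation) denoising.

    PVS voxels (bright T2, dark T1) attain high values. Division is
    guarded against near-zero denominators. Set ``denoise_weight=0`` to
    skip smoothing.
    """
    t1 = np.asarray(structural.t1w, dtype=float)
    t2 = np.asarray(structural.t2w, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("T1w and T2w must share one grid")
    if not (t1 > 0).any():
        raise ValueError("T1w volume is all non-positive")
    if denoise_weight > 0:
        t1 = denoise_tv_chambolle(t1, weight=denoise_weight)
        t2 = denoise_tv_chambolle(t2, weight=denoise_weight)
    floor = 0.05 * np.median(t1[t1 > 0])
    return t2 / np.maximum(t1, floor)


def segment_pvs(
    enhanced: np.ndarray,
    wm_mask: np.ndarray,
    voxel_size_mm: float,
    sigmas=DEFAULT_VESSELNESS_SIGMAS,
    threshold: float = DEFAULT_VESSELNESS_THRESHOLD,
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
) -> PVSResult:
    """Tubularity filtering and thresholding of the enhanced volume.

    Vesselness (bright ridges) is computed at the given scales,
    thresholded inside ``wm_mask``, and connected components (26-
    connectivity) smaller than ``min_cluster_voxels`` are discarded.
    Volume is the retained voxel count times the voxel volume; percent
    ICV uses the full grid as the intracranial proxy.
    """
    enhanced = np.asarray(enhanced, dtype=float)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if enhanced.shape != wm_mask.shape:
        raise ValueError("enhanced volume and wm_mask must share one grid")
    if not wm_mask.any():
        raise ValueError("wm_mask is empty")
    ves = frangi(enhanced, sigmas=sigmas, black_ridges=False)
    mask = (ves > threshold) & wm_mask
    if mask.any() and min_cluster_voxels > 1:
        labels = label(mask, connectivity=3)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_cluster_voxels)
        mask = mask & ~np.isin(labels, small[small > 0])
    n = int(mask.sum())
    vox_ml = voxel_size_mm**3 / 1000.0
    return PVSResult(
        pvs_mask=mask,
        pvs_volume_ml=n * vox_ml,
        pvs_volume_pct_icv=100.0 * n / mask.size,
        slice_count=None,
        severity=None,
        slice_index=None,
        voxel_size_mm=voxel_size_mm,
    )


def count_pvs_slice(pvs_mask: np.ndarray, slice_index: int) -> int:
    """Number of in-plane 8-connected PVS components on one axial slice."""
    pvs_mask = np.asarray(pvs_mask, dtype=bool)
    if not (0 <= slice_index < pvs_mask.shape[2]):
        raise ValueError(
            f"slice {slice_index} out of range for volume with {pvs_mask.shape[2]} slices"
        )
    _, n = label(pvs_mask[:, :, slice_index], connectivity=2, return_num=True)
    return int(n)


def severity_score(count, edges=DEFAULT_SEVERITY_EDGES) -> int:
    """Map a single-slice PVS count to the ordinal 0–4 severity score.

    Default bins: 0 -> 0; 1–10 -> 1; 11–20 -> 2; 21–40 -> 3; >40 -> 4.
    """
    if not float(count).is_integer():
        raise ValueError("count must be an integer")
    count = int(count)
    if count < 0:
        raise ValueError("count must be >= 0")
    for score, hi in enumerate(edges):
        if count <= hi:
            return score
    return len(edges)


def ventricle_top_slice(structural: StructuralPair, ratio_threshold: float = 2.0) -> int:
    """Counting slice: one above the superior extent of the ventricle proxy.

    The ventricle is taken as the largest connected CSF-like component
    (high T2w/T1w ratio) outside the white-matter mask.
    """
    ratio = structural.t2w / np.maximum(structural.t1w, 1e-6)
    csf = (ratio > ratio_threshold) & ~structural.wm_mask
    lab, n = label(csf, connectivity=3, return_num=True)
    if n == 0:
        raise ValueError("no ventricle-proxy found in the structural pair")
    largest = np.argmax(np.bincount(lab[lab > 0]))
    zs = np.nonzero((lab == largest).any(axis=(0, 1)))[0]
    return int(zs.max()) + 1


def quantify_pvs(
    structural: StructuralPair,
    slice_index: int | None = None,
    denoise_weight: float = DEFAULT_DENOISE_WEIGHT,
    sigmas=DEFAULT_VESSELNESS_SIGMAS,
    threshold: float = DEFAULT_VESSELNESS_THRESHOLD,
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
    severity_edges=DEFAULT_SEVERITY_EDGES,
) -> PVSResult:
    """Full PVS chain: enhance, segment, count on the designated slice, score."""
    enhanced = enhance_pvs(structural, denoise_weight=denoise_weight)
    res = segment_pvs(
        enhanced,
        structural.wm_mask,
        structural.voxel_size_mm,
        sigmas=sigmas,
        threshold=threshold,
        min_cluster_voxels=min_cluster_voxels,
    )
    if slice_index is None:
        slice_index = ventricle_top_slice(structural)
    res.slice_count = count_pvs_slice(res.pvs_mask, slice_index)
    res.severity = severity_score(res.slice_count, edges=severity_edges)
    res.slice_index = slice_index
    return res
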