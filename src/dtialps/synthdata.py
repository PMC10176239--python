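"""Synthetic diffusion/structural phantoms and cohort generation.

The diffusion phantom is a small volume laid out like the periventricular
white matter at the level of the lateral ventricles: a central CSF-like
ventricle slab (the landmark ROI placement keys on), flanked bilaterally
by medial "projection" blocks whose fibers run inferior–superior (z) and
lateral "association" blocks whose fibers run anterior–posterior (y).
Perivascular spaces around medullary veins run right–left (x), orthogonal
to both tracts, so glymphatic function is modeled phenomenologically by
adding ``d_perivascular`` to the xx element of every block tensor. The
analytic ALPS index of such a phantom is

    ALPS = (lambda_perp + d_perivascular) / lambda_perp

which serves as ground truth for the whole pipeline.

Signals follow S = S0 * exp(-b g^T D g) with optional Rician corruption.
The structural generator inserts thin CSF-contrast tubules (dark on T1w,
bright on T2w) into a white-matter background for the PVS stages.

The cohort generator draws, per subject, an ALPS-scale glymphatic
parameter shifted by group and age, a tubule burden, and a plasma NfL
concentration linear in the glymphatic parameter (negative coefficient)
and age (positive), mirroring the statistical structure a TBI-vs-control
glymphatic study assumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dtialps.tensorfit import AXIS_CONVENTION, TensorField


# ---------------------------------------------------------------------------
# specs


@dataclass
class PhantomSpec:
    """Parameters of the diffusion phantom.

    Diffusivities are in mm^2/s, b-values in s/mm^2. ``noise_sigma`` is
    the Rician noise scale as a fraction of ``S0``.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size_mm: float = 1.5
    bvals: tuple[float, ...] = (1500.0, 3000.0)
    n_dirs_per_shell: int = 98
    n_b0: int = 7
    S0: float = 1000.0
    lambda_parallel: float = 1.5e-3
    lambda_perp: float = 0.4e-3
    d_perivascular: float = 0.0
    d_background: float = 0.7e-3
    d_csf: float = 3.0e-3
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(b < 0 for b in self.bvals):
            raise ValueError("b-values must be non-negative")
        if not (self.lambda_parallel >= self.lambda_perp > 0):
            raise ValueError("need lambda_parallel >= lambda_perp > 0")
        if self.d_perivascular < 0:
            raise ValueError("d_perivascular must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_b0 < 1:
            raise ValueError("need at least one b=0 volume for a baseline")
        phantom_layout(self.grid_shape)  # raises if blocks do not fit


@dataclass
class DWIVolume:
    """4D diffusion signal plus gradient table and grid geometry."""

    signal: np.ndarray  # (X, Y, Z, V)
    bvals: np.ndarray  # (V,)
    bvecs: np.ndarray  # (V, 3), unit rows for b > 0
    voxel_size_mm: float
    axis_convention: tuple = AXIS_CONVENTION

    def __post_init__(self):
        v = self.signal.shape[-1]
        if self.bvals.shape != (v,) or self.bvecs.shape != (v, 3):
            raise ValueError("volume count mismatch between signal and gradient table")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient vectors for b>0 volumes must have unit norm")
        if (self.signal < 0).any():
            raise ValueError("signal must be non-negative")


@dataclass
class StructuralPair:
    """Co-registered T1w/T2w volumes with masks and inserted-tubule truth."""

    t1w: np.ndarray
    t2w: np.ndarray
    wm_mask: np.ndarray
    pvs_truth_mask: np.ndarray
    voxel_size_mm: float

    def __post_init__(self):
        shapes = {a.shape for a in (self.t1w, self.t2w, self.wm_mask, self.pvs_truth_mask)}
        if len(shapes) != 1:
            raise ValueError("all structural volumes must share one grid")
        if (self.pvs_truth_mask & ~self.wm_mask).any():
            raise ValueError("pvs_truth_mask must lie inside wm_mask")


@dataclass
class RoiLayout:
    """Ground-truth geometry of the phantom: block masks, ROI centers, slices."""

    blocks: dict  # name -> boolean mask over the grid
    roi_centers: dict  # name -> (x, y) in-plane center at alps_slice
    ventricle: np.ndarray  # boolean mask
    alps_slice: int
    pvs_count_slice: int


# block names, left/right per hemisphere
ROI_NAMES = ("proj_left", "proj_right", "assoc_left", "assoc_right")


def phantom_layout(grid_shape: tuple[int, int, int]) -> RoiLayout:
    """Deterministic mirror-symmetric layout of ventricle and fiber blocks.

    Raises ``ValueError`` if the grid is too small to hold the four
    blocks with a one-voxel margin.
    """
    nx, ny, nz = grid_shape
    # ventricle: central slab in x/y, lower-central slab in z
    vhw = max(2, nx // 8)  # ventricle half width in x
    vx0, vx1 = nx // 2 - vhw, nx // 2 + vhw - 1  # inclusive, mirror symmetric
    vy0, vy1 = ny // 2 - ny // 4, ny // 2 + ny // 4 - 1
    vz0 = 2 * nz // 5
    vz1 = vz0 + max(2, nz // 5) - 1
    alps_slice = (vz0 + vz1) // 2
    pvs_count_slice = vz1 + 1

    bw = max(3, nx // 8)  # block width in x
    gap = max(1, nx // 20)
    by0, by1 = ny // 2 - ny // 5, ny // 2 + ny // 5 - 1
    bz0, bz1 = max(0, alps_slice - 3), min(nz - 1, alps_slice + 3)

    # right hemisphere blocks; left is the mirror x -> nx-1-x
    pr_x0 = vx1 + 1
    pr_x1 = pr_x0 + bw - 1
    ar_x0 = pr_x1 + gap + 1
    ar_x1 = ar_x0 + bw - 1
    if ar_x1 > nx - 2:
        raise ValueError(
            f"grid_shape {grid_shape} too small: association block would end at "
            f"x={ar_x1} but needs a margin inside x<{nx - 1}"
        )
    if pvs_count_slice > nz - 2 or by0 < 1 or bz0 < 1:
        raise ValueError(f"grid_shape {grid_shape} too small along y or z")

    def box(x0, x1):
        m = np.zeros(grid_shape, dtype=bool)
        m[x0 : x1 + 1, by0 : by1 + 1, bz0 : bz1 + 1] = True
        return m

    def mirror(x0, x1):
        return nx - 1 - x1, nx - 1 - x0

    blocks = {
        "proj_right": box(pr_x0, pr_x1),
        "assoc_right": box(ar_x0, ar_x1),
        "proj_left": box(*mirror(pr_x0, pr_x1)),
        "assoc_left": box(*mirror(ar_x0, ar_x1)),
    }
    ventricle = np.zeros(grid_shape, dtype=bool)
    ventricle[vx0 : vx1 + 1, vy0 : vy1 + 1, vz0 : vz1 + 1] = True

    yc = (by0 + by1) // 2
    roi_centers = {
        "proj_right": ((pr_x0 + pr_x1) // 2, yc),
        "assoc_right": ((ar_x0 + ar_x1) // 2, yc),
        "proj_left": ((mirror(pr_x0, pr_x1)[0] + mirror(pr_x0, pr_x1)[1]) // 2, yc),
        "assoc_left": ((mirror(ar_x0, ar_x1)[0] + mirror(ar_x0, ar_x1)[1]) // 2, yc),
    }
    return RoiLayout(
        blocks=blocks,
        roi_centers=roi_centers,
        ventricle=ventricle,
        alps_slice=alps_slice,
        pvs_count_slice=pvs_count_slice,
    )


# ---------------------------------------------------------------------------
# gradient scheme


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (spherical Fibonacci points)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gradient_table(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-volume b-values and unit gradient vectors: b=0 volumes first,
    then one Fibonacci point set per shell."""
    bvals = [0.0] * spec.n_b0
    bvecs = [np.zeros(3)] * spec.n_b0
    dirs = fibonacci_sphere(spec.n_dirs_per_shell)
    for b in spec.bvals:
        bvals.extend([float(b)] * spec.n_dirs_per_shell)
        bvecs.extend(dirs)
    return np.array(bvals), np.array(bvecs)


# ---------------------------------------------------------------------------
# diffusion phantom


def ground_truth_tensors(spec: PhantomSpec) -> tuple[np.ndarray, RoiLayout]:
    """Per-voxel ground-truth tensors for the phantom geometry."""
    layout = phantom_layout(spec.grid_shape)
    D = np.zeros(spec.grid_shape + (3, 3))
    D[..., 0, 0] = D[..., 1, 1] = D[..., 2, 2] = spec.d_background
    lp, lt, dp = spec.lambda_parallel, spec.lambda_perp, spec.d_perivascular
    proj = np.diag([lt + dp, lt, lp])  # fiber along z, perivascular x boost
    assoc = np.diag([lt + dp, lp, lt])  # fiber along y
    for name, block in layout.blocks.items():
        D[block] = proj if name.startswith("proj") else assoc
    D[layout.ventricle] = np.diag([spec.d_csf] * 3)
    if np.linalg.eigvalsh(D.reshape(-1, 3, 3)).min() <= 0:
        raise ValueError("phantom tensors must be positive definite")
    return D, layout


def signal_from_tensors(
    D: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, S0: float
) -> np.ndarray:
    """Noise-free Stejskal–Tanner signals S = S0 exp(-b g^T D g)."""
    adc = np.einsum("...ij,vi,vj->...v", D, bvecs, bvecs)
    return S0 * np.exp(-bvals * adc)


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude-MRI (Rician) noise with absolute scale ``sigma``."""
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(re**2 + im**2)


def generate_phantom(spec: PhantomSpec) -> tuple[DWIVolume, TensorField, RoiLayout]:
    """Simulate the diffusion phantom.

    Returns the DWI volume, the ground-truth tensor field (with
    eigensystem, FA and MD computed from the generative tensors), and the
    block/ROI layout.
    """
    spec.validate()
    D, layout = ground_truth_tensors(spec)
    bvals, bvecs = gradient_table(spec)
    signal = signal_from_tensors(D, bvals, bvecs, spec.S0)
    rng = np.random.default_rng(spec.seed)
    signal = add_rician_noise(signal, spec.noise_sigma * spec.S0, rng)
    dwi = DWIVolume(
        signal=signal, bvals=bvals, bvecs=bvecs, voxel_size_mm=spec.voxel_size_mm
    )
    truth = TensorField.from_tensors(D, voxel_size_mm=spec.voxel_size_mm)
    return dwi, truth, layout


def analytic_alps(spec: PhantomSpec) -> float:
    """The phantom's exact ALPS index, (lambda_perp + d_perivascular) / lambda_perp."""
    return (spec.lambda_perp + spec.d_perivascular) / spec.lambda_perp


# ---------------------------------------------------------------------------
# structural phantom

# CSF-like contrast multipliers relative to white matter
_T1_WM, _T2_WM = 1.0, 0.5
_T1_CSF_FACTOR, _T2_CSF_FACTOR = 0.4, 3.0


def _tubule_voxels(
    rng: np.random.Generator, grid_shape, margin: int
) -> np.ndarray:
    """Voxel indices of one random thin tubule (width-1 rasterized segment)."""
    shape = np.array(grid_shape)
    length = int(rng.integers(6, 13))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    ext = length * np.abs(direction) / 2.0
    lo = margin + ext
    hi = shape - 1 - margin - ext
    if (hi <= lo).any():
        return None  # segment cannot fit at this orientation; caller retries
    center = rng.uniform(lo, hi)
    t = np.linspace(-length / 2, length / 2, 4 * length)
    pts = np.unique(np.round(center + t[:, None] * direction).astype(int), axis=0)
    return pts


def generate_structural(
    spec: PhantomSpec,
    n_tubules: int,
    seed: int,
    noise_sigma: float = 0.02,
    max_retries: int = 1000,
) -> StructuralPair:
    """T1w/T2w pair with ``n_tubules`` thin CSF-contrast tubules in white matter.

    Tubules are dark on T1w and bright on T2w, non-overlapping (with a
    one-voxel separation), recorded in ``pvs_truth_mask``. The ventricle
    slab appears with the same CSF contrast but is excluded from
    ``wm_mask``. Fully deterministic under ``seed``.
    """
    if n_tubules < 0:
        raise ValueError("n_tubules must be >= 0")
    layout = phantom_layout(spec.grid_shape)
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape

    wm = np.ones(shape, dtype=bool)
    wm[:2], wm[-2:] = False, False
    wm[:, :2], wm[:, -2:] = False, False
    wm[:, :, :2], wm[:, :, -2:] = False, False
    wm &= ~layout.ventricle

    occupied = layout.ventricle.copy()
    truth = np.zeros(shape, dtype=bool)
    placed = 0
    tries = 0
    while placed < n_tubules:
        if tries >= max_retries:
            raise RuntimeError(
                f"could only place {placed}/{n_tubules} non-overlapping tubules "
                f"after {max_retries} attempts"
            )
        tries += 1
        pts = _tubule_voxels(rng, shape, margin=3)
        if pts is None:
            continue
        if not wm[tuple(pts.T)].all():
            continue
        # one-voxel clearance against everything already placed
        lo = np.maximum(pts.min(axis=0) - 1, 0)
        hi = pts.max(axis=0) + 2
        neighborhood = occupied[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        cand = np.zeros(shape, dtype=bool)
        cand[tuple(pts.T)] = True
        grown = np.zeros(neighborhood.shape, dtype=bool)
        sub = cand[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    grown |= np.roll(np.roll(np.roll(sub, dx, 0), dy, 1), dz, 2)
        if (grown & neighborhood).any():
            continue
        truth |= cand
        occupied |= cand
        placed += 1

    t1 = np.full(shape, _T1_WM)
    t2 = np.full(shape, _T2_WM)
    csf = truth | layout.ventricle
    t1[csf] = _T1_WM * _T1_CSF_FACTOR
    t2[csf] = _T2_WM * _T2_CSF_FACTOR
    if noise_sigma > 0:
        t1 = np.clip(t1 + rng.normal(0, noise_sigma, shape), 1e-3, None)
        t2 = np.clip(t2 + rng.normal(0, noise_sigma, shape), 1e-3, None)
    return StructuralPair(
        t1w=t1, t2w=t2, wm_mask=wm, pvs_truth_mask=truth, voxel_size_mm=spec.voxel_size_mm
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic TBI-vs-control cohort.

    ``group_alps_means`` are population ALPS-index means at the reference
    age ``age_ref``; per-subject true ALPS adds an age slope (per year)
    and Gaussian subject-level scatter ``alps_sd``. Plasma NfL (pg/mL)
    is linear in the true ALPS parameter (``nfl_b_alps`` < 0: worse
    glymphatic function, higher NfL) and in age (``nfl_b_age`` > 0).
    Tubule burden is Poisson with an age-increasing rate.
    """

    n_tbi: int = 37
    n_control: int = 13
    age_range_tbi: tuple[float, float] = (19.0, 85.0)
    age_range_control: tuple[float, float] = (33.0, 86.0)
    male_frac_tbi: float = 0.757
    male_frac_control: float = 0.538
    group_alps_means: dict = field(default_factory=lambda: {"TBI": 1.336, "control": 1.389})
    age_slope_alps: float = -0.006
    age_ref: float = 53.0
    # residual scatter after the age effect; together with the default age
    # slope over the cohort age spread this yields a raw within-group SD of
    # ~0.16, the scale clinical ALPS cohorts report
    alps_sd: float = 0.125
    nfl_intercept: float = 72.0
    nfl_b_alps: float = -47.0
    nfl_b_age: float = 0.3
    nfl_sd: float = 9.0
    gcs_available_frac: float = 0.46
    days_range: tuple[float, float] = (62.0, 241.0)
    pvs_tubule_rate: float = 12.0
    pvs_age_slope: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_tbi < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group for statistics")
        for name in ("alps_sd", "nfl_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# nominal volume of one tubule used for the table-level PVS volume proxy
_TUBULE_MEAN_VOXELS = 9.0


def generate_cohort(
    spec: CohortSpec, phantom_base: PhantomSpec | None = None
) -> tuple[pd.DataFrame, list[PhantomSpec]]:
    """Draw a subject table and matching per-subject phantom specs.

    The table carries the generative ground truth (``alps_true``,
    ``d_perivascular``, ``n_tubules``) alongside observable columns.
    Before any imaging is run, ``alps_mean`` and the PVS columns hold
    parameter-level values, so the statistics chain can be exercised on
    table-level simulations without simulating images; the pipeline
    overwrites them with measured values when it runs.
    Pure function of (spec, phantom defaults, seed).
    """
    spec.validate()
    base = phantom_base if phantom_base is not None else PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    rows = []
    phantom_specs = []
    idx = 0
    for group, n, age_rng, male_frac in (
        ("TBI", spec.n_tbi, spec.age_range_tbi, spec.male_frac_tbi),
        ("control", spec.n_control, spec.age_range_control, spec.male_frac_control),
    ):
        for _ in range(n):
            age = rng.uniform(*age_rng)
            sex = "M" if rng.random() < male_frac else "F"
            alps_true = (
                spec.group_alps_means[group]
                + spec.age_slope_alps * (age - spec.age_ref)
                + rng.normal(0, spec.alps_sd)
            )
            # phantom perivascular diffusivity cannot be negative; the table
            # keeps the untruncated draw so cohort statistics stay Gaussian
            dp = max(alps_true - 1.0, 0.0) * base.lambda_perp
            nfl = (
                spec.nfl_intercept
                + spec.nfl_b_alps * alps_true
                + spec.nfl_b_age * age
                + rng.normal(0, spec.nfl_sd)
            )
            rate = max(spec.pvs_tubule_rate + spec.pvs_age_slope * (age - spec.age_ref), 0.0)
            n_tub = int(rng.poisson(rate))
            if group == "TBI":
                days = rng.uniform(*spec.days_range)
                gcs = (
                    float(np.clip(np.round(rng.normal(12.3, 2.9)), 3, 15))
                    if rng.random() < spec.gcs_available_frac
                    else np.nan
                )
            else:
                days, gcs = np.nan, np.nan
            vol_ml = n_tub * _TUBULE_MEAN_VOXELS * base.voxel_size_mm**3 / 1000.0
            rows.append(
                {
                    "subject_id": f"sub-{idx:03d}",
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "days_since_injury": days,
                    "gcs": gcs,
                    "nfl": max(nfl, 0.1),
                    "alps_true": alps_true,
                    "d_perivascular": dp,
                    "n_tubules": n_tub,
                    "alps_mean": alps_true,
                    "pvs_volume": vol_ml,
                    "pvs_count": n_tub,
                    "pvs_score": _score_proxy(n_tub),
                }
            )
            phantom_specs.append(
                dataclasses.replace(base, d_perivascular=dp, seed=spec.seed + idx + 1)
            )
            idx += 1
    return pd.DataFrame(rows), phantom_specs


def _score_proxy(count: int) -> int:
    # local copy of the default severity bins to avoid a circular import
    for score, hi in ((0, 0), (1, 10), (2, 20), (3, 40)):
        if count <= hi:
            return score
    return 4
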