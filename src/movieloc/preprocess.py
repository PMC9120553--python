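"""Timecourse hygiene for movie and localizer runs.

The cleaning pipeline runs, in this exact order:

1. artifact timepoint detection (composite motion > 2 mm between consecutive
   TRs, or global signal beyond 3 SD of its run mean);
2. nearest-neighbor interpolation over artifact TRs;
3. nuisance regression — one indicator ("spike") column per artifact TR plus
   five PCA-based noise components computed from eroded white matter
   (component-based noise correction, run on the scrubbed data);
4. high-pass filtering (discrete-cosine basis, 100 s cutoff);
5. ROI averaging; artifact TRs are then excluded (set to NaN).

Interpolating before the temporal filter prevents artifact energy from
smearing through the filter; NaN-ing last keeps ROI means defined wherever
any data exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dataset_io import BoldRun, Parcel
from .timecourse import Timecourse

logger = logging.getLogger(__name__)

__all__ = [
    "ArtifactMask",
    "NuisanceSet",
    "composite_displacement",
    "detect_artifact_timepoints",
    "subject_passes_qc",
    "interpolate_artifacts",
    "erode_mask",
    "compute_compcor",
    "build_nuisance_set",
    "highpass_filter",
    "dct_highpass_basis",
    "clean_voxel_timecourses",
    "roi_mean_timecourse",
    "global_signal",
    "HEAD_RADIUS_MM",
]

#: Nominal head radius used to convert rotations (radians) into worst-case
#: surface displacement (mm), following the ART toolbox convention.
HEAD_RADIUS_MM = 65.0


@dataclass
class ArtifactMask:
    """Boolean per-TR artifact flags."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValueError("artifact flags must be 1D")

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def n_trs(self) -> int:
        return self.flags.size

    @property
    def flagged_trs(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


@dataclass
class NuisanceSet:
    """T x (n_spikes + n_components) nuisance regressor matrix.

    Spike columns are one-hot indicators of artifact TRs; component columns
    are mutually orthogonal, zero-mean noise-component timecourses.
    """

    matrix: np.ndarray
    names: list[str]
    n_spikes: int
    n_components: int
    degenerate: list[bool] = field(default_factory=list)

    @property
    def spikes(self) -> np.ndarray:
        return self.matrix[:, : self.n_spikes]

    @property
    def components(self) -> np.ndarray:
        return self.matrix[:, self.n_spikes:]


# ---------------------------------------------------------------------------
# Artifact detection & QC
# ---------------------------------------------------------------------------

def composite_displacement(motion: np.ndarray,
                           head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Scalar displacement between consecutive TRs.

    Rotations (radians) are converted to worst-case arc displacement on a
    sphere of ``head_radius_mm``; the composite is the Euclidean norm of the
    six converted parameter deltas. Returns length T with a leading 0 (TR 0
    has no predecessor).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (T, 6): 3 translations mm + 3 rotations rad")
    converted = motion.copy()
    converted[:, 3:] *= head_radius_mm
    deltas = np.diff(converted, axis=0)
    disp = np.sqrt((deltas ** 2).sum(axis=1))
    return np.concatenate([[0.0], disp])


def detect_artifact_timepoints(
    motion: np.ndarray,
    global_signal: Timecourse | np.ndarray,
    motion_mm: float = 2.0,
    gs_sd: float = 3.0,
    head_radius_mm: float = HEAD_RADIUS_MM,
) -> ArtifactMask:
    """Flag TRs with >``motion_mm`` composite motion from the previous TR, or
    a global-signal excursion beyond ``gs_sd`` SDs of the run mean.

    Both thresholds are strict inequalities; TR 0 can only be flagged by the
    global-signal criterion. The global-signal mean and SD are computed over
    the full run (candidate artifact TRs included).
    """
    gs = global_signal.values if isinstance(global_signal, Timecourse) else \
        np.asarray(global_signal, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != gs.size:
        raise ValueError("motion and global signal lengths differ")
    if gs.size < 2:
        raise ValueError("need at least 2 TRs")
    disp = composite_displacement(motion, head_radius_mm)
    motion_flags = disp > motion_mm
    sd = gs.std(ddof=1)
    if sd == 0:
        gs_flags = np.zeros_like(motion_flags)
    else:
        gs_flags = np.abs(gs - gs.mean()) > gs_sd * sd
    return ArtifactMask(motion_flags | gs_flags)


def subject_passes_qc(mask: ArtifactMask) -> bool:
    """False iff one-third or more of the run's TRs are artifacts."""
    return mask.n_flagged < mask.n_trs / 3


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _nearest_good_indices(flags: np.ndarray) -> np.ndarray:
    """Index of the nearest unflagged TR per TR; ties go to the earlier TR."""
    good = np.flatnonzero(~flags)
    if good.size == 0:
        raise ValueError("all TRs flagged: nothing to interpolate from")
    t = np.arange(flags.size)
    # position of insertion into good; candidates are good[pos-1] (earlier)
    # and good[pos] (later)
    pos = np.searchsorted(good, t)
    earlier = good[np.clip(pos - 1, 0, good.size - 1)]
    later = good[np.clip(pos, 0, good.size - 1)]
    d_earlier = np.where(pos > 0, t - earlier, np.iinfo(np.int64).max)
    d_later = np.where(pos < good.size, later - t, np.iinfo(np.int64).max)
    choose_earlier = d_earlier <= d_later  # tie -> earlier
    nearest = np.where(choose_earlier, earlier, later)
    nearest[~flags] = t[~flags]
    return nearest


def interpolate_artifacts(values: Timecourse | np.ndarray,
                          mask: ArtifactMask) -> np.ndarray:
    """Nearest-neighbor interpolation over artifact TRs (1D or voxel x T)."""
    arr = values.values if isinstance(values, Timecourse) else np.asarray(values, float)
    squeeze = arr.ndim == 1
    mat = np.atleast_2d(arr)
    if mat.shape[1] != mask.n_trs:
        raise ValueError("data and artifact mask lengths differ")
    nearest = _nearest_good_indices(mask.flags)
    out = mat[:, nearest]
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# White-matter mask erosion & CompCor
# ---------------------------------------------------------------------------

def erode_mask(mask: Parcel, iterations: int = 2) -> Parcel:
    """Erode a mask with 6-connectivity; grid boundary counts as outside."""
    if iterations < 1:
        return Parcel(mask.mask.copy(), mask.label)
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask.mask, structure=structure,
                                    iterations=iterations, border_value=0)
    if not eroded.any():
        raise ValueError(
            f"mask {mask.label!r} empty after {iterations} erosion iterations; "
            "use fewer iterations or a larger mask"
        )
    return Parcel(eroded, f"{mask.label}_eroded{iterations}")


def compute_compcor(
    wm_bold: np.ndarray,
    artifact_mask: ArtifactMask | None = None,
    n_components: int = 5,
) -> tuple[np.ndarray, list[bool]]:
    """Principal-component noise timecourses from white-matter voxels.

    ``wm_bold`` is a voxel x T matrix (already restricted to the eroded
    white-matter mask). Artifact TRs are interpolated over ("scrubbed")
    before the decomposition. Each voxel's temporal mean is removed, so the
    returned unit-norm component timecourses are exactly zero-mean and
    mutually orthogonal. Sign is fixed by making each component's
    largest-magnitude spatial loading positive.

    Returns (T x k component matrix, per-component degeneracy flags). If
    fewer than ``n_components`` non-degenerate components exist the extras
    are flagged (and zero-filled) with a warning.
    """
    wm = np.asarray(wm_bold, dtype=float)
    if wm.ndim != 2:
        raise ValueError("wm_bold must be a voxel x T matrix")
    if artifact_mask is not None and artifact_mask.n_flagged:
        wm = interpolate_artifacts(wm, artifact_mask)
    wm = wm - wm.mean(axis=1, keepdims=True)
    # SVD: rows (voxels) x columns (time); right singular vectors are the
    # component timecourses, variance-ordered.
    u, s, vt = np.linalg.svd(wm, full_matrices=False)
    n_avail = s.size
    tol = max(wm.shape) * np.finfo(float).eps * (s[0] if n_avail else 0.0)
    comps = np.zeros((wm.shape[1], n_components))
    degenerate = [True] * n_components
    for k in range(min(n_components, n_avail)):
        if s[k] <= tol or s[k] < 1e-12:
            break
        load = u[:, k]
        sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
        comps[:, k] = sign * vt[k]
        degenerate[k] = False
    n_good = sum(not d for d in degenerate)
    if n_good < n_components:
        logger.warning("W-COMPCOR-RANK only %d of %d requested noise components "
                       "are non-degenerate", n_good, n_components)
    return comps[:, :n_components], degenerate


def build_nuisance_set(artifact_mask: ArtifactMask,
                       components: np.ndarray,
                       degenerate: list[bool] | None = None) -> NuisanceSet:
    """Assemble spike indicators + noise components into one regressor set."""
    T = artifact_mask.n_trs
    spikes = np.zeros((T, artifact_mask.n_flagged))
    names = []
    for j, t in enumerate(artifact_mask.flagged_trs):
        spikes[t, j] = 1.0
        names.append(f"spike_tr{t + 1}")  # user-facing 1-based
    comps = np.asarray(components, dtype=float)
    if comps.ndim != 2 or comps.shape[0] != T:
        raise ValueError("components must be T x k")
    if degenerate is None:
        degenerate = [False] * comps.shape[1]
    keep = [j for j in range(comps.shape[1]) if not degenerate[j]]
    comps = comps[:, keep]
    names += [f"compcor_{j + 1}" for j in range(comps.shape[1])]
    return NuisanceSet(
        matrix=np.hstack([spikes, comps]),
        names=names,
        n_spikes=artifact_mask.n_flagged,
        n_components=comps.shape[1],
        degenerate=list(degenerate),
    )


# ---------------------------------------------------------------------------
# High-pass filter
# ---------------------------------------------------------------------------

def dct_highpass_basis(T: int, tr_s: float, cutoff_s: float = 100.0) -> np.ndarray:
    """Discrete-cosine regressors spanning frequencies below 1/cutoff_s.

    Basis function k (k >= 1) is cos(pi * k * (t + 1/2) / T), with frequency
    k / (2 T tr_s) Hz; all k with frequency < 1/cutoff_s are returned.
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff must exceed twice the TR")
    n_k = int(np.floor(2.0 * T * tr_s / cutoff_s))
    t = np.arange(T)
    basis = np.column_stack(
        [np.cos(np.pi * k * (t + 0.5) / T) for k in range(1, n_k + 1)]
    ) if n_k else np.empty((T, 0))
    return basis


def highpass_filter(values: Timecourse | np.ndarray, tr_s: float | None = None,
                    cutoff_s: float = 100.0) -> np.ndarray:
    """Remove mean plus the projection onto the low-frequency DCT basis."""
    if isinstance(values, Timecourse):
        tr_s = values.tr_s if tr_s is None else tr_s
        arr = values.values
    else:
        if tr_s is None:
            raise ValueError("tr_s required for array input")
        arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("high-pass filter requires complete data "
                         "(interpolate artifacts first)")
    squeeze = arr.ndim == 1
    mat = np.atleast_2d(arr)
    T = mat.shape[1]
    basis = dct_highpass_basis(T, tr_s, cutoff_s)
    X = np.column_stack([np.ones(T), basis])
    beta, *_ = np.linalg.lstsq(X, mat.T, rcond=None)
    resid = mat.T - X @ beta
    out = resid.T
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Full voxelwise cleaning & ROI averaging
# ---------------------------------------------------------------------------

def clean_voxel_timecourses(
    voxel_data: np.ndarray,
    artifact_mask: ArtifactMask,
    nuisance: NuisanceSet | None,
    tr_s: float,
    cutoff_s: float = 100.0,
) -> np.ndarray:
    """Interpolate -> nuisance OLS residuals -> high-pass, per voxel.

    Residuals are orthogonal to every retained nuisance column. Collinear
    nuisance columns are dropped (pseudo-inverse with a logged warning).
    """
    Y = np.asarray(voxel_data, dtype=float)
    if Y.ndim != 2:
        raise ValueError("voxel_data must be voxel x T")
    if Y.shape[1] != artifact_mask.n_trs:
        raise ValueError("voxel data and artifact mask lengths differ")
    Y = interpolate_artifacts(Y, artifact_mask)
    T = Y.shape[1]
    if nuisance is not None and nuisance.matrix.shape[1] > 0:
        if nuisance.matrix.shape[0] != T:
            raise ValueError("nuisance matrix has wrong number of TRs")
        X = np.column_stack([np.ones(T), nuisance.matrix])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            logger.warning("W-NUISANCE-COLLINEAR nuisance matrix rank %d < %d "
                           "columns; collinear directions dropped", rank, X.shape[1])
        beta = np.linalg.pinv(X) @ Y.T
        Y = (Y.T - X @ beta).T
    return highpass_filter(Y, tr_s=tr_s, cutoff_s=cutoff_s)


def roi_mean_timecourse(
    cleaned: np.ndarray,
    roi_rows: np.ndarray,
    artifact_mask: ArtifactMask | None = None,
    tr_s: float = 2.0,
    name: str = "",
) -> Timecourse:
    """Mean over ROI voxels per TR; artifact TRs are then set to missing."""
    cleaned = np.asarray(cleaned, dtype=float)
    rows = np.asarray(roi_rows, dtype=int)
    if rows.size == 0:
        raise ValueError("empty ROI")
    if rows.max() >= cleaned.shape[0]:
        raise ValueError("ROI voxel index outside the cleaned matrix")
    mean = cleaned[rows].mean(axis=0)
    if artifact_mask is not None:
        if artifact_mask.n_trs != mean.size:
            raise ValueError("artifact mask length mismatch")
        mean = mean.copy()
        mean[artifact_mask.flags] = np.nan
    return Timecourse(mean, tr_s=tr_s, name=name)


def global_signal(bold: BoldRun, brain_mask: np.ndarray) -> Timecourse:
    """Mean over in-brain voxels per TR (brain mask: union of parcels unless
    a dedicated mask is supplied)."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != bold.shape3d:
        raise ValueError("brain mask grid does not match the BOLD run")
    vox = bold.data[brain_mask]  # (n_voxels, T)
    return Timecourse(vox.mean(axis=0), tr_s=bold.tr_s, name="global_signal")
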