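"""Synthetic multi-subject BOLD cohorts with planted ground truth.

The generator emulates the data structure the analyses assume: each of seven
visual regions (FFA, pSTS, OPA, PPA, RSC, LOC, EVC) has a latent movie
timecourse (zero-mean, unit-SD, temporally smoothed to mimic hemodynamic
autocorrelation, with a configurable inter-region correlation structure).
Within each region's search-space parcel, a planted set of "selective"
voxels carries the latent at a configurable gain; the remaining parcel
voxels carry a weak anti-preference. Adults additionally get blocked
localizer runs in which selective voxels respond preferentially to their
region's condition (faces / scenes / objects / scrambled) through the same
canonical HRF the GLM module uses. Motion traces carry planted artifact
timepoints (persistent 3-mm translation steps plus a global-signal
excursion). Child groups get developmental effects: an overall response
gain that grows with age, a fraction of the FFA latent mixed into pSTS
(decaying with age), and a +1 TR pSTS response lag in the youngest
children.

Every random draw flows from one root seed through per-subject
``numpy.random.SeedSequence`` spawns, all recorded in the ground-truth
manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import dataset_io
from .dataset_io import BlockTiming, BoldRun, Parcel, SubjectRecord, DatasetLayout
from .glm import build_block_design
from .timecourse import Timecourse

logger = logging.getLogger(__name__)

__all__ = [
    "REGIONS",
    "REGION_CONDITIONS",
    "LOCALIZER_CONDITIONS",
    "CohortConfig",
    "Geometry",
    "GroundTruthManifest",
    "default_geometry",
    "default_latent_corr",
    "make_latent_timecourses",
    "make_localizer_timing",
    "simulate_subject",
    "simulate_cohort",
    "generate_cohort",
    "CohortData",
    "SubjectSim",
]

REGIONS = ["FFA", "pSTS", "OPA", "PPA", "RSC", "LOC", "EVC"]
LOCALIZER_CONDITIONS = ["faces", "objects", "scenes", "scrambled"]

#: Preferred localizer condition per region (EVC responds most to scrambled).
REGION_CONDITIONS = {
    "FFA": "faces", "pSTS": "faces",
    "OPA": "scenes", "PPA": "scenes", "RSC": "scenes",
    "LOC": "objects", "EVC": "scrambled",
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Configuration & geometry
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the acquisition this package models: 168-TR movie runs
    at TR = 2 s, a 415.8-s palindromic 4-condition localizer (adults only,
    2 runs), 12 adults plus two child groups of 17, and k = 100 planted
    selective voxels per 216-voxel parcel.
    """

    groups: dict = field(default_factory=lambda: {"adult": 12, "3yo": 17, "8-12yo": 17})
    group_age_ranges: dict = field(default_factory=lambda: {
        "adult": (19.0, 35.0), "3yo": (3.0, 3.9), "4yo": (4.0, 4.9),
        "5yo": (5.0, 5.9), "7yo": (7.0, 7.9), "8-12yo": (8.0, 12.0),
    })
    grid_shape: tuple = (24, 24, 18)
    voxel_mm: float = 2.0
    T_movie: int = 168
    tr_s: float = 2.0
    T_localizer: int = 208
    n_localizer_runs: int = 2          # adults only
    n_selective: int = 100
    selectivity_weight: float = 1.0
    anti_weight: float = -0.15
    voxel_noise_sd: float = 0.5
    shared_noise_sd: float = 0.25
    smooth_fwhm_trs: float = 3.0
    artifact_rate: dict = field(default_factory=lambda: {"adult": 0.02, "child": 0.06})
    spike_mm: float = 3.0
    background_motion_sd_mm: float = 0.1
    gs_spike_gain: float = 8.0         # excursion amplitude in clean-GS SDs
    localizer_amp_pref: float = 2.0
    localizer_amp_nonpref: float = 0.5
    localizer_amp_nonselective: float = 0.3
    child_psts_mix: float = 0.6        # FFA fraction mixed into pSTS at age 3
    child_psts_mix_end_age: float = 8.0
    child_lag_trs: int = 1             # pSTS lag for children under 5
    child_lag_max_age: float = 5.0
    child_gain_at_3: float = 0.5       # response gain at age 3, ->1 by age 8
    n_wm_components: int = 3
    wm_component_sd: float = 1.0
    qc_fail_subjects: list = field(default_factory=list)
    qc_fail_artifact_rate: float = 0.45
    latent_corr: np.ndarray | None = None

    def rate_for(self, group: str) -> float:
        if group in self.artifact_rate:
            return self.artifact_rate[group]
        return self.artifact_rate["adult" if group == "adult" else "child"]

    def gain_for(self, age: float, group: str) -> float:
        if group == "adult":
            return 1.0
        slope = (1.0 - self.child_gain_at_3) / 5.0
        return float(min(1.0, self.child_gain_at_3 + slope * (age - 3.0)))

    def psts_mix_for(self, age: float, group: str) -> float:
        if group == "adult":
            return 0.0
        span = self.child_psts_mix_end_age - 3.0
        return float(self.child_psts_mix * max(0.0, (self.child_psts_mix_end_age - age) / span))

    def lag_for(self, age: float, group: str) -> int:
        if group == "adult" or age >= self.child_lag_max_age:
            return 0
        return self.child_lag_trs


@dataclass
class Geometry:
    shape: tuple
    affine: np.ndarray
    parcels: dict            # region -> Parcel
    wm: Parcel
    brain_mask: np.ndarray   # union of parcels

    @property
    def parcel_rows(self) -> dict:
        """region -> ascending linear voxel indices (row order convention)."""
        return {r: p.linear_indices for r, p in self.parcels.items()}


def default_geometry(grid_shape: tuple = (24, 24, 18),
                     voxel_mm: float = 2.0) -> Geometry:
    """Seven disjoint 6x6x6 parcels plus an 8x8x8 white-matter block on a
    2-mm grid, world origin at the grid center."""
    shape = tuple(grid_shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    slots = [(1, 1), (9, 1), (17, 1), (1, 9), (9, 9), (17, 9), (1, 17)]
    parcels = {}
    for region, (x0, y0) in zip(REGIONS, slots):
        m = np.zeros(shape, dtype=bool)
        m[x0:x0 + 6, y0:y0 + 6, 1:7] = True
        parcels[region] = Parcel(m, region)
    wm = np.zeros(shape, dtype=bool)
    wm[9:17, 17:min(25, shape[1]), 9:17] = True
    wm_parcel = Parcel(wm, "wm")
    brain = np.zeros(shape, dtype=bool)
    for p in parcels.values():
        brain |= p.mask
    overlap = sum(p.mask.astype(int) for p in parcels.values()) + wm_parcel.mask
    if overlap.max() > 1:
        raise ValueError("parcels/WM overlap; ground truth would be ambiguous")
    return Geometry(shape=shape, affine=affine, parcels=parcels,
                    wm=wm_parcel, brain_mask=brain)


def default_latent_corr() -> np.ndarray:
    """Inter-latent correlations: strong FFA-LOC coupling, within-domain
    coupling among scene regions, weak baseline coupling via EVC."""
    C = np.eye(7)
    idx = {r: i for i, r in enumerate(REGIONS)}

    def put(a, b, v):
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = v

    put("FFA", "pSTS", 0.40)
    put("FFA", "LOC", 0.60)
    put("pSTS", "LOC", 0.30)
    put("OPA", "PPA", 0.45)
    put("OPA", "RSC", 0.45)
    put("PPA", "RSC", 0.45)
    for r in ["FFA", "pSTS", "OPA", "PPA", "RSC", "LOC"]:
        put(r, "EVC", 0.20)
    for face in ["FFA", "pSTS"]:
        for scene in ["OPA", "PPA", "RSC"]:
            put(face, scene, 0.10)
    for scene in ["OPA", "PPA", "RSC"]:
        put("LOC", scene, 0.20)
    return C


# ---------------------------------------------------------------------------
# Latents & localizer timing
# ---------------------------------------------------------------------------

def _smooth_standardize(x: np.ndarray, fwhm_trs: float) -> np.ndarray:
    """Gaussian-smooth columns along time, then re-standardize each column."""
    if fwhm_trs > 0:
        x = gaussian_filter1d(x, sigma=fwhm_trs * _FWHM_TO_SIGMA,
                              axis=0, mode="nearest")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return x / sd


def make_latent_timecourses(
    T: int,
    labels: list[str],
    corr: np.ndarray,
    smooth_fwhm_trs: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, Timecourse]:
    """Correlated, temporally smoothed, standardized latent timecourses.

    White noise is smoothed with a Gaussian kernel (FWHM in TRs) to emulate
    hemodynamic autocorrelation, mixed through the Cholesky factor of
    ``corr`` so the sample correlation approaches ``corr`` as T grows, and
    re-standardized per series.
    """
    corr = np.asarray(corr, dtype=float)
    k = len(labels)
    if corr.shape != (k, k) or not np.allclose(corr, corr.T):
        raise ValueError("corr must be a symmetric matrix over the labels")
    eigs = np.linalg.eigvalsh(corr)
    if eigs.min() < -1e-10:
        raise ValueError("corr is not positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((T, k))
    smooth = _smooth_standardize(white, smooth_fwhm_trs)
    # PSD square root tolerates semi-definite corr (exact duplicates allowed)
    w, V = np.linalg.eigh(corr)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    mixed = _smooth_standardize(smooth @ L.T, 0.0)
    return {
        lab: Timecourse(mixed[:, j], z_scored=True, name=lab)
        for j, lab in enumerate(labels)
    }


def make_localizer_timing(
    n_blocks_per_cond: int = 4,
    block_s: float = 19.8,
    conditions: list[str] | None = None,
    seed: int | np.random.Generator = 0,
) -> BlockTiming:
    """Palindromic blocked localizer timing.

    With the defaults: two palindromes, each a random permutation of the
    four conditions followed by its mirror image (so the second half of
    each stimulus sequence reverses the first), and five fixation blocks —
    one at the start, three in the middle flanking the palindrome halves,
    one at the end. Total duration (16 + 5) x 19.8 s = 415.8 s.
    """
    if conditions is None:
        conditions = list(LOCALIZER_CONDITIONS)
    if not conditions:
        raise ValueError("need at least one condition")
    if n_blocks_per_cond % 2:
        raise ValueError("n_blocks_per_cond must be even (palindrome halves)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_palindromes = n_blocks_per_cond // 2
    order: list[str] = ["fixation"]
    for _ in range(n_palindromes):
        half = list(rng.permutation(conditions))
        order += half + ["fixation"] + half[::-1] + ["fixation"]
    # loop above appends a trailing fixation; structure is
    # F h1 F h1' F h2 F h2' F  -> 1 start + 3 middle + 1 end fixations
    rows = []
    t = 0.0
    for block in order:
        if block != "fixation":
            rows.append({"condition": block, "onset_s": round(t, 6),
                         "duration_s": block_s})
        t += block_s
    timing = BlockTiming(pd.DataFrame(rows).sort_values(
        ["condition", "onset_s"]).reset_index(drop=True))
    return timing


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthManifest:
    seed: int
    regions: dict            # region -> {selective_voxels, weight, preferred_condition}
    latent_corr: list
    latents: dict            # region -> list of floats (adult latents, T_movie)
    subjects: dict           # id -> {group, age, gain, psts_mix, lag_trs, seed,
                             #        artifact_trs_movie, artifact_trs_localizer}
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))

    def latent_array(self, region: str) -> np.ndarray:
        return np.asarray(self.latents[region], dtype=float)


@dataclass
class SubjectSim:
    """One simulated subject, reduced to the voxel sets analyses touch."""

    record: SubjectRecord
    movie_parcel_data: dict          # region -> (n_parcel_voxels, T) raw BOLD
    movie_wm_data: np.ndarray        # (n_wm_voxels, T)
    movie_motion: np.ndarray         # (T, 6)
    movie_artifact_trs: np.ndarray
    localizer_runs: list             # per run: dict(parcel_data, wm_data,
                                     #   motion, timing, artifact_trs)
    effective_latents: dict          # region -> (T,) latent this subject expressed
    movie_volume: np.ndarray | None = None      # full 4D, only when requested
    localizer_volumes: list | None = None


@dataclass
class CohortData:
    config: CohortConfig
    geometry: Geometry
    manifest: GroundTruthManifest
    subjects: dict                   # id -> SubjectSim

    def group_ids(self, group: str) -> list[str]:
        return [s for s, sim in self.subjects.items() if sim.record.group == group]


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

def _lag_series(x: np.ndarray, lag: int) -> np.ndarray:
    """Delay a series by ``lag`` TRs (response appears later); edge-hold."""
    if lag == 0:
        return x
    out = np.empty_like(x)
    out[lag:] = x[:-lag]
    out[:lag] = x[0]
    return out


def _draw_artifacts(T: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    return np.flatnonzero(rng.random(T) < rate)


def _motion_trace(T: int, artifact_trs: np.ndarray, cfg: CohortConfig,
                  rng: np.random.Generator) -> np.ndarray:
    m = np.empty((T, 6))
    m[:, :3] = rng.normal(0.0, cfg.background_motion_sd_mm, (T, 3))
    m[:, 3:] = rng.normal(0.0, cfg.background_motion_sd_mm / 65.0, (T, 3))
    # persistent translation steps, alternating sign: the composite motion
    # criterion fires exactly at the planted TRs
    sign = 1.0
    for t in artifact_trs:
        if t == 0:
            continue  # TR 0 has no motion predecessor; GS criterion covers it
        m[t:, 0] += sign * cfg.spike_mm
        sign = -sign
    return m


def _region_voxel_run(
    cfg: CohortConfig,
    geom: Geometry,
    truth_regions: dict,
    signals: dict,
    shared: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Assemble raw parcel voxel matrices for one run.

    ``signals[region]`` is the (T,) signal carried by that region's
    selective voxels at unit weight (movie latent or localizer evoked
    response, already gain-scaled).
    """
    T = shared.size
    data = {}
    for region, parcel in geom.parcels.items():
        lin = parcel.linear_indices
        n_vox = lin.size
        sel_mask = np.isin(lin, truth_regions[region]["selective_voxels"])
        w = np.where(sel_mask, truth_regions[region]["weight"], cfg.anti_weight)
        vox = np.outer(w, signals[region])
        vox += shared[None, :]
        vox += rng.normal(0.0, cfg.voxel_noise_sd, (n_vox, T))
        data[region] = vox
    return data


def _apply_gs_excursion(parcel_data: dict, wm_data: np.ndarray,
                        artifact_trs: np.ndarray, gain: float) -> None:
    """Add a global-signal excursion (in clean-GS SD units) at artifact TRs."""
    if artifact_trs.size == 0:
        return
    brain = np.vstack(list(parcel_data.values()))
    gs = brain.mean(axis=0)
    amp = gain * gs.std(ddof=1)
    sign = 1.0
    for t in artifact_trs:
        for mat in list(parcel_data.values()) + [wm_data]:
            mat[:, t] += sign * amp
        sign = -sign


def _wm_run(cfg: CohortConfig, geom: Geometry, shared: np.ndarray, T: int,
            rng: np.random.Generator) -> np.ndarray:
    n_wm = geom.wm.n_voxels
    comps = _smooth_standardize(rng.standard_normal((T, cfg.n_wm_components)),
                                cfg.smooth_fwhm_trs)
    loadings = rng.normal(0.0, 1.0, (n_wm, cfg.n_wm_components))
    wm = cfg.wm_component_sd * loadings @ comps.T
    wm += shared[None, :]
    wm += rng.normal(0.0, cfg.voxel_noise_sd, (n_wm, T))
    return wm


def simulate_subject(
    cfg: CohortConfig,
    geom: Geometry,
    truth_regions: dict,
    latents: dict,
    record: SubjectRecord,
    rng: np.random.Generator,
    keep_volumes: bool = False,
) -> SubjectSim:
    """Simulate one subject's movie run (and localizer runs for adults)."""
    T = cfg.T_movie
    group, age = record.group, record.age_years or 25.0
    gain = cfg.gain_for(age, group)
    mix = cfg.psts_mix_for(age, group)
    lag = cfg.lag_for(age, group)

    eff = {r: np.asarray(latents[r], dtype=float).copy() for r in REGIONS}
    if mix > 0 or lag > 0:
        psts = (1.0 - mix) * eff["pSTS"] + mix * eff["FFA"]
        psts = (psts - psts.mean()) / psts.std(ddof=1)
        eff["pSTS"] = _lag_series(psts, lag)
    signals = {r: gain * eff[r] for r in REGIONS}

    rate = (cfg.qc_fail_artifact_rate if record.subject_id in cfg.qc_fail_subjects
            else cfg.rate_for(group))
    art_movie = _draw_artifacts(T, rate, rng)
    motion = _motion_trace(T, art_movie, cfg, rng)
    shared = cfg.shared_noise_sd * _smooth_standardize(
        rng.standard_normal((T, 1)), cfg.smooth_fwhm_trs)[:, 0]
    parcel_data = _region_voxel_run(cfg, geom, truth_regions, signals, shared, rng)
    wm_data = _wm_run(cfg, geom, shared, T, rng)
    _apply_gs_excursion(parcel_data, wm_data, art_movie, cfg.gs_spike_gain)

    localizer_runs = []
    if group == "adult":
        for _ in range(cfg.n_localizer_runs):
            timing = make_localizer_timing(seed=rng)
            design = build_block_design(timing, cfg.T_localizer, cfg.tr_s)
            cols = {c: design.column(c) for c in LOCALIZER_CONDITIONS}
            loc_signals = {}
            for region in REGIONS:
                pref = truth_regions[region]["preferred_condition"]
                sig = np.zeros(cfg.T_localizer)
                for c in LOCALIZER_CONDITIONS:
                    amp = (cfg.localizer_amp_pref if c == pref
                           else cfg.localizer_amp_nonpref)
                    sig += amp * cols[c]
                loc_signals[region] = gain * sig
            art_loc = _draw_artifacts(cfg.T_localizer, rate, rng)
            motion_loc = _motion_trace(cfg.T_localizer, art_loc, cfg, rng)
            shared_loc = cfg.shared_noise_sd * _smooth_standardize(
                rng.standard_normal((cfg.T_localizer, 1)), cfg.smooth_fwhm_trs)[:, 0]
            # non-selective voxels respond weakly and non-preferentially
            base = cfg.localizer_amp_nonselective * sum(cols.values())
            pdata = {}
            for region, parcel in geom.parcels.items():
                lin = parcel.linear_indices
                sel = np.isin(lin, truth_regions[region]["selective_voxels"])
                vox = np.where(sel[:, None], loc_signals[region][None, :],
                               gain * base[None, :])
                vox = vox + shared_loc[None, :]
                vox = vox + rng.normal(0.0, cfg.voxel_noise_sd,
                                       (lin.size, cfg.T_localizer))
                pdata[region] = vox
            wm_loc = _wm_run(cfg, geom, shared_loc, cfg.T_localizer, rng)
            _apply_gs_excursion(pdata, wm_loc, art_loc, cfg.gs_spike_gain)
            localizer_runs.append({
                "parcel_data": pdata, "wm_data": wm_loc, "motion": motion_loc,
                "timing": timing, "artifact_trs": art_loc,
            })

    sim = SubjectSim(
        record=record,
        movie_parcel_data=parcel_data,
        movie_wm_data=wm_data,
        movie_motion=motion,
        movie_artifact_trs=art_movie,
        localizer_runs=localizer_runs,
        effective_latents={r: gain * eff[r] for r in REGIONS},
    )
    if keep_volumes:
        sim.movie_volume = _assemble_volume(geom, parcel_data, wm_data, T)
        sim.localizer_volumes = [
            _assemble_volume(geom, run["parcel_data"], run["wm_data"],
                             cfg.T_localizer)
            for run in localizer_runs
        ]
    return sim


def _assemble_volume(geom: Geometry, parcel_data: dict, wm_data: np.ndarray,
                     T: int) -> np.ndarray:
    vol = np.zeros(geom.shape + (T,), dtype=np.float32)
    flat = vol.reshape(-1, T)
    for region, parcel in geom.parcels.items():
        flat[parcel.linear_indices] = parcel_data[region]
    flat[geom.wm.linear_indices] = wm_data
    return vol


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(cfg: CohortConfig, seed: int = 0,
                    keep_volumes: bool = False) -> CohortData:
    """Simulate a full cohort in memory (reduced to parcel/WM matrices)."""
    geom = default_geometry(cfg.grid_shape, cfg.voxel_mm)
    corr = cfg.latent_corr if cfg.latent_corr is not None else default_latent_corr()
    n_subjects = sum(cfg.groups.values())
    rngs = _spawn_rngs(seed, n_subjects + 2)
    cohort_rng, latent_rng = rngs[0], rngs[1]
    subject_rngs = rngs[2:]

    latent_tcs = make_latent_timecourses(cfg.T_movie, REGIONS, np.asarray(corr),
                                         cfg.smooth_fwhm_trs, latent_rng)
    latents = {r: latent_tcs[r].values for r in REGIONS}

    truth_regions = {}
    for region, parcel in geom.parcels.items():
        lin = parcel.linear_indices
        n_sel = min(cfg.n_selective, lin.size)
        sel = np.sort(cohort_rng.choice(lin, size=n_sel, replace=False))
        truth_regions[region] = {
            "selective_voxels": [int(v) for v in sel],
            "weight": cfg.selectivity_weight,
            "preferred_condition": REGION_CONDITIONS[region],
        }

    subjects = {}
    manifest_subjects = {}
    i = 0
    for group, n in cfg.groups.items():
        lo, hi = cfg.group_age_ranges.get(group, (20.0, 40.0))
        for j in range(n):
            sid = f"sub-{group.replace('-', '')}{j + 1:02d}"
            age = float(np.round(cohort_rng.uniform(lo, hi), 2))
            record = SubjectRecord(subject_id=sid, group=group, age_years=age)
            sim = simulate_subject(cfg, geom, truth_regions, latents, record,
                                   subject_rngs[i], keep_volumes=keep_volumes)
            record.n_artifact_timepoints = int(sim.movie_artifact_trs.size)
            subjects[sid] = sim
            manifest_subjects[sid] = {
                "group": group, "age_years": age,
                "gain": cfg.gain_for(age, group),
                "psts_mix": cfg.psts_mix_for(age, group),
                "lag_trs": cfg.lag_for(age, group),
                "subject_index": i,
                "artifact_trs_movie": [int(t) for t in sim.movie_artifact_trs],
                "artifact_trs_localizer": [
                    [int(t) for t in run["artifact_trs"]]
                    for run in sim.localizer_runs
                ],
            }
            i += 1

    cfg_dict = {k: v for k, v in asdict(cfg).items() if k != "latent_corr"}
    cfg_dict["grid_shape"] = list(cfg.grid_shape)
    manifest = GroundTruthManifest(
        seed=seed,
        regions=truth_regions,
        latent_corr=np.asarray(corr).tolist(),
        latents={r: latents[r].tolist() for r in REGIONS},
        subjects=manifest_subjects,
        config=cfg_dict,
    )
    return CohortData(config=cfg, geometry=geom, manifest=manifest,
                      subjects=subjects)


def generate_cohort(cfg: CohortConfig, out_dir: str | Path,
                    seed: int = 0) -> GroundTruthManifest:
    """Simulate a cohort and write the full dataset layout to disk.

    Layout: one directory per subject (``func_movie.nii.gz``,
    ``func_localizer_run<i>.nii.gz`` for adults, per-run motion and timing
    TSVs), cohort-level ``parcels/``, ``wm_masks/``, ``participants.tsv``
    and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = DatasetLayout(out)
    cohort = simulate_cohort(cfg, seed=seed, keep_volumes=True)
    geom = cohort.geometry

    layout.parcels_dir.mkdir(exist_ok=True)
    layout.wm_masks_dir.mkdir(exist_ok=True)
    for region, parcel in geom.parcels.items():
        dataset_io.write_mask(parcel, geom.affine,
                              layout.parcels_dir / f"{region}.nii.gz")
    dataset_io.write_mask(geom.wm, geom.affine, layout.wm_masks_dir / "wm.nii.gz")

    records = []
    for sid, sim in cohort.subjects.items():
        sdir = layout.subject_dir(sid)
        sdir.mkdir(exist_ok=True)
        run = BoldRun(sim.movie_volume.astype(np.float64), cfg.tr_s, geom.affine,
                      subject_id=sid, run_label="movie")
        dataset_io.write_bold(run, layout.func_path(sid, "movie"))
        dataset_io.write_motion(sim.movie_motion, layout.motion_path(sid, "movie"))
        for r, vol in enumerate(sim.localizer_volumes or []):
            label = f"localizer_run{r + 1}"
            dataset_io.write_bold(
                BoldRun(vol.astype(np.float64), cfg.tr_s, geom.affine,
                        subject_id=sid, run_label=label),
                layout.func_path(sid, label))
            dataset_io.write_motion(sim.localizer_runs[r]["motion"],
                                    layout.motion_path(sid, label))
            dataset_io.write_timing(sim.localizer_runs[r]["timing"],
                                    layout.timing_path(sid, label))
        sim.movie_volume = None
        sim.localizer_volumes = None
        records.append(sim.record)
    dataset_io.write_participants(records, layout.participants_path)
    cohort.manifest.to_json(layout.manifest_path)
    return cohort.manifest
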