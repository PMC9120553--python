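"""End-to-end orchestration: simulate → preprocess → define ROIs → analyze.

`analyze_cohort` runs the whole analysis on an in-memory synthetic cohort
(or one loaded from disk): per-subject preprocessing and QC, adult
traditional/counter ROI definition from the localizer, leave-one-out
predictor sets, movie-ssROI definition, split-half spliced timecourses,
reverse-correlation events, and the child-adult inter-regional correlation
table (plain, partial and lag-shifted variants). `run_pipeline` is the
file-based entry point behind the CLI: it writes every artifact plus a JSON
manifest and is bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset_io
from .dataset_io import DatasetLayout, Parcel, SubjectRecord
from .glm import build_block_design, condition_tstats
from .preprocess import (ArtifactMask, build_nuisance_set, clean_voxel_timecourses,
                         compute_compcor, detect_artifact_timepoints, erode_mask,
                         roi_mean_timecourse, subject_passes_qc)
from .revcorr import GroupTimecourses, detect_events, event_response, spearman_partial, znormalize
from .roi_define import (REGION_CONTRASTS, REGIONS, TRADITIONAL_CONTRASTS,
                         SsROI, build_predictor_set, define_movie_ssroi,
                         split_half_define_extract, top_k_voxels)
from .glm import ContrastSpec, fit_contrast_tmap
from .interregional import (correlate_to_targets, fisher_z, loo_group_mean,
                            paired_t, partial_correlation, pearson_pairwise,
                            shift_timecourse)
from .synthio import (CohortConfig, CohortData, Geometry, SubjectSim,
                      LOCALIZER_CONDITIONS, simulate_cohort)
from .timecourse import Timecourse, masked_mean

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "RunConfig", "preprocess_run", "analyze_cohort",
           "run_pipeline", "CohortResults", "load_cohort_from_disk"]


@dataclass
class PipelineParams:
    """Stage parameters; defaults are the study's values."""

    motion_mm: float = 2.0
    gs_sd: float = 3.0
    highpass_s: float = 100.0
    n_compcor: int = 5
    wm_erosion: int = 2
    k: int = 100
    split_tr: int = 82
    guard_trs: int = 3
    alpha: float = 0.05
    shift_trs: int = -1


@dataclass
class RunConfig:
    dataset: str
    out_dir: str
    seed: int = 0
    simulate: bool = False
    params: PipelineParams = field(default_factory=PipelineParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)


# ---------------------------------------------------------------------------
# Preprocessing bridge
# ---------------------------------------------------------------------------

def preprocess_run(
    parcel_data: dict[str, np.ndarray],
    wm_data: np.ndarray,
    motion: np.ndarray,
    wm_eroded_rows: np.ndarray,
    tr_s: float,
    params: PipelineParams,
) -> tuple[dict[str, np.ndarray], ArtifactMask]:
    """Full cleaning of one run's parcel voxel matrices.

    Global signal is the mean over all parcel voxels (the union of parcels
    is the brain mask). Returns cleaned matrices (no NaNs; artifact TRs are
    interpolated and spike-regressed) plus the artifact mask for downstream
    NaN-ing.
    """
    brain = np.vstack([parcel_data[r] for r in parcel_data])
    gs = brain.mean(axis=0)
    mask = detect_artifact_timepoints(motion, gs, motion_mm=params.motion_mm,
                                      gs_sd=params.gs_sd)
    comps, degen = compute_compcor(wm_data[wm_eroded_rows], mask,
                                   n_components=params.n_compcor)
    nuisance = build_nuisance_set(mask, comps, degen)
    cleaned = {}
    order = list(parcel_data)
    all_clean = clean_voxel_timecourses(brain, mask, nuisance, tr_s,
                                        cutoff_s=params.highpass_s)
    row = 0
    for r in order:
        n = parcel_data[r].shape[0]
        cleaned[r] = all_clean[row:row + n]
        row += n
    return cleaned, mask


def _wm_eroded_rows(geom: Geometry, iterations: int) -> np.ndarray:
    eroded = erode_mask(geom.wm, iterations)
    return np.flatnonzero(np.isin(geom.wm.linear_indices, eroded.linear_indices))


def _nan_artifacts(mat: np.ndarray, mask: ArtifactMask) -> np.ndarray:
    out = mat.copy()
    out[:, mask.flags] = np.nan
    return out


def _parcel_rows(parcel: Parcel, roi: SsROI) -> np.ndarray:
    rowmap = {int(v): i for i, v in enumerate(parcel.linear_indices)}
    return np.array([rowmap[int(v)] for v in roi.voxels])


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------

@dataclass
class SubjectAnalysis:
    record: SubjectRecord
    movie_cleaned: dict
    movie_mask: ArtifactMask
    traditional_rois: dict | None = None
    counter_rois: dict | None = None
    movie_rois: dict | None = None
    roi_movie_tcs: dict | None = None      # 14 named tcs (regions + counters)
    spliced: dict | None = None            # region -> Timecourse (165 TRs)
    kept_trs: np.ndarray | None = None
    selectivity: pd.DataFrame | None = None


@dataclass
class CohortResults:
    qc: pd.DataFrame
    subjects: dict                         # id -> SubjectAnalysis (QC-passed)
    dropped: list
    targets: dict | None = None            # region -> adult traditional mean tc
    child_table: pd.DataFrame | None = None
    events: dict | None = None             # region -> adult EventSet
    event_responses: pd.DataFrame | None = None
    selectivity: pd.DataFrame | None = None
    kept_trs: np.ndarray | None = None


def _analyze_adult(sim: SubjectSim, geom: Geometry, params: PipelineParams,
                   wm_rows: np.ndarray, tr_s: float) -> SubjectAnalysis:
    movie_cleaned, movie_mask = preprocess_run(
        sim.movie_parcel_data, sim.movie_wm_data, sim.movie_motion,
        wm_rows, tr_s, params)
    ana = SubjectAnalysis(record=sim.record, movie_cleaned=movie_cleaned,
                          movie_mask=movie_mask)
    if not sim.localizer_runs:
        return ana
    loc = []
    for run in sim.localizer_runs:
        cleaned, mask = preprocess_run(run["parcel_data"], run["wm_data"],
                                       run["motion"], wm_rows, tr_s, params)
        T = next(iter(cleaned.values())).shape[1]
        design = build_block_design(run["timing"], T, tr_s)
        loc.append({"cleaned": cleaned, "mask": mask, "design": design})
    # traditional + counter ROIs from localizer run 1
    traditional, counter = {}, {}
    for region in REGIONS:
        parcel = geom.parcels[region]
        pos, neg = TRADITIONAL_CONTRASTS[region]
        data = _nan_artifacts(loc[0]["cleaned"][region], loc[0]["mask"])
        tmap = fit_contrast_tmap(data, loc[0]["design"],
                                 ContrastSpec({pos: 1.0, neg: -1.0}),
                                 voxel_indices=parcel.linear_indices)
        traditional[region] = top_k_voxels(tmap, parcel, k=params.k, tail="top",
                                           method="traditional", label=region)
        counter[region] = top_k_voxels(tmap, parcel, k=params.k, tail="bottom",
                                       method="counter", label=region)
    ana.traditional_rois, ana.counter_rois = traditional, counter
    # movie timecourses of traditional + counter ROIs (the predictor bank)
    tcs = {}
    for region in REGIONS:
        parcel = geom.parcels[region]
        tcs[region] = roi_mean_timecourse(
            movie_cleaned[region], _parcel_rows(parcel, traditional[region]),
            movie_mask, tr_s, name=region)
        tcs[f"{region}_counter"] = roi_mean_timecourse(
            movie_cleaned[region], _parcel_rows(parcel, counter[region]),
            movie_mask, tr_s, name=f"{region}_counter")
    ana.roi_movie_tcs = tcs
    ana._localizer = loc  # stashed for the selectivity read-out
    return ana


def _movie_and_split(ana: SubjectAnalysis, predictors, geom: Geometry,
                     params: PipelineParams, tr_s: float) -> None:
    ana.predictors_used = predictors
    ana.movie_rois = {
        region: define_movie_ssroi(ana.movie_cleaned[region], predictors,
                                   geom.parcels[region], region,
                                   k=params.k)
        for region in REGIONS
    }
    split = split_half_define_extract(
        ana.movie_cleaned, predictors, geom.parcels, k=params.k,
        split_tr=params.split_tr, guard_trs=params.guard_trs,
        artifact_mask=ana.movie_mask, tr_s=tr_s)
    ana.spliced = split.spliced
    ana.kept_trs = split.kept_trs


def _selectivity_rows(ana: SubjectAnalysis, geom: Geometry,
                      params: PipelineParams, tr_s: float) -> list[dict]:
    """Condition t statistics on localizer run 2 per ROI definition method."""
    loc = ana._localizer
    run = loc[1] if len(loc) > 1 else loc[0]
    rows = []
    for region in REGIONS:
        parcel = geom.parcels[region]
        pos, neg = TRADITIONAL_CONTRASTS[region]
        rois = {
            "group": np.arange(parcel.n_voxels),
            "movie": _parcel_rows(parcel, ana.movie_rois[region]),
            "traditional": _parcel_rows(parcel, ana.traditional_rois[region]),
        }
        for method, roi_rows in rois.items():
            tc = roi_mean_timecourse(run["cleaned"][region], roi_rows,
                                     run["mask"], tr_s)
            ts = condition_tstats(tc.values, run["design"], LOCALIZER_CONDITIONS)
            rows.append({
                "subject_id": ana.record.subject_id, "region": region,
                "roi_method": method,
                **{f"t_{c}": ts[c] for c in LOCALIZER_CONDITIONS},
                "selectivity": ts[pos] - ts[neg],
            })
    return rows


def analyze_cohort(cohort: CohortData, params: PipelineParams | None = None,
                   ) -> CohortResults:
    """Run the complete analysis over an in-memory cohort."""
    params = params or PipelineParams()
    geom = cohort.geometry
    tr_s = cohort.config.tr_s
    wm_rows = _wm_eroded_rows(geom, params.wm_erosion)

    qc_rows, analyses, dropped = [], {}, []
    for sid, sim in cohort.subjects.items():
        if sim.record.group == "adult":
            ana = _analyze_adult(sim, geom, params, wm_rows, tr_s)
        else:
            cleaned, mask = preprocess_run(sim.movie_parcel_data,
                                           sim.movie_wm_data, sim.movie_motion,
                                           wm_rows, tr_s, params)
            ana = SubjectAnalysis(record=sim.record, movie_cleaned=cleaned,
                                  movie_mask=mask)
        passed = subject_passes_qc(ana.movie_mask)
        sim.record.n_artifact_timepoints = ana.movie_mask.n_flagged
        qc_rows.append({"subject_id": sid, "group": sim.record.group,
                        "age_years": sim.record.age_years,
                        "n_artifacts": ana.movie_mask.n_flagged,
                        "passed": passed})
        if passed:
            analyses[sid] = ana
        else:
            dropped.append(sid)
            logger.warning("W-QC-DROP subject %s: %d/%d artifact TRs", sid,
                           ana.movie_mask.n_flagged, ana.movie_mask.n_trs)
    qc = pd.DataFrame(qc_rows)

    adults = [s for s, a in analyses.items() if a.record.group == "adult"]
    adult_tcs = {s: analyses[s].roi_movie_tcs for s in adults
                 if analyses[s].roi_movie_tcs is not None}

    # adults: leave-one-out predictors; children: all-adult predictors
    for sid in adults:
        predictors = build_predictor_set(adult_tcs, leave_out_id=sid)
        _movie_and_split(analyses[sid], predictors, geom, params, tr_s)
    child_predictors = build_predictor_set(adult_tcs) if adult_tcs else None
    children = [s for s, a in analyses.items() if a.record.group != "adult"]
    for sid in children:
        _movie_and_split(analyses[sid], child_predictors, geom, params, tr_s)

    kept = next(iter(analyses.values())).kept_trs if analyses else None

    # selectivity read-out (adults with localizer runs)
    sel_rows = []
    for sid in adults:
        if getattr(analyses[sid], "_localizer", None):
            sel_rows += _selectivity_rows(analyses[sid], geom, params, tr_s)
    selectivity = pd.DataFrame(sel_rows) if sel_rows else None

    # target bank: adult traditional-ROI movie mean timecourses on kept TRs
    targets = None
    if adult_tcs and kept is not None:
        full = build_predictor_set(adult_tcs).predictors
        targets = {r: Timecourse(full[r].values[kept], tr_s=tr_s, name=r)
                   for r in REGIONS}

    # child-adult inter-regional correlation long table
    child_rows = []
    if targets is not None:
        for sid, ana in analyses.items():
            for region in REGIONS:
                tc = ana.spliced[region]
                prof = correlate_to_targets(tc, targets, source=sid)
                shifted = shift_timecourse(tc, params.shift_trs)
                for tgt in REGIONS:
                    e = prof.entries[tgt]
                    child_rows.append({
                        "subject_id": sid, "group": ana.record.group,
                        "age_years": ana.record.age_years, "region": region,
                        "target": tgt, "variant": "plain", "r": e["r"],
                        "z": e["z"], "n_pairs": e["n_pairs"]})
                others = {t: targets[t] for t in REGIONS if t != region}
                try:
                    pr = partial_correlation(tc, targets[region], others)
                except ValueError:
                    pr = float("nan")
                child_rows.append({
                    "subject_id": sid, "group": ana.record.group,
                    "age_years": ana.record.age_years, "region": region,
                    "target": region, "variant": "partial", "r": pr,
                    "z": float(fisher_z(pr)) if np.isfinite(pr) else float("nan"),
                    "n_pairs": tc.n_valid})
                r_sh, n_sh = pearson_pairwise(shifted.values,
                                              targets[region].values)
                child_rows.append({
                    "subject_id": sid, "group": ana.record.group,
                    "age_years": ana.record.age_years, "region": region,
                    "target": region, "variant": f"shift{params.shift_trs}",
                    "r": r_sh, "z": float(fisher_z(r_sh)) if np.isfinite(r_sh)
                    else float("nan"), "n_pairs": n_sh})
    child_table = pd.DataFrame(child_rows) if child_rows else None

    # reverse correlation: adult events per region, responses in everyone
    events, resp_rows = None, []
    if adults:
        events = {}
        for region in REGIONS:
            group_tcs = {s: analyses[s].spliced[region] for s in adults}
            gt = GroupTimecourses.from_timecourses(group_tcs, group="adult",
                                                   region=region)
            events[region] = detect_events(gt, alpha=params.alpha)
        for sid, ana in analyses.items():
            for region in REGIONS:
                z = znormalize(ana.spliced[region])
                resp_rows.append({
                    "subject_id": sid, "group": ana.record.group,
                    "age_years": ana.record.age_years, "region": region,
                    "n_artifacts": ana.movie_mask.n_flagged,
                    "event_response": event_response(z, events[region]),
                })
    event_responses = pd.DataFrame(resp_rows) if resp_rows else None

    return CohortResults(qc=qc, subjects=analyses, dropped=dropped,
                         targets=targets, child_table=child_table,
                         events=events, event_responses=event_responses,
                         selectivity=selectivity, kept_trs=kept)


# ---------------------------------------------------------------------------
# Derived group statistics
# ---------------------------------------------------------------------------

def selectivity_contrast(results: CohortResults, method_a: str,
                         method_b: str) -> pd.DataFrame:
    """Per-region paired comparison of ROI-method selectivity across adults."""
    sel = results.selectivity
    rows = []
    for region in REGIONS:
        sub = sel[sel.region == region].pivot(index="subject_id",
                                              columns="roi_method",
                                              values="selectivity")
        res = paired_t(sub[method_a].to_numpy(), sub[method_b].to_numpy())
        rows.append({"region": region, "mean_diff":
                     float((sub[method_a] - sub[method_b]).mean()),
                     "t": res.t, "df": res.df, "p": res.p,
                     "p_one_sided": res.p / 2 if res.t > 0 else 1 - res.p / 2,
                     "d": res.cohen_d})
    return pd.DataFrame(rows)


def group_specificity(results: CohortResults, region: str,
                      group: str) -> tuple[float, float]:
    """Fraction of a group's subjects whose region timecourse correlates more
    with its own target than with the mean of the other targets; returns
    (fraction, mean advantage in Fisher z)."""
    tab = results.child_table
    sub = tab[(tab.group == group) & (tab.region == region)
              & (tab.variant == "plain")]
    wins, advs = [], []
    for sid, grp in sub.groupby("subject_id"):
        own = grp[grp.target == region]["z"].iloc[0]
        other = grp[grp.target != region]["z"].mean()
        wins.append(own > other)
        advs.append(own - other)
    return float(np.mean(wins)), float(np.mean(advs))


def age_specific_prediction(results: CohortResults, region: str,
                            young_group: str = "3yo",
                            old_group: str = "8-12yo"):
    """Self-group versus adult-group prediction of spliced timecourses.

    For each child in ``young_group``: correlation to the leave-one-out
    young-group mean versus to the adult movie-ssROI group mean (the child
    is never part of a mean it is compared against). Returns paired t
    results for the young group (self minus adult) and the old group.
    """
    analyses = results.subjects
    adults = {s: a.spliced[region] for s, a in analyses.items()
              if a.record.group == "adult"}
    young = {s: a.spliced[region] for s, a in analyses.items()
             if a.record.group == young_group}

    def _plain_mean(tcs: dict) -> Timecourse:
        m = masked_mean(np.vstack([tc.values for tc in tcs.values()]))
        return Timecourse(m, tr_s=next(iter(tcs.values())).tr_s)

    adult_mean = _plain_mean(adults)
    young_mean = _plain_mean(young)
    out = {}
    for grp_name in (young_group, old_group):
        members = {s: a.spliced[region] for s, a in analyses.items()
                   if a.record.group == grp_name}
        r_self, r_adult = [], []
        for sid, tc in members.items():
            # the child's own data never enter a mean it is compared against
            ref_young = (loo_group_mean(young, exclude_id=sid)
                         if sid in young else young_mean)
            r_self.append(fisher_z(pearson_pairwise(tc.values, ref_young.values)[0]))
            r_adult.append(fisher_z(pearson_pairwise(tc.values, adult_mean.values)[0]))
        out[grp_name] = paired_t(np.array(r_self), np.array(r_adult))
    return out


def shift_advantage(results: CohortResults, region: str, group: str,
                    shift_label: str = "shift-1") -> tuple[float, object]:
    """Mean Fisher-z advantage of the shifted over the plain correlation to
    the region's own target, plus the paired t result."""
    tab = results.child_table
    sub = tab[(tab.group == group) & (tab.region == region)
              & (tab.target == region)]
    plain = sub[sub.variant == "plain"].set_index("subject_id")["z"]
    shifted = sub[sub.variant == shift_label].set_index("subject_id")["z"]
    common = plain.index.intersection(shifted.index)
    res = paired_t(shifted[common].to_numpy(), plain[common].to_numpy())
    return float((shifted[common] - plain[common]).mean()), res


def event_response_age_trend(results: CohortResults, region: str,
                             groups: list[str] | None = None):
    """Spearman partial correlation of event response with age, controlling
    for head motion, over child subjects."""
    tab = results.event_responses
    sub = tab[tab.region == region]
    if groups is not None:
        sub = sub[sub.group.isin(groups)]
    else:
        sub = sub[sub.group != "adult"]
    return spearman_partial(sub["age_years"].to_numpy(),
                            sub["event_response"].to_numpy(),
                            sub["n_artifacts"].to_numpy())


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def load_cohort_from_disk(dataset_dir: str | Path,
                          cfg: CohortConfig | None = None) -> CohortData:
    """Rebuild an in-memory cohort view from a generated dataset directory."""
    cfg = cfg or CohortConfig()
    layout = DatasetLayout(dataset_dir)
    from .synthio import GroundTruthManifest, default_geometry
    geom_shape = cfg.grid_shape
    manifest = None
    if layout.manifest_path.exists():
        manifest = GroundTruthManifest.from_json(layout.manifest_path)
        geom_shape = tuple(manifest.config.get("grid_shape", geom_shape))
    geom = default_geometry(geom_shape, cfg.voxel_mm)
    # masks on disk are authoritative
    for region in list(geom.parcels):
        p = layout.parcels_dir / f"{region}.nii.gz"
        if p.exists():
            geom.parcels[region] = dataset_io.read_mask(p, region)
    wm_path = layout.wm_masks_dir / "wm.nii.gz"
    if wm_path.exists():
        geom.wm = dataset_io.read_mask(wm_path, "wm")

    records = dataset_io.read_participants(layout.participants_path)
    subjects = {}
    for rec in records:
        sid = rec.subject_id
        movie = dataset_io.read_bold(layout.func_path(sid, "movie"), tr_s=cfg.tr_s,
                                     subject_id=sid, run_label="movie")
        flat = movie.data.reshape(-1, movie.n_trs)
        parcel_data = {r: flat[p.linear_indices].astype(float)
                       for r, p in geom.parcels.items()}
        wm_data = flat[geom.wm.linear_indices].astype(float)
        motion = dataset_io.read_motion(layout.motion_path(sid, "movie"))
        loc_runs = []
        r_i = 1
        while layout.func_path(sid, f"localizer_run{r_i}").exists():
            label = f"localizer_run{r_i}"
            loc = dataset_io.read_bold(layout.func_path(sid, label), tr_s=cfg.tr_s,
                                       subject_id=sid, run_label=label)
            lflat = loc.data.reshape(-1, loc.n_trs)
            loc_runs.append({
                "parcel_data": {r: lflat[p.linear_indices].astype(float)
                                for r, p in geom.parcels.items()},
                "wm_data": lflat[geom.wm.linear_indices].astype(float),
                "motion": dataset_io.read_motion(layout.motion_path(sid, label)),
                "timing": dataset_io.read_timing(layout.timing_path(sid, label)),
                "artifact_trs": np.array([], dtype=int),
            })
            r_i += 1
        subjects[sid] = SubjectSim(
            record=rec, movie_parcel_data=parcel_data, movie_wm_data=wm_data,
            movie_motion=motion, movie_artifact_trs=np.array([], dtype=int),
            localizer_runs=loc_runs, effective_latents={},
        )
    return CohortData(config=cfg, geometry=geom, manifest=manifest,
                      subjects=subjects)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    manifest: dict = {"seed": config.seed, "dataset": str(config.dataset),
                      "params": asdict(config.params), "outputs": outputs,
                      "incomplete": False}
    try:
        if config.simulate:
            from .synthio import generate_cohort
            generate_cohort(config.cohort, config.dataset, seed=config.seed)
        cohort = load_cohort_from_disk(config.dataset, config.cohort)
        results = analyze_cohort(cohort, config.params)

        def _write(name: str, writer) -> None:
            path = out / name
            writer(path)
            outputs.append(name)

        _write("qc.tsv", lambda p: results.qc.to_csv(p, sep="\t", index=False))
        if results.child_table is not None:
            _write("isc_long.tsv", lambda p: results.child_table.to_csv(
                p, sep="\t", index=False, float_format="%.10g"))
        if results.selectivity is not None:
            _write("selectivity.tsv", lambda p: results.selectivity.to_csv(
                p, sep="\t", index=False, float_format="%.10g"))
        if results.events is not None:
            _write("events.json", lambda p: dataset_io.write_events_json(
                list(results.events.values()), p))
        if results.event_responses is not None:
            _write("event_responses.tsv", lambda p: results.event_responses.to_csv(
                p, sep="\t", index=False, float_format="%.10g"))
        rois = []
        for sid, ana in results.subjects.items():
            for group_attr in ("traditional_rois", "counter_rois", "movie_rois"):
                d = getattr(ana, group_attr)
                if d:
                    for roi in d.values():
                        roi_copy = SsROI(label=f"{sid}:{roi.label}",
                                         method=roi.method, voxels=roi.voxels,
                                         k=roi.k, parcel_label=roi.parcel_label)
                        rois.append(roi_copy)
        if rois:
            _write("rois.json", lambda p: dataset_io.write_roi_json(rois, p))
        manifest["qc"] = {row["subject_id"]: bool(row["passed"])
                          for _, row in results.qc.iterrows()}
        manifest["dropped"] = results.dropped
        dataset_io.save_config({"seed": config.seed, "dataset": str(config.dataset),
                                **asdict(config.params)}, out / "resolved_config.yaml")
        outputs.append("resolved_config.yaml")
    except Exception:
        manifest["incomplete"] = True
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    outputs.append("run_manifest.json")
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
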