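"""Subject-specific ROI definition: traditional, counter, and movie ssROIs.

Three ways to pick voxels inside a group search-space parcel:

* **traditional** — rank parcel voxels by the localizer contrast t value
  (faces>objects for face regions, scenes>objects for scene regions,
  objects>scrambled for LOC, scrambled>objects for EVC) and keep the top k
  (group-constrained subject-specific selection, k = 100 by default).
* **counter** — the bottom k voxels of the same ranking (the least selective
  voxels); their movie timecourses serve as extra nuisance predictors.
* **movie** — regress each parcel voxel's movie timecourse on 14 predictors
  (7 region + 7 counter mean timecourses from other subjects' traditional
  ROIs, plus an intercept) and keep the top k voxels by the t value of a
  region-specific predictor contrast (e.g. movie FFA = FFA > LOC).

The split-half variant defines movie ssROIs on each half of the run and
extracts the *other* half's timecourse from them, splicing the two
independent halves into a full-run estimate (a 3-TR guard between halves is
dropped to limit temporal autocorrelation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import Parcel
from .glm import ContrastSpec, design_from_regressors, fit_contrast_tmap, TMap
from .preprocess import ArtifactMask, roi_mean_timecourse
from .timecourse import Timecourse, masked_mean

logger = logging.getLogger(__name__)

__all__ = [
    "SsROI",
    "PredictorSet",
    "REGION_CONTRASTS",
    "REGIONS",
    "top_k_voxels",
    "build_predictor_set",
    "define_movie_ssroi",
    "split_half_define_extract",
    "SplitHalfResult",
]

REGIONS = ["FFA", "pSTS", "OPA", "PPA", "RSC", "LOC", "EVC"]

#: Localizer contrast per region, (positive condition, negative condition):
#: faces>objects for face regions, scenes>objects for scene regions,
#: objects>scrambled for LOC, scrambled>objects for EVC.
TRADITIONAL_CONTRASTS: dict[str, tuple[str, str]] = {
    "FFA": ("faces", "objects"),
    "pSTS": ("faces", "objects"),
    "OPA": ("scenes", "objects"),
    "PPA": ("scenes", "objects"),
    "RSC": ("scenes", "objects"),
    "LOC": ("objects", "scrambled"),
    "EVC": ("scrambled", "objects"),
}

#: Movie-definition contrast per region: (positive predictor, negative
#: predictor). Chosen to approximate each region's localizer contrast.
REGION_CONTRASTS: dict[str, tuple[str, str]] = {
    "FFA": ("FFA", "LOC"),
    "pSTS": ("pSTS", "LOC"),
    "OPA": ("OPA", "LOC"),
    "PPA": ("PPA", "LOC"),
    "RSC": ("RSC", "LOC"),
    "LOC": ("LOC", "EVC"),
    "EVC": ("EVC", "LOC"),
}


@dataclass
class SsROI:
    """A labeled, ordered set of <= k voxels inside a parcel."""

    label: str
    method: str                 # traditional | counter | movie | movie_half_A | movie_half_B
    voxels: np.ndarray          # linear (C-order) grid indices, selection order
    k: int
    parcel_label: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size > self.k:
            raise ValueError("more voxels than requested k")
        if np.unique(self.voxels).size != self.voxels.size:
            raise ValueError("duplicate voxels in ROI")

    @property
    def n_voxels(self) -> int:
        return self.voxels.size


@dataclass
class PredictorSet:
    """The 14 named mean timecourses used as movie-regression predictors.

    Names are the 7 region labels plus ``<region>_counter``. ``source``
    records the leave-out provenance so leave-one-out hygiene can be
    asserted structurally.
    """

    predictors: dict[str, Timecourse]
    source: str = ""
    left_out: str | None = None
    contributors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(tc) for tc in self.predictors.values()}
        if len(lengths) > 1:
            raise ValueError("predictor timecourses have unequal lengths")

    @property
    def names(self) -> list[str]:
        return list(self.predictors)

    @property
    def n_trs(self) -> int:
        return len(next(iter(self.predictors.values())))

    def restricted(self, trs: np.ndarray) -> "PredictorSet":
        """Predictors restricted to a TR subset (for split-half definition)."""
        return PredictorSet(
            predictors={n: tc.with_values(tc.values[trs])
                        for n, tc in self.predictors.items()},
            source=self.source, left_out=self.left_out,
            contributors=list(self.contributors),
        )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def top_k_voxels(tmap: TMap, parcel: Parcel, k: int = 100,
                 tail: str = "top", method: str = "traditional",
                 label: str | None = None) -> SsROI:
    """Select the k most (or least) selective parcel voxels by t value.

    Ties are broken by ascending linear voxel index (deterministic). NaN t
    values are never selected; an all-NaN parcel is an error. A parcel
    smaller than k returns every rankable voxel with a warning.
    """
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    lin = parcel.linear_indices
    if tmap.voxel_indices is not None:
        order_map = {int(v): i for i, v in enumerate(tmap.voxel_indices)}
        rows = np.array([order_map[int(v)] for v in lin if int(v) in order_map])
        lin = np.array([v for v in lin if int(v) in order_map])
        t = tmap.values[rows]
    else:
        if tmap.values.size != lin.size:
            raise ValueError("t-map has no voxel indices and its length does "
                             "not match the parcel")
        t = tmap.values
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError(f"all t values NaN within parcel {parcel.label!r}")
    t, lin = t[finite], lin[finite]
    key = -t if tail == "top" else t
    order = np.lexsort((lin, key))      # primary: t direction, tie: low index
    chosen = lin[order[:k]]
    if lin.size < k:
        logger.warning("W-SMALL-PARCEL parcel %s has %d rankable voxels < k=%d",
                       parcel.label, lin.size, k)
    return SsROI(label=label or parcel.label, method=method,
                 voxels=chosen, k=k, parcel_label=parcel.label)


# ---------------------------------------------------------------------------
# Predictor construction
# ---------------------------------------------------------------------------

def build_predictor_set(
    subject_tcs: dict[str, dict[str, Timecourse]],
    leave_out_id: str | None = None,
) -> PredictorSet:
    """Mean predictor timecourses over subjects, excluding ``leave_out_id``.

    ``subject_tcs`` maps subject id -> {predictor name -> Timecourse}, where
    the names are region labels and ``<region>_counter`` entries. Means are
    per-TR over the subjects with data at that TR; a TR missing in every
    contributor stays missing.
    """
    contributors = [s for s in subject_tcs if s != leave_out_id]
    if not contributors:
        raise ValueError("no contributing subjects after leave-out")
    if leave_out_id is not None and leave_out_id not in subject_tcs:
        logger.warning("W-LOO-ABSENT leave-out id %r not among subjects", leave_out_id)
    names = list(next(iter(subject_tcs.values())))
    predictors = {}
    for name in names:
        stack = np.vstack([subject_tcs[s][name].values for s in contributors])
        mean = masked_mean(stack)
        tr_s = subject_tcs[contributors[0]][name].tr_s
        predictors[name] = Timecourse(mean, tr_s=tr_s, name=name)
    desc = (f"mean over {len(contributors)} subjects"
            + (f" excluding {leave_out_id}" if leave_out_id else ""))
    return PredictorSet(predictors=predictors, source=desc,
                        left_out=leave_out_id, contributors=contributors)


# ---------------------------------------------------------------------------
# Movie-based definition
# ---------------------------------------------------------------------------

def _movie_tmap(voxel_data: np.ndarray, predictors: PredictorSet,
                region: str, table: dict[str, tuple[str, str]],
                voxel_indices: np.ndarray | None) -> TMap:
    pos, neg = table[region]
    regs = {}
    for name, tc in predictors.predictors.items():
        v = tc.values
        if not np.all(np.isfinite(v)):
            # predictor gaps (all contributors missing) are rare; fill by
            # linear interpolation so the design stays complete
            idx = np.arange(v.size)
            good = np.isfinite(v)
            v = np.interp(idx, idx[good], v[good])
        regs[name] = v
    # deterministic column order (contrast columns first, then sorted names)
    # plus greedy collinearity pruning: redundant non-contrast predictors are
    # dropped with a warning, making the selection invariant to the order in
    # which predictors were supplied
    T = voxel_data.shape[1]
    ordered = [pos, neg] + sorted(n for n in regs if n not in (pos, neg))
    kept_names: list[str] = []
    cols = [np.ones(T)]
    for name in ordered:
        cand = np.column_stack(cols + [regs[name]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            cols.append(regs[name])
            kept_names.append(name)
        elif name in (pos, neg):
            raise ValueError(
                f"contrast predictor {name!r} is collinear with the intercept "
                "or the other contrast predictor")
        else:
            logger.warning("W-PREDICTOR-COLLINEAR predictor %s collinear with "
                           "retained predictors; dropped", name)
    design = design_from_regressors({n: regs[n] for n in kept_names})
    return fit_contrast_tmap(voxel_data, design,
                             ContrastSpec({pos: 1.0, neg: -1.0}),
                             voxel_indices=voxel_indices)


def define_movie_ssroi(
    voxel_data: np.ndarray,
    predictors: PredictorSet,
    parcel: Parcel,
    region: str,
    table: dict[str, tuple[str, str]] | None = None,
    k: int = 100,
    method: str = "movie",
) -> SsROI:
    """Movie ssROI: top-k parcel voxels by predictor-contrast t value.

    ``voxel_data`` is the cleaned movie voxel x T matrix for the parcel's
    voxels, rows ordered by ascending linear index (the parcel convention).
    """
    if table is None:
        table = REGION_CONTRASTS
    lin = parcel.linear_indices
    if voxel_data.shape[0] != lin.size:
        raise ValueError("voxel_data rows must match parcel voxel count")
    if predictors.n_trs != voxel_data.shape[1]:
        raise ValueError("predictor length differs from movie run length")
    tmap = _movie_tmap(voxel_data, predictors, region, table, lin)
    roi = top_k_voxels(tmap, parcel, k=k, tail="top", method=method, label=region)
    return roi


# ---------------------------------------------------------------------------
# Split-half define/extract/splice
# ---------------------------------------------------------------------------

@dataclass
class SplitHalfResult:
    spliced: dict[str, Timecourse]          # region -> 165-TR spliced timecourse
    rois_half_a: dict[str, SsROI]
    rois_half_b: dict[str, SsROI]
    kept_trs: np.ndarray                    # original TR indices of the splice


def split_half_define_extract(
    parcel_data: dict[str, np.ndarray],
    predictors: PredictorSet,
    parcels: dict[str, Parcel],
    table: dict[str, tuple[str, str]] | None = None,
    k: int = 100,
    split_tr: int = 82,
    guard_trs: int = 3,
    artifact_mask: ArtifactMask | None = None,
    tr_s: float = 2.0,
) -> SplitHalfResult:
    """Define movie ssROIs per half-run and extract the crossed timecourses.

    With the defaults on a 168-TR run: half A is TRs 1-82 (1-based), a 3-TR
    guard (TRs 83-85) is discarded, half B is TRs 86-168. ROIs defined on
    half A yield half B's timecourse and vice versa; the two extracted
    halves are concatenated into a 165-TR estimate of the full-run
    timecourse whose definition and measurement never share TRs.
    """
    if table is None:
        table = REGION_CONTRASTS
    T = next(iter(parcel_data.values())).shape[1]
    if predictors.n_trs != T:
        raise ValueError("predictors and movie data disagree on run length")
    if split_tr + guard_trs >= T:
        raise ValueError("run too short for the requested split and guard")
    half_a = np.arange(0, split_tr)
    half_b = np.arange(split_tr + guard_trs, T)
    kept = np.concatenate([half_a, half_b])
    pred_a = predictors.restricted(half_a)
    pred_b = predictors.restricted(half_b)
    spliced, rois_a, rois_b = {}, {}, {}
    for region, parcel in parcels.items():
        data = parcel_data[region]
        roi_a = define_movie_ssroi(data[:, half_a], pred_a, parcel, region,
                                   table, k, method="movie_half_A")
        roi_b = define_movie_ssroi(data[:, half_b], pred_b, parcel, region,
                                   table, k, method="movie_half_B")
        lin = parcel.linear_indices
        rowmap = {int(v): i for i, v in enumerate(lin)}
        rows_a = np.array([rowmap[int(v)] for v in roi_a.voxels])
        rows_b = np.array([rowmap[int(v)] for v in roi_b.voxels])
        # crossed extraction: half-A timecourse comes from half-B-defined
        # ROIs, half-B timecourse from half-A-defined ROIs
        tc_first = data[rows_b][:, half_a].mean(axis=0)
        tc_second = data[rows_a][:, half_b].mean(axis=0)
        values = np.concatenate([tc_first, tc_second])
        if artifact_mask is not None:
            values = values.copy()
            values[artifact_mask.flags[kept]] = np.nan
        spliced[region] = Timecourse(values, tr_s=tr_s, name=f"{region}_spliced")
        rois_a[region], rois_b[region] = roi_a, roi_b
    return SplitHalfResult(spliced=spliced, rois_half_a=rois_a,
                           rois_half_b=rois_b, kept_trs=kept)
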