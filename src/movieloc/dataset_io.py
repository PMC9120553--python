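"""On-disk artifacts and shared conventions: volumes, masks, timing, tables.

Formats: NIfTI-1 for 4D BOLD runs and 3D binary masks (via nibabel); TSV for
motion parameters, block timing, participants and timecourse tables; JSON for
ROI voxel lists and event intervals; YAML for pipeline configuration.

Conventions fixed here and relied on everywhere else:

* Voxel linear indices are 0-based, C-order (``np.ravel_multi_index`` /
  ``np.unravel_index`` defaults: the last axis varies fastest).
* TRs are 0-based internally; user-facing reports (events JSON, CLI output)
  use 1-based TR numbers.
* Missing values in TSV timecourse tables are rendered as the literal ``NA``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .timecourse import Timecourse

logger = logging.getLogger(__name__)

__all__ = [
    "BoldRun",
    "Parcel",
    "BlockTiming",
    "SubjectRecord",
    "read_bold",
    "write_bold",
    "read_mask",
    "write_mask",
    "make_sphere_parcel",
    "read_timing",
    "write_timing",
    "read_motion",
    "write_motion",
    "read_participants",
    "write_participants",
    "read_timecourse_table",
    "write_timecourse_table",
    "read_roi_json",
    "write_roi_json",
    "read_events_json",
    "write_events_json",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BoldRun:
    """One subject's 4D volume series plus TR and grid geometry."""

    data: np.ndarray          # (x, y, z, t)
    tr_s: float
    affine: np.ndarray        # 4x4 voxel-to-world map
    subject_id: str = ""
    run_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D BOLD data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("a BOLD run needs at least 2 volumes")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD input contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_trs(self) -> int:
        return self.data.shape[3]


@dataclass
class Parcel:
    """A binary search-space (or other) mask on the cohort's common grid."""

    mask: np.ndarray          # 3D boolean
    label: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("parcel mask must be 3D")
        if self.n_voxels < 1:
            raise ValueError(f"parcel {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def linear_indices(self) -> np.ndarray:
        """0-based C-order linear indices of the true voxels, ascending."""
        return np.flatnonzero(self.mask.ravel(order="C"))


@dataclass
class BlockTiming:
    """Block-design timing: rows of (condition, onset_s, duration_s)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"condition", "onset_s", "duration_s"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"timing table must have columns {sorted(required)}")
        t = self.table
        if (t["onset_s"] < 0).any():
            raise ValueError("onsets must be non-negative")
        if (t["duration_s"] <= 0).any():
            raise ValueError("durations must be positive")
        for _, grp in t.groupby("condition"):
            if not grp["onset_s"].is_monotonic_increasing:
                raise ValueError("onsets must be non-decreasing within condition")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def total_duration_s(self) -> float:
        return float((self.table["onset_s"] + self.table["duration_s"]).max())


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age_years: float | None = None
    n_artifact_timepoints: int | None = None


# ---------------------------------------------------------------------------
# NIfTI volumes and masks
# ---------------------------------------------------------------------------

def read_bold(
    path: str | Path,
    tr_s: float | None = None,
    subject_id: str = "",
    run_label: str = "",
) -> BoldRun:
    """Read a 4D NIfTI BOLD run.

    The TR is taken from the header's 4th zoom; a ``tr_s`` argument (from the
    pipeline config) overrides the header, with a logged warning when they
    disagree — pediatric datasets often carry wrong header TRs.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    except Exception as exc:  # pragma: no cover - nibabel error paths
        raise IOError(f"could not read NIfTI header of {path}") from exc
    if data.ndim != 4:
        raise ValueError(f"expected 4D BOLD in {path}, got {data.ndim}D")
    if tr_s is not None:
        if header_tr > 0 and not np.isclose(header_tr, tr_s):
            logger.warning(
                "W-TR-OVERRIDE %s: header TR %.3fs overridden by config TR %.3fs",
                path, header_tr, tr_s,
            )
        tr = tr_s
    elif header_tr > 0:
        tr = header_tr
    else:
        raise ValueError(f"{path}: header TR is {header_tr}; pass tr_s explicitly")
    return BoldRun(data=data.astype(np.float64), tr_s=tr, affine=img.affine,
                   subject_id=subject_id, run_label=run_label)


def write_bold(run: BoldRun, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), run.affine)
    zooms = list(img.header.get_zooms())
    zooms = zooms[:3] + [run.tr_s]
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(Path(path)))


def read_mask(path: str | Path, label: str | None = None) -> Parcel:
    img = nib.load(str(Path(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask in {path}, got {data.ndim}D")
    return Parcel(mask=data > 0, label=label or Path(path).name.split(".")[0])


def write_mask(parcel: Parcel, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(parcel.mask.astype(np.uint8), np.asarray(affine, float))
    nib.save(img, str(Path(path)))


def make_sphere_parcel(
    center_world: Sequence[float],
    radius_mm: float,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    label: str = "sphere",
) -> Parcel:
    """Spherical parcel: voxels whose world-space centers lie within radius.

    Used e.g. to build an early-visual-cortex search space as the union of
    10 mm spheres around bilateral peak coordinates.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]
    d2 = ((world - np.asarray(center_world, float)[:, None]) ** 2).sum(axis=0)
    mask = (d2 <= radius_mm ** 2).reshape(shape)
    if not mask.any():
        raise ValueError(
            f"sphere at {list(center_world)} r={radius_mm}mm contains no voxel centers"
        )
    return Parcel(mask=mask, label=label)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_timing(path: str | Path) -> BlockTiming:
    return BlockTiming(pd.read_csv(path, sep="\t"))


def write_timing(timing: BlockTiming, path: str | Path) -> None:
    timing.table.to_csv(path, sep="\t", index=False)


def read_motion(path: str | Path) -> np.ndarray:
    """Motion TSV: per-TR trans_x/y/z (mm) and rot_x/y/z (radians)."""
    df = pd.read_csv(path, sep="\t")
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    if not set(cols).issubset(df.columns):
        raise ValueError(f"motion table {path} must have columns {cols}")
    return df[cols].to_numpy(dtype=float)


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a (T, 6) array")
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(motion, columns=cols).to_csv(path, sep="\t", index=False,
                                              float_format="%.10g")


def read_participants(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        age = row.get("age_years")
        nart = row.get("n_artifact_timepoints")
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age_years=None if pd.isna(age) else float(age),
            n_artifact_timepoints=None if pd.isna(nart) else int(nart),
        ))
    return records


def write_participants(records: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "age_years": r.age_years,
            "n_artifact_timepoints": r.n_artifact_timepoints,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_timecourse_table(tcs: Mapping[str, Timecourse | np.ndarray],
                           path: str | Path) -> None:
    """TSV with one TR per row, one named column per timecourse, NaN → ``NA``.

    Round-trips losslessly (to float repr) with :func:`read_timecourse_table`.
    """
    arrays = {}
    length = None
    for name, tc in tcs.items():
        v = tc.values if isinstance(tc, Timecourse) else np.asarray(tc, float)
        if length is None:
            length = v.size
        elif v.size != length:
            raise ValueError(
                f"timecourse {name!r} has length {v.size}, expected {length}")
        arrays[name] = v
    df = pd.DataFrame(arrays)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_timecourse_table(path: str | Path, tr_s: float = 2.0) -> dict[str, Timecourse]:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except pd.errors.EmptyDataError:
        return {}
    return {
        str(c): Timecourse(df[c].to_numpy(dtype=float), tr_s=tr_s, name=str(c))
        for c in df.columns
    }


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def write_roi_json(rois: Sequence, path: str | Path) -> None:
    """Serialize SsROIs (duck-typed: label/method/voxels/k/parcel_label)."""
    payload = [
        {
            "label": r.label,
            "method": r.method,
            "voxels": [int(v) for v in r.voxels],
            "k": int(r.k),
            "parcel_label": r.parcel_label,
            "index_order": "C",
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_events_json(eventsets: Sequence, path: str | Path) -> None:
    """Event intervals as 1-based inclusive TR ranges plus second equivalents."""
    payload = []
    for es in eventsets:
        payload.append({
            "region": es.region,
            "group": es.group,
            "alpha": es.alpha,
            "intervals_tr_1based": [[int(a) + 1, int(b) + 1] for a, b in es.intervals],
            "intervals_s": [
                [round(a * es.tr_s, 3), round((b + 1) * es.tr_s, 3)]
                for a, b in es.intervals
            ],
        })
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Dataset layout
# ---------------------------------------------------------------------------

@dataclass
class DatasetLayout:
    """Paths within a cohort directory (one subdirectory per subject)."""

    root: Path

    def __init__(self, root: str | Path):
        self.root = Path(root)

    def subject_dir(self, subject_id: str) -> Path:
        return self.root / subject_id

    def func_path(self, subject_id: str, run: str) -> Path:
        return self.subject_dir(subject_id) / f"func_{run}.nii.gz"

    def motion_path(self, subject_id: str, run: str) -> Path:
        return self.subject_dir(subject_id) / f"motion_{run}.tsv"

    def timing_path(self, subject_id: str, run: str) -> Path:
        return self.subject_dir(subject_id) / f"timing_{run}.tsv"

    @property
    def participants_path(self) -> Path:
        return self.root / "participants.tsv"

    @property
    def parcels_dir(self) -> Path:
        return self.root / "parcels"

    @property
    def wm_masks_dir(self) -> Path:
        return self.root / "wm_masks"

    @property
    def manifest_path(self) -> Path:
        return self.root / "ground_truth.json"
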