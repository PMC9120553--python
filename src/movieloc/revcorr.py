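"""Reverse correlation: events that evoke reliable positive group responses.

Each subject's region timecourse is z-normalized; at every TR the group's
values are tested against baseline 0 with a one-tailed one-sample t-test
(H1: mean > 0). Events are maximal runs of >= 2 consecutive significant TRs
(a minimum of 4 s at TR = 2 s); single significant TRs are discarded as
unreliable. Downstream, each child's mean z-scored response over the
adult-defined event TRs indexes how strongly the adult events drive that
child, and its age trend is assessed with Spearman partial correlations
controlling for head motion (number of artifact timepoints).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .timecourse import Timecourse

logger = logging.getLogger(__name__)

__all__ = [
    "EventSet",
    "GroupTimecourses",
    "znormalize",
    "detect_events",
    "event_response",
    "spearman_partial",
]


@dataclass
class EventSet:
    """Ordered, non-overlapping TR intervals of reliable positive response.

    ``intervals`` are 0-based inclusive (start, end) pairs internally;
    serialization reports 1-based TR numbers.
    """

    region: str
    group: str
    intervals: list[tuple[int, int]]
    alpha: float = 0.05
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        prev_end = -1
        for a, b in self.intervals:
            if b - a + 1 < 2:
                raise ValueError("each event must span at least 2 TRs")
            if a <= prev_end:
                raise ValueError("event intervals must be sorted and disjoint")
            prev_end = b

    @property
    def n_events(self) -> int:
        return len(self.intervals)

    @property
    def event_trs(self) -> np.ndarray:
        """Union of all event TRs (0-based)."""
        if not self.intervals:
            return np.empty(0, dtype=int)
        return np.concatenate([np.arange(a, b + 1) for a, b in self.intervals])


@dataclass
class GroupTimecourses:
    """subject x TR matrix of z-scored region timecourses."""

    matrix: np.ndarray
    group: str = ""
    region: str = ""
    subject_ids: list[str] = field(default_factory=list)
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not self.subject_ids:
            self.subject_ids = [f"s{i:03d}" for i in range(self.matrix.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_trs(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_timecourses(cls, tcs: dict[str, Timecourse], group: str = "",
                         region: str = "") -> "GroupTimecourses":
        ids = list(tcs)
        mat = np.vstack([znormalize(tcs[s]).values for s in ids])
        tr_s = tcs[ids[0]].tr_s
        return cls(matrix=mat, group=group, region=region, subject_ids=ids, tr_s=tr_s)


def znormalize(tc: Timecourse | np.ndarray) -> Timecourse:
    """Standardize non-missing entries to mean 0, SD 1 (ddof=1); keep NaNs."""
    if isinstance(tc, Timecourse):
        values, tr_s, name = tc.values, tc.tr_s, tc.name
    else:
        values, tr_s, name = np.asarray(tc, dtype=float), 2.0, ""
    good = np.isfinite(values)
    if good.sum() < 2:
        raise ValueError("z-normalization needs at least 2 non-missing values")
    v = values[good]
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("z-normalization undefined for constant input")
    out = np.full_like(values, np.nan)
    out[good] = (v - v.mean()) / sd
    return Timecourse(out, tr_s=tr_s, z_scored=True, name=name)


def detect_events(group: GroupTimecourses, alpha: float = 0.05,
                  min_len: int = 2, min_subjects: int = 3) -> EventSet:
    """Events: maximal runs of >= ``min_len`` significantly positive TRs.

    A TR is significant iff the one-tailed one-sample t-test of the group's
    values against 0 (H1: mean > 0) gives p < alpha. TRs with fewer than
    ``min_subjects`` contributing subjects are defined non-significant (an
    empty EventSet is a legitimate outcome).
    """
    M = group.matrix
    n = np.isfinite(M).sum(axis=0)
    mean = np.where(n > 0, np.nansum(M, axis=0) / np.maximum(n, 1), 0.0)
    dev = np.where(np.isfinite(M), M - mean[None, :], 0.0)
    ss = (dev ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
    sd[n < 2] = np.nan
    sig = np.zeros(M.shape[1], dtype=bool)
    testable = (n >= max(min_subjects, 2)) & np.isfinite(sd) & (sd > 0)
    safe_sd = np.where(testable, sd, 1.0)
    t_stat = np.where(testable, mean / (safe_sd / np.sqrt(np.maximum(n, 1))), 0.0)
    p = np.where(testable, stats.t.sf(t_stat, np.maximum(n - 1, 1)), 1.0)
    sig[testable] = p[testable] < alpha
    intervals = []
    start = None
    for t in range(sig.size + 1):
        on = t < sig.size and sig[t]
        if on and start is None:
            start = t
        elif not on and start is not None:
            if t - start >= min_len:
                intervals.append((start, t - 1))
            start = None
    return EventSet(region=group.region, group=group.group,
                    intervals=intervals, alpha=alpha, tr_s=group.tr_s)


def event_response(tc: Timecourse, events: EventSet) -> float:
    """Mean z-scored response across all event TRs (NaN-aware).

    Returns NaN (with a warning) for an empty EventSet or when every event
    TR is missing in the timecourse.
    """
    if not tc.z_scored:
        raise ValueError("event_response expects a z-scored timecourse")
    trs = events.event_trs
    if trs.size == 0:
        logger.warning("W-EMPTY-EVENTSET no events for %s/%s",
                       events.region, events.group)
        return float("nan")
    vals = tc.values[trs]
    good = np.isfinite(vals)
    if not good.any():
        return float("nan")
    return float(vals[good].mean())


def spearman_partial(x: np.ndarray, y: np.ndarray,
                     covariate: np.ndarray) -> tuple[float, float]:
    """Spearman partial correlation of x and y given one covariate.

    All three vectors are midrank-transformed; the partial correlation is
    computed by the residual method (each ranked variable regressed on
    [intercept, ranked covariate], residuals correlated). p comes from the
    t approximation with n - 3 degrees of freedom (two-sided).
    """
    x = np.asarray(x, float); y = np.asarray(y, float)
    z = np.asarray(covariate, float)
    good = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[good], y[good], z[good]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete observations")
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    rz = stats.rankdata(z)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input after ranking")
    X = np.column_stack([np.ones(n), rz])
    coef_x, *_ = np.linalg.lstsq(X, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(X, ry, rcond=None)
    ex, ey = rx - X @ coef_x, ry - X @ coef_y
    # ranked series fully explained by the ranked covariate -> r = 0
    tol = 1e-16
    if (ex ** 2).sum() <= tol * ((rx - rx.mean()) ** 2).sum() or \
       (ey ** 2).sum() <= tol * ((ry - ry.mean()) ** 2).sum():
        return 0.0, 1.0
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float((ex * ey).sum() / denom)
    df = n - 3
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p
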