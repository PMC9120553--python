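"""Inter-regional correlation statistics on spliced movie-ssROI timecourses.

Each subject's movie-ssROI timecourse (built by the split-half splice) is
correlated against a bank of target timecourses — typically the mean
movie timecourses of traditionally defined adult ROIs. Pearson r values are
Fisher z transformed (atanh) for group statistics; partial correlations
isolate the signal unique to one target after regressing out all others;
lag-shifted variants test whether a group's response trails the targets in
time; leave-one-out group means support age-specific-function comparisons.
Missing TRs (artifact NaNs, which differ per subject) are handled
pairwise-complete, with the pair count reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .timecourse import Timecourse, masked_mean

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationProfile",
    "GroupTestResult",
    "fisher_z",
    "pearson_pairwise",
    "correlate_to_targets",
    "partial_correlation",
    "shift_timecourse",
    "loo_group_mean",
    "one_sample_t",
    "paired_t",
]

_R_CLIP = 1 - 1e-15


@dataclass
class CorrelationProfile:
    """Per-target correlation results for one source timecourse."""

    source: str
    entries: dict[str, dict]      # target -> {r, z, n_pairs, degenerate}

    def r(self, target: str) -> float:
        return self.entries[target]["r"]

    def z(self, target: str) -> float:
        return self.entries[target]["z"]


@dataclass
class GroupTestResult:
    test: str                     # one_sample_t | paired_t
    t: float
    df: int
    p: float
    cohen_d: float
    degenerate: bool = False


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing atanh transform, clipped away from ±1."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def pearson_pairwise(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Pearson r over pairwise-complete entries; returns (r, n_pairs)."""
    a = np.asarray(a, float); b = np.asarray(b, float)
    good = np.isfinite(a) & np.isfinite(b)
    n = int(good.sum())
    if n < 3:
        return float("nan"), n
    x, y = a[good], b[good]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan"), n
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return min(max(r, -1.0), 1.0), n


def correlate_to_targets(tc: Timecourse,
                         targets: dict[str, Timecourse],
                         source: str = "") -> CorrelationProfile:
    """Pearson r (and Fisher z) of a timecourse against each named target."""
    entries = {}
    for name, target in targets.items():
        r, n = pearson_pairwise(tc.values, target.values)
        if not np.isfinite(r):
            logger.warning("W-ISC-OVERLAP target %s: only %d complete pairs "
                           "(or zero variance); entry missing", name, n)
            entries[name] = {"r": float("nan"), "z": float("nan"),
                             "n_pairs": n, "degenerate": True}
            continue
        degenerate = abs(r) >= _R_CLIP
        if degenerate:
            logger.warning("W-ISC-CLIP r=%.17g vs target %s clipped before atanh",
                           r, name)
        entries[name] = {"r": r, "z": float(fisher_z(r)), "n_pairs": n,
                         "degenerate": degenerate}
    return CorrelationProfile(source=source, entries=entries)


def partial_correlation(tc: Timecourse, target: Timecourse,
                        others: dict[str, Timecourse]) -> float:
    """Correlation of tc and target after regressing both on the others.

    Both series are OLS-residualized on [intercept + other targets] over the
    TRs where every involved series is complete, then correlated. With no
    others this reduces to the plain Pearson r. Collinear columns among the
    others are absorbed by the pseudo-inverse (logged).
    """
    x = np.asarray(tc.values, float)
    y = np.asarray(target.values, float)
    O = [np.asarray(o.values, float) for o in others.values()]
    good = np.isfinite(x) & np.isfinite(y)
    for o in O:
        good &= np.isfinite(o)
    n = int(good.sum())
    if n < len(O) + 3:
        raise ValueError(
            f"only {n} complete TRs for a partial correlation on {len(O)} others")
    x, y = x[good], y[good]
    if not O:
        r, _ = pearson_pairwise(x, y)
        return r
    X = np.column_stack([np.ones(n)] + [o[good] for o in O])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("W-PARTIAL-COLLINEAR collinear covariates in partial "
                       "correlation; redundant directions dropped")
    P = X @ np.linalg.pinv(X)
    ex, ey = x - P @ x, y - P @ y
    # a series numerically inside span(others) has no unique variance left;
    # its partial correlation is 0 by convention (flagged)
    tol = 1e-16
    if (ex ** 2).sum() <= tol * ((x - x.mean()) ** 2).sum() or \
       (ey ** 2).sum() <= tol * ((y - y.mean()) ** 2).sum():
        logger.warning("W-PARTIAL-DEGENERATE a series is fully explained by "
                       "the covariates; partial r set to 0")
        return 0.0
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        return 0.0
    return float((ex * ey).sum() / denom)


def shift_timecourse(tc: Timecourse, shift_trs: int) -> Timecourse:
    """Shift a timecourse in time; vacated TRs become missing.

    ``shift_trs = -1`` moves the series one TR *earlier*: output TR t takes
    the input's value at TR t+1 (used to test whether a child's response
    trails the adult response by one TR). Positive shifts delay the series.
    Length is preserved.
    """
    T = len(tc)
    if abs(shift_trs) >= T:
        raise ValueError("shift magnitude must be smaller than the run length")
    out = np.full(T, np.nan)
    if shift_trs == 0:
        out[:] = tc.values
    elif shift_trs < 0:
        out[:shift_trs] = tc.values[-shift_trs:]
    else:
        out[shift_trs:] = tc.values[:-shift_trs]
    return tc.with_values(out, z_scored=False)


def loo_group_mean(tcs: dict[str, Timecourse], exclude_id: str) -> Timecourse:
    """Per-TR mean over the group's other subjects (missing-aware)."""
    if len(tcs) < 2:
        raise ValueError("leave-one-out mean needs at least 2 subjects")
    if exclude_id not in tcs:
        logger.warning("W-LOO-ABSENT %r not in group; plain mean returned",
                       exclude_id)
    keep = [s for s in tcs if s != exclude_id]
    mean = masked_mean(np.vstack([tcs[s].values for s in keep]))
    first = tcs[keep[0]]
    return Timecourse(mean, tr_s=first.tr_s, name=f"mean_excl_{exclude_id}")


def one_sample_t(values: np.ndarray, mu: float = 0.0) -> GroupTestResult:
    """Two-sided one-sample t-test with Cohen's d = mean / SD."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = v.std(ddof=1)
    diff = v.mean() - mu
    if sd == 0:
        logger.warning("W-DEGENERATE-T zero variance in one-sample t-test")
        return GroupTestResult("one_sample_t", t=0.0, df=n - 1, p=1.0,
                               cohen_d=0.0, degenerate=True)
    t = diff / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return GroupTestResult("one_sample_t", t=float(t), df=n - 1, p=p,
                           cohen_d=float(diff / sd))


def paired_t(a: np.ndarray, b: np.ndarray) -> GroupTestResult:
    """Two-sided paired t-test on complete pairs; d = mean diff / SD diff."""
    a = np.asarray(a, float); b = np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    good = np.isfinite(a) & np.isfinite(b)
    d = a[good] - b[good]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        logger.warning("W-DEGENERATE-T zero variance in paired t-test")
        return GroupTestResult("paired_t", t=0.0, df=n - 1, p=1.0,
                               cohen_d=0.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return GroupTestResult("paired_t", t=float(t), df=n - 1, p=p,
                           cohen_d=float(d.mean() / sd))
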